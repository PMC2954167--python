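"""Simulated stratified association study and its correction.

The scenario: a cohort containing two ancestry subpopulations; cases are
defined by the homozygous genotype at an ancestry-informative marker (AIM),
so case status is confounded with subpopulation membership. A genome-wide
additive association scan then shows inflated test statistics (genomic
inflation factor lambda above 1), and adjusting for the top principal-
component eigenvectors restores calibration.

Scans use the additive 1-df statistic: the Cochran-Armitage trend test
without covariates, or the Wald chi-square on the genotype term of a
logistic regression with eigenvector covariates. The per-SNP logistic fits
share their covariate block, so they are solved by a vectorized batch
Newton iteration with a score-test fallback when a fit separates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix
from .pca import pca_genotypes
from .structure_snps import prune_for_structure

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))   # 0.4549364...


@dataclass
class AssociationScan:
    """Per-SNP additive association statistics."""

    table: pd.DataFrame          # snp, stat, p, direction, flag
    method: str
    adjusted: bool
    covariate_spec: str = ""

    @property
    def statistics(self) -> np.ndarray:
        return self.table["stat"].to_numpy()


def select_cases_by_genotype(gm: GenotypeMatrix, aim: str,
                             case_genotype: str = "hom_a"):
    """Case/control labels from the genotype at one marker.

    Samples homozygous for allele A at ``aim`` are cases (1), all other
    genotyped samples are controls (0); samples missing at the AIM are
    excluded. Returns (labels Series indexed by sample id, excluded ids).
    """
    if case_genotype != "hom_a":
        raise ValueError("only hom_a case selection is supported")
    j = np.flatnonzero(gm.snp_ids == aim)
    if j.size == 0:
        raise ValueError(f"AIM {aim!r} not found")
    calls = gm.calls[:, j[0]]
    keep = calls != MISSING
    labels = pd.Series((calls[keep] == 2).astype(int),
                       index=pd.Index(gm.sample_ids[keep], name="sample"))
    excluded = list(gm.sample_ids[~keep])
    return labels, excluded


# ---------------------------------------------------------------------------
# additive association statistics
# ---------------------------------------------------------------------------

def trend_statistics(G: np.ndarray, y: np.ndarray):
    """Cochran-Armitage trend chi-square per SNP (scores 0/1/2).

    Equals N times the squared Pearson correlation between phenotype and
    genotype over non-missing samples; the score test of the additive
    logistic model. Returns (stat, direction) arrays.
    """
    Gf = G.astype(float)
    mask = (G != MISSING)
    y = np.asarray(y, dtype=float)
    n = mask.sum(axis=0).astype(float)
    sy = mask.T @ y
    sg = (Gf * mask).sum(axis=0)
    sgy = (Gf * mask).T @ y
    sgg = (Gf * Gf * mask).sum(axis=0)
    syy = mask.T @ (y * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sgy - sg * sy / n
        vg = sgg - sg ** 2 / n
        vy = syy - sy ** 2 / n
        stat = np.where((vg > 1e-12) & (vy > 1e-12),
                        n * cov ** 2 / (vg * vy), 0.0)
    return stat, np.sign(cov)


def _batch_logistic_wald(G: np.ndarray, y: np.ndarray, C: np.ndarray,
                         max_iter: int = 30, tol: float = 1e-8,
                         beta_cap: float = 15.0):
    """Wald chi-square on the genotype term of per-SNP logistic models.

    All SNPs share the covariate block ``C`` (with intercept); only the
    genotype column differs, so the Newton iterations are batched across
    SNPs. Missing genotypes get zero weight. SNPs whose fit diverges or
    separates fall back to the covariate-adjusted score test.
    """
    n, L = G.shape
    y = np.asarray(y, dtype=float)
    c = C.shape[1]
    p = c + 1
    Gf = np.where(G == MISSING, 0.0, G.astype(float))
    Mk = (G != MISSING).astype(float)
    beta = np.zeros((L, p))
    base = np.log(np.clip(y.mean(), 1e-6, 1 - 1e-6) /
                  (1 - np.clip(y.mean(), 1e-6, 1 - 1e-6)))
    beta[:, 0] = base
    converged = np.zeros(L, dtype=bool)
    for _ in range(max_iter):
        eta = C @ beta[:, :c].T + Gf * beta[:, c][None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1 - mu) * Mk
        resid = (y[:, None] - mu) * Mk
        grad = np.empty((L, p))
        grad[:, :c] = resid.T @ C
        grad[:, c] = (resid * Gf).sum(axis=0)
        H = np.empty((L, p, p))
        H[:, :c, :c] = np.einsum("nc,nl,nd->lcd", C, w, C)
        cg = np.einsum("nc,nl,nl->lc", C, w, Gf)
        H[:, :c, c] = cg
        H[:, c, :c] = cg
        H[:, c, c] = (w * Gf * Gf).sum(axis=0)
        H[:, np.arange(p), np.arange(p)] += 1e-9
        try:
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(H[l], grad[l], rcond=None)[0]
                             for l in range(L)])
        beta += step
        done = np.abs(step).max(axis=1) < tol
        converged |= done
        if done.all():
            break
    bad = (~converged) | (np.abs(beta[:, c]) > beta_cap) | ~np.isfinite(beta).all(axis=1)
    # Wald statistic: beta_g^2 / var(beta_g) with var from the inverse Hessian
    eta = C @ beta[:, :c].T + Gf * beta[:, c][None, :]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1 - mu) * Mk
    H = np.empty((L, p, p))
    H[:, :c, :c] = np.einsum("nc,nl,nd->lcd", C, w, C)
    cg = np.einsum("nc,nl,nl->lc", C, w, Gf)
    H[:, :c, c] = cg
    H[:, c, :c] = cg
    H[:, c, c] = (w * Gf * Gf).sum(axis=0)
    H[:, np.arange(p), np.arange(p)] += 1e-9
    cov = np.linalg.inv(H)
    var_g = np.clip(cov[:, c, c], 1e-300, None)
    stat = beta[:, c] ** 2 / var_g
    direction = np.sign(beta[:, c])
    # score-test fallback for separated / non-converged fits
    if bad.any():
        s_stat, s_dir = _score_statistics(Gf, Mk, y, C, bad)
        stat[bad] = s_stat
        direction[bad] = s_dir
    return stat, direction, bad


def _score_statistics(Gf, Mk, y, C, which):
    """Covariate-adjusted score test of the genotype term at beta_g = 0."""
    import statsmodels.api as sm

    null = sm.GLM(y, C, family=sm.families.Binomial()).fit()
    mu0 = null.fittedvalues
    w0 = mu0 * (1 - mu0)
    CtWC = C.T @ (C * w0[:, None])
    CtWC_inv = np.linalg.inv(CtWC + 1e-9 * np.eye(C.shape[1]))
    idx = np.flatnonzero(which)
    stats_out = np.empty(idx.size)
    dirs = np.empty(idx.size)
    for t, l in enumerate(idx):
        g = Gf[:, l] * Mk[:, l]
        U = float(g @ (y - mu0))
        cwg = C.T @ (g * w0)
        V = float(g @ (g * w0) - cwg @ CtWC_inv @ cwg)
        stats_out[t] = U * U / max(V, 1e-300)
        dirs[t] = np.sign(U)
    return stats_out, dirs


def association_scan(gm: GenotypeMatrix, labels, covariates=None,
                     method: str | None = None,
                     exclude_snps=()) -> AssociationScan:
    """Per-SNP additive association scan.

    ``labels`` is a Series (sample id -> 0/1) or an array aligned with the
    matrix; samples absent from the labels are dropped. Without covariates
    the Cochran-Armitage trend statistic is used; with covariates, the Wald
    chi-square from logistic regression (batch Newton, score-test fallback
    on separation). SNPs in ``exclude_snps`` (e.g. the AIM defining the
    phenotype) are left out of the scan.
    """
    if isinstance(labels, pd.Series):
        keep = np.isin(gm.sample_ids, labels.index)
        sub = gm.take_samples(np.flatnonzero(keep))
        y = labels.loc[sub.sample_ids].to_numpy(dtype=float)
    else:
        sub = gm
        y = np.asarray(labels, dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both cases and controls are required")
    snp_mask = ~np.isin(sub.snp_ids, list(exclude_snps))
    sub = sub.take_snps(np.flatnonzero(snp_mask))
    if method is None:
        method = "trend" if covariates is None else "logistic"
    flags = np.zeros(sub.n_snps, dtype=bool)
    if method == "trend":
        stat, direction = trend_statistics(sub.calls, y)
        adjusted = False
        covspec = ""
    elif method == "logistic":
        if covariates is None:
            C = np.ones((sub.n_samples, 1))
            covspec = "intercept"
            adjusted = False
        else:
            cov = np.asarray(covariates, dtype=float)
            C = np.column_stack([np.ones(sub.n_samples), cov])
            covspec = f"intercept + {cov.shape[1]} covariates"
            adjusted = True
        stat, direction, flags = _batch_logistic_wald(sub.calls, y, C)
    else:
        raise ValueError(f"unknown method: {method!r}")
    p = stats.chi2.sf(stat, 1)
    table = pd.DataFrame({
        "snp": sub.snp_ids, "stat": stat,
        "p": np.clip(p, 1e-300, 1.0),
        "direction": direction,
        "flag": np.where(flags, "score-fallback", ""),
    })
    return AssociationScan(table=table, method=method, adjusted=adjusted,
                           covariate_spec=covspec)


def genomic_inflation(scan, warn=None) -> float:
    """Genomic-control lambda: median statistic over the null 1-df median."""
    statistics = scan.statistics if isinstance(scan, AssociationScan) \
        else np.asarray(scan, dtype=float)
    if statistics.size < 100 and warn is not None:
        warn(f"only {statistics.size} statistics; lambda is noisy")
    return float(np.median(statistics) / CHI2_1DF_MEDIAN)


def qq_table(scan) -> pd.DataFrame:
    """Observed vs expected -log10 p under the uniform null.

    Expected quantiles are the uniform order statistics rank/(n+1).
    """
    p = scan.table["p"].to_numpy() if isinstance(scan, AssociationScan) \
        else np.asarray(scan, dtype=float)
    if p.size == 0:
        raise ValueError("empty scan")
    obs = np.sort(p)
    exp = np.arange(1, p.size + 1) / (p.size + 1)
    return pd.DataFrame({"expected_p": exp, "observed_p": obs,
                         "expected_neglog10": -np.log10(exp),
                         "observed_neglog10": -np.log10(obs)})


# ---------------------------------------------------------------------------
# the full experiment
# ---------------------------------------------------------------------------

@dataclass
class StratificationReport:
    counts: pd.DataFrame              # subgroup x case/control composition
    lambda_raw: float
    lambda_adj: float
    scan_raw: AssociationScan
    scan_adj: AssociationScan
    qq_raw: pd.DataFrame
    qq_adj: pd.DataFrame
    case_fraction_high: float         # fraction of cases from the high subgroup
    control_fraction_low: float


def run_stratification_experiment(gm: GenotypeMatrix, subgroups, aim: str,
                                  seed: int = 0, per_group: int = 200,
                                  n_adjust_evs: int = 2,
                                  prune_r2: float = 0.1,
                                  prune_window_bp: int = 500_000,
                                  structure_snp_ids=None) -> StratificationReport:
    """AIM-driven case selection, raw and eigenvector-adjusted scans.

    Draws ``per_group`` samples from each subgroup (labels "high"/"low"
    aligned with ``gm`` samples), defines cases by the homozygous AIM
    genotype, scans all remaining SNPs, and repeats with the top
    ``n_adjust_evs`` eigenvectors as covariates. Eigenvectors come from a
    PCA of the sampled set restricted to LD-pruned structure SNPs (or
    ``structure_snp_ids`` when supplied).
    """
    rng = np.random.default_rng(seed)
    subgroups = np.asarray(subgroups)
    picks = []
    for grp in ("high", "low"):
        members = np.flatnonzero(subgroups == grp)
        if members.size < per_group:
            raise ValueError(f"subgroup {grp!r} has only {members.size} samples")
        picks.append(rng.choice(members, size=per_group, replace=False))
    subset = gm.take_samples(np.sort(np.concatenate(picks)))
    sub_labels = subgroups[np.sort(np.concatenate(picks))]

    labels, excluded = select_cases_by_genotype(subset, aim)
    scan_gm = subset if not excluded else subset.take_samples(
        np.flatnonzero(np.isin(subset.sample_ids, labels.index)))
    grp_of = pd.Series(sub_labels, index=subset.sample_ids).loc[labels.index]
    counts = (pd.DataFrame({"subgroup": grp_of.to_numpy(),
                            "status": np.where(labels.to_numpy() == 1,
                                               "case", "control")})
              .value_counts().unstack(fill_value=0))
    n_cases = int(labels.sum())
    case_fraction_high = float(
        ((grp_of == "high") & (labels == 1)).sum() / max(n_cases, 1))
    n_controls = int((labels == 0).sum())
    control_fraction_low = float(
        ((grp_of == "low") & (labels == 0)).sum() / max(n_controls, 1))

    if structure_snp_ids is None:
        pruned = prune_for_structure([scan_gm], r2_threshold=prune_r2,
                                     window_bp=prune_window_bp,
                                     set_names=["experiment"])
        structure_snp_ids = pruned.kept
    keep = np.flatnonzero(np.isin(scan_gm.snp_ids, list(structure_snp_ids)))
    pca = pca_genotypes(scan_gm.take_snps(keep),
                        n_components=max(n_adjust_evs, 2))
    evs = pca.eigenvectors[:, :n_adjust_evs]

    y = labels.loc[scan_gm.sample_ids]
    scan_raw = association_scan(scan_gm, y, exclude_snps=[aim])
    scan_adj = association_scan(scan_gm, y, covariates=evs,
                                exclude_snps=[aim])
    lam_raw = genomic_inflation(scan_raw)
    lam_adj = genomic_inflation(scan_adj)
    return StratificationReport(
        counts=counts, lambda_raw=lam_raw, lambda_adj=lam_adj,
        scan_raw=scan_raw, scan_adj=scan_adj,
        qq_raw=qq_table(scan_raw), qq_adj=qq_table(scan_adj),
        case_fraction_high=case_fraction_high,
        control_fraction_low=control_fraction_low)
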