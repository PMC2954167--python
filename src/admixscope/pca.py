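"""Genotype principal components analysis with Patterson normalization.

Each SNP column is centered by its mean call and scaled by
sqrt(p(1-p)) with p the observed allele frequency — the normalization of
the EIGENSTRAT lineage, under which eigenvalues of the sample covariance
relate to population differentiation. Missing calls are imputed to the SNP
mean before scaling, so they contribute nothing to covariance. Sample
projections (eigenvectors EV1, EV2, ...) reveal admixture geometry: a
three-way admixed cohort lies inside the triangle spanned by its reference
panels in the leading EV plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .genotype_io import GenotypeMatrix
from .popstats import kruskal_wallis


@dataclass
class PCAResult:
    eigenvectors: np.ndarray        # (n, m) sample projections
    eigenvalues: np.ndarray         # (m,) non-increasing
    variance_explained: np.ndarray  # per-component fraction of total variance
    snp_loadings: np.ndarray | None = None
    dropped_snps: list = field(default_factory=list)


class GenotypePCA(BaseEstimator, TransformerMixin):
    """Patterson-normalized PCA on a calls matrix (sklearn transformer).

    Parameters
    ----------
    n_components : number of leading components to keep.
    normalization : "patterson" (divide by sqrt(p(1-p))) or "standard"
        (divide by the empirical SD of the calls).

    Attributes: ``components_`` (SNP loadings), ``eigenvalues_``,
    ``explained_variance_ratio_``, ``mean_``, ``scale_``, ``kept_snps_``.
    The fitted transform of the training data is in ``projections_``.
    Projections use a deterministic sign convention: the largest-magnitude
    coordinate of each component is positive.
    """

    def __init__(self, n_components: int = 10,
                 normalization: str = "patterson"):
        self.n_components = n_components
        self.normalization = normalization

    def _normalize(self, X):
        X = np.asarray(X, dtype=float)
        X[~np.isfinite(X) | (X < 0)] = np.nan
        n_obs = np.sum(~np.isnan(X), axis=0)
        sums = np.nansum(X, axis=0)
        mean = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), 0.0)
        freq = mean / 2.0
        polymorphic = (freq > 0) & (freq < 1) & (n_obs > 0)
        if self.normalization == "patterson":
            scale = np.sqrt(np.clip(freq * (1 - freq), 1e-12, None))
        elif self.normalization == "standard":
            scale = np.sqrt(np.clip(np.nanvar(X, axis=0), 1e-12, None))
        else:
            raise ValueError(f"unknown normalization: {self.normalization!r}")
        Z = (np.where(np.isnan(X), mean, X) - mean) / scale
        return Z[:, polymorphic], mean, scale, polymorphic

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        Z, mean, scale, poly = self._normalize(X)
        n, L = Z.shape
        if n < 2 or L < 2:
            raise ValueError("need at least two samples and two polymorphic SNPs")
        self.mean_, self.scale_, self.kept_snps_ = mean, scale, poly
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        m = min(self.n_components, S.size)
        eigvals = S ** 2 / (n - 1)
        total = eigvals.sum()
        proj = U[:, :m] * S[:m]
        # sign convention: largest-magnitude coordinate positive
        for j in range(m):
            i = np.argmax(np.abs(proj[:, j]))
            if proj[i, j] < 0:
                proj[:, j] = -proj[:, j]
                Vt[j] = -Vt[j]
        self.projections_ = proj
        self.components_ = Vt[:m]
        self.eigenvalues_ = eigvals[:m]
        self.explained_variance_ratio_ = eigvals[:m] / total
        return proj

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        X = np.where(np.isfinite(X) & (X >= 0), X, np.nan)
        Z = (np.where(np.isnan(X), self.mean_, X) - self.mean_) / self.scale_
        return Z[:, self.kept_snps_] @ self.components_.T


def pca_genotypes(gm: GenotypeMatrix, n_components: int = 10,
                  normalization: str = "patterson") -> PCAResult:
    """Run genotype PCA on a GenotypeMatrix; monomorphic SNPs are dropped."""
    est = GenotypePCA(n_components=n_components, normalization=normalization)
    proj = est.fit_transform(gm.calls)
    dropped = [sid for sid, keep in zip(gm.snp_ids, est.kept_snps_) if not keep]
    return PCAResult(eigenvectors=proj,
                     eigenvalues=est.eigenvalues_,
                     variance_explained=est.explained_variance_ratio_,
                     snp_loadings=est.components_.T,
                     dropped_snps=dropped)


def correlate_q_ev(Q, pca: PCAResult, pairs, cohort_mask=None) -> pd.DataFrame:
    """Pearson correlation between ancestry coefficients and eigenvectors.

    ``pairs`` is a list of (ancestry column index, EV index, name). When
    reference panels were included in the PCA, ``cohort_mask`` restricts
    the correlation to cohort samples (Q rows must align with the masked
    eigenvector rows).
    """
    Q = np.asarray(Q, dtype=float)
    EV = pca.eigenvectors
    if cohort_mask is not None:
        EV = EV[np.asarray(cohort_mask)]
    if Q.shape[0] != EV.shape[0]:
        raise ValueError("Q and eigenvectors cover different samples")
    rows = []
    for anc, ev, *name in pairs:
        x, y = Q[:, anc], EV[:, ev]
        if x.std() < 1e-12 or y.std() < 1e-12:
            rows.append({"pair": name[0] if name else f"Q{anc}~EV{ev + 1}",
                         "r": np.nan, "p": np.nan, "flag": "zero variance"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"pair": name[0] if name else f"Q{anc}~EV{ev + 1}",
                     "r": float(r), "p": float(p), "flag": ""})
    return pd.DataFrame(rows)


def region_substructure(pca: PCAResult, samples: pd.DataFrame,
                        Q=None, regions=None, min_samples: int = 2):
    """Per-region eigenvector (and ancestry) summaries with Kruskal-Wallis
    tests of whether regions differ in ancestry.

    ``samples`` must carry a ``region`` column aligned with the PCA rows.
    Returns (summary DataFrame, dict of per-ancestry Kruskal-Wallis (H, p)).
    Regions with fewer than ``min_samples`` samples are excluded with a
    warning entry in the summary.
    """
    region_col = samples["region"].to_numpy()
    if regions is None:
        regions = [r for r in pd.unique(region_col) if r is not None]
    counts = {r: int(np.sum(region_col == r)) for r in regions}
    usable = [r for r in regions if counts[r] >= min_samples]
    if len(usable) < 2:
        raise ValueError("need at least two regions with enough samples")
    rows = []
    for r in usable:
        mask = region_col == r
        row = {"region": r, "n": counts[r]}
        for j in range(min(2, pca.eigenvectors.shape[1])):
            row[f"EV{j + 1}_mean"] = float(pca.eigenvectors[mask, j].mean())
            row[f"EV{j + 1}_sd"] = float(pca.eigenvectors[mask, j].std(ddof=1))
        if Q is not None:
            Qa = np.asarray(Q, dtype=float)
            for k in range(Qa.shape[1]):
                row[f"Q{k}_mean"] = float(Qa[mask, k].mean())
                row[f"Q{k}_sd"] = float(Qa[mask, k].std(ddof=1))
        rows.append(row)
    summary = pd.DataFrame(rows)
    tests = {}
    if Q is not None:
        Qa = np.asarray(Q, dtype=float)
        for k in range(Qa.shape[1]):
            groups = [Qa[region_col == r, k] for r in usable]
            tests[k] = kruskal_wallis(groups)
    else:
        for j in range(min(2, pca.eigenvectors.shape[1])):
            groups = [pca.eigenvectors[region_col == r, j] for r in usable]
            tests[f"EV{j + 1}"] = kruskal_wallis(groups)
    return summary, tests
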