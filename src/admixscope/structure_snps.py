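"""Selection of low-background-LD SNPs for population-structure inference.

Greedy left-to-right pruning per chromosome, applied sequentially across
several sample sets (reference panels then the cohort), keeping a SNP only
when its genotype r-squared with every already-kept SNP within a window is
below the threshold in the current sample set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix

DEFAULT_SET_ORDER = ("YRI", "ASIAN", "CEU", "NA", "CR")


def genotype_r2(x, y) -> float:
    """Composite (genotype) r²: squared Pearson correlation of 0/1/2 calls.

    Computed over pairwise-complete samples (NaN or negative entries are
    treated as missing). A pair monomorphic on the complete subset is
    defined as r² = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y) | (x < 0) | (y < 0))
    if ok.sum() < 2:
        raise ValueError("need at least two pairwise-complete samples")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx < 1e-12 or vy < 1e-12:
        return 0.0
    c = np.mean((xs - xs.mean()) * (ys - ys.mean()))
    return float(c * c / (vx * vy))


def _pairwise_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs genotype r² with pairwise-complete handling, vectorized."""
    X = calls.astype(float)
    X[calls < 0] = np.nan
    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)
    n = obs.T.astype(float) @ obs
    sx = Xz.T @ obs
    sy = obs.T.astype(float) @ Xz
    sxx = (Xz * Xz).T @ obs
    syy = obs.T.astype(float) @ (Xz * Xz)
    sxy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


@dataclass
class PruneResult:
    """Survivor list plus an audit trail of removals."""

    kept: list                                   # ordered SNP ids
    removed: dict = field(default_factory=dict)  # id -> (set name, partner id, r²)


def prune_for_structure(gms, r2_threshold: float = 0.1,
                        window_bp: int = 500_000,
                        set_names=None) -> PruneResult:
    """Sequential greedy LD pruning across multiple sample sets.

    ``gms`` is an ordered list of GenotypeMatrix objects sharing the
    candidate SNP panel (same ids, positions and order). For each sample set
    in turn, chromosomes are scanned left to right and a SNP survives only
    if its r² with every already-kept SNP within ``window_bp`` (inclusive
    bound on |pos_i - pos_j|) is strictly below ``r2_threshold``. Each set
    starts from the previous set's survivors; removals are recorded with the
    sample set, partner SNP and r² responsible.
    """
    if not gms:
        return PruneResult(kept=[])
    first = gms[0]
    for gm in gms[1:]:
        if not np.array_equal(gm.snp_ids, first.snp_ids):
            raise ValueError("all sample sets must share the candidate SNP panel")
    if set_names is None:
        set_names = [f"set{i}" for i in range(len(gms))]

    snps = first.snps
    keep_mask = np.ones(len(snps), dtype=bool)
    removed: dict = {}
    for name, gm in zip(set_names, gms):
        for chrom in snps["chrom"].unique():
            on_chrom = np.flatnonzero((snps["chrom"] == chrom).to_numpy() & keep_mask)
            if on_chrom.size < 2:
                continue
            # left-to-right by position; equal positions break by id
            order = np.lexsort((snps["id"].to_numpy()[on_chrom].astype(str),
                                snps["pos"].to_numpy()[on_chrom]))
            on_chrom = on_chrom[order]
            pos = snps["pos"].to_numpy()[on_chrom]
            calls = gm.calls[:, on_chrom]
            r2 = _pairwise_r2_matrix(calls)
            kept_local: list[int] = []
            for a in range(on_chrom.size):
                ok = True
                for b in kept_local:
                    if pos[a] - pos[b] > window_bp:
                        continue
                    if r2[a, b] >= r2_threshold:
                        removed[snps["id"].iloc[on_chrom[a]]] = (
                            name, snps["id"].iloc[on_chrom[b]], float(r2[a, b]))
                        keep_mask[on_chrom[a]] = False
                        ok = False
                        break
                if ok:
                    kept_local.append(a)
    kept = [snps["id"].iloc[j] for j in np.flatnonzero(keep_mask)]
    return PruneResult(kept=kept, removed=removed)
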