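"""Linkage-disequilibrium statistics, haplotype-block detection and
greedy tag-SNP selection.

D-prime and its confidence interval come from a two-locus haplotype EM on
unphased genotypes followed by a profile of the multinomial likelihood over
a 101-point D-prime grid (the Haploview approach, deterministic). Blocks
follow the Gabriel rule: a contiguous interval is a block when at least 95%
of its informative pairs are in "strong LD" by the D-prime CI thresholds.
Tag SNPs are chosen greedily: the SNP covering the most yet-uncovered SNPs
(genotype r-squared above threshold within a distance cap) becomes a tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .structure_snps import _pairwise_r2_matrix

GABRIEL_STRONG_LOW = 0.70    # CI lower bound for "strong LD"
GABRIEL_STRONG_HIGH = 0.98   # CI upper bound for "strong LD"
GABRIEL_RECOMB_HIGH = 0.90   # CI upper bound below which = "strong recombination"
GABRIEL_INFORMATIVE_FRAC = 0.95
MAX_BLOCK_SPAN_BP = 500_000

_DPRIME_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class LDBlock:
    chrom: str
    start_snp: str
    end_snp: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class TagBin:
    tag: str
    covered: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# two-locus haplotype EM and D-prime CI (batched over SNP pairs)
# ---------------------------------------------------------------------------

def _genotype_pair_counts(calls: np.ndarray, ii: np.ndarray, jj: np.ndarray):
    """3x3 genotype-combination counts per pair, pairwise-complete."""
    gx = calls[:, ii]
    gy = calls[:, jj]
    ok = (gx != MISSING) & (gy != MISSING)
    counts = np.zeros((9, len(ii)))
    for a in range(3):
        for b in range(3):
            counts[3 * a + b] = ((gx == a) & (gy == b) & ok).sum(axis=0)
    return counts  # rows indexed by 3*gx + gy


def _haplotype_em(counts: np.ndarray, n_iter: int = 64, tol: float = 1e-10):
    """EM haplotype frequencies (f11, f10, f01, f00) per pair.

    ``counts`` is (9, M) genotype-combination counts; haplotype 1 denotes
    allele A. Only the double heterozygote is phase-ambiguous.
    """
    c = {(a, b): counts[3 * a + b] for a in range(3) for b in range(3)}
    n11 = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    n10 = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    n01 = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    n00 = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    dh = c[1, 1]
    total = n11 + n10 + n01 + n00 + 2 * dh
    total = np.maximum(total, 1e-12)
    f = np.full((4, counts.shape[1]), 0.25)
    for _ in range(n_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        with np.errstate(invalid="ignore", divide="ignore"):
            p_cis = np.where(cis + trans > 0, cis / np.maximum(cis + trans, 1e-300), 0.5)
        f_new = np.vstack([
            (n11 + dh * p_cis) / total,
            (n10 + dh * (1 - p_cis)) / total,
            (n01 + dh * (1 - p_cis)) / total,
            (n00 + dh * p_cis) / total,
        ])
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    return f, {(a, b): c[a, b] for a in range(3) for b in range(3)}


def _dprime_from_freqs(f: np.ndarray):
    """D-prime (signed normalization) from haplotype frequencies."""
    px = f[0] + f[1]
    py = f[0] + f[2]
    D = f[0] - px * py
    dmax_pos = np.minimum(px * (1 - py), (1 - px) * py)
    dmax_neg = np.minimum(px * py, (1 - px) * (1 - py))
    dmax = np.where(D >= 0, dmax_pos, dmax_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(dmax > 1e-12, D / np.maximum(dmax, 1e-300), 0.0)
    return dprime, px, py, dmax_pos, dmax_neg


def _grid_ci(counts9: dict, px, py, sign, dmax_pos, dmax_neg,
             alpha: float = 0.05):
    """Likelihood-profile CI over the |D'| grid (allele freqs held at MLE)."""
    M = px.shape[0]
    dmax = np.where(sign >= 0, dmax_pos, dmax_neg)
    d_grid = _DPRIME_GRID[None, :]                     # (1, 101)
    D = sign[:, None] * d_grid * dmax[:, None]
    f11 = np.clip(px[:, None] * py[:, None] + D, 1e-10, 1)
    f10 = np.clip(px[:, None] * (1 - py[:, None]) - D, 1e-10, 1)
    f01 = np.clip((1 - px[:, None]) * py[:, None] - D, 1e-10, 1)
    f00 = np.clip((1 - px[:, None]) * (1 - py[:, None]) + D, 1e-10, 1)
    cell = {
        (2, 2): f11 ** 2, (2, 1): 2 * f11 * f10, (2, 0): f10 ** 2,
        (1, 2): 2 * f11 * f01, (1, 0): 2 * f10 * f00,
        (0, 2): f01 ** 2, (0, 1): 2 * f01 * f00, (0, 0): f00 ** 2,
        (1, 1): 2 * f11 * f00 + 2 * f10 * f01,
    }
    ll = np.zeros((M, _DPRIME_GRID.size))
    for key, prob in cell.items():
        ll += counts9[key][:, None] * np.log(np.clip(prob, 1e-300, None))
    w = np.exp(ll - ll.max(axis=1, keepdims=True))
    cum = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
    lo_idx = np.argmax(cum > alpha, axis=1)
    hi_idx = np.argmax(cum >= 1 - alpha, axis=1)
    return _DPRIME_GRID[lo_idx], _DPRIME_GRID[hi_idx]


def pairwise_dprime_ci(calls: np.ndarray, ii, jj):
    """Batched D-prime point estimates and likelihood-grid CIs.

    Returns (dprime, ci_low, ci_high, informative_mask) for the SNP pairs
    ``(ii[k], jj[k])``; pairs monomorphic on the complete subset are marked
    non-informative.
    """
    ii = np.asarray(ii)
    jj = np.asarray(jj)
    counts = _genotype_pair_counts(calls, ii, jj)
    f, c9 = _haplotype_em(counts)
    dprime, px, py, dmax_pos, dmax_neg = _dprime_from_freqs(f)
    poly = (px > 1e-9) & (px < 1 - 1e-9) & (py > 1e-9) & (py < 1 - 1e-9)
    sign = np.where(dprime >= 0, 1.0, -1.0)
    lo, hi = _grid_ci(c9, px, py, sign, dmax_pos, dmax_neg)
    return np.abs(dprime), lo, hi, poly


def dprime_ci(x, y) -> tuple[float, float, float]:
    """|D'| with its likelihood-profile CI for one SNP pair.

    Haplotype frequencies come from the two-locus EM on unphased calls; the
    CI is read from the normalized likelihood over a 101-point |D'| grid.
    Raises if either SNP is monomorphic on the pairwise-complete subset.
    """
    calls = np.vstack([np.asarray(x), np.asarray(y)]).T.astype(np.int8)
    d, lo, hi, ok = pairwise_dprime_ci(calls, [0], [1])
    if not ok[0]:
        raise ValueError("monomorphic SNP on the pairwise-complete subset")
    return float(d[0]), float(lo[0]), float(hi[0])


# ---------------------------------------------------------------------------
# Gabriel blocks
# ---------------------------------------------------------------------------

def _rect_sum(prefix: np.ndarray, a: int, b: int) -> float:
    """Sum of matrix entries in the square [a..b] x [a..b] via integral image."""
    return (prefix[b + 1, b + 1] - 2 * prefix[a, b + 1] + prefix[a, a])


def find_blocks(gm: GenotypeMatrix,
                strong_low: float = GABRIEL_STRONG_LOW,
                strong_high: float = GABRIEL_STRONG_HIGH,
                recomb_high: float = GABRIEL_RECOMB_HIGH,
                informative_frac: float = GABRIEL_INFORMATIVE_FRAC,
                max_span_bp: int = MAX_BLOCK_SPAN_BP) -> list[LDBlock]:
    """Detect Gabriel-rule haplotype blocks per chromosome.

    Pairs are classified from the D-prime CI: strong LD when CI low >=
    ``strong_low`` and CI high >= ``strong_high``; strong recombination
    when CI high < ``recomb_high``. Candidate intervals (span capped at
    ``max_span_bp``) qualify when at least ``informative_frac`` of their
    informative pairs are strong LD; candidates are accepted longest-first
    (ties to the left), skipping overlaps.
    """
    blocks: list[LDBlock] = []
    snps = gm.snps
    for chrom in snps["chrom"].unique():
        idx = np.flatnonzero((snps["chrom"] == chrom).to_numpy())
        if idx.size < 2:
            continue
        pos = snps["pos"].to_numpy()[idx]
        Lc = idx.size
        ii, jj = [], []
        for a in range(Lc):
            b_hi = np.searchsorted(pos, pos[a] + max_span_bp, side="right")
            for b in range(a + 1, b_hi):
                ii.append(a)
                jj.append(b)
        if not ii:
            continue
        d, lo, hi, ok = pairwise_dprime_ci(gm.calls[:, idx], ii, jj)
        strong = ok & (lo >= strong_low) & (hi >= strong_high)
        recomb = ok & (hi < recomb_high)
        informative = strong | recomb
        S = np.zeros((Lc, Lc))
        I = np.zeros((Lc, Lc))
        ia = np.asarray(ii)
        ja = np.asarray(jj)
        S[ia, ja] = S[ja, ia] = strong.astype(float)
        I[ia, ja] = I[ja, ia] = informative.astype(float)
        Sp = np.zeros((Lc + 1, Lc + 1))
        Ip = np.zeros((Lc + 1, Lc + 1))
        Sp[1:, 1:] = S.cumsum(axis=0).cumsum(axis=1)
        Ip[1:, 1:] = I.cumsum(axis=0).cumsum(axis=1)

        candidates = []
        for a in range(Lc):
            b_hi = np.searchsorted(pos, pos[a] + max_span_bp, side="right")
            for b in range(a + 1, b_hi):
                n_inf = _rect_sum(Ip, a, b) / 2
                if n_inf < 1:
                    continue
                n_strong = _rect_sum(Sp, a, b) / 2
                if n_strong / n_inf >= informative_frac and S[a, b] > 0:
                    candidates.append((pos[b] - pos[a], a, b))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(Lc, dtype=bool)
        for span, a, b in candidates:
            if used[a:b + 1].any():
                continue
            used[a:b + 1] = True
            blocks.append(LDBlock(
                chrom=str(chrom),
                start_snp=str(snps["id"].iloc[idx[a]]),
                end_snp=str(snps["id"].iloc[idx[b]]),
                start_bp=int(pos[a]), end_bp=int(pos[b]),
                n_snps=int(b - a + 1)))
    return blocks


def average_block_size(blocks_by_group: dict) -> pd.DataFrame:
    """Mean block size (bp) per chromosome and overall, per group.

    Returns a long-format table with rows per (group, chromosome) plus an
    ``overall`` row per group; groups with no blocks are flagged with NaN.
    """
    rows = []
    for group, blocks in blocks_by_group.items():
        by_chrom: dict = {}
        for blk in blocks:
            by_chrom.setdefault(blk.chrom, []).append(blk.size_bp)
        for chrom, sizes in sorted(by_chrom.items()):
            rows.append({"group": group, "chrom": chrom,
                         "n_blocks": len(sizes),
                         "mean_size_bp": float(np.mean(sizes))})
        all_sizes = [blk.size_bp for blk in blocks]
        rows.append({"group": group, "chrom": "overall",
                     "n_blocks": len(all_sizes),
                     "mean_size_bp": float(np.mean(all_sizes)) if all_sizes else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# greedy tag-SNP selection
# ---------------------------------------------------------------------------

def greedy_tagging(gm: GenotypeMatrix, r2_threshold: float = 0.8,
                   max_dist_bp: int = 500_000) -> list[TagBin]:
    """Greedy tag-SNP binning.

    Repeatedly pick the SNP covering the most yet-uncovered SNPs (r² >=
    threshold within ``max_dist_bp``), remove its bin, and continue until
    every SNP is covered; singletons tag themselves. Ties break to the
    lower bp position, then lexicographic id. The bins partition the panel.
    """
    snps = gm.snps
    ids = snps["id"].to_numpy().astype(str)
    n = len(ids)
    neighbors: list[set] = [set() for _ in range(n)]
    for chrom in snps["chrom"].unique():
        idx = np.flatnonzero((snps["chrom"] == chrom).to_numpy())
        if idx.size < 2:
            continue
        pos = snps["pos"].to_numpy()[idx]
        r2 = _pairwise_r2_matrix(gm.calls[:, idx])
        for a in range(idx.size):
            b_hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            for b in range(a + 1, b_hi):
                if r2[a, b] >= r2_threshold:
                    neighbors[idx[a]].add(idx[b])
                    neighbors[idx[b]].add(idx[a])
    uncovered = set(range(n))
    pos_all = snps["pos"].to_numpy()
    bins: list[TagBin] = []
    while uncovered:
        best, best_key = None, None
        for j in uncovered:
            cover = len(neighbors[j] & uncovered)
            key = (-cover, pos_all[j], ids[j])
            if best_key is None or key < best_key:
                best, best_key = j, key
        bin_members = ({best} | neighbors[best]) & uncovered
        bins.append(TagBin(tag=ids[best],
                           covered={ids[m] for m in bin_members}))
        uncovered -= bin_members
    return bins


def tag_count_curve(gms: dict, thresholds) -> pd.DataFrame:
    """Tag-SNP counts per population across r² thresholds.

    ``gms`` maps population label to a GenotypeMatrix on a shared SNP
    panel; the count of greedy tags at each threshold indexes the strength
    of LD in that population (fewer tags = stronger LD).
    """
    panels = list(gms.values())
    for gm in panels[1:]:
        if not np.array_equal(gm.snp_ids, panels[0].snp_ids):
            raise ValueError("populations must share the SNP panel")
    rows = []
    for pop, gm in gms.items():
        for thr in thresholds:
            bins = greedy_tagging(gm, r2_threshold=thr)
            rows.append({"population": pop, "r2_threshold": float(thr),
                         "n_tags": len(bins)})
    return pd.DataFrame(rows)
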