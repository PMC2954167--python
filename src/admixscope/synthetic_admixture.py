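"""Synthetic admixed cohorts and continental reference panels.

The generator emulates the statistical structure of a three-way admixed
Latin-American cohort (the Guanacaste, Costa Rica setting): ancestral
allele-frequency panels differentiated under a Balding-Nichols model,
per-individual ancestry proportions drawn from a two-component mixture of
Dirichlet distributions on the simplex (bimodal high-CEU / low-CEU
subpopulations), Hybrid-Isolation (HI) versus Constant-Gene-Flow (CGF)
admixture dynamics, and optional ancestry-tract linkage disequilibrium
generated by a Markov tiling of chromosomes at a rate set by the admixture
age in generations.

Study-scale constants (ancestry order EUR, NA, AFR):

* cohort mean ancestry (42.5% European, 38.3% Native American, 15.2%
  African) and coefficient dispersions (SD 0.13 European, 0.07 African);
* subpopulation centers 60/30/10 and 40/40/20;
* reference panel sizes 60 CEU, 59 YRI, 89 ASIAN, 56 NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .genotype_io import GenotypeMatrix, make_genotype_matrix

ANCESTRIES = ("CEU", "NA", "YRI")
TARGET_MEANS = (0.425, 0.383, 0.152)          # EUR, NA, AFR cohort means
TARGET_SDS = (0.13, None, 0.07)               # EUR and AFR coefficient SDs
SUBGROUP_CENTERS = ((0.60, 0.30, 0.10),       # high-CEU subpopulation
                    (0.40, 0.40, 0.20))       # low-CEU subpopulation
REFERENCE_SIZES = {"CEU": 60, "YRI": 59, "ASIAN": 89, "NA": 56}

# Approximate human chromosome lengths in Mb (autosomes 1-22 plus X),
# used only to give simulated SNPs realistic coordinates.
_CHROM_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 182, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 102, "16": 90, "17": 83, "18": 80, "19": 59,
    "20": 64, "21": 47, "22": 51, "X": 155,
}


@dataclass
class GenomeMap:
    """Chromosome bp lengths plus a uniform genetic map (default 1 cM/Mb)."""

    chrom_lengths_bp: dict
    cm_per_mb: float = 1.0

    def morgans(self, chrom: str) -> float:
        return self.chrom_lengths_bp[chrom] * self.cm_per_mb / 1e8

    def snp_positions(self, L: int):
        """Spread L SNPs over chromosomes proportionally to bp length.

        Returns (chrom labels, 1-based positions), evenly spaced per
        chromosome.
        """
        # lexicographic chromosome order so downstream (chrom, pos) string
        # sorting leaves SNP columns in place (keeps genotype columns aligned
        # with ancestral-frequency columns)
        chroms = sorted(self.chrom_lengths_bp, key=str)
        lengths = np.array([self.chrom_lengths_bp[c] for c in chroms], dtype=float)
        # largest-remainder apportionment (valid even when L < #chromosomes)
        raw = L * lengths / lengths.sum()
        counts = np.floor(raw).astype(int)
        remainder = L - counts.sum()
        if remainder > 0:
            order = np.argsort(-(raw - counts))
            counts[order[:remainder]] += 1
        chrom_col, pos_col = [], []
        for c, k in zip(chroms, counts):
            step = self.chrom_lengths_bp[c] / (k + 1)
            chrom_col.extend([c] * k)
            pos_col.extend(int(round(step * (j + 1))) for j in range(k))
        return np.array(chrom_col, dtype=object), np.array(pos_col, dtype=np.int64)


def default_genome_map(chromosomes=None, cm_per_mb: float = 1.0,
                       scale: float = 1.0) -> GenomeMap:
    """22 autosomes + X at (optionally scaled) realistic lengths."""
    chroms = list(_CHROM_MB) if chromosomes is None else [str(c) for c in chromosomes]
    return GenomeMap({c: int(_CHROM_MB[c] * 1e6 * scale) for c in chroms}, cm_per_mb)


# ---------------------------------------------------------------------------
# Ancestral allele frequencies (Balding-Nichols)
# ---------------------------------------------------------------------------

@dataclass
class AncestralFreqs:
    """K x L ancestral allele-A frequencies with the generating Fst values."""

    P: np.ndarray                 # (K, L) in (0, 1)
    fst: np.ndarray               # per-population differentiation used to draw P
    populations: tuple = ()

    @property
    def K(self) -> int:
        return self.P.shape[0]

    @property
    def L(self) -> int:
        return self.P.shape[1]


def simulate_ancestral_freqs(L: int, K: int, fst, maf_floor: float = 0.01,
                             seed=None, populations=None) -> AncestralFreqs:
    """Draw per-population allele frequencies around a shared ancestral value.

    For each SNP an ancestral frequency p ~ Uniform(0.1, 0.9) is drawn, then
    each population's frequency follows Beta(p(1-F)/F, (1-p)(1-F)/F) — the
    Balding-Nichols model, whose expected Wright-style differentiation equals
    that population's F. Frequencies are clipped to [maf_floor, 1-maf_floor].
    """
    if L < 1 or K < 1:
        raise ValueError("L and K must be positive")
    fst = np.broadcast_to(np.asarray(fst, dtype=float), (K,)).copy()
    if np.any(fst <= 0) or np.any(fst >= 1):
        raise ValueError("fst values must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=L)
    P = np.empty((K, L))
    for k in range(K):
        f = fst[k]
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        P[k] = rng.beta(a, b)
    P = np.clip(P, maf_floor, 1 - maf_floor)
    pops = tuple(populations) if populations is not None else tuple(
        f"POP{k}" for k in range(K))
    return AncestralFreqs(P=P, fst=fst, populations=pops)


def wright_fst(P: np.ndarray) -> float:
    """Hudson-style estimate of differentiation from a K x L frequency matrix.

    Average over SNPs of Var_k(p) / (p_bar (1 - p_bar)); an estimator oracle
    for the Fst parameter used to generate the frequencies.
    """
    pbar = P.mean(axis=0)
    num = P.var(axis=0, ddof=0) * P.shape[0] / (P.shape[0] - 1)
    den = pbar * (1 - pbar)
    ok = den > 1e-12
    return float(np.mean(num[ok] / den[ok]))


# ---------------------------------------------------------------------------
# Admixture designs
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureDesign:
    """Mixture-of-Dirichlets design for per-individual ancestry proportions.

    ``components`` is a list of (weight, mean vector on the simplex,
    concentration). Under the HI model each individual's Q is a single
    Dirichlet draw from its component. Under the CGF model the focal
    ancestry accumulates over ``generations`` by per-generation migrant
    replacement at rate ``cgf_rate`` (one migrant parent with probability
    2*cgf_rate per generation), so its variance grows with admixture age.
    """

    model: str = "HI"                       # "HI" or "CGF"
    n: int = 1245
    components: list = field(default_factory=list)
    generations: int = 10
    cgf_rate: float | None = None
    cgf_focal: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.model not in ("HI", "CGF"):
            raise ValueError(f"unknown admixture model: {self.model!r}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        w = np.array([c[0] for c in self.components], dtype=float)
        if self.components and not math.isclose(w.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("component weights must sum to 1")

    @property
    def K(self) -> int:
        return len(self.components[0][1])

    def moments(self):
        """Closed-form mixture mean and per-ancestry SD (HI model)."""
        w = np.array([c[0] for c in self.components])
        M = np.array([c[1] for c in self.components])
        conc = np.array([c[2] for c in self.components])
        mean = w @ M
        var_within = M * (1 - M) / (conc[:, None] + 1)
        second = w @ (var_within + M ** 2)
        sd = np.sqrt(np.maximum(second - mean ** 2, 0))
        return mean, sd


@dataclass
class TrueAncestry:
    """Generating truth for a simulated cohort."""

    Q_true: np.ndarray            # (n, K), rows on the simplex
    subgroup: np.ndarray          # per-sample component index
    tracts: list | None = None    # per (sample, haplotype): {chrom: [(start, end, anc)]}


def _mixture_anchors(target_means, target_sds, n_components=2):
    """Permutation-equivariant starting centers: split the target mean along
    the axis with the largest requested dispersion."""
    mean = np.asarray(target_means, dtype=float)
    sds = [s if s is not None else -1.0 for s in target_sds]
    axis = int(np.argmax(sds))
    d = min(0.15, mean[axis], 1 - mean[axis]) * 0.9
    anchors = []
    for sign in (1, -1):
        m = mean.copy()
        m[axis] += sign * d
        others = np.delete(np.arange(len(mean)), axis)
        m[others] -= sign * d * mean[others] / mean[others].sum()
        anchors.append(np.clip(m, 1e-3, 1 - 1e-3))
    return [a / a.sum() for a in anchors]


def calibrate_design(target_means, target_sds, components: int = 2,
                     anchors=None, n: int = 1245, model: str = "HI",
                     generations: int = 10, seed=None,
                     shared_concentration: bool = True) -> AdmixtureDesign:
    """Moment-match a mixture-of-Dirichlets design to ancestry-moment targets.

    ``target_means`` is the desired cohort-mean ancestry vector;
    ``target_sds`` gives the desired SD per ancestry, with ``None`` for
    unconstrained entries. The returned two-component design reproduces the
    requested moments to within 5% relative error (checked against the
    closed-form mixture moments); weights, component means and
    concentrations are all free, with a weak pull toward ``anchors``
    (defaults: the bimodal split along the highest-dispersion ancestry).
    """
    mean_t = np.asarray(target_means, dtype=float)
    # a small deficit from 1 is allowed (e.g. a residual ancestry excluded
    # from the targets); it is absorbed by the ancestries without an SD
    # target so the constrained means keep their stated values
    if mean_t.min() < 0 or not math.isclose(mean_t.sum(), 1.0, rel_tol=0.05):
        raise ValueError("target means must lie on (or very near) the simplex")
    deficit = 1.0 - mean_t.sum()
    free = np.array([s is None for s in target_sds])
    if abs(deficit) > 1e-12:
        if free.any():
            mean_t[free] += deficit * mean_t[free] / mean_t[free].sum()
        else:
            mean_t = mean_t / mean_t.sum()
    K = len(mean_t)
    sds = list(target_sds)
    for k, s in enumerate(sds):
        if s is not None and s ** 2 > mean_t[k] * (1 - mean_t[k]) * 0.999:
            raise ValueError(f"target SD {s} infeasible for mean {mean_t[k]}")

    specified = [s if s is not None else 0.0 for s in sds]
    if max(specified) <= 1e-3 and all(s is not None for s in sds):
        # effectively deterministic ancestry: one high-concentration component
        conc = max(1e4, float(np.max(mean_t * (1 - mean_t))) / max(max(specified), 1e-8) ** 2)
        return AdmixtureDesign(model=model, n=n,
                               components=[(1.0, mean_t.copy(), conc)],
                               generations=generations, seed=seed)

    if components != 2:
        raise ValueError("only two-component calibration is implemented")
    if anchors is None:
        anchors = _mixture_anchors(mean_t, sds)
    anchors = [np.asarray(a, dtype=float) / np.sum(a) for a in anchors]

    def unpack(theta):
        w = 1 / (1 + np.exp(-theta[0]))
        m1 = np.exp(theta[1:1 + K]); m1 /= m1.sum()
        m2 = np.exp(theta[1 + K:1 + 2 * K]); m2 /= m2.sum()
        c1, c2 = np.exp(np.clip(theta[-2], -20, 18)), np.exp(np.clip(theta[-1], -20, 18))
        if shared_concentration:
            # two comparably tight modes, as a bimodal cohort histogram implies
            c2 = c1
        return w, m1, m2, c1, c2

    def design_of(theta):
        w, m1, m2, c1, c2 = unpack(theta)
        return AdmixtureDesign(model=model, n=n,
                               components=[(w, m1, c1), (1 - w, m2, c2)],
                               generations=generations, seed=seed)

    sd_idx = [k for k, s in enumerate(sds) if s is not None]
    sd_t = np.array([sds[k] for k in sd_idx])

    def objective(theta):
        w, m1, m2, c1, c2 = unpack(theta)
        mix_mean = w * m1 + (1 - w) * m2
        second = (w * (m1 * (1 - m1) / (c1 + 1) + m1 ** 2)
                  + (1 - w) * (m2 * (1 - m2) / (c2 + 1) + m2 ** 2))
        mix_sd = np.sqrt(np.maximum(second - mix_mean ** 2, 1e-12))
        err = np.sum(((mix_mean - mean_t) / np.maximum(mean_t, 0.05)) ** 2)
        err += np.sum(((mix_sd[sd_idx] - sd_t) / sd_t) ** 2)
        err += 0.02 * (np.sum((m1 - anchors[0]) ** 2) + np.sum((m2 - anchors[1]) ** 2))
        return err

    theta0 = np.concatenate([[0.0], np.log(anchors[0]), np.log(anchors[1]),
                             [np.log(30.0), np.log(30.0)]])
    best = None
    for attempt in range(3):
        res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"maxiter": 8000, "xatol": 1e-8,
                                         "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
        theta0 = res.x  # polish
    design = design_of(best.x)
    mean_f, sd_f = design.moments()
    rel_mean = np.abs(mean_f - mean_t) / np.maximum(mean_t, 0.05)
    rel_sd = np.abs(sd_f[sd_idx] - sd_t) / sd_t if sd_idx else np.array([0.0])
    if rel_mean.max() > 0.05 or (sd_idx and rel_sd.max() > 0.05):
        raise ValueError(
            f"calibration failed to reach targets within 5%: "
            f"mean rel err {rel_mean.max():.3f}, sd rel err {rel_sd.max():.3f}")
    return design


def guanacaste_design(n: int = 1245, seed=None) -> AdmixtureDesign:
    """The study-conditions design: cohort moments calibrated to the
    42.5/38.3/15.2 mean with SD 0.13 (EUR) and 0.07 (AFR), components
    anchored at the 60/30/10 and 40/40/20 subpopulation centers."""
    return calibrate_design(TARGET_MEANS, TARGET_SDS,
                            anchors=[np.array(c) for c in SUBGROUP_CENTERS],
                            n=n, seed=seed)


# ---------------------------------------------------------------------------
# Drawing ancestry and genotypes
# ---------------------------------------------------------------------------

def _draw_q(design: AdmixtureDesign, rng: np.random.Generator):
    w = np.array([c[0] for c in design.components])
    comp = rng.choice(len(w), size=design.n, p=w)
    K = design.K
    Q = np.empty((design.n, K))
    for c, (_, m, conc) in enumerate(design.components):
        idx = np.flatnonzero(comp == c)
        if idx.size:
            alpha = np.maximum(np.asarray(m) * conc, 1e-3)
            Q[idx] = rng.dirichlet(alpha, size=idx.size)
    if design.model == "CGF":
        Q = _cgf_adjust(design, Q, rng)
    Q /= Q.sum(axis=1, keepdims=True)
    return Q, comp


def _cgf_adjust(design: AdmixtureDesign, Q: np.ndarray, rng) -> np.ndarray:
    """Overwrite the focal-ancestry coefficient with a constant-gene-flow
    accumulation: over g generations, each generation one parent is a fresh
    migrant with probability 2m, halving the resident genome."""
    f = design.cgf_focal
    mean_focal = Q[:, f].mean()
    m = design.cgf_rate
    if m is None:
        # choose m so the g-generation mean matches the design's focal mean
        m = 1 - (1 - min(mean_focal, 0.999)) ** (1 / design.generations)
    resident = np.ones(design.n)
    for _ in range(design.generations):
        migrant_parent = rng.random(design.n) < 2 * m
        resident = np.where(migrant_parent, resident * 0.5, resident)
    focal = 1 - resident
    out = Q.copy()
    rest = 1 - out[:, f]
    scale = np.where(rest > 1e-12, (1 - focal) / np.maximum(rest, 1e-12), 0.0)
    out *= scale[:, None]
    out[:, f] = focal
    return out



def simulate_cohort(design: AdmixtureDesign, freqs: AncestralFreqs,
                    genome_map: GenomeMap | None = None,
                    tract_mode: str = "iid_loci", seed=None,
                    population_label: str = "CR",
                    keep_tracts: bool = False,
                    haplotype_pool_size: int | None = 3,
                    founder_switch_per_morgan: float = 8.0,
                    ancestral_block_per_morgan: float = 2.0):
    """Simulate an admixed cohort; returns (GenotypeMatrix, TrueAncestry).

    In ``iid_loci`` mode every allele copy independently picks an ancestry
    from the individual's Q and then an allele from that ancestry's
    frequency row (no linkage, the assumption of the admixture model).

    In ``tracts`` mode each haplotype of each chromosome is a mosaic:
    ancestry breakpoints arrive at rate ``generations`` per Morgan with
    tract ancestries drawn from Q (mean ancestry-tract length 1/generations
    Morgans — admixture LD), and haplotype segments between switch events
    copy patterns from a local haplotype pool. The pool is hierarchical:
    the chromosome is partitioned into ancestral LD blocks (rate
    ``ancestral_block_per_morgan`` per Morgan), each holding
    ``haplotype_pool_size`` pattern haplotypes shared across ancestries
    with per-ancestry pattern frequencies differentiated per the panel\'s
    Fst. Unbroken segments inside an ancestral block carry only pool
    patterns (D\' = 1 at short range); switch events (ancestry switches
    plus within-ancestry founder switches at ``founder_switch_per_morgan``)
    create recombinant combinations, so strong-LD extent shrinks as the
    total switch rate — hence the admixture age — grows.
    ``haplotype_pool_size=None`` draws alleles independently per SNP within
    ancestry tracts (pure admixture LD, no background haplotype structure).
    """
    if tract_mode not in ("iid_loci", "tracts"):
        raise ValueError(f"unknown tract_mode: {tract_mode!r}")
    if tract_mode == "tracts" and genome_map is None:
        raise ValueError("tracts mode requires a genetic map")
    if genome_map is None:
        genome_map = default_genome_map()
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    Q, comp = _draw_q(design, rng)
    n, K, L = design.n, design.K, freqs.L
    if K != freqs.K:
        raise ValueError("design and frequency panel disagree on K")
    chrom, pos = genome_map.snp_positions(L)
    snp_ids = [f"rs{j:06d}" for j in range(L)]

    tracts = [] if keep_tracts else None
    if tract_mode == "iid_loci":
        calls = rng.binomial(2, Q @ freqs.P).astype(np.int8)
    else:
        calls = np.zeros((n, L), dtype=np.int8)
        g_rate = float(design.generations)
        f_rate = founder_switch_per_morgan if haplotype_pool_size else 0.0
        for c in dict.fromkeys(chrom):
            snp_idx = np.flatnonzero(chrom == c)
            length_m = genome_map.morgans(c)
            bp_per_m = genome_map.chrom_lengths_bp[c] / max(length_m, 1e-12)
            pos_m = pos[snp_idx].astype(float) / bp_per_m
            pool = None
            if haplotype_pool_size:
                pool = _ancestral_pool(rng, freqs, snp_idx, pos_m, length_m,
                                       haplotype_pool_size,
                                       ancestral_block_per_morgan)
            for i in range(n):
                for hap in range(2):
                    alleles = _mosaic_haplotype(
                        rng, Q[i], pos_m, length_m, bp_per_m, g_rate, f_rate,
                        freqs.P[:, snp_idx], pool, tracts, i, hap, c)
                    calls[i, snp_idx] += alleles

    gm = make_genotype_matrix(
        calls, snp_ids, chrom, pos,
        [f"{population_label}{i:05d}" for i in range(n)],
        populations=[population_label] * n)
    # make_genotype_matrix sorts SNPs by (chrom, pos); keep truth aligned
    truth = TrueAncestry(Q_true=Q, subgroup=comp, tracts=tracts)
    return gm, truth


def _ancestral_pool(rng, freqs, snp_idx, pos_m, length_m, S, block_rate):
    """Ancestral-LD-block partition with a shared haplotype pool per block.

    Each block holds S pattern haplotypes (alleles Bernoulli at the
    across-ancestry mean frequency) and a (K, S) matrix of per-ancestry
    pattern frequencies drawn Balding-Nichols-style around a shared base,
    so ancestries differ in which patterns they favour.
    """
    edges = [0.0]
    while True:
        nxt = edges[-1] + rng.exponential(1.0 / max(block_rate, 1e-300))
        if nxt >= length_m:
            break
        edges.append(nxt)
    edges.append(float(length_m))
    base_p = freqs.P[:, snp_idx].mean(axis=0)
    K = freqs.K
    blocks = []
    for b in range(len(edges) - 1):
        in_blk = np.flatnonzero((pos_m >= edges[b]) & (pos_m < edges[b + 1]))
        patterns = (rng.random((S, in_blk.size)) < base_p[in_blk]).astype(np.int8)
        base_w = rng.dirichlet(np.ones(S))
        W = np.empty((K, S))
        for k in range(K):
            f = freqs.fst[k]
            W[k] = rng.dirichlet(np.maximum(base_w * (1 - f) / f, 1e-3))
        blocks.append({"snps": in_blk, "patterns": patterns, "W": W})
    return {"edges": np.asarray(edges), "blocks": blocks}


def _mosaic_haplotype(rng, q, pos_m, length_m, bp_per_m, g_rate, f_rate,
                      P_chrom, pool, tracts, i, hap, chrom):
    """One haplotype as an ancestry/founder mosaic; returns per-SNP alleles.

    Switch events arrive at combined rate g_rate + f_rate per Morgan; an
    event is an ancestry switch (ancestry redrawn from q) with probability
    g_rate/(g_rate + f_rate), otherwise a founder switch only. Every event
    redraws the pool pattern. Ancestry tracts (segments between ancestry
    events) are recorded in bp when asked.
    """
    total = g_rate + f_rate
    breaks = [0.0]
    while True:
        nxt = breaks[-1] + rng.exponential(1.0 / max(total, 1e-300))
        if nxt >= length_m:
            break
        breaks.append(nxt)
    breaks.append(float(length_m))
    n_seg = len(breaks) - 1
    is_anc = rng.random(n_seg) < (g_rate / total if total > 0 else 1.0)
    is_anc[0] = True
    K = P_chrom.shape[0]
    anc_seg = np.empty(n_seg, dtype=np.int64)
    a = 0
    for s in range(n_seg):
        if is_anc[s]:
            a = rng.choice(K, p=q)
        anc_seg[s] = a

    alleles = np.zeros(pos_m.size, dtype=np.int8)
    seg_of_snp = np.clip(np.searchsorted(breaks, pos_m, side="right") - 1,
                         0, n_seg - 1)
    if pool is None:
        anc = anc_seg[seg_of_snp]
        alleles = (rng.random(pos_m.size)
                   < P_chrom[anc, np.arange(pos_m.size)]).astype(np.int8)
    else:
        edges = pool["edges"]
        blk_of_snp = np.clip(np.searchsorted(edges, pos_m, side="right") - 1,
                             0, len(pool["blocks"]) - 1)
        # a (segment, ancestral block) piece shares one pool pattern
        piece = seg_of_snp * len(pool["blocks"]) + blk_of_snp
        uniq, inverse = np.unique(piece, return_inverse=True)
        for u_idx, u in enumerate(uniq):
            seg = int(u // len(pool["blocks"]))
            blk = pool["blocks"][int(u % len(pool["blocks"]))]
            snps_here = np.flatnonzero(inverse == u_idx)
            s_pat = rng.choice(blk["W"].shape[1], p=blk["W"][anc_seg[seg]])
            local = np.searchsorted(blk["snps"], snps_here)
            alleles[snps_here] = blk["patterns"][s_pat, local]
    if tracts is not None:
        rec = []
        start = 0.0
        for s in range(1, n_seg + 1):
            if s == n_seg or is_anc[s]:
                rec.append((start * bp_per_m, breaks[s] * bp_per_m,
                            int(anc_seg[s - 1])))
                start = breaks[s]
        tracts.append({"sample": i, "haplotype": hap, "chrom": chrom,
                       "tracts": rec})
    return alleles




def simulate_reference_panels(freqs: AncestralFreqs, n_per_pop,
                              genome_map: GenomeMap | None = None,
                              seed=None) -> GenotypeMatrix:
    """Hardy-Weinberg reference panels, one population per frequency row.

    ``n_per_pop`` is a dict (population -> n) over ``freqs.populations``
    or a sequence aligned with the frequency rows.
    """
    if genome_map is None:
        genome_map = default_genome_map()
    rng = np.random.default_rng(seed)
    if isinstance(n_per_pop, dict):
        pops = list(n_per_pop)
        sizes = [n_per_pop[p] for p in pops]
        rows = [freqs.populations.index(p) for p in pops]
    else:
        sizes = list(n_per_pop)
        pops = list(freqs.populations[:len(sizes)])
        rows = list(range(len(sizes)))
    if min(sizes) < 1:
        raise ValueError("panel sizes must be positive")
    chrom, pos = genome_map.snp_positions(freqs.L)
    snp_ids = [f"rs{j:06d}" for j in range(freqs.L)]
    blocks, labels, ids = [], [], []
    for p, nn, r in zip(pops, sizes, rows):
        blocks.append(rng.binomial(2, np.broadcast_to(freqs.P[r], (nn, freqs.L))))
        labels.extend([p] * nn)
        ids.extend(f"{p}{i:04d}" for i in range(nn))
    calls = np.vstack(blocks).astype(np.int8)
    return make_genotype_matrix(calls, snp_ids, chrom, pos, ids,
                                populations=labels)


def plant_aim(gm: GenotypeMatrix, freqs: AncestralFreqs, truth: TrueAncestry,
              ancestry_index: int, freq_contrast=(0.98, 0.02),
              seed=None, snp_id=None) -> str:
    """Designate one SNP as an ancestry-informative marker (AIM).

    The chosen SNP's ancestral frequencies are overwritten: allele-A
    frequency ``freq_contrast[0]`` in the named ancestry and
    ``freq_contrast[1]`` in all others (emulating a selected variant such
    as the skin-pigmentation SNP rs1426654, nearly fixed in Europeans).
    Its genotype column is regenerated from the cohort's true ancestry.
    Returns the SNP id; ``gm`` and ``freqs`` are modified in place.
    """
    hi, lo = freq_contrast
    if not (0 <= lo <= 1 and 0 <= hi <= 1):
        raise ValueError("frequency contrast must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if snp_id is None:
        j = gm.n_snps // 2
        snp_id = gm.snp_ids[j]
    else:
        j = int(np.flatnonzero(gm.snp_ids == snp_id)[0])
    p_col = np.full(freqs.K, lo)
    p_col[ancestry_index] = hi
    freqs.P[:, j] = p_col
    q_aim = truth.Q_true @ p_col
    gm.calls[:, j] = rng.binomial(2, q_aim).astype(np.int8)
    return str(snp_id)

def plant_ld_block(gm: GenotypeMatrix, start_idx: int, end_idx: int,
                   seed=None) -> tuple[str, str]:
    """Overwrite SNP columns [start_idx, end_idx] with a two-haplotype region.

    Every sample's two haplotypes each carry one of two complementary
    patterns (chosen independently with probability 1/2), so all SNPs in
    the region are polymorphic and every within-region pair is in complete
    LD (only two of the four haplotype combinations exist, D' = 1).
    Returns the (start, end) SNP ids of the planted block; ``gm`` is
    modified in place.
    """
    if not (0 <= start_idx < end_idx < gm.n_snps):
        raise ValueError("invalid planted-block indices")
    rng = np.random.default_rng(seed)
    width = end_idx - start_idx + 1
    h0 = rng.integers(0, 2, size=width).astype(np.int8)
    copies = rng.binomial(2, 0.5, size=gm.n_samples)  # copies of pattern h0
    region = (copies[:, None] * h0[None, :]
              + (2 - copies)[:, None] * (1 - h0)[None, :])
    gm.calls[:, start_idx:end_idx + 1] = region.astype(np.int8)
    return str(gm.snp_ids[start_idx]), str(gm.snp_ids[end_idx])
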