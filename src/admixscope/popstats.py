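"""Elementary population statistics: allele frequencies, per-sample
heterozygosity, and the Kruskal-Wallis comparison of admixture coefficients
across groups."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix


def allele_frequency(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Frequency of allele A from genotype counts.

    Returns ``(2*n_aa + n_ab) / (2*(n_aa + n_ab + n_bb))``.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n_aa + n_ab + n_bb
    if total == 0:
        raise ValueError("no genotypes observed")
    return (2 * n_aa + n_ab) / (2 * total)


@dataclass
class HeterozygositySummary:
    """Per-sample heterozygosity fractions plus per-population mean/SD."""

    per_sample: pd.Series            # sample id -> fraction in [0, 1]
    group_means: pd.Series           # population -> mean
    group_sds: pd.Series             # population -> SD (ddof=1)
    flagged: list                    # sample ids with zero non-missing calls


def sample_heterozygosity(gm: GenotypeMatrix,
                          snp_subset=None) -> HeterozygositySummary:
    """Heterozygote fraction per sample: het calls / non-missing calls.

    ``snp_subset`` (optional iterable of SNP ids) restricts the computation.
    Samples with no non-missing calls are flagged and excluded from the
    group statistics.
    """
    calls = gm.calls
    if snp_subset is not None:
        subset = set(snp_subset)
        unknown = subset - set(gm.snp_ids)
        if unknown:
            raise ValueError(f"snp_subset contains unknown ids: {sorted(unknown)[:5]}")
        calls = calls[:, np.isin(gm.snp_ids, list(subset))]
    non_missing = (calls != MISSING).sum(axis=1)
    het = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(non_missing > 0, het / np.maximum(non_missing, 1), np.nan)
    per_sample = pd.Series(frac, index=gm.sample_ids, name="heterozygosity")
    flagged = list(per_sample.index[non_missing == 0])
    ok = non_missing > 0
    df = pd.DataFrame({"het": frac[ok],
                       "population": gm.samples["population"].to_numpy()[ok]})
    grouped = df.groupby("population")["het"]
    return HeterozygositySummary(
        per_sample=per_sample,
        group_means=grouped.mean(),
        group_sds=grouped.std(ddof=1),
        flagged=flagged,
    )


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test across two or more groups.

    Average ranks with the standard tie correction; p-value from the
    chi-square distribution with (g - 1) degrees of freedom. All-identical
    values return (0, 1) rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
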