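"""Genotype containers, file IO, QC filtering and panel intersection.

The central container is :class:`GenotypeMatrix`: samples x SNPs calls coded
as copies of allele A (the counted allele) with ``-1`` marking missing data,
plus per-SNP and per-sample metadata carried as pandas DataFrames.

Two text dialects are supported: VCF v4.x (GT field only) and a PLINK-style
whitespace-delimited transposed text format with a companion ``.map`` file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_SNP_COLUMNS = ["id", "chrom", "pos", "allele_a", "allele_b"]
_SAMPLE_COLUMNS = ["id", "population", "region"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; names the offending line."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls with metadata.

    Parameters
    ----------
    calls
        ``(n_samples, n_snps)`` integer array; each entry counts copies of
        ``allele_a`` (0, 1 or 2) or is ``MISSING`` (-1).
    snps
        DataFrame with columns ``id, chrom, pos, allele_a, allele_b``,
        sorted by (chrom, pos).
    samples
        DataFrame with columns ``id, population, region``.
    """

    calls: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n, m = self.calls.shape
        if len(self.samples) != n or len(self.snps) != m:
            raise ValueError(
                f"dimension mismatch: calls {self.calls.shape}, "
                f"{len(self.samples)} samples, {len(self.snps)} snps"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,missing}")
        if self.snps["id"].duplicated().any():
            dup = self.snps.loc[self.snps["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup}")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.snps["pos"] < 1).any():
            raise ValueError("SNP positions must be 1-based (>= 1)")
        key = self.snps[["chrom", "pos"]].astype({"chrom": str})
        order = key.sort_values(["chrom", "pos"], kind="stable").index
        if not (order.to_numpy() == np.arange(len(order))).all():
            raise ValueError("SNPs must be sorted by (chrom, pos)")

    # -- convenience views ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["id"].to_numpy()

    def calls_float(self) -> np.ndarray:
        """Calls as float with missing replaced by NaN."""
        c = self.calls.astype(float)
        c[self.calls == MISSING] = np.nan
        return c

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[:, index],
            self.snps.iloc[np.asarray(index)].reset_index(drop=True),
            self.samples.copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[np.asarray(index), :],
            self.snps.copy(),
            self.samples.iloc[np.asarray(index)].reset_index(drop=True),
        )

    def select_populations(self, labels) -> "GenotypeMatrix":
        mask = self.samples["population"].isin(list(labels)).to_numpy()
        return self.take_samples(np.flatnonzero(mask))

    def allele_frequencies(self) -> np.ndarray:
        """Observed allele-A frequency per SNP over non-missing calls (NaN if none)."""
        c = self.calls_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(c, axis=0) / 2.0


def make_genotype_matrix(calls, snp_ids, chrom, pos, samples_ids,
                         populations=None, regions=None,
                         allele_a=None, allele_b=None) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from arrays, sorting SNPs by (chrom, pos)."""
    calls = np.asarray(calls)
    n, m = calls.shape
    snps = pd.DataFrame({
        "id": np.asarray(snp_ids, dtype=object),
        "chrom": np.asarray(chrom, dtype=object),
        "pos": np.asarray(pos, dtype=np.int64),
        "allele_a": np.asarray(allele_a, dtype=object) if allele_a is not None else np.repeat("A", m),
        "allele_b": np.asarray(allele_b, dtype=object) if allele_b is not None else np.repeat("G", m),
    })
    order = snps.astype({"chrom": str}).sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    snps = snps.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    samples = pd.DataFrame({
        "id": np.asarray(samples_ids, dtype=object),
        "population": np.asarray(populations, dtype=object) if populations is not None else np.repeat("NA", n),
        "region": np.asarray(regions, dtype=object) if regions is not None else np.repeat(None, n),
    })
    return GenotypeMatrix(calls, snps, samples)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    rows, ids, chroms, poss, ref, alt = [], [], [], [], [], []
    for i, variant in enumerate(vcf):
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        ids.append(vid)
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        ref.append(variant.REF)
        alt.append(variant.ALT[0] if variant.ALT else ".")
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown; allele A is REF
        g = np.asarray(variant.gt_types, dtype=np.int8)
        col = np.where(g == 3, MISSING, 2 - g).astype(np.int8)
        rows.append(col)
    vcf.close()
    calls = (np.vstack(rows).T if rows
             else np.empty((len(sample_ids), 0), dtype=np.int8))
    return make_genotype_matrix(calls, ids, chroms, poss, sample_ids,
                                allele_a=ref, allele_b=alt)


def _write_vcf(gm: GenotypeMatrix, path: str) -> None:
    codes = {0: "1/1", 1: "0/1", 2: "0/0", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.sample_ids) + "\n")
        for j, snp in gm.snps.iterrows():
            gts = "\t".join(codes[int(c)] for c in gm.calls[:, j])
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.allele_a}\t"
                     f"{snp.allele_b}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK-style text (transposed genotype table + companion .map)
# ---------------------------------------------------------------------------
# <path> holds one line per sample: id population region g1 g2 ... gL with
# genotypes as allele-A copy counts and "." for missing; <path>.map holds one
# line per SNP: chrom id pos allele_a allele_b.

def _read_plink_text(path: str) -> GenotypeMatrix:
    map_path = path + ".map"
    if not os.path.exists(map_path):
        raise GenotypeParseError(f"companion map file not found: {map_path}")
    snps = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5:
                raise GenotypeParseError(f"{map_path}:{ln}: expected 5 fields, got {len(parts)}")
            chrom, sid, pos, a, b = parts
            snps.append((sid, chrom, int(pos), a, b))
    sample_ids, pops, regions, rows = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3 + len(snps):
                raise GenotypeParseError(
                    f"{path}:{ln}: expected {3 + len(snps)} fields, got {len(parts)}")
            sample_ids.append(parts[0])
            pops.append(parts[1])
            regions.append(None if parts[2] == "." else parts[2])
            row = np.full(len(snps), MISSING, dtype=np.int8)
            for j, tok in enumerate(parts[3:]):
                if tok in ("0", "1", "2"):
                    row[j] = int(tok)
            rows.append(row)
    calls = (np.vstack(rows) if rows
             else np.empty((0, len(snps)), dtype=np.int8))
    ids, chroms, poss, a_, b_ = zip(*snps) if snps else ((), (), (), (), ())
    return make_genotype_matrix(calls, ids, chroms, poss, sample_ids,
                                populations=pops, regions=regions,
                                allele_a=a_, allele_b=b_)


def _write_plink_text(gm: GenotypeMatrix, path: str) -> None:
    with open(path + ".map", "w") as fh:
        for _, snp in gm.snps.iterrows():
            fh.write(f"{snp.chrom}\t{snp.id}\t{snp.pos}\t{snp.allele_a}\t{snp.allele_b}\n")
    with open(path, "w") as fh:
        for i, sample in gm.samples.iterrows():
            region = sample.region if sample.region not in (None, "") else "."
            toks = ["." if c == MISSING else str(int(c)) for c in gm.calls[i]]
            fh.write(f"{sample.id}\t{sample.population}\t{region}\t" + "\t".join(toks) + "\n")


def read_genotypes(path: str, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    ``format`` is ``"vcf"`` or ``"plink-text"``. Calls count copies of the
    counted allele (REF for VCF); unparseable genotype tokens become missing.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink-text":
        return _read_plink_text(path)
    raise ValueError(f"unknown format: {format!r}")


def write_genotypes(gm: GenotypeMatrix, path: str, format: str = "vcf") -> None:
    """Write ``gm`` so that :func:`read_genotypes` reproduces it exactly."""
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "plink-text":
        _write_plink_text(gm, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# QC and panel intersection
# ---------------------------------------------------------------------------

def qc_filter(gm: GenotypeMatrix, min_call_rate: float = 0.95,
              min_maf: float = 0.01, log: list | None = None) -> GenotypeMatrix:
    """Drop SNPs with call rate below ``min_call_rate`` or MAF below ``min_maf``.

    MAF is computed on non-missing calls only. Sample order is preserved.
    ``log``, if given, receives per-criterion removal counts.
    """
    observed = gm.calls != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / max(gm.n_samples, 1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0,
                        (gm.calls * observed).sum(axis=0) / np.maximum(2 * n_obs, 1),
                        np.nan)
    maf = np.fmin(freq, 1.0 - freq)
    low_call = call_rate < min_call_rate
    low_maf = ~low_call & (np.isnan(maf) | (maf < min_maf))
    keep = ~(low_call | low_maf)
    if log is not None:
        log.append({"removed_call_rate": int(low_call.sum()),
                    "removed_maf": int(low_maf.sum()),
                    "kept": int(keep.sum())})
    return gm.take_snps(np.flatnonzero(keep))


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT.get(str(a).upper()) == str(b).upper()


def intersect_panels(gms: list[GenotypeMatrix], warn=None) -> list[GenotypeMatrix]:
    """Restrict matrices to their common SNPs, harmonized to the first matrix.

    Harmonization matches SNPs by id. A SNP whose alleles are swapped in a
    later matrix has its coding flipped (2<->0); strand-ambiguous A/T and C/G
    SNPs are dropped with a warning; SNPs whose alleles cannot be reconciled
    (directly or via strand complement) are dropped as well.
    """
    if len(gms) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(gms[0].snp_ids)
    for gm in gms[1:]:
        common &= set(gm.snp_ids)
    if not common:
        raise ValueError("panels share no SNP ids")

    ref = gms[0]
    ref_meta = ref.snps.set_index("id")
    keep_ids, flips = [], []  # flips: per matrix, set of snp ids to recode
    for _ in gms:
        flips.append(set())
    for sid in ref_meta.index:
        if sid not in common:
            continue
        a0 = str(ref_meta.at[sid, "allele_a"]).upper()
        b0 = str(ref_meta.at[sid, "allele_b"]).upper()
        if _is_ambiguous(a0, b0):
            if warn is not None:
                warn(f"dropping strand-ambiguous SNP {sid} ({a0}/{b0})")
            continue
        ok = True
        for k, gm in enumerate(gms[1:], start=1):
            meta = gm.snps.set_index("id")
            a = str(meta.at[sid, "allele_a"]).upper()
            b = str(meta.at[sid, "allele_b"]).upper()
            if (a, b) == (a0, b0):
                continue
            if (a, b) == (b0, a0):
                flips[k].add(sid)
            elif (_COMPLEMENT.get(a), _COMPLEMENT.get(b)) == (a0, b0):
                continue  # same orientation on opposite strand
            elif (_COMPLEMENT.get(a), _COMPLEMENT.get(b)) == (b0, a0):
                flips[k].add(sid)
            else:
                if warn is not None:
                    warn(f"dropping irreconcilable SNP {sid}")
                ok = False
                break
        if ok:
            keep_ids.append(sid)
    if not keep_ids:
        raise ValueError("no SNPs survive allele harmonization")

    # metadata (chrom/pos/alleles) harmonized to the reference matrix
    out_snps = ref.snps.set_index("id").loc[keep_ids].reset_index()[_SNP_COLUMNS]
    out = []
    for k, gm in enumerate(gms):
        idx = pd.Index(gm.snp_ids)
        calls = gm.calls[:, idx.get_indexer(keep_ids)].copy()
        if flips[k]:
            cols = np.flatnonzero(np.isin(np.asarray(keep_ids, dtype=object),
                                          list(flips[k])))
            c = calls[:, cols]
            calls[:, cols] = np.where(c == MISSING, MISSING, 2 - c)
        out.append(GenotypeMatrix(calls, out_snps.copy(), gm.samples.copy()))
    return out
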