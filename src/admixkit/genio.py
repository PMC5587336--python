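"""Genotype dataset container and I/O for PLINK binary and EIGENSTRAT layouts.

The in-memory substrate of every statistic in this package is a
:class:`GenotypeDataset`: a SNP-major dosage matrix counting copies of the
*counted* allele (``allele_ref``, the PLINK .bim A1 column), together with
SNP metadata and sample/population labels.  Dosages count the A1 allele
because f-statistics are invariant to allele polarity but frequencies are
not; the convention is fixed here once.

Genetic positions are stored internally in Morgans.  File formats that carry
centimorgans (.bim, .snp) are converted on read and write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -9  # single sentinel for both ploidies

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # variant-major v1.00


class FormatError(ValueError):
    """Malformed file content (bad magic bytes, illegal genotype codes)."""


class ConsistencyError(ValueError):
    """Companion files disagree on dimensions or identifiers."""


@dataclass
class GenotypeDataset:
    """SNP x sample dosage matrix plus metadata.

    Parameters
    ----------
    snps : pandas.DataFrame
        Columns ``chrom`` (str), ``snp_id`` (str, unique), ``genetic_pos``
        (float, Morgans), ``phys_pos`` (int, 1-based), ``allele_ref`` (the
        counted allele), ``allele_alt``.
    samples : pandas.DataFrame
        Columns ``sample_id`` (str, unique) and ``population`` (str).
    genotypes : numpy.ndarray of int8, shape (n_snps, n_samples)
        Counted-allele dosage; ``MISSING`` (-9) marks no-calls.  Diploid
        values lie in {0, 1, 2}; haploid values in {0, 1}.
    ploidy : int
        2 (diploid) or 1 (haploidized).
    """

    snps: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.snps), len(self.samples)):
            raise ConsistencyError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        allowed = {0, 1, MISSING} if self.ploidy == 1 else {0, 1, 2, MISSING}
        vals = set(np.unique(self.genotypes).tolist())
        if not vals <= allowed:
            raise ValueError(f"illegal dosage codes {sorted(vals - allowed)}")
        if self.snps["snp_id"].duplicated().any():
            raise ConsistencyError("duplicate snp_id")
        if self.samples["sample_id"].duplicated().any():
            raise ConsistencyError("duplicate sample_id")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- convenience -----------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.snps.copy(), self.samples.copy(), self.genotypes.copy(), self.ploidy
        )

    def subset_snps(self, mask_or_idx) -> "GenotypeDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            self.snps.iloc[idx], self.samples, self.genotypes[idx], self.ploidy
        )

    def subset_samples(self, mask_or_idx) -> "GenotypeDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            self.snps, self.samples.iloc[idx], self.genotypes[:, idx], self.ploidy
        )


@dataclass
class FrequencyTable:
    """Per-SNP, per-population counted-allele frequencies.

    ``p`` is NaN where ``n`` (observed haploid genome count) is zero.
    ``het`` is the observed heterozygote proportion among non-missing
    diploid genotypes (NaN for haploid input or empty populations).
    """

    populations: list[str]
    p: np.ndarray  # (n_snps, n_pops) float
    n: np.ndarray  # (n_snps, n_pops) int, haploid genome counts
    het: np.ndarray  # (n_snps, n_pops) float
    snps: pd.DataFrame = field(repr=False, default=None)

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, pop in enumerate(self.populations):
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": self.snps["snp_id"] if self.snps is not None else np.arange(self.p.shape[0]),
                        "population": pop,
                        "p": self.p[:, j],
                        "n": self.n[:, j],
                        "het": self.het[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def allele_freq_table(ds: GenotypeDataset, pops: list[str] | None = None) -> FrequencyTable:
    """Counted-allele frequency, allele count and het proportion per population.

    p-hat = counted-allele copies / non-missing allele copies; undefined
    (NaN) where a population has no calls at a SNP.
    """
    if pops is None:
        pops = ds.populations
    n_snps = ds.n_snps
    p = np.full((n_snps, len(pops)), np.nan)
    n = np.zeros((n_snps, len(pops)), dtype=np.int64)
    het = np.full((n_snps, len(pops)), np.nan)
    for j, pop in enumerate(pops):
        idx = ds.sample_indices(pop)
        g = ds.genotypes[:, idx]
        obs = g != MISSING
        n_geno = obs.sum(axis=1)
        dose = np.where(obs, g, 0).sum(axis=1)
        nj = ds.ploidy * n_geno
        with np.errstate(invalid="ignore", divide="ignore"):
            pj = dose / nj
        p[:, j] = np.where(nj > 0, pj, np.nan)
        n[:, j] = nj
        if ds.ploidy == 2:
            n_het = np.where(obs, g == 1, False).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                hj = n_het / n_geno
            het[:, j] = np.where(n_geno > 0, hj, np.nan)
    return FrequencyTable(list(pops), p, n, het, ds.snps)


# ---------------------------------------------------------------------------
# PLINK binary (bed/bim/fam)
# ---------------------------------------------------------------------------

# 2-bit PLINK codes (variant-major) -> A1 dosage
_PLINK_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)  # 00,01,10,11
_PLINK_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str) -> GenotypeDataset:
    """Read a PLINK bed/bim/fam triple into a diploid dataset.

    The .fam family ID becomes the population label.  The .bim cM column is
    converted to Morgans; if it is all zeros, genetic positions are imputed
    at 1 cM/Mb with a warning.
    """
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "phys_pos", "allele_ref", "allele_alt"],
        dtype={"chrom": str, "snp_id": str, "allele_ref": str, "allele_alt": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["population", "sample_id", "pat", "mat", "sex", "pheno"],
        dtype={"population": str, "sample_id": str},
    )
    snps = _snps_from_cm(bim)
    samples = fam[["sample_id", "population"]].copy()

    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(f"{prefix}.bed: bad magic bytes {magic!r}")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_snps, n_samples = len(snps), len(samples)
    bytes_per_snp = (n_samples + 3) // 4
    if raw.size != n_snps * bytes_per_snp:
        raise ConsistencyError(
            f"{prefix}.bed has {raw.size} genotype bytes, expected "
            f"{n_snps} x {bytes_per_snp}"
        )
    if n_snps == 0 or n_samples == 0:
        geno = np.zeros((n_snps, n_samples), dtype=np.int8)
    else:
        raw = raw.reshape(n_snps, bytes_per_snp)
        codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (raw >> (2 * k)) & 0b11
        geno = _PLINK_DECODE[codes[:, :n_samples]]
    return GenotypeDataset(snps, samples, geno, ploidy=2)


def write_plink(ds: GenotypeDataset, prefix: str) -> None:
    """Write a diploid dataset as bed/bim/fam (variant-major v1.00)."""
    if ds.ploidy != 2:
        raise ValueError("PLINK binary is diploid-only; use EIGENSTRAT for haploid data")
    bim = pd.DataFrame(
        {
            "chrom": ds.snps["chrom"],
            "snp_id": ds.snps["snp_id"],
            "cm": ds.snps["genetic_pos"] * 100.0,
            "phys_pos": ds.snps["phys_pos"],
            "a1": ds.snps["allele_ref"],
            "a2": ds.snps["allele_alt"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": ds.samples["population"],
            "iid": ds.samples["sample_id"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    n_snps, n_samples = ds.n_snps, ds.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    code_lut = np.zeros(256, dtype=np.uint8)
    for dose, code in _PLINK_ENCODE.items():
        code_lut[dose & 0xFF] = code
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        if n_snps and n_samples:
            codes = code_lut[ds.genotypes.view(np.uint8)]
            padded = np.ones((n_snps, bytes_per_snp * 4), dtype=np.uint8) * 0b11
            # pad slots encode homozygous-A2 (code 11); PLINK ignores them
            padded[:, :n_samples] = codes
            packed = np.zeros((n_snps, bytes_per_snp), dtype=np.uint8)
            for k in range(4):
                packed |= padded[:, k::4] << (2 * k)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# EIGENSTRAT (geno/snp/ind)
# ---------------------------------------------------------------------------

def read_eigenstrat(prefix: str) -> GenotypeDataset:
    """Read geno/snp/ind.  Ploidy is 1 when no '2' occurs and the .ind file
    carries a ``HAPLOID`` marker column value, else inferred diploid."""
    snp = pd.read_csv(
        f"{prefix}.snp",
        sep=r"\s+",
        header=None,
        names=["snp_id", "chrom", "morgans", "phys_pos", "allele_ref", "allele_alt"],
        dtype={"snp_id": str, "chrom": str, "allele_ref": str, "allele_alt": str},
    )
    snps = pd.DataFrame(
        {
            "chrom": snp["chrom"],
            "snp_id": snp["snp_id"],
            "genetic_pos": snp["morgans"].astype(float),
            "phys_pos": snp["phys_pos"].astype(np.int64),
            "allele_ref": snp["allele_ref"],
            "allele_alt": snp["allele_alt"],
        }
    )
    ind = pd.read_csv(
        f"{prefix}.ind",
        sep=r"\s+",
        header=None,
        names=["sample_id", "sex", "population"],
        dtype=str,
    )
    samples = ind[["sample_id", "population"]].copy()
    with open(f"{prefix}.geno") as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip() != ""]
    if len(lines) != len(snps):
        raise ConsistencyError(
            f"{prefix}.geno has {len(lines)} rows, .snp has {len(snps)}"
        )
    n_samples = len(samples)
    geno = np.empty((len(lines), n_samples), dtype=np.int8)
    trans = np.full(128, -1, dtype=np.int8)
    trans[ord("0")] = 0
    trans[ord("1")] = 1
    trans[ord("2")] = 2
    trans[ord("9")] = MISSING
    for i, line in enumerate(lines):
        if len(line) != n_samples:
            raise ConsistencyError(
                f"{prefix}.geno line {i + 1} has {len(line)} columns, expected {n_samples}"
            )
        row = trans[np.frombuffer(line.encode("ascii"), dtype=np.uint8)]
        if (row == -1).any():
            raise FormatError(f"{prefix}.geno line {i + 1}: illegal character")
        geno[i] = row
    ploidy = 1 if (ind["sex"] == "HAPLOID").all() and len(ind) > 0 else 2
    if ploidy == 2 and geno.size and not np.isin(geno, (0, 1, 2, MISSING)).all():
        raise FormatError("illegal genotype code for diploid data")
    return GenotypeDataset(snps, samples, geno, ploidy=ploidy)


def write_eigenstrat(ds: GenotypeDataset, prefix: str) -> None:
    """Write geno/snp/ind.  Haploid datasets set the .ind sex column to
    ``HAPLOID`` so ploidy round-trips."""
    snp = pd.DataFrame(
        {
            "snp_id": ds.snps["snp_id"],
            "chrom": ds.snps["chrom"],
            "morgans": ds.snps["genetic_pos"],
            "phys_pos": ds.snps["phys_pos"],
            "a1": ds.snps["allele_ref"],
            "a2": ds.snps["allele_alt"],
        }
    )
    snp.to_csv(f"{prefix}.snp", sep="\t", header=False, index=False)
    sex = "HAPLOID" if ds.ploidy == 1 else "U"
    ind = pd.DataFrame(
        {"sample_id": ds.samples["sample_id"], "sex": sex, "population": ds.samples["population"]}
    )
    ind.to_csv(f"{prefix}.ind", sep="\t", header=False, index=False)
    lut = np.full(256, ord("9"), dtype=np.uint8)
    lut[0] = ord("0")
    lut[1] = ord("1")
    lut[2] = ord("2")
    chars = lut[ds.genotypes.view(np.uint8)]
    with open(f"{prefix}.geno", "wb") as fh:
        for i in range(ds.n_snps):
            fh.write(chars[i].tobytes())
            fh.write(b"\n")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    n_intersection: int
    n_kept: int
    n_swapped: int
    n_strand_flipped: int
    n_ambiguous_dropped: int
    n_mismatch_dropped: int


def merge_datasets(
    a: GenotypeDataset, b: GenotypeDataset
) -> tuple[GenotypeDataset, MergeReport]:
    """Merge two diploid datasets on the SNP-id intersection.

    Allele labels of ``b`` are harmonized to ``a`` by swapping (dosage
    recoded 2-d) and/or strand complementing.  Strand-ambiguous A/T and C/G
    SNPs and unresolvable allele mismatches are dropped.  SNP metadata
    (positions) is taken from ``a``.
    """
    if a.ploidy != 2 or b.ploidy != 2:
        raise ValueError("merge requires diploid datasets")
    dup = set(a.samples["sample_id"]) & set(b.samples["sample_id"])
    if dup:
        raise ConsistencyError(f"sample_id collision: {sorted(dup)[:5]}")

    b_pos = {sid: i for i, sid in enumerate(b.snps["snp_id"])}
    keep_a, keep_b, actions = [], [], []
    n_amb = n_mis = n_swap = n_flip = 0
    n_inter = 0
    for ia, row in enumerate(a.snps.itertuples(index=False)):
        ib = b_pos.get(row.snp_id)
        if ib is None:
            continue
        n_inter += 1
        a1, a2 = row.allele_ref, row.allele_alt
        if {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"}):
            n_amb += 1
            continue
        b1 = b.snps["allele_ref"].iat[ib]
        b2 = b.snps["allele_alt"].iat[ib]
        action = _resolve_alleles(a1, a2, b1, b2)
        if action is None:
            n_mis += 1
            continue
        swap, flip = action
        n_swap += swap
        n_flip += flip
        keep_a.append(ia)
        keep_b.append(ib)
        actions.append(swap)

    keep_a = np.array(keep_a, dtype=np.int64)
    keep_b = np.array(keep_b, dtype=np.int64)
    swaps = np.array(actions, dtype=bool)
    ga = a.genotypes[keep_a]
    gb = b.genotypes[keep_b]
    gb = gb.copy()
    if swaps.any():
        rows = gb[swaps]
        recoded = np.where(rows == MISSING, MISSING, 2 - rows).astype(np.int8)
        gb[swaps] = recoded
    geno = np.concatenate([ga, gb], axis=1)
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    merged = GenotypeDataset(a.snps.iloc[keep_a], samples, geno, ploidy=2)
    report = MergeReport(
        n_intersection=n_inter,
        n_kept=len(keep_a),
        n_swapped=int(n_swap),
        n_strand_flipped=int(n_flip),
        n_ambiguous_dropped=n_amb,
        n_mismatch_dropped=n_mis,
    )
    return merged, report


def _resolve_alleles(a1, a2, b1, b2):
    """Return (swap, strand_flipped) mapping b's labels onto a's, or None."""
    a1, a2, b1, b2 = a1.upper(), a2.upper(), b1.upper(), b2.upper()
    if (b1, b2) == (a1, a2):
        return (False, False)
    if (b1, b2) == (a2, a1):
        return (True, False)
    c1, c2 = _COMPLEMENT.get(b1), _COMPLEMENT.get(b2)
    if c1 is None or c2 is None:
        return None
    if (c1, c2) == (a1, a2):
        return (False, True)
    if (c1, c2) == (a2, a1):
        return (True, True)
    return None


# ---------------------------------------------------------------------------

def _snps_from_cm(bim: pd.DataFrame) -> pd.DataFrame:
    snps = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "snp_id": bim["snp_id"],
            "genetic_pos": bim["cm"].astype(float) / 100.0,
            "phys_pos": bim["phys_pos"].astype(np.int64),
            "allele_ref": bim["allele_ref"],
            "allele_alt": bim["allele_alt"],
        }
    )
    if len(snps) and (snps["genetic_pos"] == 0).all():
        warnings.warn("genetic map all zero; imputing 1 cM/Mb", stacklevel=3)
        snps["genetic_pos"] = snps["phys_pos"] / 1e8  # 1 cM/Mb in Morgans
    return snps
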