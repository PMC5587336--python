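"""Data-hygiene transforms: call-rate filtering, haploidization, chimeras.

Haploidization draws one allele per genotype, producing pseudo-haploid data
whose allele frequencies are unbiased even under clustered allelic drop-out
(a drop-out tract keeps one allele of the pair, and haploidization would
have picked either with equal probability anyway).

Chimeric pseudo-diploids stack two haploidized genomes of the same
population, restoring diploid-style statistics (runs of homozygosity,
expected heterozygosity) without drop-out bias, at the cost of halving
sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeDataset


@dataclass
class QcReport:
    snps_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: dict[str, int] = field(default_factory=dict)
    pairing: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "snps_removed": self.snps_removed,
            "samples_removed": self.samples_removed,
            "pairing": [list(p) for p in self.pairing],
            "notes": self.notes,
        }


class EmptyDatasetError(ValueError):
    pass


def filter_missingness(
    ds: GenotypeDataset, snp_call_rate: float = 0.9, ind_call_rate: float = 0.9
) -> tuple[GenotypeDataset, QcReport]:
    """Remove SNPs, then individuals, whose call rate falls below threshold.

    SNP filtering happens first; individual call rates are recomputed on the
    surviving SNPs, mirroring the usual two-pass order.
    """
    for t in (snp_call_rate, ind_call_rate):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    report = QcReport(notes=["order: SNPs filtered first, then individuals"])
    obs = ds.genotypes != MISSING
    snp_rate = obs.mean(axis=1) if ds.n_samples else np.ones(ds.n_snps)
    keep_snps = snp_rate >= snp_call_rate
    report.snps_removed["call_rate"] = int((~keep_snps).sum())
    ds2 = ds.subset_snps(keep_snps)
    obs2 = ds2.genotypes != MISSING
    ind_rate = obs2.mean(axis=0) if ds2.n_snps else np.ones(ds2.n_samples)
    keep_inds = ind_rate >= ind_call_rate
    report.samples_removed["call_rate"] = int((~keep_inds).sum())
    out = ds2.subset_samples(keep_inds)
    if out.n_snps == 0 or out.n_samples == 0:
        raise EmptyDatasetError("missingness filter removed all data")
    return out, report


def haploidize(ds: GenotypeDataset, seed: int | np.random.Generator = 0) -> GenotypeDataset:
    """Randomly pick one allele at each heterozygous genotype (ploidy 1).

    Dosage maps 0 -> 0, 2 -> 1, 1 -> Bernoulli(1/2), missing preserved.
    Frequency-preserving in expectation.
    """
    if ds.ploidy == 1:
        warnings.warn("dataset already haploid; haploidize is a no-op")
        return ds.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = ds.genotypes
    out = np.where(g == 2, 1, g).astype(np.int8)
    het = g == 1
    out[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    return GenotypeDataset(ds.snps.copy(), ds.samples.copy(), out, ploidy=1)


def make_chimeras(
    ds: GenotypeDataset, seed: int | np.random.Generator = 0
) -> tuple[GenotypeDataset, QcReport]:
    """Pair haploid genomes within each population into pseudo-diploids.

    Pairing is random without replacement (seeded); an odd sample is
    dropped, and populations of size 1 are dropped with a warning.  A
    chimera site with either haploid allele missing is set missing.
    """
    if ds.ploidy != 1:
        raise ValueError("make_chimeras needs haploid input; run haploidize first")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    report = QcReport()
    cols, rows = [], []
    dropped_odd = dropped_singleton = 0
    for pop in ds.populations:
        idx = ds.sample_indices(pop)
        if idx.size < 2:
            warnings.warn(f"population {pop!r} has <2 samples; dropped from chimeras")
            dropped_singleton += idx.size
            continue
        perm = rng.permutation(idx)
        if perm.size % 2:
            dropped_odd += 1
            perm = perm[:-1]
        for k in range(0, perm.size, 2):
            i, j = perm[k], perm[k + 1]
            sid_i = ds.samples["sample_id"].iat[i]
            sid_j = ds.samples["sample_id"].iat[j]
            report.pairing.append((sid_i, sid_j))
            a = ds.genotypes[:, i].astype(np.int16)
            b = ds.genotypes[:, j].astype(np.int16)
            dose = a + b
            dose[(a == MISSING) | (b == MISSING)] = MISSING
            cols.append(dose.astype(np.int8))
            rows.append({"sample_id": f"{sid_i}+{sid_j}", "population": pop})
    report.samples_removed["odd_unpaired"] = dropped_odd
    report.samples_removed["singleton_population"] = dropped_singleton
    if not cols:
        raise EmptyDatasetError("no population had >= 2 haploid samples")
    geno = np.column_stack(cols)
    out = GenotypeDataset(ds.snps.copy(), pd.DataFrame(rows), geno, ploidy=2)
    return out, report
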