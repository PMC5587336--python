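import numpy as np
import pandas as pd
import pytest

from admixkit.genio import GenotypeDataset


def make_dataset(
    genotypes,
    populations=None,
    ploidy=2,
    chrom=None,
    phys_pos=None,
    genetic_pos=None,
    alleles=None,
):
    """Small-fixture helper: build a GenotypeDataset from a dosage matrix."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_snps, n_samples = g.shape
    if populations is None:
        populations = ["P"] * n_samples
    if chrom is None:
        chrom = ["1"] * n_snps
    if phys_pos is None:
        phys_pos = np.arange(1, n_snps + 1) * 10_000
    if genetic_pos is None:
        genetic_pos = np.asarray(phys_pos) / 1e8
    if alleles is None:
        alleles = [("A", "G")] * n_snps
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "snp_id": [f"snp{i}" for i in range(n_snps)],
            "genetic_pos": genetic_pos,
            "phys_pos": phys_pos,
            "allele_ref": [a for a, _ in alleles],
            "allele_alt": [b for _, b in alleles],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n_samples)],
            "population": populations,
        }
    )
    return GenotypeDataset(snps, samples, g, ploidy=ploidy)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n_snps, n_samples, n_pops=2, missing_rate=0.0, n_chrom=1):
    """Random diploid dataset for round-trip and property tests."""
    g = rng.integers(0, 3, size=(n_snps, n_samples)).astype(np.int8)
    if missing_rate:
        g[rng.random(g.shape) < missing_rate] = -9
    pops = [f"pop{i % n_pops}" for i in range(n_samples)]
    chrom = [str(1 + (i * n_chrom) // max(n_snps, 1)) for i in range(n_snps)]
    allele_pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "A"), ("G", "T")]
    alleles = [allele_pairs[int(rng.integers(len(allele_pairs)))] for _ in range(n_snps)]
    return make_dataset(g, populations=pops, chrom=chrom, alleles=alleles)
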