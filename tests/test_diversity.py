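"""Heterozygosity, ROH detection, and rarefaction against exhaustive oracles."""

import itertools

import numpy as np
import pytest

from admixkit import diversity, qc, simpop
from admixkit.diversity import (
    AlleleCounts,
    RohParams,
    allele_counts_from_dataset,
    detect_roh,
    observed_heterozygosity,
    rarefied_allelic_richness,
    rarefied_private_richness,
    rarefied_shared_private,
    roh_summary,
    snps_to_haplotypes,
)
from admixkit.genio import MISSING

from conftest import make_dataset


# ---------------------------------------------------------------------------
# exhaustive subset-enumeration oracle for the rarefaction statistics
# ---------------------------------------------------------------------------

def enumerate_adze(counts, g, focal, others):
    """Average over all C(N, g) subsets per population of the exact statistic.

    counts: (n_alleles, n_pops) for ONE locus.  focal: tuple of population
    indices whose subsets must contain the allele; others must miss it.
    """
    n_alleles, n_pops = counts.shape
    pools = []
    for k in range(n_pops):
        pool = []
        for a in range(n_alleles):
            pool += [a] * counts[a, k]
        pools.append(pool)
    total = 0.0
    combos = [list(itertools.combinations(pool, g)) for pool in pools]
    n_combo = [len(c) for c in combos]
    for a in range(n_alleles):
        p_present = []
        for k in range(n_pops):
            present = sum(1 for c in combos[k] if a in c)
            p_present.append(present / n_combo[k])
        term = 1.0
        for k in focal:
            term *= p_present[k]
        for k in others:
            term *= 1 - p_present[k]
        total += term
    return total


class TestRarefaction:
    def test_g1_richness_is_one(self, rng):
        counts = AlleleCounts(
            ["A", "B"], rng.integers(0, 5, size=(30, 4, 2)) + np.array([[1], [0], [0], [0]])
        )
        curve = rarefied_allelic_richness(counts, "A", 1)
        assert curve.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_biallelic_enumeration_example(self):
        # one locus, pop counts 2/2 of each allele (N=4), g=2
        counts = AlleleCounts(["A"], np.array([[[2], [2]]]))
        curve = rarefied_allelic_richness(counts, "A", 2)
        # P(allele seen in 2 draws) = 1 - C(2,2)/C(4,2) = 5/6 per allele
        assert curve.values[1] == pytest.approx(2 * (5 / 6), abs=1e-12)

    def test_exhaustive_equivalence_all_statistics(self, rng):
        # random loci with total counts <= 12 per pop: exact equality
        for trial in range(8):
            k_alleles = int(rng.integers(2, 5))
            counts1 = rng.multinomial(int(rng.integers(4, 13)), np.ones(k_alleles) / k_alleles)
            counts2 = rng.multinomial(int(rng.integers(4, 13)), np.ones(k_alleles) / k_alleles)
            counts3 = rng.multinomial(int(rng.integers(4, 13)), np.ones(k_alleles) / k_alleles)
            locus = np.stack([counts1, counts2, counts3], axis=1)
            ac = AlleleCounts(["A", "B", "C"], locus[None])
            g = int(rng.integers(1, min(counts1.sum(), counts2.sum(), counts3.sum()) + 1))
            rich = rarefied_allelic_richness(ac, "A", g).values[g - 1]
            assert rich == pytest.approx(enumerate_adze(locus, g, (0,), ()), abs=1e-12)
            priv = rarefied_private_richness(ac, "A", g).values[g - 1]
            assert priv == pytest.approx(enumerate_adze(locus, g, (0,), (1, 2)), abs=1e-12)
            sp = rarefied_shared_private(ac, "A", "B", g).values[g - 1]
            assert sp == pytest.approx(enumerate_adze(locus, g, (0, 1), (2,)), abs=1e-12)

    def test_private_absent_elsewhere_factorization(self):
        # allele only in pop 0 (count 3 of 20): private = presence prob exactly
        locus = np.array([[3, 0, 0], [17, 20, 20]])
        ac = AlleleCounts(["A", "B", "C"], locus[None])
        g = 10
        priv = rarefied_private_richness(ac, "A", g).values[g - 1]
        # presence of the pop-A-only allele plus cross terms from the shared allele
        q_shared_elsewhere = 0.0  # allele 1 fixed elsewhere: Q = 0 for g >= 1
        p_focal_allele0 = 1.0
        for t in range(g):
            p_focal_allele0 *= (17 - t) / (20 - t)
        p_focal_allele0 = 1 - p_focal_allele0
        assert priv == pytest.approx(p_focal_allele0, abs=1e-12)

    def test_richness_monotone_in_g(self, rng):
        for _ in range(20):
            loci = rng.integers(0, 6, size=(40, 3, 2))
            loci[:, 0, :] += 1
            ac = AlleleCounts(["A", "B"], loci)
            curve = rarefied_allelic_richness(ac, "A", 6)
            assert (np.diff(curve.values) >= -1e-12).all()

    def test_private_richness_can_decrease(self):
        # not a bug: presence in the focal population saturates while the
        # chance other populations miss a shared allele keeps falling, so the
        # product can decline; the exhaustive oracle shows the same decline
        locus = np.array([[6, 1, 1], [2, 7, 7]])  # allele 0 common in A, rare elsewhere
        ac = AlleleCounts(["A", "B", "C"], locus[None])
        curve = rarefied_private_richness(ac, "A", 8)
        assert curve.values[7] < curve.values[3]
        for g in (4, 8):
            assert curve.values[g - 1] == pytest.approx(
                enumerate_adze(locus, g, (0,), (1, 2)), abs=1e-12
            )

    def test_invalid_g_rejected(self):
        ac = AlleleCounts(["A"], np.ones((1, 2, 1), dtype=int))
        with pytest.raises(ValueError):
            rarefied_allelic_richness(ac, "A", 0)


class TestHeterozygosity:
    def test_all_homozygous_zero(self):
        ds = make_dataset([[0, 2], [2, 0]])
        per_ind, per_pop = observed_heterozygosity(ds)
        assert (per_ind["het_obs"] == 0).all()

    def test_hwe_simulation(self, rng):
        g = rng.binomial(2, 0.5, size=(5000, 20)).astype(np.int8)
        _, per_pop = observed_heterozygosity(make_dataset(g))
        se = np.sqrt(0.5 * 0.5 / (5000 * 20))
        assert abs(per_pop["het_obs_mean"][0] - 0.5) < 3 * se

    def test_haploid_input_directed_to_chimeras(self):
        with pytest.raises(ValueError, match="chimeras"):
            observed_heterozygosity(make_dataset([[0, 1]], ploidy=1))

    def test_dropout_bias_vs_chimeric_rescue(self, rng):
        # naive observed het shrinks by the drop-out rate; the chimeric
        # pipeline's expected het stays unbiased
        rate = 0.2
        n_snps, n_ind = 8000, 40
        p = rng.uniform(0.3, 0.7, n_snps)
        g = rng.binomial(2, p[:, None], size=(n_snps, n_ind)).astype(np.int8)
        ds = simpop.apply_dropout(make_dataset(g), rate, 2e6, rng)
        truth = float(np.mean(2 * p * (1 - p)))
        _, naive = observed_heterozygosity(ds)
        chim, _ = qc.make_chimeras(qc.haploidize(ds, 3), 3)
        _, rescued = observed_heterozygosity(chim)
        assert naive["het_obs_mean"][0] == pytest.approx(truth * (1 - rate), rel=0.10)
        assert rescued["het_exp"][0] == pytest.approx(truth, rel=0.02)


class TestRoh:
    def _planted(self, rng, tract_bp, spacing=10_000, n_snps=3000, het_rate=0.5):
        pos = np.arange(1, n_snps + 1) * spacing
        col = rng.choice([0, 1, 2], size=n_snps, p=[0.25, 0.5, 0.25]).astype(np.int8)
        start = n_snps // 3
        n_tract = tract_bp // spacing
        col[start : start + n_tract] = rng.choice([0, 2], size=n_tract).astype(np.int8)
        ds = make_dataset(col[:, None], phys_pos=pos)
        return ds, (pos[start], pos[start + n_tract - 1])

    def test_fully_heterozygous_no_segments(self):
        ds = make_dataset(np.ones((2000, 1), dtype=np.int8),
                          phys_pos=np.arange(1, 2001) * 10_000)
        assert detect_roh(ds) == []

    def test_planted_two_mb_tract_recovered(self, rng):
        ds, (t0, t1) = self._planted(rng, 2_000_000)
        segs = detect_roh(ds)
        assert len(segs) == 1
        s = segs[0]
        overlap = min(s.end_bp, t1) - max(s.start_bp, t0) + 1
        assert overlap / (t1 - t0 + 1) >= 0.95

    def test_short_tract_not_called(self, rng):
        ds, _ = self._planted(rng, 100_000)
        assert detect_roh(ds) == []

    def test_unsorted_positions_rejected(self, rng):
        ds, _ = self._planted(rng, 2_000_000)
        ds.snps.loc[5, "phys_pos"] = 10**9
        with pytest.raises(ValueError, match="unsorted"):
            detect_roh(ds)

    def test_allele_relabel_invariance(self, rng):
        ds, _ = self._planted(rng, 2_000_000)
        flipped = ds.copy()
        flipped.genotypes = np.where(
            flipped.genotypes == MISSING, MISSING, 2 - flipped.genotypes
        ).astype(np.int8)
        s1 = [(s.start_bp, s.end_bp) for s in detect_roh(ds)]
        s2 = [(s.start_bp, s.end_bp) for s in detect_roh(flipped)]
        assert s1 == s2

    def test_summary_bins(self):
        segs = [
            diversity.RohSegment("x", "1", 1, 750_000, 80),
            diversity.RohSegment("x", "2", 1, 3_000_000, 200),
        ]
        out = roh_summary(segs, ["x", "y"])
        row_x = out[out["sample_id"] == "x"].iloc[0]
        assert row_x["0.5-1Mb"] == pytest.approx(0.75)
        assert row_x["2-4Mb"] == pytest.approx(3.0)
        assert out[out["sample_id"] == "y"].iloc[0][1:].sum() == 0

    def test_summary_matches_recount(self, rng):
        segs = []
        for i in range(50):
            ln = int(rng.integers(500_000, 10_000_000))
            segs.append(diversity.RohSegment("s", "1", 1, ln, 100))
        out = roh_summary(segs, ["s"])
        total = out.iloc[0, 1:].sum()
        assert total == pytest.approx(sum(s.length_bp / 1e6 for s in segs), rel=1e-9)


class TestHaplotypeLoci:
    def test_monomorphic_window_single_allele(self):
        g = np.zeros((5, 4), dtype=np.int8)
        ac = snps_to_haplotypes(make_dataset(g, ploidy=1))
        assert ac.n_loci == 1
        assert (ac.counts[0].sum(axis=0) == 4).all()
        assert (ac.counts[0] > 0).sum() == 1  # one distinct allele

    def test_one_snp_difference_two_alleles(self):
        g = np.zeros((5, 2), dtype=np.int8)
        g[2, 1] = 1
        ac = snps_to_haplotypes(make_dataset(g, ploidy=1))
        assert (ac.counts[0].sum(axis=1) > 0).sum() == 2

    def test_diploid_rejected(self):
        with pytest.raises(ValueError, match="haploid"):
            snps_to_haplotypes(make_dataset(np.zeros((5, 2), dtype=np.int8)))

    def test_missing_haplotypes_dropped(self):
        g = np.zeros((5, 3), dtype=np.int8)
        g[1, 0] = MISSING
        ac = snps_to_haplotypes(make_dataset(g, ploidy=1))
        assert ac.counts[0].sum() == 2

    def test_rank_correlation_with_snp_richness(self, rng):
        # populations with graded diversity: SNP-based and haplotype-based
        # rarefied richness should rank them the same way
        from scipy.stats import spearmanr

        n_pops, n_per, n_snps = 8, 12, 600
        freqs, genos, labels = [], [], []
        for k in range(n_pops):
            F = 0.02 + 0.06 * k / (n_pops - 1)
            p = simpop.simulate_branch_freqs(rng.uniform(0.1, 0.9, n_snps), F, rng)
            genos.append(rng.binomial(1, p[:, None], size=(n_snps, n_per)).astype(np.int8))
            labels += [f"P{k}"] * n_per
        ds = make_dataset(np.hstack(genos), populations=labels, ploidy=1)
        snp_counts = allele_counts_from_dataset(ds)
        hap_counts = snps_to_haplotypes(ds)
        g = 10
        snp_rich = [
            rarefied_allelic_richness(snp_counts, f"P{k}", g).values[-1]
            for k in range(n_pops)
        ]
        hap_rich = [
            rarefied_allelic_richness(hap_counts, f"P{k}", g).values[-1]
            for k in range(n_pops)
        ]
        rho = spearmanr(snp_rich, hap_rich).statistic
        assert rho > 0.8
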