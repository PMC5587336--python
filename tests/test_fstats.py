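"""f-statistics against direct-summation oracles and their algebraic identities."""

import numpy as np
import pandas as pd
import pytest

from admixkit import fstats, simpop
from admixkit.fstats import (
    InsufficientDataError,
    block_jackknife,
    block_partition,
    compute_d,
    compute_f2,
    compute_f3,
    compute_f4,
    compute_f4_ratio,
)
from admixkit.genio import FrequencyTable

from conftest import make_dataset


def freq_table(p, n, n_blocks=5, het=None):
    """FrequencyTable fixture from explicit per-pop frequency columns."""
    p = np.asarray(p, dtype=float)
    n_arr = np.full(p.shape, n, dtype=np.int64)
    het_arr = np.full(p.shape, np.nan) if het is None else np.asarray(het)
    pops = [f"P{i}" for i in range(p.shape[1])]
    n_snps = p.shape[0]
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "genetic_pos": np.linspace(0, 0.05 * n_blocks, n_snps, endpoint=False),
            "phys_pos": np.arange(1, n_snps + 1),
            "allele_ref": "A",
            "allele_alt": "G",
        }
    )
    return FrequencyTable(pops, p, n_arr, het_arr, snps)


def jackknife_oracle(vals, blocks):
    """Direct enumeration of the weighted delete-one-block jackknife."""
    nb = blocks.max() + 1
    sums = np.array([vals[blocks == b].sum() for b in range(nb)])
    cnts = np.array([(blocks == b).sum() for b in range(nb)])
    est = vals.mean()
    loo = np.array([(sums.sum() - sums[b]) / (cnts.sum() - cnts[b]) for b in range(nb)])
    n, g = cnts.sum(), nb
    h = n / cnts
    theta_j = g * est - ((1 - cnts / n) * loo).sum()
    tau = h * est - (h - 1) * loo
    var = np.mean((tau - theta_j) ** 2 / (h - 1))
    return est, np.sqrt(var)


class TestBlocks:
    def test_partition_contiguous_and_complete(self, rng):
        n = 1000
        snps = pd.DataFrame(
            {
                "chrom": ["1"] * 600 + ["2"] * 400,
                "snp_id": [f"s{i}" for i in range(n)],
                "genetic_pos": np.concatenate(
                    [np.linspace(0, 1, 600), np.linspace(0, 0.6, 400)]
                ),
                "phys_pos": np.arange(1, n + 1),
                "allele_ref": "A",
                "allele_alt": "G",
            }
        )
        blocks = block_partition(snps, block_cm=5.0)
        assert blocks.min() == 0
        # contiguity: block ids are non-decreasing along the map
        assert (np.diff(blocks) >= 0).all()
        assert len(np.unique(blocks)) == blocks.max() + 1

    def test_identical_blocks_zero_se(self):
        sums = np.full(10, 3.0)
        cnts = np.full(10, 7.0)
        est, se = block_jackknife(sums, cnts)
        assert est == pytest.approx(3 / 7)
        assert se == pytest.approx(0, abs=1e-12)

    def test_jackknife_matches_enumeration_with_outlier(self, rng):
        vals = rng.normal(size=200)
        vals[:10] += 5.0  # outlier block
        blocks = np.repeat(np.arange(10), 20)
        sums = np.bincount(blocks, weights=vals)
        cnts = np.bincount(blocks).astype(float)
        est, se = block_jackknife(sums, cnts)
        est_o, se_o = jackknife_oracle(vals, blocks)
        assert est == pytest.approx(est_o, abs=1e-12)
        assert se == pytest.approx(se_o, rel=1e-10)

    def test_jackknife_se_near_clt(self, rng):
        ratios = []
        for _ in range(200):
            vals = rng.normal(size=400)
            blocks = np.repeat(np.arange(20), 20)
            sums = np.bincount(blocks, weights=vals)
            _, se = block_jackknife(sums, np.bincount(blocks).astype(float))
            ratios.append(se / (vals.std(ddof=1) / np.sqrt(vals.size)))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_single_block_rejected(self):
        with pytest.raises(InsufficientDataError):
            block_jackknife(np.array([1.0]), np.array([5.0]))


class TestDirectSummationOracle:
    """10-SNP fixtures: statistics equal brute-force per-SNP formulas."""

    @pytest.fixture
    def table(self, rng):
        p = rng.uniform(0.05, 0.95, size=(10, 4))
        return freq_table(p, n=20, n_blocks=2)

    def test_f2_uncorrected(self, table):
        p = table.p
        expect = np.mean((p[:, 0] - p[:, 1]) ** 2)
        r = compute_f2(table, "P0", "P1", corrected=False)
        assert r.estimate == pytest.approx(expect, abs=1e-14)

    def test_f2_corrected(self, table):
        p, n = table.p, 20
        h = p * (1 - p) * n / (n - 1)
        expect = np.mean((p[:, 0] - p[:, 1]) ** 2 - h[:, 0] / n - h[:, 1] / n)
        r = compute_f2(table, "P0", "P1", corrected=True)
        assert r.estimate == pytest.approx(expect, abs=1e-14)

    def test_f3_corrected(self, table):
        p, n = table.p, 20
        hx = p[:, 0] * (1 - p[:, 0]) * n / (n - 1)
        expect = np.mean((p[:, 0] - p[:, 1]) * (p[:, 0] - p[:, 2]) - hx / n)
        r = compute_f3(table, "P0", "P1", "P2")
        assert r.estimate == pytest.approx(expect, abs=1e-14)

    def test_f4(self, table):
        p = table.p
        expect = np.mean((p[:, 0] - p[:, 1]) * (p[:, 2] - p[:, 3]))
        r = compute_f4(table, "P0", "P1", "P2", "P3")
        assert r.estimate == pytest.approx(expect, abs=1e-14)

    def test_d(self, table):
        p = table.p
        num = (p[:, 0] - p[:, 1]) * (p[:, 2] - p[:, 3])
        den = (p[:, 0] + p[:, 1] - 2 * p[:, 0] * p[:, 1]) * (
            p[:, 2] + p[:, 3] - 2 * p[:, 2] * p[:, 3]
        )
        r = compute_d(table, "P0", "P1", "P2", "P3")
        assert r.estimate == pytest.approx(num.sum() / den.sum(), abs=1e-14)


class TestF2:
    def test_duplicate_population_is_zero(self, rng):
        # a population against a copy of itself: uncorrected f2 = 0 exactly
        p = rng.uniform(0.2, 0.8, size=(50, 1))
        table = freq_table(np.hstack([p, p]), n=30)
        r = compute_f2(table, "P0", "P1", corrected=False)
        assert r.estimate == 0.0

    def test_corrected_f2_unbiased_on_resampled_pop(self, rng):
        # two samples from the SAME population: corrected f2 ~ 0
        p_true = rng.uniform(0.2, 0.8, 20_000)
        t = []
        for _ in range(2):
            t.append(rng.binomial(40, p_true) / 40)
        table = freq_table(np.column_stack(t), n=40)
        r = compute_f2(table, "P0", "P1")
        assert abs(r.estimate) < 4 * r.se
        assert abs(r.estimate) < 2e-4

    def test_f2_drift_moments(self, rng):
        F = 0.05
        p_anc = rng.uniform(0.05, 0.95, 50_000)
        pa = simpop.simulate_branch_freqs(p_anc, F, rng)
        pb = simpop.simulate_branch_freqs(p_anc, F, rng)
        table = freq_table(np.column_stack([pa, pb]), n=10_000)
        expect = np.mean(2 * F * p_anc * (1 - p_anc))
        r = compute_f2(table, "P0", "P1")
        assert r.estimate == pytest.approx(expect, rel=0.10)


class TestF3:
    def test_admixture_signal_negative_z(self, rng):
        F = 0.1
        p_anc = rng.uniform(0.05, 0.95, 50_000)
        pa = simpop.simulate_branch_freqs(p_anc, F, rng)
        pb = simpop.simulate_branch_freqs(p_anc, F, rng)
        px_true = 0.5 * pa + 0.5 * pb
        n = 50
        p = np.column_stack(
            [
                rng.binomial(2 * n, px_true) / (2 * n),
                rng.binomial(2 * n, pa) / (2 * n),
                rng.binomial(2 * n, pb) / (2 * n),
            ]
        )
        r = compute_f3(freq_table(p, n=2 * n, n_blocks=20), "P0", "P1", "P2")
        assert r.estimate < 0 and r.z < -3

    def test_source_symmetry_exact(self, rng):
        p = rng.uniform(0.1, 0.9, size=(100, 3))
        t = freq_table(p, n=20)
        assert compute_f3(t, "P0", "P1", "P2").estimate == compute_f3(t, "P0", "P2", "P1").estimate

    def test_degenerate_target_bounded(self, rng):
        # X == A: f3 = E[(pX-pX)(pX-pB)] = 0 uncorrected
        p = rng.uniform(0.1, 0.9, size=(50, 2))
        t = freq_table(np.column_stack([p[:, 0], p[:, 0], p[:, 1]]), n=30)
        r = compute_f3(t, "P0", "P1", "P2", corrected=False)
        assert r.estimate == 0.0

    def test_normalized_variant_scales(self, rng):
        p = rng.uniform(0.1, 0.9, size=(200, 3))
        t = freq_table(p, n=40)
        plain = compute_f3(t, "P0", "P1", "P2")
        norm = compute_f3(t, "P0", "P1", "P2", normalized=True)
        assert np.sign(plain.estimate) == np.sign(norm.estimate)
        assert norm.statistic == "f3n"


class TestF4D:
    def test_equal_right_pair_zero(self, rng):
        p = rng.uniform(0.1, 0.9, size=(50, 3))
        t = freq_table(np.column_stack([p[:, 0], p[:, 1], p[:, 2], p[:, 2]]), n=20)
        assert compute_f4(t, "P0", "P1", "P2", "P3").estimate == 0.0
        assert compute_d(t, "P0", "P1", "P2", "P3").estimate == 0.0

    def test_antisymmetry_exact(self, rng):
        p = rng.uniform(0.1, 0.9, size=(80, 4))
        t = freq_table(p, n=20)
        base = compute_f4(t, "P0", "P1", "P2", "P3").estimate
        assert compute_f4(t, "P1", "P0", "P2", "P3").estimate == -base
        assert compute_f4(t, "P0", "P1", "P3", "P2").estimate == -base

    def test_additivity_identity(self, rng):
        p = rng.uniform(0.1, 0.9, size=(80, 5))
        t = freq_table(p, n=20)
        lhs = compute_f4(t, "P0", "P1", "P2", "P4").estimate
        rhs = (
            compute_f4(t, "P0", "P1", "P2", "P3").estimate
            + compute_f4(t, "P0", "P1", "P3", "P4").estimate
        )
        assert lhs == pytest.approx(rhs, abs=1e-15)

    def test_d_pair_exchange_symmetry(self, rng):
        p = rng.uniform(0.1, 0.9, size=(80, 4))
        t = freq_table(p, n=20)
        assert (
            compute_d(t, "P0", "P1", "P2", "P3").estimate
            == compute_d(t, "P2", "P3", "P0", "P1").estimate
        )

    def test_allele_flip_invariance(self, rng):
        p = rng.uniform(0.1, 0.9, size=(80, 4))
        t1, t2 = freq_table(p, n=20), freq_table(1 - p, n=20)
        for fn in (compute_f4, compute_d):
            assert fn(t1, "P0", "P1", "P2", "P3").estimate == pytest.approx(
                fn(t2, "P0", "P1", "P2", "P3").estimate, abs=1e-14
            )
        assert compute_f2(t1, "P0", "P1", corrected=False).estimate == pytest.approx(
            compute_f2(t2, "P0", "P1", corrected=False).estimate, abs=1e-14
        )


class TestF4Ratio:
    def test_target_equals_unadmixed_reference(self, rng):
        import warnings

        p = rng.uniform(0.1, 0.9, size=(100, 4))
        # pops: P0,P1 outgroups; P2 = Mota-like; P3 = LBK-like; target == P2
        t = freq_table(p, n=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # toy denominator is weak
            r = compute_f4_ratio(t, ("P0", "P1", "P2", "P3"), ("P0", "P1", "P2", "P3"))
            assert r.estimate == 1.0
            r0 = compute_f4_ratio(t, ("P0", "P1", "P3", "P3"), ("P0", "P1", "P2", "P3"))
            assert r0.estimate == 0.0

    def test_alpha_recovery_single(self, rng):
        from admixkit.presets import f4ratio_freq_tables

        alpha = 0.45
        t = f4ratio_freq_tables(alpha, rng, n_snps=50_000)
        r = compute_f4_ratio(t, ("CHB", "GBR", "Target", "LBK"), ("CHB", "GBR", "Mota", "LBK"))
        assert 1 - r.estimate == pytest.approx(alpha, abs=2 * r.se)


class TestBatch:
    def test_run_batch_tsv(self, rng, tmp_path):
        g = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        pops = ["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5
        # map long enough for several 5 cM jackknife blocks
        ds = make_dataset(g, populations=pops, phys_pos=np.arange(1, 201) * 1_000_000)
        req = tmp_path / "req.tsv"
        req.write_text(
            "statistic\tpop1\tpop2\tpop3\tpop4\n"
            "f2\tA\tB\t\t\n"
            "f3\tA\tB\tC\t\n"
            "d\tA\tB\tC\tD\n"
        )
        out = fstats.run_batch(ds, str(req))
        assert list(out["statistic"]) == ["f2", "f3", "D"]
        assert (out["n_snps"] > 0).all()
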