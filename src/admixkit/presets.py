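"""Ready-made synthetic scenarios mirroring the study designs this package
targets: an admixed Nile-valley-like population with a known Eurasian
fraction and admixture date, plus null scenarios for calibration.

Population labels follow the proxy roles of the real analyses: two eastern
and western Eurasian outgroups (CHB-like, GBR-like), an ancient Eurasian
(LBK-like), an ancient unadmixed East African (Mota-like), a Nilotic base
population (Nuer-like), a Eurasian donor (TSI-like), and an admixed target.
Drift values are chosen to give differentiation on the order of what SNP
arrays show between these groups (FST of a few percent).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genio import FrequencyTable, GenotypeDataset
from .simpop import AdmixtureEvent, PopulationSpec, SimConfig, simulate_dataset

# shared internal branches make f4(CHB,GBR; *, LBK) informative
F4_TREE = {
    "EUR": {
        "F": 0.05,
        "children": {
            "CHB": {"F": 0.03},
            "WEUR": {
                "F": 0.03,
                "children": {
                    "GBR": {"F": 0.01},
                    "LBK": {"F": 0.02},
                    "TSI": {"F": 0.01},
                },
            },
        },
    },
    "AFR": {
        "F": 0.03,
        "children": {
            "Mota": {"F": 0.03},
            "Nuer": {"F": 0.01},
        },
    },
}


def f4ratio_config(
    alpha: float,
    seed: int,
    n_snps: int = 50_000,
    gens_ago: float = 30.0,
    n_target: int = 20,
    n_other: int = 20,
) -> SimConfig:
    """Admixed target = alpha x TSI-like + (1 - alpha) x Nuer-like.

    The f4-ratio f4(CHB,GBR;Target,LBK) / f4(CHB,GBR;Mota,LBK) then
    estimates the Nuer-like (African) proportion 1 - alpha, so the Eurasian
    fraction is 1 minus the ratio.
    """
    pops = [
        PopulationSpec(nm, size_n=n_other)
        for nm in ("CHB", "GBR", "LBK", "TSI", "Mota", "Nuer")
    ] + [PopulationSpec("Target", size_n=n_target)]
    return SimConfig(
        populations=pops,
        events=[AdmixtureEvent("Target", "TSI", "Nuer", alpha, gens_ago)],
        tree=F4_TREE,
        n_snps=n_snps,
        n_chrom=1,
        chrom_length=max(1.0, n_snps / 10_000),
        seed=seed,
    )


def dating_config(
    alpha: float,
    gens_ago: float,
    seed: int,
    n_chrom: int = 8,
    n_snps: int = 4_000,
    n_target: int = 30,
    n_ref: int = 30,
    drift_ref: float = 0.1,
) -> SimConfig:
    """LD-dating scenario: target admixed between two well-separated refs."""
    pops = [
        PopulationSpec("RefA", drift_F=drift_ref, size_n=n_ref),
        PopulationSpec("RefB", drift_F=drift_ref, size_n=n_ref),
        PopulationSpec("Target", size_n=n_target),
    ]
    return SimConfig(
        populations=pops,
        events=[AdmixtureEvent("Target", "RefA", "RefB", alpha, gens_ago)],
        n_snps=n_snps,
        n_chrom=n_chrom,
        chrom_length=1.0,
        seed=seed,
    )


def null_dating_config(
    seed: int,
    n_chrom: int = 8,
    n_snps: int = 4_000,
    n_target: int = 30,
    n_ref: int = 30,
    drift_ref: float = 0.1,
) -> SimConfig:
    """As :func:`dating_config` but the target never admixed (drift sibling)."""
    pops = [
        PopulationSpec("RefA", drift_F=drift_ref, size_n=n_ref),
        PopulationSpec("RefB", drift_F=drift_ref, size_n=n_ref),
        PopulationSpec("Target", drift_F=0.02, size_n=n_target),
    ]
    return SimConfig(
        populations=pops, n_snps=n_snps, n_chrom=n_chrom, chrom_length=1.0, seed=seed
    )


# ---------------------------------------------------------------------------
# fast frequency-level simulation for calibration loops
# ---------------------------------------------------------------------------

def _snp_frame(n_snps: int, n_blocks: int) -> pd.DataFrame:
    # evenly spaced map so 5 cM blocks give exactly n_blocks blocks
    gpos = np.linspace(0, 0.05 * n_blocks, n_snps, endpoint=False)
    return pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "genetic_pos": gpos,
            "phys_pos": np.arange(1, n_snps + 1) * 1000,
            "allele_ref": "A",
            "allele_alt": "G",
        }
    )


def sample_freq_table(
    pop_freqs: dict[str, np.ndarray],
    n_diploid: int,
    rng: np.random.Generator,
    n_blocks: int = 20,
) -> FrequencyTable:
    """Binomial sampling noise on true frequencies, as a FrequencyTable.

    Equivalent to simulating 2 n_diploid allele copies per population and
    taking sample frequencies — the fast path for calibration loops where
    only frequencies (not genotypes) enter the statistic.
    """
    pops = list(pop_freqs)
    n_snps = len(next(iter(pop_freqs.values())))
    p = np.empty((n_snps, len(pops)))
    n = np.full((n_snps, len(pops)), 2 * n_diploid, dtype=np.int64)
    for j, pop in enumerate(pops):
        counts = rng.binomial(2 * n_diploid, pop_freqs[pop])
        p[:, j] = counts / (2 * n_diploid)
    het = np.full_like(p, np.nan)
    return FrequencyTable(pops, p, n, het, _snp_frame(n_snps, n_blocks))


def dstat_null_freq_table(
    seed: int | np.random.Generator,
    n_snps: int = 20_000,
    n_diploid: int = 10,
    n_blocks: int = 20,
    f_internal: float = 0.05,
    f_leaf: float = 0.02,
) -> FrequencyTable:
    """Tree ((A,B),(C,D)) with no gene flow: E[D(A,B;C,D)] = 0."""
    from .simpop import drift_tree_freqs

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, n_snps)
    tree = {
        "AB": {"F": f_internal, "children": {"A": {"F": f_leaf}, "B": {"F": f_leaf}}},
        "CD": {"F": f_internal, "children": {"C": {"F": f_leaf}, "D": {"F": f_leaf}}},
    }
    freqs = drift_tree_freqs(p_anc, tree, rng)
    return sample_freq_table(freqs, n_diploid, rng, n_blocks)


def f4ratio_freq_tables(
    alpha: float,
    seed: int | np.random.Generator,
    n_snps: int = 50_000,
    n_diploid: int = 20,
    n_blocks: int = 40,
) -> FrequencyTable:
    """Frequency-level version of :func:`f4ratio_config` for replicate loops."""
    from .simpop import drift_tree_freqs

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, n_snps)
    freqs = drift_tree_freqs(p_anc, F4_TREE, rng)
    freqs["Target"] = alpha * freqs["TSI"] + (1 - alpha) * freqs["Nuer"]
    return sample_freq_table(freqs, n_diploid, rng, n_blocks)
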