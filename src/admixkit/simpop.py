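"""Synthetic multi-population genotype data with known truth.

Population divergence is modelled with Balding-Nichols beta drift: a branch
that accumulates differentiation F transforms an ancestral frequency p into
a draw from Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
F p(1-p).  Closed-form moments make downstream oracles exact, which is why
this model is used instead of generation-by-generation Wright-Fisher.

Admixture g generations ago with proportion alpha is simulated directly at
the haplotype level: each haplotype is a mosaic of ancestry tracts whose
breakpoints follow a Poisson process of rate g per Morgan, each tract drawn
from source 1 with probability alpha.  The resulting ancestry autocovariance
at genetic distance d decays as exp(-g d) and the mean ancestry fraction is
alpha — exactly the admixture-LD signal the dating module estimates.

Ancestral frequencies default to Uniform(0.05, 0.95), a crude emulation of
SNP-array ascertainment toward common variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genio import MISSING, GenotypeDataset


@dataclass
class PopulationSpec:
    """A sampled population: branch drift F (Balding-Nichols) and sample size."""

    name: str
    drift_F: float = 0.0
    size_n: int = 10

    def __post_init__(self):
        if not 0 <= self.drift_F < 1:
            raise ValueError("drift_F must be in [0, 1)")
        if self.size_n < 1:
            raise ValueError("size_n must be >= 1")


@dataclass
class AdmixtureEvent:
    """Target formed g generations ago as alpha:source1 + (1-alpha):source2."""

    target: str
    source1: str
    source2: str
    alpha: float
    gens_ago: float

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.gens_ago < 1:
            raise ValueError("gens_ago must be >= 1 (use a plain mixture for g=0)")
        if self.source1 == self.source2:
            raise ValueError("sources must differ")
        if self.target in (self.source1, self.source2):
            raise ValueError("target cannot be one of its own sources")


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset; seed fixes the output.

    ``tree``, when given, replaces the flat star phylogeny: it is a nested
    mapping ``{node: {"F": branch_F, "children": {...}}}`` whose leaves are
    population names.  f4-style statistics need shared internal branches,
    which a star phylogeny cannot produce.
    """

    populations: list[PopulationSpec]
    events: list[AdmixtureEvent] = field(default_factory=list)
    tree: dict | None = None
    n_snps: int = 5000  # per chromosome
    n_chrom: int = 2
    chrom_length: float = 1.0  # Morgans
    freq_low: float = 0.05
    freq_high: float = 0.95
    missing_rate: float = 0.0
    dropout_rate: float = 0.0
    dropout_tract_bp: float = 2_000_000.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.missing_rate, self.dropout_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for ev in self.events:
            for nm in (ev.target, ev.source1, ev.source2):
                if nm not in names:
                    raise ValueError(f"unknown population {nm!r} in event")

    @property
    def admixed_targets(self) -> set[str]:
        return {ev.target for ev in self.events}

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pops = [PopulationSpec(**p) for p in raw.pop("populations")]
        events = [AdmixtureEvent(**e) for e in raw.pop("events", [])]
        return cls(populations=pops, events=events, **raw)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def simulate_branch_freqs(
    p_anc: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Drift ancestral frequencies down a branch of Balding-Nichols F.

    Identity when F == 0; otherwise Beta draws with mean p and variance
    F p (1-p).
    """
    if not 0 <= F < 1:
        raise ValueError("F must be in [0, 1)")
    p_anc = np.asarray(p_anc, dtype=float)
    if np.any(p_anc <= 0) or np.any(p_anc >= 1):
        raise ValueError("ancestral frequencies must be strictly inside (0, 1)")
    if F == 0:
        return p_anc.copy()
    scale = (1 - F) / F
    return rng.beta(p_anc * scale, (1 - p_anc) * scale)


def drift_tree_freqs(
    p_anc: np.ndarray, tree: dict, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Drift frequencies down a nested branch tree.

    ``tree`` maps node name -> {"F": branch differentiation, "children":
    nested mapping (absent for leaves)}.  Returns leaf-name -> frequency
    vector.  Traversal order is the mapping order, so the same seed gives
    the same draws.
    """
    out: dict[str, np.ndarray] = {}

    def walk(subtree: dict, p_node: np.ndarray):
        for name, spec in subtree.items():
            F = float(spec.get("F", 0.0))
            p_branch = simulate_branch_freqs(np.clip(p_node, 1e-9, 1 - 1e-9), F, rng)
            children = spec.get("children")
            if children:
                walk(children, p_branch)
            else:
                out[name] = p_branch

    walk(tree, np.asarray(p_anc, dtype=float))
    return out


def simulate_genotypes(
    freqs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    ploidy: int = 2,
) -> np.ndarray:
    """Binomial(ploidy, p) genotypes, (n_snps, n) int8, missing entries added."""
    freqs = np.asarray(freqs, dtype=float)
    g = rng.binomial(ploidy, freqs[:, None], size=(freqs.size, n)).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(g.shape) < missing_rate
        g[miss] = MISSING
    return g


def _snp_table(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNPs, 1 Mb/cM physical scale, per chromosome."""
    rows = []
    for c in range(config.n_chrom):
        gpos = np.linspace(0, config.chrom_length, config.n_snps, endpoint=False)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": str(c + 1),
                    "snp_id": [f"snp{c + 1}_{i}" for i in range(config.n_snps)],
                    "genetic_pos": gpos,
                    "phys_pos": (gpos * 1e8).astype(np.int64) + 1,
                    "allele_ref": "A",
                    "allele_alt": "G",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_admixed_haplotypes(
    event: AdmixtureEvent,
    source_freqs: dict[str, np.ndarray],
    genetic_pos: np.ndarray,
    chrom: np.ndarray,
    n_diploid: int,
    rng: np.random.Generator,
    return_ancestry: bool = False,
    return_tracts: bool = False,
):
    """Mosaic haplotypes for an admixed population.

    Tract breakpoints are a Poisson process of rate ``gens_ago`` per Morgan
    along each chromosome; every tract is independently assigned source 1
    with probability alpha; alleles are Bernoulli(p_source) per SNP.  Two
    independent haplotypes form each diploid.

    Returns genotypes (n_snps, n_diploid), optionally followed by the
    per-haplotype ancestry indicator array (n_snps, 2*n_diploid; 1 =
    source1) and by the interior tract lengths (Morgans) of the breakpoint
    process, which are iid Exponential(rate gens_ago) by construction.
    """
    g = float(event.gens_ago)
    if g < 1:
        raise ValueError("gens_ago must be >= 1")
    p1 = np.asarray(source_freqs[event.source1], dtype=float)
    p2 = np.asarray(source_freqs[event.source2], dtype=float)
    n_snps = p1.size
    n_hap = 2 * n_diploid
    anc = np.empty((n_snps, n_hap), dtype=np.int8)
    tract_lengths: list[np.ndarray] = []
    chrom = np.asarray(chrom)
    for ch in pd.unique(chrom):
        sel = np.flatnonzero(chrom == ch)
        pos = np.asarray(genetic_pos)[sel]
        L = pos.max() - pos.min() if sel.size else 0.0
        start = pos.min() if sel.size else 0.0
        for h in range(n_hap):
            # breakpoints as cumulative Exp(1/g) increments: an exact Poisson
            # process whose per-tract draws are iid Exponential(rate g)
            n_guess = int(g * L + 6 * np.sqrt(g * L + 1) + 10)
            incs = rng.exponential(1.0 / g, n_guess)
            cs = np.cumsum(incs)
            while cs[-1] < L:
                more = rng.exponential(1.0 / g, n_guess)
                incs = np.concatenate([incs, more])
                cs = np.concatenate([cs, cs[-1] + np.cumsum(more)])
            bps = start + cs[cs < L]
            n_bp = bps.size
            tract_idx = np.searchsorted(bps, pos, side="right")
            tract_anc = rng.random(n_bp + 1) < event.alpha
            anc[sel, h] = tract_anc[tract_idx]
            if return_tracts:
                # true generative draws for every tract starting in-window
                tract_lengths.append(incs[: n_bp + 1])
    u = rng.random((n_snps, n_hap))
    p_here = np.where(anc == 1, p1[:, None], p2[:, None])
    hap = (u < p_here).astype(np.int8)
    geno = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    extras = []
    if return_ancestry:
        extras.append(anc)
    if return_tracts:
        extras.append(
            np.concatenate(tract_lengths) if tract_lengths else np.empty(0)
        )
    if extras:
        return (geno, *extras)
    return geno


def apply_dropout(
    ds: GenotypeDataset,
    rate: float,
    tract_len: float,
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Clustered allelic drop-out mimicking whole-genome-amplification artifacts.

    For every individual, physical tracts (exponential lengths with mean
    ``tract_len`` bp, expected genome fraction ``rate``) lose one strand:
    each heterozygote inside a tract becomes one of its homozygotes, the
    surviving allele chosen once per tract.  Observed heterozygosity inside
    tracts drops to zero, so genome-wide het shrinks by a factor (1 - rate).
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if ds.ploidy != 2:
        raise ValueError("drop-out applies to diploid data")
    out = ds.copy()
    if rate == 0:
        return out
    geno = out.genotypes
    for ch in pd.unique(ds.snps["chrom"]):
        sel = np.flatnonzero((ds.snps["chrom"] == ch).to_numpy())
        pos = ds.snps["phys_pos"].to_numpy()[sel].astype(float)
        lo, hi = pos.min(), pos.max() + 1
        span = hi - lo
        for s in range(ds.n_samples):
            if rate >= 1:
                tracts = [(lo, hi)]
            else:
                # renewal process: expected covered fraction = rate
                n_tracts = rng.poisson(span * rate / tract_len)
                starts = rng.uniform(lo - tract_len, hi, size=n_tracts)
                lens = rng.exponential(tract_len, size=n_tracts)
                tracts = list(zip(starts, starts + lens))
            for t0, t1 in tracts:
                inside = sel[(pos >= t0) & (pos < t1)]
                if inside.size == 0:
                    continue
                keep_ref = rng.random() < 0.5
                col = geno[inside, s]
                het = col == 1
                col[het] = 2 if keep_ref else 0
                geno[inside, s] = col
    return out


# ---------------------------------------------------------------------------
# top-level generator
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig, return_truth: bool = False
) -> GenotypeDataset | tuple[GenotypeDataset, dict]:
    """Generate a full dataset from a SimConfig.

    Each population's frequencies drift independently from shared ancestral
    frequencies; admixture-event targets are built as haplotype mosaics of
    their sources' frequency panels.  Truth (per-population frequencies,
    ancestry indicators) is returned when requested, for oracle tests.
    """
    rng = np.random.default_rng(config.seed)
    snps = _snp_table(config)
    n_snps = len(snps)
    p_anc = rng.uniform(config.freq_low, config.freq_high, size=n_snps)

    admixed = config.admixed_targets
    if config.tree is not None:
        freqs = drift_tree_freqs(p_anc, config.tree, rng)
        missing = [
            p.name for p in config.populations
            if p.name not in freqs and p.name not in admixed
        ]
        if missing:
            raise ValueError(f"populations missing from tree: {missing}")
    else:
        freqs = {}
        for pop in config.populations:
            if pop.name not in admixed:
                freqs[pop.name] = simulate_branch_freqs(p_anc, pop.drift_F, rng)

    event_by_target = {ev.target: ev for ev in config.events}
    genos, sample_rows = [], []
    truth: dict = {"freqs": freqs, "p_anc": p_anc, "ancestry": {}}
    for pop in config.populations:
        ev = event_by_target.get(pop.name)
        if ev is None:
            g = simulate_genotypes(freqs[pop.name], pop.size_n, rng)
        else:
            g, anc = simulate_admixed_haplotypes(
                ev,
                freqs,
                snps["genetic_pos"].to_numpy(),
                snps["chrom"].to_numpy(),
                pop.size_n,
                rng,
                return_ancestry=True,
            )
            truth["ancestry"][pop.name] = anc
        genos.append(g)
        sample_rows += [
            {"sample_id": f"{pop.name}_{i}", "population": pop.name}
            for i in range(pop.size_n)
        ]
    geno = np.concatenate(genos, axis=1)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING
    ds = GenotypeDataset(snps, pd.DataFrame(sample_rows), geno, ploidy=2)
    if config.dropout_rate > 0:
        ds = apply_dropout(ds, config.dropout_rate, config.dropout_tract_bp, rng)
    if return_truth:
        return ds, truth
    return ds
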