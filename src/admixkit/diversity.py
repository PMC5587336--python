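"""Within-population diversity: heterozygosity, ROH, rarefaction.

Rarefaction standardizes allelic richness to a common sample size of g
allele copies per locus: for allele i with count N_i of N sampled copies in
population k, the probability it appears in a subsample of size g is

    P_ik = 1 - C(N - N_i, g) / C(N, g)

and Q_ik = 1 - P_ik its absence probability.  Expected richness is the sum
of P over alleles; private richness multiplies by absence everywhere else;
shared-private richness by joint presence in two populations and absence in
the rest.  The combinatorial ratios are evaluated as exact telescoping
products, so results match exhaustive subset enumeration to rounding error.

Runs of homozygosity use a PLINK-style scan: fixed-size sliding windows
vote on each SNP, maximal stretches of eligible SNPs become segments, and
length/SNP-count/density/gap thresholds prune them.  On array data ROH are
meaningful from roughly 0.5 Mb upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeDataset, allele_freq_table


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def observed_heterozygosity(ds: GenotypeDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual observed het plus per-population summaries.

    Returns (per_individual, per_population).  The population table carries
    mean/SD of observed het and the unbiased expected heterozygosity
    2 p (1 - p) n/(n - 1) averaged over SNPs.  Feed chimeric data when
    allelic drop-out is suspected: observed het is biased by drop-out, the
    chimera-based expected het is not.
    """
    if ds.ploidy != 2:
        raise ValueError(
            "observed heterozygosity needs diploid data; "
            "run make_chimeras on haploidized input first"
        )
    g = ds.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    n_het = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = n_het / n_obs
    per_ind = pd.DataFrame(
        {
            "sample_id": ds.samples["sample_id"],
            "population": ds.samples["population"],
            "het_obs": het,
            "n_snps": n_obs,
        }
    )
    ft = allele_freq_table(ds)
    rows = []
    for j, pop in enumerate(ft.populations):
        sub = per_ind[per_ind["population"] == pop]["het_obs"]
        n = ft.n[:, j].astype(float)
        p = ft.p[:, j]
        ok = (n >= 2) & ~np.isnan(p)
        exp_het = float(np.mean(2 * p[ok] * (1 - p[ok]) * n[ok] / (n[ok] - 1)))
        rows.append(
            {
                "population": pop,
                "het_obs_mean": float(sub.mean()),
                "het_obs_sd": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
                "het_exp": exp_het,
                "n_individuals": int(len(sub)),
            }
        )
    return per_ind, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass
class RohSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int  # 1-based inclusive
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class RohParams:
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    min_window_pass_frac: float = 0.05
    min_snps: int = 25
    min_length_bp: int = 500_000
    max_snp_spacing_bp: int = 50_000   # density: >= 1 SNP per this many bp
    max_gap_bp: int = 100_000


def detect_roh(ds: GenotypeDataset, params: RohParams | None = None) -> list[RohSegment]:
    """PLINK-style sliding-window ROH scan on a diploid (typically chimeric)
    dataset.  SNPs must be position-sorted within chromosomes."""
    if ds.ploidy != 2:
        raise ValueError("ROH detection needs diploid data")
    if params is None:
        params = RohParams()
    w = params.window_snps
    chrom_arr = ds.snps["chrom"].to_numpy()
    pos_all = ds.snps["phys_pos"].to_numpy()
    segments: list[RohSegment] = []
    for ch in pd.unique(chrom_arr):
        sel = np.flatnonzero(chrom_arr == ch)
        pos = pos_all[sel]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNPs unsorted on chromosome {ch}")
        G = ds.genotypes[sel]
        m = sel.size
        for s in range(ds.n_samples):
            col = G[:, s]
            het = (col == 1).astype(np.int64)
            mis = (col == MISSING).astype(np.int64)
            if m >= w:
                ch_het = np.convolve(het, np.ones(w, dtype=np.int64), "valid")
                ch_mis = np.convolve(mis, np.ones(w, dtype=np.int64), "valid")
                win_pass = (ch_het <= params.window_max_het) & (
                    ch_mis <= params.window_max_missing
                )
                # windows spanning SNP i start in [i-w+1, i]
                cum = np.concatenate([[0], np.cumsum(win_pass)])
                n_win = win_pass.size
                lo = np.clip(np.arange(m) - w + 1, 0, n_win - 1)
                hi = np.clip(np.arange(m), 0, n_win - 1)
                passing = cum[hi + 1] - cum[lo]
                spanning = hi - lo + 1
                eligible = passing / spanning >= params.min_window_pass_frac
            else:
                eligible = np.zeros(m, dtype=bool)
            segments.extend(
                _segments_from_eligible(
                    eligible, pos, ds.samples["sample_id"].iat[s], str(ch), params
                )
            )
    return segments


def _segments_from_eligible(eligible, pos, sample_id, chrom, params):
    out = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return out
    # split runs of eligible SNPs at index jumps or physical gaps
    brk = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > params.max_gap_bp)
    )
    for run in np.split(idx, brk + 1):
        n = run.size
        if n < params.min_snps:
            continue
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        length = end - start + 1
        if length < params.min_length_bp:
            continue
        if length / n > params.max_snp_spacing_bp:
            continue
        out.append(RohSegment(sample_id, chrom, start, end, n))
    return out


def roh_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_bp": s.length_bp,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
    )


DEFAULT_ROH_BINS_MB = (0.5, 1.0, 2.0, 4.0, 8.0, np.inf)


def roh_summary(
    segments: list[RohSegment],
    sample_ids: list[str] | None = None,
    bins_mb: tuple[float, ...] = DEFAULT_ROH_BINS_MB,
) -> pd.DataFrame:
    """Per-individual total ROH length (Mb) in each length category.

    ``sample_ids`` forces all-zero rows for individuals without segments.
    """
    edges = np.asarray(bins_mb, dtype=float)
    labels = [
        f"{edges[i]:g}-{edges[i + 1]:g}Mb" if np.isfinite(edges[i + 1]) else f">{edges[i]:g}Mb"
        for i in range(len(edges) - 1)
    ]
    df = roh_to_frame(segments)
    if sample_ids is None:
        sample_ids = sorted(df["sample_id"].unique())
    totals = pd.DataFrame(0.0, index=pd.Index(sample_ids, name="sample_id"), columns=labels)
    for row in df.itertuples(index=False):
        mb = row.length_bp / 1e6
        k = int(np.searchsorted(edges, mb, side="right")) - 1
        if 0 <= k < len(labels) and row.sample_id in totals.index:
            totals.loc[row.sample_id, labels[k]] += mb
    return totals.reset_index()


# ---------------------------------------------------------------------------
# ADZE-style rarefaction
# ---------------------------------------------------------------------------

@dataclass
class AlleleCounts:
    """Allele counts per locus and population, padded over the allele axis.

    counts has shape (n_loci, max_alleles, n_pops); absent alleles carry
    zero counts (harmless: presence probability 0, absence probability 1).
    """

    populations: list[str]
    counts: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None


def allele_counts_from_dataset(
    ds: GenotypeDataset, pops: list[str] | None = None
) -> AlleleCounts:
    """Biallelic counted/other allele counts per SNP and population."""
    ft = allele_freq_table(ds, pops)
    n = ft.n.astype(np.int64)
    ref = np.rint(np.nan_to_num(ft.p) * n).astype(np.int64)
    counts = np.stack([ref, n - ref], axis=1)  # (loci, 2, pops)
    return AlleleCounts(list(ft.populations), counts)


@dataclass
class RarefactionCurve:
    kind: str  # richness | private | shared_private
    population: str | tuple[str, str]
    g: np.ndarray
    values: np.ndarray
    n_loci_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        pop = self.population if isinstance(self.population, str) else "+".join(self.population)
        return pd.DataFrame(
            {
                "population": pop,
                "g": self.g,
                "statistic": self.kind,
                "value": self.values,
                "n_loci": self.n_loci_used,
            }
        )


def _absence_prob(counts: np.ndarray, totals: np.ndarray, g: int) -> np.ndarray:
    """Q = C(N - Ni, g) / C(N, g) as an exact telescoping product.

    counts (..., alleles, pops) against totals (..., pops); entries where
    N < g are meaningless and must be masked by the caller.
    """
    q = np.ones(counts.shape, dtype=float)
    totals_f = totals.astype(float)[..., None, :]
    rem = totals_f - counts
    safe_tot = np.maximum(totals_f, g)  # avoid division by zero on dropped loci
    for t in range(g):
        q *= np.maximum(rem - t, 0.0) / (safe_tot - t)
    return q


def rarefied_allelic_richness(
    counts: AlleleCounts, population: str, g_max: int
) -> RarefactionCurve:
    """Expected number of distinct alleles per locus in samples of g copies."""
    if g_max < 1:
        raise ValueError("g must be >= 1")
    j = counts.pop_index(population)
    cj = counts.counts[:, :, [j]]
    totals = cj.sum(axis=1)
    gs = np.arange(1, g_max + 1)
    vals, used = [], []
    for g in gs:
        ok = totals[:, 0] >= g
        q = _absence_prob(cj[ok], totals[ok], int(g))
        vals.append(float((1.0 - q).sum(axis=(1, 2)).mean()))
        used.append(int(ok.sum()))
    return RarefactionCurve("richness", population, gs, np.array(vals), np.array(used))


def _multi_pop_curve(
    counts: AlleleCounts, focal: tuple[int, ...], kind: str, g_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Shared machinery for private / shared-private richness."""
    c = counts.counts
    totals = c.sum(axis=1)  # (loci, pops)
    gs = np.arange(1, g_max + 1)
    vals, used = [], []
    others = [k for k in range(len(counts.populations)) if k not in focal]
    for g in gs:
        ok = (totals >= g).all(axis=1)
        q = _absence_prob(c[ok], totals[ok], int(g))  # (loci, alleles, pops)
        p = 1.0 - q
        term = np.ones(q.shape[:2])
        for j in focal:
            term = term * p[:, :, j]
        for k in others:
            term = term * q[:, :, k]
        vals.append(float(term.sum(axis=1).mean()))
        used.append(int(ok.sum()))
    return np.array(vals), np.array(used)


def rarefied_private_richness(
    counts: AlleleCounts, population: str, g_max: int
) -> RarefactionCurve:
    """Expected alleles found in ``population`` and missed in every other."""
    if g_max < 1:
        raise ValueError("g must be >= 1")
    j = counts.pop_index(population)
    vals, used = _multi_pop_curve(counts, (j,), "private", g_max)
    return RarefactionCurve("private", population, np.arange(1, g_max + 1), vals, used)


def rarefied_shared_private(
    counts: AlleleCounts, pop_a: str, pop_b: str, g_max: int
) -> RarefactionCurve:
    """Expected alleles found in both focal populations and nowhere else."""
    if g_max < 1:
        raise ValueError("g must be >= 1")
    ja, jb = counts.pop_index(pop_a), counts.pop_index(pop_b)
    if ja == jb:
        raise ValueError("shared-private needs two distinct populations")
    vals, used = _multi_pop_curve(counts, (ja, jb), "shared_private", g_max)
    return RarefactionCurve(
        "shared_private", (pop_a, pop_b), np.arange(1, g_max + 1), vals, used
    )


# ---------------------------------------------------------------------------
# short haplotypes
# ---------------------------------------------------------------------------

def snps_to_haplotypes(ds: GenotypeDataset, window: int = 5) -> AlleleCounts:
    """Combine non-overlapping runs of ``window`` consecutive SNPs into
    multi-allelic loci (distinct allele strings are the alleles).

    Needs haploidized input — diploid genotypes have unknown phase.
    Haplotypes containing a missing call are dropped per locus; trailing
    partial windows are discarded.
    """
    if ds.ploidy != 1:
        raise ValueError("haplotype loci need haploid input (phase unknown for diploids)")
    chrom_arr = ds.snps["chrom"].to_numpy()
    pops = ds.populations
    pop_of = ds.samples["population"].to_numpy()
    loci_counts: list[np.ndarray] = []
    for ch in pd.unique(chrom_arr):
        sel = np.flatnonzero(chrom_arr == ch)
        pos = ds.snps["phys_pos"].to_numpy()[sel]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNPs unsorted on chromosome {ch}")
        G = ds.genotypes[sel]
        for w0 in range(0, sel.size - window + 1, window):
            block = G[w0 : w0 + window]  # (window, samples)
            good = (block != MISSING).all(axis=0)
            if not good.any():
                continue
            keys = [tuple(block[:, s]) for s in np.flatnonzero(good)]
            alleles = sorted(set(keys))
            a_index = {a: i for i, a in enumerate(alleles)}
            cnt = np.zeros((len(alleles), len(pops)), dtype=np.int64)
            for s, key in zip(np.flatnonzero(good), keys):
                cnt[a_index[key], pops.index(pop_of[s])] += 1
            loci_counts.append(cnt)
    if not loci_counts:
        return AlleleCounts(pops, np.zeros((0, 1, len(pops)), dtype=np.int64))
    kmax = max(c.shape[0] for c in loci_counts)
    padded = np.zeros((len(loci_counts), kmax, len(pops)), dtype=np.int64)
    for i, c in enumerate(loci_counts):
        padded[i, : c.shape[0]] = c
    return AlleleCounts(pops, padded)
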