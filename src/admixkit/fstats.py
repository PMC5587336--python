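"""Allele-frequency f-statistics and D-statistics with block-jackknife errors.

All statistics are moments of population allele-frequency differences:

    f2(A,B)      = E[(pA - pB)^2]                (shared drift distance)
    f3(X; A,B)   = E[(pX - pA)(pX - pB)]         (negative => X admixed)
    f4(A,B; C,D) = E[(pA - pB)(pC - pD)]         (treeness / gene flow)
    D(A,B; C,D)  = sum num / sum den, den = (pA + pB - 2 pA pB)(pC + pD - 2 pC pD)

Sample frequencies are noisy, so f2 and f3 subtract the unbiased
within-population heterozygosity correction h/n with
h = n p(1-p)/(n-1); f4 and D need no correction because the two factors
involve disjoint populations.

Standard errors come from a weighted delete-one-block jackknife over
contiguous genetic-map blocks (default 5 cM), which is robust to LD between
nearby SNPs.  An f4-ratio — the quotient of two f4 statistics over the same
SNP set — estimates an admixture proportion when the assumed topology
holds; its jackknife deletes each block from numerator and denominator
simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import FrequencyTable, GenotypeDataset, allele_freq_table


class InsufficientDataError(ValueError):
    pass


@dataclass
class FStatResult:
    statistic: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_snps: int

    def __repr__(self) -> str:  # compact, qpDstat-like
        args = ",".join(self.pops)
        return (
            f"{self.statistic}({args}) = {self.estimate:.6g} "
            f"se {self.se:.3g} Z {self.z:.3f} "
            f"[{self.n_snps} SNPs, {self.n_blocks} blocks]"
        )

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pops": list(self.pops),
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "n_blocks": self.n_blocks,
            "n_snps": self.n_snps,
        }


# ---------------------------------------------------------------------------
# blocks & jackknife
# ---------------------------------------------------------------------------

def block_partition(
    snps: pd.DataFrame, block_cm: float = 5.0, fallback_snps: int = 500
) -> np.ndarray:
    """Assign every SNP to a contiguous block.

    Blocks are fixed genetic-map chunks of ``block_cm`` centimorgans within
    each chromosome; if the map is degenerate (all positions equal) blocks
    fall back to runs of ``fallback_snps`` consecutive SNPs.
    """
    gpos = snps["genetic_pos"].to_numpy(dtype=float)
    chrom = snps["chrom"].to_numpy()
    blocks = np.zeros(len(snps), dtype=np.int64)
    offset = 0
    for ch in pd.unique(chrom):
        sel = np.flatnonzero(chrom == ch)
        g = gpos[sel]
        if g.max() > g.min():
            local = np.floor((g - g.min()) / (block_cm / 100.0)).astype(np.int64)
        else:
            local = np.arange(sel.size) // fallback_snps
        # renumber to consecutive block ids
        _, local = np.unique(local, return_inverse=True)
        blocks[sel] = local + offset
        offset += local.max() + 1
    return blocks


def weighted_jackknife(
    estimate: float, loo_estimates: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife standard error.

    ``loo_estimates`` are the statistic recomputed with each block removed;
    ``weights`` are per-block SNP counts.  Returns (estimate, se) using the
    weighted jackknife variance with unequal block sizes.
    """
    loo = np.asarray(loo_estimates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if loo.size < 2:
        raise InsufficientDataError("jackknife needs >= 2 blocks")
    n = w.sum()
    g = loo.size
    h = n / w
    theta_j = g * estimate - np.sum((1 - w / n) * loo)
    tau = h * estimate - (h - 1) * loo
    var = np.mean((tau - theta_j) ** 2 / (h - 1))
    return estimate, float(np.sqrt(var))


def block_jackknife(
    block_sums: np.ndarray, block_weights: np.ndarray
) -> tuple[float, float]:
    """Estimate and SE for a ratio-of-sums statistic sum(v)/sum(w) by blocks."""
    s = np.asarray(block_sums, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    keep = w > 0
    s, w = s[keep], w[keep]
    if s.size < 2:
        raise InsufficientDataError("jackknife needs >= 2 non-empty blocks")
    S, W = s.sum(), w.sum()
    est = S / W
    loo = (S - s) / (W - w)
    return weighted_jackknife(est, loo, w)


def _ratio_jackknife(
    num_sums: np.ndarray, den_sums: np.ndarray, weights: np.ndarray
) -> tuple[float, float, int]:
    """Jackknife of sum(num)/sum(den), deleting blocks simultaneously."""
    keep = np.asarray(weights) > 0
    num, den, w = num_sums[keep], den_sums[keep], np.asarray(weights, float)[keep]
    if num.size < 2:
        raise InsufficientDataError("jackknife needs >= 2 non-empty blocks")
    N, D = num.sum(), den.sum()
    if D == 0:
        raise InsufficientDataError("degenerate ratio: zero denominator")
    est = N / D
    loo = (N - num) / (D - den)
    e, se = weighted_jackknife(est, loo, w)
    return e, se, num.size


# ---------------------------------------------------------------------------
# frequency plumbing
# ---------------------------------------------------------------------------

def _as_freqs(data, pops: list[str]) -> FrequencyTable:
    if isinstance(data, GenotypeDataset):
        return allele_freq_table(data, pops)
    if isinstance(data, FrequencyTable):
        missing = [p for p in pops if p not in data.populations]
        if missing:
            raise KeyError(f"unknown populations {missing}")
        return data
    raise TypeError("data must be a GenotypeDataset or FrequencyTable")


def _columns(ft: FrequencyTable, pops: list[str]):
    idx = [ft.pop_index(p) for p in pops]
    return ft.p[:, idx], ft.n[:, idx]


def _het_correction(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """h/n with h = n p (1-p) / (n-1): unbiased sampling-noise correction."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return p * (1 - p) / (n - 1)


def _finish(
    name: str,
    pops: tuple[str, ...],
    values: np.ndarray,
    mask: np.ndarray,
    blocks: np.ndarray,
) -> FStatResult:
    if mask.sum() == 0:
        raise InsufficientDataError(f"{name}{pops}: no usable SNPs")
    b = blocks[mask]
    v = values[mask]
    n_b = blocks.max() + 1
    sums = np.bincount(b, weights=v, minlength=n_b)
    cnts = np.bincount(b, minlength=n_b)
    est, se = block_jackknife(sums, cnts)
    z = est / se if se > 0 else 0.0
    return FStatResult(name, pops, float(est), float(se), float(z), int((cnts > 0).sum()), int(mask.sum()))


def _blocks_for(data, snps: pd.DataFrame | None, block_cm: float) -> np.ndarray:
    if isinstance(data, GenotypeDataset):
        return block_partition(data.snps, block_cm)
    if snps is not None:
        return block_partition(snps, block_cm)
    raise ValueError("FrequencyTable without SNP metadata: cannot build blocks")


# ---------------------------------------------------------------------------
# the statistics
# ---------------------------------------------------------------------------

def compute_f2(data, A: str, B: str, corrected: bool = True, block_cm: float = 5.0) -> FStatResult:
    """f2(A,B): squared frequency difference, bias-corrected by default."""
    if A == B:
        raise ValueError("f2 needs two distinct populations")
    ft = _as_freqs(data, [A, B])
    p, n = _columns(ft, [A, B])
    mask = ~np.isnan(p).any(axis=1)
    vals = (p[:, 0] - p[:, 1]) ** 2
    if corrected:
        mask &= (n >= 2).all(axis=1)
        with np.errstate(invalid="ignore"):
            vals = vals - _het_correction(p[:, 0], n[:, 0]) - _het_correction(p[:, 1], n[:, 1])
    blocks = _blocks_for(data, ft.snps, block_cm)
    return _finish("f2", (A, B), vals, mask, blocks)


def compute_f3(
    data,
    X: str,
    A: str,
    B: str,
    corrected: bool = True,
    normalized: bool = False,
    block_cm: float = 5.0,
) -> FStatResult:
    """f3(X; A, B): admixture test for target X between A- and B-like sources.

    Z < -3 is conventionally a significant admixture signal.  With the
    outgroup as X this is outgroup-f3 (shared-drift measure, no admixture
    interpretation).  ``normalized`` divides by the target's unbiased
    heterozygosity (ratio of sums), the variant some tool chains report.
    """
    if len({X, A, B}) != 3:
        raise ValueError("f3 needs three distinct populations")
    ft = _as_freqs(data, [X, A, B])
    p, n = _columns(ft, [X, A, B])
    mask = ~np.isnan(p).any(axis=1)
    vals = (p[:, 0] - p[:, 1]) * (p[:, 0] - p[:, 2])
    if corrected:
        mask &= n[:, 0] >= 2
        with np.errstate(invalid="ignore"):
            vals = vals - _het_correction(p[:, 0], n[:, 0])
    blocks = _blocks_for(data, ft.snps, block_cm)
    if not normalized:
        return _finish("f3", (X, A, B), vals, mask, blocks)
    with np.errstate(invalid="ignore", divide="ignore"):
        hx = 2.0 * n[:, 0] / (n[:, 0] - 1) * p[:, 0] * (1 - p[:, 0])
    mask &= n[:, 0] >= 2
    mask &= np.isfinite(vals) & np.isfinite(hx)
    b = blocks[mask]
    n_b = blocks.max() + 1
    num = np.bincount(b, weights=vals[mask], minlength=n_b)
    den = np.bincount(b, weights=hx[mask], minlength=n_b)
    cnt = np.bincount(b, minlength=n_b)
    est, se, nb = _ratio_jackknife(num, den, cnt)
    z = est / se if se > 0 else 0.0
    return FStatResult("f3n", (X, A, B), est, se, z, nb, int(mask.sum()))


def compute_f4(data, A: str, B: str, C: str, D: str, block_cm: float = 5.0) -> FStatResult:
    """f4(A,B; C,D) = mean (pA - pB)(pC - pD); no bias correction needed."""
    if len({A, B, C, D}) != 4:
        raise ValueError("f4 needs four distinct populations")
    ft = _as_freqs(data, [A, B, C, D])
    p, _ = _columns(ft, [A, B, C, D])
    mask = ~np.isnan(p).any(axis=1)
    vals = (p[:, 0] - p[:, 1]) * (p[:, 2] - p[:, 3])
    blocks = _blocks_for(data, ft.snps, block_cm)
    return _finish("f4", (A, B, C, D), vals, mask, blocks)


def compute_d(data, A: str, B: str, C: str, D: str, block_cm: float = 5.0) -> FStatResult:
    """Normalized f4 (ABBA-BABA D-statistic); |Z| > 3 flags tree rejection."""
    if len({A, B, C, D}) != 4:
        raise ValueError("D needs four distinct populations")
    ft = _as_freqs(data, [A, B, C, D])
    p, _ = _columns(ft, [A, B, C, D])
    mask = ~np.isnan(p).any(axis=1)
    pa, pb, pc, pd_ = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    num = (pa - pb) * (pc - pd_)
    den = (pa + pb - 2 * pa * pb) * (pc + pd_ - 2 * pc * pd_)
    blocks = _blocks_for(data, ft.snps, block_cm)
    if mask.sum() == 0:
        raise InsufficientDataError("D: no usable SNPs")
    b = blocks[mask]
    n_b = blocks.max() + 1
    ns = np.bincount(b, weights=num[mask], minlength=n_b)
    dsums = np.bincount(b, weights=den[mask], minlength=n_b)
    cnt = np.bincount(b, minlength=n_b)
    est, se, nb = _ratio_jackknife(ns, dsums, cnt)
    z = est / se if se > 0 else 0.0
    return FStatResult("D", (A, B, C, D), est, se, z, nb, int(mask.sum()))


def compute_f4_ratio(
    data,
    num: tuple[str, str, str, str],
    den: tuple[str, str, str, str],
    block_cm: float = 5.0,
) -> FStatResult:
    """Ratio of two f4 statistics over the same SNP set.

    With num = (O1, O2; X, E) and den = (O1, O2; U, E) this estimates the
    U-like ancestry proportion of X (and 1 - ratio the E-like proportion)
    under the assumed topology.  The jackknife deletes blocks from both
    sums simultaneously, so the SE accounts for their correlation.
    """
    pops = list(dict.fromkeys(list(num) + list(den)))
    ft = _as_freqs(data, pops)
    pn, _ = _columns(ft, list(num))
    pdn, _ = _columns(ft, list(den))
    mask = ~(np.isnan(pn).any(axis=1) | np.isnan(pdn).any(axis=1))
    if mask.sum() == 0:
        raise InsufficientDataError("f4-ratio: no usable SNPs")
    v_num = (pn[:, 0] - pn[:, 1]) * (pn[:, 2] - pn[:, 3])
    v_den = (pdn[:, 0] - pdn[:, 1]) * (pdn[:, 2] - pdn[:, 3])
    blocks = _blocks_for(data, ft.snps, block_cm)
    b = blocks[mask]
    n_b = blocks.max() + 1
    ns = np.bincount(b, weights=v_num[mask], minlength=n_b)
    dsums = np.bincount(b, weights=v_den[mask], minlength=n_b)
    cnt = np.bincount(b, minlength=n_b)
    den_est, den_se = block_jackknife(dsums, cnt)
    if den_se > 0 and abs(den_est / den_se) < 3:
        warnings.warn(
            f"f4-ratio denominator weak (|Z| = {abs(den_est / den_se):.2f} < 3); "
            "ratio may be unstable"
        )
    est, se, nb = _ratio_jackknife(ns, dsums, cnt)
    z = est / se if se > 0 else 0.0
    return FStatResult("f4_ratio", tuple(num) + tuple(den), est, se, z, nb, int(mask.sum()))


# ---------------------------------------------------------------------------
# batch runner (qpDstat-style tabular idiom)
# ---------------------------------------------------------------------------

_DISPATCH = {
    "f2": (compute_f2, 2),
    "f3": (compute_f3, 3),
    "f4": (compute_f4, 4),
    "d": (compute_d, 4),
}


def run_batch(data, requests: pd.DataFrame | str) -> pd.DataFrame:
    """Evaluate a table of statistic requests.

    ``requests`` is a TSV path or DataFrame with columns ``statistic`` and
    ``pop1..pop4`` (unused trailing pops empty).  Returns one FStatResult
    row per request.
    """
    if isinstance(requests, str):
        requests = pd.read_csv(requests, sep="\t", dtype=str).fillna("")
    rows = []
    for req in requests.itertuples(index=False):
        name = req.statistic.lower()
        if name not in _DISPATCH:
            raise ValueError(f"unknown statistic {req.statistic!r}")
        fn, k = _DISPATCH[name]
        pops = [getattr(req, f"pop{i + 1}") for i in range(k)]
        rows.append(fn(data, *pops).to_dict())
    out = pd.DataFrame(rows)
    out["pops"] = out["pops"].map(lambda ps: ",".join(ps))
    return out
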