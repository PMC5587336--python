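"""Pairwise population differentiation and the pseudo-unadmixed correction.

Two estimators are provided:

* Weir & Cockerham's theta-hat from the 1984 variance components a (among
  populations), b (among individuals within populations) and c (within
  individuals), combined as a ratio of sums across SNPs.
* Wright's/Hudson-style FST = (H_T - H_S) / H_T computed directly from
  frequencies, which also works on corrected (pseudo-unadmixed) frequency
  vectors where no genotypes exist.

The pseudo-unadmixed construction strips a known admixture component from a
target population's frequencies: if p_target = alpha * p_donor +
(1 - alpha) * p_base, then p_base = (p_target - alpha * p_donor) /
(1 - alpha).  Raw values outside [0,1] (sampling noise) are clipped and
counted.  alpha is typically taken from an f4-ratio estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genio import FrequencyTable, GenotypeDataset, allele_freq_table
from .fstats import InsufficientDataError, block_jackknife, block_partition


# ---------------------------------------------------------------------------
# Weir & Cockerham
# ---------------------------------------------------------------------------

def wc_components(
    p: np.ndarray, n_dip: np.ndarray, het: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP W&C (1984) variance components for r populations.

    Parameters are per-SNP arrays of shape (n_snps, r): sample allele
    frequency, diploid sample size, observed heterozygote proportion.
    Returns (a, b, c).
    """
    r = p.shape[1]
    nbar = n_dip.mean(axis=1)
    sum_n = n_dip.sum(axis=1)
    pbar = (n_dip * p).sum(axis=1) / sum_n
    s2 = (n_dip * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n_dip * het).sum(axis=1) / sum_n
    nc = (sum_n - (n_dip**2).sum(axis=1) / sum_n) / (r - 1)
    a = (nbar / nc) * (
        s2
        - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_fst(
    ds: GenotypeDataset,
    A: str,
    B: str,
    block_cm: float = 5.0,
    with_se: bool = False,
):
    """Weir & Cockerham theta-hat between two populations (ratio of sums).

    Monomorphic-in-both SNPs contribute nothing and are dropped; a fully
    monomorphic SNP set raises.  ``with_se`` adds a block-jackknife SE.
    """
    ft = allele_freq_table(ds, [A, B])
    p = ft.p
    n_dip = ft.n / 2.0
    het = ft.het
    mask = ~np.isnan(p).any(axis=1) & (n_dip >= 2).all(axis=1) & ~np.isnan(het).any(axis=1)
    a, b, c = wc_components(p, np.where(mask[:, None], n_dip, 2), np.nan_to_num(het))
    tot = a + b + c
    mask &= np.isfinite(a) & np.isfinite(tot)
    poly = mask & (tot != 0)
    if poly.sum() == 0:
        raise InsufficientDataError("W&C FST undefined: no polymorphic SNPs")
    theta = a[poly].sum() / tot[poly].sum()
    if not with_se:
        return float(theta)
    blocks = block_partition(ds.snps, block_cm)
    nb = blocks.max() + 1
    # jackknife over ratio of block sums of a and a+b+c
    asum = np.bincount(blocks[poly], weights=a[poly], minlength=nb)
    tsum = np.bincount(blocks[poly], weights=tot[poly], minlength=nb)
    cnt = np.bincount(blocks[poly], minlength=nb)
    keep = cnt > 0
    S, T = asum.sum(), tsum.sum()
    loo = (S - asum[keep]) / (T - tsum[keep])
    from .fstats import weighted_jackknife

    est, se = weighted_jackknife(theta, loo, cnt[keep])
    return float(est), float(se)


def wrights_fst(
    freqs_a: np.ndarray, freqs_b: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Wright's FST from frequency vectors: (H_T - H_S) / H_T, ratio of sums.

    H_S = mean of 2p(1-p) over the two populations, H_T = 2 pbar (1 - pbar).
    NaN frequencies are dropped pairwise.
    """
    pa = np.asarray(freqs_a, dtype=float)
    pb = np.asarray(freqs_b, dtype=float)
    mask = ~(np.isnan(pa) | np.isnan(pb))
    pa, pb = pa[mask], pb[mask]
    w = np.ones(pa.size) if weights is None else np.asarray(weights, float)[mask]
    hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2.0
    pbar = (pa + pb) / 2.0
    ht = 2 * pbar * (1 - pbar)
    den = (w * ht).sum()
    if den == 0:
        raise InsufficientDataError("Wright's FST undefined: H_T is zero at all SNPs")
    return float((w * (ht - hs)).sum() / den)


# ---------------------------------------------------------------------------
# pseudo-unadmixed frequencies
# ---------------------------------------------------------------------------

@dataclass
class PseudoUnadmixedFreqs:
    p: np.ndarray
    alpha: float
    n_clipped: int


def pseudo_unadmixed_freqs(
    p_target: np.ndarray, p_donor: np.ndarray, alpha: float
) -> PseudoUnadmixedFreqs:
    """Strip an alpha-sized donor component from target allele frequencies.

    p_un = (p_target - alpha * p_donor) / (1 - alpha), clipped to [0, 1];
    the clip count is reported so heavy clipping (alpha too large, wrong
    donor) is visible.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    pt = np.asarray(p_target, dtype=float)
    pdn = np.asarray(p_donor, dtype=float)
    raw = (pt - alpha * pdn) / (1.0 - alpha)
    clipped = np.clip(raw, 0.0, 1.0)
    n_clip = int(np.nansum((raw < 0) | (raw > 1)))
    return PseudoUnadmixedFreqs(clipped, alpha, n_clip)


# ---------------------------------------------------------------------------
# matrices and trees
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray
    estimator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


def pairwise_fst_matrix(
    ds: GenotypeDataset, pops: list[str] | None = None, estimator: str = "wc"
) -> FstMatrix:
    """Symmetric matrix of pairwise FST (zero diagonal)."""
    if pops is None:
        pops = ds.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    k = len(pops)
    m = np.zeros((k, k))
    ft = allele_freq_table(ds, pops) if estimator == "wright" else None
    for i in range(k):
        for j in range(i + 1, k):
            if estimator == "wc":
                v = wc_fst(ds, pops[i], pops[j])
            elif estimator == "wright":
                v = wrights_fst(ft.p[:, i], ft.p[:, j])
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            m[i, j] = m[j, i] = v
    return FstMatrix(list(pops), m, estimator)


def upgma_tree(matrix: FstMatrix) -> str:
    """UPGMA (average linkage) tree on the FST matrix, returned as newick.

    Small negative estimates are floored at zero for clustering only;
    branch lengths are half the merge-height differences, so leaf-to-root
    distances are ultrametric.
    """
    m = matrix.values
    if np.isnan(m).any():
        i, j = map(int, np.argwhere(np.isnan(m))[0])
        raise ValueError(
            f"NaN distance between {matrix.populations[i]} and {matrix.populations[j]}"
        )
    d = np.maximum(m, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    return _linkage_to_newick(Z, matrix.populations)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        la = h - height[a]
        lb = h - height[b]
        node[n + k] = f"({node[a]}:{la:.8g},{node[b]}:{lb:.8g})"
        height[n + k] = h
    return node[n + len(Z) - 1] + ";"
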