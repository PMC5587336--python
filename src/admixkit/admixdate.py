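"""Admixture dating from the decay of admixture LD with genetic distance.

An admixture event g generations ago leaves allelic association between
loci that decays with recombination as exp(-g d) at genetic distance d.
The estimator is the covariance-weighted LD statistic of the ALDER/ROLLOFF
family: for SNP pairs (i, j) on the same chromosome,

    a(d) = < cov(dosage_i, dosage_j) * delta_i * delta_j >_{pairs at distance d}

where delta = p_ref1 - p_ref2 is the frequency difference between two
reference populations flanking the admixture event, and the covariance is
taken across target individuals.  Binned in genetic distance and fitted by
weighted least squares to A exp(-g d) + c (optionally a two-event sum of
exponentials), the decay rate g estimates the age of the event in
generations; calendar years are g times the generation time (default 30 y).

Standard errors come from a leave-one-chromosome-out jackknife.  The
amplitude Z-score (A over its jackknife SE) is the significance of the
admixture signal; the date Z is reported alongside because published tables
are ambiguous about which of the two their Z refers to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .genio import MISSING, GenotypeDataset, allele_freq_table
from .fstats import weighted_jackknife
from . import qc


class FitFailureError(RuntimeError):
    pass


@dataclass
class WeightedLDCurve:
    bin_centers_cm: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray
    d_min_cm: float
    d_max_cm: float
    bin_width_cm: float
    target: str
    refs: tuple[str, str]
    chroms: list[str] = field(default_factory=list)
    chrom_sums: np.ndarray | None = None    # (n_chrom, n_bins)
    chrom_counts: np.ndarray | None = None  # (n_chrom, n_bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_cm": self.bin_centers_cm,
                "weighted_ld": self.values,
                "n_pairs": self.pair_counts,
            }
        )

    def drop_chrom(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Curve values and counts with chromosome index k removed."""
        sums = self.chrom_sums.sum(axis=0) - self.chrom_sums[k]
        cnts = self.chrom_counts.sum(axis=0) - self.chrom_counts[k]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = sums / cnts
        return vals, cnts


@dataclass
class DateEstimate:
    g_hat: float
    amplitude: float
    affine: float
    se_g: float
    z: float            # amplitude / jackknife SE of amplitude
    z_date: float       # g_hat / se_g
    model: int
    generation_time: float
    g2_hat: float | None = None
    amplitude2: float | None = None

    @property
    def years(self) -> float:
        return self.g_hat * self.generation_time

    def to_dict(self) -> dict:
        return {
            "g": self.g_hat,
            "se_g": self.se_g,
            "amplitude": self.amplitude,
            "affine": self.affine,
            "z_amplitude": self.z,
            "z_date": self.z_date,
            "model": self.model,
            "years": self.years,
            "generation_time": self.generation_time,
            "g2": self.g2_hat,
            "amplitude2": self.amplitude2,
        }


# ---------------------------------------------------------------------------
# curve computation
# ---------------------------------------------------------------------------

def weighted_ld_curve(
    ds: GenotypeDataset,
    target: str,
    ref1: str,
    ref2: str,
    d_min_cm: float = 0.5,
    d_max_cm: float = 30.0,
    bin_width_cm: float = 0.1,
    chunk: int = 1024,
) -> WeightedLDCurve:
    """Binned weighted LD of the target population against reference weights.

    Works on diploid or haploidized targets (dosage covariance is ploidy
    agnostic).  d_min suppresses background LD; pairs beyond d_max carry no
    signal.  Requires a non-degenerate genetic map.
    """
    if len({target, ref1, ref2}) != 3:
        raise ValueError("target and references must be distinct")
    gpos = ds.snps["genetic_pos"].to_numpy(dtype=float)
    if gpos.max() <= gpos.min():
        raise ValueError("genetic map required (positions are degenerate)")
    ft = allele_freq_table(ds, [ref1, ref2])
    delta = ft.p[:, 0] - ft.p[:, 1]

    tgt = ds.genotypes[:, ds.sample_indices(target)].astype(np.float64)
    obs = tgt != MISSING
    tgt[~obs] = np.nan
    usable = ~np.isnan(delta) & (obs.sum(axis=1) >= 2)

    n_bins = int(np.ceil((d_max_cm - d_min_cm) / bin_width_cm))
    edges0 = d_min_cm / 100.0
    width_m = bin_width_cm / 100.0
    dmin_m, dmax_m = d_min_cm / 100.0, d_max_cm / 100.0

    chroms = [str(c) for c in pd.unique(ds.snps["chrom"])]
    chrom_sums = np.zeros((len(chroms), n_bins))
    chrom_counts = np.zeros((len(chroms), n_bins), dtype=np.int64)
    chrom_arr = ds.snps["chrom"].to_numpy()

    for ci, ch in enumerate(chroms):
        sel = np.flatnonzero((chrom_arr == ch) & usable)
        if sel.size < 2:
            continue
        pos = gpos[sel]
        order = np.argsort(pos, kind="stable")
        sel, pos = sel[order], pos[order]
        X = tgt[sel]
        M = ~np.isnan(X)
        cnt = M.sum(axis=1)
        mean = np.nansum(X, axis=1) / cnt
        Xc = np.where(M, X - mean[:, None], 0.0)
        Y = Xc * delta[sel][:, None]
        Mf = M.astype(np.float64)
        m = sel.size
        for r0 in range(0, m - 1, chunk):
            r1 = min(r0 + chunk, m - 1)
            c0 = r0 + 1
            c1 = int(np.searchsorted(pos, pos[r1 - 1] + dmax_m, side="right"))
            if c1 <= c0:
                continue
            P = Y[r0:r1] @ Y[c0:c1].T
            Np = Mf[r0:r1] @ Mf[c0:c1].T
            D = pos[c0:c1][None, :] - pos[r0:r1][:, None]
            rows = np.arange(r0, r1)[:, None]
            cols = np.arange(c0, c1)[None, :]
            valid = (cols > rows) & (D >= dmin_m) & (D < dmax_m) & (Np >= 2)
            if not valid.any():
                continue
            b = ((D[valid] - edges0) / width_m).astype(np.int64)
            b = np.clip(b, 0, n_bins - 1)
            contrib = P[valid] / (Np[valid] - 1.0)
            chrom_sums[ci] += np.bincount(b, weights=contrib, minlength=n_bins)
            chrom_counts[ci] += np.bincount(b, minlength=n_bins)

    tot_counts = chrom_counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = chrom_sums.sum(axis=0) / tot_counts
    centers = d_min_cm + (np.arange(n_bins) + 0.5) * bin_width_cm
    return WeightedLDCurve(
        centers,
        values,
        tot_counts,
        d_min_cm,
        d_max_cm,
        bin_width_cm,
        target,
        (ref1, ref2),
        chroms,
        chrom_sums,
        chrom_counts,
    )


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

_G_STARTS = (5.0, 20.0, 50.0, 150.0)


def _fit_bins(d_m: np.ndarray, y: np.ndarray, w: np.ndarray, model: int):
    """Weighted LSQ of one- or two-exponential decay; returns parameter tuple."""
    sw = np.sqrt(w / w.sum())
    a0 = max(float(y[0]), 1e-6)
    best = None
    if model == 1:
        def resid(theta):
            A, g, c = theta
            return sw * (A * np.exp(-g * d_m) + c - y)

        for g0 in _G_STARTS:
            try:
                sol = least_squares(
                    resid,
                    x0=[a0, g0, 0.0],
                    bounds=([0.0, 1e-3, -np.inf], [np.inf, 2000.0, np.inf]),
                    max_nfev=2000,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitFailureError("exponential fit failed from all starts")
        A, g, c = best.x
        return (A, g, c)
    if model == 2:
        def resid2(theta):
            A1, g1, A2, g2, c = theta
            return sw * (A1 * np.exp(-g1 * d_m) + A2 * np.exp(-g2 * d_m) + c - y)

        starts = [(a, b) for a in _G_STARTS for b in _G_STARTS if b > a]
        for g1, g2 in starts:
            try:
                sol = least_squares(
                    resid2,
                    x0=[a0 / 2, g1, a0 / 2, g2, 0.0],
                    bounds=(
                        [0.0, 1e-3, 0.0, 1e-3, -np.inf],
                        [np.inf, 2000.0, np.inf, 2000.0, np.inf],
                    ),
                    max_nfev=4000,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitFailureError("two-exponential fit failed from all starts")
        A1, g1, A2, g2, c = best.x
        if g1 < g2:  # report oldest event first
            A1, g1, A2, g2 = A2, g2, A1, g1
        return (A1, g1, A2, g2, c)
    raise ValueError("model must be 1 or 2")


def fit_decay(
    curve: WeightedLDCurve, model: int = 1, generation_time: float = 30.0
) -> DateEstimate:
    """Fit A exp(-g d) + c (or a two-event sum) to a weighted-LD curve.

    Bins are weighted by pair counts; distance is handled in Morgans so g is
    in generations.  SEs are not available from a single curve — use
    :func:`date_admixture` for jackknife errors.
    """
    keep = (curve.pair_counts > 0) & np.isfinite(curve.values)
    if keep.sum() < 10:
        raise FitFailureError("need >= 10 non-empty bins")
    d_m = curve.bin_centers_cm[keep] / 100.0
    y = curve.values[keep]
    w = curve.pair_counts[keep].astype(float)
    params = _fit_bins(d_m, y, w, model)
    if model == 1:
        A, g, c = params
        return DateEstimate(g, A, c, np.nan, np.nan, np.nan, 1, generation_time)
    A1, g1, A2, g2, c = params
    return DateEstimate(
        g1, A1, c, np.nan, np.nan, np.nan, 2, generation_time, g2_hat=g2, amplitude2=A2
    )


def date_admixture(
    ds: GenotypeDataset,
    target: str,
    ref1: str,
    ref2: str,
    model: int = 1,
    generation_time: float = 30.0,
    haploidize_target: bool = True,
    seed: int = 0,
    d_min_cm: float = 0.5,
    d_max_cm: float = 30.0,
    bin_width_cm: float = 0.1,
) -> DateEstimate:
    """Full dating: curve + fit + leave-one-chromosome-out jackknife.

    The target is haploidized first by default, mirroring the practice of
    running LD dating on pseudo-haploid data so allelic drop-out cannot
    fake LD.  Requires >= 2 chromosomes for the jackknife.
    """
    n_chrom = ds.snps["chrom"].nunique()
    if n_chrom < 2:
        raise ValueError("jackknife needs >= 2 chromosomes")
    work = ds
    if haploidize_target and ds.ploidy == 2:
        work = qc.haploidize(ds, seed)
    curve = weighted_ld_curve(
        work, target, ref1, ref2, d_min_cm, d_max_cm, bin_width_cm
    )
    full = fit_decay(curve, model, generation_time)

    g_loo, a_loo, wts = [], [], []
    for k in range(len(curve.chroms)):
        vals, cnts = curve.drop_chrom(k)
        sub = WeightedLDCurve(
            curve.bin_centers_cm, vals, cnts, d_min_cm, d_max_cm, bin_width_cm,
            target, (ref1, ref2),
        )
        est_k = fit_decay(sub, model, generation_time)
        g_loo.append(est_k.g_hat)
        a_loo.append(est_k.amplitude)
        wts.append(curve.chrom_counts[k].sum())
    wts = np.asarray(wts, dtype=float)
    _, se_g = weighted_jackknife(full.g_hat, np.asarray(g_loo), wts)
    _, se_a = weighted_jackknife(full.amplitude, np.asarray(a_loo), wts)
    z_amp = full.amplitude / se_a if se_a > 0 else np.inf
    z_date = full.g_hat / se_g if se_g > 0 else np.inf
    return DateEstimate(
        full.g_hat,
        full.amplitude,
        full.affine,
        float(se_g),
        float(z_amp),
        float(z_date),
        model,
        generation_time,
        g2_hat=full.g2_hat,
        amplitude2=full.amplitude2,
    )
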