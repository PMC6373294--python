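"""Hilbert filter-bank power and weighted phase lag index connectivity.

Power is estimated per 0.25-Hz bin between 1 and 20 Hz as the squared
instantaneous amplitude of the zero-phase narrowband-filtered signal;
relative power divides each bin by the 1-20 Hz total per channel (x100).
Connectivity uses the WPLI,

    WPLI_ij = |sum_t Im X_t| / sum_t |Im X_t|,
    X_t = analytic_i(t) * conj(analytic_j(t)),

pooled over arbitrary sample masks — a behavioural-state window, the
samples labelled as one microstate, or their intersection.  WPLI is blind
to zero-lag (volume-conducted) coupling; pairs whose denominator vanishes
are flagged degenerate and reported as 0 so ROI medians stay defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .io import Recording
from .microstates import LabelSequence
from .montage import Montage

__all__ = [
    "BandGrid",
    "narrowband_analytic",
    "RelativePower",
    "relative_power",
    "theta_alpha_ratio",
    "WPLIMatrix",
    "wpli_matrix",
    "microstate_wpli",
    "roi_median_wpli",
]

_EDGE_PAD_HZ = 0.1   # widen narrowband design edges so bin-edge tones pass flat
_FILTER_ORDER = 4


@dataclass(frozen=True)
class BandGrid:
    """0.25-Hz analysis bins spanning 1-20 Hz plus named bands.

    Bins are half-open [f, f+0.25); a named band must be a union of whole
    bins.  Defaults follow the spectral peaks of the drowsy transition:
    theta 5-6 Hz, alpha 9.5-10.5 Hz.
    """

    f_lo: float = 1.0
    f_hi: float = 20.0
    width: float = 0.25
    named: tuple = (("theta", (5.0, 6.0)), ("alpha", (9.5, 10.5)))

    @property
    def bins(self) -> list[tuple[float, float]]:
        n = int(round((self.f_hi - self.f_lo) / self.width))
        return [(self.f_lo + i * self.width, self.f_lo + (i + 1) * self.width)
                for i in range(n)]

    def band_bins(self, band) -> list[tuple[float, float]]:
        """Constituent bins of a named band or explicit (lo, hi) tuple."""
        if isinstance(band, str):
            named = dict(self.named)
            if band not in named:
                raise KeyError(f"unknown band '{band}'")
            band = named[band]
        lo, hi = band
        eps = 1e-9
        out = [b for b in self.bins if b[0] >= lo - eps and b[1] <= hi + eps]
        if not out or abs(out[0][0] - lo) > eps or abs(out[-1][1] - hi) > eps:
            raise ValueError(f"band {band} is not a union of whole bins")
        return out


def _as_data(rec) -> tuple[np.ndarray, float]:
    if isinstance(rec, Recording):
        return rec.data, rec.sfreq
    raise TypeError("expected a Recording")


def narrowband_analytic(rec, fbin, sfreq: float | None = None) -> np.ndarray:
    """Complex analytic signal of one narrowband bin, per channel.

    Zero-phase Butterworth band-pass (order 4, edges padded by 0.1 Hz so a
    tone at a bin edge keeps its amplitude), then the Hilbert analytic
    signal: modulus = instantaneous amplitude, angle = instantaneous phase.
    """
    if sfreq is None:
        data, sfreq = _as_data(rec)
    else:
        data = np.atleast_2d(np.asarray(rec, dtype=float))
    lo, hi = fbin
    nyq = sfreq / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"bin {fbin} outside (0, Nyquist)")
    lo_d = max(lo - _EDGE_PAD_HZ, 0.25 * lo)
    hi_d = min(hi + _EDGE_PAD_HZ, 0.999 * nyq)
    sos = sps.butter(_FILTER_ORDER, [lo_d, hi_d], "bandpass", fs=sfreq,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, data, axis=1)
    n = filtered.shape[1]
    analytic = sps.hilbert(filtered, N=next_fast_len(n), axis=1)[:, :n]
    return analytic


@dataclass
class RelativePower:
    """Percent of 1-20 Hz power per channel per bin (rows sum to 100)."""

    values: np.ndarray            # (n_channels, n_bins)
    bins: list
    labels: tuple = ()


def _band_power(data, sfreq, bins, mask) -> np.ndarray:
    """Mean squared analytic amplitude per channel per bin over ``mask``."""
    out = np.empty((data.shape[0], len(bins)))
    for j, fbin in enumerate(bins):
        amp = np.abs(narrowband_analytic(data, fbin, sfreq))
        out[:, j] = (amp[:, mask] ** 2).mean(axis=1)
    return out


def relative_power(rec, grid: BandGrid | None = None,
                   mask: np.ndarray | None = None) -> RelativePower:
    """Relative spectral power (percent) per channel and 0.25-Hz bin."""
    data, sfreq = _as_data(rec)
    grid = grid or BandGrid()
    if mask is None:
        mask = np.ones(data.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty sample mask")
    power = _band_power(data, sfreq, grid.bins, mask)
    values = power / power.sum(axis=1, keepdims=True) * 100.0
    labels = rec.labels if isinstance(rec, Recording) else ()
    return RelativePower(values=values, bins=grid.bins, labels=labels)


def theta_alpha_ratio(rec, mask: np.ndarray | None = None,
                      grid: BandGrid | None = None):
    """Summed theta (5-6 Hz) over summed alpha (9.5-10.5 Hz) band power.

    Returns
    -------
    (per_channel, median) — channels with zero alpha power get ``inf``.
    """
    data, sfreq = _as_data(rec)
    grid = grid or BandGrid()
    if mask is None:
        mask = np.ones(data.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty sample mask")
    th = _band_power(data, sfreq, grid.band_bins("theta"), mask).sum(axis=1)
    al = _band_power(data, sfreq, grid.band_bins("alpha"), mask).sum(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(al > 0, th / np.maximum(al, 1e-300), np.inf)
    return ratio, float(np.median(ratio))


@dataclass
class WPLIMatrix:
    """Symmetric channel-pair WPLI in [0, 1] for one band and condition."""

    values: np.ndarray
    degenerate: np.ndarray
    band: tuple | str
    n_pooled: int
    condition: str = ""
    labels: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("WPLI matrix must be symmetric")
        off = ~np.eye(v.shape[0], dtype=bool)
        if np.any((v[off] < -1e-9) | (v[off] > 1 + 1e-9)):
            raise ValueError("WPLI values must lie in [0, 1]")


def _wpli_accumulate(analytic: np.ndarray, mask: np.ndarray,
                     phase_only: bool, chunk: int = 2048):
    """(num, den, amp) sums for all channel pairs over masked samples."""
    Z = analytic[:, mask]
    if phase_only:
        mod = np.abs(Z)
        mod[mod == 0] = 1.0
        Z = Z / mod
    R, I = np.real(Z), np.imag(Z)
    num = R @ I.T - I @ R.T                    # sum_t Im X_t (antisymmetric)
    n_ch, n_t = Z.shape
    # |Im X_t| has no pairwise-sum shortcut; chunked accumulation in
    # float32 (absolute sums are well conditioned) keeps memory flat
    R32, I32 = R.astype(np.float32), I.astype(np.float32)
    den = np.zeros((n_ch, n_ch))
    for s in range(0, n_t, chunk):
        r = R32[:, s:s + chunk]
        i = I32[:, s:s + chunk]
        im = r[:, None, :] * i[None, :, :]
        im -= i[:, None, :] * r[None, :, :]
        np.abs(im, out=im)
        den += im.sum(axis=2, dtype=np.float64)
    amp = np.abs(Z).sum(axis=1)
    return np.abs(num), den, amp


def _wpli_from_sums(num, den, amp) -> tuple[np.ndarray, np.ndarray]:
    scale = np.outer(amp, amp)
    degenerate = den <= 1e-12 * np.maximum(scale, 1e-300)
    values = np.zeros_like(den)
    ok = ~degenerate
    values[ok] = num[ok] / den[ok]
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(degenerate, True)
    return values, degenerate


def wpli_matrix(rec, band=None, mask: np.ndarray | None = None,
                grid: BandGrid | None = None, phase_only: bool = False,
                condition: str = "") -> WPLIMatrix:
    """WPLI over masked samples, averaged across the band's 0.25-Hz bins.

    With ``band=None`` the analytic signal of the input as given is used
    (no narrowband filtering) — the estimator-level view, appropriate when
    the input is already narrowband or for null calibration, where
    narrowband filter memory would otherwise dominate the sampling
    distribution.

    ``phase_only=True`` discards amplitude weighting (unit-modulus phases)
    as a sensitivity variant; the default is the amplitude-weighted
    imaginary cross-spectrum that defines the WPLI.
    """
    data, sfreq = _as_data(rec)
    grid = grid or BandGrid()
    if mask is None:
        mask = np.ones(data.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_pooled = int(mask.sum())
    if n_pooled == 0:
        raise ValueError("empty sample mask")
    if n_pooled < 100:
        warnings.warn(f"only {n_pooled} pooled samples for WPLI", stacklevel=2)
    bins = [None] if band is None else grid.band_bins(band)
    per_bin = []
    degen_all = None
    for fbin in bins:
        if fbin is None:
            n_t = data.shape[1]
            analytic = sps.hilbert(data - data.mean(axis=1, keepdims=True),
                                   N=next_fast_len(n_t), axis=1)[:, :n_t]
        else:
            analytic = narrowband_analytic(data, fbin, sfreq)
        num, den, amp = _wpli_accumulate(analytic, mask, phase_only)
        v, dg = _wpli_from_sums(num, den, amp)
        per_bin.append(v)
        degen_all = dg if degen_all is None else (degen_all & dg)
    values = np.mean(per_bin, axis=0)
    labels = rec.labels if isinstance(rec, Recording) else ()
    return WPLIMatrix(values=values, degenerate=degen_all, band=band,
                      n_pooled=n_pooled, condition=condition, labels=labels)


def microstate_wpli(rec, seq: LabelSequence, band,
                    state_mask: np.ndarray | None = None,
                    grid: BandGrid | None = None,
                    phase_only: bool = False) -> dict:
    """One WPLI matrix per microstate, pooling state-masked samples whose
    label equals that microstate.

    Narrowband filtering is done once per bin and shared across the k
    conditioning masks.  A microstate with no samples in the mask yields a
    fully degenerate zero matrix.
    """
    data, sfreq = _as_data(rec)
    grid = grid or BandGrid()
    if state_mask is None:
        state_mask = np.ones(data.shape[1], dtype=bool)
    state_mask = np.asarray(state_mask, dtype=bool)
    if len(seq) != data.shape[1]:
        raise ValueError("label sequence not aligned to recording samples")
    bins = grid.band_bins(band)
    k = seq.k
    sums = {m: None for m in range(k)}
    counts = {}
    for fbin in bins:
        analytic = narrowband_analytic(data, fbin, sfreq)
        for m in range(k):
            mask = state_mask & (seq.labels == m)
            counts[m] = int(mask.sum())
            if counts[m] == 0:
                continue
            num, den, amp = _wpli_accumulate(analytic, mask, phase_only)
            v, dg = _wpli_from_sums(num, den, amp)
            if sums[m] is None:
                sums[m] = [v, dg.astype(int)]
            else:
                sums[m][0] += v
                sums[m][1] += dg.astype(int)
    labels = rec.labels if isinstance(rec, Recording) else ()
    out = {}
    n_ch = data.shape[0]
    for m in range(k):
        if counts.get(m, 0) == 0:
            out[m] = WPLIMatrix(values=np.zeros((n_ch, n_ch)),
                                degenerate=np.ones((n_ch, n_ch), dtype=bool),
                                band=band, n_pooled=0,
                                condition=f"microstate={m}", labels=labels)
        else:
            v = sums[m][0] / len(bins)
            dg = sums[m][1] == len(bins)
            out[m] = WPLIMatrix(values=v, degenerate=dg, band=band,
                                n_pooled=counts[m],
                                condition=f"microstate={m}", labels=labels)
    return out


def roi_median_wpli(mat: WPLIMatrix, montage: Montage) -> dict:
    """Median WPLI within the anterior ROI, within the posterior ROI,
    between them, and over the full scalp (unique pairs only)."""
    if not mat.labels:
        raise ValueError("WPLI matrix carries no channel labels")
    lut = {l: i for i, l in enumerate(mat.labels)}
    missing = [l for roi in (montage.roi_anterior, montage.roi_posterior)
               for l in roi if l not in lut]
    if missing:
        raise ValueError(f"ROI channels missing from matrix: {missing}")
    ant = np.array([lut[l] for l in montage.roi_anterior])
    post = np.array([lut[l] for l in montage.roi_posterior])

    def unique_pairs(rows, cols=None):
        if cols is None:
            vals = [mat.values[i, j] for a, i in enumerate(rows)
                    for j in rows[a + 1:]]
        else:
            vals = [mat.values[i, j] for i in rows for j in cols]
        return np.asarray(vals)

    n = mat.values.shape[0]
    iu = np.triu_indices(n, k=1)
    return {
        "within_anterior": float(np.median(unique_pairs(ant))),
        "within_posterior": float(np.median(unique_pairs(post))),
        "between": float(np.median(unique_pairs(ant, post))),
        "full_scalp": float(np.median(mat.values[iu])),
        "n_pairs": {
            "within_anterior": len(ant) * (len(ant) - 1) // 2,
            "within_posterior": len(post) * (len(post) - 1) // 2,
            "between": len(ant) * len(post),
        },
    }
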