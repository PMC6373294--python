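"""Microstate topography clustering, labelling and temporal parameters.

The clustering is the classic polarity-invariant modified k-means over
GFP-peak topographies: samples are average-referenced and unit-normalised,
assignment uses the highest absolute spatial correlation, and each map is
re-estimated as the first principal component of its cluster.  On
unit-norm, mean-free samples the global explained variance reduces to the
mean squared spatial correlation, and both alternating steps increase it,
so the fit trace ascends monotonically; iteration stops when the GEV gain
drops below ``gev_tol`` or after ``max_iter`` iterations, and the best of
``restarts`` random initialisations is kept.

Label sequences are optionally regularised with windowed temporal smoothing
(neighbourhood ``b`` samples, penalty ``lambda``), which trades per-sample
fit against label agreement within +/-b samples.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage

__all__ = [
    "gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "canonical_templates",
    "MicrostateModel",
    "fit_microstates",
    "compute_gev",
    "LabelSequence",
    "label_sequence",
    "smooth_labels",
    "microstate_metrics",
    "match_to_templates",
    "save_model",
    "load_model",
]


def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: population SD across channels per time point.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("GFP requires at least 2 channels")
    return data.std(axis=0, ddof=0)


def find_gfp_peaks(series: np.ndarray, n_peaks: int = 5000) -> np.ndarray:
    """Indices of strict local maxima of a GFP series, in temporal order,
    truncated to the first ``n_peaks``.

    Emits a warning (and returns all peaks) if fewer than requested exist.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("series too short for peak detection")
    interior = series[1:-1]
    is_peak = (interior > series[:-2]) & (interior > series[2:])
    idx = np.flatnonzero(is_peak) + 1
    if len(idx) < n_peaks:
        warnings.warn(
            f"only {len(idx)} GFP peaks available (requested {n_peaks})",
            stacklevel=2,
        )
        return idx
    return idx[:n_peaks]


def _demean(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=-1, keepdims=True)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two topographies across channels.

    Signed; polarity-invariant users take the absolute value.  Constant
    vectors have no defined correlation and raise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("topographies differ in channel count")
    a, b = _demean(a), _demean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a constant topography")
    return float(a @ b / (na * nb))


def _corr_rows(X: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations: (n_samples, k)."""
    Xd = _demean(X)
    Md = _demean(maps)
    xn = np.linalg.norm(Xd, axis=1, keepdims=True)
    mn = np.linalg.norm(Md, axis=1, keepdims=True)
    xn[xn == 0] = 1.0
    return (Xd / xn) @ (Md / mn).T


def canonical_templates(montage: Montage) -> np.ndarray:
    """Analytic idealisations of the four canonical microstate shapes.

    These are NOT the literature group-average maps: they are simple
    geometric fields (A: left-posterior <-> right-anterior gradient,
    B: the mirror image, C: anterior <-> posterior gradient, D: focal
    fronto-central peak) used only to fix the A-D label order of fitted
    maps via :func:`match_to_templates`.
    """
    x, y = montage.positions[:, 0], montage.positions[:, 1]
    d = np.exp(-((x - 0.0) ** 2 + (y - 0.2) ** 2) / (2 * 0.35 ** 2))
    raw = np.vstack([x + y, y - x, y, d])
    raw = raw - raw.mean(axis=1, keepdims=True)
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


@dataclass
class MicrostateModel:
    """k unit-norm microstate topographies with fit diagnostics."""

    maps: np.ndarray
    k: int
    gev_total: float
    iterations: int
    converged: bool
    seed: int
    restarts: int
    gev_traces: list = field(default_factory=list)  # one ascent trace per restart

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.k < 1 or self.maps.shape[0] != self.k:
            raise ValueError("model must hold k >= 1 maps")
        if not np.allclose(np.linalg.norm(self.maps, axis=1), 1.0, atol=1e-9):
            raise ValueError("maps must be unit norm")
        if not 0.0 <= self.gev_total <= 1.0 + 1e-12:
            raise ValueError("gev_total must lie in [0, 1]")


def _normalise_samples(samples: np.ndarray) -> np.ndarray:
    X = _demean(np.asarray(samples, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("cannot normalise constant (zero-GFP) samples")
    return X / norms[:, None]


def _first_pc(U: np.ndarray, previous: np.ndarray) -> np.ndarray:
    """Leading principal axis of the rows of U, sign-aligned to ``previous``."""
    C = U.T @ U
    vals, vecs = np.linalg.eigh(C)
    v = vecs[:, -1]
    if v @ previous < 0:
        v = -v
    return v


def fit_microstates(samples: np.ndarray, k: int = 4, max_iter: int = 1000,
                    gev_tol: float = 1e-9, seed: int = 0,
                    restarts: int = 20) -> MicrostateModel:
    """Polarity-invariant modified k-means on a set of topographies.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Topographies (rows), typically GFP-peak samples.  They are
        average-referenced and unit-normalised internally.
    k : int
        Number of maps (4 by convention).
    max_iter, gev_tol : stopping rule per restart.
    seed, restarts : initial maps are random samples; the highest-GEV
        restart wins.  Empty clusters are reseeded from the currently
        worst-explained sample.
    """
    U = _normalise_samples(samples)
    n = U.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)

    best = None
    traces = []
    for _ in range(restarts):
        maps = U[rng.choice(n, size=k, replace=False)].copy()
        prev_gev = -np.inf
        trace = []
        labels = np.zeros(n, dtype=int)
        converged = False
        for it in range(1, max_iter + 1):
            C = U @ maps.T
            labels = np.argmax(np.abs(C), axis=1)
            # reseed empty clusters from the worst-explained sample
            for i in range(k):
                while not np.any(labels == i):
                    worst = np.argmin(np.abs(C[np.arange(n), labels]))
                    maps[i] = U[worst]
                    C = U @ maps.T
                    labels = np.argmax(np.abs(C), axis=1)
            for i in range(k):
                members = U[labels == i]
                maps[i] = _first_pc(members, maps[i])
            gev = float(np.mean((U @ maps.T)[np.arange(n), labels] ** 2))
            trace.append(gev)
            if gev - prev_gev < gev_tol:
                prev_gev = gev
                converged = True
                break
            prev_gev = gev
        traces.append(np.asarray(trace))
        if best is None or prev_gev > best[0]:
            best = (prev_gev, maps.copy(), it, converged)

    gev_best, maps, iterations, converged = best
    # deterministic sign: largest-magnitude channel positive
    for i in range(k):
        if maps[i][np.argmax(np.abs(maps[i]))] < 0:
            maps[i] = -maps[i]
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return MicrostateModel(maps=maps, k=k, gev_total=gev_best,
                           iterations=iterations, converged=converged,
                           seed=seed, restarts=restarts, gev_traces=traces)


def compute_gev(data: np.ndarray, labels: np.ndarray, maps: np.ndarray,
                gfp_series: np.ndarray | None = None):
    """Global explained variance per map and in total.

    GEV_i = sum_{t: label_t = i} (GFP_t * corr(x_t, map_i))^2
            / sum_t GFP_t^2

    Parameters
    ----------
    data : ndarray (n_channels, n_samples)
    labels : ndarray (n_samples,)
    maps : ndarray (k, n_channels)
    gfp_series : optional precomputed GFP of ``data``.

    Returns
    -------
    (per_map, total) : (ndarray shape (k,), float)
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if gfp_series is None:
        gfp_series = gfp(data)
    denom = float(np.sum(gfp_series ** 2))
    if denom == 0:
        raise ValueError("GEV undefined: all-zero GFP")
    corr = _corr_rows(data.T, maps)
    contrib = (gfp_series * corr[np.arange(len(labels)), labels]) ** 2
    k = maps.shape[0]
    per_map = np.array([contrib[labels == i].sum() for i in range(k)]) / denom
    return per_map, float(per_map.sum())


@dataclass
class LabelSequence:
    """Per-sample microstate assignment for one span of EEG."""

    labels: np.ndarray
    abs_corr: np.ndarray
    sfreq: float
    smoothing_b: int = 0
    k: int = 4

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.abs_corr = np.asarray(self.abs_corr, dtype=float)
        if self.labels.shape != self.abs_corr.shape:
            raise ValueError("labels and abs_corr must be the same length")
        if np.any((self.abs_corr < -1e-9) | (self.abs_corr > 1 + 1e-9)):
            raise ValueError("abs_corr must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)


def label_sequence(data: np.ndarray, maps: np.ndarray,
                   sfreq: float) -> LabelSequence:
    """Assign every sample to the map with the highest absolute spatial
    correlation (ties -> lowest map index)."""
    data = np.asarray(data, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if data.shape[0] != maps.shape[1]:
        raise ValueError(
            f"channel mismatch: data has {data.shape[0]}, maps {maps.shape[1]}"
        )
    corr = _corr_rows(data.T, maps)
    labels = np.argmax(np.abs(corr), axis=1)
    abs_corr = np.abs(corr[np.arange(len(labels)), labels])
    return LabelSequence(labels=labels, abs_corr=abs_corr, sfreq=sfreq,
                         smoothing_b=0, k=maps.shape[0])


def _smoothing_cost(data: np.ndarray, maps: np.ndarray,
                    init_labels: np.ndarray) -> np.ndarray:
    """Per-sample, per-map misfit term of the smoothing objective.

    e[t, l] = (x_t'x_t - (a_l'x_t)^2) / (2 sigma^2 (N - 1)), with the
    residual scale sigma^2 estimated once from the initial labelling and
    held fixed (keeps the objective identical across passes and for the
    exhaustive oracle).
    """
    X = _demean(data.T)                       # (T, N)
    M = _demean(maps)
    M = M / np.linalg.norm(M, axis=1, keepdims=True)
    n_ch = X.shape[1]
    x2 = np.sum(X ** 2, axis=1)
    proj2 = (X @ M.T) ** 2
    resid0 = x2 - proj2[np.arange(len(x2)), init_labels]
    sigma2 = max(float(resid0.mean() / (n_ch - 1)), 1e-300)
    return (x2[:, None] - proj2) / (2.0 * sigma2 * (n_ch - 1))


def _neighbour_counts(labels: np.ndarray, k: int, b: int) -> np.ndarray:
    """counts[t, l]: same-label neighbours of t within +/-b, excluding t."""
    T = len(labels)
    onehot = np.zeros((T, k))
    onehot[np.arange(T), labels] = 1.0
    cs = np.vstack([np.zeros((1, k)), np.cumsum(onehot, axis=0)])
    lo = np.maximum(np.arange(T) - b, 0)
    hi = np.minimum(np.arange(T) + b + 1, T)
    window = cs[hi] - cs[lo]
    return window - onehot


def smooth_labels(seq: LabelSequence, data: np.ndarray, maps: np.ndarray,
                  b: int = 5, lam: float = 5.0,
                  max_pass: int = 100) -> LabelSequence:
    """Windowed temporal smoothing of a label sequence.

    Each pass simultaneously reassigns every sample to the map minimising
    (misfit) - lambda * (same-label neighbours within +/-b samples), until
    the labelling is stable (or cycles, or ``max_pass``).  ``b = 0``
    returns the input labelling unchanged.
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    if b == 0:
        return LabelSequence(labels=seq.labels.copy(),
                             abs_corr=seq.abs_corr.copy(), sfreq=seq.sfreq,
                             smoothing_b=0, k=seq.k)
    e = _smoothing_cost(data, maps, seq.labels)
    labels = seq.labels.copy()
    previous = None
    for _ in range(max_pass):
        counts = _neighbour_counts(labels, seq.k, b)
        new = np.argmin(e - lam * counts, axis=1)
        if np.array_equal(new, labels) or (
                previous is not None and np.array_equal(new, previous)):
            labels = new
            break
        previous, labels = labels, new
    corr = _corr_rows(_demean(data.T), maps)
    abs_corr = np.abs(corr[np.arange(len(labels)), labels])
    return LabelSequence(labels=labels, abs_corr=abs_corr, sfreq=seq.sfreq,
                         smoothing_b=b, k=seq.k)


def _segment_runs(labels: np.ndarray):
    """(label, length) pairs of maximal runs."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def microstate_metrics(seq: LabelSequence, data: np.ndarray | None = None,
                       maps: np.ndarray | None = None,
                       mask: np.ndarray | None = None) -> pd.DataFrame:
    """Duration, coverage and (optionally) GEV per microstate.

    duration_ms is the mean contiguous run length (runs truncated by span
    or mask edges count as runs; a microstate never visited gets 0.0);
    coverage_pct sums to 100 across microstates.  GEV is filled when
    ``data`` and ``maps`` are given.  With ``mask``, the sequence is split
    into the mask's contiguous segments and runs never bridge a gap.
    """
    if len(seq) == 0:
        raise ValueError("empty label sequence")
    k = seq.k
    if mask is None:
        segments = [np.arange(len(seq))]
    else:
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError("mask selects no samples")
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        segments = np.split(idx, breaks)

    run_sum = np.zeros(k)
    run_count = np.zeros(k)
    cover = np.zeros(k)
    for seg in segments:
        for lab, length in _segment_runs(seq.labels[seg]):
            run_sum[lab] += length
            run_count[lab] += 1
        cover += np.bincount(seq.labels[seg], minlength=k)

    total = cover.sum()
    duration_ms = np.where(run_count > 0, run_sum / np.maximum(run_count, 1)
                           * 1000.0 / seq.sfreq, 0.0)
    out = pd.DataFrame({
        "duration_ms": duration_ms,
        "coverage_pct": cover / total * 100.0,
    }, index=pd.RangeIndex(k, name="microstate"))
    if data is not None and maps is not None:
        sel = np.concatenate(segments)
        per_map, _ = compute_gev(np.asarray(data)[:, sel], seq.labels[sel],
                                 maps)
        out["gev"] = per_map
    return out


def match_to_templates(maps: np.ndarray, templates: np.ndarray):
    """Order fitted maps against template maps (polarity-invariant).

    Exhaustively maximises the summed absolute spatial correlation over all
    k! assignments.

    Returns
    -------
    reordered : ndarray
        ``maps`` permuted so row i corresponds to template i.
    perm : tuple of int
        ``perm[i]`` is the original index of the map assigned to template i.
    pair_corr : ndarray
        Absolute correlation of each matched pair.
    """
    maps = np.asarray(maps, dtype=float)
    templates = np.asarray(templates, dtype=float)
    if maps.shape != templates.shape:
        raise ValueError("maps and templates must share k and channel count")
    k = maps.shape[0]
    C = np.abs(_corr_rows(templates, maps))  # (k templates, k maps)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(C[i, perm[i]] for i in range(k))
        if score > best_score:
            best_perm, best_score = perm, score
    pair_corr = np.array([C[i, best_perm[i]] for i in range(k)])
    return maps[list(best_perm)], tuple(best_perm), pair_corr


def save_model(path, model: MicrostateModel, channel_labels=None) -> None:
    doc = {
        "format": "hypnostates-microstate-model-v1",
        "k": model.k,
        "gev_total": model.gev_total,
        "iterations": model.iterations,
        "converged": model.converged,
        "seed": model.seed,
        "restarts": model.restarts,
        "channel_labels": list(channel_labels) if channel_labels else None,
        "maps": [[float(v) for v in row] for row in model.maps],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> MicrostateModel:
    doc = json.loads(Path(path).read_text())
    return MicrostateModel(
        maps=np.asarray(doc["maps"], dtype=float), k=doc["k"],
        gev_total=doc["gev_total"], iterations=doc["iterations"],
        converged=doc["converged"], seed=doc["seed"],
        restarts=doc["restarts"],
    )
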