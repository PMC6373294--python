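"""Hit/miss trial classification and selection of the two balanced 5-min
behavioural-state windows.

A trial is a hit when a button response follows the stimulus within the
(liberal) 6-s window, regardless of correctness.  The responsive window is
the fixed early interval [30 s, 330 s); the unresponsive window is found
algorithmically as the later 5-min interval containing as many misses as
possible.  If a hit occurs inside the unresponsive window, the 10 s before
and after the stimulus are excluded from its sample mask.

Intervals are half-open seconds; conversion to samples is floor(t * fs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Recording

__all__ = [
    "classify_trials",
    "select_responsive_period",
    "select_unresponsive_period",
    "build_state_masks",
    "StateMasks",
]

RESPONSE_WINDOW_S = 6.0
EXCLUSION_PAD_S = 10.0


def classify_trials(events: pd.DataFrame, window: float = RESPONSE_WINDOW_S
                    ) -> np.ndarray:
    """Boolean hit flag per trial: a response exists with 0 < rt <= window."""
    if window <= 0:
        raise ValueError("response window must be positive")
    rt = events["response_time_s"] - events["stim_time_s"]
    return ((rt > 0) & (rt <= window)).to_numpy()


def select_responsive_period(rec: Recording, events: pd.DataFrame,
                             start_s: float = 30.0, length_s: float = 300.0,
                             miss_warn_frac: float = 0.10):
    """The early fixed responsive window [start, start+length) seconds.

    Warns (without failing) if the miss fraction inside the window exceeds
    ``miss_warn_frac`` — occasional misses are expected even while alert.
    """
    end_s = start_s + length_s
    if rec.duration_s < end_s:
        raise ValueError(
            f"recording of {rec.duration_s:.1f}s shorter than responsive "
            f"window end {end_s:.1f}s")
    hits = classify_trials(events)
    inside = (events["stim_time_s"] >= start_s) & (events["stim_time_s"] < end_s)
    n_in = int(inside.sum())
    if n_in:
        miss_frac = 1.0 - hits[inside.to_numpy()].mean()
        if miss_frac > miss_warn_frac:
            warnings.warn(
                f"responsive window contains {miss_frac:.0%} misses",
                stacklevel=2)
    return (start_s, end_s)


def select_unresponsive_period(events: pd.DataFrame, after: float,
                               length: float = 300.0, step: float = 1.0):
    """Later 5-min window maximising the miss count.

    Candidate windows start at ``after + i*step``; ties are broken by the
    smallest miss-to-hit ratio, then by the earliest start.
    """
    stim = events["stim_time_s"].to_numpy()
    hits = classify_trials(events)
    t_end = stim.max() if len(stim) else -np.inf
    if t_end < after + length:
        raise ValueError("events do not extend far enough past `after` to "
                         "fit an unresponsive window")
    best = None
    start = after
    while start + length <= t_end + step:
        inside = (stim >= start) & (stim < start + length)
        n_miss = int((~hits[inside]).sum())
        n_hit = int(hits[inside].sum())
        if n_hit > 0:
            ratio = n_miss / n_hit
        elif n_miss > 0:
            ratio = -np.inf   # pure-miss window beats any mixed window
        else:
            ratio = np.inf    # stimulus-free window is the weakest tie
        key = (-n_miss, ratio, start)
        if best is None or key < best[0]:
            best = (key, (start, start + length))
        start += step
    return best[1]


@dataclass
class StateMasks:
    """Boolean per-sample masks for the two behavioural states."""

    responsive: np.ndarray
    unresponsive: np.ndarray
    excluded_windows: list          # [start, end) seconds cleared around hits
    sfreq: float

    def __post_init__(self) -> None:
        self.responsive = np.asarray(self.responsive, dtype=bool)
        self.unresponsive = np.asarray(self.unresponsive, dtype=bool)
        if np.any(self.responsive & self.unresponsive):
            raise ValueError("state masks must be disjoint")


def build_state_masks(rec: Recording, events: pd.DataFrame,
                      resp_window, unresp_window,
                      exclusion_pad_s: float = EXCLUSION_PAD_S) -> StateMasks:
    """Per-sample masks for the two windows, with +/-10 s cleared around
    every hit stimulus inside the unresponsive window.

    The responsive mask is never reduced by exclusions.
    """
    r0, r1 = resp_window
    u0, u1 = unresp_window
    if max(r0, u0) < min(r1, u1):
        raise ValueError("state windows overlap")
    n = rec.n_samples
    fs = rec.sfreq

    def to_mask(t0, t1):
        m = np.zeros(n, dtype=bool)
        m[int(np.floor(t0 * fs)):int(np.floor(t1 * fs))] = True
        return m

    resp = to_mask(r0, r1)
    unresp = to_mask(u0, u1)
    hits = classify_trials(events)
    excluded = []
    for stim, hit in zip(events["stim_time_s"], hits):
        if hit and u0 <= stim < u1:
            e0 = max(stim - exclusion_pad_s, u0)
            e1 = min(stim + exclusion_pad_s, u1)
            unresp[int(np.floor(e0 * fs)):int(np.floor(e1 * fs))] = False
            excluded.append((float(e0), float(e1)))
    return StateMasks(responsive=resp, unresponsive=unresp,
                      excluded_windows=excluded, sfreq=fs)
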