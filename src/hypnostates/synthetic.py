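"""Ground-truthed synthetic drowsy-EEG cohorts.

Each synthetic subject starts out responsive (posterior ~10 Hz alpha with
phase-lagged frontoparietal coupling, prompt button responses) and becomes
unresponsive later in the recording (~5.5 Hz theta, responses replaced by
misses).  Four planted quasi-stable topographies switch with
state-dependent dwell times and coverage; the fourth map ("D",
fronto-central) dwells longer and covers more time when unresponsive, and
theta-band ROI coupling is phase-consistent only while it is active.  All
generation is a pure function of (spec, seed).

Signal model, per sample t with active map m(t) and behavioural state s(t):

    x(t) = A_ms * env(t) * sin(psi_t) * map_{m(t)}
         + sum_{ch in ROIs} g_ch * A_s * sin(theta_t + delta_ch + u_t * eta_ch(t))
         + white noise,        then average-referenced.

``psi`` and ``theta`` are independent phase processes whose frequency
switches from alpha to theta at the unresponsive onset; ``delta_ch`` are
fixed per-channel phase offsets (a travelling-wave gradient, so channel
pairs have constant non-zero lags that WPLI can detect); ``eta_ch`` is
per-channel Brownian phase jitter switched in (``u_t`` ~ 1) whenever the
coupling is "off", which destroys phase consistency without changing band
power.  During responsiveness the coupling is always on; during
unresponsiveness it is on only while the true label is D (configurable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording, write_edf, write_events
from .montage import Montage, make_montage

__all__ = [
    "CohortSpec",
    "TruthSidecar",
    "sample_state_timeline_and_events",
    "sample_microstate_truth",
    "planted_topographies",
    "synthesize_recording",
    "simulate_subject",
    "write_cohort",
    "read_sidecar",
]

RESPONSIVE, UNRESPONSIVE = 0, 1


class SpecError(ValueError):
    """Configuration error in a CohortSpec."""


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Defaults encode the study conditions: 16 subjects, 500 Hz, 63 channels,
    stimuli every 8.4 s on average (minimum gap 6.2 s), lognormal reaction
    times with mean 1.5 s and SD 0.7 s while responsive, and a microstate-D
    dwell/coverage increase plus theta coupling after the unresponsive
    onset.  Dwell means are in ms, coverage targets in percent (per state,
    summing to 100), amplitudes in µV.
    """

    n_subjects: int = 16
    duration_s: float = 780.0
    sample_rate: float = 500.0
    n_channels: int = 63
    unresp_onset_s: float = 420.0
    transition_s: float = 40.0

    isi_mean_s: float = 8.4
    isi_min_s: float = 6.2
    rt_mean_s: float = 1.5
    rt_sd_s: float = 0.7
    rt_max_s: float = 6.0
    miss_rate_responsive: float = 0.02
    response_leak_rate: float = 0.02

    dwell_ms_responsive: tuple = (40.0, 40.0, 40.0, 40.0)
    dwell_ms_unresponsive: tuple = (55.0, 50.0, 55.0, 90.0)
    coverage_pct_responsive: tuple = (26.0, 28.0, 27.0, 19.0)
    coverage_pct_unresponsive: tuple = (22.0, 18.0, 25.0, 35.0)

    alpha_freq_hz: float = 10.0
    theta_freq_hz: float = 5.5
    microstate_amp_uv: float = 60.0   # vector norm of the map component at carrier peaks
    alpha_amp_uv: float = 4.0         # per-channel ROI oscillator amplitude, responsive
    theta_amp_uv: float = 4.0         # per-channel ROI oscillator amplitude, unresponsive
    roi_phase_lag_rad: float = float(np.pi / 4)
    d_theta_coupling: bool = True
    d_theta_gain: float = 2.5         # oscillator amplitude boost in coupled episodes
    d_episode_mean_s: float = 4.0     # mean on/off duration of coupling episodes
    d_coverage_on_pct: float = 60.0   # microstate-D coverage inside an episode
    map_jitter: float = 0.15
    noise_sd_uv: float = 2.0

    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.dwell_ms_responsive)
        for name in ("dwell_ms_unresponsive", "coverage_pct_responsive",
                     "coverage_pct_unresponsive"):
            if len(getattr(self, name)) != k:
                raise SpecError(f"{name} must have {k} entries")
        for cov in (self.coverage_pct_responsive, self.coverage_pct_unresponsive):
            if abs(sum(cov) - 100.0) > 1e-6:
                raise SpecError("coverage targets per state must sum to 100%")
            if min(cov) <= 0:
                raise SpecError("coverage targets must be positive")
        if self.isi_min_s > self.isi_mean_s:
            raise SpecError("minimum inter-stimulus gap must not exceed the mean")
        for name in ("duration_s", "sample_rate", "isi_mean_s", "rt_mean_s",
                     "rt_sd_s"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        for dw in self.dwell_ms_responsive + self.dwell_ms_unresponsive:
            if dw / 1000.0 * self.sample_rate <= 2.0:
                raise SpecError("dwell means must exceed 2 samples")
        cov_d = self.coverage_pct_unresponsive[-1]
        off = 2.0 * cov_d - self.d_coverage_on_pct
        if not (0.0 <= off < 100.0) or not (0.0 < self.d_coverage_on_pct < 100.0):
            raise SpecError("d_coverage_on_pct incompatible with the "
                            "unresponsive microstate-D coverage target")

    @property
    def k(self) -> int:
        return len(self.dwell_ms_responsive)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))

    def null(self) -> "CohortSpec":
        """Variant with no state differences (pipeline calibration)."""
        return replace(
            self,
            dwell_ms_unresponsive=self.dwell_ms_responsive,
            coverage_pct_unresponsive=self.coverage_pct_responsive,
            theta_freq_hz=self.alpha_freq_hz,
            theta_amp_uv=self.alpha_amp_uv,
            d_theta_coupling=False,
            d_coverage_on_pct=self.coverage_pct_responsive[-1],
        )


@dataclass
class TruthSidecar:
    """Ground truth accompanying one synthetic recording.

    ``coupling`` marks the slow theta-coupling episodes of the unresponsive
    span (microstate D is enriched inside them); always 0 while responsive.
    """

    labels: np.ndarray          # per-sample true microstate index
    state: np.ndarray           # per-sample behavioural state (0/1)
    maps: np.ndarray            # k x channels, unit norm, zero mean
    params: dict
    seed: int
    coupling: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.coupling is None:
            self.coupling = np.zeros(len(self.labels), dtype=np.int8)
        self.coupling = np.asarray(self.coupling, dtype=np.int8)
        if not len(self.labels) == len(self.state) == len(self.coupling):
            raise ValueError("labels/state/coupling timelines differ in length")
        if np.any(np.diff(self.state.astype(int)) < 0):
            raise ValueError("state timeline must be responsive before unresponsive")
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("planted topographies must be unit norm")


def _rle(values: np.ndarray) -> list:
    """Run-length encode as [value, start, end) triples."""
    values = np.asarray(values)
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    return [[int(values[s]), int(s), int(e)] for s, e in zip(starts, ends)]


def _unrle(runs: list, n: int) -> np.ndarray:
    out = np.empty(n, dtype=np.int8)
    for v, s, e in runs:
        out[s:e] = v
    return out


def write_sidecar(path, truth: TruthSidecar) -> None:
    doc = {
        "format": "hypnostates-truth-v1",
        "seed": truth.seed,
        "params": truth.params,
        "n_samples": int(len(truth.labels)),
        "maps": [[round(float(v), 9) for v in row] for row in truth.maps],
        "state_rle": _rle(truth.state),
        "label_rle": _rle(truth.labels),
        "coupling_rle": _rle(truth.coupling),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_sidecar(path) -> TruthSidecar:
    doc = json.loads(Path(path).read_text())
    n = doc["n_samples"]
    return TruthSidecar(
        labels=_unrle(doc["label_rle"], n),
        state=_unrle(doc["state_rle"], n),
        maps=np.asarray(doc["maps"], dtype=float),
        params=doc["params"],
        seed=doc["seed"],
        coupling=_unrle(doc["coupling_rle"], n),
    )


# ---------------------------------------------------------------------------
# timeline + events

def state_timeline(spec: CohortSpec) -> np.ndarray:
    """Per-sample behavioural state: responsive from 0, unresponsive from
    the configured onset."""
    n = spec.n_samples
    onset = int(round(spec.unresp_onset_s * spec.sample_rate))
    out = np.zeros(n, dtype=np.int8)
    out[onset:] = UNRESPONSIVE
    return out


def sample_state_timeline_and_events(spec: CohortSpec, seed: int):
    """Draw the stimulus/response log for one subject.

    Inter-stimulus gaps are ``isi_min + Exponential(isi_mean - isi_min)``.
    While responsive, each stimulus receives a lognormal reaction time
    (mean ``rt_mean_s``, SD ``rt_sd_s``, truncated at ``rt_max_s``) except
    for a small miss rate; across the optional transition band the miss
    probability ramps up linearly; once unresponsive, responses occur only
    at the leak rate.

    Returns
    -------
    (state, events) : (ndarray of int8, DataFrame)
    """
    if spec.duration_s < 720.0:
        raise SpecError("duration must be at least 12 min so both 5-min "
                        "state windows fit")
    rng = np.random.default_rng([int(seed), 1])
    # lognormal with the requested distribution mean/SD
    sigma2 = np.log1p((spec.rt_sd_s / spec.rt_mean_s) ** 2)
    mu = np.log(spec.rt_mean_s) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)

    t = 0.0
    rows = []
    onset, trans = spec.unresp_onset_s, spec.transition_s
    while True:
        t = t + spec.isi_min_s + rng.exponential(spec.isi_mean_s - spec.isi_min_s)
        if t >= spec.duration_s - spec.rt_max_s:
            break
        if t < onset - trans:
            p_miss = spec.miss_rate_responsive
        elif t < onset:
            frac = (t - (onset - trans)) / trans
            p_miss = spec.miss_rate_responsive + frac * (
                1.0 - spec.response_leak_rate - spec.miss_rate_responsive)
        else:
            p_miss = 1.0 - spec.response_leak_rate
        miss = rng.random() < p_miss
        rt = np.nan
        if not miss:
            rt = float(np.exp(rng.normal(mu, sigma)))
            while rt > spec.rt_max_s:
                rt = float(np.exp(rng.normal(mu, sigma)))
        rows.append({
            "stim_time_s": round(t, 4),
            "category": "animal" if rng.random() < 0.5 else "object",
            "response_time_s": round(t + rt, 4) if not miss else np.nan,
        })
    events = pd.DataFrame(rows, columns=["stim_time_s", "category",
                                         "response_time_s"])
    events["rt_s"] = events["response_time_s"] - events["stim_time_s"]
    return state_timeline(spec), events


# ---------------------------------------------------------------------------
# microstate truth sequence

def _transition_weights(coverage, dwell_samples, n_iter: int = 200):
    """Next-state sampling weights whose semi-Markov stationary occupancy
    matches the coverage targets.

    With next-state probability proportional to ``w_j`` (self excluded) the
    visit-frequency stationary distribution is not exactly proportional to
    ``w``; a short fixed-point iteration corrects for the exclusion.
    """
    cov = np.asarray(coverage, dtype=float)
    dwell = np.asarray(dwell_samples, dtype=float)
    f_target = cov / dwell
    f_target = f_target / f_target.sum()
    k = len(cov)
    w = f_target.copy()
    for _ in range(n_iter):
        P = np.tile(w, (k, 1))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        w = w * f_target / np.maximum(pi, 1e-12)
        w = w / w.sum()
    return w


def sample_coupling_episodes(spec: CohortSpec, state: np.ndarray,
                             seed: int) -> np.ndarray:
    """Slow on/off theta-coupling episode process for the unresponsive span.

    Alternating exponential episodes with mean ``d_episode_mean_s`` each;
    zero everywhere while responsive.  These episodes carry the
    phase-consistent frontoparietal theta coupling and concentrate
    microstate D, so that conditioning connectivity on the D timecourse
    recovers the coupling despite the seconds-scale memory of 0.25-Hz
    narrowband filters.
    """
    rng = np.random.default_rng([int(seed), 5])
    n = len(state)
    out = np.zeros(n, dtype=np.int8)
    idx = np.flatnonzero(state == UNRESPONSIVE)
    if len(idx) == 0:
        return out
    mean_samples = spec.d_episode_mean_s * spec.sample_rate
    pos = idx[0]
    on = bool(rng.random() < 0.5)
    while pos < n:
        length = int(rng.exponential(mean_samples)) + 1
        end = min(pos + length, n)
        if on:
            out[pos:end] = 1
        pos = end
        on = not on
    return out


def _unresponsive_phase_coverage(spec: CohortSpec, on: bool) -> np.ndarray:
    """Coverage targets inside/outside a coupling episode.

    Microstate D covers ``d_coverage_on_pct`` inside episodes and the
    mirror value outside (episodes are half the time, so the state-level
    target is preserved); the other maps share the remainder in their
    target proportions.
    """
    cov = np.asarray(spec.coverage_pct_unresponsive, dtype=float)
    d_target = cov[-1]
    d_phase = spec.d_coverage_on_pct if on else 2.0 * d_target - spec.d_coverage_on_pct
    others = cov[:-1] * (100.0 - d_phase) / cov[:-1].sum()
    return np.concatenate([others, [d_phase]])


def sample_microstate_truth(spec: CohortSpec, state: np.ndarray, seed: int,
                            coupling: np.ndarray | None = None) -> np.ndarray:
    """Semi-Markov true label sequence.

    Run lengths are geometric with a 2-sample floor and mean equal to the
    configured dwell for the behavioural state at run onset; successive
    states never repeat and are drawn so long-run coverage approaches the
    per-state targets.  In the unresponsive span, microstate D is enriched
    inside coupling episodes (and depleted outside) while preserving the
    state-level coverage target.
    """
    rng = np.random.default_rng([int(seed), 2])
    fs = spec.sample_rate
    n = len(state)
    k = spec.k
    if coupling is None:
        coupling = sample_coupling_episodes(spec, state, seed)
    dwell = {
        RESPONSIVE: np.asarray(spec.dwell_ms_responsive) / 1000.0 * fs,
        UNRESPONSIVE: np.asarray(spec.dwell_ms_unresponsive) / 1000.0 * fs,
    }
    cover = {
        (RESPONSIVE, 0): np.asarray(spec.coverage_pct_responsive, dtype=float),
        (UNRESPONSIVE, 0): _unresponsive_phase_coverage(spec, False),
        (UNRESPONSIVE, 1): _unresponsive_phase_coverage(spec, True),
    }
    weights = {key: _transition_weights(cov, dwell[key[0]])
               for key, cov in cover.items()}

    def _key(pos):
        st = int(state[pos])
        return (st, int(coupling[pos]) if st == UNRESPONSIVE else 0)

    labels = np.empty(n, dtype=np.int8)
    current = int(rng.choice(k, p=cover[_key(0)] / 100.0))
    pos = 0
    while pos < n:
        key = _key(pos)
        mean_run = dwell[key[0]][current]
        p = min(1.0, 1.0 / (mean_run - 1.0))
        run = 1 + int(rng.geometric(p))
        end = min(pos + run, n)
        labels[pos:end] = current
        pos = end
        w = weights[key].copy()
        w[current] = 0.0
        current = int(rng.choice(k, p=w / w.sum()))
    return labels


# ---------------------------------------------------------------------------
# planted maps + raw signal

def planted_topographies(montage: Montage, seed: int,
                         jitter: float = 0.15) -> np.ndarray:
    """Four unit-norm, zero-mean, mutually orthogonal planted maps.

    Starts from the analytic idealisations of the four canonical
    topographies, adds a smooth per-subject random field of relative
    amplitude ``jitter``, then symmetrically orthogonalises (Löwdin) so the
    cluster structure is well separated.
    """
    from .microstates import canonical_templates

    rng = np.random.default_rng([int(seed), 4])
    maps = canonical_templates(montage).copy()
    if jitter > 0:
        pos = montage.positions
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        K = np.exp(-d2 / (2 * 0.3 ** 2))
        for i in range(maps.shape[0]):
            fld = K @ rng.normal(size=montage.n_channels)
            fld -= fld.mean()
            fld /= np.linalg.norm(fld)
            maps[i] = maps[i] + jitter * fld
    # Löwdin orthogonalisation of the row space
    G = maps @ maps.T
    evals, evecs = np.linalg.eigh(G)
    G_isqrt = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    maps = G_isqrt @ maps
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps


def _roi_gains_offsets(montage: Montage, lag: float):
    """Per-channel oscillator gains and fixed phase offsets.

    Posterior channels share a tight phase cluster near zero; anterior
    channels form a travelling-wave gradient starting ``lag`` radians later,
    so anterior-anterior and anterior-posterior pairs both see constant
    non-zero lags.
    """
    n = montage.n_channels
    gains = np.zeros(n)
    offsets = np.zeros(n)
    for roi_idx, centre, base, spread in (
        (montage.posterior_idx(), (0.0, -0.55), 0.0, 0.12 * np.pi),
        (montage.anterior_idx(), (0.0, 0.55), lag, 0.6 * np.pi),
    ):
        pos = montage.positions[roi_idx]
        d2 = ((pos - np.asarray(centre)) ** 2).sum(axis=1)
        gains[roi_idx] = np.exp(-d2 / (2 * 0.45 ** 2))
        order = np.argsort(pos[:, 0])  # left-to-right wave
        off = np.empty(len(roi_idx))
        off[order] = base + np.linspace(0.0, spread, len(roi_idx))
        offsets[roi_idx] = off
    return gains, offsets


def synthesize_recording(truth: TruthSidecar, montage: Montage,
                         spec: CohortSpec) -> Recording:
    """Render the raw multichannel signal for one subject (µV)."""
    if truth.maps.shape[1] != montage.n_channels:
        raise ValueError("truth maps and montage disagree on channel count")
    rng = np.random.default_rng([int(truth.seed), 3])
    fs = spec.sample_rate
    n_t = len(truth.labels)
    n_ch = montage.n_channels
    state = truth.state.astype(int)
    t = np.arange(n_t) / fs

    # carrier for the active topography: alpha while responsive, theta after
    freq = np.where(state == RESPONSIVE, spec.alpha_freq_hz, spec.theta_freq_hz)
    psi = 2 * np.pi * np.cumsum(freq) / fs + np.cumsum(
        rng.normal(0.0, 0.03, n_t))
    env = 1.0 + 0.25 * np.sin(2 * np.pi * 0.08 * t + rng.uniform(0, 2 * np.pi))
    carrier = spec.microstate_amp_uv * env * np.sin(psi)

    data = np.empty((n_ch, n_t))
    noise = spec.noise_sd_uv
    for i in range(truth.maps.shape[0]):
        mask = truth.labels == i
        data[:, mask] = np.outer(truth.maps[i], carrier[mask])

    # ROI-coupled oscillators with a distinct phase process
    theta_ph = 2 * np.pi * np.cumsum(freq) / fs + np.cumsum(
        rng.normal(0.0, 0.03, n_t)) + rng.uniform(0, 2 * np.pi)
    amp = np.where(state == RESPONSIVE, spec.alpha_amp_uv, spec.theta_amp_uv)
    coupled = (state == RESPONSIVE)
    if spec.d_theta_coupling:
        episode = (state == UNRESPONSIVE) & (truth.coupling == 1)
        coupled = coupled | episode
        amp = np.where(episode, spec.theta_amp_uv * spec.d_theta_gain, amp)
    uncoupled = (~coupled).astype(float)
    # soft blend of the jitter over ~20 ms to avoid hard phase clicks
    w = np.ones(11) / 11.0
    u = np.convolve(uncoupled, w, mode="same")

    gains, offsets = _roi_gains_offsets(montage, spec.roi_phase_lag_rad)
    active = np.flatnonzero(gains > 0.05)
    for ch in active:
        eta = np.cumsum(rng.normal(0.0, 0.22, n_t))
        data[ch] += gains[ch] * amp * np.sin(theta_ph + offsets[ch] + u * eta)

    if noise > 0:
        data += rng.normal(0.0, noise, (n_ch, n_t))
    data -= data.mean(axis=0, keepdims=True)

    rec = Recording(data=data, sfreq=fs, labels=montage.labels,
                    montage=montage, reference="common_average")
    rec.log("synthesize_recording", seed=truth.seed)
    return rec


def simulate_subject(spec: CohortSpec, seed: int,
                     montage: Montage | None = None):
    """Generate one subject: (Recording, events, TruthSidecar)."""
    if montage is None:
        montage = make_montage(spec.n_channels)
    state, events = sample_state_timeline_and_events(spec, seed)
    coupling = sample_coupling_episodes(spec, state, seed)
    labels = sample_microstate_truth(spec, state, seed, coupling)
    maps = planted_topographies(montage, seed, spec.map_jitter)
    truth = TruthSidecar(
        labels=labels, state=state, maps=maps, coupling=coupling,
        params={
            "alpha_freq_hz": spec.alpha_freq_hz,
            "theta_freq_hz": spec.theta_freq_hz,
            "roi_phase_lag_rad": spec.roi_phase_lag_rad,
            "microstate_amp_uv": spec.microstate_amp_uv,
            "alpha_amp_uv": spec.alpha_amp_uv,
            "theta_amp_uv": spec.theta_amp_uv,
            "noise_sd_uv": spec.noise_sd_uv,
            "sample_rate": spec.sample_rate,
            "unresp_onset_s": spec.unresp_onset_s,
        },
        seed=int(seed),
    )
    rec = synthesize_recording(truth, montage, spec)
    return rec, events, truth


def write_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write a full cohort to disk: per subject one EDF, one events CSV and
    one truth sidecar, plus a manifest.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = make_montage(spec.n_channels)
    rng = np.random.default_rng(spec.seed)
    subject_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, spec.n_subjects)]
    manifest = {"format": "hypnostates-cohort-v1", "seed": spec.seed,
                "n_subjects": spec.n_subjects, "subjects": []}
    for i, sseed in enumerate(subject_seeds):
        sid = f"sub-{i + 1:02d}"
        rec, events, truth = simulate_subject(spec, sseed, montage)
        edf = out / f"{sid}_eeg.edf"
        csv = out / f"{sid}_events.csv"
        sidecar = out / f"{sid}_truth.json"
        try:
            write_edf(edf, rec.data, rec.sfreq, rec.labels)
            write_events(csv, events)
            write_sidecar(sidecar, truth)
        except OSError as exc:
            raise OSError(f"failed writing cohort file: {exc}") from exc
        manifest["subjects"].append({
            "id": sid, "seed": sseed, "edf": edf.name,
            "events": csv.name, "truth": sidecar.name,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
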