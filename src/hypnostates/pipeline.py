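"""End-to-end cohort analysis: simulate (or load) a cohort, fit the group
microstate model, extract per-state microstate parameters, test them with
repeated-measures statistics, condition WPLI connectivity on the microstate
timecourse, and run leave-one-subject-out responsiveness prediction.

Connectivity is evaluated on the ROI channel subset (the anterior and
posterior groups) — the reported quantities are ROI-pair medians, for which
the ROI submatrix is sufficient and substantially cheaper than the full
63 x 63 pair set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Recording
from .microstates import (MicrostateModel, canonical_templates, find_gfp_peaks,
                          fit_microstates, gfp, label_sequence,
                          match_to_templates, microstate_metrics, smooth_labels)
from .montage import Montage, make_montage
from .prediction import CVResult, build_trial_features, loso_cv
from .preprocess import bandpass_filter, center_and_average_reference
from .segmentation import (build_state_masks, select_responsive_period,
                           select_unresponsive_period)
from .spectral import BandGrid, microstate_wpli, roi_median_wpli, wpli_matrix
from .stats import (paired_t_cohens_d, rm_anova_2way, simple_effects_posthoc,
                    storey_fdr)
from .synthetic import CohortSpec, simulate_subject

__all__ = [
    "preprocess_recording",
    "subject_state_masks",
    "collect_state_peaks",
    "CohortAnalysis",
    "analyze_cohort",
]


def preprocess_recording(rec: Recording, low: float = 1.0, high: float = 40.0,
                         drop=()) -> Recording:
    """Standard chain: band-pass, drop channels, centre, average-reference."""
    out = bandpass_filter(rec, low, high)
    return center_and_average_reference(out, drop)


def subject_state_masks(rec: Recording, events: pd.DataFrame,
                        resp_start_s: float = 30.0, length_s: float = 300.0):
    """The two balanced 5-min state windows and their sample masks."""
    resp = select_responsive_period(rec, events, start_s=resp_start_s,
                                    length_s=length_s)
    unresp = select_unresponsive_period(events, after=resp[1], length=length_s)
    return build_state_masks(rec, events, resp, unresp)


def collect_state_peaks(rec: Recording, masks, n_per_state: int = 5000,
                        edge_s: float = 1.0) -> np.ndarray:
    """GFP-peak topographies from both state windows (rows = samples).

    The first/last second of the recording is excluded from peak selection
    (filter edge transients).
    """
    g = gfp(rec.data)
    edge = int(edge_s * rec.sfreq)
    valid = np.zeros(rec.n_samples, dtype=bool)
    valid[edge:rec.n_samples - edge] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        peaks = find_gfp_peaks(g, n_peaks=len(g))
    peaks = peaks[valid[peaks]]
    chunks = []
    for mask in (masks.responsive, masks.unresponsive):
        in_state = peaks[mask[peaks]][:n_per_state]
        chunks.append(rec.data[:, in_state].T)
    return np.vstack(chunks)


@dataclass
class CohortAnalysis:
    """Bundle of everything the cohort-level analysis computes."""

    model: MicrostateModel
    template_match: np.ndarray            # |corr| of each ordered map vs template
    metrics: pd.DataFrame                 # subject x state x microstate parameters
    anova: dict                           # parameter -> RmAnovaResult
    posthoc: dict                         # parameter -> simple-effects table
    connectivity: pd.DataFrame | None
    connectivity_tests: dict | None
    trials: pd.DataFrame | None
    cv: dict                              # feature_set -> CVResult
    truth_recovery: pd.DataFrame | None = None


def _state_metrics(rec, masks, model, b, lam):
    """Label each 5-min window once, then aggregate within the state mask."""
    rows = []
    for state, mask in (("responsive", masks.responsive),
                        ("unresponsive", masks.unresponsive)):
        idx = np.flatnonzero(mask)
        span = slice(idx.min(), idx.max() + 1)
        data = rec.data[:, span]
        seq = label_sequence(data, model.maps, rec.sfreq)
        seq = smooth_labels(seq, data, model.maps, b=b, lam=lam)
        sub_mask = mask[span]
        met = microstate_metrics(seq, data=data, maps=model.maps,
                                 mask=sub_mask)
        met = met.reset_index()
        met["state"] = state
        rows.append(met)
    return pd.concat(rows, ignore_index=True)


def analyze_cohort(spec: CohortSpec, seed: int | None = None,
                   n_peaks_per_state: int = 2000, restarts: int = 10,
                   smoothing_b: int = 5, smoothing_lambda: float = 5.0,
                   feature_sets=("combined",), svm_grid=None,
                   do_connectivity: bool = True,
                   do_prediction: bool = True) -> CohortAnalysis:
    """Run the full pipeline on a freshly simulated cohort.

    ``n_peaks_per_state`` caps the per-subject GFP peaks pooled into the
    group clustering (the group set is subjects x states x this cap).
    """
    if seed is None:
        seed = spec.seed
    montage = make_montage(spec.n_channels)
    rng = np.random.default_rng(seed)
    subject_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1,
                                                  spec.n_subjects)]
    grid = BandGrid()

    subjects = []
    peak_sets = []
    for i, sseed in enumerate(subject_seeds):
        sid = f"sub-{i + 1:02d}"
        raw, events, truth = simulate_subject(spec, sseed, montage)
        rec = preprocess_recording(raw)
        masks = subject_state_masks(rec, events)
        peak_sets.append(collect_state_peaks(rec, masks, n_peaks_per_state))
        subjects.append((sid, rec, events, truth, masks))

    model = fit_microstates(np.vstack(peak_sets), k=spec.k,
                            seed=int(rng.integers(0, 2 ** 31 - 1)),
                            restarts=restarts)
    ordered, _, tmpl_corr = match_to_templates(
        model.maps, canonical_templates(montage))
    model.maps = ordered / np.linalg.norm(ordered, axis=1, keepdims=True)

    # how well the group maps recover each subject's planted topographies
    rec_rows = []
    for sid, _, _, truth, _ in subjects:
        _, _, corr = match_to_templates(model.maps, truth.maps)
        rec_rows.append({"subject": sid, "min_abs_corr": corr.min(),
                         "mean_abs_corr": corr.mean()})
    truth_recovery = pd.DataFrame(rec_rows).set_index("subject")

    met_rows = []
    for sid, rec, _, _, masks in subjects:
        met = _state_metrics(rec, masks, model, smoothing_b, smoothing_lambda)
        met["subject"] = sid
        met_rows.append(met)
    metrics = pd.concat(met_rows, ignore_index=True)

    anova, posthoc = {}, {}
    k = spec.k
    n = len(subjects)
    for param in ("duration_ms", "coverage_pct", "gev"):
        table = np.empty((n, k, 2))
        for si, (sid, *_rest) in enumerate(subjects):
            for bi, state in enumerate(("responsive", "unresponsive")):
                sel = metrics[(metrics.subject == sid)
                              & (metrics.state == state)].sort_values("microstate")
                table[si, :, bi] = sel[param].to_numpy()
        anova[param] = rm_anova_2way(table)
        posthoc[param] = simple_effects_posthoc(table)

    connectivity = conn_tests = None
    if do_connectivity:
        roi_labels = list(montage.roi_anterior) + list(montage.roi_posterior)
        roi_idx = montage.index(roi_labels)
        roi_montage = montage.subset(roi_labels)
        conn_rows = []
        for sid, rec, _, _, masks in subjects:
            roi_rec = Recording(data=rec.data[roi_idx], sfreq=rec.sfreq,
                                labels=roi_labels, montage=roi_montage,
                                reference="recorded")
            for state, mask in (("responsive", masks.responsive),
                                ("unresponsive", masks.unresponsive)):
                w_idx = np.flatnonzero(mask)
                w_span = slice(w_idx.min(), w_idx.max() + 1)
                span_rec = Recording(data=roi_rec.data[:, w_span],
                                     sfreq=rec.sfreq, labels=roi_labels,
                                     montage=roi_montage, reference="recorded")
                m = wpli_matrix(span_rec, "alpha", mask[w_span], grid)
                med = roi_median_wpli(m, roi_montage)
                conn_rows.append({"subject": sid, "state": state,
                                  "band": "alpha", "microstate": "all",
                                  **{kk: med[kk] for kk in
                                     ("within_anterior", "within_posterior",
                                      "between")}})
            idx = np.flatnonzero(masks.unresponsive)
            span = slice(idx.min(), idx.max() + 1)
            full_span = rec.data[:, span]
            seq = label_sequence(full_span, model.maps, rec.sfreq)
            seq = smooth_labels(seq, full_span, model.maps, b=smoothing_b,
                                lam=smoothing_lambda)
            roi_span_rec = Recording(data=roi_rec.data[:, span],
                                     sfreq=rec.sfreq,
                                     labels=roi_labels, montage=roi_montage,
                                     reference="recorded")
            per_ms = microstate_wpli(roi_span_rec, seq, "theta",
                                     masks.unresponsive[span], grid)
            for mi, mat in per_ms.items():
                med = roi_median_wpli(mat, roi_montage)
                conn_rows.append({"subject": sid, "state": "unresponsive",
                                  "band": "theta",
                                  "microstate": "ABCD"[mi],
                                  **{kk: med[kk] for kk in
                                     ("within_anterior", "within_posterior",
                                      "between")}})
        connectivity = pd.DataFrame(conn_rows)

        conn_tests = {}
        alpha_between = connectivity[(connectivity.band == "alpha")].pivot_table(
            index="subject", columns="state", values="between")
        conn_tests["alpha_between_resp_vs_unresp"] = paired_t_cohens_d(
            alpha_between["responsive"], alpha_between["unresponsive"])
        theta_ant = connectivity[(connectivity.band == "theta")].pivot_table(
            index="subject", columns="microstate", values="within_anterior")
        pvals, tstats = [], []
        for other in "ABC":
            res = paired_t_cohens_d(theta_ant["D"], theta_ant[other])
            pvals.append(res.p)
            tstats.append(res.statistic)
        conn_tests["theta_anterior_D_vs_ABC"] = {
            "t": tstats, "p": pvals, "q": list(storey_fdr(pvals)),
            "mean_diff": [float((theta_ant["D"] - theta_ant[o]).mean())
                          for o in "ABC"],
        }

    trials = None
    cv = {}
    if do_prediction:
        trial_frames = []
        for sid, rec, events, _, _ in subjects:
            trial_frames.append(build_trial_features(
                rec, events, model, subject=sid, smoothing_b=smoothing_b,
                smoothing_lambda=smoothing_lambda, grid=grid))
        trials = pd.concat(trial_frames, ignore_index=True)
        for fset in feature_sets:
            cv[fset] = loso_cv(trials, feature_set=fset, grid=svm_grid,
                               seed=seed)

    return CohortAnalysis(model=model, template_match=tmpl_corr,
                          metrics=metrics, anova=anova, posthoc=posthoc,
                          connectivity=connectivity,
                          connectivity_tests=conn_tests, trials=trials,
                          cv=cv, truth_recovery=truth_recovery)
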