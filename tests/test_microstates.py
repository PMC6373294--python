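"""Clustering, labelling, smoothing and metrics, each checked against an
independent oracle (hand formulas, brute-force enumeration, exact dynamic
programming) rather than against the implementation itself."""

import itertools
import statistics

import numpy as np
import pytest

from hypnostates.microstates import (LabelSequence, canonical_templates,
                                     compute_gev, find_gfp_peaks,
                                     fit_microstates, gfp, label_sequence,
                                     match_to_templates, microstate_metrics,
                                     smooth_labels, spatial_correlation,
                                     _smoothing_cost, load_model, save_model)

# ---------------------------------------------------------------------- GFP


def test_gfp_hand_values():
    assert gfp(np.array([[1.0], [-1.0], [0.0], [0.0]]))[0] == pytest.approx(
        np.sqrt(0.5))
    assert gfp(np.full((5, 3), 2.7)).max() == 0.0
    x = np.random.default_rng(0).normal(size=(8, 10))
    assert np.allclose(gfp(2 * x), 2 * gfp(x))


def test_gfp_single_channel_rejected():
    with pytest.raises(ValueError):
        gfp(np.ones((1, 10)))


def test_gfp_peaks_definition():
    assert find_gfp_peaks(np.array([0, 1, 0, 2, 0.0])).tolist() == [1, 3]
    with pytest.warns(UserWarning):
        assert len(find_gfp_peaks(np.arange(10.0))) == 0


def test_gfp_peaks_sinusoid_count():
    # 9.97 Hz is incommensurate with the 500 Hz grid, so every cycle has a
    # unique strict maximum (at exactly 10 Hz, sample ties can hide peaks)
    t = np.arange(0, 300, 1 / 500)
    series = 1.0 + 0.5 * np.sin(2 * np.pi * 9.97 * t)
    with pytest.warns(UserWarning):
        peaks = find_gfp_peaks(series, n_peaks=5000)
    assert abs(len(peaks) - round(300 * 9.97)) <= 3


def test_gfp_peaks_truncates_to_first_n():
    t = np.arange(0, 300, 1 / 500)
    series = 1.0 + 0.5 * np.sin(2 * np.pi * 10 * t)
    peaks = find_gfp_peaks(series, n_peaks=100)
    assert len(peaks) == 100
    assert np.all(np.diff(peaks) > 0)


# --------------------------------------------------- spatial correlation


def test_spatial_correlation_identities(rng):
    a = rng.normal(size=12)
    assert spatial_correlation(a, a) == pytest.approx(1.0)
    assert spatial_correlation(a, -a) == pytest.approx(-1.0)
    b = rng.normal(size=12)
    b = b - b.mean()
    a0 = a - a.mean()
    b_perp = b - (b @ a0) / (a0 @ a0) * a0
    assert spatial_correlation(a, b_perp) == pytest.approx(0.0, abs=1e-12)


def test_spatial_correlation_errors(rng):
    with pytest.raises(ValueError):
        spatial_correlation(np.ones(5), rng.normal(size=5))
    with pytest.raises(ValueError):
        spatial_correlation(rng.normal(size=5), rng.normal(size=6))


# ------------------------------------------------------------------- GEV


def _gev_bruteforce(data, labels, maps):
    """Direct loop evaluation of GEV_i = sum (GFP*corr)^2 / sum GFP^2."""
    n_ch, n_t = data.shape
    denom = 0.0
    per_map = [0.0] * maps.shape[0]
    for t in range(n_t):
        col = data[:, t]
        g = statistics.pstdev(col)
        denom += g * g
    for t in range(n_t):
        col = data[:, t]
        g = statistics.pstdev(col)
        r = statistics.correlation(list(col), list(maps[labels[t]]))
        per_map[labels[t]] += (g * r) ** 2
    return np.array(per_map) / denom


def test_gev_matches_bruteforce(rng):
    data = rng.normal(size=(8, 200))
    maps = rng.normal(size=(4, 8))
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    labels = rng.integers(0, 4, 200)
    per_map, total = compute_gev(data, labels, maps)
    expected = _gev_bruteforce(data, labels, maps)
    assert np.abs(per_map - expected).max() < 1e-12
    assert total == pytest.approx(expected.sum(), abs=1e-12)
    assert 0.0 <= total <= 1.0


def test_gev_perfect_fit_is_one(rng):
    maps = rng.normal(size=(2, 6))
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    labels = np.array([0, 1] * 50)
    scale = rng.uniform(0.5, 2.0, 100) * np.where(rng.random(100) < 0.5, -1, 1)
    data = (maps[labels] * scale[:, None]).T
    _, total = compute_gev(data, labels, maps)
    assert total == pytest.approx(1.0, abs=1e-12)


def test_gev_orthogonal_map_zero(rng):
    data = np.zeros((4, 10))
    data[0] = 1.0
    data[1] = -1.0  # constant topography [1,-1,0,0] over time
    maps = np.array([[0.0, 0.0, 1.0, -1.0]]) / np.sqrt(2)
    per_map, _ = compute_gev(data, np.zeros(10, int), maps)
    assert per_map[0] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        compute_gev(np.zeros((4, 10)), np.zeros(10, int), maps)


# ------------------------------------------------------------------- fit


def test_fit_single_component_recovers_generator(rng):
    topo = rng.normal(size=10)
    topo -= topo.mean()
    scale = rng.uniform(0.5, 2, 300) * np.where(rng.random(300) < 0.5, -1, 1)
    samples = np.outer(scale, topo)
    model = fit_microstates(samples, k=1, restarts=3, seed=0)
    assert abs(spatial_correlation(model.maps[0], topo)) == pytest.approx(1.0)


def test_fit_recovers_planted_maps(montage, rng):
    maps = canonical_templates(montage)
    # orthonormalise so the planted clusters are well separated
    q, _ = np.linalg.qr(maps.T)
    maps = q.T[:4]
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    labels = rng.integers(0, 4, 1500)
    scale = rng.uniform(5, 15, 1500) * np.where(rng.random(1500) < 0.5, -1, 1)
    samples = maps[labels] * scale[:, None] + rng.normal(0, 0.8, (1500, 63))
    model = fit_microstates(samples, k=4, restarts=8, seed=1)
    _, _, corr = match_to_templates(model.maps, maps)
    assert corr.min() >= 0.95
    assert model.gev_total > 0.5


def test_fit_gev_trace_ascends(montage, rng):
    samples = rng.normal(size=(400, 20))
    model = fit_microstates(samples, k=4, restarts=5, seed=0)
    for trace in model.gev_traces:
        assert np.all(np.diff(trace) >= -1e-12)


def test_fit_requires_enough_samples(rng):
    with pytest.raises(ValueError):
        fit_microstates(rng.normal(size=(3, 8)), k=4)


def test_fit_deterministic(rng):
    samples = rng.normal(size=(200, 12))
    a = fit_microstates(samples, k=3, restarts=4, seed=9)
    b = fit_microstates(samples, k=3, restarts=4, seed=9)
    assert np.array_equal(a.maps, b.maps)
    assert a.gev_total == b.gev_total


# ------------------------------------------------------------- labelling


def test_labeling_polarity_and_ties(rng):
    # four mutually orthogonal mean-free maps over 5 channels
    maps = np.array([
        [1.0, -1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, -1.0, 0.0],
        [1.0, 1.0, 1.0, 1.0, -4.0],
        [1.0, 1.0, -1.0, -1.0, 0.0],
    ])
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    data = np.column_stack([-maps[2], maps[1] + maps[3]])
    seq = label_sequence(data, maps, 500.0)
    assert seq.labels[0] == 2           # polarity ignored
    assert seq.labels[1] == 1           # exact tie between 1 and 3 -> lowest


def test_labeling_channel_mismatch(rng):
    with pytest.raises(ValueError):
        label_sequence(rng.normal(size=(8, 5)), rng.normal(size=(4, 9)), 500.0)


def test_labeling_scale_and_polarity_invariance(rng):
    maps = rng.normal(size=(4, 16))
    data = rng.normal(size=(16, 300))
    base = label_sequence(data, maps, 500.0)
    flip = np.where(rng.random(300) < 0.5, -1.0, 1.0)
    alt = label_sequence(data * flip * 3.7, maps, 500.0)
    assert np.array_equal(base.labels, alt.labels)


# ------------------------------------------------------------- smoothing


def _dp_minimise(e, lam, b, k):
    """Exact minimiser of sum_t e[t,l_t] - lam * #{same-label pairs within b}
    by dynamic programming over the last-b-labels state."""
    T = e.shape[0]
    states = {(): 0.0}
    back = []
    for t in range(T):
        new = {}
        bp = {}
        for state, cost in states.items():
            for l in range(k):
                add = e[t, l] - lam * sum(1 for s in state if s == l)
                ns = (state + (l,))[-b:]
                c = cost + add
                if ns not in new or c < new[ns] - 1e-15:
                    new[ns] = c
                    bp[ns] = (state, l)
        states = new
        back.append(bp)
    end = min(states, key=states.get)
    best_cost = states[end]
    labels = []
    state = end
    for t in range(T - 1, -1, -1):
        state, l = back[t][state]
        labels.append(l)
    return np.array(labels[::-1]), best_cost


def _toy_flip_case():
    """50-sample homogeneous run with one flipped label."""
    maps = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    data = np.tile(maps[0], (50, 1)).T
    seq = label_sequence(data, maps, 500.0)
    flipped = seq.labels.copy()
    flipped[25] = 1
    seq_flip = LabelSequence(labels=flipped, abs_corr=seq.abs_corr,
                             sfreq=500.0, k=2)
    return data, maps, seq_flip


def test_smoothing_b0_is_identity(rng):
    maps = rng.normal(size=(4, 12))
    data = rng.normal(size=(12, 200))
    seq = label_sequence(data, maps, 500.0)
    out = smooth_labels(seq, data, maps, b=0)
    assert np.array_equal(out.labels, seq.labels)


def test_smoothing_removes_flip_and_matches_exact_minimiser():
    data, maps, seq_flip = _toy_flip_case()
    out = smooth_labels(seq_flip, data, maps, b=5, lam=5.0)
    e = _smoothing_cost(data, maps, seq_flip.labels)
    dp_labels, dp_cost = _dp_minimise(e, 5.0, 5, 2)
    assert np.array_equal(out.labels, dp_labels)
    assert not out.labels[25]  # the flip is gone


def test_smoothing_objective_decreases_and_dp_bounds(rng):
    """On noisy data the pass-wise smoother must improve the shared global
    objective, bounded below by the exact DP optimum (which it need not
    reach — it is a local, per-pass minimiser)."""
    maps = rng.normal(size=(2, 6))
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    labels_true = (np.arange(40) // 10) % 2
    data = (maps[labels_true] * 3).T + rng.normal(0, 1.2, (6, 40))
    seq = label_sequence(data, maps, 500.0)
    out = smooth_labels(seq, data, maps, b=3, lam=2.0)
    e = _smoothing_cost(data, maps, seq.labels)
    dp_labels, dp_cost = _dp_minimise(e, 2.0, 3, 2)

    def energy(lab):
        cost = e[np.arange(len(lab)), lab].sum()
        pairs = sum(1 for t in range(len(lab)) for d in range(1, 4)
                    if t + d < len(lab) and lab[t] == lab[t + d])
        return cost - 2.0 * pairs

    assert energy(out.labels) <= energy(seq.labels) + 1e-9
    assert energy(out.labels) >= dp_cost - 1e-9
    assert energy(dp_labels) == pytest.approx(dp_cost, abs=1e-9)


def test_smoothing_reduces_segment_count():
    rng = np.random.default_rng(42)
    for _ in range(20):
        maps = rng.normal(size=(4, 10))
        maps -= maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        true = rng.integers(0, 4, 30).repeat(15)
        data = (maps[true] * 4).T + rng.normal(0, 1.5, (10, len(true)))
        seq = label_sequence(data, maps, 500.0)
        out = smooth_labels(seq, data, maps, b=5, lam=5.0)
        n_before = 1 + np.count_nonzero(np.diff(seq.labels))
        n_after = 1 + np.count_nonzero(np.diff(out.labels))
        assert n_after <= n_before


# --------------------------------------------------------------- metrics


def test_metrics_hand_arithmetic():
    labels = np.tile(np.repeat([0, 1], 10), 5)
    seq = LabelSequence(labels=labels, abs_corr=np.ones_like(labels, float),
                        sfreq=500.0, k=2)
    met = microstate_metrics(seq)
    assert met["duration_ms"].tolist() == [20.0, 20.0]
    assert met["coverage_pct"].sum() == pytest.approx(100.0)

    seq2 = LabelSequence(labels=np.array([0, 0, 1, 1]),
                         abs_corr=np.ones(4), sfreq=500.0, k=2)
    met2 = microstate_metrics(seq2)
    assert met2["coverage_pct"].tolist() == [50.0, 50.0]
    assert met2["duration_ms"].tolist() == [4.0, 4.0]


def test_metrics_unvisited_map_and_mask_segments():
    seq = LabelSequence(labels=np.array([0] * 10 + [1] * 10),
                        abs_corr=np.ones(20), sfreq=500.0, k=3)
    met = microstate_metrics(seq)
    assert met.loc[2, "coverage_pct"] == 0.0
    assert met.loc[2, "duration_ms"] == 0.0
    # a mask gap must break runs rather than bridge them
    mask = np.ones(20, bool)
    mask[8:12] = False
    met_m = microstate_metrics(seq, mask=mask)
    assert met_m.loc[0, "duration_ms"] == pytest.approx(8 * 2.0)
    assert met_m["coverage_pct"].sum() == pytest.approx(100.0)


# ------------------------------------------------------------- templates


def test_match_recovers_shuffle_and_polarity(montage, rng):
    maps = canonical_templates(montage)
    perm = rng.permutation(4)
    flip = np.where(rng.random(4) < 0.5, -1.0, 1.0)
    shuffled = maps[perm] * flip[:, None]
    reordered, found, corr = match_to_templates(shuffled, maps)
    assert np.allclose(corr, 1.0)
    assert np.allclose(np.abs(reordered), np.abs(maps), atol=1e-12)


def test_match_equals_assignment_oracle(rng):
    """Exhaustive matching must equal the optimal-assignment solution (and
    beat greedy row-wise matching where it fails)."""
    from scipy.optimize import linear_sum_assignment

    from hypnostates.microstates import _corr_rows

    for trial in range(20):
        maps = rng.normal(size=(4, 10))
        templates = rng.normal(size=(4, 10))
        _, perm, corr = match_to_templates(maps, templates)
        C = np.abs(_corr_rows(templates, maps))
        rows, cols = linear_sum_assignment(-C)
        assert corr.sum() == pytest.approx(C[rows, cols].sum(), abs=1e-12)


def test_model_roundtrip(tmp_path, rng):
    samples = rng.normal(size=(100, 8))
    model = fit_microstates(samples, k=2, restarts=2, seed=0)
    save_model(tmp_path / "m.json", model, channel_labels=list("abcdefgh"))
    back = load_model(tmp_path / "m.json")
    assert np.allclose(back.maps, model.maps)
    assert back.gev_total == pytest.approx(model.gev_total)
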