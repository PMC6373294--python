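"""Filter-bank design contracts, relative power normalisation, and WPLI
closed forms / null behaviour."""

import numpy as np
import pytest

from hypnostates.io import Recording
from hypnostates.microstates import LabelSequence
from hypnostates.spectral import (BandGrid, microstate_wpli, narrowband_analytic,
                                  relative_power, roi_median_wpli,
                                  theta_alpha_ratio, wpli_matrix)

FS = 500.0


def _rec(data, montage=None, labels=None):
    n = data.shape[0]
    labels = labels or tuple(f"ch{i}" for i in range(n))
    from hypnostates.montage import Montage
    pos = np.column_stack([np.linspace(-0.5, 0.5, n), np.zeros(n)])
    m = Montage(labels=labels, positions=pos, roi_anterior=(),
                roi_posterior=())
    return Recording(data=data, sfreq=FS, labels=labels, montage=m)


def test_grid_has_76_contiguous_bins():
    grid = BandGrid()
    bins = grid.bins
    assert len(bins) == 76
    assert bins[0] == (1.0, 1.25) and bins[-1] == (19.75, 20.0)
    for a, b in zip(bins, bins[1:]):
        assert a[1] == b[0]
    assert len(grid.band_bins("theta")) == 4
    assert len(grid.band_bins("alpha")) == 4
    with pytest.raises(ValueError):
        grid.band_bins((5.1, 6.0))  # not a union of whole bins


@pytest.mark.parametrize("fbin", [(9.75, 10.0), (10.0, 10.25)])
def test_narrowband_tone_amplitude_at_bin_edge(fbin):
    t = np.arange(0, 60, 1 / FS)
    x = np.sin(2 * np.pi * 10.0 * t)[None, :]
    amp = np.abs(narrowband_analytic(x, fbin, sfreq=FS))[0]
    interior = amp[int(2 * FS):-int(2 * FS)]
    assert abs(interior.mean() - 1.0) < 0.05
    assert amp.min() >= 0.0


def test_narrowband_stopband_and_validation():
    t = np.arange(0, 60, 1 / FS)
    x = np.sin(2 * np.pi * 10.0 * t)[None, :]
    amp = np.abs(narrowband_analytic(x, (5.0, 5.25), sfreq=FS))[0]
    assert amp[int(2 * FS):-int(2 * FS)].mean() <= 0.05
    with pytest.raises(ValueError):
        narrowband_analytic(x, (260.0, 260.25), sfreq=FS)


def test_relative_power_rows_sum_to_100(rng):
    rec = _rec(rng.normal(size=(3, 20000)))
    rp = relative_power(rec)
    assert np.allclose(rp.values.sum(axis=1), 100.0, atol=1e-6)
    assert np.all(rp.values >= 0)
    with pytest.raises(ValueError):
        relative_power(rec, mask=np.zeros(20000, bool))


def test_relative_power_concentrates_on_tone(rng):
    t = np.arange(0, 40, 1 / FS)
    x = np.sin(2 * np.pi * 10.0 * t) + 0.01 * rng.normal(size=len(t))
    rp = relative_power(_rec(x[None, :]))
    grid = BandGrid()
    alpha_idx = [i for i, b in enumerate(grid.bins)
                 if b in grid.band_bins("alpha")]
    assert rp.values[0, alpha_idx].sum() >= 80.0


def test_relative_power_flat_for_white_noise(rng):
    rec = _rec(rng.normal(size=(1, 100000)))
    rp = relative_power(rec)
    assert np.all(np.abs(rp.values[0] - 100.0 / 76) <= 0.5)


def test_relative_power_gain_invariant(rng):
    data = rng.normal(size=(2, 20000))
    a = relative_power(_rec(data)).values
    b = relative_power(_rec(data * 37.0)).values
    assert np.allclose(a, b, atol=1e-9)


def test_theta_alpha_ratio_constructions(rng):
    t = np.arange(0, 40, 1 / FS)
    tone10 = np.sin(2 * np.pi * 10.0 * t)
    tone55 = np.sin(2 * np.pi * 5.5 * t)
    _, r_equal = theta_alpha_ratio(_rec((tone10 + tone55)[None, :]))
    assert 0.8 < r_equal < 1.25
    _, r_alpha = theta_alpha_ratio(_rec(tone10[None, :]))
    assert r_alpha < 0.05
    per_ch, _ = theta_alpha_ratio(_rec(np.vstack([tone10, np.zeros_like(t)])))
    assert np.isinf(per_ch[1])  # zero alpha power flagged as infinite


def test_wpli_constant_quarter_lag_is_one():
    t = np.arange(0, 30, 1 / FS)
    x = np.vstack([np.sin(2 * np.pi * 10 * t),
                   np.sin(2 * np.pi * 10 * t - np.pi / 2)])
    mask = np.zeros(len(t), bool)
    mask[int(2 * FS):-int(2 * FS)] = True
    mat = wpli_matrix(_rec(x), "alpha", mask)
    assert mat.values[0, 1] == pytest.approx(1.0, abs=1e-9)
    assert not mat.degenerate[0, 1]


def test_wpli_zero_lag_flagged_degenerate():
    t = np.arange(0, 10, 1 / FS)
    x = np.tile(np.sin(2 * np.pi * 10 * t), (2, 1))
    mat = wpli_matrix(_rec(x), "alpha")
    assert mat.values[0, 1] == 0.0
    assert mat.degenerate[0, 1]


def test_wpli_independent_noise_is_small(rng):
    # estimator-level null (band=None): narrowband filtering would leave
    # only ~T*bandwidth effective samples and inflate the null instead
    small = 0
    for _ in range(20):
        x = rng.normal(size=(2, 10000))
        mat = wpli_matrix(_rec(x), band=None)
        if mat.values[0, 1] < 0.05:
            small += 1
    assert small >= 19


def test_wpli_amplitude_rescaling_invariant(rng):
    x = rng.normal(size=(3, 8000))
    a = wpli_matrix(_rec(x), "theta").values
    b = wpli_matrix(_rec(x * np.array([[2.0], [0.5], [7.0]])), "theta").values
    assert np.allclose(a, b, atol=1e-6)
    assert np.allclose(a, a.T)
    assert np.all((a >= 0) & (a <= 1))


def test_wpli_band_average_equals_bin_mean(rng):
    x = rng.normal(size=(2, 8000))
    grid = BandGrid()
    band = wpli_matrix(_rec(x), "theta", grid=grid).values[0, 1]
    bins = [wpli_matrix(_rec(x), b, grid=grid).values[0, 1]
            for b in grid.band_bins("theta")]
    assert band == pytest.approx(np.mean(bins), abs=1e-12)


def test_microstate_wpli_constant_labels_match_unconditioned(rng):
    x = rng.normal(size=(2, 6000))
    seq = LabelSequence(labels=np.zeros(6000, int), abs_corr=np.ones(6000),
                        sfreq=FS, k=2)
    per = microstate_wpli(_rec(x), seq, "theta")
    ref = wpli_matrix(_rec(x), "theta")
    assert per[0].values[0, 1] == pytest.approx(ref.values[0, 1], abs=1e-12)
    assert per[1].n_pooled == 0
    assert per[1].degenerate.all()


def test_roi_median_wpli_constructions(montage):
    from hypnostates.spectral import WPLIMatrix

    labels = montage.labels
    n = len(labels)
    ones = np.ones((n, n)) - np.eye(n)
    mat = WPLIMatrix(values=ones, degenerate=np.zeros((n, n), bool),
                     band="alpha", n_pooled=1000, labels=labels)
    med = roi_median_wpli(mat, montage)
    assert med["within_anterior"] == med["within_posterior"] == med["between"] == 1.0
    assert med["n_pairs"] == {"within_anterior": 171, "within_posterior": 190,
                              "between": 380}

    v = np.full((n, n), 0.1)
    ant = montage.anterior_idx()
    v[np.ix_(ant, ant)] = 0.8
    np.fill_diagonal(v, 0.0)
    mat2 = WPLIMatrix(values=v, degenerate=np.zeros((n, n), bool),
                      band="alpha", n_pooled=1000, labels=labels)
    med2 = roi_median_wpli(mat2, montage)
    assert med2["within_anterior"] == 0.8
    assert med2["within_posterior"] == 0.1
    assert med2["between"] == 0.1


def test_roi_median_wpli_missing_channel(montage):
    from hypnostates.spectral import WPLIMatrix

    labels = montage.labels[:10]
    mat = WPLIMatrix(values=np.zeros((10, 10)),
                     degenerate=np.ones((10, 10), bool), band="alpha",
                     n_pooled=10, labels=labels)
    with pytest.raises(ValueError, match="missing"):
        roi_median_wpli(mat, montage)
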