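"""Morse-wavelet band power, epoch descriptors and context stacking."""

import numpy as np
import pytest

from sqsleep import (
    DEFAULT_BANDS,
    FeatureMatrix,
    Recording,
    band_power_series,
    cwt_power,
    epoch_features,
    extract_night,
    stack_context,
)
from sqsleep.features import BROADBAND, feature_names

from conftest import FS, sinusoid_epoch


def _series(tf):
    out = {b.name: band_power_series(tf, b) for b in DEFAULT_BANDS}
    return out, band_power_series(tf, BROADBAND)


def test_band_definitions_are_the_classical_ones():
    edges = [(b.name, b.f_lo, b.f_hi) for b in DEFAULT_BANDS]
    assert edges == [
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("lower_beta", 13.0, 22.0),
        ("upper_beta", 22.0, 32.0),
    ]
    for prev, nxt in zip(DEFAULT_BANDS, DEFAULT_BANDS[1:]):
        assert prev.f_hi == nxt.f_lo  # ascending, non-overlapping


def test_cwt_zero_signal_zero_power():
    tf = cwt_power(np.zeros(int(30 * FS)), FS)
    assert np.all(tf.power == 0)
    assert np.all(np.diff(tf.freqs) > 0)


@pytest.mark.parametrize("freq", [2.0, 10.0, 25.0])
def test_cwt_peak_frequency_matches_fft_oracle(freq):
    """The scalogram peaks where the FFT of the signal peaks."""
    x = sinusoid_epoch(freq)
    tf = cwt_power(x, FS)
    profile = tf.power.mean(axis=1)
    f_cwt = tf.freqs[np.argmax(profile)]
    spec = np.abs(np.fft.rfft(x))
    f_fft = np.fft.rfftfreq(len(x), 1 / FS)[np.argmax(spec)]
    # within one logarithmic grid step of the independent FFT estimate
    step = tf.freqs[1] / tf.freqs[0]
    assert f_cwt / f_fft < step and f_fft / f_cwt < step


def test_cwt_broadband_power_tracks_variance(rng):
    """Time-averaged CWT power of white noise follows its variance."""
    scales = rng.uniform(0.5, 5.0, size=40)
    powers, variances = [], []
    for s in scales:
        x = s * rng.standard_normal(int(5 * FS))
        tf = cwt_power(x, FS)
        powers.append(band_power_series(tf, BROADBAND).mean())
        variances.append(np.var(x))
    r = np.corrcoef(powers, variances)[0, 1]
    assert r > 0.9


def test_band_series_spectral_concentration():
    tf = cwt_power(sinusoid_epoch(2.0), FS)
    series, _ = _series(tf)
    delta = series["delta"].mean()
    for name in ("theta", "alpha", "lower_beta", "upper_beta"):
        assert delta >= 10 * series[name].mean()


def test_band_series_zero_signal():
    tf = cwt_power(np.zeros(int(30 * FS)), FS)
    series, bb = _series(tf)
    assert all(np.all(s == 0) for s in series.values())
    assert np.all(bb == 0)


def test_band_row_sums_are_a_subcover_of_broadband(rng):
    """Summed band rows never exceed the broadband row sum."""
    tf = cwt_power(rng.standard_normal(int(30 * FS)), FS)
    total = np.zeros(tf.power.shape[1])
    for b in DEFAULT_BANDS:
        rows = (tf.freqs >= b.f_lo) & (tf.freqs < b.f_hi)
        total += tf.power[rows].sum(axis=0)
    broad = tf.power[(tf.freqs >= 0.5) & (tf.freqs <= 100.0)].sum(axis=0)
    assert np.all(total <= broad + 1e-12)


def test_band_outside_grid_rejected():
    from sqsleep import BandDefinition

    tf = cwt_power(np.zeros(1000), FS)
    with pytest.raises(ValueError, match="outside"):
        band_power_series(tf, BandDefinition("hf", 150.0, 200.0))


def test_sinusoid_activation_duration():
    """A 2 Hz tone activates delta for the whole epoch, alpha not at all."""
    tf = cwt_power(sinusoid_epoch(2.0), FS)
    series, bb = _series(tf)
    f = epoch_features(series, bb)
    names = [n[4:] for n in feature_names(1)]
    d = dict(zip(names, f))
    assert d["delta_activation"] == pytest.approx(30.0, abs=1.0)
    assert d["alpha_activation"] <= 1.0
    assert d["delta_meanpower"] >= 10 * d["theta_meanpower"]


def test_constant_power_conventions():
    """Zero-variance power: skew/kurt 0 by convention, maximal entropy."""
    n = int(30 * FS)
    const = np.full(n, 2.5)
    series = {b.name: const for b in DEFAULT_BANDS}
    f = epoch_features(series, const)
    d = dict(zip([n_[4:] for n_ in feature_names(1)], f))
    assert d["delta_varpower"] == 0.0
    assert d["delta_skewness"] == 0.0
    assert d["delta_kurtosis"] == 0.0
    assert d["delta_entropy"] == pytest.approx(np.log(n))
    assert d["delta_activation"] == 0.0  # constant never exceeds 1.5x median


def test_activation_duration_bounded(rng):
    tf = cwt_power(rng.standard_normal(int(30 * FS)), FS)
    series, bb = _series(tf)
    f = epoch_features(series, bb)
    d = dict(zip([n[4:] for n in feature_names(1)], f))
    for b in DEFAULT_BANDS:
        assert 0.0 <= d[f"{b.name}_activation"] <= 30.0


def test_mostly_masked_epoch_invalid(rng):
    n = int(30 * FS)
    series = {b.name: rng.random(n) for b in DEFAULT_BANDS}
    mask = np.zeros(n, dtype=bool)
    mask[: n // 20] = True  # 5% < 10% minimum
    assert epoch_features(series, rng.random(n), mask=mask) is None


def test_scaling_invariance(rng):
    """Amplitude scaling by c: mean x c^2, var x c^4, shape features fixed."""
    x = rng.standard_normal(int(30 * FS))
    c = 3.0
    f1 = _features_of(x)
    f2 = _features_of(c * x)
    names = [n[4:] for n in feature_names(1)]
    d1, d2 = dict(zip(names, f1)), dict(zip(names, f2))
    for b in DEFAULT_BANDS:
        assert d2[f"{b.name}_meanpower"] == pytest.approx(
            c**2 * d1[f"{b.name}_meanpower"], rel=1e-9
        )
        assert d2[f"{b.name}_varpower"] == pytest.approx(
            c**4 * d1[f"{b.name}_varpower"], rel=1e-9
        )
        for metric in ("skewness", "kurtosis", "entropy", "activation"):
            assert d2[f"{b.name}_{metric}"] == pytest.approx(
                d1[f"{b.name}_{metric}"], rel=1e-9
            )


def _features_of(x, mask=None):
    tf = cwt_power(x, FS, mask=mask)
    series, bb = _series(tf)
    m = mask if mask is not None else np.ones(len(x), dtype=bool)
    return epoch_features(series, bb, mask=m)


def test_masked_samples_never_influence_features(rng):
    """Masked values are invisible: a masked burst changes no feature."""
    n = int(4 * 30 * FS)
    x = rng.normal(0, 20, n)
    mask = np.ones(n, dtype=bool)
    burst = slice(2 * 6210 + 1000, 2 * 6210 + 1200)
    mask[burst] = False
    x_burst = x.copy()
    x_burst[burst] += 400.0
    rec_a = Recording(x[None, :], FS, ("x",), valid_mask=mask[None, :])
    rec_b = Recording(x_burst[None, :], FS, ("x",), valid_mask=mask[None, :])
    fa = extract_night(rec_a)
    fb = extract_night(rec_b)
    assert np.array_equal(fa.values, fb.values)
    assert np.array_equal(fa.epoch_valid, fb.epoch_valid)


def test_extract_night_shape_and_validity(rng):
    n_ep = 10
    sig = rng.normal(0, 20, (2, n_ep * int(30 * FS)))
    rec = Recording(sig, FS, ("P-C", "D-C"))
    rec.valid_mask[0, 3 * 6210 : 4 * 6210] = False  # epoch 3, channel 1
    fm = extract_night(rec)
    assert fm.values.shape == (n_ep, 60)
    assert not fm.epoch_valid[3]
    assert fm.epoch_valid.sum() == n_ep - 1
    assert fm.feature_names[0] == "ch1_delta_meanpower"


def test_extract_night_channel_permutation_permutes_blocks(rng):
    sig = rng.normal(0, 20, (2, 5 * 6210))
    rec = Recording(sig, FS, ("a", "b"))
    rec_swapped = Recording(sig[::-1], FS, ("b", "a"))
    fa = extract_night(rec)
    fb = extract_night(rec_swapped)
    assert np.allclose(fa.values[:, :30], fb.values[:, 30:])
    assert np.allclose(fa.values[:, 30:], fb.values[:, :30])


def test_stack_context_definition():
    """Row k of the stacked matrix is rows k-1, k, k+1, k+2 of the input."""
    vals = np.arange(5)[:, None] * np.ones((1, 3))
    fm = FeatureMatrix(vals, ["a", "b", "c"], np.ones(5, bool))
    st = stack_context(fm)
    assert st.values.shape == (5, 12)
    assert list(st.values[2]) == [1] * 3 + [2] * 3 + [3] * 3 + [4] * 3
    # edges replicate
    assert list(st.values[0]) == [0] * 6 + [1] * 3 + [2] * 3
    assert list(st.values[4]) == [3] * 3 + [4] * 9


def test_stack_context_single_epoch_tiles():
    fm = FeatureMatrix(np.array([[1.0, 2.0]]), ["a", "b"], np.ones(1, bool))
    st = stack_context(fm)
    assert list(st.values[0]) == [1.0, 2.0] * 4


def test_stack_context_column_count_and_names():
    fm = FeatureMatrix(np.zeros((4, 60)), feature_names(2), np.ones(4, bool))
    st = stack_context(fm)
    assert st.values.shape[1] == 240
    assert st.feature_names[0] == "ch1_delta_meanpower_prev1"
    assert len(set(st.feature_names)) == 240


def test_stack_context_skips_invalid_neighbours():
    """An invalid epoch's NaNs never leak into its neighbours' context."""
    vals = np.arange(5, dtype=float)[:, None]
    vals[2] = np.nan
    valid = np.array([True, True, False, True, True])
    st = stack_context(FeatureMatrix(vals, ["a"], valid))
    assert np.array_equal(st.epoch_valid, valid)
    ok = st.values[valid]
    assert np.all(np.isfinite(ok))
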