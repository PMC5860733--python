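"""Morlet CWT, z-scoring and sparse half-ellipsoid bump extraction."""

import numpy as np
import pytest

from eegdx import MorletParams, bm_feature, channel_bump_models, fit_bumps, morlet_cwt, zscore_map
from eegdx.bumps import _atom

FS = 256.0


def _tone(freq, dur=20.0, amp=1.0):
    t = np.arange(0, dur, 1 / FS)
    return amp * np.sin(2 * np.pi * freq * t)


def _zero_map(dur=20.0):
    tf = morlet_cwt(np.zeros(int(dur * FS)), MorletParams(), FS)
    tf.magnitude[:] = 0.0
    with pytest.warns(UserWarning):
        return zscore_map(tf)


def test_tone_peaks_at_its_frequency():
    tf = morlet_cwt(_tone(10.0), MorletParams(), FS)
    peak = tf.freqs[np.argmax(tf.magnitude.mean(axis=1))]
    assert peak == pytest.approx(10.0, abs=0.25)
    mid = tf.magnitude[np.argmin(np.abs(tf.freqs - 10.0)), tf.n_times // 2]
    assert mid == pytest.approx(1.0, rel=0.02)  # |W| estimates tone amplitude


def test_cwt_linearity():
    x = np.random.default_rng(0).standard_normal(int(4 * FS))
    a = morlet_cwt(x, MorletParams(), FS).magnitude
    b = morlet_cwt(2.0 * x, MorletParams(), FS).magnitude
    np.testing.assert_allclose(b, 2.0 * a, rtol=1e-9)


def test_two_tones_make_two_ridges():
    tf = morlet_cwt(_tone(6.0) + _tone(20.0), MorletParams(), FS)
    profile = tf.magnitude.mean(axis=1)
    # FFT oracle: the two spectral peaks sit at 6 and 20 Hz
    for f0 in (6.0, 20.0):
        i = np.argmin(np.abs(tf.freqs - f0))
        lo, hi = max(0, i - 4), min(len(profile), i + 5)
        assert profile[lo:hi].max() > 0.5 * profile.max()
    trough = profile[np.argmin(np.abs(tf.freqs - 13.0))]
    assert trough < 0.5 * profile.max()


def test_grid_beyond_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        morlet_cwt(_tone(5.0), MorletParams(f_max=200.0), FS)


def test_zscore_rows_have_zero_mean_unit_sd():
    rng = np.random.default_rng(1)
    tf = morlet_cwt(rng.standard_normal(int(20 * FS)), MorletParams(), FS)
    tf = zscore_map(tf)
    valid = tf.valid_mask()
    for i in range(0, tf.freqs.size, 7):
        row = tf.z[i, valid[i]]
        assert abs(row.mean()) < 1e-10
        assert row.std() == pytest.approx(1.0, abs=1e-9)


def test_zscore_idempotent_on_zscored_magnitude():
    rng = np.random.default_rng(2)
    tf = morlet_cwt(rng.standard_normal(int(10 * FS)), MorletParams(), FS)
    tf = zscore_map(tf)
    tf2 = morlet_cwt(rng.standard_normal(int(10 * FS)), MorletParams(), FS)
    tf2.magnitude = tf.z.copy()
    tf2 = zscore_map(tf2)
    valid = tf.valid_mask()
    np.testing.assert_allclose(tf2.z[valid], tf.z[valid], atol=1e-9)


def test_constant_row_zeroed_with_warning():
    tf = morlet_cwt(_tone(10.0, dur=6.0), MorletParams(), FS)
    tf.magnitude[0, :] = 5.0  # flat 1-Hz row
    with pytest.warns(UserWarning, match="constant"):
        tf = zscore_map(tf)
    assert np.all(tf.z[0] == 0.0)


def test_all_zero_map_yields_no_bumps():
    tf = _zero_map(dur=10.0)
    model = fit_bumps(tf)
    assert model.bumps == []


def test_unscored_map_rejected():
    tf = morlet_cwt(_tone(10.0, 6.0), MorletParams(), FS)
    with pytest.raises(ValueError, match="z-scored"):
        fit_bumps(tf)


def test_planted_atom_recovered_precisely():
    tf = _zero_map()
    truth = np.array([5.0, 10.0, 10.0, 0.4, 2.0])  # a, tc, fc, wt, wf
    tf.z = _atom(np.arange(tf.n_times) / FS, tf.freqs, truth)
    model = fit_bumps(tf)
    b = model.bumps[0]
    assert b.t_center == pytest.approx(10.0, abs=0.25)
    assert b.f_center == pytest.approx(10.0, abs=1.0)
    assert b.amplitude == pytest.approx(5.0, rel=0.2)
    assert b.t_width == pytest.approx(0.4, rel=0.3)
    assert b.f_width == pytest.approx(2.0, rel=0.3)


def test_two_separated_bursts_in_noise_recovered_and_residual_decreases():
    rng = np.random.default_rng(3)
    tf = _zero_map()
    grid_t = np.arange(tf.n_times) / FS
    truth = [np.array([5.0, 5.0, 6.0, 0.5, 1.5]), np.array([4.5, 14.0, 18.0, 0.3, 3.0])]
    tf.z = sum(_atom(grid_t, tf.freqs, th) for th in truth)
    tf.z = tf.z + 0.5 * rng.standard_normal(tf.z.shape)
    model = fit_bumps(tf, max_bumps=10)
    energies = [model.initial_energy] + model.residual_energy
    assert np.all(np.diff(energies) <= 1e-9)
    for th in truth:
        assert any(
            abs(b.t_center - th[1]) < 0.25 and abs(b.f_center - th[2]) < 1.0
            for b in model.bumps
        )


def test_time_shift_equivariance():
    rng = np.random.default_rng(4)
    base = 10 * rng.standard_normal(int(20 * FS))
    burst = np.zeros_like(base)
    t = np.arange(base.size) / FS
    burst += 60 * np.exp(-0.5 * ((t - 8.0) / 0.2) ** 2) * np.cos(2 * np.pi * 6 * (t - 8.0))
    shift = int(2.0 * FS)

    def centers(x):
        model = fit_bumps(zscore_map(morlet_cwt(x, MorletParams(), FS)), max_bumps=5)
        return [b for b in model.bumps if abs(b.f_center - 6) < 2]

    c0 = centers(base + burst)
    c1 = centers(base + np.roll(burst, shift))
    assert c0 and c1
    t0 = min(c0, key=lambda b: abs(b.t_center - 8.0)).t_center
    t1 = min(c1, key=lambda b: abs(b.t_center - 10.0)).t_center
    assert t1 - t0 == pytest.approx(2.0, abs=0.1)


def test_bm_feature_counts_only_band_bumps(small_cohort):
    rec = small_cohort[0]
    models = channel_bump_models(rec, "Occipital")
    rate_all = sum(
        bm_feature(rec, "Occipital", band, models=models)
        for band in ("4-8", "8-12", "12-30")
    )
    n_in_bands = sum(
        sum(1 for b in m.bumps if 4 <= b.f_center < 30) for m in models.values()
    )
    dur = next(iter(models.values())).duration
    assert rate_all == pytest.approx(n_in_bands / (len(models) * dur), rel=1e-6)
    # aggregation modes all finite, amplitude modes non-negative
    for agg in ("rate", "mean_amplitude", "total_amplitude"):
        v = bm_feature(rec, "Occipital", "8-12", agg=agg, models=models)
        assert np.isfinite(v) and v >= 0


def test_bump_frame_export(small_cohort):
    from eegdx.bumps import bumps_to_frame

    models = channel_bump_models(small_cohort[0], ["O1"])
    df = bumps_to_frame(models)
    assert list(df.columns) == ["channel", "t_center", "f_center", "t_width", "f_width", "amplitude"]
    assert (df.amplitude >= 2.0).all()  # default extraction threshold
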