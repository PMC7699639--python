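"""Wavelet power, session normalization, binning and bootstrap matching."""

import numpy as np
import pytest

from conftest import make_recording, make_trials
from memscan.datatypes import Recording
from memscan.spectral import (TFR, band_centers, band_power, bin_power,
                              bootstrap_match, default_freqs, morlet_tfr,
                              select_trials, zscore_session)


def test_default_frequency_grid():
    f = default_freqs()
    assert len(f) == 32
    assert f[0] == pytest.approx(2.0)
    assert f[-1] == pytest.approx(431.0)
    assert np.allclose(np.diff(np.log(f)), np.log(431 / 2) / 31)
    assert band_centers().min() >= 80 and band_centers().max() <= 120


def _sine_recording(freq_hz, n_s=12.0, fs=1000.0, amp=1.0):
    t = np.arange(int(n_s * fs)) / fs
    return make_recording(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs)


def test_morlet_power_peaks_at_stimulus_frequency():
    # epochs must exceed the longest (2 Hz, 6-cycle) wavelet: use 3 s windows
    rec = _sine_recording(100.0, n_s=18.0)
    trials = make_trials([2.0, 7.0, 12.0], duration_s=3.0)
    tfr = morlet_tfr(rec, trials, window=(0.0, 3.0), buffer_s=1.0)
    mean_over_time = tfr.power.mean(axis=(0, 1, 3))
    nearest = np.argmin(np.abs(tfr.freqs - 100.0))
    assert np.argmax(mean_over_time) == nearest


def test_log_power_shift_under_amplitude_doubling():
    trials = make_trials([2.0, 5.0], duration_s=2.0)
    p1 = morlet_tfr(_sine_recording(100.0, amp=1.0), trials, freqs=[100.0]).power
    p2 = morlet_tfr(_sine_recording(100.0, amp=2.0), trials, freqs=[100.0]).power
    shift = (p2 - p1).mean()
    assert shift == pytest.approx(np.log(4.0), rel=1e-3)


def test_out_of_bounds_epoch_skipped_and_logged():
    rec = _sine_recording(50.0, n_s=5.0)
    trials = make_trials([0.2, 2.0], duration_s=1.0)   # first epoch under-runs buffer
    tfr = morlet_tfr(rec, trials, freqs=[50.0], window=(0.0, 1.0), buffer_s=1.0)
    assert len(tfr.trial_index) == 1
    assert len(tfr.log) == 1


def test_zscore_session_normalizes_per_channel_and_frequency():
    rng = np.random.default_rng(0)
    rec = make_recording(rng.standard_normal((2, 20000)))
    trials = make_trials([2.0, 6.0, 10.0, 14.0], duration_s=3.0)
    z = zscore_session(morlet_tfr(rec, trials, freqs=[10.0, 80.0], window=(0.0, 3.0)))
    for ch in range(2):
        for fi in range(2):
            v = z.power[:, ch, fi, :]
            assert abs(v.mean()) < 1e-10
            assert abs(v.std() - 1.0) < 1e-6
    assert z.zscored


def test_zscore_excludes_masked_artifacts():
    rng = np.random.default_rng(1)
    traces = rng.standard_normal((1, 20000))
    mask = np.zeros_like(traces, dtype=bool)
    trials = make_trials([2.0, 6.0, 10.0, 14.0], duration_s=3.0)
    clean = zscore_session(morlet_tfr(make_recording(traces), trials,
                                      freqs=[80.0], window=(0.0, 3.0)))
    dirty = traces.copy()
    dirty[0, 6500:6600] += 500.0
    mask[0, 6400:6700] = True
    z = zscore_session(morlet_tfr(make_recording(dirty), trials, freqs=[80.0],
                                  window=(0.0, 3.0), artifact_mask=mask))
    # masked samples are NaN and excluded; clean-trial z-scores barely move
    assert np.isnan(z.power[1]).any()
    ref = clean.power[0, 0, 0, :]
    got = z.power[0, 0, 0, :]
    assert np.nanmax(np.abs(got - ref)) < 0.05


def _toy_tfr(values, fs=10.0):
    """1-trial 1-channel 1-frequency TFR from a plain sample vector."""
    v = np.asarray(values, dtype=float)[None, None, None, :]
    return TFR(power=v, freqs=np.array([100.0]), times=np.arange(v.shape[-1]) / fs,
               fs=fs, trial_index=np.array([0]),
               valid=np.ones((1, v.shape[-1]), dtype=bool), zscored=True)


def test_binning_hand_example_and_step_function():
    # 6 samples at 10 Hz, 0.2 s bins / 0.1 s step -> bins avg pairs of samples
    tfr = _toy_tfr([1.0, 3.0, 5.0, 7.0, 9.0, 11.0])
    b = bin_power(tfr, width=0.2, step=0.1)
    assert b.values[0, 0, 0].tolist() == [2.0, 4.0, 6.0, 8.0, 10.0]
    assert np.allclose(b.bin_centers, [0.1, 0.2, 0.3, 0.4, 0.5])
    # step 0 -> 1 at a bin boundary: before 0, straddling 0.5, after 1
    tfr2 = _toy_tfr([0.0] * 4 + [1.0] * 4)
    b2 = bin_power(tfr2, width=0.4, step=0.2)
    assert b2.values[0, 0, 0].tolist() == [0.0, 0.5, 1.0]
    # constant series -> every bin equals the constant
    b3 = bin_power(_toy_tfr([3.3] * 8), width=0.4, step=0.2)
    assert np.allclose(b3.values, 3.3)


def test_binning_requires_sample_aligned_widths():
    with pytest.raises(ValueError):
        bin_power(_toy_tfr([0.0] * 10), width=0.25, step=0.1)


def test_binning_commutes_with_trial_averaging():
    rng = np.random.default_rng(3)
    v = rng.standard_normal((5, 1, 1, 20))
    tfr = TFR(power=v, freqs=np.array([100.0]), times=np.arange(20) / 10.0, fs=10.0,
              trial_index=np.arange(5), valid=np.ones((5, 20), dtype=bool))
    binned_then_mean = bin_power(tfr, 0.4, 0.2).values.mean(axis=0)
    mean_tfr = TFR(power=v.mean(axis=0, keepdims=True), freqs=tfr.freqs,
                   times=tfr.times, fs=tfr.fs, trial_index=np.array([0]),
                   valid=np.ones((1, 20), dtype=bool))
    mean_then_bin = bin_power(mean_tfr, 0.4, 0.2).values[0]
    assert np.allclose(binned_then_mean, mean_then_bin)


def test_band_power_averages_in_band_centers():
    v = np.zeros((1, 1, 3, 4))
    v[0, 0] = [[1.0] * 4, [3.0] * 4, [100.0] * 4]
    b = bin_power(TFR(power=v, freqs=np.array([90.0, 110.0, 200.0]),
                      times=np.arange(4) / 10.0, fs=10.0, trial_index=np.array([0]),
                      valid=np.ones((1, 4), dtype=bool)), 0.2, 0.1)
    bp = band_power(b, band=(80.0, 120.0))
    assert np.allclose(bp.values, 2.0)


def test_select_trials_drops_slow_responses():
    trials = make_trials([1.0, 5.0, 9.0], duration_s=2.0, phase="recognition")
    trials.loc[1, "response_time_s"] = 11.0
    kept = select_trials(trials, phase="recognition")
    assert kept["trial_id"].tolist() == [0, 2]


# ---------------------------------------------------------------------------
# bootstrap trial matching


def test_bootstrap_match_identity_and_determinism():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((10, 4))
    b = rng.standard_normal((10, 4))
    ma, mb = bootstrap_match(a, b, n_iter=100, seed=1)
    assert np.allclose(ma, a.mean(axis=0)) and np.allclose(mb, b.mean(axis=0))
    big = rng.standard_normal((50, 4))
    m1, _ = bootstrap_match(big, b, n_iter=50, seed=7)
    m2, _ = bootstrap_match(big, b, n_iter=50, seed=7)
    assert np.array_equal(m1, m2)
    with pytest.raises(ValueError):
        bootstrap_match(a, b, n_iter=0)


def test_bootstrap_match_converges_to_full_mean():
    rng = np.random.default_rng(5)
    big = rng.standard_normal(400) + 1.0
    small = rng.standard_normal(25)
    matched, _ = bootstrap_match(big, small, n_iter=10_000, seed=2)
    se = big.std(ddof=1) / np.sqrt(25) / np.sqrt(10_000 / 20.0)
    assert abs(matched - big.mean()) < max(4 * se, 0.02)
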