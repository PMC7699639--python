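"""Referencing, conditioning and both artifact-rejection tiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_recording
from memscan.preprocess import (apply_bipolar, build_bipolar, condition_signal,
                                detect_artifact_events, reject_by_quartile)


def _grid_meta(n_rows, n_cols, region="PT", grid_id="g0"):
    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            rows.append(dict(label=f"c{r}_{c}", region=region, grid_id=grid_id,
                             grid_row=r, grid_col=c, is_depth=False))
    return pd.DataFrame(rows)


@pytest.mark.parametrize("shape,expected", [
    ((2, 2), 4),       # 2 horizontal + 2 vertical
    ((1, 4), 3),       # strip
    ((8, 8), 112),     # n(m-1) + m(n-1)
])
def test_bipolar_pair_counts(shape, expected):
    m = build_bipolar(_grid_meta(*shape))
    assert len(m.pairs) == expected


def test_bipolar_subtraction_and_common_mode_cancellation():
    meta = _grid_meta(1, 3)
    traces = np.array([[1., 2., 3., 4., 5.],
                       [0., 1., 1., 2., 2.],
                       [5., 5., 5., 5., 5.]])
    rec = make_recording(traces)
    rec.channel_meta = meta
    m = build_bipolar(meta)
    out = apply_bipolar(rec, m)
    assert np.array_equal(out.traces[0], traces[0] - traces[1])
    # adding any common signal to all contacts leaves virtual traces unchanged
    common = np.sin(np.arange(5))
    rec2 = make_recording(traces + common)
    rec2.channel_meta = meta
    out2 = apply_bipolar(rec2, m)
    assert np.allclose(out.traces, out2.traces)
    # identical signal on both contacts -> zero; constant offset -> constant
    recc = make_recording(np.vstack([traces[0], traces[0] - 2.0, traces[2]]))
    recc.channel_meta = meta
    outc = apply_bipolar(recc, m)
    assert np.allclose(outc.traces[0], 2.0)


def test_notch_attenuates_line_noise_and_passes_signal():
    fs = 1000.0
    t = np.arange(int(4 * fs)) / fs
    rec60 = make_recording(np.sin(2 * np.pi * 60 * t), fs=fs)
    out60 = condition_signal(rec60)
    core = slice(500, -500)      # ignore filter edges
    assert np.sqrt((out60.traces[0, core] ** 2).mean()) < 0.1 * np.sqrt(0.5)
    rec10 = make_recording(np.sin(2 * np.pi * 10 * t), fs=fs)
    out10 = condition_signal(rec10)
    ratio = out10.traces[0, core].std() / rec10.traces[0, core].std()
    assert abs(ratio - 1.0) < 0.01


def test_resampling_halves_2000hz_input():
    rec = make_recording(np.random.default_rng(0).standard_normal(4000), fs=2000.0)
    out = condition_signal(rec)
    assert out.fs == 1000.0
    assert out.n_samples == 2000
    with pytest.raises(ValueError):
        condition_signal(make_recording(np.zeros(1000), fs=512.0))


def test_quartile_rule_hand_examples():
    # {1,2,3,4}: Q1=1.75, Q3=3.25 -> threshold 3.25 + 2.3*1.5 = 6.70
    keep, log = reject_by_quartile([1, 2, 3, 4])
    assert keep.all()
    assert log["threshold"] == pytest.approx(6.70)
    keep, _ = reject_by_quartile([1, 2, 3, 100])
    assert keep.tolist() == [True, True, True, False]
    # zero IQR: strict inequality keeps everything
    keep, _ = reject_by_quartile([5.0, 5.0, 5.0, 5.0])
    assert keep.all()


def test_quartile_rule_skips_tiny_samples():
    with pytest.warns(UserWarning):
        keep, log = reject_by_quartile([1, 2, 300])
    assert keep.all() and not log["applied"]


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.1, 1e4), min_size=4, max_size=30),
       st.floats(0.01, 100.0))
def test_quartile_rule_is_scale_equivariant(values, c):
    keep1, _ = reject_by_quartile(values)
    keep2, _ = reject_by_quartile([c * v for v in values])
    assert keep1.tolist() == keep2.tolist()


def _background(rng, n, fs=1000.0):
    """Band-limited Gaussian background (a spike must out-gradient it)."""
    from scipy import signal as sg
    sos = sg.butter(4, 40.0, btype="lowpass", fs=fs, output="sos")
    x = sg.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def test_single_spike_masked_with_100ms_margins():
    rng = np.random.default_rng(0)
    fs = 1000.0
    x = _background(rng, 5000)
    spike = 8.0 * np.concatenate([np.linspace(0, 1, 3), np.linspace(1, -1, 5),
                                  np.linspace(-1, 0, 12)])
    x[2000:2020] += spike
    mask = detect_artifact_events(x, fs).sample_mask
    spans = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    assert len(spans) == 2                                # exactly one span
    lo, hi = spans
    assert lo <= 2000 - 95 and hi >= 2020 + 95            # ~±100 ms margins
    assert lo >= 2000 - 110 and hi <= 2020 + 110
    # masking is idempotent: re-running the detector reproduces the same mask
    assert np.array_equal(detect_artifact_events(x, fs).sample_mask, mask)


def test_close_spikes_merge_and_clean_signal_unmasked():
    fs = 1000.0
    t = np.arange(3000) / fs
    # a pure low-frequency sinusoid has bounded z everywhere: empty mask
    clean = np.sin(2 * np.pi * 5 * t)
    assert detect_artifact_events(clean, fs).sample_mask.sum() == 0
    rng = np.random.default_rng(2)
    x = _background(rng, 5000)
    spike = 9.0 * np.concatenate([np.linspace(0, 1, 3), np.linspace(1, -1, 5),
                                  np.linspace(-1, 0, 12)])
    x[2000:2020] += spike
    x[2050:2070] += spike                                 # 50 ms apart -> merged
    mask = detect_artifact_events(x, fs).sample_mask
    spans = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    assert len(spans) == 2


def test_short_trace_rejected():
    with pytest.raises(ValueError):
        detect_artifact_events(np.zeros(100), 1000.0)


def test_outlier_trials_dropped_by_quartile_tier():
    from memscan.preprocess import reject_trials_and_electrodes
    from memscan.simulate import default_config, generate_recording
    cfg = default_config(region_channels={"PT": 3}, n_lists=4,
                         encoding_duration_s=1.0, rt_min_s=1.2, rt_max_s=2.0,
                         spike_rate_per_min=0.0, outlier_trial_frac=0.07,
                         burst_amplitude=0.3)
    rec, trials, gt = generate_recording(cfg, seed=31)
    mask = reject_trials_and_electrodes(rec, trials)
    dropped = set(trials.loc[~mask.trial_keep, "trial_id"])
    assert set(gt.outlier_trials).issubset(dropped)
    assert mask.log[0]["entity"] == "trial" and mask.log[0]["w"] == 2.3
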