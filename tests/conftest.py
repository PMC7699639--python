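import numpy as np
import pandas as pd
import pytest

from memscan.datatypes import Recording
from memscan.simulate import default_config, generate_recording


def make_recording(traces, fs=1000.0, region="PT"):
    """Wrap a raw (channels x samples) array in a Recording."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    meta = pd.DataFrame([
        dict(label=f"{region}{k}", region=region, grid_id="g0",
             grid_row=k, grid_col=0, is_depth=False)
        for k in range(traces.shape[0])])
    return Recording(traces=traces, fs=fs, channel_meta=meta)


def make_trials(onsets_s, duration_s=1.0, phase="encoding"):
    """Minimal trial table with one image per onset."""
    rows = []
    for k, t in enumerate(onsets_s):
        rows.append(dict(trial_id=k, list_id=k // 4, image_id=k, phase=phase,
                         condition="repeated", correct=True,
                         image_onset_s=t, image_offset_s=t + duration_s,
                         response_time_s=duration_s if phase == "recognition" else np.nan))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_session():
    """One small synthetic session shared by read-only tests."""
    cfg = default_config(
        region_channels={"PT": 3, "MTL": 3}, n_lists=3,
        encoding_duration_s=1.0, pre_image_gap_s=1.0,
        rt_mean_s=1.5, rt_sigma=0.1, rt_min_s=1.2, rt_max_s=2.0,
        spike_rate_per_min=0.0)
    rec, trials, gt = generate_recording(cfg, seed=42)
    return cfg, rec, trials, gt
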