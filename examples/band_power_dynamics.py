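"""High-gamma (80-120 Hz) power dynamics and regional onset estimation.

Computes Morlet band power on recognition trials, contrasts manipulated-
correct against repeated-correct trials with bootstrap trial matching, and
estimates each region's onset of the condition difference by the
local-minimum-to-peak line fit.  The generator injects the difference at
270 ms (PT) and 480 ms (MTL), so PT should lead.
"""

import numpy as np

from memscan import generate_recording
from memscan.dynamics import estimate_onset, instantaneous_slope
from memscan.simulate import default_config
from memscan.spectral import (band_centers, band_power, bin_power,
                              bootstrap_match, morlet_tfr, select_trials,
                              zscore_session)

cfg = default_config(
    region_channels={"PT": 4, "MTL": 4}, n_lists=14,
    encoding_duration_s=1.0, pre_image_gap_s=1.2,
    rt_mean_s=2.6, rt_sigma=0.05, rt_min_s=2.4, rt_max_s=3.0,
    effect_amplitude=1.0, effect_onsets_s={"PT": 0.27, "MTL": 0.48},
    alpha_amplitude=0.0, spike_rate_per_min=0.0,
    burst_amplitude=1.0, mod_depth=0.2, pattern_gain_sd=0.3, pattern_noise=0.1)
rec, trials, gt = generate_recording(cfg, seed=11)

rec_trials = select_trials(trials, phase="recognition")
tfr = zscore_session(morlet_tfr(rec, rec_trials, freqs=band_centers(),
                                window=(0.0, 2.0), buffer_s=0.5))
binned = band_power(bin_power(tfr))             # 200 ms bins, 100 ms step

rows = trials.loc[binned.trial_index]
manip = (rows.condition.isin(["added", "removed"]) & rows.correct).to_numpy()
repc = ((rows.condition == "repeated") & rows.correct).to_numpy()
print(f"{manip.sum()} manipulated-correct vs {repc.sum()} repeated-correct trials "
      f"(bootstrap-matched, 100 iterations)")

for region in ("PT", "MTL"):
    ch = rec.channels_in_region(region)
    series = binned.values[:, ch, 0, :].mean(axis=1)
    mean_m, mean_r = bootstrap_match(series[manip], series[repc], n_iter=100, seed=1)
    diff = mean_m - mean_r
    est = estimate_onset(diff, binned.bin_centers, search_window=(0.0, 2.0))
    slope = instantaneous_slope(diff, binned.bin_centers, window=(0.0, 0.5))
    print(f"{region}: onset {1000 * est.onset_s:5.0f} ms (injected "
          f"{1000 * gt.effect_onsets_s[region]:3.0f} ms), "
          f"half-peak {1000 * est.half_peak_s:5.0f} ms, peak {est.peak_s:.2f} s, "
          f"early slope {slope:+.3f} z/bin")
print("PT leading MTL indicates the difference signal ascends the visual hierarchy.")
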