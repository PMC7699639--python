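"""Encoding-retrieval reinstatement with a within-list shuffle null.

Each image evokes a distributed 80-120 Hz pattern that recurs at
recognition.  Cosine similarity between encoding and retrieval feature
vectors forms a trial-wise reinstatement map; pairing retrieval trials
with encoding epochs of other images from the same 4-image list (all
derangements enumerated) gives the image-specificity null.  A 2-D
sign-flip cluster test across synthetic participants marks significance.
"""

import numpy as np

from memscan import generate_recording
from memscan.cluster import cluster_2d
from memscan.reinstatement import build_features, cosine_map, shuffle_null
from memscan.simulate import default_config
from memscan.spectral import (band_centers, band_power, bin_power, morlet_tfr,
                              select_trials, zscore_session)

cfg = default_config(
    region_channels={"PT": 4}, n_lists=4,
    encoding_duration_s=1.4, pre_image_gap_s=1.0,
    rt_mean_s=1.7, rt_sigma=0.05, rt_min_s=1.5, rt_max_s=2.0,
    effect_amplitude=0.0, alpha_amplitude=0.0, spike_rate_per_min=0.0,
    burst_amplitude=1.2, mod_depth=0.3, pattern_gain_sd=0.7, pattern_noise=0.25)

diff_maps = []
for participant in range(6):
    rec, trials, _ = generate_recording(cfg, seed=20 + participant)
    phase_maps = {}
    for phase in ("encoding", "recognition"):
        tr = select_trials(trials, phase=phase)
        tfr = zscore_session(morlet_tfr(rec, tr, freqs=band_centers(),
                                        window=(0.0, 1.4), buffer_s=0.5))
        phase_maps[phase] = band_power(bin_power(tfr))
    feats = build_features(phase_maps["encoding"], phase_maps["recognition"], trials)
    true = cosine_map(feats)                       # (images, enc bins, ret bins)
    null = shuffle_null(feats)
    diff_maps.append(np.nanmean(true, axis=0) - np.nanmean(null, axis=0))

diff_maps = np.stack(diff_maps)
res = cluster_2d(diff_maps, seed=0)
sig = [c for c in res.significant() if c.sign > 0]
print(f"mean true-minus-shuffled reinstatement: {np.nanmean(diff_maps):+.3f} "
      "(> 0 means patterns are image-specific)")
if sig:
    c = sig[0]
    print(f"significant 2-D cluster: {len(c.bins)} epoch pairs, "
          f"sum-of-t {c.stat:.0f}, p = {c.p:.3f} "
          "(exceeds every max-cluster statistic under participant sign flips)")
else:
    print("no significant cluster (expected only if patterns were shared)")
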