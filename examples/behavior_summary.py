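"""Gaze fixations, critical-region viewing and working-memory capacity.

Detects fixations with the 2-degree / 100 ms dispersion rule, scores them
against each recognition image's critical-region rectangle, and estimates
Cowan's K = (HitRate + CorrectRejectionRate - 1) * N from the recognition
accuracies.
"""

import numpy as np

from memscan import generate_gaze, generate_recording
from memscan.behavior import (behavior_summary, critical_region_metrics,
                              detect_fixations)
from memscan.simulate import default_config

cfg = default_config(region_channels={"PT": 2}, n_lists=10,
                     encoding_duration_s=1.0, rt_mean_s=2.5, rt_sigma=0.2,
                     rt_min_s=1.5, rt_max_s=5.0, spike_rate_per_min=0.0)
rec, trials, gt = generate_recording(cfg, seed=5)
gaze, dwells = generate_gaze(trials, seed=5, ground_truth=gt)

fixations = detect_fixations(gaze)
print(f"{len(fixations)} fixations detected from "
      f"{len(gaze.samples)} gaze samples at {gaze.fs:g} Hz")

rects = gaze.regions.set_index("image_id")
hits, fractions = [], []
for row in trials[trials.phase == "recognition"].itertuples():
    fx = [f for f in fixations
          if row.image_onset_s <= f.onset_s < row.image_offset_s]
    r = rects.loc[row.image_id]
    m = critical_region_metrics(fx, (r.x0, r.y0, r.x1, r.y1))
    hits.append(m["any_fixation_in_region"])
    fractions.append(m["time_fraction_in_region"])
print(f"P(>=1 fixation in critical region) = {np.mean(hits):.2f}; "
      f"mean fraction of viewing time in region = {np.mean(fractions):.2f}")

s = behavior_summary(trials)
for cond, e in sorted(s["conditions"].items()):
    print(f"  {cond:8s}: recognized {100 * e['p_correct']:4.0f}% of {e['n']} trials")
print(f"hit rate {s['hit_rate']:.3f}, correct rejections "
      f"{s['correct_rejection_rate']:.3f} -> Cowan's K = "
      f"{s['cowans_k'][8]:.1f} (N=8) to {s['cowans_k'][20]:.1f} (N=20) "
      "items held in memory per list")
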