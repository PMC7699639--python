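"""Inter-region lag, alpha coherence and phase synchrony.

Cross-correlograms of 10 ms-binned high-gamma power recover the injected
40 ms PT-before-MTL envelope lead; a 100-permutation chance correlogram
from mismatched trials captures the stimulus-locked component.  Alpha-band
(8-12 Hz) coherence and the phase-locking value pick up the injected
phase-lagged coupling on manipulated-correct trials.
"""

import numpy as np

from memscan import generate_recording
from memscan.connectivity import (band_phase, chance_crosscorrelogram,
                                  crosscorrelogram, msc_coherence,
                                  peak_lag_stats, plv)
from memscan.simulate import default_config
from memscan.spectral import band_centers, morlet_tfr, select_trials, zscore_session

cfg = default_config(
    region_channels={"PT": 2, "MTL": 2}, n_lists=6,
    encoding_duration_s=1.0, pre_image_gap_s=1.2,
    rt_mean_s=2.2, rt_sigma=0.05, rt_min_s=2.0, rt_max_s=2.6,
    effect_amplitude=0.0, burst_amplitude=1.5, mod_depth=0.8,
    pattern_gain_sd=0.3, pattern_noise=0.1, spike_rate_per_min=0.0,
    alpha_amplitude=1.0)
rec, trials, gt = generate_recording(cfg, seed=9)
rec_trials = select_trials(trials, phase="recognition")

# --- lag from cross-correlograms (first second after image onset) --------
tfr = zscore_session(morlet_tfr(rec, rec_trials, freqs=band_centers(),
                                window=(0.0, 1.0), buffer_s=0.5))
bp = tfr.power.mean(axis=2)
true_ccgs, chance_ccgs = [], []
for i in rec.channels_in_region("PT"):
    for j in rec.channels_in_region("MTL"):
        true_ccgs.append(crosscorrelogram(bp[:, i], bp[:, j], fs=rec.fs))
        chance_ccgs.append(chance_crosscorrelogram(bp[:, i], bp[:, j],
                                                   fs=rec.fs, seed=1))
pairs, summary = peak_lag_stats(true_ccgs, chance_ccgs,
                                participant_ids=[0] * len(true_ccgs))
print(f"peak lag {summary['mean_peak_lag_ms']:+.0f} ms over {len(pairs)} electrode "
      f"pairs (injected {gt.envelope_lag_ms:+.0f} ms; positive = PT leads MTL)")

# --- alpha coherence: coupled vs uncoupled conditions --------------------
rows = trials.loc[tfr.trial_index]
coupled = (rows.condition.isin(["added", "removed"]) & rows.correct).to_numpy()
i, j = rec.channels_in_region("PT")[0], rec.channels_in_region("MTL")[0]


def _alpha_coh(sel):
    segs = []
    for row in rows[sel].itertuples():
        s0 = int(row.image_onset_s * rec.fs) + 300
        segs.append((rec.traces[i, s0:s0 + 1000], rec.traces[j, s0:s0 + 1000]))
    f, c = msc_coherence(np.stack([s[0] for s in segs]),
                         np.stack([s[1] for s in segs]), fs=rec.fs)
    return c[(f >= 8) & (f <= 12)].mean()


print(f"alpha coherence 300-1300 ms: coupled {_alpha_coh(coupled):.2f} vs "
      f"uncoupled {_alpha_coh(~coupled):.2f} (coupling injected only on "
      "manipulated-correct trials)")

# --- phase-locking value across coupled trials ---------------------------
epochs_i, epochs_j = [], []
for row in rows[coupled].itertuples():
    s0 = int(row.image_onset_s * rec.fs)
    epochs_i.append(rec.traces[i, s0 + 400:s0 + 1400])
    epochs_j.append(rec.traces[j, s0 + 400:s0 + 1400])
r = plv(band_phase(np.stack(epochs_i), rec.fs, band=(8.0, 12.0)),
        band_phase(np.stack(epochs_j), rec.fs, band=(8.0, 12.0)))
print(f"alpha PLV across {coupled.sum()} coupled trials: {r.mean():.2f} "
      "(1 = perfectly consistent phase lag)")
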