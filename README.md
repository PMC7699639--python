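# memscan

Event-locked analysis of intracranial EEG (iEEG) recorded during a
visuospatial recognition-memory task, built around the question of how the
brain detects a mismatch between what is seen and what is remembered.
Participants encode lists of four natural scenes and later judge whether
each scene was repeated or manipulated (an item added or removed);
`memscan` implements the full signal-analysis chain used to characterise
the neural signature of that comparison:

* **Preprocessing** — bipolar referencing from grid/strip geometry,
  resampling to 1 kHz, a 4th-order 60 Hz Butterworth notch, and two tiers
  of artifact rejection: a quartile rule on per-trial/per-electrode mean
  absolute voltage (drop iff value > Q3 + 2.3·(Q3 − Q1)) and an
  event-level mask for samples whose gradient or 250 Hz high-passed
  amplitude exceeds a session z-score of 5 (±100 ms margins).
* **Spectral power** — complex Morlet wavelets (wavelet number 6, 32
  log-spaced frequencies over 2–431 Hz), log-transformed power z-scored
  per channel, frequency and session, then binned into 200 ms epochs
  stepped every 100 ms.  High-gamma (80–120 Hz) band power is the mean
  z-score over the wavelet centers inside that band.  Condition contrasts
  use a 100-iteration bootstrap to equate trial counts.
* **Reinstatement** — cosine similarity between encoding and retrieval
  feature vectors (one z-scored band-power entry per electrode,
  K = L·F features) forms a trial-wise map C(i, j) over epoch pairs;
  image specificity is tested against a within-list shuffle null in which
  retrieval trials are paired with encoding epochs of *other* images from
  the same 4-image list (all derangements enumerated).
* **Connectivity** — trial-averaged cross-correlograms of 10 ms-binned
  high-gamma power (with a 100-permutation mismatched-trial chance
  correlogram) estimate inter-region lag; Welch magnitude-squared
  coherence C(f) = |P_xy|²/(P_xx·P_yy) and the phase-locking value
  R̄ = |mean exp(i(φ_p − φ_q))| quantify alpha-band (8–12 Hz) coupling.
* **Temporal dynamics** — region peak-time label-shuffle tests,
  instantaneous slope over the first 500 ms, and onset estimation by
  fitting a line from the local minimum preceding the peak of a condition
  difference series to the peak and taking its zero crossing.
* **Cluster statistics** — nonparametric cluster-based permutation tests
  (sum-of-t cluster statistic, max-statistic correction) with
  participant-level sign flips (exact 2ⁿ enumeration for n ≤ 10) or
  trial-level label shuffles, in 1-D (time) and 2-D (time×time,
  time×frequency).
* **Behaviour** — dispersion-based (I-DT) fixation detection (2°,
  ≥100 ms), critical-region viewing metrics, and Cowan's working-memory
  capacity K = (HitRate + CorrectRejectionRate − 1)·N.

Real patient recordings are not redistributable, so the package ships a
first-class synthetic-data generator (`memscan.simulate`) that emulates
the relevant signal structure — image-specific spatial gain patterns,
region-specific condition onsets, a fixed inter-region envelope lag,
alpha coupling, line noise, spikes, outlier trials, gaze dwells — with a
serialized `GroundTruth` so every estimator can be scored against known
answers (`memscan.studies`).

## Worked example

```bash
python examples/lag_and_coherence.py
```

prints, for a two-region synthetic session with a 40 ms injected
PT→MTL envelope lead and alpha coupling on manipulated-correct trials:

```
peak lag +40 ms over 4 electrode pairs (injected +40 ms; positive = PT leads MTL)
alpha coherence 300-1300 ms: coupled 0.77 vs uncoupled 0.06 (coupling injected only on manipulated-correct trials)
alpha PLV across 15 coupled trials: 0.90 (1 = perfectly consistent phase lag)
```

The peak of the trial-averaged cross-correlogram recovers the injected
lead exactly (one 10 ms bin resolution); coherence and phase locking are
elevated only in the condition that carries the injected coupling.  The
other scripts in `examples/` walk through simulation and container I/O,
preprocessing, band-power onset estimation (`PT: onset 156 ms … MTL:
onset 308 ms` for effects injected at 270/480 ms — the 200 ms analysis
bins shift both onsets earlier by a constant, preserving the ordering),
reinstatement mapping, and the behavioural summary.

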