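# Methods

## The analysis model

`memscan` treats an iEEG session as a channels × samples voltage array with
per-channel region labels (LOC, PAR, PT, MTL) and a trial table of
event-locked image presentations (encoding and recognition phases; repeated /
added / removed conditions; correctness; response times).  All signal
processing assumes a common sampling rate per session (1000 or 2000 Hz,
conditioned to 1000 Hz), 0-based sample indexing with sample k at time k/fs,
and half-open epochs [start, end).

### Preprocessing

Bipolar referencing subtracts immediately adjacent contacts within each grid
or strip (depth probes are 1-D strips); an n×m grid yields n(m−1)+m(n−1)
virtual electrodes, each inheriting the shared region label (straddling pairs
take the anode's label and are logged).  Conditioning resamples 2 kHz input
by 2 (polyphase) and applies a 4th-order Butterworth band-stop at 59–61 Hz.
All filtering in the package is zero-phase (forward–backward): latency
quantities (onsets, lags, first-significant times) are the scientific target
and must not inherit filter group delay.

Artifact rejection has two tiers.  The quartile rule drops any trial (then
any electrode) whose mean absolute voltage exceeds Q3 + w·(Q3 − Q1) with
w = 2.3; quartiles use linear interpolation, and the comparison is strict so
an all-equal sample is never rejected.  The statistic is mean *absolute*
voltage by default — a signed mean hovers near zero for any zero-mean signal
and would make the rule vacuous — with the signed variant available as a
switch.  The event-level detector z-scores, over the whole session, (a) the
first difference of the trace and (b) the trace after a 250 Hz 4th-order
high-pass, and masks samples where either |z| > 5, together with ±100 ms on
each side (overlapping spans merge).  The signed high-passed signal is
z-scored rather than its rectified amplitude: rectification halves the
effective threshold and lets ordinary Gaussian tails through at rates that
dilate into percent-level data loss.  A guard skips the high-frequency
channel when its residue is below 10⁻³ of the trace's scale (pure
low-frequency inputs leave only stopband leakage and filtfilt edge
transients, which must not be z-amplified into events).

### Spectral power

Power and phase come from complex Morlet wavelets (wavelet number 6) at 32
log-spaced center frequencies f_k = 2·(431/2)^(k/31), k = 0…31, computed by
`mne.time_frequency.tfr_array_morlet` on epochs padded with 1 s buffers that
absorb convolution edges and are trimmed afterwards (epochs must exceed the
3 s length of the 2 Hz wavelet).  Power is ln(|W|² + ε) with ε = 10⁻⁴⁰ —
the floor only guards exact zeros and is invisible after normalization.
Z-scoring is per channel × frequency over all retained session samples
(a per-frequency-only pooled variant is a switch); it makes every
downstream statistic invariant to per-channel gain.  Binning averages
200 ms windows stepped by 100 ms, left-aligned and half-open, dropping the
final partial bin; bin centers label the time axis.  Recognition epochs
are analysed from image onset to the response, response times above 10 s
excluded; samples beyond a trial's extent are flagged invalid and propagate
as NaN.  The 80–120 Hz band statistic is the mean z-score over the wavelet
centers inside the closed interval (two centers, ≈90.7 and ≈107.9 Hz, under
the default grid).  Unequal condition counts are equated by averaging 100
bootstrap subsample means of the larger condition at the smaller count.

### Reinstatement

For each temporal epoch a feature vector stacks the band-power z-scores of
the scoped electrodes (electrode-major, band-minor; K = L·F entries, K = L
in the default single-band analysis).  Trial-wise reinstatement maps are
cosine similarities between all encoding/retrieval epoch pairs; cosine is
used rather than Pearson because a coherent broadband power increase is
reinstatement, not noise to be centered away.  Normalization z-scores each
map cell across trials (cell-wise; a global-moment variant is a switch).
The specificity null pairs each retrieval trial with encoding epochs of a
different image from the same 4-image list: all derangements of the list
(9 for size 4) are enumerated and averaged, removing Monte-Carlo noise;
size-1 lists are excluded and logged.  Retrieval-locked time series average
the normalized map over the encoding epochs found significant by the 2-D
cluster test.

### Connectivity

Cross-correlograms: band power over the first second after onset is averaged
into non-overlapping 10 ms bins; each trial's series pair is correlated at
every lag (Pearson per lag, raw covariance as a switch) and the correlation
averaged over trials.  Positive lag means the first channel leads.  The
chance correlogram repeats this 100 times on randomly mismatched trial pairs
(A-trial ≠ B-trial), capturing whatever coupling the shared stimulus alone
induces.  Peak lags are searched within ±200 ms (ties broken toward zero);
per-pair significance compares true vs chance values within ±50 ms by paired
t; participants contribute their mean pair lag to a two-sided one-sample t
against zero.

Coherence uses Welch's magnitude-squared estimator (500 ms Hann segments,
50 % overlap inside 1 s epochs) on common-average-referenced contacts —
bipolar referencing subtracts away exactly the low-frequency coherence under
study.  The phase-locking value takes Hilbert phases of the 4th-order
zero-phase band-passed signals and computes the modulus of the mean unit
phasor of phase differences across trials per time point; it is amplitude-
blind by construction and compared against a 1 s pre-image baseline with a
one-tailed paired t across electrode pairs.

### Temporal dynamics

The peak-time test compares the argmax times of two regions'
across-participant mean series against a null that swaps the two region
labels independently per participant (all 2ⁿ patterns enumerated for
n ≤ 12).  A property worth knowing: when both regions carry responses of
equal amplitude, every swap pattern reproduces the same absolute peak-time
difference and the test has no power; its sensitivity comes from amplitude
and shape asymmetry between regions, which real regional series (and the
synthetic ones) possess.  The instantaneous slope is the mean adjacent-bin
difference over bins in the first 500 ms — telescoping, so exact on ramps.
Onset estimation finds the global peak of the condition-difference series
inside a 0–2 s window (configurable; chosen to cover the injected effect
support), walks back to the nearest strict local minimum (plateaus resolve
to their latest bin; absent a minimum, the window start is used and
logged), fits a least-squares line through the bins between minimum and
peak, and reports the line's zero crossing.  The crossing is clamped into
[local minimum, peak] — a crossing extrapolated before the local minimum
indicates a degenerate (short, shallow) fit, and the clamp enforces the
estimate's defining invariant (minimum < onset ≤ peak); pre-stimulus
crossings clamp to zero.  Both clamps set a flag.  Half-peak times
interpolate linearly between bins.  Because the series is built from 200 ms
bins labelled by centers, estimated onsets sit systematically earlier than
the injected instants by roughly half a bin plus the rise-time geometry;
orderings and differences between regions are unaffected, which is why the
validation scores ordering rather than absolute onset.

### Cluster statistics

Pointwise statistics are paired t across participants (or pooled-variance
unpaired t across trials); zero-variance bins return the largest
representable statistic with p = 0 (nonzero mean) or t = 0 (zero mean) and
are logged as degenerate.  Clusters are contiguous suprathreshold
(pointwise p < 0.05) bins of common sign — runs in 1-D, 4-connected
components in 2-D (8-connectivity switchable) — scored by their summed t.
The null records, per permutation, the maximum |cluster statistic| over
both signs, which corrects for multiple comparisons across bins and both
tails.  Participant-level nulls reverse difference signs (exact 2ⁿ
enumeration for n ≤ 10, in which case cluster p is the exact null fraction
including the identity; otherwise 1000 draws with the
(1 + #{null ≥ obs})/(1 + N) convention so p is never zero).  Trial-level
nulls permute condition labels (counts preserved; a redraw guard logs any
degenerate permutation).  Sign-flip t statistics are computed vectorized
over all permutations: squared differences are flip-invariant, so only
per-permutation means need recomputing.

### Behaviour

Fixation detection is I-DT: a window of consecutive samples grows while its
maximum pairwise distance (bounding-box diagonal switchable) stays within
2°, and emits a fixation when it spans ≥100 ms; gaps longer than two sample
periods split windows; the window advances past each emitted fixation.  The
incremental update (each new sample checked against current members) keeps
long stationary periods linear-ish rather than cubic.  Critical-region
metrics are per-trial: any-fixation-inside, fraction of summed fixation
time inside (0, not missing, for fixation-free trials), and click-inside.
Cowan's K = (HR + CR − 1)·N with HR the recognition accuracy for
manipulated images — by default the mean of the added and removed rates,
which with the task's rates (0.65, 0.68, repeated 0.88) gives K = 4.4 at
N = 8 and 10.9 at N = 20, the bounds implied by 4-image lists of 2–5 items
each; pooled-trial HR is a switch.  Negative K (below-chance responding) is
returned as-is with a flag.

## The synthetic-data generator

`memscan.simulate` emulates the signal structure the pipeline measures,
without biophysics.  Defaults follow the study conditions: 60 lists of 4
images per session, 5 s encoding presentations after 1 s fixation gaps,
recognition shown until a lognormal response (median 2.5 s, clipped to
[1, 9.5] s), conditions 28/36/36 % repeated/added/removed with accuracies
88/65/68 %, fs = 1000 Hz, and region channel counts of a few electrodes
per region.  Signal components, all on a unit-SD pink (1/f) background:

* an 80–120 Hz band-limited burst during every image, with trapezoidal
  envelope (150 ms rise, 200 ms decay) and default amplitude 0.5 — small in
  raw voltage, as real high-gamma responses are, so the event-level
  artifact detector is not triggered by physiology;
* image-specific per-channel multiplicative gains (lognormal, σ = 0.5)
  drawn once per image and reused at recognition — the substrate of
  reinstatement; a `pattern_noise` lognormal jitter (σ = 0.2) models
  trial-to-trial pattern variability, which is otherwise uncharacterised;
  `shared_patterns` collapses all images onto one gain vector for null
  studies;
* an excess burst on manipulated-correct recognition trials with
  region-specific onsets (defaults 270 ms PT, 295 ms PAR, 480 ms MTL;
  250 ms rise, 1 s support) — the condition effect;
* a slow (≤12 Hz) positive modulation of each trial's envelope, shared
  between the lead and lag regions with the lag region's entire envelope a
  40 ms-delayed copy — what cross-correlograms recover;
* optional 60 Hz line noise, sharp biphasic 20 ms spike transients at 8×
  the background SD (fast rise and polarity reversal so they exceed the
  z > 5 gradient threshold by construction), and outlier trials with
  per-channel constant deflections large enough to trip the quartile rule
  and survive bipolar referencing.

Carriers are independent across channels so that only the power envelope,
not the raw waveform, is shared within a region (shared raw carriers would
vanish under bipolar referencing).  Gaze streams place configurable
in-region and out-of-region dwells (jitter σ = 0.15°, well inside the 2°
dispersion bound) separated by 30 ms saccades on a 120 Hz grid, with the
dwell table recorded as ground truth.  What the generator does *not*
emulate: 1/f knee structure, inter-electrode noise correlations, true
oscillatory bursting statistics, saccade kinematics, or any physiology —
so passing validation studies demonstrates correctness of the estimators
under the stated signal model, not performance on real recordings.

## Validation studies and problem sizes

`memscan.studies` runs end-to-end recoveries on deliberately small sessions
(2–4 electrodes per region, 4–14 lists, 1–2 s presentations) so that
whole studies with 50–100 regenerations complete in minutes; the study
configs raise burst/effect amplitudes relative to defaults to reach the
signal-to-noise a full-size session (hundreds of trials, tens of
electrodes) would provide with the default amplitudes.  Fixed seeds make
every study reproducible, and each regeneration draws its seed from one
`numpy` Generator.  The studies: Cowan's K worked examples (exact); 40 ms
lag recovery within one 10 ms bin over 50 regenerations; sign-flip cluster
family-wise error over 200 null experiments at n = 8 (exact enumeration)
plus exact-vs-sampled agreement at n = 5; reinstatement 2-D cluster
significance under image-specific vs shared gains (50 regenerations each);
onset-ordering recovery for 270/480 ms injections over 100 regenerations;
PLV/MSC closed-form identities (PLV = 1 at constant lag, ≈√(π/4N) under
uniform phases; MSC = 1 for identical signals, ≈1/K for K independent
segments); and spike-mask sensitivity/specificity.

## Known limitations

The onset estimator's absolute values carry the half-bin-plus-rise bias
described above; compare onsets, not their absolute values, across
conditions estimated the same way.  The peak-time shuffle test is blind to
pure latency shifts between equal-amplitude responses.  Coherence epochs
shorter than two Welch segments are rejected rather than padded.  The
generator's condition effect multiplies the same carrier as the base burst,
so effect and base power are not independent within a trial.  Electrode-
and trial-level quartile rejection run trials first, then electrodes, on
the retained trials; the joint procedure is order-dependent in edge cases.
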