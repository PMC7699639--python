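"""Synthetic iEEG sessions with known ground truth.

The generator emulates the signal structure that the analysis pipeline is
built to measure, without modelling physiology:

* pink (1/f) background noise per channel, optionally with 60 Hz line noise,
  biphasic spike transients and high-amplitude outlier trials;
* an event-locked 80–120 Hz burst on every image presentation, whose
  per-channel amplitude is scaled by an image-specific spatial gain vector
  drawn once per image — the same gains at encoding and recognition, which
  is what makes encoding–retrieval reinstatement measurable;
* an excess high-gamma response on manipulated-correct recognition trials
  with a configurable, region-specific onset (the condition effect);
* a slow trial-specific amplitude modulation of the burst that is shared
  between two regions with a fixed envelope lag (the lead region's envelope
  precedes the lag region's), which cross-correlograms should recover;
* alpha-band (8–12 Hz) phase-lagged coupling between the two regions on a
  configurable subset of trials.

All times are seconds, sample indexing is 0-based, epochs are half-open
``[start, end)``.  A fixed seed yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import Recording, GroundTruth, GazeStream, REGIONS, validate_trials

__all__ = ["SimConfig", "GazeConfig", "generate_recording", "generate_gaze", "default_config"]


@dataclass
class SimConfig:
    """Generator parameters.  Defaults follow the study conditions.

    Sessions comprise ``n_lists`` lists of four images: four sequential
    encoding presentations (5 s each, 1 s fixation gap) followed by the same
    images in the same order at recognition, each shown until the response.
    Recognition images are repeated/added/removed in 28/36/36 % proportion
    with per-condition accuracies of 88/65/68 %.
    """

    # --- layout ---------------------------------------------------------
    region_channels: dict = field(
        default_factory=lambda: {"LOC": 3, "PT": 8, "PAR": 6, "MTL": 8})
    n_lists: int = 60
    images_per_list: int = 4
    fs: float = 1000.0
    encoding_duration_s: float = 5.0
    pre_image_gap_s: float = 1.0
    tail_s: float = 2.0                       # padding after the last trial
    # --- behaviour ------------------------------------------------------
    p_repeated: float = 0.28
    p_added: float = 0.36
    p_removed: float = 0.36
    p_correct: dict = field(
        default_factory=lambda: {"repeated": 0.88, "added": 0.65, "removed": 0.68})
    rt_mean_s: float = 2.5
    rt_sigma: float = 0.35                    # lognormal shape
    rt_min_s: float = 1.0
    rt_max_s: float = 9.5
    # --- background -----------------------------------------------------
    noise_sd: float = 1.0                     # pink-noise SD (arbitrary µV scale)
    pink_exponent: float = 1.0                # power ~ 1/f^exponent
    line_noise_amplitude: float = 0.0         # 60 Hz sinusoid, optional
    # --- image burst ----------------------------------------------------
    burst_band: tuple = (80.0, 120.0)
    burst_amplitude: float = 0.5              # x noise SD, before spatial gain
    burst_rise_s: float = 0.15
    burst_decay_s: float = 0.2
    pattern_gain_sd: float = 0.5              # lognormal sigma of image-specific gains
    pattern_noise: float = 0.2                # trial-level lognormal gain jitter
    shared_patterns: bool = False             # all images share one gain vector
    # --- condition effect ----------------------------------------------
    effect_amplitude: float = 0.4             # excess burst on manipulated-correct
    effect_onsets_s: dict = field(
        default_factory=lambda: {"LOC": 0.15, "PT": 0.27, "PAR": 0.295, "MTL": 0.48})
    effect_rise_s: float = 0.25
    effect_duration_s: float = 1.0
    # --- inter-region envelope lag --------------------------------------
    lead_region: str = "PT"
    lag_region: str = "MTL"
    envelope_lag_ms: float = 40.0
    mod_depth: float = 0.6                    # slow trial-specific modulation depth
    mod_bandwidth_hz: float = 12.0
    # --- alpha coupling --------------------------------------------------
    alpha_amplitude: float = 0.8
    alpha_freq_hz: float = 10.0
    alpha_phase_lag: float = math.pi / 4
    alpha_window_s: tuple = (0.3, 1.8)
    alpha_conditions: tuple = ("added", "removed")   # coupled when correct
    # --- artifacts -------------------------------------------------------
    spike_rate_per_min: float = 0.5           # per channel
    spike_amplitude_sd: float = 8.0           # x noise SD
    spike_duration_s: float = 0.02
    outlier_trial_frac: float = 0.0
    outlier_scale: float = 6.0


def default_config(**overrides) -> SimConfig:
    """The default study conditions, with keyword overrides."""
    return replace(SimConfig(), **overrides)


# ---------------------------------------------------------------------------
# helpers


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, sd: float) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise with the requested standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple) -> np.ndarray:
    """Unit-SD noise band-limited to ``band`` (4th-order Butterworth)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def _slow_modulation(rng: np.random.Generator, n: int, fs: float,
                     bandwidth: float, depth: float) -> np.ndarray:
    """Positive slow modulation 1 + depth * lowpassed noise, clipped at 0.05."""
    sos = signal.butter(4, bandwidth, btype="lowpass", fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, rng.standard_normal(n))
    s = z.std()
    if s > 0:
        z = z / s
    return np.clip(1.0 + depth * z, 0.05, None)


def _burst_base(t: np.ndarray, dur: float, rise: float, decay: float) -> np.ndarray:
    """Trapezoidal envelope: linear rise, sustain over the image, linear decay."""
    env = np.zeros_like(t)
    up = (t >= 0) & (t < rise)
    env[up] = t[up] / rise
    env[(t >= rise) & (t < dur)] = 1.0
    down = (t >= dur) & (t < dur + decay)
    env[down] = 1.0 - (t[down] - dur) / decay
    return env


def _effect_env(t: np.ndarray, onset: float, rise: float, dur: float) -> np.ndarray:
    """Condition-excess envelope: zero before ``onset``, linear rise to 1 over
    ``rise``, then linear decay back to zero over the remaining duration."""
    env = np.zeros_like(t)
    up = (t >= onset) & (t < onset + rise)
    env[up] = (t[up] - onset) / rise
    down = (t >= onset + rise) & (t < onset + dur)
    fall = dur - rise
    if fall > 0:
        env[down] = 1.0 - (t[down] - (onset + rise)) / fall
    return env


# ---------------------------------------------------------------------------
# trial table


def _make_trials(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_images = cfg.n_lists * cfg.images_per_list
    p = np.array([cfg.p_repeated, cfg.p_added, cfg.p_removed])
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("condition proportions must sum to 1")
    conditions = rng.choice(["repeated", "added", "removed"], size=n_images, p=p)
    rows = []
    t = 0.0
    trial_id = 0
    for lst in range(cfg.n_lists):
        images = [lst * cfg.images_per_list + k for k in range(cfg.images_per_list)]
        for img in images:
            t += cfg.pre_image_gap_s
            rows.append(dict(trial_id=trial_id, list_id=lst, image_id=img,
                             phase="encoding", condition=conditions[img],
                             correct=True, image_onset_s=t,
                             image_offset_s=t + cfg.encoding_duration_s,
                             response_time_s=np.nan))
            t += cfg.encoding_duration_s
            trial_id += 1
        for img in images:
            t += cfg.pre_image_gap_s
            rt = float(np.clip(rng.lognormal(math.log(cfg.rt_mean_s), cfg.rt_sigma),
                               cfg.rt_min_s, cfg.rt_max_s))
            cond = conditions[img]
            correct = bool(rng.random() < cfg.p_correct[cond])
            rows.append(dict(trial_id=trial_id, list_id=lst, image_id=img,
                             phase="recognition", condition=cond,
                             correct=correct, image_onset_s=t,
                             image_offset_s=t + rt, response_time_s=rt))
            t += rt
            trial_id += 1
    trials = pd.DataFrame(rows)
    return validate_trials(trials)


def _make_channel_meta(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for gi, (region, n) in enumerate(cfg.region_channels.items()):
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        for k in range(n):
            rows.append(dict(label=f"{region}{k}", region=region, grid_id=f"g{gi}",
                             grid_row=k, grid_col=0, is_depth=(region == "MTL")))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# main generator


def generate_recording(config: Optional[SimConfig] = None, seed: int = 0):
    """Generate one synthetic session.

    Returns ``(Recording, trial_table, GroundTruth)``.  The same
    ``(config, seed)`` pair always produces bit-identical output.
    """
    cfg = config or SimConfig()
    if cfg.n_lists <= 0 or cfg.images_per_list <= 0:
        raise ValueError("config yields zero trials")
    if cfg.fs < 2.0 * max(cfg.burst_band[1], 60.0 if cfg.line_noise_amplitude else 0.0,
                          cfg.alpha_freq_hz):
        raise ValueError("fs below twice the maximum synthesis frequency")
    for name in ("burst_amplitude", "effect_amplitude", "alpha_amplitude",
                 "noise_sd", "mod_depth"):
        if getattr(cfg, name) < 0:
            raise ValueError(f"negative {name}")

    rng = np.random.default_rng(seed)
    trials = _make_trials(cfg, rng)
    meta = _make_channel_meta(cfg)
    n_ch = len(meta)
    fs = cfg.fs
    n_samples = int(math.ceil((trials["image_offset_s"].max() + cfg.tail_s) * fs))

    gt = GroundTruth(seed=seed,
                     effect_amplitude=cfg.effect_amplitude,
                     effect_onsets_s=dict(cfg.effect_onsets_s),
                     effect_duration_s=cfg.effect_duration_s,
                     envelope_lag_ms=cfg.envelope_lag_ms,
                     lead_region=cfg.lead_region, lag_region=cfg.lag_region)

    # image-specific spatial gains (recurring at encoding and recognition)
    n_images = cfg.n_lists * cfg.images_per_list
    if cfg.shared_patterns:
        shared = np.exp(rng.normal(0.0, cfg.pattern_gain_sd, size=n_ch))
        gains = {img: shared.copy() for img in range(n_images)}
    else:
        gains = {img: np.exp(rng.normal(0.0, cfg.pattern_gain_sd, size=n_ch))
                 for img in range(n_images)}
    gt.image_gains = gains

    # background
    traces = np.empty((n_ch, n_samples))
    for ch in range(n_ch):
        traces[ch] = _pink_noise(rng, n_samples, fs, cfg.pink_exponent, cfg.noise_sd)
    if cfg.line_noise_amplitude > 0:
        t_all = np.arange(n_samples) / fs
        phase0 = rng.uniform(0, 2 * math.pi)
        traces += cfg.line_noise_amplitude * np.sin(2 * math.pi * 60.0 * t_all + phase0)

    # per-channel band-limited carriers (independent across channels so that
    # only the power envelope, not the raw waveform, is shared within region)
    carriers = np.empty((n_ch, n_samples))
    for ch in range(n_ch):
        carriers[ch] = _bandlimited_noise(rng, n_samples, fs, cfg.burst_band)

    region_of = meta["region"].to_numpy()
    lag_samples = int(round(cfg.envelope_lag_ms / 1000.0 * fs))
    envelopes = {r: np.zeros(n_samples) for r in cfg.region_channels}

    manip = trials["condition"].isin(["added", "removed"])
    is_effect_trial = (trials["phase"] == "recognition") & manip & trials["correct"]

    for row in trials.itertuples():
        onset = row.image_onset_s
        dur = row.image_offset_s - row.image_onset_s
        # window with margin for decay and lag
        w0 = int(round(onset * fs))
        w1 = min(n_samples, int(round((row.image_offset_s + cfg.burst_decay_s + 0.2) * fs)))
        nt = w1 - w0
        if nt <= 0:
            continue
        t_rel = np.arange(nt) / fs
        # slow trial-specific modulation, shared across regions; generated with
        # margin so the lag-region copy is a pure delay
        mod_full = _slow_modulation(rng, nt + lag_samples, fs,
                                    cfg.mod_bandwidth_hz, cfg.mod_depth)
        mod_lead = mod_full[lag_samples:]
        mod_lag = mod_full[:nt] if lag_samples > 0 else mod_lead
        effect_on = bool(is_effect_trial.iloc[row.Index])
        trial_jitter = np.exp(rng.normal(0.0, cfg.pattern_noise, size=n_ch))
        gain_vec = gains[row.image_id]
        for region in cfg.region_channels:
            # the lag region's whole burst envelope is a delayed copy of the
            # lead region's; the condition effect keeps its own regional onset
            if region == cfg.lag_region:
                mod = mod_lag
                tt = t_rel - lag_samples / fs
            else:
                mod = mod_lead
                tt = t_rel
            amp = cfg.burst_amplitude * _burst_base(tt, dur, cfg.burst_rise_s,
                                                    cfg.burst_decay_s)
            if effect_on and region in cfg.effect_onsets_s:
                amp = amp + cfg.effect_amplitude * _effect_env(
                    t_rel, cfg.effect_onsets_s[region], cfg.effect_rise_s,
                    cfg.effect_duration_s)
            env = amp * mod
            envelopes[region][w0:w1] += env
            ch_idx = np.flatnonzero(region_of == region)
            for ch in ch_idx:
                traces[ch, w0:w1] += (gain_vec[ch] * trial_jitter[ch]) * env * carriers[ch, w0:w1]
        # alpha coupling on configured trials
        if (row.phase == "recognition" and row.correct
                and row.condition in cfg.alpha_conditions and cfg.alpha_amplitude > 0):
            a0, a1 = cfg.alpha_window_s
            s0 = int(round((onset + a0) * fs))
            s1 = min(n_samples, int(round((onset + min(a1, dur)) * fs)))
            if s1 > s0:
                tt = np.arange(s1 - s0) / fs
                phi0 = rng.uniform(0, 2 * math.pi)
                taper = signal.windows.tukey(s1 - s0, 0.25)
                lead_wave = cfg.alpha_amplitude * taper * np.sin(
                    2 * math.pi * cfg.alpha_freq_hz * tt + phi0)
                lag_wave = cfg.alpha_amplitude * taper * np.sin(
                    2 * math.pi * cfg.alpha_freq_hz * tt + phi0 - cfg.alpha_phase_lag)
                for ch in np.flatnonzero(region_of == cfg.lead_region):
                    traces[ch, s0:s1] += lead_wave
                for ch in np.flatnonzero(region_of == cfg.lag_region):
                    traces[ch, s0:s1] += lag_wave
                gt.alpha.setdefault("trial_ids", []).append(int(row.trial_id))
    gt.alpha.update(freq=cfg.alpha_freq_hz, phase_lag=cfg.alpha_phase_lag,
                    amplitude=cfg.alpha_amplitude)
    gt.band_envelopes = envelopes

    # spike transients: sharp biphasic 20 ms deflection at spike_amplitude_sd x SD
    # (fast rise and polarity reversal, slower recovery -- IED-like, and by
    # construction above the z > 5 gradient threshold)
    if cfg.spike_rate_per_min > 0:
        dur_min = n_samples / fs / 60.0
        n_spike_samp = max(6, int(round(cfg.spike_duration_s * fs)))
        n_up = max(2, n_spike_samp // 8)
        n_down = max(3, n_spike_samp // 5)
        n_rec = n_spike_samp - n_up - n_down
        shape = np.concatenate([
            np.linspace(0.0, 1.0, n_up, endpoint=False),
            np.linspace(1.0, -1.0, n_down, endpoint=False),
            np.linspace(-1.0, 0.0, n_rec),
        ])
        for ch in range(n_ch):
            n_spk = rng.poisson(cfg.spike_rate_per_min * dur_min)
            times = np.sort(rng.uniform(0.5, n_samples / fs - 0.5, size=n_spk))
            gt.spike_times_s[ch] = list(map(float, times))
            for ts in times:
                s0 = int(round(ts * fs))
                seg = traces[ch, s0:s0 + n_spike_samp]
                seg += cfg.spike_amplitude_sd * cfg.noise_sd * shape[:len(seg)]

    # outlier trials: large common low-frequency deflection over the trial
    if cfg.outlier_trial_frac > 0:
        n_out = int(round(cfg.outlier_trial_frac * len(trials)))
        out_ids = rng.choice(trials["trial_id"].to_numpy(), size=n_out, replace=False)
        gt.outlier_trials = sorted(map(int, out_ids))
        for tid in gt.outlier_trials:
            row = trials.loc[trials["trial_id"] == tid].iloc[0]
            s0 = int(round(row["image_onset_s"] * fs))
            s1 = min(n_samples, int(round(row["image_offset_s"] * fs)))
            # per-channel amplitudes so the deflection survives bipolar referencing
            amp = cfg.outlier_scale * cfg.noise_sd * (0.5 + rng.random(n_ch))
            traces[:, s0:s1] += amp[:, None]

    rec = Recording(traces=traces, fs=fs, channel_meta=meta,
                    session_id=f"synthetic-{seed}")
    return rec, trials, gt


# ---------------------------------------------------------------------------
# gaze


@dataclass
class GazeConfig:
    """Parameters of the synthetic gaze stream (degrees of visual angle)."""

    screen_extent_deg: tuple = (40.0, 30.0)
    rect_size_deg: tuple = (6.0, 6.0)
    fs: float = 120.0
    n_dwells_in: int = 2
    n_dwells_out: int = 3
    dwell_mean_s: float = 0.3
    dwell_min_s: float = 0.12
    saccade_s: float = 0.03
    jitter_deg: float = 0.15


def generate_gaze(trials: pd.DataFrame, config: Optional[GazeConfig] = None,
                  seed: int = 0, ground_truth: Optional[GroundTruth] = None):
    """Piecewise-stationary gaze during recognition trials.

    Each recognition trial gets a critical-region rectangle and a shuffled
    sequence of in-region and out-of-region dwells separated by fast
    saccades.  Returns ``(GazeStream, dwell_table)``; the dwell table (one
    row per dwell with trial, centroid, duration and in-region flag) is also
    attached to ``ground_truth`` when given.
    """
    cfg = config or GazeConfig()
    rng = np.random.default_rng(seed)
    W, H = cfg.screen_extent_deg
    rw, rh = cfg.rect_size_deg
    if rw > W or rh > H:
        raise ValueError("critical-region rectangle exceeds the screen extent")
    rec_trials = trials[trials["phase"] == "recognition"]
    t_end = trials["image_offset_s"].max() + 0.5
    tgrid = np.arange(0.0, t_end, 1.0 / cfg.fs)
    x = np.full_like(tgrid, W / 2.0)
    y = np.full_like(tgrid, H / 2.0)

    rect_rows, dwell_rows = [], []
    for row in rec_trials.itertuples():
        x0 = rng.uniform(0, W - rw)
        y0 = rng.uniform(0, H - rh)
        rect = (x0, y0, x0 + rw, y0 + rh)
        rect_rows.append(dict(image_id=row.image_id, x0=rect[0], y0=rect[1],
                              x1=rect[2], y1=rect[3]))
        dwells = []
        for _ in range(cfg.n_dwells_in):
            cx = rng.uniform(rect[0] + 0.5, rect[2] - 0.5)
            cy = rng.uniform(rect[1] + 0.5, rect[3] - 0.5)
            dwells.append((cx, cy, True))
        for _ in range(cfg.n_dwells_out):
            while True:
                cx, cy = rng.uniform(0.5, W - 0.5), rng.uniform(0.5, H - 0.5)
                if not (rect[0] - 1 < cx < rect[2] + 1 and rect[1] - 1 < cy < rect[3] + 1):
                    break
            dwells.append((cx, cy, False))
        rng.shuffle(dwells)
        t = row.image_onset_s + 0.05
        t_stop = row.image_offset_s - 0.05
        for cx, cy, inside in dwells:
            dur = max(cfg.dwell_min_s, rng.normal(cfg.dwell_mean_s, 0.05))
            if t + dur > t_stop:
                break
            sel = (tgrid >= t) & (tgrid < t + dur)
            n = int(sel.sum())
            x[sel] = cx + rng.normal(0, cfg.jitter_deg, n)
            y[sel] = cy + rng.normal(0, cfg.jitter_deg, n)
            dwell_rows.append(dict(trial_id=row.trial_id, image_id=row.image_id,
                                   t_on_s=t, duration_s=dur, x_deg=cx, y_deg=cy,
                                   in_region=inside))
            t += dur + cfg.saccade_s

    samples = pd.DataFrame({"t_s": tgrid, "x_deg": x, "y_deg": y})
    regions = pd.DataFrame(rect_rows)
    dwell_table = pd.DataFrame(dwell_rows)
    if ground_truth is not None:
        ground_truth.gaze_dwells = dwell_table
    return GazeStream(samples=samples, regions=regions, fs=cfg.fs), dwell_table
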