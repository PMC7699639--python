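"""Morlet time-frequency decomposition, normalization and binning.

Power is computed with complex Morlet wavelets (wavelet number 6) at 32
log-spaced frequencies spanning 2-431 Hz, squared and log-transformed, then
z-scored per channel and frequency over the whole session.  Downstream
statistics operate on 200 ms bins stepped every 100 ms (50 % overlap);
"80-120 Hz band power" is the mean z-score over wavelet centers inside that
interval.  A bootstrap subsampling procedure equates trial counts between
conditions before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet

from .datatypes import Recording

__all__ = [
    "TFR", "BinnedPower", "default_freqs", "band_centers", "morlet_tfr",
    "zscore_session", "bin_power", "band_power", "bootstrap_match",
    "select_trials",
]

WAVELET_NUMBER = 6
LOG_FLOOR = 1e-40
HG_BAND = (80.0, 120.0)


def default_freqs(n: int = 32, fmin: float = 2.0, fmax: float = 431.0) -> np.ndarray:
    """Log-spaced wavelet center frequencies, endpoints inclusive."""
    k = np.arange(n)
    return fmin * (fmax / fmin) ** (k / (n - 1))


def band_centers(band: tuple = HG_BAND, freqs: Optional[np.ndarray] = None) -> np.ndarray:
    """The default wavelet centers that fall inside ``band`` (inclusive)."""
    f = default_freqs() if freqs is None else np.asarray(freqs)
    return f[(f >= band[0]) & (f <= band[1])]


@dataclass
class TFR:
    """Trials x channels x frequencies x samples log-power (and phase)."""

    power: np.ndarray                    # log-power; z-units after zscore_session
    freqs: np.ndarray
    times: np.ndarray                    # relative to the alignment event (s)
    fs: float
    trial_index: np.ndarray              # row indices into the trial table
    valid: np.ndarray                    # (trials, samples) bool
    phase: Optional[np.ndarray] = None
    zscored: bool = False
    log: list = field(default_factory=list)


@dataclass
class BinnedPower:
    """Trials x channels x frequencies(or bands) x bins mean power."""

    values: np.ndarray
    bin_centers: np.ndarray
    freqs: np.ndarray                    # centers, or band edges' midpoints
    trial_index: np.ndarray
    width: float
    step: float


def select_trials(trials: pd.DataFrame, phase: Optional[str] = None,
                  max_rt_s: float = 10.0) -> pd.DataFrame:
    """Drop recognition trials with response time > ``max_rt_s`` (no-response
    safeguard) and optionally restrict to one phase."""
    out = trials
    if phase is not None:
        out = out[out["phase"] == phase]
    rt = out.get("response_time_s")
    if rt is not None:
        out = out[(out["phase"] != "recognition") | rt.isna() | (rt <= max_rt_s)]
    return out


def morlet_tfr(rec: Recording, trials: pd.DataFrame,
               freqs: Optional[Sequence[float]] = None,
               wavelet_number: float = WAVELET_NUMBER,
               window: tuple = (0.0, 2.0), buffer_s: float = 1.0,
               keep_phase: bool = False,
               artifact_mask: Optional[np.ndarray] = None) -> TFR:
    """Morlet wavelet transform of event-locked epochs.

    Epochs cover ``window`` seconds around each trial's image onset plus a
    ``buffer_s`` margin on both sides that absorbs convolution edge effects
    and is trimmed afterwards.  Power is the natural log of the squared
    magnitude (with a small positive floor); phase is the argument.  Trials
    whose padded epoch falls outside the recording are skipped and logged.
    Samples after a recognition trial's response (or after image offset at
    encoding) are flagged invalid in ``TFR.valid``.  ``artifact_mask`` is an
    optional (channels x samples) session mask; masked samples become NaN.
    """
    freqs = np.asarray(default_freqs() if freqs is None else freqs, dtype=float)
    fs = rec.fs
    n_buf = int(round(buffer_s * fs))
    s_win = (int(round(window[0] * fs)), int(round(window[1] * fs)))
    n_time = s_win[1] - s_win[0]
    epochs, kept, valid_rows, log = [], [], [], []
    mask_rows = []
    for row in trials.itertuples():
        onset = int(round(row.image_onset_s * fs))
        a, b = onset + s_win[0] - n_buf, onset + s_win[1] + n_buf
        if a < 0 or b > rec.n_samples:
            log.append(f"trial {row.trial_id}: epoch [{a}, {b}) outside recording; skipped")
            continue
        epochs.append(rec.traces[:, a:b])
        kept.append(row.Index)
        end_s = row.image_offset_s - row.image_onset_s
        t_rel = (np.arange(s_win[0], s_win[1])) / fs
        valid_rows.append(t_rel < end_s + 1e-9)
        if artifact_mask is not None:
            mask_rows.append(artifact_mask[:, onset + s_win[0]:onset + s_win[1]])
    if not epochs:
        raise ValueError("no trial epoch lies inside the recording")
    data = np.stack(epochs)                      # (n_ep, n_ch, n_t + 2*buf)
    out = tfr_array_morlet(data, sfreq=fs, freqs=freqs, n_cycles=wavelet_number,
                           zero_mean=True, use_fft=True, output="complex")
    out = out[..., n_buf:n_buf + n_time]
    power = np.log(np.abs(out) ** 2 + LOG_FLOOR)
    phase = np.angle(out) if keep_phase else None
    if artifact_mask is not None:
        m = np.stack(mask_rows)                  # (n_ep, n_ch, n_time)
        power[np.broadcast_to(m[:, :, None, :], power.shape)] = np.nan
    times = np.arange(s_win[0], s_win[1]) / fs
    return TFR(power=power, freqs=freqs, times=times, fs=fs,
               trial_index=np.asarray(kept), valid=np.asarray(valid_rows),
               phase=phase, log=log)


def zscore_session(tfr: TFR, per_channel: bool = True) -> TFR:
    """Z-score power per frequency (and channel) over all retained samples.

    Pools every valid, unmasked sample of the session (all trials, all time
    points).  ``per_channel=False`` pools across channels as well, matching
    a per-frequency-only normalization.  Zero variance raises, naming the
    offending channel/frequency.
    """
    p = tfr.power.copy()
    invalid = ~tfr.valid[:, None, None, :]
    p_stat = np.where(np.broadcast_to(invalid, p.shape), np.nan, p)
    axes = (0, 3) if per_channel else (0, 1, 3)
    mu = np.nanmean(p_stat, axis=axes, keepdims=True)
    sd = np.nanstd(p_stat, axis=axes, keepdims=True)
    if np.any(sd == 0):
        bad = np.argwhere(np.squeeze(sd == 0))
        raise ValueError(f"zero power variance at (channel, frequency) {bad[:3].tolist()}")
    z = (p - mu) / sd
    return TFR(power=z, freqs=tfr.freqs, times=tfr.times, fs=tfr.fs,
               trial_index=tfr.trial_index, valid=tfr.valid, phase=tfr.phase,
               zscored=True, log=list(tfr.log))


def bin_power(tfr: TFR, width: float = 0.2, step: float = 0.1) -> BinnedPower:
    """Average z-scored power into left-aligned half-open bins.

    Bin ``b`` covers ``[t0 + b*step, t0 + b*step + width)`` relative to the
    alignment event; the last partial bin is dropped.  Invalid samples are
    excluded (NaN-aware); all-invalid bins are NaN.  ``width`` and ``step``
    must be integer multiples of the sample period.
    """
    dt = 1.0 / tfr.fs
    w = width / dt
    s = step / dt
    if abs(w - round(w)) > 1e-6 or abs(s - round(s)) > 1e-6:
        raise ValueError("width and step must be multiples of the sample period")
    w, s = int(round(w)), int(round(s))
    n_samp = tfr.power.shape[-1]
    starts = np.arange(0, n_samp - w + 1, s)
    p = tfr.power.copy()
    p[np.broadcast_to(~tfr.valid[:, None, None, :], p.shape)] = np.nan
    vals = np.empty(tfr.power.shape[:-1] + (len(starts),))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN bins
        for b, s0 in enumerate(starts):
            vals[..., b] = np.nanmean(p[..., s0:s0 + w], axis=-1)
    centers = tfr.times[0] + starts * dt + width / 2.0
    return BinnedPower(values=vals, bin_centers=centers, freqs=tfr.freqs,
                       trial_index=tfr.trial_index, width=width, step=step)


def band_power(binned: BinnedPower, band: tuple = HG_BAND) -> BinnedPower:
    """Collapse the frequency axis to the mean z-score over centers in ``band``."""
    sel = (binned.freqs >= band[0]) & (binned.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"no wavelet centers inside band {band}")
    vals = np.nanmean(binned.values[:, :, sel, :], axis=2, keepdims=True)
    return BinnedPower(values=vals, bin_centers=binned.bin_centers,
                       freqs=np.array([np.mean(band)]),
                       trial_index=binned.trial_index,
                       width=binned.width, step=binned.step)


def bootstrap_match(values_a: np.ndarray, values_b: np.ndarray,
                    n_iter: int = 100, seed: int | np.random.Generator = 0):
    """Trial-count-matched condition means.

    ``values_a``/``values_b`` are per-trial arrays (trials first axis).  The
    larger condition's mean is the average over ``n_iter`` subsample means
    drawn at the smaller condition's trial count; the smaller condition's
    mean is its plain average.  Returns ``(mean_a, mean_b)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both conditions must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    na, nb = len(values_a), len(values_b)

    def _mean(v):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(v, axis=0)

    if na == nb:
        return _mean(values_a), _mean(values_b)
    big, small, n_small = ((values_a, values_b, nb) if na > nb
                           else (values_b, values_a, na))
    acc = np.zeros(np.asarray(big).shape[1:])
    for _ in range(n_iter):
        idx = rng.choice(len(big), size=n_small, replace=False)
        acc += _mean(np.asarray(big)[idx])
    matched = acc / n_iter
    if na > nb:
        return matched, _mean(small)
    return _mean(small), matched
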