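"""Inter-region coupling: cross-correlograms, coherence, phase locking.

The lag between two regions' high-gamma envelopes is estimated from
trial-averaged cross-correlograms of 10 ms-binned band power over the first
second after image onset; a chance correlogram built from mismatched trial
pairings captures the purely stimulus-locked component.  A positive peak
lag means the first channel's power leads the second's.

Spectral dependence is quantified by Welch magnitude-squared coherence on
common-average-referenced contacts and, independent of amplitude, by the
phase-locking value (PLV): the modulus of the mean unit phasor of
Hilbert-derived phase differences across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "CrossCorrelogram", "crosscorrelogram", "chance_crosscorrelogram",
    "peak_lag", "peak_lag_stats", "msc_coherence", "band_phase", "plv",
    "common_average_reference",
]

CCG_BIN_S = 0.010
PEAK_SEARCH_S = 0.2
TEST_WINDOW_S = 0.05


@dataclass
class CrossCorrelogram:
    """Lagged correlation of two binned power series, trial averaged."""

    lags_ms: np.ndarray
    values: np.ndarray
    kind: str = "true"            # "true" | "chance"
    n_trials: int = 0
    log: list = field(default_factory=list)


def _rebin(x: np.ndarray, factor: int) -> np.ndarray:
    """Average consecutive groups of ``factor`` samples (last partial dropped)."""
    n = (x.shape[-1] // factor) * factor
    return x[..., :n].reshape(*x.shape[:-1], -1, factor).mean(axis=-1)


def _lagged_corr(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson correlation per lag for one trial pair of binned series.

    Positive lag k correlates ``a[:-k]`` with ``b[k:]``: if ``a`` leads
    ``b`` by delay d then the correlation peaks at ``k = d``.  Lags with
    fewer than 2 overlapping bins are NaN.
    """
    n = len(a)
    out = np.full(2 * max_lag + 1, np.nan)
    for i, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            x, y = a[:n - k] if k else a, b[k:]
        else:
            x, y = a[-k:], b[:n + k]
        if len(x) < 2:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        out[i] = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return out


def crosscorrelogram(power_a: np.ndarray, power_b: np.ndarray, fs: float,
                     bin_s: float = CCG_BIN_S, max_lag_s: float = 0.25,
                     normalized: bool = True) -> CrossCorrelogram:
    """True cross-correlogram of two per-trial band-power series.

    ``power_a``/``power_b`` are (n_trials, n_samples) arrays (same trials,
    e.g. the first second after image onset).  Series are averaged into
    non-overlapping ``bin_s`` bins, correlated per trial at every lag
    (Pearson-normalized by default; set ``normalized=False`` for raw
    covariance) and averaged over trials.
    """
    a = np.asarray(power_a, dtype=float)
    b = np.asarray(power_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("power series shapes differ")
    factor = int(round(bin_s * fs))
    ab, bb = _rebin(a, factor), _rebin(b, factor)
    max_lag = int(round(max_lag_s / bin_s))
    vals = np.full((ab.shape[0], 2 * max_lag + 1), np.nan)
    for t in range(ab.shape[0]):
        x, y = ab[t], bb[t]
        if not normalized:
            x = x - x.mean()
            y = y - y.mean()
            n = len(x)
            for i, k in enumerate(range(-max_lag, max_lag + 1)):
                xx, yy = (x[:n - k] if k else x, y[k:]) if k >= 0 else (x[-k:], y[:n + k])
                if len(xx) >= 2:
                    vals[t, i] = (xx * yy).mean()
        else:
            vals[t] = _lagged_corr(x, y, max_lag)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean_vals = np.nanmean(vals, axis=0)
    lags_ms = np.arange(-max_lag, max_lag + 1) * bin_s * 1000.0
    return CrossCorrelogram(lags_ms=lags_ms, values=mean_vals, kind="true",
                            n_trials=ab.shape[0])


def chance_crosscorrelogram(power_a: np.ndarray, power_b: np.ndarray, fs: float,
                            n_perm: int = 100, seed: int | np.random.Generator = 0,
                            bin_s: float = CCG_BIN_S, max_lag_s: float = 0.25,
                            normalized: bool = True) -> CrossCorrelogram:
    """Chance correlogram from mismatched trial pairings.

    Each of ``n_perm`` permutations correlates channel A on one randomly
    chosen trial with channel B on a *different* randomly chosen trial; the
    average over permutations captures the stimulus-locked component that
    survives trial mismatching.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(power_a, dtype=float)
    b = np.asarray(power_b, dtype=float)
    n_trials = a.shape[0]
    if n_trials < 2:
        raise ValueError("chance correlogram needs >= 2 trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factor = int(round(bin_s * fs))
    ab, bb = _rebin(a, factor), _rebin(b, factor)
    max_lag = int(round(max_lag_s / bin_s))
    acc = np.zeros(2 * max_lag + 1)
    cnt = np.zeros(2 * max_lag + 1)
    for _ in range(n_perm):
        i = rng.integers(n_trials)
        j = rng.integers(n_trials)
        while j == i:
            j = rng.integers(n_trials)
        v = _lagged_corr(ab[i], bb[j], max_lag) if normalized else None
        if v is None:
            x = ab[i] - ab[i].mean()
            y = bb[j] - bb[j].mean()
            v = np.full(2 * max_lag + 1, np.nan)
            n = len(x)
            for ii, k in enumerate(range(-max_lag, max_lag + 1)):
                xx, yy = (x[:n - k] if k else x, y[k:]) if k >= 0 else (x[-k:], y[:n + k])
                if len(xx) >= 2:
                    v[ii] = (xx * yy).mean()
        good = ~np.isnan(v)
        acc[good] += v[good]
        cnt += good
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = acc / cnt
    lags_ms = np.arange(-max_lag, max_lag + 1) * bin_s * 1000.0
    return CrossCorrelogram(lags_ms=lags_ms, values=vals, kind="chance",
                            n_trials=n_trials)


def peak_lag(ccg: CrossCorrelogram, search_ms: float = PEAK_SEARCH_S * 1000.0):
    """Lag (ms) of the correlogram maximum within ±``search_ms``.

    Ties are broken toward the lag nearest zero (logged).
    """
    sel = np.abs(ccg.lags_ms) <= search_ms + 1e-9
    lags = ccg.lags_ms[sel]
    vals = ccg.values[sel]
    finite = np.isfinite(vals)
    vals = np.where(finite, vals, -np.inf)
    best = vals.max()
    cand = np.flatnonzero(vals == best)
    if len(cand) > 1:
        ccg.log.append(f"{len(cand)}-way peak tie; choosing lag nearest 0")
    pick = cand[np.argmin(np.abs(lags[cand]))]
    return float(lags[pick])


def peak_lag_stats(true_ccgs: Sequence[CrossCorrelogram],
                   chance_ccgs: Sequence[CrossCorrelogram],
                   participant_ids: Sequence,
                   test_window_ms: float = TEST_WINDOW_S * 1000.0,
                   search_ms: float = PEAK_SEARCH_S * 1000.0):
    """Region-pair latency summary across electrode pairs and participants.

    Per electrode pair: peak lag of the true correlogram and a paired t test
    of true vs chance values within ±``test_window_ms``.  Per participant:
    mean peak lag over pairs.  Across participants: two-sided one-sample t
    of mean peak lags against zero.  Returns ``(pair_table, summary)``.
    """
    rows = []
    for ccg_t, ccg_c, pid in zip(true_ccgs, chance_ccgs, participant_ids):
        lag = peak_lag(ccg_t, search_ms=search_ms)
        sel = np.abs(ccg_t.lags_ms) <= test_window_ms + 1e-9
        tvals, cvals = ccg_t.values[sel], ccg_c.values[sel]
        good = np.isfinite(tvals) & np.isfinite(cvals)
        if good.sum() >= 2:
            tt, tp = stats.ttest_rel(tvals[good], cvals[good])
        else:
            tt, tp = np.nan, np.nan
        rows.append(dict(participant=pid, peak_lag_ms=lag,
                         pair_t=float(tt), pair_p=float(tp)))
    pairs = pd.DataFrame(rows)
    per_part = pairs.groupby("participant")["peak_lag_ms"].mean()
    if len(per_part) >= 2:
        t_stat, p_val = stats.ttest_1samp(per_part.to_numpy(), 0.0)
    else:
        t_stat, p_val = np.nan, np.nan
    summary = dict(mean_peak_lag_ms=float(per_part.mean()),
                   sem_peak_lag_ms=float(per_part.sem()) if len(per_part) > 1 else np.nan,
                   n_participants=int(len(per_part)),
                   t=float(t_stat), p=float(p_val))
    return pairs, summary


# ---------------------------------------------------------------------------
# coherence


def common_average_reference(traces: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every sample."""
    return traces - traces.mean(axis=0, keepdims=True)


def msc_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                  nperseg: int = 500, noverlap: Optional[int] = None,
                  window: str = "hann"):
    """Welch magnitude-squared coherence C(f) = |Pxy|^2 / (Pxx Pyy).

    ``x``/``y`` may be 1-D (one epoch) or (n_epochs, n_samples); epochs are
    averaged in the cross-/auto-spectra.  Requires at least 2 segments in
    total.  Returns ``(freqs, C)`` with C in [0, 1].
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y shapes differ")
    if noverlap is None:
        noverlap = nperseg // 2
    step = nperseg - noverlap
    n_seg_total = x.shape[0] * max(0, 1 + (x.shape[1] - nperseg) // step)
    if n_seg_total < 2:
        raise ValueError("epoch too short: fewer than 2 Welch segments")
    f, pxx = signal.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    _, pyy = signal.welch(y, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    _, pxy = signal.csd(x, y, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    pxx, pyy, pxy = pxx.mean(axis=0), pyy.mean(axis=0), pxy.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(pxy) ** 2 / (pxx * pyy)
    return f, np.clip(C, 0.0, 1.0)


def alpha_band_mean(freqs: np.ndarray, C: np.ndarray,
                    band: tuple = (8.0, 12.0)) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.nanmean(C[..., sel]))


def zscore_session_values(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardize coherence (or PLV) values by the session mean and SD.

    ``axis`` indexes the pooled dimension (epochs for coherence spectra,
    time points for PLV series).  Zero-variance entries raise.
    """
    v = np.asarray(values, dtype=float)
    mu = np.nanmean(v, axis=axis, keepdims=True)
    sd = np.nanstd(v, axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero variance; cannot z-score")
    return (v - mu) / sd


# ---------------------------------------------------------------------------
# phase locking


def band_phase(trace: np.ndarray, fs: float, band: tuple = (8.0, 12.0)) -> np.ndarray:
    """Instantaneous phase of the band-passed analytic signal.

    4th-order Butterworth band-pass (zero-phase), then the Hilbert
    transform's argument.  Works along the last axis.
    """
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(trace, dtype=float), axis=-1)
    return np.angle(signal.hilbert(filt, axis=-1))


def plv(phase_p: np.ndarray, phase_q: np.ndarray) -> np.ndarray:
    """Phase-locking value across trials at every time point.

    ``phase_p``/``phase_q`` are (n_trials, n_times) phase arrays of the two
    channels; the PLV at time t is ``|mean_n exp(i (phi_p - phi_q))|``,
    in [0, 1], 1 meaning a perfectly consistent phase lag.  Requires >= 2
    trials.
    """
    p = np.asarray(phase_p)
    q = np.asarray(phase_q)
    if p.shape != q.shape:
        raise ValueError("phase array shapes differ")
    if p.shape[0] < 2:
        raise ValueError("PLV requires >= 2 trials")
    return np.abs(np.exp(1j * (p - q)).mean(axis=0))


def plv_baseline_contrast(plv_task: np.ndarray, plv_baseline: np.ndarray):
    """One-tailed paired t test (task > baseline) across electrode pairs.

    ``plv_task``/``plv_baseline`` are per-pair mean PLV values.  Returns
    ``(t, p_one_tailed)``.
    """
    t, p = stats.ttest_rel(plv_task, plv_baseline)
    p_one = p / 2.0 if t > 0 else 1.0 - p / 2.0
    return float(t), float(p_one)
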