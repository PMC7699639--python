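"""Temporal characterization of band-power time series.

Region-wise timing is assessed four ways: a region-label shuffle test on
the peak time of the across-participant mean series; the mean instantaneous
slope (adjacent-bin differences) over the first 500 ms; an onset estimate
from a line fit between the local minimum preceding the peak and the peak,
taking the line's zero crossing; and the per-electrode time of the first
significant condition difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cluster import ClusterResult

__all__ = [
    "OnsetEstimate", "peak_time_shuffle_test", "instantaneous_slope",
    "estimate_onset", "first_significant_time",
]


@dataclass
class OnsetEstimate:
    """Onset and latency summary for one difference time series."""

    onset_s: Optional[float]
    half_peak_s: Optional[float]
    peak_s: float
    local_min_s: float
    slope: float                 # fitted line, z-units per second
    intercept: float
    clamped: bool = False        # pre-stimulus crossing reported as 0
    log: list = field(default_factory=list)


def _peak_time(series: np.ndarray, centers: np.ndarray, log: Optional[list] = None):
    """Earliest global maximum (ties logged)."""
    m = np.nanmax(series)
    cand = np.flatnonzero(series == m)
    if len(cand) > 1 and log is not None:
        log.append(f"{len(cand)}-way peak tie; earliest taken")
    return centers[cand[0]], cand[0]


def peak_time_shuffle_test(series_a: np.ndarray, series_b: np.ndarray,
                           bin_centers: np.ndarray, n_perm: int = 1000,
                           seed: int | np.random.Generator = 0,
                           enumerate_max_n: int = 12):
    """Region-label shuffle test for the peak-time difference.

    ``series_a``/``series_b`` are (n_participants, n_bins) band-power time
    series for two regions in the same participants.  The true statistic is
    the difference of the peak times of the across-participant means.  The
    null swaps the two region labels independently within each participant;
    all 2^n swap patterns are enumerated for n <= ``enumerate_max_n``,
    otherwise ``n_perm`` random draws are used.  Returns
    ``(true_diff_s, p_two_sided, null_diffs)``.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("series must share shape with >= 2 participants")
    n = a.shape[0]
    log: list = []
    ta, _ = _peak_time(a.mean(axis=0), bin_centers, log)
    tb, _ = _peak_time(b.mean(axis=0), bin_centers, log)
    true = ta - tb
    if n <= enumerate_max_n:
        patterns = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :] & 1).astype(bool)
        exact = True
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        patterns = rng.random((n_perm, n)) < 0.5
        exact = False
    null = np.empty(len(patterns))
    for i, swap in enumerate(patterns):
        ma = np.where(swap[:, None], b, a).mean(axis=0)
        mb = np.where(swap[:, None], a, b).mean(axis=0)
        null[i] = _peak_time(ma, bin_centers)[0] - _peak_time(mb, bin_centers)[0]
    if exact:
        p = float((np.abs(null) >= abs(true) - 1e-12).mean())
    else:
        p = float((1 + (np.abs(null) >= abs(true) - 1e-12).sum()) / (1 + len(null)))
    return float(true), p, null


def instantaneous_slope(series: np.ndarray, bin_centers: np.ndarray,
                        window: tuple = (0.0, 0.5)) -> float:
    """Mean adjacent-bin difference inside ``window`` (z-units per bin step).

    For a linear ramp this telescopes to the exact per-bin slope.  Both
    bins of each difference must lie inside the window.
    """
    series = np.asarray(series, dtype=float)
    sel = (bin_centers >= window[0] - 1e-9) & (bin_centers <= window[1] + 1e-9)
    if sel.sum() < 2:
        raise ValueError("window contains fewer than 2 bins")
    return float(np.nanmean(np.diff(series[sel])))


def region_slope_contrast(slopes_a: Sequence[float], slopes_b: Sequence[float]):
    """Unpaired t test of per-participant mean slopes between two regions."""
    t, p = stats.ttest_ind(np.asarray(slopes_a), np.asarray(slopes_b))
    return float(t), float(p)


def estimate_onset(diff_series: np.ndarray, bin_centers: np.ndarray,
                   search_window: tuple = (0.0, 2.0)) -> OnsetEstimate:
    """Onset of a condition-difference rise via local-minimum-to-peak line fit.

    The peak is the global maximum inside ``search_window``; the local
    minimum is the nearest preceding strict local minimum (plateaus resolve
    to their latest bin; absent one, the window start is used and logged).
    A least-squares line through all bins between the two is extrapolated
    to zero: its crossing is the onset (clamped at 0, flagged, when the
    crossing is pre-stimulus; undefined when the fitted slope is <= 0).
    The half-peak time is the first time the series reaches half the peak
    value (linear interpolation between bins), clamped at the local
    minimum.
    """
    s = np.asarray(diff_series, dtype=float)
    c = np.asarray(bin_centers, dtype=float)
    log: list = []
    win = np.flatnonzero((c >= search_window[0] - 1e-9) & (c <= search_window[1] + 1e-9))
    if len(win) < 2:
        raise ValueError("search window contains fewer than 2 bins")
    seg = s[win]
    peak_rel = int(np.nanargmax(seg))
    peak_idx = win[peak_rel]
    peak_val = s[peak_idx]
    if not peak_val > 0:
        log.append("no positive peak in window")
    # nearest preceding strict local minimum; plateau -> latest plateau bin
    min_idx = win[0]
    found = False
    i = peak_idx - 1
    while i > win[0]:
        if s[i] < s[i + 1] and s[i] <= s[i - 1]:
            min_idx = i
            found = True
            break
        i -= 1
    if not found:
        log.append("no preceding local minimum; window start used")
    xs = c[min_idx:peak_idx + 1]
    ys = s[min_idx:peak_idx + 1]
    good = ~np.isnan(ys)
    onset = None
    clamped = False
    if good.sum() >= 2:
        slope, intercept = np.polyfit(xs[good], ys[good], 1)
        if slope > 0:
            onset = -intercept / slope
            # the crossing must lie between the local minimum and the peak;
            # degenerate fits extrapolating past the local minimum are clamped
            if onset < c[min_idx] and found:
                onset = float(c[min_idx])
                clamped = True
                log.append("zero crossing before local minimum; clamped")
            if onset < 0:
                onset = 0.0
                clamped = True
        else:
            log.append("fitted slope <= 0; onset undefined")
    else:
        slope = intercept = np.nan
        log.append("insufficient bins for line fit")
    # half-peak with linear interpolation, clamped at the local minimum time
    half = 0.5 * peak_val
    half_t = None
    for j in range(min_idx, peak_idx + 1):
        if s[j] >= half:
            if j == min_idx or np.isnan(s[j - 1]):
                half_t = c[j]
            else:
                frac = (half - s[j - 1]) / (s[j] - s[j - 1])
                half_t = c[j - 1] + frac * (c[j] - c[j - 1])
            break
    if half_t is not None:
        half_t = max(half_t, float(c[min_idx]))
    return OnsetEstimate(onset_s=onset, half_peak_s=half_t,
                         peak_s=float(c[peak_idx]), local_min_s=float(c[min_idx]),
                         slope=float(slope), intercept=float(intercept),
                         clamped=clamped, log=log)


def first_significant_time(results: Sequence[ClusterResult],
                           bin_centers: np.ndarray, alpha: float = 0.05):
    """Earliest significant-cluster bin per electrode.

    ``results`` holds one trial-level cluster result per electrode.
    Electrodes without a significant cluster are excluded (logged in the
    returned log list).  Returns ``(times_s, log)``.
    """
    times, log = [], []
    for k, res in enumerate(results):
        sig = res.significant(alpha)
        if not sig:
            log.append(f"electrode {k}: no significant cluster; excluded")
            continue
        first_bin = min(int(np.atleast_1d(c.bins).min()) for c in sig)
        times.append(float(bin_centers[first_bin]))
    return np.asarray(times), log
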