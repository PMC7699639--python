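"""Gaze fixations, critical-region scoring and working-memory capacity.

Fixations are detected with a dispersion-threshold (I-DT) rule: a group of
consecutive gaze samples is a fixation when it spans >= 100 ms while the
spread stays within 2 degrees of visual angle.  Viewing behaviour toward
each image's critical region (the manipulated item's rectangle) is
summarized per condition.  Working-memory capacity uses Cowan's K:
``K = (HitRate + CorrectRejectionRate - 1) * N`` for memory set size N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import GazeStream

__all__ = [
    "Fixation", "detect_fixations", "critical_region_metrics", "cowans_k",
    "behavior_summary",
]

DISPERSION_DEG = 2.0
MIN_FIX_DUR_S = 0.1


@dataclass
class Fixation:
    onset_s: float
    offset_s: float
    x_deg: float
    y_deg: float
    dispersion_deg: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _max_pairwise(xs: np.ndarray, ys: np.ndarray) -> float:
    dx = xs[:, None] - xs[None, :]
    dy = ys[:, None] - ys[None, :]
    return float(np.sqrt(dx * dx + dy * dy).max())


def detect_fixations(gaze: GazeStream, dispersion_deg: float = DISPERSION_DEG,
                     min_dur_s: float = MIN_FIX_DUR_S,
                     metric: str = "pairwise") -> list:
    """Dispersion-threshold (I-DT) fixation detection.

    Grows a sample window while its spread stays within ``dispersion_deg``
    — maximum pairwise distance by default, or the bounding-box diagonal
    with ``metric='bbox'`` — and emits a fixation when the window lasts at
    least ``min_dur_s``.  Time gaps longer than two sample periods split
    windows.  The centroid is the mean of the member samples.
    """
    if metric not in ("pairwise", "bbox"):
        raise ValueError("metric must be 'pairwise' or 'bbox'")
    t = gaze.samples["t_s"].to_numpy()
    x = gaze.samples["x_deg"].to_numpy()
    y = gaze.samples["y_deg"].to_numpy()
    dt_nominal = 1.0 / gaze.fs
    fixations = []
    i = 0
    n = len(t)
    while i < n:
        # grow the window incrementally: the max pairwise distance only needs
        # each new point checked against the members so far
        j = i + 1
        disp = 0.0
        while j < n:
            if t[j] - t[j - 1] > 2.0 * dt_nominal + 1e-9:
                break
            if metric == "pairwise":
                d_new = float(np.hypot(x[i:j] - x[j], y[i:j] - y[j]).max())
                cand = max(disp, d_new)
            else:
                xs, ys = x[i:j + 1], y[i:j + 1]
                cand = float(np.hypot(xs.max() - xs.min(), ys.max() - ys.min()))
            if cand > dispersion_deg:
                break
            disp = cand
            j += 1
        # window [i, j) satisfied the dispersion bound
        if t[j - 1] - t[i] + dt_nominal >= min_dur_s and j - i >= 2:
            xs, ys = x[i:j], y[i:j]
            fixations.append(Fixation(onset_s=float(t[i]), offset_s=float(t[j - 1]),
                                      x_deg=float(xs.mean()), y_deg=float(ys.mean()),
                                      dispersion_deg=disp))
            i = j
        else:
            i += 1
    return fixations


def _in_rect(x: float, y: float, rect) -> bool:
    return rect[0] <= x <= rect[2] and rect[1] <= y <= rect[3]


def critical_region_metrics(fixations: list, rect, click_xy=None) -> dict:
    """Critical-region viewing metrics for one trial.

    Returns the probability-relevant indicators: whether any fixation fell
    inside the rectangle, the fraction of summed fixation time spent inside
    (0.0, not missing, when there are no fixations), and whether the mouse
    click (if any) landed inside.
    """
    total = sum(f.duration_s for f in fixations)
    inside = [f for f in fixations if _in_rect(f.x_deg, f.y_deg, rect)]
    t_in = sum(f.duration_s for f in inside)
    out = dict(any_fixation_in_region=bool(inside),
               time_fraction_in_region=(t_in / total) if total > 0 else 0.0,
               n_fixations=len(fixations))
    if click_xy is not None:
        out["click_in_region"] = _in_rect(click_xy[0], click_xy[1], rect)
    return out


def cowans_k(hit_rate: float, correct_rejection_rate: float, set_size: float) -> float:
    """Cowan's K working-memory capacity: (HR + CR - 1) * N.

    Rates must lie in [0, 1]; ``set_size`` must be positive.  Negative K
    (below-chance performance) is returned as-is.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= correct_rejection_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    return (hit_rate + correct_rejection_rate - 1.0) * set_size


def behavior_summary(trials: pd.DataFrame, gaze: Optional[GazeStream] = None,
                     fixations: Optional[list] = None,
                     set_sizes=(8, 20), hit_rate_mode: str = "mean",
                     max_rt_s: float = 10.0) -> dict:
    """Per-condition recognition/RT summary plus Cowan's K estimates.

    The hit rate is the recognition accuracy for manipulated images —
    ``hit_rate_mode='mean'`` (default) averages the added and removed
    condition rates, ``'pooled'`` pools their trials — and the correct
    rejection rate is the accuracy for repeated images.  Trials with
    response times above ``max_rt_s`` are excluded.
    """
    rec = trials[trials["phase"] == "recognition"].copy()
    rt = rec.get("response_time_s")
    if rt is not None:
        rec = rec[rt.isna() | (rt <= max_rt_s)]
    per_cond = {}
    for cond, grp in rec.groupby("condition"):
        entry = dict(n=len(grp), p_correct=float(grp["correct"].mean()))
        if "response_time_s" in grp:
            entry["rt_correct_s"] = float(grp.loc[grp["correct"], "response_time_s"].mean())
            if (~grp["correct"]).any():
                entry["rt_incorrect_s"] = float(
                    grp.loc[~grp["correct"], "response_time_s"].mean())
        per_cond[cond] = entry
    if hit_rate_mode == "mean":
        hr = float(np.mean([per_cond[c]["p_correct"] for c in ("added", "removed")
                            if c in per_cond]))
    elif hit_rate_mode == "pooled":
        manip = rec[rec["condition"].isin(["added", "removed"])]
        hr = float(manip["correct"].mean())
    else:
        raise ValueError("hit_rate_mode must be 'mean' or 'pooled'")
    cr = per_cond.get("repeated", {}).get("p_correct", np.nan)
    ks = {int(n): cowans_k(hr, cr, n) for n in set_sizes}
    return dict(conditions=per_cond, hit_rate=hr, correct_rejection_rate=cr,
                cowans_k=ks)
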