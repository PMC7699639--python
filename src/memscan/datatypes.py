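"""Core in-memory containers shared by all analysis stages.

A :class:`Recording` is the unit of signal processing: a channels x samples
voltage array with per-channel metadata (region of interest, grid geometry).
Trial structure lives in a plain :class:`pandas.DataFrame` (see
:data:`TRIAL_COLUMNS`) so that epoching and condition contrasts compose with
ordinary dataframe operations.  :class:`GroundTruth` records every injected
component of a synthetic session so that downstream estimators can be scored
against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

#: Regions of interest along the visual-memory hierarchy.
REGIONS = ("LOC", "PAR", "PT", "MTL", "OTHER")

#: Mandatory columns of a trial table.
TRIAL_COLUMNS = [
    "trial_id",
    "list_id",
    "image_id",
    "phase",        # "encoding" | "recognition"
    "condition",    # "repeated" | "added" | "removed"
    "correct",      # bool
    "image_onset_s",
    "image_offset_s",
]

#: Optional trial-table columns (kept when present, never required).
TRIAL_OPTIONAL_COLUMNS = ["response_time_s", "click_x", "click_y"]

CHANNEL_COLUMNS = ["label", "region", "grid_id", "grid_row", "grid_col", "is_depth"]


@dataclass
class Recording:
    """Continuous multichannel voltage traces with channel metadata.

    Parameters
    ----------
    traces
        ``(n_channels, n_samples)`` float array, microvolts.  Sample ``k``
        occurs at time ``k / fs`` seconds (0-based).
    fs
        Sampling rate in Hz; shared by all channels.
    channel_meta
        One row per channel, columns :data:`CHANNEL_COLUMNS` (plus optional
        ``x, y, z`` coordinates in mm).  Row order matches trace rows.
    session_id
        Opaque session identifier.
    """

    traces: np.ndarray
    fs: float
    channel_meta: pd.DataFrame
    session_id: str = "session0"

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_meta) != self.traces.shape[0]:
            raise ValueError(
                f"channel_meta has {len(self.channel_meta)} rows for "
                f"{self.traces.shape[0]} trace channels"
            )
        missing = [c for c in CHANNEL_COLUMNS if c not in self.channel_meta.columns]
        if missing:
            raise ValueError(f"channel_meta missing columns: {missing}")
        bad = set(self.channel_meta["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channels_in_region(self, region: str) -> np.ndarray:
        """Indices of channels whose metadata assigns them to ``region``."""
        return np.flatnonzero((self.channel_meta["region"] == region).to_numpy())


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check mandatory trial-table columns and ordering invariants.

    Raises ``ValueError`` naming the first missing column.  Returns the
    table unchanged on success.
    """
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise ValueError(f"trial table missing mandatory column '{col}'")
    dup = trials.duplicated(subset=["image_id", "phase"])
    if dup.any():
        raise ValueError("duplicate (image_id, phase) rows in trial table")
    enc = trials[trials["phase"] == "encoding"].set_index("image_id")["image_onset_s"]
    rec = trials[trials["phase"] == "recognition"].set_index("image_id")["image_onset_s"]
    common = enc.index.intersection(rec.index)
    if len(common) and not (rec.loc[common].to_numpy() > enc.loc[common].to_numpy()).all():
        raise ValueError("recognition onset precedes encoding onset for some image")
    return trials


@dataclass
class GazeStream:
    """Gaze samples at ~120 Hz plus per-image critical-region rectangles.

    ``samples`` has columns ``t_s, x_deg, y_deg`` with strictly increasing
    ``t_s``; ``regions`` has columns ``image_id, x0, y0, x1, y1`` (degrees).
    """

    samples: pd.DataFrame
    regions: pd.DataFrame
    fs: float = 120.0

    def __post_init__(self) -> None:
        t = self.samples["t_s"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("gaze timestamps must be strictly increasing")


@dataclass
class GroundTruth:
    """Every injected component of a synthetic session, keyed by seed.

    Given ``seed`` and the generator config the synthetic dataset is fully
    determined; this object additionally caches the injected quantities an
    estimator should recover (spatial gains, lag, onsets, artifact times).
    ``band_envelopes`` holds the per-region noiseless 80–120 Hz amplitude
    envelope over the whole session (not serialized; regenerable).
    """

    seed: int
    image_gains: dict = field(default_factory=dict)        # image_id -> per-channel gain array
    effect_amplitude: float = 0.0
    effect_onsets_s: dict = field(default_factory=dict)    # region -> onset (s)
    effect_duration_s: float = 0.0
    envelope_lag_ms: float = 0.0
    lead_region: str = "PT"
    lag_region: str = "MTL"
    alpha: dict = field(default_factory=dict)              # freq, phase_lag, amplitude, trial_ids
    spike_times_s: dict = field(default_factory=dict)      # channel index -> list of times
    outlier_trials: list = field(default_factory=list)
    gaze_dwells: Optional[pd.DataFrame] = None
    band_envelopes: Optional[dict] = None                  # region -> (n_samples,) array

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "image_gains": {str(k): np.asarray(v).tolist() for k, v in self.image_gains.items()},
            "effect_amplitude": self.effect_amplitude,
            "effect_onsets_s": self.effect_onsets_s,
            "effect_duration_s": self.effect_duration_s,
            "envelope_lag_ms": self.envelope_lag_ms,
            "lead_region": self.lead_region,
            "lag_region": self.lag_region,
            "alpha": {k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v)
                      for k, v in self.alpha.items()},
            "spike_times_s": {str(k): list(map(float, v)) for k, v in self.spike_times_s.items()},
            "outlier_trials": list(map(int, self.outlier_trials)),
            "gaze_dwells": (self.gaze_dwells.to_dict(orient="list")
                            if self.gaze_dwells is not None else None),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        gt = cls(seed=int(d["seed"]))
        gt.image_gains = {int(k): np.asarray(v) for k, v in d["image_gains"].items()}
        gt.effect_amplitude = d["effect_amplitude"]
        gt.effect_onsets_s = d["effect_onsets_s"]
        gt.effect_duration_s = d["effect_duration_s"]
        gt.envelope_lag_ms = d["envelope_lag_ms"]
        gt.lead_region = d["lead_region"]
        gt.lag_region = d["lag_region"]
        gt.alpha = d["alpha"]
        gt.spike_times_s = {int(k): v for k, v in d["spike_times_s"].items()}
        gt.outlier_trials = d["outlier_trials"]
        if d.get("gaze_dwells") is not None:
            gt.gaze_dwells = pd.DataFrame(d["gaze_dwells"])
        return gt
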