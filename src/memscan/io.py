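"""On-disk containers: HDF5 traces with a JSON sidecar, TSV tables.

Layout of a dataset directory::

    traces.h5        /sessions/<session_id>/traces   (channels x samples, float64)
    traces.json      {"fs": ..., "session_id": ..., "channel_meta": [...]}
    events.tsv       trial table (tab-separated, one header line)
    gaze.tsv         t_s, x_deg, y_deg
    gaze_regions.tsv image_id, x0, y0, x1, y1
    ground_truth.json  (optional)

Channel order is fixed by the sidecar's ``channel_meta`` list and matched
against the array on load; writing then reading reproduces the trace array
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .datatypes import (Recording, GazeStream, GroundTruth, TRIAL_COLUMNS,
                        CHANNEL_COLUMNS, validate_trials)

__all__ = [
    "save_recording", "load_recording", "save_trials", "load_trials",
    "save_gaze", "load_gaze", "save_dataset", "load_dataset",
]


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write traces to ``<path>/traces.h5`` plus ``traces.json`` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "traces.h5", "w") as f:
        grp = f.require_group(f"sessions/{rec.session_id}")
        grp.create_dataset("traces", data=rec.traces)
    sidecar = {
        "fs": rec.fs,
        "session_id": rec.session_id,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_meta": rec.channel_meta.to_dict(orient="records"),
    }
    (path / "traces.json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = json.loads((path / "traces.json").read_text())
    for key in ("fs", "session_id", "channel_meta"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing mandatory field '{key}'")
    with h5py.File(path / "traces.h5", "r") as f:
        grp = f[f"sessions/{sidecar['session_id']}"]
        traces = np.asarray(grp["traces"])
    meta = pd.DataFrame(sidecar["channel_meta"])
    if len(meta) != traces.shape[0]:
        raise ValueError(
            f"sidecar lists {len(meta)} channels but array has {traces.shape[0]}")
    if "n_samples" in sidecar and sidecar["n_samples"] != traces.shape[1]:
        raise ValueError("sidecar/array sample-count mismatch")
    if np.isnan(traces).any():
        raise ValueError("NaN values in stored traces")
    return Recording(traces=traces, fs=float(sidecar["fs"]), channel_meta=meta,
                     session_id=sidecar["session_id"])


def save_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_trials(trials)
    trials.to_csv(path, sep="\t", index=False)
    return path


def load_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    return validate_trials(trials)


def save_gaze(gaze: GazeStream, path: str | Path) -> Path:
    """Write ``gaze.tsv`` and ``gaze_regions.tsv`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    gaze.samples.to_csv(path / "gaze.tsv", sep="\t", index=False)
    gaze.regions.to_csv(path / "gaze_regions.tsv", sep="\t", index=False)
    return path


def load_gaze(path: str | Path) -> GazeStream:
    path = Path(path)
    samples = pd.read_csv(path / "gaze.tsv", sep="\t")
    for col in ("t_s", "x_deg", "y_deg"):
        if col not in samples.columns:
            raise ValueError(f"gaze table missing mandatory column '{col}'")
    regions = pd.read_csv(path / "gaze_regions.tsv", sep="\t")
    for col in ("image_id", "x0", "y0", "x1", "y1"):
        if col not in regions.columns:
            raise ValueError(f"gaze region table missing mandatory column '{col}'")
    return GazeStream(samples=samples, regions=regions)


def save_dataset(path: str | Path, rec: Recording, trials: pd.DataFrame,
                 ground_truth: Optional[GroundTruth] = None,
                 gaze: Optional[GazeStream] = None) -> Path:
    path = Path(path)
    save_recording(rec, path)
    save_trials(trials, path / "events.tsv")
    if ground_truth is not None:
        (path / "ground_truth.json").write_text(ground_truth.to_json())
    if gaze is not None:
        save_gaze(gaze, path)
    return path


def load_dataset(path: str | Path):
    """Load ``(Recording, trials, GroundTruth | None, GazeStream | None)``."""
    path = Path(path)
    rec = load_recording(path)
    trials = load_trials(path / "events.tsv")
    gt = None
    if (path / "ground_truth.json").exists():
        gt = GroundTruth.from_json((path / "ground_truth.json").read_text())
    gaze = None
    if (path / "gaze.tsv").exists():
        gaze = load_gaze(path)
    return rec, trials, gt, gaze
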