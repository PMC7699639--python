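"""Encoding-retrieval representational similarity (reinstatement).

For every temporal epoch a feature vector holds the mean z-scored band
power of each electrode (and band): K = L*F entries.  For each image the
cosine similarity between every encoding epoch i and retrieval epoch j
forms a reinstatement map C(i, j).  Image specificity is assessed against a
within-list shuffle null in which each retrieval trial is paired with the
encoding epochs of a *different* image from the same list (a derangement,
enumerated exactly and averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectral import BinnedPower

__all__ = [
    "FeatureSet", "build_features", "cosine_map", "normalize_maps",
    "shuffle_null", "reinstatement_timeseries",
]


@dataclass
class FeatureSet:
    """Per-image encoding and retrieval feature-vector sequences.

    ``enc``/``ret`` have shape (n_images, n_epochs, K) with identical entry
    order (electrode-major, band-minor) in both phases.
    """

    image_ids: np.ndarray
    list_ids: np.ndarray
    enc: np.ndarray
    ret: np.ndarray
    enc_centers: np.ndarray
    ret_centers: np.ndarray
    log: list = field(default_factory=list)


def build_features(enc_binned: BinnedPower, ret_binned: BinnedPower,
                   trials: pd.DataFrame,
                   electrodes: Optional[Sequence[int]] = None) -> FeatureSet:
    """Assemble matched encoding/retrieval feature vectors per image.

    ``enc_binned``/``ret_binned`` are binned power for the encoding and
    recognition epochs of one session (trials x channels x bands x bins).
    ``electrodes`` restricts the channel scope (e.g. one region of
    interest).  Images present in both phases are kept; masked bins
    propagate as NaN and exclude the affected epoch pairs downstream.
    """
    if electrodes is not None and len(electrodes) == 0:
        raise ValueError("empty electrode scope")

    def _vectors(binned: BinnedPower) -> np.ndarray:
        v = binned.values
        if electrodes is not None:
            v = v[:, list(electrodes)]
        t, ch, fb, b = v.shape
        # epoch-wise feature vector: electrode-major, band-minor
        return v.reshape(t, ch * fb, b).transpose(0, 2, 1)   # (trials, bins, K)

    enc_v = _vectors(enc_binned)
    ret_v = _vectors(ret_binned)
    enc_rows = trials.loc[enc_binned.trial_index]
    ret_rows = trials.loc[ret_binned.trial_index]
    enc_by_img = {img: k for k, img in enumerate(enc_rows["image_id"])}
    keep_imgs, ei, ri = [], [], []
    for k, img in enumerate(ret_rows["image_id"]):
        if img in enc_by_img:
            keep_imgs.append(img)
            ei.append(enc_by_img[img])
            ri.append(k)
    lists = ret_rows.iloc[ri]["list_id"].to_numpy()
    return FeatureSet(image_ids=np.asarray(keep_imgs), list_ids=lists,
                      enc=enc_v[ei], ret=ret_v[ri],
                      enc_centers=enc_binned.bin_centers,
                      ret_centers=ret_binned.bin_centers)


def _cosine(E: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Cosine similarity between all epoch pairs of one image.

    ``E``: (n_enc, K); ``R``: (n_ret, K).  NaN features or zero-norm vectors
    yield NaN entries.
    """
    En = np.linalg.norm(E, axis=1)
    Rn = np.linalg.norm(R, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (E @ R.T) / np.outer(En, Rn)
    C[:, Rn == 0] = np.nan
    C[En == 0, :] = np.nan
    return C


def cosine_map(features: FeatureSet) -> np.ndarray:
    """Raw reinstatement maps C[n, i, j] in [-1, 1] for every image n."""
    n, n_enc, K = features.enc.shape
    n_ret = features.ret.shape[1]
    maps = np.empty((n, n_enc, n_ret))
    for k in range(n):
        maps[k] = _cosine(features.enc[k], features.ret[k])
    return maps


def normalize_maps(maps: np.ndarray, mode: str = "cellwise") -> np.ndarray:
    """Standardize reinstatement maps across trials.

    ``cellwise`` (default): each (i, j) cell is z-scored by that cell's
    mean and SD over trials; zero-variance cells become NaN.  ``global``:
    every entry is standardized by the session-wide mean and SD of all
    cells over all trials.  Requires >= 2 trials.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("normalization requires >= 2 trials")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        if mode == "cellwise":
            mu = np.nanmean(maps, axis=0, keepdims=True)
            sd = np.nanstd(maps, axis=0, keepdims=True)
        elif mode == "global":
            mu = np.nanmean(maps)
            sd = np.nanstd(maps)
        else:
            raise ValueError("mode must be 'cellwise' or 'global'")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (maps - mu) / sd
    if mode == "cellwise":
        out[:, np.asarray(sd)[0] == 0] = np.nan
    elif sd == 0:
        out[:] = np.nan
    return out


def _derangements(n: int):
    return [p for p in permutations(range(n)) if all(p[i] != i for i in range(n))]


def shuffle_null(features: FeatureSet) -> np.ndarray:
    """Within-list shuffled reinstatement maps, derangements enumerated.

    For each list, every retrieval trial is paired with the encoding epochs
    of a different image from the same list; all derangements of the list
    are enumerated (9 for a 4-image list) and the resulting maps averaged.
    Lists with a single image are excluded (their null is NaN, logged).
    """
    n, n_enc, K = features.enc.shape
    n_ret = features.ret.shape[1]
    null = np.full((n, n_enc, n_ret), np.nan)
    for lst in np.unique(features.list_ids):
        members = np.flatnonzero(features.list_ids == lst)
        m = len(members)
        if m < 2:
            features.log.append(f"list {lst} has {m} image(s); excluded from null")
            continue
        ders = _derangements(m)
        acc = np.zeros((m, n_enc, n_ret))
        cnt = np.zeros((m, n_enc, n_ret))
        for d in ders:
            for pos, enc_pos in enumerate(d):
                C = _cosine(features.enc[members[enc_pos]], features.ret[members[pos]])
                good = ~np.isnan(C)
                acc[pos][good] += C[good]
                cnt[pos] += good
        with np.errstate(invalid="ignore", divide="ignore"):
            null[members] = acc / cnt
    return null


def reinstatement_timeseries(norm_map: np.ndarray, enc_mask: np.ndarray) -> np.ndarray:
    """Retrieval-locked reinstatement time series.

    ``norm_map`` is a (n_enc, n_ret) normalized reinstatement map (typically
    a participant average); ``enc_mask`` flags the encoding epochs with
    significant image-specific reinstatement.  Returns, for every retrieval
    epoch, the mean reinstatement over the masked encoding epochs.
    """
    enc_mask = np.asarray(enc_mask, dtype=bool)
    if enc_mask.sum() == 0:
        raise ValueError("empty encoding-epoch mask")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.asarray(norm_map)[enc_mask, :], axis=0)
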