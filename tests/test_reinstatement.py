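"""Feature vectors, cosine maps, normalization and the within-list null."""

import numpy as np
import pandas as pd
import pytest

from memscan.reinstatement import (FeatureSet, build_features, cosine_map,
                                   normalize_maps, reinstatement_timeseries,
                                   shuffle_null, _derangements)
from memscan.spectral import BinnedPower


def _binned(values, trial_index):
    v = np.asarray(values, dtype=float)
    return BinnedPower(values=v, bin_centers=0.1 + 0.1 * np.arange(v.shape[-1]),
                       freqs=np.array([100.0]), trial_index=np.asarray(trial_index),
                       width=0.2, step=0.1)


def _trials(n_images, per_list=4):
    rows = []
    for img in range(n_images):
        for k, phase in enumerate(("encoding", "recognition")):
            rows.append(dict(trial_id=2 * img + k, list_id=img // per_list,
                             image_id=img, phase=phase, condition="repeated",
                             correct=True, image_onset_s=0.0, image_offset_s=1.0))
    return pd.DataFrame(rows)


def test_feature_vector_length_is_electrodes_times_bands():
    rng = np.random.default_rng(0)
    trials = _trials(4)
    enc_idx = trials.index[trials.phase == "encoding"]
    ret_idx = trials.index[trials.phase == "recognition"]
    for n_ch, n_bands, K in [(3, 1, 3), (2, 4, 8)]:
        enc = _binned(rng.standard_normal((4, n_ch, n_bands, 5)), enc_idx)
        ret = _binned(rng.standard_normal((4, n_ch, n_bands, 5)), ret_idx)
        f = build_features(enc, ret, trials)
        assert f.enc.shape == (4, 5, K) and f.ret.shape == (4, 5, K)
    # electrode scoping restricts the feature set
    enc = _binned(rng.standard_normal((4, 3, 1, 5)), enc_idx)
    ret = _binned(rng.standard_normal((4, 3, 1, 5)), ret_idx)
    scoped = build_features(enc, ret, trials, electrodes=[0, 2])
    assert scoped.enc.shape[-1] == 2
    assert np.allclose(scoped.enc, build_features(enc, ret, trials).enc[:, :, [0, 2]])
    with pytest.raises(ValueError):
        build_features(enc, ret, trials, electrodes=[])


def test_cosine_map_closed_forms():
    f = FeatureSet(image_ids=np.array([0]), list_ids=np.array([0]),
                   enc=np.array([[[1.0, 0.0], [3.0, 4.0], [1.0, 1.0]]]),
                   ret=np.array([[[1.0, 0.0], [1.0, 1.0]]]),
                   enc_centers=np.arange(3), ret_centers=np.arange(2))
    C = cosine_map(f)[0]
    assert C[0, 0] == pytest.approx(1.0)                      # identical vectors
    assert C[0, 1] == pytest.approx(1.0 / np.sqrt(2.0))       # (1,0) vs (1,1)
    assert C[2, 1] == pytest.approx(1.0)
    # orthogonal vectors -> 0
    f2 = FeatureSet(image_ids=np.array([0]), list_ids=np.array([0]),
                    enc=np.array([[[1.0, 0.0]]]), ret=np.array([[[0.0, 2.0]]]),
                    enc_centers=np.arange(1), ret_centers=np.arange(1))
    assert cosine_map(f2)[0][0, 0] == pytest.approx(0.0)


def test_cosine_map_invariant_to_positive_rescaling():
    rng = np.random.default_rng(1)
    enc = rng.standard_normal((3, 4, 5))
    ret = rng.standard_normal((3, 4, 5))
    f = FeatureSet(np.arange(3), np.zeros(3), enc, ret, np.arange(4), np.arange(4))
    C1 = cosine_map(f)
    f2 = FeatureSet(np.arange(3), np.zeros(3), enc * 7.3, ret * 0.11,
                    np.arange(4), np.arange(4))
    assert np.allclose(C1, cosine_map(f2))


def test_zero_norm_vectors_become_missing():
    f = FeatureSet(np.array([0]), np.array([0]),
                   enc=np.array([[[0.0, 0.0], [1.0, 0.0]]]),
                   ret=np.array([[[1.0, 1.0]]]),
                   enc_centers=np.arange(2), ret_centers=np.arange(1))
    C = cosine_map(f)[0]
    assert np.isnan(C[0, 0]) and np.isfinite(C[1, 0])


def test_normalization_hand_example_and_shift_invariance():
    maps = np.array([[[1.0]], [[3.0]]])                       # 2 trials, 1 cell
    z = normalize_maps(maps)
    sd = np.std([1.0, 3.0])                                   # population SD
    assert z[0, 0, 0] == pytest.approx((1 - 2) / sd)
    assert z[1, 0, 0] == pytest.approx((3 - 2) / sd)
    rng = np.random.default_rng(2)
    m = rng.standard_normal((5, 3, 3))
    assert np.allclose(normalize_maps(m), normalize_maps(m + 4.2), atol=1e-12)
    # identical maps across trials -> zero variance -> NaN cells
    same = np.ones((3, 2, 2))
    assert np.isnan(normalize_maps(same)).all()
    with pytest.raises(ValueError):
        normalize_maps(maps[:1])


def test_derangement_enumeration():
    assert _derangements(2) == [(1, 0)]
    assert len(_derangements(3)) == 2
    assert len(_derangements(4)) == 9


def test_shuffle_null_pairs_within_list_without_self_pairing():
    rng = np.random.default_rng(3)
    # 2-image list: the only derangement swaps them
    enc = rng.standard_normal((2, 3, 4))
    ret = rng.standard_normal((2, 3, 4))
    f = FeatureSet(np.arange(2), np.zeros(2), enc, ret, np.arange(3), np.arange(3))
    null = shuffle_null(f)
    swapped = FeatureSet(np.arange(2), np.zeros(2), enc[[1, 0]], ret,
                         np.arange(3), np.arange(3))
    assert np.allclose(null, cosine_map(swapped))
    # singleton list has no derangement: NaN and a log entry
    f1 = FeatureSet(np.arange(1), np.zeros(1), enc[:1], ret[:1],
                    np.arange(3), np.arange(3))
    assert np.isnan(shuffle_null(f1)).all()
    assert f1.log


def test_true_equals_shuffled_when_patterns_are_shared():
    """With one common pattern plus i.i.d. noise, matched and mismatched
    pairings are exchangeable: E[true - shuffled] = 0."""
    rng = np.random.default_rng(4)
    pattern = rng.standard_normal(6) + 3.0
    enc = pattern + 0.3 * rng.standard_normal((8, 5, 6))
    ret = pattern + 0.3 * rng.standard_normal((8, 5, 6))
    f = FeatureSet(np.arange(8), np.repeat([0, 1], 4), enc, ret,
                   np.arange(5), np.arange(5))
    diff = np.nanmean(cosine_map(f)) - np.nanmean(shuffle_null(f))
    assert abs(diff) < 0.01


def test_image_specific_patterns_raise_true_above_shuffled():
    rng = np.random.default_rng(5)
    patterns = rng.standard_normal((8, 6)) * 2.0
    enc = patterns[:, None, :] + 0.3 * rng.standard_normal((8, 5, 6))
    ret = patterns[:, None, :] + 0.3 * rng.standard_normal((8, 5, 6))
    f = FeatureSet(np.arange(8), np.repeat([0, 1], 4), enc, ret,
                   np.arange(5), np.arange(5))
    assert np.nanmean(cosine_map(f)) - np.nanmean(shuffle_null(f)) > 0.2


def test_timeseries_extraction_from_masked_rows():
    m = np.arange(12.0).reshape(3, 4)
    # full mask -> column means; single-epoch mask -> that row
    assert np.allclose(reinstatement_timeseries(m, [True] * 3), m.mean(axis=0))
    assert np.allclose(reinstatement_timeseries(m, [False, True, False]), m[1])
    with pytest.raises(ValueError):
        reinstatement_timeseries(m, [False, False, False])
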