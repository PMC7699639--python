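"""Cluster-based permutation tests in one and two dimensions.

Pointwise t statistics are thresholded (p < 0.05 by default), contiguous
suprathreshold bins of common sign form clusters (1-D runs; 4-connected
pixels in 2-D), and each cluster's statistic is the sum of its t values.
The null distribution collects the maximum |cluster statistic| over
sign-flipped (participant-level) or label-shuffled (trial-level) data;
cluster p-values compare against those maxima, which corrects for multiple
comparisons across bins.  For n <= 10 participants all 2^n sign flips are
enumerated exactly instead of sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ClusterResult", "pointwise_tstats", "signflip_cluster_test",
    "trialshuffle_cluster_test", "cluster_2d", "significant_mask",
]

T_DEGENERATE = 1e12
ENUMERATE_MAX_N = 10


@dataclass
class Cluster:
    bins: np.ndarray          # flat indices (1-D) or (k, 2) index array (2-D)
    stat: float               # sum of t statistics
    p: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list
    t: np.ndarray
    p_pointwise: np.ndarray
    null_max: np.ndarray
    threshold_p: float
    tail: str
    exact: bool = False
    log: list = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p < alpha]


def pointwise_tstats(diffs: np.ndarray):
    """Paired t statistic and two-sided p per bin.

    ``diffs`` is (n_participants, ...) of per-participant condition
    differences.  Zero-variance nonzero-mean bins get the largest
    representable statistic (degenerate, logged by callers); zero-variance
    zero-mean bins get t = 0, p = 1.  NaN entries are ignored per bin
    (participants lacking that bin), requiring >= 2 values.
    """
    d = np.asarray(diffs, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    n_eff = np.sum(~np.isnan(d), axis=0)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(d, axis=0)
        sd = np.nanstd(d, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n_eff))
    degen = (sd == 0) & (n_eff >= 2)
    t = np.where(degen & (mean != 0), np.sign(mean) * T_DEGENERATE, t)
    t = np.where(degen & (mean == 0), 0.0, t)
    t = np.where(n_eff < 2, np.nan, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n_eff - 1, 1))
    p = np.where(degen & (mean != 0), 0.0, p)
    return t, p


def _find_clusters(t: np.ndarray, p: np.ndarray, threshold_p: float,
                   tail: str, connectivity: int = 4):
    """Suprathreshold clusters of common sign.  Works for 1-D and 2-D maps."""
    clusters = []
    structure = None
    if t.ndim == 2 and connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    signs = {"two": (1, -1), "greater": (1,), "less": (-1,)}[tail]
    for sign in signs:
        mask = np.isfinite(t) & (p < threshold_p) & (sign * t > 0)
        labels, n = ndimage.label(mask, structure=structure) if t.ndim == 2 \
            else ndimage.label(mask)
        for k in range(1, n + 1):
            idx = np.argwhere(labels == k)
            stat = float(t[labels == k].sum())
            clusters.append(Cluster(bins=idx.squeeze(-1) if t.ndim == 1 else idx,
                                    stat=stat, p=np.nan, sign=sign))
    return clusters


def _max_cluster_stat(t: np.ndarray, p: np.ndarray, threshold_p: float,
                      tail: str, connectivity: int = 4) -> float:
    cl = _find_clusters(t, p, threshold_p, tail, connectivity)
    return max((abs(c.stat) for c in cl), default=0.0)


def _signflip_matrix(n: int, n_perm: int, rng: Optional[np.random.Generator],
                     enumerate_max_n: int = ENUMERATE_MAX_N):
    """Sign matrix (n_perm x n): exact 2^n enumeration for small n."""
    if n <= enumerate_max_n:
        bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :] & 1
        return np.where(bits == 1, -1.0, 1.0), True
    return rng.choice([-1.0, 1.0], size=(n_perm, n)), False


def _null_from_signs(diffs: np.ndarray, signs: np.ndarray, threshold_p: float,
                     tail: str, connectivity: int) -> np.ndarray:
    """Max |cluster stat| for every sign-flip row; vectorized t computation.

    Squared differences are invariant under sign flips, so only the mean
    changes per permutation: var' = (m2 - mean'^2) * n/(n-1).
    """
    d = diffs.reshape(diffs.shape[0], -1)
    shape = diffs.shape[1:]
    n = d.shape[0]
    finite = ~np.isnan(d)
    n_eff = finite.sum(axis=0)
    d0 = np.where(finite, d, 0.0)
    m2 = (d0 ** 2).sum(axis=0) / np.maximum(n_eff, 1)
    means = (signs @ d0) / np.maximum(n_eff, 1)          # (n_perm, bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (m2[None, :] - means ** 2) * n_eff / np.maximum(n_eff - 1, 1)
        var = np.clip(var, 0.0, None)
        t = means / np.sqrt(var / np.maximum(n_eff, 1))
    degen = (var == 0)
    t = np.where(degen & (means != 0), np.sign(means) * T_DEGENERATE, t)
    t = np.where(degen & (means == 0), 0.0, t)
    t = np.where(n_eff[None, :] < 2, np.nan, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n_eff - 1, 1)[None, :])
    p = np.where(degen & (means != 0), 0.0, p)
    out = np.empty(signs.shape[0])
    for i in range(signs.shape[0]):
        out[i] = _max_cluster_stat(t[i].reshape(shape), p[i].reshape(shape),
                                   threshold_p, tail, connectivity)
    return out


def signflip_cluster_test(diffs: np.ndarray, n_perm: int = 1000,
                          seed: int | np.random.Generator = 0,
                          threshold_p: float = 0.05, tail: str = "two",
                          connectivity: int = 4,
                          enumerate_max_n: int = ENUMERATE_MAX_N) -> ClusterResult:
    """Participant-level sign-flip cluster permutation test.

    ``diffs`` is (n_participants, n_bins) or (n_participants, I, J) of
    paired condition differences.  The null randomly reverses each
    participant's difference sign; with n <= ``enumerate_max_n`` all 2^n
    flip patterns are enumerated (exact test), otherwise ``n_perm`` draws
    are used with the (1 + #{null >= obs}) / (1 + n_perm) convention.
    """
    if not (0.0 < threshold_p < 1.0):
        raise ValueError("threshold_p must lie in (0, 1)")
    d = np.asarray(diffs, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, p = pointwise_tstats(d)
    clusters = _find_clusters(t, p, threshold_p, tail, connectivity)
    signs, exact = _signflip_matrix(d.shape[0], n_perm, rng, enumerate_max_n)
    null = _null_from_signs(d, signs, threshold_p, tail, connectivity)
    for c in clusters:
        if exact:
            c.p = float((null >= abs(c.stat) - 1e-12).mean())
        else:
            c.p = float((1 + (null >= abs(c.stat) - 1e-12).sum()) / (1 + len(null)))
    clusters.sort(key=lambda c: -abs(c.stat))
    return ClusterResult(clusters=clusters, t=t, p_pointwise=p, null_max=null,
                         threshold_p=threshold_p, tail=tail, exact=exact)


def trialshuffle_cluster_test(values: np.ndarray, labels: np.ndarray,
                              n_perm: int = 1000,
                              seed: int | np.random.Generator = 0,
                              threshold_p: float = 0.05,
                              tail: str = "two") -> ClusterResult:
    """Trial-level condition-shuffle cluster test (per electrode).

    ``values`` is (n_trials, n_bins); ``labels`` a boolean/2-level condition
    vector.  The true statistic is the unpaired (pooled-variance) t per
    bin; the null permutes condition labels over trials.  Permutations that
    would empty a condition are redrawn (impossible for plain label
    permutations, guarded anyway and logged).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    levels = np.unique(lab)
    if len(levels) != 2:
        raise ValueError("labels must have exactly 2 levels")
    ga, gb = (lab == levels[0]), (lab == levels[1])
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("need >= 2 trials per condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _t_unpaired(mask_a):
        a, b = v[mask_a], v[~mask_a]
        na, nb = a.shape[0], b.shape[0]
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        sp2 = (a.var(axis=0, ddof=1) * (na - 1) + b.var(axis=0, ddof=1) * (nb - 1)) / (na + nb - 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        degen = sp2 == 0
        t = np.where(degen & (ma != mb), np.sign(ma - mb) * T_DEGENERATE, t)
        t = np.where(degen & (ma == mb), 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), na + nb - 2)
        p = np.where(degen & (ma != mb), 0.0, p)
        return t, p

    t, p = _t_unpaired(ga)
    clusters = _find_clusters(t, p, threshold_p, tail)
    null = np.empty(n_perm)
    log = []
    for i in range(n_perm):
        while True:
            perm = rng.permutation(len(lab))
            mask = ga[perm]
            if mask.sum() >= 2 and (~mask).sum() >= 2:
                break
            log.append("degenerate permutation redrawn")
        tn, pn = _t_unpaired(mask)
        null[i] = _max_cluster_stat(tn, pn, threshold_p, tail)
    for c in clusters:
        c.p = float((1 + (null >= abs(c.stat) - 1e-12).sum()) / (1 + n_perm))
    clusters.sort(key=lambda c: -abs(c.stat))
    return ClusterResult(clusters=clusters, t=t, p_pointwise=p, null_max=null,
                         threshold_p=threshold_p, tail=tail, log=log)


def cluster_2d(diff_maps: np.ndarray, n_perm: int = 1000,
               seed: int | np.random.Generator = 0, threshold_p: float = 0.05,
               tail: str = "two", connectivity: int = 4,
               enumerate_max_n: int = ENUMERATE_MAX_N) -> ClusterResult:
    """Two-dimensional cluster test on participant difference maps.

    ``diff_maps`` is (n_participants, I, J) — e.g. true-minus-shuffled
    reinstatement maps (time x time) or coherence contrasts
    (time x frequency).  Clusters are 4-connected by default
    (``connectivity=8`` includes diagonals); otherwise identical to
    :func:`signflip_cluster_test`.
    """
    d = np.asarray(diff_maps, dtype=float)
    if d.ndim != 3:
        raise ValueError("diff_maps must be (participants, I, J)")
    return signflip_cluster_test(d, n_perm=n_perm, seed=seed,
                                 threshold_p=threshold_p, tail=tail,
                                 connectivity=connectivity,
                                 enumerate_max_n=enumerate_max_n)


def significant_mask(result: ClusterResult, shape: tuple,
                     alpha: float = 0.05, sign: Optional[int] = None) -> np.ndarray:
    """Boolean mask of bins inside significant clusters."""
    mask = np.zeros(shape, dtype=bool)
    for c in result.significant(alpha):
        if sign is not None and c.sign != sign:
            continue
        if len(shape) == 1:
            mask[np.atleast_1d(c.bins)] = True
        else:
            mask[tuple(np.atleast_2d(c.bins).T)] = True
    return mask
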