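"""End-to-end recovery studies on synthetic data with known ground truth.

Each study generates data with the synthetic-data module, runs the relevant
slice of the analysis pipeline, and scores the result against the injected
truth.  They are the package's validation suite: the acceptance script and
the acceptance tests both call these functions.  Problem sizes are scaled
to small sessions (few electrodes, a handful of lists) so that whole
studies with tens of regenerations complete in minutes; see the methods
note for the exact conditions.
"""

from __future__ import annotations

import numpy as np

from . import behavior, cluster, connectivity, dynamics, reinstatement, spectral
from .preprocess import detect_artifact_events
from .simulate import SimConfig, default_config, generate_recording
from .spectral import band_centers, bin_power, band_power, bootstrap_match, \
    morlet_tfr, select_trials, zscore_session

__all__ = [
    "cowans_k_examples", "lag_recovery_study", "cluster_fwer_study",
    "enumeration_agreement", "reinstatement_specificity_study",
    "onset_ordering_study", "plv_msc_identities", "spike_masking_study",
]


def _spawn(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31 - 1))


# ---------------------------------------------------------------------------


def cowans_k_examples() -> dict:
    """Worked Cowan's K examples from the task's printed hit/rejection rates.

    Hit rate 0.665 is the mean of the added (0.65) and removed (0.68)
    recognition rates; the correct rejection rate is 0.88.  Lists of four
    images contain roughly 8-20 items, bounding the memory set size.
    """
    hr, cr = 0.665, 0.88
    return {
        "k_set8": round(behavior.cowans_k(hr, cr, 8), 1),
        "k_set20": round(behavior.cowans_k(hr, cr, 20), 1),
    }


# ---------------------------------------------------------------------------


def _lag_config(lag_ms: float) -> SimConfig:
    return default_config(
        region_channels={"PT": 2, "MTL": 2}, n_lists=5,
        encoding_duration_s=1.0, pre_image_gap_s=1.2,
        rt_mean_s=1.6, rt_sigma=0.05, rt_min_s=1.4, rt_max_s=2.0,
        effect_amplitude=0.0, alpha_amplitude=0.0, spike_rate_per_min=0.0,
        burst_amplitude=1.5, mod_depth=0.8, pattern_gain_sd=0.3,
        pattern_noise=0.1, envelope_lag_ms=lag_ms)


def lag_recovery_study(n_rep: int = 50, seed: int = 0, lag_ms: float = 40.0,
                       tol_ms: float = 10.0) -> dict:
    """Recover an injected PT->MTL high-gamma envelope lead.

    Each regeneration simulates a small two-region session whose burst
    envelope in MTL is a ``lag_ms`` delayed copy of the PT envelope, runs
    the band power -> cross-correlogram -> peak-lag pipeline over all
    PT x MTL electrode pairs, and records the mean peak lag.  Success is a
    mean within ``tol_ms`` (one 10 ms bin) of the injected lag.
    """
    rng = np.random.default_rng(seed)
    cfg = _lag_config(lag_ms)
    lags = []
    for _ in range(n_rep):
        rep_seed = _spawn(rng)
        rec, trials, _gt = generate_recording(cfg, seed=rep_seed)
        rec_trials = select_trials(trials, phase="recognition")
        tfr = morlet_tfr(rec, rec_trials, freqs=band_centers(),
                         window=(0.0, 1.0), buffer_s=0.5)
        tfrz = zscore_session(tfr)
        bp = tfrz.power.mean(axis=2)                       # (trials, ch, samples)
        pt = rec.channels_in_region("PT")
        mtl = rec.channels_in_region("MTL")
        true_ccgs, chance_ccgs = [], []
        for i in pt:
            for j in mtl:
                true_ccgs.append(connectivity.crosscorrelogram(
                    bp[:, i], bp[:, j], fs=rec.fs))
                chance_ccgs.append(connectivity.chance_crosscorrelogram(
                    bp[:, i], bp[:, j], fs=rec.fs, n_perm=100, seed=rng))
        _, summary = connectivity.peak_lag_stats(
            true_ccgs, chance_ccgs, participant_ids=[0] * len(true_ccgs))
        lags.append(summary["mean_peak_lag_ms"])
    lags = np.asarray(lags)
    ok = np.abs(lags - lag_ms) <= tol_ms
    return {"recovery_rate": float(ok.mean()), "mean_lag_ms": float(lags.mean()),
            "lags_ms": lags, "n_rep": n_rep, "injected_lag_ms": lag_ms}


# ---------------------------------------------------------------------------


def cluster_fwer_study(n_experiments: int = 200, n_participants: int = 8,
                       n_bins: int = 40, seed: int = 0,
                       alpha: float = 0.05) -> dict:
    """Family-wise error of the sign-flip cluster test on null data.

    Each simulated experiment draws zero-mean unit-variance participant
    difference series; the outcome is whether any cluster reaches
    ``p < alpha`` after max-statistic correction.  With n <= 10 the 2^n
    flip patterns are enumerated, making the test exact up to the
    discreteness of the null.
    """
    rng = np.random.default_rng(seed)
    false_pos = 0
    for _ in range(n_experiments):
        diffs = rng.standard_normal((n_participants, n_bins))
        res = cluster.signflip_cluster_test(diffs, seed=rng)
        if res.significant(alpha):
            false_pos += 1
    return {"fwer": false_pos / n_experiments, "n_experiments": n_experiments,
            "n_participants": n_participants}


def enumeration_agreement(n_participants: int = 5, n_bins: int = 30,
                          n_perm: int = 2000, seed: int = 0) -> dict:
    """Sampled vs exact sign-flip cluster p-values at small n.

    Adds a sustained effect so at least one cluster forms, then compares
    the exact 2^n enumeration p with a sampled-permutation p for the
    largest cluster.  Their difference should sit within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    diffs = rng.standard_normal((n_participants, n_bins)) * 0.5
    diffs[:, 10:18] += 1.0
    exact = cluster.signflip_cluster_test(diffs, seed=rng)
    sampled = cluster.signflip_cluster_test(diffs, n_perm=n_perm, seed=rng,
                                            enumerate_max_n=0)
    p_exact = exact.clusters[0].p
    p_sampled = sampled.clusters[0].p
    mc_se = float(np.sqrt(p_exact * (1 - p_exact) / n_perm))
    return {"p_exact": p_exact, "p_sampled": p_sampled, "mc_se": mc_se,
            "agree": abs(p_exact - p_sampled) <= max(2 * mc_se, 2.0 / n_perm)}


# ---------------------------------------------------------------------------


def _reinstatement_config(shared: bool) -> SimConfig:
    return default_config(
        region_channels={"PT": 4}, n_lists=4,
        encoding_duration_s=1.4, pre_image_gap_s=1.0,
        rt_mean_s=1.7, rt_sigma=0.05, rt_min_s=1.5, rt_max_s=2.0,
        effect_amplitude=0.0, alpha_amplitude=0.0, spike_rate_per_min=0.0,
        burst_amplitude=1.2, mod_depth=0.3, pattern_gain_sd=0.7,
        pattern_noise=0.25, shared_patterns=shared)


def _participant_reinstatement_diff(cfg: SimConfig, seed: int) -> np.ndarray:
    """Mean true-minus-shuffled reinstatement map for one synthetic participant."""
    rec, trials, _gt = generate_recording(cfg, seed=seed)
    window = (0.0, cfg.encoding_duration_s)
    maps = {}
    for phase in ("encoding", "recognition"):
        tr = select_trials(trials, phase=phase)
        tfr = morlet_tfr(rec, tr, freqs=band_centers(), window=window,
                         buffer_s=0.5)
        tfrz = zscore_session(tfr)
        maps[phase] = band_power(bin_power(tfrz))
    feats = reinstatement.build_features(maps["encoding"], maps["recognition"], trials)
    true_maps = reinstatement.cosine_map(feats)
    null_maps = reinstatement.shuffle_null(feats)
    return np.nanmean(true_maps, axis=0) - np.nanmean(null_maps, axis=0)


def reinstatement_specificity_study(n_rep: int = 50, shared: bool = False,
                                    n_participants: int = 6, seed: int = 0,
                                    alpha: float = 0.05) -> dict:
    """Image specificity of reinstatement against the within-list null.

    With image-specific spatial gains, the true-minus-shuffled map should
    carry a significant positive 2-D cluster across participants in nearly
    every regeneration; with gains shared by all images the true and
    shuffled pairings are exchangeable and significance should stay at the
    false-positive level.
    """
    rng = np.random.default_rng(seed)
    cfg = _reinstatement_config(shared)
    n_sig = 0
    mean_diffs = []
    for _ in range(n_rep):
        diffs = np.stack([
            _participant_reinstatement_diff(cfg, _spawn(rng))
            for _ in range(n_participants)])
        res = cluster.cluster_2d(diffs, seed=rng)
        if any(c.sign > 0 for c in res.significant(alpha)):
            n_sig += 1
        mean_diffs.append(float(np.nanmean(diffs)))
    return {"significant_rate": n_sig / n_rep, "n_rep": n_rep,
            "mean_true_minus_shuffled": float(np.mean(mean_diffs)),
            "shared_patterns": shared}


# ---------------------------------------------------------------------------


def _onset_config() -> SimConfig:
    return default_config(
        region_channels={"PT": 4, "MTL": 4}, n_lists=14,
        encoding_duration_s=1.0, pre_image_gap_s=1.2,
        rt_mean_s=2.6, rt_sigma=0.05, rt_min_s=2.4, rt_max_s=3.0,
        effect_amplitude=1.0, effect_onsets_s={"PT": 0.27, "MTL": 0.48},
        alpha_amplitude=0.0, spike_rate_per_min=0.0,
        burst_amplitude=1.0, mod_depth=0.2, pattern_gain_sd=0.3,
        pattern_noise=0.1)


def onset_ordering_study(n_rep: int = 100, seed: int = 0) -> dict:
    """Recover the regional ordering of condition-difference onsets.

    Injects an excess high-gamma response on manipulated-correct trials
    starting at 270 ms in PT and 480 ms in MTL, runs band power ->
    bootstrap trial matching -> difference series -> line-fit onset
    estimation per region, and scores whether the PT onset precedes the
    MTL onset.
    """
    rng = np.random.default_rng(seed)
    cfg = _onset_config()
    ok = 0
    onsets = {"PT": [], "MTL": []}
    for _ in range(n_rep):
        rec, trials, _gt = generate_recording(cfg, seed=_spawn(rng))
        rec_trials = select_trials(trials, phase="recognition")
        tfr = morlet_tfr(rec, rec_trials, freqs=band_centers(),
                         window=(0.0, 2.0), buffer_s=0.5)
        tfrz = zscore_session(tfr)
        binned = band_power(bin_power(tfrz))
        rows = trials.loc[binned.trial_index]
        manip = (rows["condition"].isin(["added", "removed"]) & rows["correct"]).to_numpy()
        rep_c = ((rows["condition"] == "repeated") & rows["correct"]).to_numpy()
        est = {}
        for region in ("PT", "MTL"):
            ch = rec.channels_in_region(region)
            series = binned.values[:, ch, 0, :].mean(axis=1)   # (trials, bins)
            mean_a, mean_b = bootstrap_match(series[manip], series[rep_c],
                                             n_iter=100, seed=rng)
            est[region] = dynamics.estimate_onset(mean_a - mean_b,
                                                  binned.bin_centers,
                                                  search_window=(0.0, 2.0))
        a, b = est["PT"].onset_s, est["MTL"].onset_s
        if a is not None and b is not None:
            onsets["PT"].append(a)
            onsets["MTL"].append(b)
            if a < b:
                ok += 1
    return {"ordering_rate": ok / n_rep, "n_rep": n_rep,
            "mean_onset_pt_ms": 1000.0 * float(np.mean(onsets["PT"])),
            "mean_onset_mtl_ms": 1000.0 * float(np.mean(onsets["MTL"])),
            "injected_ms": {"PT": 270.0, "MTL": 480.0}}


# ---------------------------------------------------------------------------


def plv_msc_identities(seed: int = 0, n_sims: int = 1000) -> dict:
    """Closed-form sanity identities for PLV and magnitude-squared coherence.

    PLV is exactly 1 for a constant phase lag and, for uniform random phase
    differences over N trials, concentrates near sqrt(pi / (4 N)) (the
    Rayleigh resultant expectation).  MSC is exactly 1 for identical
    signals and biased to about 1/K for independent noise with K averaged
    segments.
    """
    rng = np.random.default_rng(seed)
    n_trials, n_time = 40, 200
    base = rng.uniform(-np.pi, np.pi, size=(n_trials, n_time))
    plv_const = float(connectivity.plv(base, base - 0.7).mean())
    N = 100
    diffs = rng.uniform(-np.pi, np.pi, size=(n_sims, N))
    plv_uniform = float(np.abs(np.exp(1j * diffs).mean(axis=1)).mean())

    fs, nperseg, K = 1000.0, 500, 8
    x = rng.standard_normal(int(fs * 4))
    _, c_same = connectivity.msc_coherence(x, x, fs, nperseg=nperseg)
    msc_identical = float(c_same.mean())
    vals = np.empty(n_sims)
    for i in range(n_sims):
        a = rng.standard_normal(nperseg * K)
        b = rng.standard_normal(nperseg * K)
        _, c = connectivity.msc_coherence(a, b, fs, nperseg=nperseg, noverlap=0)
        vals[i] = c.mean()
    return {"plv_constant_lag": plv_const,
            "plv_uniform_n100": plv_uniform,
            "plv_uniform_expected": float(np.sqrt(np.pi / (4 * N))),
            "msc_identical": msc_identical,
            "msc_independent_k8": float(vals.mean()),
            "msc_independent_expected": 1.0 / K,
            "n_sims": n_sims}


# ---------------------------------------------------------------------------


def spike_masking_study(seed: int = 0) -> dict:
    """Sensitivity and specificity of event-level artifact masking.

    Generates a session with injected biphasic spike transients, runs the
    z > 5 gradient/high-frequency detector per channel, and reports the
    fraction of injected spikes whose samples are masked plus the fraction
    of spike-free samples that the mask removes.
    """
    cfg = default_config(
        region_channels={"PT": 2}, n_lists=4,
        encoding_duration_s=2.0, pre_image_gap_s=1.0,
        rt_mean_s=2.0, rt_sigma=0.05, rt_min_s=1.8, rt_max_s=2.5,
        effect_amplitude=0.0, alpha_amplitude=0.0,
        burst_amplitude=0.3, mod_depth=0.2,
        spike_rate_per_min=6.0)
    rec, _trials, gt = generate_recording(cfg, seed=seed)
    fs = rec.fs
    hit = tot = 0
    clean_masked = clean_total = 0
    for ch in range(rec.n_channels):
        mask = detect_artifact_events(rec.traces[ch], fs).sample_mask
        spikes = gt.spike_times_s.get(ch, [])
        near = np.zeros(rec.n_samples, dtype=bool)
        for ts in spikes:
            mid = int(round((ts + cfg.spike_duration_s / 2) * fs))
            tot += 1
            if mask[mid]:
                hit += 1
            a = max(0, int((ts - 0.12) * fs))
            b = min(rec.n_samples, int((ts + cfg.spike_duration_s + 0.12) * fs))
            near[a:b] = True
        clean_masked += int((mask & ~near).sum())
        clean_total += int((~near).sum())
    return {"sensitivity": hit / tot if tot else np.nan,
            "n_spikes": tot,
            "clean_masked_fraction": clean_masked / clean_total}
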