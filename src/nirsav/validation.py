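"""Calibration and recovery study harnesses.

These functions run the package end to end under the study's paradigm
conditions (block schedule, 10 Hz sampling, 46 channels, n = 20 per cohort)
and summarise operating characteristics: type-I calibration of the planned
contrasts, uniformity of the decoding permutation p-value under the null,
recovery of planted super-additive effects, and the exclusion-rule audit
against simulated ground truth.  They power both the acceptance test suite
and scripts/acceptance.py.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .decoding import build_patterns, informative_channels, permutation_p
from .preprocess import preprocess_cohort
from .simulate import (
    ArtifactConfig, AttritionConfig, EffectSpec, SimulationConfig,
    simulate_cohort, simulate_null_window_means,
)
from .univariate import analyze_channels

ALPHA = 0.05


def _seed(root: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(root), *map(int, tags)])


def _null_config(seed_seq: np.random.SeedSequence, n: int = 20,
                 session_s: float = 240.0) -> SimulationConfig:
    return SimulationConfig(
        seed=int(seed_seq.generate_state(1)[0] % (2**31)),
        n_younger=n, n_older=0, n_pandemic_younger=0, n_pandemic_older=0,
        session_length_s=session_s,
        artifact=ArtifactConfig(spike_rate_per_min=0.0, shift_rate_per_min=0.0),
        attrition=AttritionConfig(p_channel_missing=0.0),
    )


# ---------------------------------------------------------------------------
def null_contrast_calibration(seed: int, n_cohorts: int = 50,
                              n: int = 20) -> dict:
    """Planned-contrast rejection rate at alpha=.05 on no-effect cohorts run
    through the full signal pipeline, pooled over channels, chromophores and
    activation windows; also the pooled t of window-minus-baseline
    differences (should hover near 0)."""
    n_rej = n_tot = 0
    diffs: list[np.ndarray] = []
    for k in range(n_cohorts):
        cfg = _null_config(_seed(seed, 1, k), n=n)
        recs, _ = simulate_cohort(cfg)
        table, verdicts = preprocess_cohort(recs)
        st = analyze_channels(table, "younger")
        n_rej += int((st.p < ALPHA).sum())
        n_tot += len(st)
        wide = table.pivot_table(
            index=["participant", "condition", "channel", "chromophore"],
            columns="window", values="mean")
        for w in ("W1", "W2"):
            diffs.append((wide[w] - wide["baseline"]).values)
    d = np.concatenate(diffs)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    return {"rejection_rate": n_rej / n_tot, "n_tests": n_tot,
            "window_diff_t": float(t), "n_diffs": len(d)}


def null_decoding_calibration(seed: int, n_cohorts: int = 200,
                              n: int = 20, n_perm: int = 200) -> dict:
    """Permutation p-values of LOPO decoding on null cohorts (window-mean
    level) against the uniform distribution (Kolmogorov-Smirnov)."""
    ps = np.empty(n_cohorts)
    accs = np.empty(n_cohorts)
    for k in range(n_cohorts):
        ss = _seed(seed, 2, k)
        rng = np.random.default_rng(ss)
        table = simulate_null_window_means(n, rng)
        patterns = build_patterns(table, "HbO", "W1", "all", "younger")
        res = permutation_p(patterns, n_perm=n_perm, seed=rng)
        ps[k], accs[k] = res.p, res.accuracy
    ks = stats.kstest(ps, "uniform")
    mean_acc = accs.mean()
    half_ci = 1.96 * accs.std(ddof=1) / np.sqrt(n_cohorts)
    return {"pvalues": ps, "ks_stat": float(ks.statistic),
            "ks_p": float(ks.pvalue), "mean_accuracy": float(mean_acc),
            "accuracy_ci": (float(mean_acc - half_ci), float(mean_acc + half_ci))}


# ---------------------------------------------------------------------------
PLANTED_CHANNELS = (24, 26, 27, 29)  # right inferior-frontal / sup-temporal


def recovery_study(seed: int, n_reps: int = 20, n: int = 20,
                   amplitude_factor: float = 3.0, n_perm: int = 200) -> dict:
    """Cohorts with right-hemisphere super-additive HbO effects (amplitude =
    ``amplitude_factor`` x white-noise sd): label accuracy of detected
    planted channels, right- vs left-subset decoding p, and coverage of the
    planted channels by the top-30% informative set."""
    n_super = n_sub = n_detected = 0
    right_ps, left_ps = [], []
    coverage = 0
    for k in range(n_reps):
        cfg = _null_config(_seed(seed, 3, k), n=n)
        amp = amplitude_factor * cfg.noise.white_sd
        cfg.effects = [EffectSpec(channels=PLANTED_CHANNELS, amplitude_um=amp,
                                  additivity="super")]
        recs, _ = simulate_cohort(cfg)
        table, _ = preprocess_cohort(recs)
        st = analyze_channels(table, "younger")
        planted = st[(st.chromophore == "HbO") & st.channel.isin(PLANTED_CHANNELS)
                     & (st.p < ALPHA)]
        n_detected += len(planted)
        n_super += int((planted.additivity == "super").sum())
        n_sub += int((planted.additivity == "sub").sum())

        rng = np.random.default_rng(_seed(seed, 4, k))
        right = build_patterns(table, "HbO", "W1", "right", "younger")
        res = permutation_p(right, n_perm=n_perm, seed=rng)
        right_ps.append(res.p)
        _, top = informative_channels(right)
        coverage += set(PLANTED_CHANNELS) <= set(top)
        left = build_patterns(table, "HbO", "W1", "left", "younger")
        left_ps.append(permutation_p(left, n_perm=n_perm, seed=rng).p)
    return {
        "n_detected": n_detected, "n_super": n_super, "n_sub": n_sub,
        "super_fraction": n_super / max(n_detected, 1),
        "median_right_p": float(np.median(right_ps)),
        "median_left_p": float(np.median(left_ps)),
        "informative_coverage": coverage / n_reps,
    }


# ---------------------------------------------------------------------------
def _expected_exclusions(recs, truth, params):
    """Apply the inclusion rules directly to the simulator's ground truth."""
    guard, e1 = params.pre_trial_guard_s, params.epoch_window_s[1]
    out = {}
    for rec in recs:
        pid = rec.participant_id
        stim = rec.stim_events()
        n_ch = rec.n_channels
        dropped = {cid - 1 for cid in truth.dropped_channels[pid]}
        segs = truth.artifact_segments[pid]
        hit = np.zeros((len(stim), n_ch), dtype=bool)
        for ch, t0, t1 in segs:
            for ti, ev in enumerate(stim):
                if t0 < ev.onset_s + e1 and t1 > ev.onset_s - guard:
                    if ch is None:
                        hit[ti, :] = True
                    else:
                        hit[ti, ch] = True
        excluded = np.zeros(n_ch, dtype=bool)
        excluded[list(dropped)] = True
        excluded |= hit.sum(axis=0) > params.max_artifact_trials
        look_rej = np.array(truth.looking[pid]) < 1.0 - params.max_lookaway
        keep = ~excluded
        trial_ok = ~look_rej & ~hit[:, keep].any(axis=1)
        per_cond = {}
        for cond in ("bimodal", "alternating"):
            per_cond[cond] = sum(ok and ev.condition == cond
                                 for ok, ev in zip(trial_ok, stim))
        included = (keep.sum() >= params.min_channels and
                    all(v >= params.min_trials_per_condition
                        for v in per_cond.values()))
        out[pid] = {"included": bool(included), "usable": int(keep.sum()),
                    "surviving": {c: int(v) for c, v in per_cond.items()},
                    "looking_rejected": int(look_rej.sum()),
                    "motion_rejected_trials": int(hit[:, keep].any(axis=1).sum())}
    return out


def exclusion_audit(seed: int, n: int = 20) -> dict:
    """Run the pipeline with ground-truth artifact lists on an attrition-heavy
    cohort and count disagreements with the rule engine applied directly to
    the planted truth."""
    cfg = SimulationConfig(
        seed=int(_seed(seed, 5).generate_state(1)[0] % (2**31)),
        n_younger=n, n_older=0, n_pandemic_younger=0, n_pandemic_older=0,
        session_length_s=240.0,
        artifact=ArtifactConfig(spike_rate_per_min=2.0, shift_rate_per_min=0.2),
        attrition=AttritionConfig(p_channel_missing=0.25,
                                  looking_alpha=2.0, looking_beta=1.5),
    )
    recs, truth = simulate_cohort(cfg)
    from .preprocess import PreprocessParams, preprocess_recording

    params = PreprocessParams()
    expected = _expected_exclusions(recs, truth, params)
    mismatches = 0
    n_excluded = 0
    for rec in recs:
        arts = truth.artifact_segments[rec.participant_id]
        epochs, verdict, _ = preprocess_recording(rec, params,
                                                  artifacts=arts)
        exp = expected[rec.participant_id]
        got = {
            "included": verdict.included,
            "usable": verdict.n_usable_channels,
            "surviving": verdict.surviving_trials,
            "looking_rejected": int(epochs.looking_rejected.sum()),
            "motion_rejected_trials": int(
                epochs.motion_rejected[:, ~epochs.channel_excluded]
                .any(axis=1).sum()),
        }
        if got != exp:
            mismatches += 1
        n_excluded += not verdict.included
    return {"n_participants": len(recs), "n_excluded": n_excluded,
            "mismatches": mismatches, "expected": expected}
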