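"""Pattern construction, LOPO folds, permutation inference, channel weights."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from nirsav import (
    build_patterns, decode, default_montage, informative_channels,
    lopo_accuracy, permutation_p,
)
from nirsav.decoding import PatternSet, fit_predict, _plan_folds
from nirsav.preprocess import WM_COLUMNS


def pattern_table(X_by_pid, channels, window="W1", chromophore="HbO"):
    """X_by_pid: pid -> {condition: vector (may contain NaN = missing)}."""
    rows = []
    for pid, conds in X_by_pid.items():
        for cond, vec in conds.items():
            for ch, v in zip(channels, vec):
                if np.isnan(v):
                    continue
                rows.append((pid, "younger", cond, ch, chromophore, window,
                             float(v), 6))
    return pd.DataFrame(rows, columns=WM_COLUMNS)


def separable_cohort(n=10, n_ch=8, flip_half=True, seed=0):
    rng = np.random.default_rng(seed)
    data = {}
    for i in range(n):
        base = rng.normal(0, 0.05, n_ch)
        a = base + np.r_[np.ones(n_ch // 2), -np.ones(n_ch - n_ch // 2)]
        b = base - np.r_[np.ones(n_ch // 2), -np.ones(n_ch - n_ch // 2)]
        data[f"p{i:02d}"] = {"alternating": a, "bimodal": b}
    return data


class TestBuildPatterns:
    def test_zscore_normalisation(self):
        rng = np.random.default_rng(1)
        channels = list(range(1, 47))
        data = {f"p{i}": {"alternating": rng.normal(5, 2, 46),
                          "bimodal": rng.normal(5, 2, 46)} for i in range(8)}
        ps = build_patterns(pattern_table(data, channels), "HbO", "W1")
        np.testing.assert_allclose(np.nanmean(ps.X, axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.nanstd(ps.X, axis=0, ddof=1), 1.0,
                                   atol=1e-10)

    def test_left_subset_restricts_channels(self, montage):
        rng = np.random.default_rng(2)
        channels = list(range(1, 47))
        data = {f"p{i}": {"alternating": rng.normal(size=46),
                          "bimodal": rng.normal(size=46)} for i in range(6)}
        ps = build_patterns(pattern_table(data, channels), "HbO", "W1",
                            subset="left")
        assert ps.channel_ids == montage.hemisphere_ids("left")

    def test_missing_channel_stays_missing(self):
        rng = np.random.default_rng(3)
        channels = list(range(1, 47))
        data = {f"p{i}": {"alternating": rng.normal(size=46),
                          "bimodal": rng.normal(size=46)} for i in range(6)}
        data["p0"]["alternating"][11] = np.nan  # channel 12 missing
        ps = build_patterns(pattern_table(data, channels), "HbO", "W1")
        j = ps.channel_ids.index(12)
        assert np.isnan(ps.X[0, j]) and np.isnan(ps.X[1, j])
        assert not np.isnan(ps.X[2:, j]).any()


class TestLopo:
    def test_separable_construction_is_perfect(self):
        table = pattern_table(separable_cohort(), list(range(1, 9)))
        ps = build_patterns(table, "HbO", "W1")
        res = lopo_accuracy(ps)
        assert res.accuracy == 1.0
        assert res.accuracy_by_participant == 1.0
        assert res.n_folds == 10

    def test_fold_masks_drop_test_participants_missing_channels(self):
        data = separable_cohort(n=6)
        channels = list(range(1, 9))
        for cond in data["p00"]:
            data["p00"][cond][6:] = np.nan  # p00 lacks channels 7, 8
        table = pattern_table(data, channels)
        ps = build_patterns(table, "HbO", "W1")
        folds = _plan_folds(ps, "intersection")
        f0 = folds[0]
        assert ps.participants[f0.test_part] == "p00"
        assert f0.Xtr.shape[1] == 6 and f0.Xte.shape[1] == 6
        assert folds[1].Xtr.shape[1] == 6  # p00 in training limits others too

    def test_accuracy_invariant_to_channel_order_and_affine_scale(self):
        rng = np.random.default_rng(5)
        channels = list(range(1, 13))
        data = {f"p{i}": {"alternating": rng.normal(size=12) + 0.4,
                          "bimodal": rng.normal(size=12) - 0.4}
                for i in range(8)}
        t1 = pattern_table(data, channels)
        perm = rng.permutation(12)
        data_perm = {p: {c: v[perm] for c, v in d.items()}
                     for p, d in data.items()}
        t2 = pattern_table({p: d for p, d in data_perm.items()},
                           [channels[j] for j in perm])
        data_scaled = {p: {c: 3.0 * v + 7.0 for c, v in d.items()}
                       for p, d in data.items()}
        t3 = pattern_table(data_scaled, channels)
        accs = [lopo_accuracy(build_patterns(t, "HbO", "W1")).accuracy
                for t in (t1, t2, t3)]
        assert accs[0] == accs[1] == accs[2]

    def test_too_few_participants_rejected(self):
        table = pattern_table(separable_cohort(n=2), list(range(1, 9)))
        with pytest.raises(ValueError, match="at least 3"):
            lopo_accuracy(build_patterns(table, "HbO", "W1"))


class TestFastPathEquivalence:
    def test_fast_predict_matches_svc(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            d = int(rng.integers(2, 30))
            X = rng.normal(size=(2 * n, d))
            y = np.tile([0.0, 1.0], n)
            X[y == 1] += rng.normal() * 0.8
            Xt = rng.normal(size=(2, d))
            ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(Xt)
            fast = fit_predict(X, y, Xt, fast=True)
            np.testing.assert_array_equal(ref, fast)


class TestPermutation:
    def test_floor_p_when_observed_beats_all(self):
        table = pattern_table(separable_cohort(n=12), list(range(1, 9)))
        ps = build_patterns(table, "HbO", "W1")
        res = permutation_p(ps, n_perm=200, seed=0)
        assert res.accuracy == 1.0
        assert res.p == pytest.approx(1 / 201)

    def test_all_ties_give_p_one(self):
        # patterns identical across conditions: every labelling is equivalent
        rng = np.random.default_rng(8)
        base = {f"p{i}": rng.normal(size=6) for i in range(6)}
        data = {p: {"alternating": v, "bimodal": v} for p, v in base.items()}
        ps = build_patterns(pattern_table(data, list(range(1, 7))), "HbO", "W1")
        res = permutation_p(ps, n_perm=50, seed=1)
        assert res.p == 1.0

    def test_deterministic_under_seed(self):
        table = pattern_table(separable_cohort(n=8, seed=3),
                              list(range(1, 9)))
        ps = build_patterns(table, "HbO", "W1")
        r1 = permutation_p(ps, n_perm=100, seed=42)
        r2 = permutation_p(ps, n_perm=100, seed=42)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_accuracies, r2.null_accuracies)

    def test_invalid_n_perm(self):
        table = pattern_table(separable_cohort(n=4), list(range(1, 9)))
        ps = build_patterns(table, "HbO", "W1")
        with pytest.raises(ValueError):
            permutation_p(ps, n_perm=0, seed=0)


class TestInformativeChannels:
    def _patterns(self, n=10, n_ch=40, seed=0, missing=()):
        rng = np.random.default_rng(seed)
        channels = list(range(1, n_ch + 1))
        data = {}
        for i in range(n):
            a = rng.normal(size=n_ch)
            b = rng.normal(size=n_ch)
            b[:4] += 5.0  # strong signal channels 1-4
            data[f"p{i:02d}"] = {"alternating": a, "bimodal": b}
        for pid, chs in missing:
            for cond in data[pid]:
                for ch in chs:
                    data[pid][cond][ch - 1] = np.nan
        return build_patterns(pattern_table(data, channels), "HbO", "W1")

    def test_top_fraction_count(self):
        ps = self._patterns()
        weights, top = informative_channels(ps)
        assert len(weights) == 40
        assert len(top) == 12  # ceil(0.3 * 40)

    def test_availability_threshold(self):
        # channel 40 missing for 3 of 10 participants -> below 80%
        ps = self._patterns(missing=[(f"p{i:02d}", [40]) for i in range(3)])
        weights, top = informative_channels(ps)
        assert 40 not in weights.index
        assert len(weights) == 39

    def test_class_swap_symmetry(self):
        ps = self._patterns(seed=5)
        _, top = informative_channels(ps)
        swapped = PatternSet(
            X=ps.X.reshape(-1, 2, ps.X.shape[1])[:, ::-1, :].reshape(ps.X.shape),
            participants=ps.participants, channel_ids=ps.channel_ids,
            subset=ps.subset, chromophore=ps.chromophore, window=ps.window,
            age_group=ps.age_group)
        _, top_swapped = informative_channels(swapped)
        assert top == top_swapped

    def test_planted_channels_recovered(self):
        ps = self._patterns(seed=6)
        _, top = informative_channels(ps)
        assert {1, 2, 3, 4} <= set(top)


class TestDecodeOrchestration:
    def test_decode_on_recovered_cohort(self, effect_cohort_table):
        res = decode(effect_cohort_table, "HbO", "W1", "right", "younger",
                     n_perm=100, seed=0)
        assert res.accuracy > 0.8
        assert res.p < 0.05
        assert {24, 26, 27, 29} <= set(res.informative_channels)
        left = decode(effect_cohort_table, "HbO", "W1", "left", "younger",
                      n_perm=100, seed=0)
        assert left.p > 0.05
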