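import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, wilcoxon

from fallwave import (
    best_operating_point,
    bonferroni,
    cross_validated_scores,
    false_alarm_rate,
    roc_vertical_average,
    stratified_kfold,
    wilcoxon_signed_rank_paired,
    youden_index,
)
from fallwave.evaluation import CVSplit
from fallwave.features import FeatureConfig
from fallwave.signals import InvalidInputError


def scores_frame(fall_scores, adl_scores, fold=0):
    rows = [{"id": f"f{i}", "label": "fall", "s": v, "fold": fold}
            for i, v in enumerate(fall_scores)]
    rows += [{"id": f"a{i}", "label": "adl", "s": v, "fold": fold}
             for i, v in enumerate(adl_scores)]
    return pd.DataFrame(rows)


def staircase_auc(fall_scores, adl_scores):
    """Exhaustive pairwise oracle: P(fall > adl) + 0.5 P(tie)."""
    wins = ties = 0
    for f in fall_scores:
        for a in adl_scores:
            wins += f > a
            ties += f == a
    return (wins + 0.5 * ties) / (len(fall_scores) * len(adl_scores))


class TestStratifiedKFold:
    def test_fold_sizes(self):
        labels = ["fall"] * 30 + ["adl"] * 100
        split = stratified_kfold(labels, n_folds=10, seed=0)
        for k in range(10):
            test = split.test_indices(k)
            assert sum(1 for i in test if labels[i] == "fall") == 3
            assert sum(1 for i in test if labels[i] == "adl") == 10

    def test_deterministic_given_seed(self):
        labels = ["fall"] * 20 + ["adl"] * 50
        a = stratified_kfold(labels, n_folds=5, seed=3)
        b = stratified_kfold(labels, n_folds=5, seed=3)
        np.testing.assert_array_equal(a.fold, b.fold)

    def test_partition(self):
        labels = ["fall"] * 12 + ["adl"] * 28
        split = stratified_kfold(labels, n_folds=4, seed=1)
        all_idx = np.concatenate([split.test_indices(k) for k in range(4)])
        assert sorted(all_idx) == list(range(40))

    def test_too_few_recordings(self):
        with pytest.raises(InvalidInputError):
            stratified_kfold(["fall"] * 5 + ["adl"] * 50, n_folds=10)

    def test_single_fold_forbidden(self):
        with pytest.raises(InvalidInputError):
            stratified_kfold(["fall"] * 30 + ["adl"] * 30, n_folds=1)


class TestCrossValidatedScores:
    def test_every_recording_scored_once(self, small_dataset):
        labels = [r.label for r in small_dataset]
        split = stratified_kfold(labels, n_folds=4, seed=0)
        scores = cross_validated_scores(small_dataset, FeatureConfig(), split)
        assert sorted(scores["id"]) == sorted(r.id for r in small_dataset)
        assert len(scores) == len(small_dataset)

    def test_fold_without_falls_is_error(self, small_dataset):
        labels = np.array([r.label for r in small_dataset])
        fold = np.zeros(len(labels), dtype=int)
        fold[labels == "adl"] = 1        # fold 0 trains on ADLs only
        bad = CVSplit(fold=fold, n_folds=2)
        with pytest.raises(InvalidInputError):
            cross_validated_scores(small_dataset, FeatureConfig(), bad)

    def test_cv_scores_track_all_data_wavelet(self, small_dataset):
        from fallwave import build_feature_table, compute_sv
        from fallwave import average_fall_pattern, pattern_to_wavelet

        labels = [r.label for r in small_dataset]
        split = stratified_kfold(labels, n_folds=4, seed=0)
        cv = cross_validated_scores(small_dataset, FeatureConfig(), split)
        falls = [compute_sv(r) for r in small_dataset if r.label == "fall"]
        w_all = pattern_to_wavelet(average_fall_pattern(falls))
        full = build_feature_table(small_dataset, w_all)
        merged = cv.set_index("id").join(full.set_index("id"), rsuffix="_all")
        r = np.corrcoef(merged["wavelet"], merged["wavelet_all"])[0, 1]
        assert r > 0.9


class TestROCVerticalAverage:
    def test_perfect_separation(self):
        df = scores_frame([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        roc = roc_vertical_average(df, "s")
        assert roc.auc == pytest.approx(1.0, abs=2e-3)
        assert roc.max_yi == pytest.approx(1.0, abs=2e-3)
        # full sensitivity everywhere below perfect specificity
        assert roc.sensitivity[roc.specificity <= 0.999].min() == 1.0

    def test_uninformative_ties_give_half_auc(self):
        df = scores_frame([1.0] * 5, [1.0] * 10)
        roc = roc_vertical_average(df, "s")
        assert roc.auc == pytest.approx(0.5, abs=2e-3)

    def test_printed_small_set_matches_enumeration(self):
        falls, adls = [3.0, 2.0], [1.0, 2.5]
        roc = roc_vertical_average(scores_frame(falls, adls), "s")
        assert roc.auc == pytest.approx(staircase_auc(falls, adls), abs=2e-3)

    def test_mann_whitney_identity_tie_free(self, rng):
        falls = rng.normal(2.0, 1.0, 40)
        adls = rng.normal(0.0, 1.0, 60)
        roc = roc_vertical_average(scores_frame(falls, adls), "s")
        assert roc.auc == pytest.approx(staircase_auc(falls, adls), abs=2e-3)

    def test_monotone_averaged_curve(self, rng):
        df = pd.concat([
            scores_frame(rng.normal(1.5, 1, 10), rng.normal(0, 1, 20), fold=k)
            for k in range(3)
        ], ignore_index=True)
        roc = roc_vertical_average(df, "s")
        assert (np.diff(roc.sensitivity) <= 1e-12).all()

    def test_invariance_under_monotone_transform(self, rng):
        falls = rng.normal(1.0, 1.0, 15)
        adls = rng.normal(0.0, 1.0, 30)
        r1 = roc_vertical_average(scores_frame(falls, adls), "s")
        r2 = roc_vertical_average(
            scores_frame(np.exp(falls), np.exp(adls)), "s")
        np.testing.assert_allclose(r1.sensitivity, r2.sensitivity, atol=1e-12)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_lower_is_fall_orientation(self, rng):
        falls = rng.normal(-2.0, 1.0, 15)
        adls = rng.normal(0.0, 1.0, 30)
        roc = roc_vertical_average(scores_frame(falls, adls), "s",
                                   higher_is_fall=False)
        assert roc.auc == pytest.approx(
            staircase_auc(-falls, -adls), abs=2e-3)

    def test_single_class_fold_names_fold(self):
        df = scores_frame([1.0, 2.0], [])
        with pytest.raises(InvalidInputError, match="fold 0"):
            roc_vertical_average(df, "s")


class TestYoudenAndOperatingPoint:
    @pytest.mark.parametrize(
        "sens, spec, expected",
        [(0.90, 0.897, 0.797), (1.0, 1.0, 1.0), (0.85, 0.863, 0.713),
         (0.90, 0.615, 0.515)],
    )
    def test_values(self, sens, spec, expected):
        assert youden_index(sens, spec) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            youden_index(1.2, 0.5)

    def test_perfect_roc_point(self):
        roc = roc_vertical_average(
            scores_frame([5.0, 6.0], [1.0, 2.0]), "s")
        sens, spec, _ = best_operating_point(roc)
        assert sens == pytest.approx(1.0)
        assert spec == pytest.approx(1.0)

    def test_tie_rule_prefers_specificity(self):
        roc = roc_vertical_average(scores_frame([1.0] * 5, [1.0] * 5), "s")
        _, spec, _ = best_operating_point(roc)
        assert spec == pytest.approx(1.0)   # YI flat: highest specificity wins

    def test_max_yi_matches_grid_scan(self, rng):
        df = scores_frame(rng.normal(1, 1, 20), rng.normal(0, 1, 40))
        roc = roc_vertical_average(df, "s")
        brute = max(s + g - 1.0
                    for s, g in zip(roc.sensitivity, roc.specificity))
        assert roc.max_yi == pytest.approx(brute, abs=1e-12)


class TestFalseAlarmRate:
    @pytest.mark.parametrize(
        "spec, expected_count, expected_rate",
        [(0.897, 120.5, 0.72), (0.863, 160.3, 0.95), (0.615, 450.4, 2.68),
         (1.0, 0.0, 0.0)],
    )
    def test_printed_values(self, spec, expected_count, expected_rate):
        count, rate = false_alarm_rate(spec, 1170, 168.0)
        assert round(count, 1) == expected_count
        assert round(rate, 2) == expected_rate

    def test_invalid_hours(self):
        with pytest.raises(InvalidInputError):
            false_alarm_rate(0.9, 1170, 0.0)


def brute_force_wilcoxon(x, y):
    """Literal 2^m sign enumeration (zeros dropped, mid-ranks for ties)."""
    from scipy.stats import rankdata

    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= abs(w_obs - center) - 1e-9:
            count += 1
    return count / 2**m


class TestWilcoxon:
    def test_identical_pairs_give_one(self):
        assert wilcoxon_signed_rank_paired([1, 2, 3, 4, 5],
                                           [1, 2, 3, 4, 5]) == 1.0

    def test_all_positive_differences_n10(self):
        x = np.arange(10) + 1.0
        y = x - np.linspace(0.5, 1.5, 10)
        assert wilcoxon_signed_rank_paired(x, y) == pytest.approx(
            2.0 / 1024.0, abs=1e-12)

    def test_matches_brute_enumeration(self, rng):
        for n in (6, 8, 10, 12):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert wilcoxon_signed_rank_paired(x, y) == pytest.approx(
                brute_force_wilcoxon(x, y), abs=1e-12)

    def test_matches_brute_enumeration_with_ties(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x - np.array([0.5, -0.5, 0.5, 1.0, -1.0, 1.0, 0.0])
        assert wilcoxon_signed_rank_paired(x, y) == pytest.approx(
            brute_force_wilcoxon(x, y), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        expected = wilcoxon(x, y, method="exact").pvalue
        assert wilcoxon_signed_rank_paired(x, y) == pytest.approx(
            expected, abs=1e-12)

    def test_normal_approximation_large_n(self, rng):
        x = rng.normal(0.3, 1.0, 60)
        y = rng.normal(0.0, 1.0, 60)
        p_mine = wilcoxon_signed_rank_paired(x, y)
        p_scipy = wilcoxon(x, y, method="approx", correction=False).pvalue
        assert p_mine == pytest.approx(p_scipy, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            wilcoxon_signed_rank_paired([1, 2], [2, 3])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.002], 2) == [True]
        assert bonferroni([0.152], 2) == [False]
        assert bonferroni([0.05 / 2], 2) == [True]   # boundary inclusive

    def test_m_must_cover_tests(self):
        with pytest.raises(InvalidInputError):
            bonferroni([0.01, 0.02, 0.03], 2)


class TestStatisticProperties:
    """Invariants of the statistics, searched over generated inputs."""

    from hypothesis import given, settings, strategies as st

    @given(sens=st.floats(0, 1), spec=st.floats(0, 1))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_youden_index_bounds(self, sens, spec):
        yi = youden_index(sens, spec)
        assert -1.0 <= yi <= 1.0

    @given(seed=st.integers(0, 2**16), n=st.integers(5, 11))
    @settings(derandomize=True, deadline=None, max_examples=20)
    def test_wilcoxon_symmetric_and_bounded(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        p = wilcoxon_signed_rank_paired(x, y)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(wilcoxon_signed_rank_paired(y, x),
                                  abs=1e-12)
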