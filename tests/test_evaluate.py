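"""Metric implementations vs independent oracles; bootstrap reproducibility."""

import numpy as np
import pytest

from histopatch.evaluate import (
    bootstrap_ci,
    evaluate_cohort,
    metrics_at,
    roc_auc,
    select_threshold,
    slide_score,
)


def _pair_counting_auc(scores, labels):
    """Independent oracle: fraction of positive-negative pairs ranked
    correctly, ties counted half (Mann-Whitney)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_full_tie_is_half(self):
        assert roc_auc([0.6, 0.6], [1, 0]) == 0.5

    def test_single_inversion_example(self):
        # 9 positive-negative pairs, one inverted: 8/9
        auc = roc_auc([0.9, 0.8, 0.4, 0.5, 0.3, 0.2], [1, 1, 1, 0, 0, 0])
        assert auc == pytest.approx(8 / 9, abs=1e-10)

    def test_matches_pair_counting_oracle_on_small_inputs(self, rng):
        # 300 random problems of up to 12 points, discrete scores force ties
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 5, n) / 4.0
            assert roc_auc(scores, labels) == pytest.approx(
                _pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        warped = 1 / (1 + np.exp(-7 * (scores - 0.3)))
        assert roc_auc(scores, labels) == pytest.approx(roc_auc(warped, labels))

    def test_single_class_rejected_with_named_class(self):
        with pytest.raises(ValueError, match="negative"):
            roc_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError, match="positive"):
            roc_auc([0.1, 0.2], [0, 0])


class TestMetricsAt:
    def test_perfect_split(self):
        assert metrics_at([0.9, 0.1], [1, 0], 0.5) == (1.0, 1.0, 1.0, 1.0)

    def test_all_positive_predictions(self):
        f1, acc, sens, spec = metrics_at([0.9, 0.9], [1, 0], 0.5)
        assert (sens, spec, acc) == (1.0, 0.0, 0.5)

    def test_hand_computed_confusion_table(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = [0.9, 0.9, 0.9, 0.1, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        f1, acc, sens, spec = metrics_at(scores, labels, 0.5)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(5 / 6)
        assert acc == pytest.approx(0.8)
        assert f1 == pytest.approx(0.75)

    def test_threshold_rule_is_strict(self):
        # score exactly at the threshold is a negative prediction
        _, _, sens, _ = metrics_at([0.62], [1], 0.62)
        assert sens == 0.0

    def test_undefined_ratio_reported_as_nan(self, caplog):
        with caplog.at_level("WARNING"):
            _, _, sens, _ = metrics_at([0.1, 0.2], [0, 0], 0.5)
        assert np.isnan(sens)

    def test_sensitivity_specificity_monotone_in_threshold(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        sens_list, spec_list = [], []
        for t in np.linspace(0, 1, 21):
            _, _, sens, spec = metrics_at(scores, labels, t)
            sens_list.append(sens)
            spec_list.append(spec)
        assert all(a >= b - 1e-12 for a, b in zip(sens_list, sens_list[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec_list, spec_list[1:]))


class TestSelectThreshold:
    def test_perfectly_separated_returns_highest_optimal_cut(self):
        t = select_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        # J is maximal for any cut in [0.2, 0.8); ties break upward
        assert t == pytest.approx(0.2)
        f1, acc, sens, spec = metrics_at([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], t)
        assert sens == spec == 1.0

    def test_matches_exhaustive_search_with_inversion(self, rng):
        scores = np.array([0.9, 0.55, 0.6, 0.4, 0.3])
        labels = np.array([1, 1, 0, 0, 0])
        t = select_threshold(scores, labels)
        n_pos, n_neg = 2, 3

        def j(cut):
            pred = scores > cut
            return (pred & (labels == 1)).sum() / n_pos + (
                (~pred) & (labels == 0)
            ).sum() / n_neg - 1

        best = max(j(c) for c in scores)
        assert j(t) == pytest.approx(best)

    def test_selected_threshold_reproduces_max_j(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        t = select_threshold(scores, labels)
        _, _, sens, spec = metrics_at(scores, labels, t)
        j_all = []
        for c in np.unique(scores):
            _, _, s1, s2 = metrics_at(scores, labels, c)
            j_all.append(s1 + s2 - 1)
        assert sens + spec - 1 == pytest.approx(max(j_all))


class TestSlideScore:
    def test_max_patch_probability(self):
        assert slide_score([0.1, 0.93, 0.1]) == 0.93
        assert slide_score(np.zeros((4, 4))) == 0.0

    def test_order_invariant(self, rng):
        vals = rng.random(30)
        assert slide_score(vals) == slide_score(vals[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no patch"):
            slide_score([])


class TestBootstrap:
    def test_degenerate_data_zero_width_interval(self):
        lo, hi = bootstrap_ci(lambda d: 0.42, [1, 2, 3], n_boot=50, seed=0)
        assert lo == hi == 0.42

    def test_same_seed_identical_interval(self, rng):
        data = list(rng.random(20))
        f = lambda d: float(np.mean(d))  # noqa: E731
        assert bootstrap_ci(f, data, seed=7) == bootstrap_ci(f, data, seed=7)

    def test_interval_contains_point_estimate_for_mean(self, rng):
        data = list(rng.normal(0.5, 0.05, 200))
        lo, hi = bootstrap_ci(lambda d: float(np.mean(d)), data, n_boot=300, seed=1)
        assert lo <= np.mean(data) <= hi

    def test_failing_replicates_redrawn(self, rng):
        # metric fails when a resample lacks class 1; with few slides this
        # happens often but the interval must still be produced
        data = [(np.array([0.9]), np.array([1]))] + [
            (np.array([0.1]), np.array([0])) for _ in range(3)
        ]

        def auc(sl):
            scores = np.concatenate([s for s, _ in sl])
            labels = np.concatenate([l for _, l in sl])
            return roc_auc(scores, labels)

        lo, hi = bootstrap_ci(auc, data, n_boot=50, seed=3)
        assert 0.0 <= lo <= hi <= 1.0


def test_evaluate_cohort_assembles_report(rng):
    by_slide = {}
    slide_labels = {}
    for i in range(6):
        is_cancer = i % 2
        n = 30
        labels = rng.integers(0, 2, n) if is_cancer else np.zeros(n, int)
        scores = np.clip(labels * 0.6 + rng.random(n) * 0.35, 0, 1)
        by_slide[f"s{i}"] = (scores, labels)
        slide_labels[f"s{i}"] = int(is_cancer)
    report = evaluate_cohort(by_slide, slide_labels, threshold=0.5, n_boot=60, seed=2)
    assert 0.5 < report.patch_auc <= 1.0
    assert report.slide_auc is not None
    assert report.n_slides == 6
    assert set(report.ci) >= {"patch_auc", "f1", "accuracy", "sensitivity", "specificity"}
    lo, hi = report.ci["patch_auc"]
    assert lo <= hi
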