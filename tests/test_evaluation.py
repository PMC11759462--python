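"""One-vs-rest metrics, the Mann–Whitney AUC, and relative corruption error."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from vqfusion.evaluation import (
    CLASSES, MetricReport, PredictionSet, binary_auc, one_vs_rest_metrics,
    predictions_to_frame, relative_corruption_error,
)


def pairwise_concordance_auc(y_true, scores):
    """Exhaustive pair-enumeration oracle: ties count one half."""
    pos = [s for y, s in zip(y_true, scores) if y]
    neg = [s for y, s in zip(y_true, scores) if not y]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def make_preds(labels, scores, tag="none"):
    return PredictionSet(
        case_ids=[f"c{i}" for i in range(len(labels))],
        labels=np.asarray(labels),
        scores=np.asarray(scores, dtype=float),
        perturbation=tag,
    )


class TestBinaryAuc:
    def test_matches_pairwise_oracle_on_small_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, size=n).astype(bool)
            if y.all() or not y.any():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert binary_auc(y, s) == pytest.approx(
                pairwise_concordance_auc(y, s), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        y = rng.integers(0, 2, size=50).astype(bool)
        y[0], y[1] = True, False
        s = rng.random(50)
        assert binary_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=30).astype(bool)
        y[0], y[1] = True, False
        s = rng.random(30)
        for f in (np.exp, np.tanh, lambda x: 3 * x + 7):
            assert binary_auc(y, f(s)) == pytest.approx(binary_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_auc(np.ones(4, dtype=bool), np.arange(4.0))


class TestOneVsRestMetrics:
    def test_perfect_predictions_give_all_ones(self):
        labels = [0, 0, 1, 1, 2, 2]
        scores = np.eye(3)[labels] * 0.9 + 0.05
        scores /= scores.sum(axis=1, keepdims=True)
        report = one_vs_rest_metrics(make_preds(labels, scores))
        for cname in CLASSES:
            for metric, value in report.per_class[cname].items():
                assert value == pytest.approx(1.0), (cname, metric)
        assert report.overall_accuracy == 1.0

    def test_anti_concordant_scores_give_zero_auc(self):
        labels = [0, 0, 1, 2]
        scores = np.array([
            [0.1, 0.5, 0.4],
            [0.2, 0.4, 0.4],
            [0.6, 0.2, 0.2],
            [0.5, 0.3, 0.2],
        ])
        report = one_vs_rest_metrics(make_preds(labels, scores))
        assert report.per_class["low"]["auc"] == 0.0

    def test_six_case_set_matches_hand_computation(self):
        """2 cases per class, one 'medium' case misclassified as 'low'."""
        labels = [0, 0, 1, 1, 2, 2]
        scores = np.array([
            [0.8, 0.1, 0.1],
            [0.7, 0.2, 0.1],
            [0.6, 0.3, 0.1],   # medium predicted low
            [0.1, 0.8, 0.1],
            [0.1, 0.2, 0.7],
            [0.2, 0.2, 0.6],
        ])
        report = one_vs_rest_metrics(make_preds(labels, scores))
        low = report.per_class["low"]
        # low vs rest: predictions low = cases 0,1,2 → TP=2 FP=1 TN=3 FN=0
        assert low["accuracy"] == pytest.approx(5 / 6)
        assert low["precision"] == pytest.approx(2 / 3)
        assert low["recall"] == pytest.approx(1.0)
        assert low["specificity"] == pytest.approx(3 / 4)
        assert low["auc"] == pytest.approx(
            pairwise_concordance_auc([1, 1, 0, 0, 0, 0], scores[:, 0])
        )
        med = report.per_class["medium"]
        assert med["recall"] == pytest.approx(1 / 2)
        for cname in CLASSES:
            assert report.per_class[cname]["auc"] == pytest.approx(
                pairwise_concordance_auc(
                    [l == CLASSES.index(cname) for l in labels],
                    scores[:, CLASSES.index(cname)],
                )
            )

    def test_average_is_unweighted_mean_of_classes(self, rng):
        labels = rng.integers(0, 3, size=30)
        labels[:3] = [0, 1, 2]
        scores = rng.dirichlet(np.ones(3), size=30)
        report = one_vs_rest_metrics(make_preds(labels, scores))
        for metric in ("accuracy", "auc", "recall"):
            expected = np.mean([report.per_class[c][metric] for c in CLASSES])
            assert report.averaged[metric] == pytest.approx(expected, abs=1e-12)

    def test_absent_class_excluded_with_warning(self):
        labels = [0, 0, 1, 1]
        scores = np.tile([0.4, 0.4, 0.2], (4, 1))
        with pytest.warns(UserWarning):
            report = one_vs_rest_metrics(make_preds(labels, scores))
        assert np.isnan(report.per_class["high"]["auc"])
        assert np.isfinite(report.averaged["auc"])

    def test_score_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            make_preds([0, 1], [[0.5, 0.2, 0.2], [0.3, 0.3, 0.4]])


class TestRelativeCorruptionError:
    def test_self_comparison_is_exactly_100(self):
        out = relative_corruption_error(0.9, [0.8, 0.7], 0.9, [0.8, 0.7])
        assert out["rce_percent"] == 100.0
        assert out["rce_ratio"] == 1.0

    def test_half_degradation_gives_50(self):
        out = relative_corruption_error(0.9, [0.85, 0.8], 0.9, [0.8, 0.7])
        assert out["rce_percent"] == pytest.approx(50.0)
        assert out["rce_percent_reversed"] == pytest.approx(200.0)

    def test_hand_computed_grid(self):
        ours = [0.75, 0.72, 0.70]
        other = [0.70, 0.60, 0.62]
        expected = 100 * np.mean([0.05, 0.08, 0.10]) / np.mean([0.10, 0.20, 0.18])
        out = relative_corruption_error(0.80, ours, 0.80, other)
        assert out["rce_percent"] == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_corruption_error(0.9, [0.8], 0.9, [0.9])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            relative_corruption_error(0.9, [0.8, 0.7], 0.9, [0.8])


def test_predictions_frame_round_trips_labels(rng):
    labels = [0, 1, 2]
    scores = np.eye(3) * 0.8 + 0.1 - 0.03333333
    scores = scores / scores.sum(axis=1, keepdims=True)
    preds = make_preds(labels, scores, tag="gaussian@0.05")
    df = predictions_to_frame(preds)
    assert list(df["label"]) == ["low", "medium", "high"]
    assert set(df.columns) >= {"case_id", "p_low", "p_medium", "p_high",
                               "perturbation"}
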