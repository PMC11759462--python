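"""One-vs-rest multiclass metrics and the relative corruption error (RCE).

Each of the three risk classes (low / medium / high) is scored as a binary
problem against the other two combined: confusion-matrix metrics use the
argmax prediction, AUC uses the class's probability column and equals the
probability that a random positive outscores a random negative (ties count
half, i.e. the Mann–Whitney statistic). Class-averaged values are the
unweighted mean over the three classes.

RCE compares robustness between two models over a shared corruption grid:

    RCE = 100 · mean_k(clean_ours − corrupted_ours,k)
              / mean_k(clean_other − corrupted_other,k)

Values below 100 mean "ours" loses less AUC under corruption. Both
orientations (and the raw ratio) are reported, since either model can play
the reference role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CLASSES", "PredictionSet", "MetricReport", "binary_auc",
    "one_vs_rest_metrics", "relative_corruption_error", "predictions_to_frame",
]

CLASSES = ("low", "medium", "high")
_METRICS = ("accuracy", "specificity", "precision", "recall", "auc")


@dataclass
class PredictionSet:
    """Per-case 3-class probabilities with true labels."""

    case_ids: list[str]
    labels: np.ndarray           # ints in {0,1,2} indexing CLASSES
    scores: np.ndarray           # (n, 3) rows summing to 1
    perturbation: str = "none"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.case_ids), 3):
            raise ValueError("scores must be (n_cases, 3)")
        if (self.scores < -1e-9).any():
            raise ValueError("scores must be nonnegative")
        sums = self.scores.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each score row must sum to 1 (±1e-6)")


@dataclass
class MetricReport:
    per_class: dict[str, dict[str, float]]
    averaged: dict[str, float]
    n_per_class: dict[str, int]
    overall_accuracy: float
    perturbation: str = "none"

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(**{"class": c}, **m) for c, m in self.per_class.items()]
        rows.append(dict(**{"class": "average"}, **self.averaged))
        return pd.DataFrame(rows)


def binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + ½·P(tie)."""
    y_true = np.asarray(y_true, dtype=bool)
    n_pos, n_neg = int(y_true.sum()), int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def one_vs_rest_metrics(preds: PredictionSet) -> MetricReport:
    """Per-class and class-averaged accuracy/specificity/precision/recall/AUC."""
    labels, scores = preds.labels, preds.scores
    pred_class = scores.argmax(axis=1)
    n = len(labels)
    per_class: dict[str, dict[str, float]] = {}
    n_per_class: dict[str, int] = {}
    for ci, cname in enumerate(CLASSES):
        pos = labels == ci
        n_per_class[cname] = int(pos.sum())
        if pos.sum() == 0 or pos.sum() == n:
            warnings.warn(
                f"class '{cname}' absent (or alone); metrics undefined, "
                "excluded from the average"
            )
            per_class[cname] = {m: float("nan") for m in _METRICS}
            continue
        ppos = pred_class == ci
        tp = int((ppos & pos).sum())
        fp = int((ppos & ~pos).sum())
        tn = int((~ppos & ~pos).sum())
        fn = int((~ppos & pos).sum())
        per_class[cname] = {
            "accuracy": (tp + tn) / n,
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn),
            "auc": binary_auc(pos, scores[:, ci]),
        }
    averaged = {}
    for m in _METRICS:
        vals = [v[m] for v in per_class.values() if np.isfinite(v[m])]
        averaged[m] = float(np.mean(vals)) if vals else float("nan")
    return MetricReport(
        per_class=per_class,
        averaged=averaged,
        n_per_class=n_per_class,
        overall_accuracy=float((pred_class == labels).mean()),
        perturbation=preds.perturbation,
    )


def relative_corruption_error(
    clean_auc_ours: float,
    perturbed_aucs_ours: list[float] | np.ndarray,
    clean_auc_other: float,
    perturbed_aucs_other: list[float] | np.ndarray,
) -> dict[str, float]:
    """RCE (%) of "ours" against "other" over a shared corruption grid."""
    ours = np.asarray(perturbed_aucs_ours, dtype=np.float64)
    other = np.asarray(perturbed_aucs_other, dtype=np.float64)
    if ours.shape != other.shape or ours.size == 0:
        raise ValueError("both models need the same nonempty perturbation grid")
    num = float(np.mean(clean_auc_ours - ours))
    den = float(np.mean(clean_auc_other - other))
    if den == 0.0:
        raise ZeroDivisionError("reference model shows zero mean degradation")
    return {
        "rce_percent": 100.0 * num / den,
        "rce_ratio": num / den,
        "rce_percent_reversed": 100.0 * den / num if num != 0 else float("inf"),
        "mean_degradation_ours": num,
        "mean_degradation_other": den,
    }


def predictions_to_frame(preds: PredictionSet) -> pd.DataFrame:
    """CSV-ready frame: case id, label, p_low, p_medium, p_high, perturbation."""
    return pd.DataFrame({
        "case_id": preds.case_ids,
        "label": [CLASSES[i] for i in preds.labels],
        "p_low": preds.scores[:, 0],
        "p_medium": preds.scores[:, 1],
        "p_high": preds.scores[:, 2],
        "perturbation": preds.perturbation,
    })
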