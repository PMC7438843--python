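"""Majority-voting ensemble and performance summaries.

With three binary voters a majority always exists, so the ensemble label is
simply the class predicted by at least two classifiers. The ensemble's
continuous score (needed for an AUC) is the arithmetic mean of the three
classifier scores by default; a discrete vote-fraction alternative is also
provided. Held-out predictions are pooled within each repeat
(micro-average), scored, and the point estimates reported as means over
repeats, keeping the per-repeat AUC vectors for distributional comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .classify import CVConfig
from .errors import ValidationError

CLASSIFIER_ORDER = ("rf", "svm", "knn", "voting")
METRIC_ORDER = ("accuracy", "specificity", "sensitivity", "auc")


def majority_vote(labels_rf, labels_svm, labels_knn) -> np.ndarray:
    """Per-sample class held by at least two of the three classifiers."""
    a, b, c = (np.asarray(v, dtype=int) for v in (labels_rf, labels_svm, labels_knn))
    if not (a.shape == b.shape == c.shape):
        raise ValidationError("vote vectors must have equal length")
    for v in (a, b, c):
        if np.any((v != 0) & (v != 1)):
            raise ValidationError("vote vectors must be binary 0/1")
    return ((a + b + c) >= 2).astype(int)


def voting_score(score_rf, score_svm, score_knn) -> np.ndarray:
    """Ensemble continuous score: arithmetic mean of the three scores."""
    stacked = np.vstack(
        [np.asarray(s, dtype=float) for s in (score_rf, score_svm, score_knn)]
    )
    if np.any(stacked < 0) or np.any(stacked > 1):
        raise ValidationError("classifier scores must lie in [0, 1]")
    return stacked.mean(axis=0)


def vote_fraction(labels_rf, labels_svm, labels_knn) -> np.ndarray:
    """Alternative ensemble score: fraction of positive votes (0, 1/3, 2/3, 1)."""
    a, b, c = (np.asarray(v, dtype=int) for v in (labels_rf, labels_svm, labels_knn))
    return (a + b + c) / 3.0


def compute_metrics(predicted_labels, scores, truth) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, and rank-based AUC.

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative, counting ties as one half; it requires both classes in
    the truth vector.
    """
    y_pred = np.asarray(predicted_labels, dtype=int)
    y_score = np.asarray(scores, dtype=float)
    y_true = np.asarray(truth, dtype=int)
    if np.unique(y_true).size < 2:
        raise ValidationError("AUC is undefined when truth contains a single class")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "auc": float(roc_auc_score(y_true, y_score)),
    }


@dataclass
class PerformanceSummary:
    """Mean metrics per classifier plus the per-repeat AUC distributions.

    ``table`` has metric rows (accuracy, specificity, sensitivity, auc) and
    one column per classifier including "voting"; ``auc_distribution`` maps
    each classifier to its length-n_repeats AUC vector.
    """

    table: pd.DataFrame
    auc_distribution: dict[str, np.ndarray]

    @property
    def voting_auc(self) -> float:
        return float(self.table.loc["auc", "voting"])


def add_voting_predictions(
    fold_predictions: pd.DataFrame, include_vote_fraction: bool = False
) -> pd.DataFrame:
    """Append "voting" rows (majority label, mean score) to tidy predictions.

    With ``include_vote_fraction``, a second ensemble entry
    "voting_fraction" is appended whose score is the discrete fraction of
    positive votes, for comparing the two ensemble-score constructions.
    """
    required = {"rf", "svm", "knn"}
    present = set(fold_predictions["classifier"].unique())
    if not required <= present:
        raise ValidationError(f"voting needs classifiers {sorted(required)}, got {sorted(present)}")
    wide_label = fold_predictions.pivot_table(
        index=["repeat", "sample"], columns="classifier", values="label"
    )
    wide_score = fold_predictions.pivot_table(
        index=["repeat", "sample"], columns="classifier", values="score"
    )
    if wide_label[["rf", "svm", "knn"]].isna().any().any():
        raise ValidationError("incomplete fold predictions: a classifier is missing samples")
    base = fold_predictions[fold_predictions["classifier"] == "rf"].set_index(
        ["repeat", "sample"]
    )
    # align the pivoted (sorted) frames to the base row order
    wide_label = wide_label.loc[base.index]
    wide_score = wide_score.loc[base.index]
    voting = pd.DataFrame(
        {
            "fold": base["fold"],
            "classifier": "voting",
            "truth": base["truth"],
            "label": majority_vote(
                wide_label["rf"].to_numpy(),
                wide_label["svm"].to_numpy(),
                wide_label["knn"].to_numpy(),
            ),
            "score": voting_score(
                wide_score["rf"].to_numpy(),
                wide_score["svm"].to_numpy(),
                wide_score["knn"].to_numpy(),
            ),
        },
        index=base.index,
    ).reset_index()
    parts = [fold_predictions, voting]
    if include_vote_fraction:
        fraction = voting.copy()
        fraction["classifier"] = "voting_fraction"
        fraction["score"] = vote_fraction(
            wide_label["rf"].to_numpy(),
            wide_label["svm"].to_numpy(),
            wide_label["knn"].to_numpy(),
        )
        parts.append(fraction)
    return pd.concat(parts, ignore_index=True)


def summarize_run(fold_predictions: pd.DataFrame, cv_config: CVConfig | None = None) -> PerformanceSummary:
    """Score pooled held-out predictions per repeat and average over repeats.

    Within a repeat every sample is held out exactly once, so pooling folds
    gives one prediction per sample; the four metrics are computed on that
    pool, then averaged across repeats. Raises if any repeat is incomplete.
    """
    preds = fold_predictions
    if "voting" not in set(preds["classifier"].unique()):
        preds = add_voting_predictions(preds)
    n_samples = preds["sample"].nunique()
    per_repeat: dict[str, list[dict]] = {}
    for (rep, clf), group in preds.groupby(["repeat", "classifier"], sort=True):
        if group.shape[0] != n_samples or group["sample"].nunique() != n_samples:
            raise ValidationError(
                f"repeat {rep}, classifier {clf}: expected {n_samples} pooled held-out "
                f"predictions, got {group.shape[0]}"
            )
        per_repeat.setdefault(clf, []).append(
            compute_metrics(group["label"], group["score"], group["truth"])
        )
    if cv_config is not None:
        for clf, rows in per_repeat.items():
            if len(rows) != cv_config.n_repeats:
                raise ValidationError(
                    f"classifier {clf}: {len(rows)} repeats summarized, expected {cv_config.n_repeats}"
                )
    columns = [c for c in CLASSIFIER_ORDER if c in per_repeat] + [
        c for c in per_repeat if c not in CLASSIFIER_ORDER
    ]
    table = pd.DataFrame(
        {
            clf: {m: float(np.mean([r[m] for r in per_repeat[clf]])) for m in METRIC_ORDER}
            for clf in columns
        }
    ).loc[list(METRIC_ORDER), columns]
    auc_distribution = {
        clf: np.array([r["auc"] for r in per_repeat[clf]]) for clf in columns
    }
    return PerformanceSummary(table=table, auc_distribution=auc_distribution)
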