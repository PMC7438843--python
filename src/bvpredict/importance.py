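"""Variable importance per classifier and the rank-averaged ensemble ranking.

Each classifier gets its own importance criterion: permutation importance
(mean decrease in held-out accuracy) for the random forest, backward
recursive feature elimination by cross-validated accuracy for the SVM, and
leave-one-feature-out accuracy degradation for KNN (a defined, testable
surrogate for the "support" criterion, whose original construction is not
reconstructable). Each criterion yields an integer rank per feature
(1 = most important). The ensemble "voting" rank orders features by the mean
of the three ranks; ties are broken by the best (minimum) single-classifier
rank, then by label order.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, _SEED_MOD, _build_estimator, fit_predict
from .errors import ValidationError

RANK_COLUMNS = ("rank_knn", "rank_rf", "rank_svm")


def _ordinal_ranks(importances: np.ndarray) -> np.ndarray:
    """Descending-importance ranks 1..p; ties resolved by feature order."""
    return rankdata(-np.asarray(importances, dtype=float), method="ordinal").astype(int)


def _cv_splits(y: np.ndarray, n_folds: int, seed: int):
    n_folds = min(n_folds, int(np.unique(y, return_counts=True)[1].min()))
    if n_folds < 2:
        raise ValidationError("too few samples per class for importance cross-validation")
    splitter = StratifiedKFold(n_folds, shuffle=True, random_state=seed % _SEED_MOD)
    return list(splitter.split(np.zeros(y.shape[0]), y))


def _cv_accuracy(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, splits, seed: int) -> float:
    accs = []
    for tr, te in splits:
        labels, _ = fit_predict(spec, {}, X[tr], y[tr], X[te], seed=seed)
        accs.append(float(np.mean(labels == y[te])))
    return float(np.mean(accs))


def rf_importance(
    features,
    labels,
    spec: ClassifierSpec,
    seed: int = 0,
    n_folds: int = 5,
    n_shuffles: int = 10,
) -> np.ndarray:
    """Rank features by permutation importance of a random forest.

    Within each of ``n_folds`` stratified folds the forest is fit on the
    training part and each feature column of the held-out part is shuffled
    ``n_shuffles`` times; the mean decrease in held-out accuracy, averaged
    over folds, is the importance. Larger decrease = better (smaller) rank.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    splits = _cv_splits(y, n_folds, seed)
    drops = np.zeros(X.shape[1])
    for tr, te in splits:
        est = _build_estimator(spec.kind, dict(spec.fixed_params), seed)
        est.fit(X[tr], y[tr])  # one fit per fold; permutations only re-predict
        base_acc = float(np.mean(est.predict(X[te]) == y[te]))
        for j in range(X.shape[1]):
            for _ in range(n_shuffles):
                X_perm = X[te].copy()
                X_perm[:, j] = rng.permutation(X_perm[:, j])
                perm_acc = float(np.mean(est.predict(X_perm) == y[te]))
                drops[j] += (base_acc - perm_acc) / (n_shuffles * len(splits))
    return _ordinal_ranks(drops)


def svm_rfe_importance(
    features,
    labels,
    spec: ClassifierSpec,
    seed: int = 0,
    n_folds: int = 3,
) -> np.ndarray:
    """Rank features by backward recursive elimination of the SVM.

    At each step, every remaining feature is tentatively removed and the
    cross-validated accuracy of the SVM on the reduced set measured; the
    feature whose removal degrades performance least is eliminated. The
    elimination order, reversed, gives the ranks: the last survivor is
    rank 1, the first feature removed is rank p.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    p = X.shape[1]
    if p < 2:
        raise ValidationError("recursive elimination needs at least 2 features")
    splits = _cv_splits(y, n_folds, seed)
    active = list(range(p))
    ranks = np.zeros(p, dtype=int)
    next_rank = p
    while len(active) > 1:
        best_feature, best_score = None, -np.inf
        for f in active:
            reduced = [g for g in active if g != f]
            score = _cv_accuracy(spec, X[:, reduced], y, splits, seed)
            if score > best_score:
                best_feature, best_score = f, score
        ranks[best_feature] = next_rank
        next_rank -= 1
        active.remove(best_feature)
    ranks[active[0]] = 1
    return ranks


def knn_importance(
    features,
    labels,
    spec: ClassifierSpec,
    seed: int = 0,
    n_folds: int = 5,
) -> np.ndarray:
    """Rank features by leave-one-feature-out KNN accuracy degradation.

    Each feature's importance is the drop in cross-validated KNN accuracy
    when that single feature is withheld (largest drop = rank 1).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    p = X.shape[1]
    if p < 2:
        raise ValidationError("leave-one-feature-out needs at least 2 features")
    splits = _cv_splits(y, n_folds, seed)
    base = _cv_accuracy(spec, X, y, splits, seed)
    drops = np.array(
        [
            base - _cv_accuracy(spec, np.delete(X, j, axis=1), y, splits, seed)
            for j in range(p)
        ]
    )
    return _ordinal_ranks(drops)


def average_ranks(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate three per-classifier rank columns into the voting rank.

    ``rank_table`` is indexed by feature label with integer columns
    rank_knn, rank_rf, rank_svm (1 = most important; the columns may come
    from a top-k subset, so they need not be permutations of 1..k). Adds
    mean_rank and voting_rank, where voting_rank orders features by
    ascending mean rank, breaking ties by the minimum single-classifier
    rank and then by label order.
    """
    missing = [c for c in RANK_COLUMNS if c not in rank_table.columns]
    if missing:
        raise ValidationError(f"rank table missing columns: {missing}")
    table = rank_table.copy()
    for col in RANK_COLUMNS:
        values = table[col]
        if values.isna().any():
            raise ValidationError(f"rank column {col!r} has missing entries")
        if (values < 1).any() or (values != values.astype(int)).any():
            raise ValidationError(f"rank column {col!r} must hold positive integers")
    table["mean_rank"] = table[list(RANK_COLUMNS)].mean(axis=1)
    min_rank = table[list(RANK_COLUMNS)].min(axis=1)
    order = sorted(
        range(table.shape[0]),
        key=lambda i: (table["mean_rank"].iloc[i], min_rank.iloc[i], str(table.index[i])),
    )
    voting = np.empty(table.shape[0], dtype=int)
    voting[order] = np.arange(1, table.shape[0] + 1)
    table["voting_rank"] = voting
    return table


def ensemble_importance(
    features,
    labels,
    specs: Mapping[str, ClassifierSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Full importance table: three per-classifier rankings plus voting rank.

    ``specs`` must provide "rf", "svm" and "knn" classifier specs (their
    fixed_params are used; grids are ignored here). Computed on the supplied
    training set — typically the resampled training set the models saw.
    """
    frame = features.values if hasattr(features, "values") and hasattr(features, "feature_labels") else features
    if isinstance(frame, pd.DataFrame):
        feature_labels = frame.columns.tolist()
        X = frame.to_numpy(dtype=float)
    else:
        X = np.asarray(frame, dtype=float)
        feature_labels = [f"feature_{j + 1}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    table = pd.DataFrame(
        {
            "rank_knn": knn_importance(X, y, specs["knn"], seed=seed),
            "rank_rf": rf_importance(X, y, specs["rf"], seed=seed),
            "rank_svm": svm_rfe_importance(X, y, specs["svm"], seed=seed),
        },
        index=pd.Index(feature_labels, name="feature"),
    )
    return average_ranks(table)


def top_k_overlap(table: pd.DataFrame, k: int = 20) -> dict[str, list[str]]:
    """Venn-style listing of top-k features per classifier and their overlap."""
    tops = {col: set(table.index[table[col] <= k]) for col in RANK_COLUMNS}
    shared = set.intersection(*tops.values())
    listing = {col: sorted(tops[col]) for col in RANK_COLUMNS}
    listing["shared_all"] = sorted(shared)
    return listing
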