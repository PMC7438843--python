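"""Class rebalancing: SMOTE oversampling plus random majority undersampling.

Incident BV occurs in roughly a third of couples, so a classifier trained on
the raw cohort is biased toward the persistently negative majority. SMOTE
(Chawla-style) synthesizes minority points on the segment between a minority
sample and one of its k nearest minority neighbors; the majority class is
then randomly thinned. Every synthetic row is flagged, and its parent pair
is recorded so the convex-combination contract can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

RESAMPLE_MODES = ("pre_cv", "within_fold")


@dataclass
class ResampleConfig:
    """SMOTE / undersampling settings.

    smote_percent: synthetic minority points as a percentage of the minority
        size (100 doubles the minority; 0 is a no-op).
    k_neighbors: neighborhood size for SMOTE interpolation (must be smaller
        than the minority class).
    majority_target: majority rows to keep; "balanced" means the size of the
        augmented minority. An explicit integer reproduces published counts.
    mode: "pre_cv" resamples the full training set once before repeated
        cross-validation (faithful to the original analysis); "within_fold"
        resamples each training partition only, so held-out samples are all
        original — the leakage-free variant used for calibration.
    """

    smote_percent: float = 100
    k_neighbors: int = 5
    majority_target: Union[int, str] = "balanced"
    seed: int = 0
    mode: str = "pre_cv"

    def __post_init__(self) -> None:
        if self.smote_percent < 0:
            raise ValidationError(f"smote_percent must be >= 0, got {self.smote_percent}")
        if self.k_neighbors < 1:
            raise ValidationError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if isinstance(self.majority_target, str) and self.majority_target != "balanced":
            raise ValidationError(
                f'majority_target must be a positive integer or "balanced", got {self.majority_target!r}'
            )
        if isinstance(self.majority_target, int) and self.majority_target < 1:
            raise ValidationError(f"majority_target must be >= 1, got {self.majority_target}")
        if self.mode not in RESAMPLE_MODES:
            raise ValidationError(f"mode must be one of {RESAMPLE_MODES}, got {self.mode!r}")


@dataclass
class ResampledTrainingSet:
    """Feature matrix + labels after rebalancing, with per-row provenance.

    ``provenance`` holds "original" or "synthetic" per row; ``parents`` holds,
    for each synthetic row, the positional indices (into the ORIGINAL input)
    of the base minority sample and the neighbor it was interpolated toward.
    """

    features: pd.DataFrame
    labels: np.ndarray
    provenance: np.ndarray
    parents: Optional[np.ndarray] = None

    @property
    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    arr = np.asarray(features, dtype=float)
    return pd.DataFrame(arr)


def smote_oversample(features, labels, config: ResampleConfig) -> ResampledTrainingSet:
    """Augment the minority class with SMOTE-interpolated synthetic samples.

    Synthesizes round(smote_percent/100 * minority size) points. Base points
    cycle through the minority class (each used floor(n_syn / n_min) times,
    with the remainder chosen at random without replacement); for each, one
    of its k nearest minority neighbors (Euclidean distance, self excluded)
    is picked uniformly and the new point is x + u * (x' - x), u ~ U(0, 1).
    """
    frame = _as_frame(features)
    y = np.asarray(labels, dtype=int)
    if frame.shape[0] != y.shape[0]:
        raise ValidationError("features and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("SMOTE requires both classes present")
    minority_label = int(classes[np.argmin(counts)])
    minority_idx = np.flatnonzero(y == minority_label)
    n_min = minority_idx.size
    if n_min <= config.k_neighbors:
        raise ValidationError(
            f"minority class has {n_min} samples but k_neighbors={config.k_neighbors}; "
            "lower k_neighbors below the minority class size"
        )

    n_syn = int(round(config.smote_percent / 100 * n_min))
    if n_syn == 0:
        return ResampledTrainingSet(
            features=frame.copy(),
            labels=y.copy(),
            provenance=np.full(y.shape[0], "original", dtype=object),
            parents=np.empty((0, 2), dtype=int),
        )

    rng = np.random.default_rng(config.seed)
    X = frame.to_numpy(dtype=float)
    X_min = X[minority_idx]
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(X_min)
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self

    reps = n_syn // n_min
    base = np.tile(np.arange(n_min), reps)
    remainder = n_syn - reps * n_min
    if remainder:
        base = np.concatenate([base, rng.choice(n_min, size=remainder, replace=False)])

    chosen = neighbor_idx[base, rng.integers(0, config.k_neighbors, size=n_syn)]
    gaps = rng.uniform(0.0, 1.0, size=n_syn)[:, None]
    synthetic = X_min[base] + gaps * (X_min[chosen] - X_min[base])

    syn_frame = pd.DataFrame(
        synthetic,
        columns=frame.columns,
        index=[f"synthetic_{i + 1}" for i in range(n_syn)],
    )
    out_features = pd.concat([frame, syn_frame], axis=0)
    out_labels = np.concatenate([y, np.full(n_syn, minority_label, dtype=int)])
    provenance = np.concatenate(
        [np.full(y.shape[0], "original", dtype=object), np.full(n_syn, "synthetic", dtype=object)]
    )
    parents = np.column_stack([minority_idx[base], minority_idx[chosen]])
    return ResampledTrainingSet(out_features, out_labels, provenance, parents)


def undersample_majority(training_set: ResampledTrainingSet, config: ResampleConfig) -> ResampledTrainingSet:
    """Thin the majority class to ``majority_target`` rows without replacement.

    Minority rows (original and synthetic) are untouched and provenance is
    preserved. "balanced" targets the size of the augmented minority class.
    """
    y = training_set.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training set must contain both classes")
    majority_label = int(classes[np.argmax(counts)])
    majority_size = int(counts.max())

    target = config.majority_target
    if target == "balanced":
        target = int(counts.min())
    if target < 1:
        raise ValidationError("majority_target would leave a single-class training set")
    if target > majority_size:
        raise ValidationError(
            f"majority_target={target} exceeds current majority size {majority_size}"
        )

    rng = np.random.default_rng(config.seed + 1)
    majority_pos = np.flatnonzero(y == majority_label)
    keep_majority = np.sort(rng.choice(majority_pos, size=target, replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(y != majority_label), keep_majority]))

    # remap parent indices is unnecessary: parents index the ORIGINAL input
    return ResampledTrainingSet(
        features=training_set.features.iloc[keep],
        labels=y[keep],
        provenance=training_set.provenance[keep],
        parents=training_set.parents,
    )


def rebalance(features, labels, config: ResampleConfig) -> ResampledTrainingSet:
    """SMOTE oversampling followed by majority undersampling."""
    return undersample_majority(smote_oversample(features, labels, config), config)
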