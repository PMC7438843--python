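"""Compositional preprocessing: taxon filtering, zero imputation, CLR, min-max.

Raw 16S read counts are compositional: only relative abundances carry
information, and the data are sparse (many true and sampling zeros). The
pipeline therefore (1) drops taxa contributing less than a small fraction of
all reads at a site, (2) replaces zeros with sub-count draws from
Uniform(0.5, 0.95) so logarithms are defined, (3) applies the centered
log-ratio transform per sample, and (4) min-max rescales each feature to
[0, 1] so that distance-based learners weight features comparably.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

VALID_SITES = ("meatal", "glans_coronal_sulcus", "other")

CIRCUMCISION_FEATURE = "Circumcised"


@dataclass
class TaxaCountTable:
    """Samples x taxa integer read counts for one anatomic site.

    ``counts`` is a DataFrame indexed by sample id with taxon labels as
    columns. Duplicate sample ids or taxon labels are rejected, as are
    negative, non-finite, or non-integer counts.
    """

    counts: pd.DataFrame
    site: str = "other"

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise ValidationError(
                f"unknown site {self.site!r}; expected one of {VALID_SITES}"
            )
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon labels: {dups}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.isfinite(values)):
                    raise ValidationError("counts contain non-finite values")
                if np.any(values != np.floor(values)):
                    raise ValidationError("counts contain non-integer values")
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if np.any(values < 0):
                raise ValidationError("counts contain negative values")

    @property
    def sample_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def taxon_labels(self) -> list:
        return self.counts.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]


@dataclass
class FeatureMatrix:
    """Samples x features real-valued matrix (post CLR and/or min-max)."""

    values: pd.DataFrame

    @property
    def feature_labels(self) -> list:
        return self.values.columns.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.index.tolist()


@dataclass
class PreprocessConfig:
    """Knobs for the count -> feature-matrix pipeline.

    min_fraction: a taxon is kept iff it contributes at least this fraction
        of the table's grand total of reads (default 1e-4, i.e. 0.01%).
    impute_low/impute_high: bounds of the uniform draw replacing zeros.
    include_circumcision: append a 0/1 circumcision-status feature.
    strict_normalization: defer min-max scaling to cross-validation time,
        fitting the column statistics on each training partition only
        (the default fits them once over all samples, reproducing the
        original procedure).
    """

    min_fraction: float = 1e-4
    impute_low: float = 0.5
    impute_high: float = 0.95
    seed: int = 0
    include_circumcision: bool = True
    strict_normalization: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.impute_low < self.impute_high < 1):
            raise ValidationError(
                "require 0 < impute_low < impute_high < 1, got "
                f"({self.impute_low}, {self.impute_high})"
            )
        if not (0 <= self.min_fraction < 1):
            raise ValidationError(f"min_fraction must be in [0, 1), got {self.min_fraction}")


def filter_taxa(table: TaxaCountTable, min_fraction: float = 1e-4) -> TaxaCountTable:
    """Keep taxa contributing at least ``min_fraction`` of all reads.

    The threshold is inclusive and computed against the grand total over every
    sample in the table (one anatomic site per table), so the decision for a
    taxon depends only on raw counts and is idempotent under re-filtering.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValidationError("cannot filter an empty count table")
    grand_total = int(table.counts.to_numpy().sum())
    col_sums = table.counts.sum(axis=0)
    keep = col_sums >= min_fraction * grand_total
    if not bool(keep.any()):
        raise ValidationError(
            f"filtering at min_fraction={min_fraction} removed every taxon"
        )
    return replace(table, counts=table.counts.loc[:, keep])


def impute_zeros(table: TaxaCountTable, config: PreprocessConfig) -> pd.DataFrame:
    """Replace each zero count by an independent Uniform(low, high) draw.

    Non-zero counts pass through unchanged; the result is strictly positive
    and safe to log. Draws are deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    values = table.counts.to_numpy().astype(float)
    zero_mask = values == 0
    values[zero_mask] = rng.uniform(config.impute_low, config.impute_high, size=int(zero_mask.sum()))
    return pd.DataFrame(values, index=table.counts.index, columns=table.counts.columns)


def clr_transform(matrix: pd.DataFrame) -> FeatureMatrix:
    """Centered log-ratio transform, row-wise: ln(x_i) - mean_j ln(x_j).

    Rows map to the zero-sum hyperplane; the transform is invariant to
    per-sample scaling, which removes sequencing-depth effects.
    """
    values = np.asarray(matrix, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot CLR-transform an empty matrix")
    if np.any(values <= 0):
        raise ValidationError(
            "CLR requires strictly positive entries; impute zeros first"
        )
    logs = np.log(values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return FeatureMatrix(pd.DataFrame(clr, index=matrix.index, columns=matrix.columns))


def minmax_normalize(features: FeatureMatrix) -> FeatureMatrix:
    """Rescale each feature column to [0, 1]: (x - min) / (max - min).

    Statistics are taken over all samples in the matrix. A constant column
    (max == min) maps to all zeros rather than dividing by zero; such a
    column is uninformative either way.
    """
    values = features.values.to_numpy(dtype=float)
    if values.shape[0] < 1:
        raise ValidationError("min-max normalization needs at least one sample")
    col_min = values.min(axis=0)
    col_max = values.max(axis=0)
    span = col_max - col_min
    safe_span = np.where(span == 0, 1.0, span)
    scaled = (values - col_min) / safe_span
    scaled[:, span == 0] = 0.0
    return FeatureMatrix(
        pd.DataFrame(scaled, index=features.values.index, columns=features.values.columns)
    )


def assemble_features(
    table: TaxaCountTable,
    records: Sequence,
    config: PreprocessConfig,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Full preprocessing for a built cohort: filter -> impute -> CLR -> min-max.

    ``records`` are cohort CoupleRecords with outcomes already derived and
    restricted to the retained couples (one count row per couple, matched by
    couple id). If ``config.include_circumcision``, a binary circumcision
    feature is appended after normalization (it is already in [0, 1]).

    With ``config.strict_normalization`` the min-max step is skipped here
    (the returned values are raw CLR coordinates, unbounded); scaling is
    then fitted per training partition during cross-validation.

    Returns the feature matrix and the 0/1 outcome labels aligned to its rows.
    """
    from .cohort import Outcome  # deferred to avoid an import cycle

    by_id = {r.couple_id: r for r in records}
    missing = [sid for sid in table.sample_ids if sid not in by_id]
    if missing:
        raise ValidationError(f"count rows without a cohort record: {missing}")
    labels = np.empty(table.n_samples, dtype=int)
    circumcised = np.empty(table.n_samples, dtype=float)
    for i, sid in enumerate(table.sample_ids):
        rec = by_id[sid]
        if rec.outcome == Outcome.INCIDENT:
            labels[i] = 1
        elif rec.outcome == Outcome.PERSISTENT_NEGATIVE:
            labels[i] = 0
        else:
            raise ValidationError(
                f"couple {rec.couple_id!r} has outcome {rec.outcome}; "
                "build the cohort before assembling features"
            )
        circumcised[i] = 1.0 if rec.circumcised else 0.0

    filtered = filter_taxa(table, config.min_fraction)
    imputed = impute_zeros(filtered, config)
    clr = clr_transform(imputed)
    normalized = clr if config.strict_normalization else minmax_normalize(clr)
    values = normalized.values
    if config.include_circumcision:
        values = values.copy()
        values[CIRCUMCISION_FEATURE] = circumcised
    return FeatureMatrix(values), labels
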