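"""Reading and writing the pipeline's tab/comma-separated file formats.

Count tables: first column sample id, header row of taxon labels, integer
cells. Metadata: columns couple_id, circumcised (0/1), nugent_m0, nugent_m1,
nugent_m6, nugent_m12 (follow-ups may be blank, meaning the visit was
missed). Output tables end with a comment line naming the configuration
hash so every file is traceable to the run that wrote it; readers skip
``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import FOLLOWUP_MONTHS, CoupleRecord
from .errors import ValidationError
from .preprocess import FeatureMatrix, TaxaCountTable

_METADATA_NUGENT_COLS = {0: "nugent_m0", 1: "nugent_m1", 6: "nugent_m6", 12: "nugent_m12"}


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping (canonical JSON, sha256)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _detect_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValidationError(f"{path}: empty file")


def _append_hash(path, hash_value: str | None) -> None:
    if hash_value:
        with open(path, "a") as fh:
            fh.write(f"# config: {hash_value}\n")


def read_count_table(path, site: str = "other") -> TaxaCountTable:
    """Parse a samples x taxa count table, validating integer counts."""
    sep = _detect_sep(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if frame.shape[0] == 0:
        raise ValidationError(f"{path}: no samples (header-only file)")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate taxon labels {dups}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    for col in numeric.columns:
        values = numeric[col]
        bad = values.isna() | (values != np.floor(values.fillna(0)))
        if bad.any():
            sid = frame.index[bad.to_numpy()][0]
            raw = frame.loc[sid, col]
            raise ValidationError(
                f"{path}: non-integer count {raw!r} at sample {sid!r}, taxon {col!r}"
            )
    return TaxaCountTable(numeric.astype(np.int64), site=site)


def write_count_table(table: TaxaCountTable, path, sep: str = "\t") -> None:
    frame = table.counts.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=sep)


def read_metadata(path) -> list[CoupleRecord]:
    """Parse couple metadata; blank follow-up scores mean the visit is absent."""
    sep = _detect_sep(path)
    try:
        frame = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    for required in ("couple_id", "circumcised", "nugent_m0"):
        if required not in frame.columns:
            raise ValidationError(f"{path}: missing required column {required!r}")
    records = []
    for _, row in frame.iterrows():
        visits: dict[int, int] = {}
        for month, col in _METADATA_NUGENT_COLS.items():
            if col not in frame.columns:
                continue
            value = row[col]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            number = float(value)
            if number != int(number):
                raise ValidationError(
                    f"{path}: couple {row['couple_id']!r}: Nugent score {value!r} "
                    f"in {col} is not an integer"
                )
            visits[month] = int(number)
        records.append(
            CoupleRecord(
                couple_id=str(row["couple_id"]),
                circumcised=bool(int(row["circumcised"])),
                nugent_by_visit=visits,
            )
        )
    return records


def write_metadata(records: Sequence[CoupleRecord], path, sep: str = "\t") -> None:
    rows = []
    for r in records:
        row = {"couple_id": r.couple_id, "circumcised": int(r.circumcised)}
        for month, col in _METADATA_NUGENT_COLS.items():
            row[col] = r.nugent_by_visit.get(month, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_feature_matrix(
    features: FeatureMatrix,
    path,
    labels: np.ndarray | None = None,
    provenance: np.ndarray | None = None,
    hash_value: str | None = None,
) -> None:
    """Write a feature matrix, optionally with label and provenance columns."""
    frame = features.values.copy() if isinstance(features, FeatureMatrix) else features.copy()
    if labels is not None:
        frame["label"] = np.asarray(labels, dtype=int)
    if provenance is not None:
        frame["provenance"] = provenance
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")
    _append_hash(path, hash_value)


def read_feature_matrix(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = None
    if "label" in frame.columns:
        labels = frame.pop("label").to_numpy(dtype=int)
    frame.drop(columns=[c for c in ("provenance",) if c in frame.columns], inplace=True)
    return frame, labels


def write_performance_summary(table: pd.DataFrame, path, hash_value: str | None = None) -> None:
    out = table.copy()
    out.index.name = "metric"
    out.to_csv(path, sep="\t", float_format="%.6f")
    _append_hash(path, hash_value)


def write_importance_table(table: pd.DataFrame, path, hash_value: str | None = None) -> None:
    out = table.sort_values("voting_rank")
    out.to_csv(path, sep="\t", float_format="%.4f")
    _append_hash(path, hash_value)


def write_auc_vector(values, path, hash_value: str | None = None) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(values, dtype=float):
            fh.write(f"{v:.8f}\n")
    _append_hash(path, hash_value)


def read_auc_vector(path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line))
    if not values:
        raise ValidationError(f"{path}: no AUC values found")
    return np.array(values)
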