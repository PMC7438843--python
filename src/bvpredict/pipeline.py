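"""End-to-end pipeline: cohort -> preprocess -> resample -> classify -> evaluate.

A single :class:`RunConfig` (usually loaded from a YAML file) ties every
stage together. One global seed propagates to each stochastic stage (stage
seeds are derived deterministically when not set explicitly), so two runs
with identical configuration produce byte-identical numeric outputs. The
run writes a performance summary, the importance table, per-repeat AUC
vectors, and a JSON manifest that echoes the configuration, derived seeds,
stage dimensions, and software versions — enough to re-run identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CVConfig, default_specs, desk_specs, run_repeated_cv
from .cohort import CoupleRecord, build_cohort, outcome_counts
from .compare import permutation_t_test
from .ensemble import PerformanceSummary, add_voting_predictions, summarize_run
from .errors import ValidationError
from .importance import ensemble_importance
from .io import (
    config_hash,
    read_count_table,
    read_metadata,
    write_auc_vector,
    write_importance_table,
    write_performance_summary,
)
from .preprocess import (
    FeatureMatrix,
    PreprocessConfig,
    TaxaCountTable,
    assemble_features,
    minmax_normalize,
)
from .resample import ResampleConfig, rebalance
from .simulate import CohortSimConfig

logger = logging.getLogger("bvpredict")

_SEED_MOD = 2**31 - 1


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``classifiers`` selects "desk" (fixed single-point settings, fast) or
    "tuned" (the standard grids searched by nested inner cross-validation).
    ``paper_scale`` raises n_repeats to 1000, the published scale.
    """

    counts_path: Optional[str] = None
    metadata_path: Optional[str] = None
    out_dir: str = "results"
    site: str = "meatal"
    sensitivity_mode: bool = False
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    classifiers: str = "desk"
    tune_grids: bool = True
    compute_importance: bool = True
    vote_fraction_auc: bool = False
    paper_scale: bool = False
    simulate: Optional[CohortSimConfig] = None

    def __post_init__(self) -> None:
        if self.classifiers not in ("desk", "tuned"):
            raise ValidationError(f'classifiers must be "desk" or "tuned", got {self.classifiers!r}')
        if self.paper_scale:
            self.cv = replace(self.cv, n_repeats=1000)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        seed = int(data.get("seed", 0))

        def sub(name, cls_, offset, seed_key="seed"):
            section = dict(data.pop(name, {}) or {})
            section.setdefault(seed_key, (seed + offset) % _SEED_MOD)
            return cls_(**section)

        preprocess = sub("preprocess", PreprocessConfig, 1)
        resample = sub("resample", ResampleConfig, 2)
        cv = sub("cv", CVConfig, 3, seed_key="base_seed")
        simulate = None
        if "simulate" in data:
            section = dict(data.pop("simulate") or {})
            section.setdefault("seed", seed % _SEED_MOD)
            effects = section.get("effect_taxa")
            if effects:
                section["effect_taxa"] = {int(k): float(v) for k, v in effects.items()}
            simulate = CohortSimConfig(**section)
        known = {
            "counts_path", "metadata_path", "out_dir", "site", "sensitivity_mode",
            "seed", "classifiers", "tune_grids", "compute_importance",
            "vote_fraction_auc", "paper_scale",
        }
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            preprocess=preprocess, resample=resample, cv=cv, simulate=simulate, **data
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        data = asdict(self)
        if data.get("simulate") and data["simulate"].get("base_concentrations") is not None:
            data["simulate"]["base_concentrations"] = [
                float(v) for v in data["simulate"]["base_concentrations"]
            ]
        return data

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


@dataclass
class PipelineResult:
    """In-memory bundle of one pipeline run."""

    labels: np.ndarray
    features: FeatureMatrix
    predictions: pd.DataFrame
    summary: PerformanceSummary
    importance: Optional[pd.DataFrame]
    stage_dims: dict
    config: Optional[RunConfig] = None


def analyze(
    table: TaxaCountTable,
    records: list[CoupleRecord],
    config: RunConfig,
) -> PipelineResult:
    """Run the analysis stages on in-memory inputs.

    Resampling follows ``config.resample.mode``: "pre_cv" rebalances the
    full training set once and cross-validates the resampled set (the
    published procedure); "within_fold" rebalances each training partition
    only, so held-out samples are all original. With
    ``config.preprocess.strict_normalization`` (within_fold only), min-max
    statistics are additionally fitted per training partition. Variable
    importance is always computed on the fully resampled training set,
    matching the single published ranking.
    """
    stage_dims: dict = {"n_records": len(records)}
    stage_dims["outcomes"] = outcome_counts(records, config.sensitivity_mode)
    cohort_table, labels, retained = build_cohort(records, table, config.sensitivity_mode)
    stage_dims["n_retained"] = len(retained)
    stage_dims["n_incident"] = int(labels.sum())
    logger.info("cohort: %d records -> %d retained (%d incident)",
                len(records), len(retained), int(labels.sum()))

    strict = config.preprocess.strict_normalization
    if strict and config.resample.mode != "within_fold":
        raise ValidationError(
            "strict_normalization requires resample mode 'within_fold' "
            "(SMOTE distances are defined on the scaled features)"
        )
    features, labels = assemble_features(cohort_table, retained, config.preprocess)
    stage_dims["n_features"] = len(features.feature_labels)
    logger.info("preprocess: %d x %d feature matrix", features.values.shape[0],
                features.values.shape[1])

    specs = (
        desk_specs()
        if config.classifiers == "desk"
        else default_specs(len(features.feature_labels))
    )

    # importance uses the full resampled training set; in strict mode that
    # full set is scaled over all samples, exactly as the default pipeline
    full_scaled = minmax_normalize(features).values if strict else features.values
    full_resampled = rebalance(full_scaled, labels, config.resample)
    stage_dims["resampled_counts"] = full_resampled.class_counts
    logger.info("resample (%s): class counts %s", config.resample.mode,
                full_resampled.class_counts)

    if config.resample.mode == "pre_cv":
        cv_X, cv_y = full_resampled.features, full_resampled.labels
        resampler = None
    else:
        cv_X, cv_y = features.values, labels

        def resampler(X, y, seed, _cfg=config.resample):
            rs = rebalance(X, y, replace(_cfg, seed=int(seed)))
            return rs.features.to_numpy(dtype=float), rs.labels

    fold_transform = _train_fitted_minmax if strict else None
    predictions = run_repeated_cv(
        cv_X, cv_y, specs, config.cv, resampler=resampler,
        tune_grids=config.tune_grids, fold_transform=fold_transform,
    )
    predictions = add_voting_predictions(predictions, include_vote_fraction=config.vote_fraction_auc)
    summary = summarize_run(predictions, config.cv)
    logger.info("evaluate: voting AUC %.3f over %d repeats", summary.voting_auc,
                config.cv.n_repeats)

    importance_table = None
    if config.compute_importance:
        importance_table = ensemble_importance(
            full_resampled.features,
            full_resampled.labels,
            specs,
            seed=(config.seed + 4) % _SEED_MOD,
        )
        logger.info("importance: ranked %d features", importance_table.shape[0])

    return PipelineResult(
        labels=labels,
        features=features,
        predictions=predictions,
        summary=summary,
        importance=importance_table,
        stage_dims=stage_dims,
        config=config,
    )


def _train_fitted_minmax(X_train: np.ndarray, X_test: np.ndarray):
    """Min-max scaling with statistics from the training partition only.

    Constant training columns map to 0; held-out values may fall slightly
    outside [0, 1] when they exceed the training range (not clipped).
    """
    lo = X_train.min(axis=0)
    hi = X_train.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    constant = hi == lo
    scaled_train = (X_train - lo) / span
    scaled_test = (X_test - lo) / span
    scaled_train[:, constant] = 0.0
    scaled_test[:, constant] = 0.0
    return scaled_train, scaled_test


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read inputs, run :func:`analyze`, and write the output bundle."""
    if not config.counts_path or not config.metadata_path:
        raise ValidationError("run_pipeline requires counts_path and metadata_path")
    for p in (config.counts_path, config.metadata_path):
        if not Path(p).exists():
            raise ValidationError(f"input path does not exist: {p}")
    table = read_count_table(config.counts_path, site=config.site)
    records = read_metadata(config.metadata_path)
    result = analyze(table, records, config)
    write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash
    write_performance_summary(result.summary.table, out / "performance_summary.tsv", h)
    if result.importance is not None:
        write_importance_table(result.importance, out / "importance.tsv", h)
    for clf, aucs in result.summary.auc_distribution.items():
        write_auc_vector(aucs, out / f"auc_{clf}.txt", h)
    manifest = {
        "config": config.to_dict(),
        "config_hash": h,
        "stage_dims": result.stage_dims,
        "performance": {
            clf: {m: float(v) for m, v in col.items()}
            for clf, col in result.summary.table.to_dict().items()
        },
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote outputs to %s (config %s)", out, h)


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "bvpredict": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scipy": scipy.__version__,
    }
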