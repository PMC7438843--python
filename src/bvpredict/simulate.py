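"""Synthetic couples cohorts with the structure the analysis assumes.

Generates one baseline penile sample per couple from a Dirichlet-multinomial:
per-taxon Dirichlet concentrations control mean composition and sparsity
(defaults follow a power-law rank-abundance profile so that a handful of taxa
dominate and low-rank taxa are present in only a minority of samples, as in
real penile 16S tables), sequencing depth is log-normal with parameters
solved from the target median and interquartile range, and incident-BV
couples have the concentrations of a configurable set of "effect" taxa
multiplied by exp(shift) so that compositional closure is preserved.
Per-visit Nugent scores are synthesized consistent with the drawn outcome so
the cohort module recovers the same labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FOLLOWUP_MONTHS, CoupleRecord
from .errors import ValidationError
from .preprocess import TaxaCountTable

# Fraction of non-BV baselines scoring 0-3 (the rest are intermediate 4-6),
# matching the composition of observed incidence cohorts.
P_BASELINE_NORMAL = 0.845


def default_base_concentrations(n_taxa: int, total: float = 3.0, exponent: float = 1.2) -> np.ndarray:
    """Power-law Dirichlet concentrations: alpha_i proportional to rank^-exponent.

    A small total concentration (default 3) yields strongly overdispersed,
    sparse compositions: the top-ranked taxon averages roughly 20% relative
    abundance while mid-ranked taxa drop out of many samples entirely.
    """
    if n_taxa <= 0:
        raise ValidationError(f"n_taxa must be positive, got {n_taxa}")
    weights = np.arange(1, n_taxa + 1, dtype=float) ** -exponent
    return total * weights / weights.sum()


@dataclass
class CohortSimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the observed couples cohort: ~31% incidence, ~59%
    circumcised partners, ~50 sparse compositional taxa, and sequencing depth
    with median 25,997 and IQR 19,524-33,779. ``effect_taxa`` maps taxon
    indices to natural-log fold shifts applied to the Dirichlet
    concentrations of incident couples (empty = null cohort).
    """

    n_couples: int
    n_taxa: int = 50
    incidence: float = 0.31
    p_circumcised: float = 0.59
    effect_taxa: Mapping[int, float] = field(default_factory=dict)
    base_concentrations: Optional[np.ndarray] = None
    depth_median: int = 25997
    depth_iqr: tuple[int, int] = (19524, 33779)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples <= 0:
            raise ValidationError(f"n_couples must be positive, got {self.n_couples}")
        if self.n_taxa <= 0:
            raise ValidationError(f"n_taxa must be positive, got {self.n_taxa}")
        for name, p in (("incidence", self.incidence), ("p_circumcised", self.p_circumcised)):
            if not (0 <= p <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        for idx in self.effect_taxa:
            if not (0 <= idx < self.n_taxa):
                raise ValidationError(
                    f"effect taxon index {idx} out of range for n_taxa={self.n_taxa}"
                )
        lo, hi = self.depth_iqr
        if not (0 < lo < self.depth_median < hi):
            raise ValidationError(
                f"require depth_iqr[0] < depth_median < depth_iqr[1], got "
                f"{lo} / {self.depth_median} / {hi}"
            )
        if self.base_concentrations is None:
            self.base_concentrations = default_base_concentrations(self.n_taxa)
        else:
            self.base_concentrations = np.asarray(self.base_concentrations, dtype=float)
            if self.base_concentrations.shape != (self.n_taxa,):
                raise ValidationError("base_concentrations length must equal n_taxa")
            if np.any(self.base_concentrations <= 0):
                raise ValidationError("base_concentrations must be strictly positive")


def depth_lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """Solve log-normal (mu, sigma) from the depth median and IQR.

    The median fixes mu = ln(median); the quartile ratio fixes
    sigma = ln(q3/q1) / (2 * z_0.75). Two printed summaries, two parameters.
    """
    z75 = stats.norm.ppf(0.75)
    mu = np.log(median)
    sigma = np.log(iqr[1] / iqr[0]) / (2 * z75)
    return mu, sigma


def _synthesize_nugent(rng: np.random.Generator, incident: bool) -> dict[int, int]:
    """Per-visit Nugent scores consistent with the drawn outcome.

    Baseline is 0-6 (0-3 with probability P_BASELINE_NORMAL, else 4-6);
    incident couples score 7-10 at one follow-up drawn uniformly from
    months {1, 6, 12}, and 0-6 at the others.
    """
    if rng.random() < P_BASELINE_NORMAL:
        baseline = int(rng.integers(0, 4))
    else:
        baseline = int(rng.integers(4, 7))
    scores = {0: baseline}
    incident_month = int(rng.choice(FOLLOWUP_MONTHS)) if incident else None
    for month in FOLLOWUP_MONTHS:
        if month == incident_month:
            scores[month] = int(rng.integers(7, 11))
        else:
            scores[month] = int(rng.integers(0, 7))
    return scores


def generate_cohort(config: CohortSimConfig) -> tuple[TaxaCountTable, list[CoupleRecord]]:
    """Draw one synthetic cohort: count table plus couple metadata.

    Deterministic given the config (including its seed). Row sums of the
    count table equal the drawn sequencing depths exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_couples
    outcomes = rng.random(n) < config.incidence
    circumcised = rng.random(n) < config.p_circumcised

    mu, sigma = depth_lognormal_params(config.depth_median, config.depth_iqr)
    depths = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(int)

    shifted = config.base_concentrations.copy()
    for idx, shift in config.effect_taxa.items():
        shifted[idx] *= np.exp(shift)

    counts = np.empty((n, config.n_taxa), dtype=np.int64)
    for i in range(n):
        alpha = shifted if outcomes[i] else config.base_concentrations
        composition = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], composition)

    width = len(str(n))
    couple_ids = [f"C{i + 1:0{width}d}" for i in range(n)]
    taxon_labels = [f"taxon_{j + 1:03d}" for j in range(config.n_taxa)]
    table = TaxaCountTable(
        pd.DataFrame(counts, index=couple_ids, columns=taxon_labels), site="meatal"
    )
    records = [
        CoupleRecord(
            couple_id=couple_ids[i],
            circumcised=bool(circumcised[i]),
            nugent_by_visit=_synthesize_nugent(rng, bool(outcomes[i])),
        )
        for i in range(n)
    ]
    return table, records
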