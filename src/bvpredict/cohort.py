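"""Cohort derivation: incident-BV outcomes from longitudinal Nugent scores.

Each couple contributes the woman's Nugent score (0-10) at baseline (month 0)
and at scheduled follow-ups (months 1, 6, 12). A score of 7-10 defines
bacterial vaginosis. Couples whose woman has BV at baseline cannot contribute
incidence and are excluded; among the rest, incident BV is the first
follow-up visit scoring 7-10, and couples with no attended follow-up are
excluded. A sensitivity variant additionally excludes intermediate baselines
(4-6), which may be misclassified or developing BV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .preprocess import TaxaCountTable

FOLLOWUP_MONTHS = (1, 6, 12)
VISIT_MONTHS = (0,) + FOLLOWUP_MONTHS

BV_THRESHOLD = 7  # Nugent 7-10 defines BV
INTERMEDIATE_RANGE = (4, 6)  # Nugent 4-6, excluded in sensitivity mode


class Outcome(str, Enum):
    EXCLUDED_BASELINE_BV = "excluded_baseline_bv"
    EXCLUDED_INTERMEDIATE = "excluded_intermediate"
    EXCLUDED_NO_FOLLOWUP = "excluded_no_followup"
    PERSISTENT_NEGATIVE = "persistent_negative"
    INCIDENT = "incident"


RETAINED_OUTCOMES = (Outcome.PERSISTENT_NEGATIVE, Outcome.INCIDENT)


@dataclass
class CoupleRecord:
    """One couple: circumcision status and the woman's per-visit Nugent scores.

    ``nugent_by_visit`` maps visit month (0, 1, 6 or 12) to an integer score;
    follow-up visits may be missing. ``outcome`` and
    ``time_to_incident_months`` are set by :func:`derive_outcome`.
    """

    couple_id: str
    circumcised: bool
    nugent_by_visit: Mapping[int, int] = field(default_factory=dict)
    outcome: Optional[Outcome] = None
    time_to_incident_months: Optional[int] = None

    def __post_init__(self) -> None:
        for month, score in self.nugent_by_visit.items():
            if month not in VISIT_MONTHS:
                raise ValidationError(
                    f"couple {self.couple_id!r}: visit month {month} is not one of {VISIT_MONTHS}"
                )
            if not (isinstance(score, (int, np.integer)) and 0 <= score <= 10):
                raise ValidationError(
                    f"couple {self.couple_id!r}: Nugent score {score!r} at month {month} "
                    "must be an integer in [0, 10]"
                )


def derive_outcome(record: CoupleRecord, sensitivity_mode: bool = False) -> CoupleRecord:
    """Classify one couple into exactly one outcome category.

    Precedence: baseline BV exclusion, then (sensitivity mode only) the
    intermediate-baseline exclusion, then the no-follow-up exclusion; the
    remainder are incident at the earliest follow-up scoring 7-10, else
    persistently negative. Only the first incident visit defines the label.
    """
    visits = record.nugent_by_visit
    if 0 not in visits:
        raise ValidationError(f"couple {record.couple_id!r}: missing baseline Nugent score")
    baseline = visits[0]
    followups = sorted(m for m in visits if m != 0)

    if baseline >= BV_THRESHOLD:
        outcome, time_to = Outcome.EXCLUDED_BASELINE_BV, None
    elif sensitivity_mode and INTERMEDIATE_RANGE[0] <= baseline <= INTERMEDIATE_RANGE[1]:
        outcome, time_to = Outcome.EXCLUDED_INTERMEDIATE, None
    elif not followups:
        outcome, time_to = Outcome.EXCLUDED_NO_FOLLOWUP, None
    else:
        incident_months = [m for m in followups if visits[m] >= BV_THRESHOLD]
        if incident_months:
            outcome, time_to = Outcome.INCIDENT, incident_months[0]
        else:
            outcome, time_to = Outcome.PERSISTENT_NEGATIVE, None
    return replace(record, outcome=outcome, time_to_incident_months=time_to)


def build_cohort(
    records: Sequence[CoupleRecord],
    counts: TaxaCountTable,
    sensitivity_mode: bool = False,
) -> tuple[TaxaCountTable, np.ndarray, list[CoupleRecord]]:
    """Derive outcomes for all couples and restrict to the analysis cohort.

    Retains couples with outcome persistent_negative (label 0) or incident
    (label 1), in the order the records were given. Every retained couple
    must have a count row whose sample id equals its couple id.

    Returns the restricted count table, the label vector, and the retained
    records with outcomes set.
    """
    derived = [derive_outcome(r, sensitivity_mode) for r in records]
    retained = [r for r in derived if r.outcome in RETAINED_OUTCOMES]

    available = set(counts.sample_ids)
    missing = [r.couple_id for r in retained if r.couple_id not in available]
    if missing:
        raise ValidationError(
            f"retained couples without a count row: {missing}"
        )
    ids = [r.couple_id for r in retained]
    labels = np.array([1 if r.outcome == Outcome.INCIDENT else 0 for r in retained], dtype=int)
    sub = counts.counts.loc[ids] if ids else counts.counts.iloc[0:0]
    table = replace(counts, counts=sub)
    return table, labels, retained


def outcome_counts(records: Sequence[CoupleRecord], sensitivity_mode: bool = False) -> dict:
    """Tally of outcome categories over all input records (bookkeeping aid)."""
    tally = {o.value: 0 for o in Outcome}
    for r in records:
        tally[derive_outcome(r, sensitivity_mode).outcome.value] += 1
    return tally
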