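"""Shared fixtures: small synthetic tables and a cohort with published margins."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bvpredict import CoupleRecord, TaxaCountTable


def make_published_margin_records() -> list[CoupleRecord]:
    """211 couples whose outcome margins match the published cohort tables.

    43 couples have BV (Nugent 7-10) at baseline. Of the 168 retained, 142
    have baseline 0-3 and 26 have baseline 4-6; 52 develop incident BV (37
    from normal baselines at months 1/6/12 = 13/16/8, 15 from intermediate
    baselines at 10/4/1) and 116 remain negative. 99 male partners are
    circumcised, 26 of them in incident couples.
    """
    records: list[CoupleRecord] = []

    def add(n, baseline, incident_month, circumcised):
        for _ in range(n):
            visits = {0: baseline}
            for month in (1, 6, 12):
                visits[month] = 8 if month == incident_month else 2
            records.append(
                CoupleRecord(
                    couple_id=f"C{len(records) + 1:03d}",
                    circumcised=circumcised,
                    nugent_by_visit=visits,
                )
            )

    # incident couples: 26 circumcised, 26 not, preserving the time-to-event
    # split by baseline category (normal 13/16/8, intermediate 10/4/1)
    incident_plan = (
        [(2, m) for m in (1,) * 13 + (6,) * 16 + (12,) * 8]
        + [(5, m) for m in (1,) * 10 + (6,) * 4 + (12,) * 1]
    )
    for i, (baseline, month) in enumerate(incident_plan):
        add(1, baseline, month, circumcised=i < 26)
    # persistent negatives: 105 normal + 11 intermediate baselines; 73 circumcised
    for i in range(105):
        add(1, 1, None, circumcised=i < 73)
    for _ in range(11):
        add(1, 5, None, circumcised=False)
    # baseline-BV exclusions
    add(43, 9, None, circumcised=False)
    assert len(records) == 211
    return records


def make_count_table(sample_ids, n_taxa=5, seed=0, site="meatal") -> TaxaCountTable:
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 200, size=(len(sample_ids), n_taxa))
    return TaxaCountTable(
        pd.DataFrame(
            counts,
            index=list(sample_ids),
            columns=[f"taxon_{j + 1:03d}" for j in range(n_taxa)],
        ),
        site=site,
    )


@pytest.fixture
def published_margin_records():
    return make_published_margin_records()


@pytest.fixture
def small_table():
    return make_count_table([f"C{i:03d}" for i in range(1, 7)], n_taxa=4, seed=3)
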