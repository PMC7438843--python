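"""Filtering, zero imputation, CLR, and min-max normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.composition import clr as skbio_clr

from bvpredict import (
    CohortSimConfig,
    FeatureMatrix,
    PreprocessConfig,
    TaxaCountTable,
    ValidationError,
    assemble_features,
    build_cohort,
    clr_transform,
    filter_taxa,
    generate_cohort,
    impute_zeros,
    minmax_normalize,
)


def table_from(counts, **kwargs):
    frame = pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(len(counts))],
        columns=[f"t{j}" for j in range(len(counts[0]))],
    )
    return TaxaCountTable(frame, **kwargs)


class TestFilterTaxa:
    def test_inclusive_threshold_at_exactly_one_hundredth_percent(self):
        # grand total 1,000,000: a 100-read taxon sits exactly at 0.01%
        t = table_from([[100, 99, 999801]])
        filtered = filter_taxa(t, 1e-4)
        assert filtered.taxon_labels == ["t0", "t2"]

    def test_all_zero_taxon_removed(self):
        t = table_from([[0, 10], [0, 20]])
        assert filter_taxa(t, 1e-4).taxon_labels == ["t1"]

    def test_filtering_is_idempotent(self):
        t = table_from([[5, 1, 0], [5, 0, 0], [90, 1, 1]])
        once = filter_taxa(t, 0.02)
        twice = filter_taxa(once, 0.02)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_removing_every_taxon_is_an_error(self):
        with pytest.raises(ValidationError, match="every taxon"):
            filter_taxa(table_from([[1, 1]]), 0.9)

    def test_sample_rows_and_taxon_order_preserved(self):
        t = table_from([[50, 1, 50], [50, 0, 50]])
        filtered = filter_taxa(t, 0.2)
        assert filtered.sample_ids == t.sample_ids
        assert filtered.taxon_labels == ["t0", "t2"]


class TestImputeZeros:
    def test_zeros_replaced_within_interval_nonzeros_unchanged(self):
        t = table_from([[0, 10, 0]])
        out = impute_zeros(t, PreprocessConfig(seed=1))
        assert out.iloc[0, 1] == 10
        for j in (0, 2):
            assert 0.5 <= out.iloc[0, j] < 0.95
        assert out.iloc[0, 0] != out.iloc[0, 2]  # independent draws
        assert (out.to_numpy() > 0).all()

    def test_all_positive_table_returned_identically(self):
        t = table_from([[1, 2], [3, 4]])
        out = impute_zeros(t, PreprocessConfig(seed=1))
        assert (out.to_numpy() == t.counts.to_numpy()).all()

    def test_same_seed_reproduces_draws(self):
        t = table_from([[0, 0, 5], [0, 1, 0]])
        a = impute_zeros(t, PreprocessConfig(seed=7))
        b = impute_zeros(t, PreprocessConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)


class TestClr:
    def test_constant_composition_maps_to_zero(self):
        out = clr_transform(pd.DataFrame([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), 0, atol=1e-12)

    def test_closed_form_row(self):
        out = clr_transform(pd.DataFrame([[1.0, np.e**2, np.e**-2]]))
        np.testing.assert_allclose(out.values.to_numpy()[0], [0, 2, -2], atol=1e-12)

    def test_matches_skbio_reference(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.uniform(0.5, 50, size=(6, 5)))
        np.testing.assert_allclose(
            clr_transform(x).values.to_numpy(), skbio_clr(x.to_numpy()), atol=1e-10
        )

    def test_nonpositive_entry_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            clr_transform(pd.DataFrame([[1.0, 0.0]]))

    @settings(max_examples=50, derandomize=True)
    @given(
        row=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=12),
        scale=st.floats(0.01, 100),
    )
    def test_row_sum_zero_and_scale_invariance(self, row, scale):
        x = pd.DataFrame([row])
        out = clr_transform(x).values.to_numpy()
        assert abs(out.sum()) < 1e-9
        scaled = clr_transform(x * scale).values.to_numpy()
        np.testing.assert_allclose(out, scaled, atol=1e-9)


class TestMinMax:
    def test_direct_evaluation_of_the_formula(self):
        fm = FeatureMatrix(pd.DataFrame({"f": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(
            minmax_normalize(fm).values["f"].to_numpy(), [0, 0.5, 1]
        )

    def test_endpoints_map_to_zero_and_one(self):
        rng = np.random.default_rng(3)
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(8, 3))))
        out = minmax_normalize(fm).values.to_numpy()
        assert (out >= 0).all() and (out <= 1).all()
        assert np.allclose(out.min(axis=0), 0) and np.allclose(out.max(axis=0), 1)

    def test_constant_column_maps_to_zero(self):
        fm = FeatureMatrix(pd.DataFrame({"f": [7.0, 7.0, 7.0]}))
        np.testing.assert_allclose(minmax_normalize(fm).values["f"].to_numpy(), 0)

    def test_idempotent_on_full_range_output(self):
        fm = FeatureMatrix(pd.DataFrame({"f": [2.0, 4.0, 6.0]}))
        once = minmax_normalize(fm)
        twice = minmax_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestAssembleFeatures:
    @pytest.fixture
    def cohort(self):
        table, records = generate_cohort(CohortSimConfig(n_couples=30, n_taxa=12, seed=4))
        sub, labels, retained = build_cohort(records, table)
        return sub, retained, labels

    def test_circumcision_column_appended_after_normalization(self, cohort):
        sub, retained, labels = cohort
        with_c, labels_c = assemble_features(sub, retained, PreprocessConfig(seed=0))
        without_c, _ = assemble_features(
            sub, retained, PreprocessConfig(seed=0, include_circumcision=False)
        )
        assert with_c.feature_labels[-1] == "Circumcised"
        assert len(with_c.feature_labels) == len(without_c.feature_labels) + 1
        np.testing.assert_array_equal(labels_c, labels)
        circ = with_c.values["Circumcised"].to_numpy()
        assert set(np.unique(circ)) <= {0.0, 1.0}
        expected = [1.0 if r.circumcised else 0.0 for r in retained]
        np.testing.assert_array_equal(circ, expected)

    def test_all_values_within_unit_interval(self, cohort):
        sub, retained, _ = cohort
        fm, _ = assemble_features(sub, retained, PreprocessConfig(seed=0))
        values = fm.values.to_numpy()
        assert (values >= 0).all() and (values <= 1).all()

    def test_underived_records_rejected(self, cohort):
        sub, retained, _ = cohort
        from dataclasses import replace

        undone = [replace(r, outcome=None) for r in retained]
        with pytest.raises(ValidationError, match="cohort"):
            assemble_features(sub, undone, PreprocessConfig(seed=0))


def test_invalid_preprocess_configs_rejected():
    with pytest.raises(ValidationError):
        PreprocessConfig(impute_low=0.9, impute_high=0.5)
    with pytest.raises(ValidationError):
        PreprocessConfig(min_fraction=1.5)
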