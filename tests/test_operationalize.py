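from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbnet.operationalize import (
    DomainError,
    above_average_flag,
    apply_recodes,
    categorize_climate,
    complete_case_filter,
    default_recode_maps,
    derive_education,
    derive_household_size,
    derive_migration,
    derive_netuse,
    derive_pa,
    derive_sitting,
    passthrough_maps,
    tertile_split,
)
from sbnet.schema import default_survey_schema
from sbnet.synthetic_data import build_ground_truth, sample_categorical, sample_dataset


class TestDeriveSitting:
    @pytest.mark.parametrize(
        "raw,expected",
        [(1, 1), (2, 1), (3, 1), (4, 2), (5, 2), (6, 3), (7, 3), (8, 3), (9, 4), (10, 4)],
    )
    def test_band_assignment(self, raw, expected):
        assert derive_sitting(raw) == expected

    @pytest.mark.parametrize("raw", [0, 11, -3])
    def test_out_of_range_rejected(self, raw):
        with pytest.raises(DomainError):
            derive_sitting(raw)


class TestDerivePA:
    @pytest.mark.parametrize(
        "mpa,vpa,expected",
        [
            (0, 0, 0),        # inactive: both exactly zero
            (100, 50, 1),     # low: both below cutoffs, not both zero
            (180, 90, 3),     # highly: both at/above cutoffs
            (160, 0, 2),      # sufficiently: one cutoff met
            (0, 75, 2),
            (150, 75, 3),
            (149, 74, 1),
            (10, 0, 1),
        ],
    )
    def test_classification(self, mpa, vpa, expected):
        assert derive_pa(mpa, vpa) == expected

    def test_negative_minutes_rejected(self):
        with pytest.raises(DomainError):
            derive_pa(-1, 0)

    @given(st.integers(0, 2000), st.integers(0, 2000))
    @settings(max_examples=200, deadline=None)
    def test_classes_partition_the_plane(self, mpa, vpa):
        cls = derive_pa(mpa, vpa)
        if mpa >= 150 and vpa >= 75:
            assert cls == 3
        elif mpa >= 150 or vpa >= 75:
            assert cls == 2
        elif mpa == 0 and vpa == 0:
            assert cls == 0
        else:
            assert cls == 1


class TestDeriveNetuse:
    @pytest.mark.parametrize("h,w,e,expected", [(0, 2, 0, 2), (0, 0, 0, 0), (1, 1, 1, 1)])
    def test_max_rule(self, h, w, e, expected):
        assert derive_netuse(h, w, e) == expected

    def test_invalid_code_rejected(self):
        with pytest.raises(DomainError):
            derive_netuse(0, 3, 0)


class TestDeriveEducation:
    @pytest.mark.parametrize(
        "age,expected", [(14, 1), (15, 1), (16, 2), (17, 2), (19, 2), (20, 3), (22, 3)]
    )
    def test_bands(self, age, expected):
        assert derive_education(age) == expected


class TestCategorizeClimate:
    @pytest.mark.parametrize(
        "temp,expected",
        [(16, "hot"), (15.01, "hot"), (15, "moderate"), (12, "moderate"),
         (10, "moderate"), (9.9, "cold")],
    )
    def test_temperature_bands(self, temp, expected):
        assert categorize_climate(temp, 1.0)[0] == expected

    @pytest.mark.parametrize(
        "precip,expected",
        [(0.1, "dry"), (0.19, "dry"), (0.2, "moderate"), (2.0, "moderate"), (3.0, "wet")],
    )
    def test_precipitation_bands(self, precip, expected):
        assert categorize_climate(12.0, precip)[1] == expected

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            categorize_climate(math.nan, 1.0)
        with pytest.raises(DomainError):
            categorize_climate(12.0, math.inf)


class TestHouseholdAndMigration:
    @pytest.mark.parametrize(
        "a,b,c,expected", [(0, 0, 0, 0), (1, 0, 1, 2), (2, 1, 2, 3), (0, 0, 5, 3)]
    )
    def test_household_size_capped(self, a, b, c, expected):
        assert derive_household_size(a, b, c) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            derive_household_size(-1, 0, 0)

    @pytest.mark.parametrize(
        "nat,res,expected", [("FR", "DE", 1), ("FR", "FR", 0), ("PL", "IE", 1)]
    )
    def test_migration_mismatch(self, nat, res, expected):
        assert derive_migration(nat, res) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(DomainError):
            derive_migration("XX", "FR")


class TestTertileSplit:
    def test_exact_thirds(self):
        out = tertile_split(list(range(1, 10)))
        np.testing.assert_array_equal(out, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            tertile_split([5.0] * 10)

    def test_boundary_ties_go_to_lower_tertile(self):
        """Brute-force quantile oracle: ties at a cut point all share the
        lower tertile, and partition sizes differ by at most the tie count."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = rng.integers(0, 6, size=30).astype(float)
            if np.unique(values).size < 3:
                continue
            out = tertile_split(values)
            q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
            # oracle: direct comparison with the cut points
            expected = np.where(values <= q1, 1, np.where(values <= q2, 2, 3))
            np.testing.assert_array_equal(out, expected)
            # equal raw values always share a tertile
            for v in np.unique(values):
                assert np.unique(out[values == v]).size == 1


class TestAboveAverageFlag:
    def test_strict_order(self):
        assert above_average_flag([5.0], 4.0)[0] == 1

    def test_tie_maps_to_zero(self):
        assert above_average_flag([4.0], 4.0)[0] == 0

    def test_own_mean_reference(self):
        np.testing.assert_array_equal(above_average_flag([1, 2, 3], 2.0), [0, 0, 1])

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            above_average_flag([math.nan], 1.0)
        with pytest.raises(DomainError):
            above_average_flag([1.0], math.nan)


def _raw_table(n=200, seed=0):
    model = build_ground_truth(seed=1, edge_density=0.07)
    return sample_dataset(model, n, seed=seed)


class TestApplyRecodes:
    def test_facility_agreement_on_one_item_is_high(self):
        raw = _raw_table(4)
        raw["facility_item1_4"] = [2, 4, 3, 1]  # tend-agree, disagree x2, agree
        raw["facility_item2_4"] = [4, 4, 2, 3]
        out = apply_recodes(raw)
        assert list(out["facility"]) == ["high", "low", "high", "high"]

    def test_social_class_collapse(self):
        raw = _raw_table(3)
        raw["social_class_3"] = [1, 2, 3]
        out = apply_recodes(raw)
        assert list(out["social_class"]) == ["working", "middle_higher", "middle_higher"]

    def test_relationship_single_with_children(self):
        raw = _raw_table(20)
        # raw code 9: single living with children
        raw.loc[0, "relationship_14"] = 9
        out = apply_recodes(raw)
        assert out["partner"].iloc[0] == "no"
        assert out["children"].iloc[0] == "yes"

    def test_missing_inputs_propagate(self):
        raw = _raw_table(3)
        raw.loc[1, "sitting_10cat"] = np.nan
        out = apply_recodes(raw)
        assert pd.isna(out.loc[1, "sitting"])
        assert not pd.isna(out.loc[0, "sitting"])

    def test_out_of_domain_value_names_field_and_row(self):
        raw = _raw_table(3)
        raw.loc[2, "urbanity_3"] = 9
        with pytest.raises(DomainError, match="urbanity_3.*row 2"):
            apply_recodes(raw)

    def test_recoding_categorical_output_is_rejected(self):
        raw = _raw_table(5)
        categorical = apply_recodes(raw)
        with pytest.raises(DomainError, match="refusing to re-map"):
            apply_recodes(categorical)

    def test_missing_source_field_is_an_error(self):
        raw = _raw_table(5).drop(columns=["sitting_10cat"])
        with pytest.raises(DomainError, match="sitting"):
            apply_recodes(raw)

    def test_still_studying_uses_current_age(self):
        raw = _raw_table(20)
        raw.loc[0, "education_stop_age"] = 0
        raw.loc[0, "age"] = 17
        raw.loc[1, "education_stop_age"] = 0
        raw.loc[1, "age"] = 30
        out = apply_recodes(raw)
        assert out["education"].iloc[0] == "16_19"
        assert out["education"].iloc[1] == "ge20"

    def test_still_studying_without_age_is_missing(self):
        raw = _raw_table(1).drop(columns=["age"])
        raw["education_stop_age"] = [0]
        maps = [m for m in default_recode_maps() if m.target == "education"]
        out = maps[0].apply(raw)
        assert pd.isna(out.iloc[0])

    def test_totality_over_declared_domains(self):
        """Every raw code of every single-source code map yields a level."""
        domains = {
            "sitting_10cat": range(1, 11),
            "life_satisfaction_4": range(1, 5),
            "occupation_18": range(1, 19),
            "social_class_3": range(1, 4),
            "financial_burden_3": range(1, 4),
            "own_computer": range(0, 2),
            "own_internet": range(0, 2),
            "own_car": range(0, 2),
            "healthcare_quality_4": range(1, 5),
            "urbanity_3": range(1, 4),
            "municipality_item_4": range(1, 5),
            "relationship_14": range(1, 15),
            "sb_guidelines_flag": range(0, 2),
            "pa_guidelines_flag": range(0, 2),
            "transport_policy_flag": range(0, 2),
        }
        schema = {v.name: v for v in default_survey_schema()}
        for rm in default_recode_maps():
            if len(rm.sources) != 1 or rm.sources[0] not in domains:
                continue
            field = rm.sources[0]
            table = pd.DataFrame({field: list(domains[field])})
            result = rm.apply(table)
            assert not result.isna().any(), f"{rm.target}: unmapped raw code"
            declared = set(schema[rm.target].levels)
            assert set(result) <= declared, f"{rm.target}: undeclared level"


class TestPassthroughRoundTrip:
    def test_categorical_data_unchanged(self):
        model = build_ground_truth(seed=3, edge_density=0.07)
        data = sample_categorical(model, 300, seed=3)
        frame = data.to_frame().astype(object)
        out = apply_recodes(frame, maps=passthrough_maps(model.schema))
        pd.testing.assert_frame_equal(
            out.astype(str), frame.astype(str), check_dtype=False
        )


class TestCompleteCaseFilter:
    def test_rows_with_missing_removed(self):
        raw = _raw_table(10)
        recoded = apply_recodes(raw)
        recoded.loc[[1, 4, 7], "sitting"] = np.nan
        ds = complete_case_filter(recoded)
        assert ds.n_rows == 7

    def test_no_missing_is_identity(self):
        recoded = apply_recodes(_raw_table(10))
        ds = complete_case_filter(recoded)
        assert ds.n_rows == 10

    def test_all_missing_gives_empty_and_pipeline_refuses(self):
        from sbnet.pipeline import RunConfig, run_full_analysis

        recoded = apply_recodes(_raw_table(5))
        recoded["sitting"] = np.nan
        ds = complete_case_filter(recoded)
        assert ds.n_rows == 0
        with pytest.raises(ValueError, match="empty stratum"):
            run_full_analysis(RunConfig(replicates=2, n=10), ds)
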