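"""Cohort construction: filters, conversions, BMI bounds, flagging, joins."""

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.cohort import (apply_bmi_filter, build_analysis_table, compute_bmi,
                             convert_age_band, convert_weight_band, deduplicate,
                             filter_suspected, flag_target_events)

from conftest import make_small_scenario


class TestSuspectedFilter:
    def test_one_row_per_category_keeps_suspected(self, tiny_tables):
        _, drug, _ = tiny_tables
        drug = pd.concat([drug, pd.DataFrame([{
            "case_id": "C2", "drug_name": "drug B",
            "involvement": "interaction", "atc_code": "B01"}])], ignore_index=True)
        kept = filter_suspected(drug)
        assert set(kept["involvement"]) == {"suspected"}
        assert len(kept) == 2

    def test_all_concomitant_gives_empty(self):
        drug = pd.DataFrame({"case_id": ["C1"] * 3, "drug_name": list("abc"),
                             "involvement": ["concomitant"] * 3, "atc_code": [np.nan] * 3})
        assert len(filter_suspected(drug)) == 0

    def test_suspected_share_matches_involvement_mix(self):
        cfg = make_small_scenario(n_cases=10_000, involvement_mix=(0.5, 0.3, 0.2))
        _, drug, _, _ = pv.generate_cohort(cfg)
        n = len(drug)
        kept = len(filter_suspected(drug))
        se = np.sqrt(n * 0.5 * 0.5)
        assert abs(kept - 0.5 * n) <= 3 * se


class TestDeduplicate:
    def test_exact_duplicate_removed_first_kept(self):
        drug = pd.DataFrame({"case_id": ["C1", "C1"], "drug_name": ["a", "a"],
                             "involvement": ["suspected"] * 2, "atc_code": ["X", "X"]})
        reac = pd.DataFrame({"case_id": ["C1"], "preferred_term": ["Nausea"],
                             "outcome": [np.nan]})
        d2, r2 = deduplicate(drug, reac)
        assert len(d2) == 1 and len(r2) == 1

    def test_idempotent_on_clean_tables(self, tiny_tables):
        _, drug, reac = tiny_tables
        once = deduplicate(drug, reac)
        twice = deduplicate(*once)
        pd.testing.assert_frame_equal(once[0], twice[0])
        pd.testing.assert_frame_equal(once[1], twice[1])

    def test_removed_count_equals_planted_duplicates(self):
        cfg = make_small_scenario(n_cases=5000, duplicate_rate=0.1, seed=11)
        _, drug, reac, truth = pv.generate_cohort(cfg)
        d2, r2 = deduplicate(drug, reac)
        assert len(drug) - len(d2) == truth.n_dup_drug_rows
        assert len(reac) - len(r2) == truth.n_dup_reac_rows


class TestConversions:
    @pytest.mark.parametrize("band, expected", [
        ("under 10", 5.0),
        ("60s", 65.0),
        ("20s", 25.0),
        ("90s", 95.0),
        ("45", 45.0),
    ])
    def test_age_band_midpoints(self, band, expected):
        assert convert_age_band(band) == expected

    @pytest.mark.parametrize("band", ["", np.nan, None, "unknown", "sixty"])
    def test_unparseable_age_is_missing(self, band):
        assert np.isnan(convert_age_band(band))

    @pytest.mark.parametrize("value, expected", [
        ("60 kg range", 65.0),
        ("40 kg range", 45.0),
        (52.1, 52.1),
        ("52.1", 52.1),
    ])
    def test_weight_band_midpoints(self, value, expected):
        assert convert_weight_band(value) == pytest.approx(expected)

    def test_unparseable_weight_is_missing(self):
        assert np.isnan(convert_weight_band("heavy"))


class TestBmi:
    def test_round_numbers(self):
        assert compute_bmi(200.0, 80.0) == pytest.approx(20.0)

    def test_hand_arithmetic(self):
        # ratio of the target-group mean height/weight; note a mean of
        # per-case ratios differs from this ratio of means
        assert compute_bmi(154.0, 52.1) == pytest.approx(21.97, abs=0.01)

    @pytest.mark.parametrize("height, weight", [(0.0, 60.0), (160.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, height, weight):
        with pytest.raises(ValueError):
            compute_bmi(height, weight)

    def test_boundary_semantics_strict_inequalities(self):
        rows = pd.DataFrame({"bmi": [9.9, 10.0, 100.0, 100.1, np.nan]})
        kept, low, high = apply_bmi_filter(rows)
        assert low == 1 and high == 1
        assert sorted(kept["bmi"].dropna()) == [10.0, 100.0]
        assert kept["bmi"].isna().sum() == 1

    def test_all_missing_bmi_nothing_excluded(self):
        rows = pd.DataFrame({"bmi": [np.nan] * 4})
        kept, low, high = apply_bmi_filter(rows)
        assert len(kept) == 4 and low == 0 and high == 0


class TestFlagging:
    @pytest.mark.parametrize("term, expected", [
        ("Atypical femur fracture", True),
        ("Open reduction of fracture", True),
        ("Fractured sacrum", True),
        ("Fall", False),
        ("Nausea", False),
    ])
    def test_substring_rule(self, term, expected):
        rows = pd.DataFrame({"preferred_term": [term]})
        assert flag_target_events(rows)["is_target_event"].iloc[0] == expected

    def test_explicit_term_list_rule(self):
        allow = pv.fracture_term_list()
        rows = pd.DataFrame({"preferred_term": ["Atypical femur fracture", "Fall",
                                                "Some other fracture-ish term"]})
        flagged = flag_target_events(rows, term_rule=allow)
        assert list(flagged["is_target_event"]) == [True, False, False]

    def test_flagging_is_pure_function_of_term(self):
        rows = pd.DataFrame({"preferred_term": ["Rib fracture", "Rib fracture"]})
        out = flag_target_events(rows)
        assert out["is_target_event"].nunique() == 1


class TestBuildAnalysisTable:
    def test_one_case_two_events_gives_two_rows(self):
        demo = pd.DataFrame({"case_id": ["C1"], "sex": ["female"], "age_band": ["60s"],
                             "height_cm": [154.0], "weight_kg": [52.1]})
        drug = pd.DataFrame({"case_id": ["C1"], "drug_name": ["drug A"],
                             "involvement": ["suspected"], "atc_code": ["A01"]})
        reac = pd.DataFrame({"case_id": ["C1", "C1"],
                             "preferred_term": ["Femur fracture", "Nausea"],
                             "outcome": [np.nan, np.nan]})
        rows, report = build_analysis_table(demo, drug, reac)
        assert len(rows) == 2
        assert report.n_target_event_rows == 1
        assert rows["age_years"].iloc[0] == 65.0
        assert rows["bmi"].iloc[0] == pytest.approx(21.97, abs=0.01)

    def test_case_absent_from_demo_dropped_and_counted(self, tiny_tables):
        demo, drug, reac = tiny_tables
        demo = demo[demo["case_id"] != "C2"]
        rows, report = build_analysis_table(demo, drug, reac)
        assert "C2" not in set(rows["case_id"])
        assert report.n_unmatched_case_rows == 1

    def test_empty_join_warns_and_returns_empty(self, tiny_tables, caplog):
        demo, drug, reac = tiny_tables
        drug = drug[drug["involvement"] == "interaction"]
        with caplog.at_level("WARNING"):
            rows, report = build_analysis_table(demo, drug, reac)
        assert len(rows) == 0 and report.n_final == 0

    def test_count_conservation(self, default_cohort):
        r = default_cohort.report
        assert r.n_suspected_rows >= r.n_drug_after_dedup
        assert r.n_final == r.n_joined_rows - r.n_bmi_low_excluded - r.n_bmi_high_excluded
        assert 0 <= r.n_target_event_rows <= r.n_final

    def test_rerun_is_deterministic(self, tiny_tables):
        rows1, rep1 = build_analysis_table(*tiny_tables)
        rows2, rep2 = build_analysis_table(*tiny_tables)
        pd.testing.assert_frame_equal(rows1, rows2)
        assert rep1 == rep2

    def test_excluded_rows_are_exactly_planted_outliers(self):
        cfg = make_small_scenario(n_cases=6000, outlier_rate=0.02, seed=13)
        demo, drug, reac, truth = pv.generate_cohort(cfg)
        rows_all, _ = build_analysis_table(demo, drug, reac,
                                           bmi_bounds=(-np.inf, np.inf))
        rows, report = build_analysis_table(demo, drug, reac)
        excluded = rows_all[(rows_all["bmi"] < 10) | (rows_all["bmi"] > 100)]
        assert report.n_bmi_low_excluded + report.n_bmi_high_excluded == len(excluded)
        assert set(excluded["case_id"]) <= set(truth.outlier_case_ids)

    def test_target_rows_match_truth_record(self):
        cfg = make_small_scenario(n_cases=6000, seed=17)
        demo, drug, reac, truth = pv.generate_cohort(cfg)
        _, report = build_analysis_table(demo, drug, reac)
        cases = truth.cases
        expected = int((cases["n_drugs"] * cases["n_target_terms"]).sum())
        assert report.n_target_event_rows == expected

    def test_report_text_round_trip(self, tmp_path, tiny_tables):
        _, report = build_analysis_table(*tiny_tables)
        path = report.write(tmp_path / "report.txt")
        text = path.read_text()
        assert f"n_final\t{report.n_final}" in text
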