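"""Cleaning steps: deduplication, role filter, drug matching, extraction."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from pvsignal import (
    DrugDictionary,
    SyntheticConfig,
    clean_pipeline,
    deduplicate,
    descriptive_summary,
    extract_events,
    filter_suspect_roles,
    generate,
    match_target_drug,
)
from pvsignal.preprocess import age_group_of, normalize_name, percentage

from conftest import demo_row, make_cases, make_tables


class TestDeduplicate:
    def test_latest_fda_dt_wins_for_same_primaryid(self):
        tables = make_tables(demo=[
            demo_row("P1", fda_dt=20240101),
            demo_row("P1", fda_dt=20240301),
        ])
        out = deduplicate(tables)
        assert len(out.demo) == 1
        assert out.demo["fda_dt"].iloc[0] == 20240301

    def test_single_record_unchanged(self):
        tables = make_tables(demo=[demo_row("P1")])
        out = deduplicate(tables)
        pd.testing.assert_frame_equal(out.demo, tables.demo)

    def test_largest_caseversion_wins_at_equal_date(self):
        tables = make_tables(demo=[
            demo_row("P1", version=1, fda_dt=20240101),
            demo_row("P1", version=2, fda_dt=20240101),
        ])
        out = deduplicate(tables)
        assert out.demo["caseversion"].iloc[0] == 2

    def test_same_caseid_keeps_most_recent_version_only(self):
        tables = make_tables(
            demo=[
                demo_row("P1", caseid="C9", version=1, fda_dt=20240101),
                demo_row("P2", caseid="C9", version=3, fda_dt=20240301),
            ],
            reac=[{"primaryid": "P1", "pt": "Nausea"}, {"primaryid": "P2", "pt": "Rash"}],
        )
        out = deduplicate(tables)
        assert list(out.demo["primaryid"]) == ["P2"]
        assert list(out.reac["primaryid"]) == ["P2"]

    def test_full_key_tie_keeps_last_in_file_order(self):
        tables = make_tables(demo=[
            demo_row("P1", caseid="C1", version=1, fda_dt=20240101, sex="male"),
            demo_row("P1", caseid="C1", version=1, fda_dt=20240101, sex="female"),
        ])
        out = deduplicate(tables)
        assert len(out.demo) == 1
        assert out.demo["sex"].iloc[0] == "female"

    @pytest.mark.parametrize("seed", [0, 3])
    def test_idempotent_and_never_grows(self, seed):
        tables, _ = generate(SyntheticConfig(n_reports=300, duplicate_rate=0.2, seed=seed))
        once = deduplicate(tables)
        twice = deduplicate(once)
        for name in tables.table_names():
            assert len(getattr(once, name)) <= len(getattr(tables, name))
            pd.testing.assert_frame_equal(getattr(once, name), getattr(twice, name))


class TestFilterSuspectRoles:
    def test_per_row_role_rule(self):
        tables = make_tables(
            demo=[demo_row("P1"), demo_row("P2"), demo_row("P3")],
            drug=[
                {"primaryid": "P1", "drug_seq": 1, "role_cod": "PS", "drugname": "A"},
                {"primaryid": "P2", "drug_seq": 1, "role_cod": "C", "drugname": "A"},
                {"primaryid": "P3", "drug_seq": 1, "role_cod": "SS", "drugname": "A"},
                {"primaryid": "P3", "drug_seq": 2, "role_cod": "I", "drugname": "B"},
            ],
        )
        out = filter_suspect_roles(tables)
        kept = set(zip(out.drug["primaryid"], out.drug["role_cod"]))
        assert kept == {("P1", "PS"), ("P3", "SS")}

    def test_unknown_role_treated_as_non_suspect(self, caplog):
        tables = make_tables(
            demo=[demo_row("P1")],
            drug=[{"primaryid": "P1", "drug_seq": 1, "role_cod": "XX", "drugname": "A"}],
        )
        with caplog.at_level("WARNING"):
            out = filter_suspect_roles(tables)
        assert out.drug.empty
        assert any("unknown role" in r.message for r in caplog.records)


class TestMatchTargetDrug:
    def _tables(self, drugname, prod_ai, route):
        return make_tables(
            demo=[demo_row("P1")],
            drug=[{"primaryid": "P1", "drug_seq": 1, "role_cod": "PS",
                   "drugname": drugname, "prod_ai": prod_ai, "route": route}],
        )

    @pytest.mark.parametrize("drugname,prod_ai,route,expected", [
        ("ATROPINE SULFATE", None, "OPHTHALMIC", True),
        ("ATROPINE", None, None, False),          # missing route excluded
        ("ISOPTO", "atropine", "Ophthalmic", True),  # via PROD_AI, case-insensitive
        ("ATROPINE SULFATE 1%", None, "ORAL", False),  # unaccepted route
        ("TIMOLOL", None, "OPHTHALMIC", False),   # name mismatch
    ])
    def test_name_and_route_rule(self, atropine_dict, drugname, prod_ai, route, expected):
        flags = match_target_drug(self._tables(drugname, prod_ai, route), atropine_dict)
        assert flags.loc["P1"] == expected

    def test_monotone_in_dictionary(self, atropine_dict):
        tables = self._tables("HOMATROPINE HYDROBROMIDE", None, "TOPICAL OCULAR")
        base = match_target_drug(tables, atropine_dict)
        richer = DrugDictionary(
            generic_names=atropine_dict.generic_names | {"HOMATROPINE"},
            brand_names=atropine_dict.brand_names,
            accepted_routes=atropine_dict.accepted_routes | {"TOPICAL OCULAR"},
        )
        extended = match_target_drug(tables, richer)
        assert (extended | ~base).all()  # adding terms never unflags
        assert extended.loc["P1"] and not base.loc["P1"]

    def test_empty_dictionary_is_an_error(self):
        with pytest.raises(ValueError):
            DrugDictionary(generic_names=frozenset(), brand_names=frozenset(),
                           accepted_routes=frozenset({"OPHTHALMIC"}))

    def test_normalization_idempotent(self):
        once = normalize_name(" Atropine  Sulfate 1% ")
        assert normalize_name(once) == once == "ATROPINE SULFATE 1"


class TestExtractEvents:
    def test_repeated_pts_collapse_to_set(self):
        tables = make_tables(
            demo=[demo_row("P1")],
            reac=[{"primaryid": "P1", "pt": "Mydriasis"},
                  {"primaryid": "P1", "pt": "MYDRIASIS "},
                  {"primaryid": "P1", "pt": "Eye pain"}],
        )
        cases = extract_events(tables, pd.Series(True, index=["P1"]))
        assert cases.cases["pts"].iloc[0] == frozenset({"Mydriasis", "Eye pain"})

    def test_age_30_months_bins_to_infant_group(self):
        assert age_group_of(30, "months") == "<=3"

    @pytest.mark.parametrize("value,unit,expected", [
        (3, "years", "<=3"),
        (4, "years", "4-18"),
        (18, "years", "4-18"),
        (19, "years", "19-64"),
        (64, "years", "19-64"),
        (65, "years", ">=65"),
        (400, "days", "<=3"),
        (None, "years", None),
        (10, None, None),
    ])
    def test_age_bin_boundaries(self, value, unit, expected):
        assert age_group_of(value, unit) == expected

    def test_missing_sex_kept_as_missing_category(self):
        tables = make_tables(
            demo=[demo_row("P1", sex=None)],
            reac=[{"primaryid": "P1", "pt": "Rash"}],
        )
        cases = extract_events(tables, pd.Series(True, index=["P1"]))
        assert pd.isna(cases.cases["sex"].iloc[0])
        summary = descriptive_summary(cases)
        assert summary["sex"]["category"].tolist() == ["Missing or unknown"]
        assert summary["sex"]["pct"].tolist() == [100.0]

    def test_case_without_reactions_dropped_and_counted(self):
        tables = make_tables(
            demo=[demo_row("P1"), demo_row("P2")],
            reac=[{"primaryid": "P2", "pt": "Rash"}],
        )
        cases = extract_events(tables, pd.Series(True, index=["P1", "P2"]))
        assert len(cases) == 1
        assert cases.provenance["dropped_no_reaction"] == 1


class TestProvenance:
    def test_counts_partition_raw_reports(self, atropine_dict):
        tables, _ = generate(SyntheticConfig(n_reports=400, duplicate_rate=0.15, seed=5))
        cases = clean_pipeline(tables, atropine_dict)
        p = cases.provenance
        assert p["raw_reports"] == len(tables.demo)
        assert p["raw_reports"] == p["dropped_duplicates"] + p["dropped_no_reaction"] + p["retained"]


class TestDescriptiveSummary:
    def test_percentages_match_reporting_convention(self):
        assert percentage(749, 1511) == 49.57
        assert percentage(804, 1511) == 53.21

    def test_summary_counts_and_missing_rows(self):
        cases = make_cases([
            {"caseid": "c1", "target_drug": True, "pts": {"A"}, "sex": "male",
             "age_group": "19-64", "country": "CA", "outcomes": {"death"}},
            {"caseid": "c2", "target_drug": True, "pts": {"A"}, "sex": "male"},
            {"caseid": "c3", "target_drug": True, "pts": {"B"}, "sex": "female",
             "indications": {"Myopia"}},
            {"caseid": "c4", "target_drug": True, "pts": {"B"}},
            {"caseid": "c5", "target_drug": False, "pts": {"A"}, "sex": "male"},
        ])
        summary = descriptive_summary(cases)
        sex = summary["sex"].set_index("category")
        assert sex.loc["Male", "n"] == 2 and sex.loc["Male", "pct"] == 50.0
        assert sex.loc["Missing or unknown", "n"] == 1
        outcomes = summary["outcomes"].set_index("category")
        assert outcomes.loc["Death", "n"] == 1
        assert outcomes.loc["Missing or unknown", "n"] == 3
        indications = summary["indications"].set_index("category")
        assert indications.loc["Myopia", "pct"] == 25.0

    def test_no_target_cases_is_an_error(self):
        cases = make_cases([{"caseid": "c1", "target_drug": False, "pts": {"A"}}])
        with pytest.raises(ValueError):
            descriptive_summary(cases)
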