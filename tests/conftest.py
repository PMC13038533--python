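"""Shared fixtures: compact builders for canonical quarterly tables."""

from __future__ import annotations

import pandas as pd
import pytest

from pvsignal import CleanCaseSet, DrugDictionary, QuarterlyTables

DEMO_COLUMNS = ["primaryid", "caseid", "caseversion", "fda_dt", "sex",
                "country", "event_dt", "age_value", "age_unit"]
DRUG_COLUMNS = ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "route"]
REAC_COLUMNS = ["primaryid", "pt"]
OUTC_COLUMNS = ["primaryid", "outcome_code"]
INDI_COLUMNS = ["primaryid", "indi_drug_seq", "indi_pt"]

_INT_COLS = {"caseversion", "fda_dt", "event_dt", "drug_seq", "indi_drug_seq"}
_FLOAT_COLS = {"age_value"}


def _frame(rows: list[dict], columns: list[str]) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=columns)
    for col in columns:
        if col in _INT_COLS:
            frame[col] = pd.to_numeric(frame[col], errors="coerce").astype("Int64")
        elif col in _FLOAT_COLS:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        else:
            frame[col] = frame[col].astype("string")
    return frame


def make_tables(demo=(), drug=(), reac=(), outc=(), indi=()) -> QuarterlyTables:
    """Build canonical typed tables from row dicts; omitted fields are missing."""
    return QuarterlyTables(
        demo=_frame(list(demo), DEMO_COLUMNS),
        drug=_frame(list(drug), DRUG_COLUMNS),
        reac=_frame(list(reac), REAC_COLUMNS),
        outc=_frame(list(outc), OUTC_COLUMNS),
        indi=_frame(list(indi), INDI_COLUMNS),
        quarter_label="test",
    )


def demo_row(pid, caseid=None, version=1, fda_dt=20240101, **kw) -> dict:
    return {"primaryid": pid, "caseid": caseid or pid, "caseversion": version,
            "fda_dt": fda_dt, **kw}


def make_cases(rows: list[dict]) -> CleanCaseSet:
    """Case-set builder: each row needs caseid, target_drug, pts (iterable)."""
    records = []
    for row in rows:
        records.append({
            "caseid": row["caseid"],
            "sex": row.get("sex", pd.NA),
            "age_group": row.get("age_group", pd.NA),
            "country": row.get("country", pd.NA),
            "indications": frozenset(row.get("indications", ())),
            "outcomes": frozenset(row.get("outcomes", ())),
            "target_drug": bool(row["target_drug"]),
            "pts": frozenset(row["pts"]),
        })
    frame = pd.DataFrame(records, columns=["caseid", "sex", "age_group", "country",
                                           "indications", "outcomes", "target_drug", "pts"])
    frame["target_drug"] = frame["target_drug"].astype(bool)
    for col in ("sex", "age_group", "country"):
        frame[col] = frame[col].astype("string")
    return CleanCaseSet(cases=frame, provenance={"raw_reports": len(frame),
                                                 "dropped_duplicates": 0,
                                                 "dropped_no_reaction": 0,
                                                 "retained": len(frame)})


@pytest.fixture
def atropine_dict() -> DrugDictionary:
    return DrugDictionary(
        generic_names=frozenset({"ATROPINE"}),
        brand_names=frozenset({"ISOPTO ATROPINE"}),
        accepted_routes=frozenset({"OPHTHALMIC", "OCULAR", "INTRAOCULAR"}),
    )
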