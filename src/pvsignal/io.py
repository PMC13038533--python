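"""Reading and writing FAERS-dialect quarterly report tables.

Public FAERS quarterly extracts ship as ``$``-delimited ASCII files, one per
table (DEMO, DRUG, REAC, OUTC, INDI), with a single header row. This module
parses them into typed :class:`pandas.DataFrame` objects with canonical
lower-case column names, and serializes the pipeline's cleaned case set with
a round-trip-safe missing-value convention.

Schema drift across quarters is tolerated: column names are matched
case-insensitively after trimming, and unknown extra columns are ignored with
a warning. Dates are kept as ``YYYYMMDD`` integers; the deduplication rules
only need their ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

FAERS_DELIMITER = "$"

#: canonical (lower-case) column names required per table; extra columns are
#: dropped with a warning, missing ones raise.
REQUIRED_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid", "caseversion", "fda_dt"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
}

#: optional columns kept when present
OPTIONAL_COLUMNS: dict[str, list[str]] = {
    "demo": ["sex", "age", "age_cod", "occr_country", "event_dt"],
    "drug": ["prod_ai", "route"],
    "reac": [],
    "outc": [],
    "indi": [],
}

#: accepted header aliases (lower-case) -> canonical name
COLUMN_ALIASES: dict[str, str] = {
    "gndr_cod": "sex",  # pre-2014 DEMO files code sex as GNDR_COD
    "drug_seq1": "drug_seq",
    "indi_drug_seq": "indi_drug_seq",
    "reporter_country": "occr_country",
}

SEX_CODES = {"M": "male", "F": "female"}
AGE_UNIT_CODES = {
    "YR": "years",
    "YEAR": "years",
    "YRS": "years",
    "MON": "months",
    "MO": "months",
    "DY": "days",
    "DAY": "days",
}
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "OT": "other_serious",
}


@dataclass
class QuarterlyTables:
    """The five raw report tables for one or more quarters, pre-cleaning."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    quarter_label: str = ""

    def table_names(self) -> tuple[str, ...]:
        return ("demo", "drug", "reac", "outc", "indi")

    def copy(self) -> "QuarterlyTables":
        return QuarterlyTables(
            demo=self.demo.copy(),
            drug=self.drug.copy(),
            reac=self.reac.copy(),
            outc=self.outc.copy(),
            indi=self.indi.copy(),
            quarter_label=self.quarter_label,
        )

    def check_referential_integrity(self) -> dict[str, int]:
        """Count rows in child tables whose primaryid is absent from DEMO.

        Violations are logged, not fatal: real quarters contain orphans.
        """
        known = set(self.demo["primaryid"])
        orphans = {}
        for name in ("drug", "reac", "outc", "indi"):
            table = getattr(self, name)
            n = int((~table["primaryid"].isin(known)).sum())
            orphans[name] = n
            if n:
                logger.warning("%s: %d rows reference a primaryid absent from DEMO", name, n)
        return orphans


def parse_date_yyyymmdd(values: pd.Series) -> pd.Series:
    """Parse a column of YYYYMMDD date strings to nullable integers.

    Anything that is not an 8-digit valid calendar date becomes missing and
    is counted in a warning.
    """
    text = values.astype("string").str.strip()
    eight_digits = text.str.fullmatch(r"\d{8}").fillna(False)
    parsed = pd.to_datetime(text.where(eight_digits), format="%Y%m%d", errors="coerce")
    out = pd.Series(pd.NA, index=values.index, dtype="Int64")
    ok = parsed.notna()
    out[ok] = text[ok].astype("int64")
    n_bad = int((text.notna() & (text != "") & ~ok).sum())
    if n_bad:
        logger.warning("%d unparseable dates set to missing", n_bad)
    return out


def _normalize_header(columns: list[str]) -> list[str]:
    out = []
    for c in columns:
        c = str(c).strip().lower()
        out.append(COLUMN_ALIASES.get(c, c))
    return out


def _read_raw(path: Path, delimiter: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            dtype=str,
            keep_default_na=False,
            na_values=[""],
            encoding="utf-8",
            encoding_errors="replace",
            engine="python",
        )
    except pd.errors.EmptyDataError:
        logger.warning("%s is empty; returning empty table", path)
        return pd.DataFrame()
    frame.columns = _normalize_header(list(frame.columns))
    return frame


def _coerce_table(frame: pd.DataFrame, name: str, path: Path) -> pd.DataFrame:
    required = REQUIRED_COLUMNS[name]
    optional = OPTIONAL_COLUMNS[name]
    if frame.empty and frame.shape[1] == 0:
        return pd.DataFrame(columns=required + optional)
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"{name.upper()} file {path} is missing mandatory column {col.upper()!r}")
    keep = [c for c in required + optional if c in frame.columns]
    extra = [c for c in frame.columns if c not in keep]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", name.upper(), extra)
    frame = frame[keep].copy()
    for col in optional:
        if col not in frame.columns:
            frame[col] = pd.NA

    # string fields: trim whitespace
    for col in frame.columns:
        if frame[col].dtype == object or str(frame[col].dtype) == "string":
            frame[col] = frame[col].astype("string").str.strip()
            frame.loc[frame[col] == "", col] = pd.NA

    if name == "demo":
        frame["caseversion"] = pd.to_numeric(frame["caseversion"], errors="coerce").astype("Int64")
        frame["fda_dt"] = parse_date_yyyymmdd(frame["fda_dt"])
        frame["event_dt"] = parse_date_yyyymmdd(frame["event_dt"])
        frame["sex"] = frame["sex"].str.upper().map(SEX_CODES).astype("string")
        frame["age_value"] = pd.to_numeric(frame["age"], errors="coerce")
        frame.loc[frame["age_value"] < 0, "age_value"] = float("nan")
        frame["age_unit"] = frame["age_cod"].str.upper().map(AGE_UNIT_CODES).astype("string")
        frame = frame.rename(columns={"occr_country": "country"})
        frame = frame.drop(columns=["age", "age_cod"])
        if frame["primaryid"].isna().any():
            n = int(frame["primaryid"].isna().sum())
            logger.warning("DEMO: %d rows with empty primaryid kept and flagged", n)
    elif name == "drug":
        frame["drug_seq"] = pd.to_numeric(frame["drug_seq"], errors="coerce").astype("Int64")
        frame["role_cod"] = frame["role_cod"].str.upper()
    elif name == "reac":
        frame = frame[frame["pt"].notna()].copy()
    elif name == "outc":
        code = frame["outc_cod"].str.upper()
        unknown = code.notna() & ~code.isin(OUTCOME_CODES)
        if unknown.any():
            logger.warning("OUTC: %d unknown outcome codes set to missing", int(unknown.sum()))
        frame["outcome_code"] = code.map(OUTCOME_CODES).astype("string")
        frame = frame.drop(columns=["outc_cod"])
        frame = frame.drop_duplicates(subset=["primaryid", "outcome_code"])
    elif name == "indi":
        frame["indi_drug_seq"] = pd.to_numeric(frame["indi_drug_seq"], errors="coerce").astype("Int64")
    return frame.reset_index(drop=True)


def read_quarterly_tables(
    paths: Mapping[str, str | Path],
    delimiter: str = FAERS_DELIMITER,
    quarter_label: str = "",
) -> QuarterlyTables:
    """Read the five FAERS-dialect ASCII tables into a :class:`QuarterlyTables`.

    Parameters
    ----------
    paths
        Mapping with keys ``demo, drug, reac, outc, indi`` to file paths.
        Each file has one header row; fields are ``delimiter``-separated.
    delimiter
        Field separator; ``"$"`` as in the public extracts, but ``","`` and
        ``"\\t"`` are accepted for hand-written fixtures.

    Raises
    ------
    ValueError
        If a mandatory column is absent (the error names the column).
    FileNotFoundError
        If a path does not exist.
    """
    tables = {}
    for name in ("demo", "drug", "reac", "outc", "indi"):
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"{name.upper()} file not found: {path}")
        raw = _read_raw(path, delimiter)
        table = _coerce_table(raw, name, path)
        logger.info("%s: parsed %d rows from %s", name.upper(), len(table), path)
        tables[name] = table
    qt = QuarterlyTables(quarter_label=quarter_label, **tables)
    qt.check_referential_integrity()
    return qt


_SEX_CODES_OUT = {v: k for k, v in SEX_CODES.items()}
_AGE_UNIT_OUT = {"years": "YR", "months": "MON", "days": "DY"}
_OUTCOME_OUT = {v: k for k, v in OUTCOME_CODES.items()}


def write_quarterly_tables(
    tables: QuarterlyTables,
    directory: str | Path,
    delimiter: str = FAERS_DELIMITER,
) -> dict[str, Path]:
    """Write a :class:`QuarterlyTables` back to FAERS-dialect ASCII files.

    Inverse of :func:`read_quarterly_tables` up to field normalization
    (sex/age-unit/outcome codes are re-encoded; missing values become empty
    fields). Returns the path written per table.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    demo = tables.demo.copy()
    demo["sex"] = demo["sex"].map(_SEX_CODES_OUT)
    demo["age"] = demo["age_value"]
    demo["age_cod"] = demo["age_unit"].map(_AGE_UNIT_OUT)
    demo = demo.rename(columns={"country": "occr_country"})
    demo = demo[["primaryid", "caseid", "caseversion", "fda_dt", "sex",
                 "age", "age_cod", "occr_country", "event_dt"]]
    outc = tables.outc.copy()
    outc["outc_cod"] = outc["outcome_code"].map(_OUTCOME_OUT)
    frames = {
        "demo": demo,
        "drug": tables.drug[["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "route"]],
        "reac": tables.reac[["primaryid", "pt"]],
        "outc": outc[["primaryid", "outc_cod"]],
        "indi": tables.indi[["primaryid", "indi_drug_seq", "indi_pt"]],
    }
    for name, frame in frames.items():
        path = directory / f"{name.upper()}{tables.quarter_label}.txt"
        out = frame.copy()
        out.columns = [c.upper() for c in out.columns]
        out.to_csv(path, sep=delimiter, index=False, na_rep="", float_format="%g")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# cleaned-dataset serialization
# ---------------------------------------------------------------------------

#: token separating members of a set-valued field in the cleaned CSV
SET_DELIMITER = "|"
#: the cleaned CSV writes missing scalars as the empty string; the sidecar
#: schema records this convention so "" round-trips to missing, never to "".
MISSING_TOKEN = ""

_CLEAN_COLUMNS = [
    "caseid",
    "sex",
    "age_group",
    "country",
    "indications",
    "outcomes",
    "target_drug",
    "pts",
]
_SET_COLUMNS = ("indications", "outcomes", "pts")


def _join_set(value) -> str:
    if not value:
        return MISSING_TOKEN
    return SET_DELIMITER.join(sorted(value))


def _split_set(value) -> frozenset:
    if value is None or (isinstance(value, float)) or pd.isna(value) or value == MISSING_TOKEN:
        return frozenset()
    return frozenset(str(value).split(SET_DELIMITER))


def write_clean_dataset(cases, path: str | Path) -> Path:
    """Serialize a cleaned case set to CSV plus a sidecar JSON schema.

    Missing scalars are written as the empty string, set-valued fields as
    ``|``-joined sorted members; the sidecar documents both conventions and
    carries the provenance counts. ``read_clean_dataset(write(x)) == x``
    field-for-field.
    """
    path = Path(path)
    frame = cases.cases.copy()
    for col in _SET_COLUMNS:
        frame[col] = frame[col].map(_join_set)
    frame["target_drug"] = frame["target_drug"].map({True: "1", False: "0"})
    for col in ("sex", "age_group", "country"):
        frame[col] = frame[col].astype("string").fillna(MISSING_TOKEN)
    frame = frame[_CLEAN_COLUMNS]
    frame.to_csv(path, index=False)
    schema = {
        "columns": _CLEAN_COLUMNS,
        "set_columns": list(_SET_COLUMNS),
        "set_delimiter": SET_DELIMITER,
        "missing_token": MISSING_TOKEN,
        "missing_means": "value absent (never the literal empty string)",
        "provenance": cases.provenance,
    }
    schema_path = path.with_suffix(path.suffix + ".schema.json")
    schema_path.write_text(json.dumps(schema, indent=2, sort_keys=True))
    return path


def read_clean_dataset(path: str | Path):
    """Read back a cleaned case set written by :func:`write_clean_dataset`."""
    from .preprocess import CleanCaseSet  # local import: preprocess imports io

    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    for col in _SET_COLUMNS:
        frame[col] = frame[col].map(_split_set)
    frame["target_drug"] = frame["target_drug"].map({"1": True, "0": False})
    for col in ("sex", "age_group", "country"):
        frame[col] = frame[col].astype("string")
        frame.loc[frame[col] == MISSING_TOKEN, col] = pd.NA
    schema_path = path.with_suffix(path.suffix + ".schema.json")
    provenance: dict[str, int] = {}
    if schema_path.exists():
        provenance = json.loads(schema_path.read_text()).get("provenance", {})
    return CleanCaseSet(cases=frame, provenance=provenance)
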