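"""Report cleaning: deduplication, suspect-role filtering, target-drug
identification with route restriction, and extraction into an
analysis-ready case set.

The cleaning mirrors the standard regulatory-agency workflow for
spontaneous-report databases:

1. **Deduplication** by exact key matching on (PRIMARYID, CASEID,
   CASEVERSION, FDA_DT): among records sharing a PRIMARYID keep the latest
   FDA_DT, breaking ties by the largest CASEID then CASEVERSION; among
   records sharing a CASEID keep only the most recent case version.
2. **Suspect roles**: only Primary Suspect (PS) and Secondary Suspect (SS)
   drug records count toward target-drug identification; Concomitant (C)
   and Interacting (I) records are noise for that purpose.
3. **Target-drug matching**: generic and brand names are searched in both
   DRUGNAME and PROD_AI after normalization, and a report qualifies only if
   the matching suspect record's administration ROUTE is in the accepted
   (ocular) set — records with a missing or unaccepted route never qualify.
4. **Event extraction**: one case per retained report, with MedDRA
   preferred terms (PTs) normalized, demographics binned, and missing
   values kept as an explicit "Missing or unknown" category.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .io import QuarterlyTables

logger = logging.getLogger(__name__)

SUSPECT_ROLES = frozenset({"PS", "SS"})
KNOWN_ROLES = frozenset({"PS", "SS", "C", "I"})

#: FAERS route vocabulary accepted as ocular administration (configurable)
DEFAULT_ACCEPTED_ROUTES = frozenset({"OPHTHALMIC", "OCULAR", "INTRAOCULAR", "TOPICAL OCULAR"})

MISSING_LABEL = "Missing or unknown"

AGE_GROUPS = ("<=3", "4-18", "19-64", ">=65")

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def normalize_name(name: str | None) -> str:
    """Normalize a free-text drug name: uppercase, strip punctuation,
    collapse internal whitespace. Idempotent."""
    if name is None or (isinstance(name, float) and pd.isna(name)) or pd.isna(name):
        return ""
    text = _PUNCT_RE.sub(" ", str(name).upper())
    return _WS_RE.sub(" ", text).strip()


def normalize_pt(pt: str) -> str:
    """Canonical form of a MedDRA preferred term: collapse whitespace,
    capitalize the first letter only (MedDRA sentence-case convention)."""
    text = _WS_RE.sub(" ", str(pt)).strip()
    if not text:
        return text
    return text[0].upper() + text[1:].lower()


@dataclass(frozen=True)
class DrugDictionary:
    """Target-drug definition: name lists plus the accepted route vocabulary.

    Matching is substring containment of normalized dictionary terms inside
    the normalized DRUGNAME / PROD_AI (free-text names carry salts and
    strengths, e.g. ``ATROPINE SULFATE 1%``); exact-token matching is
    available via ``match_mode="token"``.
    """

    generic_names: frozenset[str]
    brand_names: frozenset[str]
    accepted_routes: frozenset[str] = DEFAULT_ACCEPTED_ROUTES
    match_mode: str = "substring"

    def __post_init__(self):
        object.__setattr__(self, "generic_names", frozenset(normalize_name(n) for n in self.generic_names) - {""})
        object.__setattr__(self, "brand_names", frozenset(normalize_name(n) for n in self.brand_names) - {""})
        object.__setattr__(self, "accepted_routes", frozenset(normalize_name(r) for r in self.accepted_routes) - {""})
        if not (self.generic_names or self.brand_names) or not self.accepted_routes:
            raise ValueError("DrugDictionary needs at least one name and one accepted route")
        if self.match_mode not in ("substring", "token"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    @property
    def all_names(self) -> frozenset[str]:
        return self.generic_names | self.brand_names

    def matches_name(self, raw: str | None) -> bool:
        text = normalize_name(raw)
        if not text:
            return False
        if self.match_mode == "token":
            tokens = set(text.split())
            return any(set(term.split()) <= tokens for term in self.all_names)
        return any(term in text for term in self.all_names)

    def accepts_route(self, raw: str | None) -> bool:
        return normalize_name(raw) in self.accepted_routes


@dataclass
class CleanCaseSet:
    """Deduplicated, event-level case set plus per-step provenance counts.

    ``cases`` columns: caseid, sex, age_group, country, indications (set),
    outcomes (set), target_drug (bool), pts (frozenset of PT strings).
    """

    cases: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cases)

    def target_cases(self) -> pd.DataFrame:
        return self.cases[self.cases["target_drug"]]


# ---------------------------------------------------------------------------
# Step 1: deduplication
# ---------------------------------------------------------------------------

def deduplicate(tables: QuarterlyTables) -> QuarterlyTables:
    """Collapse duplicate reports by exact key matching.

    Within a PRIMARYID the record with the latest FDA_DT wins; at equal
    FDA_DT the largest CASEID, then the largest CASEVERSION wins; a full-key
    tie is broken by file order (last wins, count logged). Within a CASEID
    only the most recent version (largest CASEVERSION, then latest FDA_DT)
    is retained. Child-table rows of dropped reports are removed.

    Idempotent, and never increases any table's row count.
    """
    demo = tables.demo.copy()
    if demo.empty:
        return tables.copy()
    demo["_order"] = range(len(demo))
    # sortable numeric caseid where possible (FAERS caseids are numeric)
    demo["_caseid_num"] = pd.to_numeric(demo["caseid"], errors="coerce")

    def _rank(frame: pd.DataFrame, by: list[str]) -> pd.DataFrame:
        return frame.sort_values(by=by + ["_order"], kind="stable", na_position="first")

    # pass 1: one survivor per PRIMARYID (latest FDA_DT, then caseid/version)
    ranked = _rank(demo, ["fda_dt", "_caseid_num", "caseversion"])
    n_before = len(ranked)
    ranked = ranked.drop_duplicates(subset=["primaryid"], keep="last")
    full_key_ties = n_before - len(ranked)

    # pass 2: one survivor per CASEID (most recent version)
    has_caseid = ranked["caseid"].notna()
    with_case = _rank(ranked[has_caseid], ["caseversion", "fda_dt"])
    with_case = with_case.drop_duplicates(subset=["caseid"], keep="last")
    demo_out = pd.concat([with_case, ranked[~has_caseid]])
    demo_out = demo_out.sort_values("_order").drop(columns=["_order", "_caseid_num"])

    dropped = len(demo) - len(demo_out)
    if full_key_ties:
        logger.info("deduplicate: %d records removed at the PRIMARYID pass", full_key_ties)
    logger.info("deduplicate: %d of %d reports dropped as duplicates", dropped, len(demo))

    keep_ids = set(demo_out["primaryid"].dropna())
    out = {"demo": demo_out.reset_index(drop=True)}
    for name in ("drug", "reac", "outc", "indi"):
        table = getattr(tables, name)
        out[name] = table[table["primaryid"].isin(keep_ids)].reset_index(drop=True)
    return QuarterlyTables(quarter_label=tables.quarter_label, **out)


# ---------------------------------------------------------------------------
# Step 2: suspect-role filtering
# ---------------------------------------------------------------------------

def filter_suspect_roles(tables: QuarterlyTables) -> QuarterlyTables:
    """Drop drug records whose role is not PS or SS.

    Reports whose only link to the target drug was a concomitant or
    interacting record can then no longer qualify as target cases. Unknown
    role codes are treated as non-suspect and logged.
    """
    drug = tables.drug
    role = drug["role_cod"].astype("string").str.strip().str.upper()
    unknown = role.notna() & ~role.isin(KNOWN_ROLES)
    if unknown.any():
        logger.warning("filter_suspect_roles: %d rows with unknown role codes treated as non-suspect",
                       int(unknown.sum()))
    keep = role.isin(SUSPECT_ROLES)
    out = tables.copy()
    out.drug = drug[keep.fillna(False)].reset_index(drop=True)
    logger.info("filter_suspect_roles: kept %d of %d drug rows", len(out.drug), len(drug))
    return out


# ---------------------------------------------------------------------------
# Step 3: target-drug identification
# ---------------------------------------------------------------------------

def match_target_drug(tables: QuarterlyTables, dictionary: DrugDictionary) -> pd.Series:
    """Flag each report whose suspect drug records identify the target drug.

    A report qualifies iff some suspect drug row matches the dictionary on
    DRUGNAME or PROD_AI *and* carries an accepted administration route.
    Rows matching on name with a missing or unaccepted route never flag —
    only confirmed target-route administrations are analyzed.

    Returns a boolean Series indexed by primaryid over all reports in DEMO.
    Monotone in the dictionary: adding names or routes never unflags.
    """
    drug = tables.drug
    name_hit = drug["drugname"].map(dictionary.matches_name) | drug["prod_ai"].map(dictionary.matches_name)
    route_ok = drug["route"].map(dictionary.accepts_route)
    hits = drug.loc[(name_hit & route_ok).to_numpy(), "primaryid"]
    flagged = set(hits.dropna())
    n_name_only = int((name_hit & ~route_ok).sum())
    if n_name_only:
        logger.info("match_target_drug: %d name matches excluded for missing/unaccepted route", n_name_only)
    index = tables.demo["primaryid"]
    return pd.Series(index.isin(flagged).to_numpy(), index=index, name="target_drug")


# ---------------------------------------------------------------------------
# Step 4: event extraction
# ---------------------------------------------------------------------------

def age_in_years(age_value, age_unit) -> float | None:
    if pd.isna(age_value) or pd.isna(age_unit):
        return None
    factor = {"years": 1.0, "months": 1.0 / 12.0, "days": 1.0 / 365.25}.get(str(age_unit))
    if factor is None:
        return None
    return float(age_value) * factor


def age_group_of(age_value, age_unit) -> str | None:
    """Bin an age into the strata <=3 / 4-18 / 19-64 / >=65 (years).

    Months/days are converted to years, then floored to completed years
    before binning (30 months = 2.5 years -> <=3; 18 years 6 months is
    still 18 completed years -> 4-18). Unknown units map to missing.
    """
    years = age_in_years(age_value, age_unit)
    if years is None:
        return None
    whole = math.floor(years)
    if whole <= 3:
        return "<=3"
    if whole <= 18:
        return "4-18"
    if whole <= 64:
        return "19-64"
    return ">=65"


def extract_events(tables: QuarterlyTables, flags: pd.Series) -> CleanCaseSet:
    """Build one clean case per retained report.

    PTs are whitespace/case-normalized and collected as a set (a case
    contributes a PT at most once); demographics are binned with missing
    values kept as an explicit missing category; cases with zero reaction
    rows are dropped and counted in the provenance.
    """
    demo = tables.demo
    pts_by_id = (
        tables.reac.assign(pt=tables.reac["pt"].map(normalize_pt))
        .groupby("primaryid")["pt"].agg(frozenset)
    )
    outc_by_id = tables.outc.dropna(subset=["outcome_code"]).groupby("primaryid")["outcome_code"].agg(frozenset)
    indi = tables.indi.dropna(subset=["indi_pt"])
    indi_by_id = indi.assign(indi_pt=indi["indi_pt"].map(normalize_pt)).groupby("primaryid")["indi_pt"].agg(frozenset)

    rows = []
    n_no_reaction = 0
    for rec in demo.itertuples(index=False):
        pid = rec.primaryid
        pts = pts_by_id.get(pid, frozenset())
        if not pts:
            n_no_reaction += 1
            continue
        rows.append({
            "caseid": rec.caseid if pd.notna(rec.caseid) else pid,
            "sex": rec.sex if pd.notna(rec.sex) else pd.NA,
            "age_group": age_group_of(rec.age_value, rec.age_unit) or pd.NA,
            "country": rec.country if pd.notna(rec.country) else pd.NA,
            "indications": indi_by_id.get(pid, frozenset()),
            "outcomes": outc_by_id.get(pid, frozenset()),
            "target_drug": bool(flags.get(pid, False)),
            "pts": pts,
        })
    cases = pd.DataFrame(rows, columns=["caseid", "sex", "age_group", "country",
                                        "indications", "outcomes", "target_drug", "pts"])
    if not cases.empty:
        cases["sex"] = cases["sex"].astype("string")
        cases["age_group"] = cases["age_group"].astype("string")
        cases["country"] = cases["country"].astype("string")
        dup_cases = int(cases["caseid"].duplicated().sum())
        if dup_cases:
            logger.warning("extract_events: %d duplicate caseids after cleaning", dup_cases)
    provenance = {
        "raw_cases": len(demo) + n_no_reaction * 0,  # filled by clean_pipeline
        "dropped_no_reaction": n_no_reaction,
        "retained": len(cases),
    }
    provenance["raw_cases"] = provenance["dropped_no_reaction"] + provenance["retained"]
    logger.info("extract_events: %d cases retained, %d dropped (no reactions)", len(cases), n_no_reaction)
    return CleanCaseSet(cases=cases, provenance=provenance)


def clean_pipeline(tables: QuarterlyTables, dictionary: DrugDictionary) -> CleanCaseSet:
    """Run deduplication, role filtering, target matching and extraction.

    The provenance counts partition the raw report count exactly:
    ``raw_reports = dropped_duplicates + dropped_no_reaction + retained``.
    """
    n_raw = len(tables.demo)
    deduped = deduplicate(tables)
    n_dupes = n_raw - len(deduped.demo)
    suspect = filter_suspect_roles(deduped)
    flags = match_target_drug(suspect, dictionary)
    cases = extract_events(deduped, flags)
    cases.provenance = {
        "raw_reports": n_raw,
        "dropped_duplicates": n_dupes,
        "dropped_no_reaction": cases.provenance["dropped_no_reaction"],
        "retained": cases.provenance["retained"],
        "target_cases": int(cases.cases["target_drug"].sum()) if len(cases) else 0,
    }
    return cases


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def percentage(count: int, denominator: int) -> float:
    """A percentage rounded to two decimals, the convention used in
    descriptive report tables (749 of 1511 -> 49.57)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / denominator, 2)


def _freq_table(labels: pd.Series, denominator: int, order: list[str] | None = None) -> pd.DataFrame:
    filled = labels.fillna(MISSING_LABEL)
    counts = filled.value_counts()
    if order is not None:
        keys = [k for k in order if k in counts.index]
        keys += [k for k in counts.index if k not in keys]
        counts = counts.reindex(keys)
    frame = counts.rename_axis("category").reset_index(name="n")
    frame["pct"] = [percentage(int(n), denominator) for n in frame["n"]]
    return frame


def descriptive_summary(cases: CleanCaseSet) -> dict[str, pd.DataFrame]:
    """Frequency tables (n, %) over the target-drug cases.

    One table each for sex, age group, indications, reporting countries and
    clinical outcomes; the denominator is the number of target cases, and
    every table carries an explicit "Missing or unknown" row when missing
    values are present. Set-valued fields (indications, outcomes) count a
    case once per distinct member; their missing row counts cases with an
    empty set.
    """
    target = cases.target_cases()
    denom = len(target)
    if denom == 0:
        raise ValueError("no target-drug cases to summarize")

    sex_labels = target["sex"].map({"male": "Male", "female": "Female"})
    out = {
        "sex": _freq_table(sex_labels, denom, ["Male", "Female", MISSING_LABEL]),
        "age_group": _freq_table(target["age_group"], denom, list(AGE_GROUPS) + [MISSING_LABEL]),
    }

    outcome_labels = {
        "other_serious": "Other serious (important medical event)",
        "hospitalization": "Hospitalization - initial or prolonged",
        "disability": "Disability",
        "death": "Death",
        "life_threatening": "Life-threatening",
    }
    for name, label_map in (("indications", None), ("countries", None), ("outcomes", outcome_labels)):
        col = "country" if name == "countries" else name
        if name == "countries":
            labels = target[col]
        else:
            exploded = []
            for members in target[col]:
                if members:
                    exploded.extend(sorted(members))
                else:
                    exploded.append(MISSING_LABEL)
            labels = pd.Series(exploded, dtype="string") if exploded else pd.Series([], dtype="string")
            if label_map:
                labels = labels.map(lambda v: label_map.get(v, v))
        out[name] = _freq_table(labels, denom)
    return out
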