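"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of FAERS quarterly extracts — multi-source duplicate
reports keyed by PRIMARYID/CASEID/CASEVERSION/FDA_DT, drug records with
role codes and free-text names, routes with missing values, PT-coded
reactions, demographics with missing categories — while planting known
relative reporting rates for chosen drug-event pairs so that every
pipeline stage and statistical property can be exercised offline against
the generator's own bookkeeping.

The planted effect is a multiplier on the event-selection probability for
reports that will survive the cleaning rules as target-drug cases
(suspect role + accepted route), renormalized over the event vocabulary;
the planted ``log2 RR`` is then the recoverable estimand of the shrunk
observed/expected ratio.

What the generator deliberately does **not** emulate: drug
co-prescription correlation, reporting time trends across quarters, and
MedDRA coding noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import QuarterlyTables
from .preprocess import DrugDictionary, clean_pipeline
from .stats import DisproportionalityModel
from .terminology import TermMap

logger = logging.getLogger(__name__)

#: default event vocabulary: (PT, SOC, base sampling weight)
DEFAULT_EVENT_VOCAB: tuple[tuple[str, str, float], ...] = (
    ("Mydriasis", "Eye disorders", 0.040),
    ("Eye pain", "Eye disorders", 0.060),
    ("Vision blurred", "Eye disorders", 0.055),
    ("Eye irritation", "Eye disorders", 0.045),
    ("Visual acuity reduced", "Eye disorders", 0.035),
    ("Photophobia", "Eye disorders", 0.030),
    ("Conjunctival hyperaemia", "Eye disorders", 0.025),
    ("Endophthalmitis", "Infections and infestations", 0.012),
    ("Nasopharyngitis", "Infections and infestations", 0.050),
    ("Headache", "Nervous system disorders", 0.090),
    ("Dizziness", "Nervous system disorders", 0.070),
    ("Somnolence", "Nervous system disorders", 0.040),
    ("Anticholinergic syndrome", "Nervous system disorders", 0.008),
    ("Nausea", "Gastrointestinal disorders", 0.085),
    ("Diarrhoea", "Gastrointestinal disorders", 0.065),
    ("Dry mouth", "Gastrointestinal disorders", 0.035),
    ("Tachycardia", "Cardiac disorders", 0.030),
    ("Palpitations", "Cardiac disorders", 0.035),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.060),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.050),
    ("Fatigue", "General disorders and administration site conditions", 0.075),
    ("Pyrexia", "General disorders and administration site conditions", 0.045),
    ("Drug ineffective", "General disorders and administration site conditions", 0.040),
    ("Fall", "Injury, poisoning and procedural complications", 0.020),
)

DEFAULT_OTHER_DRUGS: tuple[str, ...] = (
    "TIMOLOL MALEATE", "LATANOPROST", "METFORMIN", "LISINOPRIL",
    "IBUPROFEN", "OMEPRAZOLE", "SERTRALINE", "AMOXICILLIN",
)

DEFAULT_ROLE_MIX: tuple[tuple[str, float], ...] = (("PS", 0.60), ("SS", 0.15), ("C", 0.20), ("I", 0.05))

_OTHER_ROUTES = ("ORAL", "INTRAVENOUS", "SUBCUTANEOUS", "TOPICAL")
_ACCEPTED_ROUTES = ("OPHTHALMIC", "OCULAR", "INTRAOCULAR")
_COUNTRIES = ("CA", "FR", "US", "GB", "DE")
_OUTCOME_CODES = ("other_serious", "hospitalization", "disability", "death", "life_threatening")
_OUTCOME_WEIGHTS = (0.58, 0.27, 0.05, 0.05, 0.05)
_INDICATIONS = ("Iridocyclitis", "Myopia", "Ophthalmological examination", "Uveitis")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for one synthetic quarter.

    Defaults describe a mid-sized quarter: 5,000 reports of which ~20%
    carry the target ophthalmic drug, realistic role and route mixes, 10%
    near-duplicates, and moderate demographic missingness.
    """

    n_reports: int = 5000
    target_generic: str = "ATROPINE"
    target_brands: tuple[str, ...] = ("ISOPTO ATROPINE", "ATROPEN")
    other_drugs: tuple[str, ...] = DEFAULT_OTHER_DRUGS
    event_vocab: tuple[tuple[str, str, float], ...] = DEFAULT_EVENT_VOCAB
    target_report_prob: float = 0.20
    target_route_prob: float = 0.75
    missing_route_prob: float = 0.15
    duplicate_rate: float = 0.10
    role_mix: tuple[tuple[str, float], ...] = DEFAULT_ROLE_MIX
    planted_effects: tuple[tuple[str, str, float], ...] = ()  # (drug, PT, RR)
    sex_missing_prob: float = 0.15
    age_missing_prob: float = 0.25
    country_missing_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 0:
            raise ValueError("n_reports must be non-negative")
        if len(self.event_vocab) < 2 or not (self.other_drugs or self.target_generic):
            raise ValueError("degenerate config: vocabularies must have at least two entries")
        for p in (self.target_report_prob, self.target_route_prob, self.missing_route_prob,
                  self.duplicate_rate, self.sex_missing_prob, self.age_missing_prob,
                  self.country_missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for _, _, rr in self.planted_effects:
            if rr < 0:
                raise ValueError("planted RR must be >= 0")

    def drug_dictionary(self) -> DrugDictionary:
        """The dictionary that identifies this config's target drug."""
        return DrugDictionary(
            generic_names=frozenset({self.target_generic}),
            brand_names=frozenset(self.target_brands),
            accepted_routes=frozenset(_ACCEPTED_ROUTES),
        )

    def term_map(self) -> TermMap:
        return TermMap.from_pairs((pt, soc) for pt, soc, _ in self.event_vocab)


@dataclass
class GroundTruth:
    """Generator bookkeeping that the pipeline's output must reproduce."""

    #: per emitted report (primaryid): will it survive cleaning as a target case?
    target_flags: pd.Series
    #: planted (drug, PT) -> RR
    planted_rr: dict[tuple[str, str], float]
    #: injected duplicate clusters: caseid -> [original primaryid, clone primaryid]
    duplicate_clusters: dict[str, list[str]]

    @property
    def n_injected_duplicates(self) -> int:
        return sum(len(v) - 1 for v in self.duplicate_clusters.values())


def _event_probs(config: SyntheticConfig, boosted: bool) -> np.ndarray:
    base = np.array([w for _, _, w in config.event_vocab], dtype=float)
    base = base / base.sum()
    if not boosted:
        return base
    pts = [pt for pt, _, _ in config.event_vocab]
    mult = np.ones_like(base)
    for drug, pt, rr in config.planted_effects:
        if drug.upper() == config.target_generic.upper() and pt in pts:
            mult[pts.index(pt)] = rr
    probs = base * mult
    total = probs.sum()
    if total <= 0:
        raise ValueError("planted effects zero out the whole event vocabulary")
    return probs / total


def generate(config: SyntheticConfig) -> tuple[QuarterlyTables, GroundTruth]:
    """Generate one synthetic quarter plus its ground truth.

    Identical seeds give byte-identical tables. Every injected duplicate
    cluster shares a CASEID with an incremented CASEVERSION and a later
    FDA_DT, so deduplication must collapse it to exactly one survivor.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    empty_truth = GroundTruth(
        target_flags=pd.Series(dtype=bool),
        planted_rr={(d, p): rr for d, p, rr in config.planted_effects},
        duplicate_clusters={},
    )
    if n == 0:
        empty = QuarterlyTables(
            demo=pd.DataFrame(columns=["primaryid", "caseid", "caseversion", "fda_dt",
                                       "sex", "country", "event_dt", "age_value", "age_unit"]),
            drug=pd.DataFrame(columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "route"]),
            reac=pd.DataFrame(columns=["primaryid", "pt"]),
            outc=pd.DataFrame(columns=["primaryid", "outcome_code"]),
            indi=pd.DataFrame(columns=["primaryid", "indi_drug_seq", "indi_pt"]),
            quarter_label="synthetic",
        )
        return empty, empty_truth

    caseids = np.array([f"{2_000_000 + i}" for i in range(n)])
    primaryids = np.array([f"{2_000_000 + i}1" for i in range(n)])  # caseid + version suffix
    fda_dt = 20240101 + rng.integers(0, 28, n)  # days within a reporting month

    carries_target = rng.random(n) < config.target_report_prob
    roles = [r for r, _ in config.role_mix]
    role_p = np.array([p for _, p in config.role_mix], dtype=float)
    role_p = role_p / role_p.sum()
    target_role = rng.choice(roles, size=n, p=role_p)
    route_u = rng.random(n)
    route_kind = np.where(route_u < config.missing_route_prob, "missing",
                          np.where(route_u < config.missing_route_prob
                                   + (1 - config.missing_route_prob) * config.target_route_prob,
                                   "accepted", "other"))
    target_route = np.where(route_kind == "accepted",
                            rng.choice(_ACCEPTED_ROUTES, size=n),
                            rng.choice(_OTHER_ROUTES, size=n))
    flags = carries_target & np.isin(target_role, ("PS", "SS")) & (route_kind == "accepted")

    # ---- drug table -------------------------------------------------------
    drug_rows = {k: [] for k in ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "route")}
    n_other = rng.choice([0, 1, 2, 3], size=n, p=[0.45, 0.30, 0.15, 0.10])
    n_other[~carries_target] = np.maximum(1, n_other[~carries_target])
    other_names = config.other_drugs
    use_brand = rng.random(n) < 0.5
    for i in range(n):
        seq = 1
        if carries_target[i]:
            name = config.target_brands[0] if use_brand[i] and config.target_brands else config.target_generic
            drug_rows["primaryid"].append(primaryids[i])
            drug_rows["drug_seq"].append(seq)
            drug_rows["role_cod"].append(target_role[i])
            drug_rows["drugname"].append(name)
            drug_rows["prod_ai"].append(config.target_generic + " SULFATE")
            drug_rows["route"].append(None if route_kind[i] == "missing" else target_route[i])
            seq += 1
        for _ in range(n_other[i]):
            drug_rows["primaryid"].append(primaryids[i])
            drug_rows["drug_seq"].append(seq)
            drug_rows["role_cod"].append(str(rng.choice(roles, p=role_p)))
            drug_rows["drugname"].append(str(rng.choice(other_names)))
            drug_rows["prod_ai"].append(None)
            drug_rows["route"].append(str(rng.choice(_OTHER_ROUTES)) if rng.random() > 0.2 else None)
            seq += 1
    drug = pd.DataFrame(drug_rows)

    # ---- reactions --------------------------------------------------------
    pts = np.array([pt for pt, _, _ in config.event_vocab])
    p_base = _event_probs(config, boosted=False)
    p_boost = _event_probs(config, boosted=True)
    k_events = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
    reac_pid, reac_pt = [], []
    for i in range(n):
        chosen = rng.choice(len(pts), size=k_events[i], p=p_boost if flags[i] else p_base)
        for j in chosen:
            reac_pid.append(primaryids[i])
            reac_pt.append(pts[j])
    reac = pd.DataFrame({"primaryid": reac_pid, "pt": reac_pt})

    # ---- demographics -----------------------------------------------------
    sex = rng.choice(["male", "female"], size=n)
    sex = np.where(rng.random(n) < config.sex_missing_prob, None, sex)
    age_years = rng.integers(1, 86, n).astype(float)
    in_months = rng.random(n) < 0.10
    age_value = np.where(in_months, age_years * 12.0, age_years)
    age_unit = np.where(in_months, "months", "years")
    age_missing = rng.random(n) < config.age_missing_prob
    country = rng.choice(_COUNTRIES, size=n)
    country = np.where(rng.random(n) < config.country_missing_prob, None, country)
    demo = pd.DataFrame({
        "primaryid": primaryids,
        "caseid": caseids,
        "caseversion": 1,
        "fda_dt": fda_dt,
        "sex": sex,
        "country": country,
        "event_dt": fda_dt - 7,
        "age_value": np.where(age_missing, np.nan, age_value),
        "age_unit": np.where(age_missing, None, age_unit),
    })

    # ---- outcomes and indications ----------------------------------------
    has_outc = rng.random(n) < 0.6
    outc = pd.DataFrame({
        "primaryid": primaryids[has_outc],
        "outcome_code": rng.choice(_OUTCOME_CODES, size=int(has_outc.sum()), p=_OUTCOME_WEIGHTS),
    })
    has_indi = rng.random(n) < 0.4
    indi = pd.DataFrame({
        "primaryid": primaryids[has_indi],
        "indi_drug_seq": 1,
        "indi_pt": rng.choice(_INDICATIONS, size=int(has_indi.sum())),
    })

    # ---- duplicate injection ---------------------------------------------
    n_dup = int(round(config.duplicate_rate * n))
    clusters: dict[str, list[str]] = {}
    flag_index = list(primaryids)
    flag_values = list(flags)
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        clone_demo = demo.iloc[dup_idx].copy()
        clone_ids = np.array([f"{cid}2" for cid in caseids[dup_idx]])
        clone_demo["primaryid"] = clone_ids
        clone_demo["caseversion"] = 2
        clone_demo["fda_dt"] = clone_demo["fda_dt"] + 100  # next reporting month
        id_map = dict(zip(primaryids[dup_idx], clone_ids))
        demo = pd.concat([demo, clone_demo], ignore_index=True)

        def _clone_child(table: pd.DataFrame) -> pd.DataFrame:
            part = table[table["primaryid"].isin(id_map)].copy()
            part["primaryid"] = part["primaryid"].map(id_map)
            return pd.concat([table, part], ignore_index=True)

        drug, reac, outc, indi = (_clone_child(t) for t in (drug, reac, outc, indi))
        for orig, clone in id_map.items():
            cid = orig[:-1]
            clusters[cid] = [orig, clone]
        flag_index += list(clone_ids)
        flag_values += list(flags[dup_idx])

    # canonical dtypes matching read_quarterly_tables output
    demo["caseversion"] = demo["caseversion"].astype("Int64")
    demo["fda_dt"] = demo["fda_dt"].astype("Int64")
    demo["event_dt"] = demo["event_dt"].astype("Int64")
    for col in ("sex", "country", "age_unit"):
        demo[col] = demo[col].astype("string")
    drug["drug_seq"] = drug["drug_seq"].astype("Int64")
    for col in ("role_cod", "drugname", "prod_ai", "route"):
        drug[col] = drug[col].astype("string")
    reac["pt"] = reac["pt"].astype("string")
    outc["outcome_code"] = outc["outcome_code"].astype("string")
    indi["indi_drug_seq"] = indi["indi_drug_seq"].astype("Int64")
    indi["indi_pt"] = indi["indi_pt"].astype("string")
    for frame in (demo, drug, reac, outc, indi):
        frame["primaryid"] = frame["primaryid"].astype("string")
    demo["caseid"] = demo["caseid"].astype("string")

    tables = QuarterlyTables(demo=demo, drug=drug, reac=reac, outc=outc, indi=indi,
                             quarter_label="synthetic")
    truth = GroundTruth(
        target_flags=pd.Series(flag_values, index=pd.Index(flag_index, name="primaryid"), dtype=bool),
        planted_rr={(d, p): rr for d, p, rr in config.planted_effects},
        duplicate_clusters=clusters,
    )
    logger.info("generate: %d reports (+%d injected duplicates), %d target-flagged",
                n, truth.n_injected_duplicates, int(flags.sum()))
    return tables, truth


def recovery_experiment(
    config: SyntheticConfig,
    rr_grid: tuple[float, ...] = (1.0, 2.0, 5.0, 20.0),
    n_reps: int = 20,
    planted_pt: str = "Mydriasis",
) -> pd.DataFrame:
    """Power/bias table for the planted relative reporting rate.

    For each RR in the grid, ``n_reps`` quarters are generated with the
    (target drug, ``planted_pt``) pair planted at that RR, cleaned, and
    scanned. The table reports, per RR: the mean ``log2`` of the classical
    ROR and its bias against ``log2 RR`` — the boost-and-renormalize design
    makes the reporting *odds* ratio exactly RR, so the classical ROR is
    the consistent recovery of the planted multiplier, while the
    observed/expected shrunk ratio is attenuated by the target reports
    inside its expected-count denominator and is reported only
    descriptively — plus the fraction of replicates whose ``IC_025``
    exceeds zero (detection rate). Detection is monotone non-decreasing in
    RR up to simulation noise.

    Replicate seeds are derived deterministically from ``config.seed``.
    """
    if n_reps < 1 or any(rr < 1 for rr in rr_grid):
        raise ValueError("need n_reps >= 1 and rr_grid values >= 1")
    rows = []
    for rr in rr_grid:
        log2_rors, log2_ratios, detected = [], [], 0
        for rep in range(n_reps):
            seed = (config.seed * 100_003 + int(rr * 1000) * 97 + rep) % (2**31 - 1)
            cfg = replace(config,
                          planted_effects=((config.target_generic, planted_pt, float(rr)),),
                          seed=seed)
            tables, _ = generate(cfg)
            cases = clean_pipeline(tables, cfg.drug_dictionary())
            res = DisproportionalityModel(cases, level="PT", term_map=cfg.term_map()).fit()
            row = res.frame[res.frame["term"] == planted_pt]
            if row.empty:
                log2_rors.append(float("nan"))
                log2_ratios.append(float("nan"))
                continue
            log2_rors.append(float(np.log2(row["ror"].iloc[0])))
            log2_ratios.append(float(row["ic"].iloc[0]))
            if float(row["ic_025"].iloc[0]) > 0:
                detected += 1
        mean_log2_ror = float(np.nanmean(log2_rors))
        rows.append({
            "rr": rr,
            "log2_rr": float(np.log2(rr)),
            "mean_log2_ror": mean_log2_ror,
            "bias": mean_log2_ror - float(np.log2(rr)),
            "mean_log2_shrunk": float(np.nanmean(log2_ratios)),
            "detection_rate": detected / n_reps,
            "n_reps": n_reps,
        })
    return pd.DataFrame(rows)
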