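"""End-to-end orchestration: clean -> count -> signal -> prioritize -> report.

A run takes either raw FAERS-dialect files or a synthetic-data
configuration, applies the cleaning steps, fits PT- and SOC-level
disproportionality models, scores significant signals with the clinical
priority rubric, and writes a reproducible output bundle:

* ``clean_cases.csv`` (+ sidecar schema) — the cleaned case set
* ``descriptive_*.csv`` — frequency tables over target cases
* ``signals_pt.csv`` / ``signals_soc.csv`` — long-format signal tables
  (forest-plot ready)
* ``priority.csv`` — rubric components, totals, tiers
* ``manifest.json`` — seed, config hash, package version, per-stage drop
  counts and tier counts

Outputs are byte-identical under a fixed config and seed. An
annotation-only mode scores a pre-computed signal table without raw data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import QuarterlyTables, read_quarterly_tables, write_clean_dataset
from .preprocess import CleanCaseSet, DrugDictionary, clean_pipeline, descriptive_summary
from .priority import prioritize_all, tier_counts
from .stats import DisproportionalityModel
from .synthetic import SyntheticConfig, generate
from .terminology import MedicalEventList, TermMap

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_paths`` (mapping table name -> file path) or
    ``synthetic`` must be given. ``evidence_path`` points to an optional
    annotation CSV (``pt,evidence_grade[,event_status]``); unannotated
    signals default to evidence "-".
    """

    output_dir: str | Path
    input_paths: dict[str, str] | None = None
    synthetic: SyntheticConfig | None = None
    drug_dict: DrugDictionary | None = None
    term_map: TermMap | None = None
    event_lists: MedicalEventList | None = None
    evidence_path: str | Path | None = None
    signal_rule: str = "either"
    ror_mode: str = "point"
    delimiter: str = "$"
    seed: int = 0

    def __post_init__(self):
        if (self.input_paths is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_paths or synthetic must be set")
        if self.synthetic is not None and self.drug_dict is None:
            self.drug_dict = self.synthetic.drug_dictionary()
        if self.synthetic is not None and self.term_map is None:
            self.term_map = self.synthetic.term_map()
        if self.drug_dict is None:
            raise ValueError("a drug dictionary is required for raw-file runs")

    def config_hash(self) -> str:
        def _enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, TermMap):
                return sorted(obj.pt_to_soc.items())
            if isinstance(obj, MedicalEventList):
                return {"ime": sorted(obj.ime_pts), "dme": sorted(obj.dme_pts)}
            if isinstance(obj, dict):
                return {k: _enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_enc(v) for v in obj]
            return obj
        payload = {k: _enc(v) for k, v in vars(self).items() if k != "output_dir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_evidence(path: str | Path | None) -> pd.DataFrame | None:
    if path is None:
        return None
    frame = pd.read_csv(path, dtype="string")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "pt" not in frame.columns or "evidence_grade" not in frame.columns:
        raise ValueError(f"evidence table {path} needs columns pt,evidence_grade")
    return frame


def _death_counts(cases: CleanCaseSet, terms) -> dict[str, int]:
    """Fatal-report count per term among target cases (mortality dimension)."""
    target = cases.target_cases()
    counts = {t: 0 for t in terms}
    for pts, outcomes in zip(target["pts"], target["outcomes"]):
        if "death" not in outcomes:
            continue
        for t in pts:
            if t in counts:
                counts[t] += 1
    return counts


def _annotate_signals(
    signals: pd.DataFrame,
    event_lists: MedicalEventList | None,
    evidence: pd.DataFrame | None,
) -> pd.DataFrame:
    """Attach event_status and evidence columns to a signal table."""
    out = signals.rename(columns={"a": "cases"}).copy()
    out["deaths"] = out.get("deaths", 0)
    if event_lists is not None:
        out["event_status"] = out["term"].map(event_lists.status_of)
    else:
        out["event_status"] = "none"
    out["evidence"] = "-"
    if evidence is not None:
        key = {str(p).casefold(): g for p, g in zip(evidence["pt"], evidence["evidence_grade"])}
        out["evidence"] = [key.get(t.casefold(), "-") for t in out["term"]]
        if "event_status" in evidence.columns:
            override = {str(p).casefold(): s for p, s in zip(evidence["pt"], evidence["event_status"])
                        if pd.notna(s)}
            out["event_status"] = [override.get(t.casefold(), s)
                                   for t, s in zip(out["term"], out["event_status"])]
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the output bundle.

    Returns the mapping of artifact name -> written path. Any stage failure
    aborts with the stage name in the exception message.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "load"
    try:
        if cfg.synthetic is not None:
            tables, _truth = generate(dataclasses.replace(cfg.synthetic, seed=cfg.seed))
        else:
            tables = read_quarterly_tables(cfg.input_paths, delimiter=cfg.delimiter)

        stage = "clean"
        cases = clean_pipeline(tables, cfg.drug_dict)
        artifacts["clean_cases"] = write_clean_dataset(cases, out_dir / "clean_cases.csv")

        stage = "descriptive"
        for name, table in descriptive_summary(cases).items():
            path = out_dir / f"descriptive_{name}.csv"
            table.to_csv(path, index=False)
            artifacts[f"descriptive_{name}"] = path

        stage = "signals"
        results = {}
        for level in ("PT", "SOC"):
            res = DisproportionalityModel(cases, level=level, term_map=cfg.term_map,
                                          rule=cfg.signal_rule).fit()
            results[level] = res
            path = out_dir / f"signals_{level.lower()}.csv"
            res.to_csv(path)
            artifacts[f"signals_{level.lower()}"] = path

        stage = "prioritize"
        annotated = _annotate_signals(results["PT"].signals, cfg.event_lists,
                                      _load_evidence(cfg.evidence_path))
        deaths = _death_counts(cases, annotated["term"])
        annotated["deaths"] = annotated["term"].map(deaths)
        prioritized = prioritize_all(annotated, ror_mode=cfg.ror_mode)
        path = out_dir / "priority.csv"
        prioritized.to_csv(path, index=False)
        artifacts["priority"] = path

        stage = "manifest"
        manifest = {
            "pvsignal_version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "signal_rule": cfg.signal_rule,
            "ror_mode": cfg.ror_mode,
            "provenance": cases.provenance,
            "n_signals_pt": int(len(results["PT"].signals)),
            "n_signals_soc": int(len(results["SOC"].signals)),
            "tier_counts": tier_counts(prioritized),
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        artifacts["manifest"] = path
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("run_pipeline: wrote %d artifacts to %s", len(artifacts), out_dir)
    return artifacts


def prioritize_signal_table(
    signals: pd.DataFrame,
    event_lists: MedicalEventList | None = None,
    evidence: pd.DataFrame | None = None,
    ror_mode: str = "point",
) -> pd.DataFrame:
    """Annotation-only entry point: score a pre-computed signal table.

    ``signals`` needs columns term, cases (or a), ror, ror_l95, deaths;
    event_status/evidence may be present already or are attached from
    ``event_lists`` / ``evidence``.
    """
    frame = signals.copy()
    if "a" in frame.columns and "cases" not in frame.columns:
        frame = frame.rename(columns={"a": "cases"})
    if "event_status" not in frame.columns or "evidence" not in frame.columns:
        frame = _annotate_signals(frame, event_lists, evidence)
    return prioritize_all(frame, ror_mode=ror_mode)
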