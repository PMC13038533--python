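"""Clinical-priority triage of disproportionality signals.

Statistical disproportionality alone says nothing about how urgently a
signal deserves clinical follow-up. Each significant signal is therefore
scored on five dimensions, 0-2 points each:

==========================  =========  ==========  =========
dimension                   2 points   1 point     0 points
==========================  =========  ==========  =========
number of target events     > 50       10 - 50     < 10
ROR                         > 5        2 - 5       1 - 2
mortality proportion        > 50%      25 - 50%    < 25%
IME / DME designation       DME        IME         none
supporting evidence         ++         +           -
==========================  =========  ==========  =========

Boundary closure (the published ranges are printed open): a count of
exactly 50 scores 1; an ROR of exactly 5 or exactly 2 scores 1; a
mortality proportion of exactly 25% or 50% scores 1. The ROR dimension
bins the point estimate by default (``ror_mode="point"``); binning the
lower 95% bound instead is available via ``ror_mode="lower"``.

The total (0-10) maps to tiers: 0-4 weak, 5-7 moderate, 8-10 strong.

The evidence grade (++ / + / -) is an expert judgment — label or SmPC
documentation, RCT or systematic-review support with biological
plausibility — supplied as an annotation table, never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

EVIDENCE_GRADES = ("++", "+", "-")
EVENT_STATUSES = ("DME", "IME", "none")
TIERS = ("weak", "moderate", "strong")

DIMENSIONS = ("cases", "ror", "mortality", "event_status", "evidence")


@dataclass(frozen=True)
class PriorityInput:
    """Inputs to the rubric for one signal."""

    term: str
    n_cases: int
    ror_value: float
    death_count: int = 0
    event_status: str = "none"
    evidence_grade: str = "-"

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0 <= self.death_count <= self.n_cases:
            raise ValueError("death_count must be between 0 and n_cases")
        if self.event_status not in EVENT_STATUSES:
            raise ValueError(f"event_status must be one of {EVENT_STATUSES}")
        if self.evidence_grade not in EVIDENCE_GRADES:
            raise ValueError(f"evidence_grade must be one of {EVIDENCE_GRADES}")

    @property
    def death_proportion(self) -> float:
        return self.death_count / self.n_cases


@dataclass(frozen=True)
class PriorityResult:
    """Component scores, total and tier for one signal."""

    term: str
    component_scores: dict[str, int]
    total: int
    tier: str


def _score_cases(n: int) -> int:
    if n > 50:
        return 2
    if n >= 10:
        return 1
    return 0


def _score_ror(ror: float) -> int:
    if ror < 1.0:
        logger.warning("priority scoring: ROR %.3g < 1 (signals should exceed 1); scored 0", ror)
        return 0
    if ror > 5.0:
        return 2
    if ror >= 2.0:
        return 1
    return 0


def _score_mortality(proportion: float) -> int:
    if proportion > 0.5:
        return 2
    if proportion >= 0.25:
        return 1
    return 0


def _score_event_status(status: str) -> int:
    return {"DME": 2, "IME": 1, "none": 0}[status]


def _score_evidence(grade: str) -> int:
    return {"++": 2, "+": 1, "-": 0}[grade]


def classify_tier(total: int) -> str:
    """weak for 0-4, moderate for 5-7, strong for 8-10."""
    if not 0 <= total <= 10:
        raise ValueError("total must be in [0, 10]")
    if total <= 4:
        return "weak"
    if total <= 7:
        return "moderate"
    return "strong"


def score_priority(inp: PriorityInput) -> PriorityResult:
    """Apply the five-dimension rubric and attach the tier."""
    components = {
        "cases": _score_cases(inp.n_cases),
        "ror": _score_ror(inp.ror_value),
        "mortality": _score_mortality(inp.death_proportion),
        "event_status": _score_event_status(inp.event_status),
        "evidence": _score_evidence(inp.evidence_grade),
    }
    total = sum(components.values())
    return PriorityResult(term=inp.term, component_scores=components, total=total, tier=classify_tier(total))


def prioritize_all(signals: pd.DataFrame, ror_mode: str = "point") -> pd.DataFrame:
    """Score a table of annotated signals.

    Parameters
    ----------
    signals
        One row per significant signal with columns ``term``, ``cases``
        (observed count), ``ror`` and ``ror_l95``, ``deaths``,
        ``event_status`` (DME/IME/none) and ``evidence`` (++/+/-).
    ror_mode
        ``"point"`` (default) bins the ROR point estimate; ``"lower"``
        bins the lower 95% bound.

    Returns
    -------
    DataFrame with the five component scores, ``total`` and ``tier`` per
    row; tier counts are logged.
    """
    if ror_mode not in ("point", "lower"):
        raise ValueError(f"ror_mode must be 'point' or 'lower', got {ror_mode!r}")
    rows = []
    for rec in signals.itertuples(index=False):
        ror_value = rec.ror if ror_mode == "point" else rec.ror_l95
        result = score_priority(PriorityInput(
            term=rec.term,
            n_cases=int(rec.cases),
            ror_value=float(ror_value),
            death_count=int(rec.deaths),
            event_status=rec.event_status,
            evidence_grade=rec.evidence,
        ))
        rows.append({
            "term": result.term,
            **{f"score_{k}": v for k, v in result.component_scores.items()},
            "total": result.total,
            "tier": result.tier,
        })
    out = pd.DataFrame(rows, columns=["term"] + [f"score_{k}" for k in DIMENSIONS] + ["total", "tier"])
    counts = {tier: int((out["tier"] == tier).sum()) if len(out) else 0 for tier in TIERS}
    logger.info("prioritize_all: %d signals -> %s", len(out), counts)
    return out


def tier_counts(prioritized: pd.DataFrame) -> dict[str, int]:
    """Count of signals per tier (all three tiers always present)."""
    return {tier: int((prioritized["tier"] == tier).sum()) if len(prioritized) else 0 for tier in TIERS}
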