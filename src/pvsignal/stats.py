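r"""Disproportionality statistics for spontaneous-report signal detection.

Every drug-event pair is reduced to a 2x2 contingency table over the
case-term universe::

                     event of interest    all other events
    target drug              a                   b
    all other drugs          c                   d

with margins ``N_drug = a+b``, ``N_event = a+c`` and ``N_total = a+b+c+d``.
The counting unit is the unique (case, term) pair: a case contributes a
term at most once, at either the preferred-term (PT) or the System Organ
Class (SOC) level.

Two families of statistics are computed side by side:

* the classical reporting odds ratio ``ROR = ad / bc`` with the Woolf
  95% interval ``exp(ln ROR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``
  (Haldane-Anscombe +0.5 on all cells when any cell is zero, flagged);
* the shrinkage observed/expected ratio
  ``(N_observed + 0.5) / (N_expected + 0.5)`` with
  ``N_expected = N_drug * N_event / N_total``, whose base-2 logarithm is
  the information component ``IC``, bounded by the closed-form credible
  interval approximations

  .. math::

     IC_{025} = IC - 3.3\,(N_{obs}+0.5)^{-1/2} - 2\,(N_{obs}+0.5)^{-3/2}

     IC_{975} = IC + 2.4\,(N_{obs}+0.5)^{-1/2} - 0.5\,(N_{obs}+0.5)^{-3/2}

A pair is flagged as a signal when its lower ROR bound exceeds 1 **or**
its ``IC_{025}`` exceeds 0, with at least three observed reports (the
stricter "both" conjunction is available by configuration).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .preprocess import CleanCaseSet
from .terminology import TermMap

logger = logging.getLogger(__name__)

Z_95 = 1.96  # two-sided 95% normal quantile, as conventionally printed

#: minimum observed reports for a pair to qualify as a signal
MIN_SIGNAL_COUNT = 3


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair, plus derived margins."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def expected_count(n_drug: float, n_event: float, n_total: float) -> float:
    """Expected pair count under independence: ``N_drug * N_event / N_total``."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_drug * n_event / n_total


def shrunk_ratio_and_ic(n_observed: float, n_expected: float) -> tuple[float, float]:
    """Shrinkage observed/expected ratio and its information component.

    Both counts are stabilized by +0.5 so rare events cannot produce
    degenerate ratios; the IC is ``log2`` of the same shrunk ratio.
    """
    if n_observed < 0 or n_expected < 0:
        raise ValueError("counts must be non-negative")
    ratio = (n_observed + 0.5) / (n_expected + 0.5)
    return ratio, math.log2(ratio)


def ic_interval(ic: float, n_observed: float) -> tuple[float, float]:
    """Closed-form 95% credible bounds for the information component.

    The width depends only on the observed count and shrinks to zero as it
    grows; the approximation is accurate to ~1e-2 against the exact gamma
    posterior for all counts.
    """
    if n_observed < 0:
        raise ValueError("n_observed must be non-negative")
    s = n_observed + 0.5
    half = s ** -0.5
    three_half = s ** -1.5
    ic_025 = ic - 3.3 * half - 2.0 * three_half
    ic_975 = ic + 2.4 * half - 0.5 * three_half
    return ic_025, ic_975


def classical_ror(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """Classical reporting odds ratio with the Woolf 95% interval.

    Returns ``(ror, lower, upper, zero_cell_corrected)``. Any zero cell
    triggers the Haldane-Anscombe correction (+0.5 to all four cells),
    reported via the flag rather than by failing.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = table.has_zero_cell
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lower = math.exp(math.log(ror) - Z_95 * se)
    upper = math.exp(math.log(ror) + Z_95 * se)
    return ror, lower, upper, corrected


def flag_signal(n_observed: int, ror_l95: float, ic_025: float, rule: str = "either") -> bool:
    """Apply the signal criterion.

    ``rule="either"`` (default): lower ROR bound > 1 *or* IC025 > 0, with at
    least three observed reports. ``rule="both"`` requires both bounds.
    """
    if rule == "either":
        stat_ok = ror_l95 > 1.0 or ic_025 > 0.0
    elif rule == "both":
        stat_ok = ror_l95 > 1.0 and ic_025 > 0.0
    else:
        raise ValueError(f"unknown signal rule {rule!r}")
    return bool(stat_ok and n_observed >= MIN_SIGNAL_COUNT)


# ---------------------------------------------------------------------------
# case-term universe
# ---------------------------------------------------------------------------

def _case_terms(cases: CleanCaseSet, level: str, term_map: TermMap | None) -> tuple[list[frozenset], np.ndarray]:
    """Per-case term sets at the requested level plus the target mask."""
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    frame = cases.cases
    target = frame["target_drug"].to_numpy(dtype=bool)
    if level == "PT":
        sets = [frozenset(p) for p in frame["pts"]]
    else:
        if term_map is None:
            raise ValueError("a TermMap is required at level='SOC'")
        sets = [frozenset(term_map.soc_of(p) for p in pts) for pts in frame["pts"]]
    return sets, target


def build_contingency(
    cases: CleanCaseSet,
    term: str,
    level: str = "PT",
    term_map: TermMap | None = None,
) -> ContingencyTable:
    """2x2 table for one term over the case-term pair universe.

    ``a+b+c+d`` is invariant across terms at a fixed level (the universe
    size); a term absent from the data yields a valid table with a = c = 0.
    """
    sets, target = _case_terms(cases, level, term_map)
    n_total = sum(len(s) for s in sets)
    n_drug = sum(len(s) for s, t in zip(sets, target) if t)
    a = sum(1 for s, t in zip(sets, target) if t and term in s)
    n_event = a + sum(1 for s, t in zip(sets, target) if not t and term in s)
    return ContingencyTable(a=a, b=n_drug - a, c=n_event - a, d=n_total - n_drug - (n_event - a))


def _result_row(term: str, level: str, soc: str, table: ContingencyTable, rule: str) -> dict:
    n_exp = expected_count(table.n_drug, table.n_event, table.n_total)
    ror_shrunk, ic = shrunk_ratio_and_ic(table.a, n_exp)
    ic_025, ic_975 = ic_interval(ic, table.a)
    ror, ror_l95, ror_u95, corrected = classical_ror(table)
    return {
        "term": term,
        "level": level,
        "soc": soc,
        "a": table.a,
        "b": table.b,
        "c": table.c,
        "d": table.d,
        "n_expected": n_exp,
        "ror": ror,
        "ror_l95": ror_l95,
        "ror_u95": ror_u95,
        "ror_shrunk": ror_shrunk,
        "ic": ic,
        "ic_025": ic_025,
        "ic_975": ic_975,
        "significant": flag_signal(table.a, ror_l95, ic_025, rule),
        "zero_cell_corrected": corrected,
    }


class DisproportionalityModel:
    """Disproportionality scan of every event term reported with the target drug.

    Parameters
    ----------
    cases
        Cleaned, deduplicated case set with the per-case ``target_drug``
        flag and PT sets (see :func:`pvsignal.preprocess.clean_pipeline`).
    level
        ``"PT"`` for preferred terms, ``"SOC"`` to aggregate events to
        System Organ Classes via ``term_map`` before counting.
    term_map
        PT -> SOC map; required at SOC level, used for annotation at PT level.
    rule
        Signal criterion: ``"either"`` (default) or ``"both"`` (see
        :func:`flag_signal`).

    Examples
    --------
    >>> model = DisproportionalityModel(cases, level="PT", term_map=tmap)
    >>> res = model.fit()
    >>> res.signals[["term", "a", "ror", "ic_025"]]
    """

    def __init__(
        self,
        cases: CleanCaseSet,
        level: str = "PT",
        term_map: TermMap | None = None,
        rule: str = "either",
    ):
        if level not in ("PT", "SOC"):
            raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
        if level == "SOC" and term_map is None:
            raise ValueError("a TermMap is required at level='SOC'")
        if rule not in ("either", "both"):
            raise ValueError(f"unknown signal rule {rule!r}")
        self.cases = cases
        self.level = level
        self.term_map = term_map
        self.rule = rule

    @classmethod
    def from_clean_csv(cls, path, **kwargs) -> "DisproportionalityModel":
        from .io import read_clean_dataset

        return cls(read_clean_dataset(path), **kwargs)

    def fit(self) -> "DisproportionalityResults":
        """Scan all terms reported with the target drug.

        One result row per distinct term among target-drug cases, sorted by
        the lower ROR bound descending with the term name as tie-break.
        """
        sets, target = _case_terms(self.cases, self.level, self.term_map)
        n_total = sum(len(s) for s in sets)
        n_drug = sum(len(s) for s, t in zip(sets, target) if t)

        target_counts: dict[str, int] = {}
        other_counts: dict[str, int] = {}
        for s, t in zip(sets, target):
            bucket = target_counts if t else other_counts
            for term in s:
                bucket[term] = bucket.get(term, 0) + 1

        rows = []
        for term in sorted(target_counts):
            a = target_counts[term]
            c = other_counts.get(term, 0)
            table = ContingencyTable(a=a, b=n_drug - a, c=c, d=n_total - n_drug - c)
            soc = self.term_map.soc_of(term) if (self.term_map and self.level == "PT") else term
            rows.append(_result_row(term, self.level, soc, table, self.rule))

        frame = pd.DataFrame(rows, columns=list(_result_row("", "PT", "", ContingencyTable(0, 0, 0, 1), "either")))
        if len(frame):
            frame = frame.sort_values(["ror_l95", "term"], ascending=[False, True], kind="stable")
            frame = frame.reset_index(drop=True)
        return DisproportionalityResults(model=self, frame=frame, n_total=n_total, n_drug=n_drug)


class DisproportionalityResults:
    """Fitted disproportionality scan: one row per term with counts, the
    classical ROR and Woolf interval, the shrunk ratio, the IC with its
    credible bounds, and the signal flag."""

    def __init__(self, model: DisproportionalityModel, frame: pd.DataFrame, n_total: int, n_drug: int):
        self.model = model
        self.frame = frame
        self.n_total = n_total
        self.n_drug = n_drug

    @property
    def signals(self) -> pd.DataFrame:
        """Rows meeting the signal criterion."""
        return self.frame[self.frame["significant"]].reset_index(drop=True)

    def contingency(self, term: str) -> ContingencyTable:
        row = self.frame[self.frame["term"] == term]
        if row.empty:
            raise KeyError(term)
        r = row.iloc[0]
        return ContingencyTable(a=int(r.a), b=int(r.b), c=int(r.c), d=int(r.d))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.to_csv(path, index=False, float_format="%.6g")

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable summary: scan dimensions plus the strongest signals."""
        n_terms = len(self.frame)
        n_sig = int(self.frame["significant"].sum())
        lines = [
            f"Disproportionality scan ({self.model.level} level, rule={self.model.rule!r})",
            f"  cases: {len(self.model.cases)} ({int(self.model.cases.cases['target_drug'].sum())} target)",
            f"  case-term universe: {self.n_total} pairs, {self.n_drug} with the target drug",
            f"  terms scanned: {n_terms}; signals: {n_sig}",
            "",
        ]
        cols = ["term", "a", "n_expected", "ror", "ror_l95", "ror_u95", "ic", "ic_025", "significant"]
        shown = self.frame[cols].head(max_rows)
        lines.append(shown.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        if n_terms > max_rows:
            lines.append(f"... {n_terms - max_rows} more terms")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<DisproportionalityResults: {len(self.frame)} terms, "
                f"{int(self.frame['significant'].sum())} signals>")


def scan_all_terms(
    cases: CleanCaseSet,
    term_map: TermMap | None = None,
    level: str = "PT",
    rule: str = "either",
) -> pd.DataFrame:
    """Convenience wrapper: fit a :class:`DisproportionalityModel` and return
    the long results table."""
    return DisproportionalityModel(cases, level=level, term_map=term_map, rule=rule).fit().frame
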