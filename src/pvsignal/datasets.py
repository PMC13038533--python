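"""Bundled reference data.

``ophthalmic_atropine_signal_panel.csv`` is an 83-row PT-level panel from a
published FAERS disproportionality analysis of ophthalmic atropine: per
preferred term, the case count, classical ROR with its 95% CI, death count,
EMA IME/DME designation, expert evidence grade, and the published clinical
priority score and tier. It serves as the validation surface for the
priority rubric and the terminology annotations.

Derived from the same panel and shipped as independent CSVs in the formats
the runtime loaders accept: a toy PT -> SOC map (``pt_soc_map_toy.csv``) and
the IME/DME PT lists (``ime_pts_toy.csv`` / ``dme_pts_toy.csv``). All three
are fixtures covering only the panel's vocabulary — real analyses supply a
full MedDRA map and the current EMA lists.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .terminology import MedicalEventList, TermMap

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"

PANEL_FILE = "ophthalmic_atropine_signal_panel.csv"
PT_SOC_FILE = "pt_soc_map_toy.csv"
IME_FILE = "ime_pts_toy.csv"
DME_FILE = "dme_pts_toy.csv"

#: panel row whose published priority label does not follow from its own
#: printed inputs under any reading of the rubric (recomputes to 3 = weak)
KNOWN_DISCORDANT_TERM = "Toxicity to various agents"


def data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def load_signal_panel() -> pd.DataFrame:
    """The 83-row reference signal panel.

    Columns: soc, pt, cases, ror, ror_l95, ror_u95, deaths, event_status
    (DME/IME/none), evidence (++/+/-), printed_score, printed_tier.
    """
    frame = pd.read_csv(data_path(PANEL_FILE), dtype={"evidence": "string"})
    assert len(frame) == 83, "reference panel must have exactly 83 rows"
    return frame


def load_toy_term_map() -> TermMap:
    """PT -> SOC map covering the reference panel's vocabulary.

    Panel PTs grouped under "Missing or unknown" are deliberately absent
    from the map: the lookup sentinel reproduces that grouping.
    """
    return TermMap.from_csv(data_path(PT_SOC_FILE))


def load_toy_event_lists() -> MedicalEventList:
    """IME/DME lists restricted to the reference panel's designations."""
    return MedicalEventList.from_csv(data_path(IME_FILE), data_path(DME_FILE))


def panel_as_priority_input(panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reference panel reshaped for :func:`pvsignal.priority.prioritize_all`."""
    frame = load_signal_panel() if panel is None else panel
    out = frame.rename(columns={"pt": "term"})
    return out[["term", "cases", "ror", "ror_l95", "deaths", "event_status", "evidence",
                "printed_score", "printed_tier"]]
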