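"""MedDRA-style terminology services: PT -> System Organ Class lookup and
annotation against the EMA Important / Designated Medical Event lists.

The full MedDRA dictionary is licensed and cannot be redistributed, so the
term map is a runtime CSV input (``pt,soc``); the package bundles a toy map
covering the ophthalmic-atropine reference panel for tests and examples.
IME/DME lists are likewise versioned external CSVs with bundled fixtures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .preprocess import MISSING_LABEL, normalize_pt

#: SOC returned for PTs absent from the map
UNMAPPED_SOC = MISSING_LABEL


def _key(pt: str) -> str:
    """Case-insensitive lookup key for a PT."""
    return normalize_pt(pt).casefold()


@dataclass(frozen=True)
class TermMap:
    """Mapping from preferred term to its primary System Organ Class.

    Lookups are deterministic and case-insensitive; unmapped PTs resolve to
    the sentinel ``"Missing or unknown"``.
    """

    pt_to_soc: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "TermMap":
        mapping: dict[str, str] = {}
        for pt, soc in pairs:
            key = _key(pt)
            soc = str(soc).strip()
            if key in mapping and mapping[key] != soc:
                raise ValueError(f"PT {pt!r} mapped to two SOCs: {mapping[key]!r} and {soc!r}")
            mapping[key] = soc
        return cls(pt_to_soc=mapping)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TermMap":
        """Load a ``pt,soc`` CSV (one header row)."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            fields = {f.strip().lower(): f for f in reader.fieldnames or []}
            if "pt" not in fields or "soc" not in fields:
                raise ValueError(f"term map {path} must have columns pt,soc")
            return cls.from_pairs((row[fields["pt"]], row[fields["soc"]]) for row in reader)

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc.get(_key(pt), UNMAPPED_SOC)

    def __len__(self) -> int:
        return len(self.pt_to_soc)


def soc_of(pt: str, term_map: TermMap) -> str:
    """System Organ Class of ``pt``, or ``"Missing or unknown"`` if unmapped."""
    return term_map.soc_of(pt)


@dataclass(frozen=True)
class MedicalEventList:
    """EMA Important (IME) and Designated (DME) Medical Event PT lists.

    A PT on both lists is classified DME: designated events are the rarer,
    more serious subset and take precedence for priority scoring.
    """

    ime_pts: frozenset[str]
    dme_pts: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "ime_pts", frozenset(_key(p) for p in self.ime_pts))
        object.__setattr__(self, "dme_pts", frozenset(_key(p) for p in self.dme_pts))

    @classmethod
    def from_csv(cls, ime_path: str | Path, dme_path: str | Path) -> "MedicalEventList":
        """Load one-column ``pt`` CSVs (header row required)."""
        return cls(ime_pts=_read_pt_column(ime_path), dme_pts=_read_pt_column(dme_path))

    def status_of(self, pt: str) -> str:
        key = _key(pt)
        if key in self.dme_pts:
            return "DME"
        if key in self.ime_pts:
            return "IME"
        return "none"


def _read_pt_column(path: str | Path) -> frozenset[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = {f.strip().lower(): f for f in reader.fieldnames or []}
        if "pt" not in fields:
            raise ValueError(f"event list {path} must have a 'pt' column")
        return frozenset(row[fields["pt"]] for row in reader if row[fields["pt"]].strip())


def ime_dme_status(pt: str, lists: MedicalEventList) -> str:
    """``"DME"``, ``"IME"`` or ``"none"`` for a PT; DME wins when listed on both."""
    return lists.status_of(pt)
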