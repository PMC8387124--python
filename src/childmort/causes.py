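"""ICD-10 cause-of-death grouping.

Death records carry either an ICD-10 chapter identifier (Roman numeral
``"I"`` .. ``"XXII"``) or a code-level value such as ``"Q03"``. A
:class:`CauseGroup` names a set of chapters and/or code ranges; predefined
groups cover the analyses this package performs:

* ``TOTAL`` — every chapter (all-cause mortality);
* ``NEOPLASMS`` — chapter II;
* ``OTHER_DISEASES`` — chapters I–XV with chapter II removed, the
  aggregate of disease chapters not attributed to neoplasms;
* ``CACNS`` — congenital anomalies of the central nervous system, a
  code-level subset of chapter XVII (default Q00–Q07, overridable since
  the precise list is a modelling choice).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

ROMAN_CHAPTERS: tuple[str, ...] = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
    "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
    "XXI", "XXII",
)

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")
_RANGE_RE = re.compile(r"^([A-Z])(\d{2})-([A-Z])(\d{2})$")

#: First letter(s) of ICD-10 codes per chapter, for chapter membership of codes.
_CHAPTER_CODE_RANGES: dict[str, list[tuple[str, str]]] = {
    "I": [("A00", "B99")],
    "II": [("C00", "D48")],
    "III": [("D50", "D89")],
    "IV": [("E00", "E90")],
    "V": [("F00", "F99")],
    "VI": [("G00", "G99")],
    "VII": [("H00", "H59")],
    "VIII": [("H60", "H95")],
    "IX": [("I00", "I99")],
    "X": [("J00", "J99")],
    "XI": [("K00", "K93")],
    "XII": [("L00", "L99")],
    "XIII": [("M00", "M99")],
    "XIV": [("N00", "N99")],
    "XV": [("O00", "O99")],
    "XVI": [("P00", "P96")],
    "XVII": [("Q00", "Q99")],
    "XVIII": [("R00", "R99")],
    "XIX": [("S00", "T98")],
    "XX": [("V01", "Y98")],
    "XXI": [("Z00", "Z99")],
    "XXII": [("U00", "U99")],
}


class VocabularyError(ValueError):
    """The group and the table do not share a coding vocabulary."""


def _code_key(code: str) -> tuple[str, int]:
    m = _CODE_RE.match(code)
    if m is None:
        raise ValueError(f"not an ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


def code_in_range(code: str, rng: str) -> bool:
    """True if ICD-10 ``code`` lies in the inclusive range ``"Q00-Q07"``."""
    m = _RANGE_RE.match(rng)
    if m is None:
        raise ValueError(f"not an ICD-10 code range: {rng!r}")
    lo = (m.group(1), int(m.group(2)))
    hi = (m.group(3), int(m.group(4)))
    return lo <= _code_key(code) <= hi


def chapter_of_code(code: str) -> str:
    """ICD-10 chapter (Roman numeral) containing a code."""
    for chapter, ranges in _CHAPTER_CODE_RANGES.items():
        for lo, hi in ranges:
            if code_in_range(code, f"{lo}-{hi}"):
                return chapter
    raise ValueError(f"code {code!r} not in any ICD-10 chapter")


def is_code(value: str) -> bool:
    return _CODE_RE.match(value) is not None


@dataclass(frozen=True)
class CauseGroup:
    """A named set of ICD-10 chapters and/or code ranges."""

    name: str
    chapters: frozenset[str] = field(default_factory=frozenset)
    code_ranges: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = self.chapters - set(ROMAN_CHAPTERS)
        if unknown:
            raise ValueError(f"unknown ICD-10 chapters: {sorted(unknown)}")
        for rng in self.code_ranges:
            if _RANGE_RE.match(rng) is None:
                raise ValueError(f"malformed code range {rng!r}")

    @property
    def is_total(self) -> bool:
        return self.name == "TOTAL"

    def matches(self, cause: str) -> bool:
        """Whether a table's cause value (chapter or code) is in the group."""
        if self.is_total:
            return True
        if cause in set(ROMAN_CHAPTERS):
            if self.code_ranges and not self.chapters:
                raise VocabularyError(
                    f"group {self.name!r} is defined at code level; "
                    "code-level data required"
                )
            return cause in self.chapters
        if is_code(cause):
            if self.code_ranges:
                return any(code_in_range(cause, rng) for rng in self.code_ranges)
            return chapter_of_code(cause) in self.chapters
        raise VocabularyError(f"unrecognised cause value {cause!r}")


TOTAL = CauseGroup("TOTAL")
NEOPLASMS = CauseGroup("NEOPLASMS", chapters=frozenset({"II"}))
#: Chapters I–XV without chapter II.
OTHER_DISEASES = CauseGroup(
    "OTHER_DISEASES",
    chapters=frozenset(ROMAN_CHAPTERS[:15]) - {"II"},
)
#: Congenital anomalies of the CNS; default code set, user-overridable.
CACNS = CauseGroup("CACNS", code_ranges=("Q00-Q07",))

PREDEFINED_GROUPS: dict[str, CauseGroup] = {
    "TOTAL": TOTAL,
    "NEOPLASMS": NEOPLASMS,
    "OTHER_DISEASES": OTHER_DISEASES,
    "CACNS": CACNS,
    **{ch: CauseGroup(ch, chapters=frozenset({ch})) for ch in ROMAN_CHAPTERS},
}


def chapter_group(chapter: str) -> CauseGroup:
    """Single-chapter group."""
    if chapter not in ROMAN_CHAPTERS:
        raise ValueError(f"unknown chapter {chapter!r}")
    return PREDEFINED_GROUPS[chapter]


def resolve_cause_group(group: CauseGroup, table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a death-count table to a cause group.

    ``TOTAL`` returns the table unchanged. An empty result is a warning,
    not an error: zero deaths from a group is meaningful.
    """
    if group.is_total:
        return table.copy()
    mask = table["cause"].map(group.matches)
    out = table[mask].copy()
    if out.empty:
        logger.warning("cause group %s matched no records", group.name)
    return out
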