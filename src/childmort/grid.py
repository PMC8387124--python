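"""Demographic age grid: sub-year infant bands plus whole-year childhood bands.

The WHO mortality database splits the first year of life into four
categories — "0 days" [0, 1) day, "1-6 days" [1, 7) days, "7-27 days"
[7, 28) days and "28-365 days" [28, 365) days — and uses multi-year bands
afterwards. All ages are carried internally in years, with day-denominated
bounds converted at 365 days per year (the convention implied by the
"28-365 days" label itself). Each category is represented by the
arithmetic mean of its endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

DAYS_PER_YEAR = 365.0


class Band(str, Enum):
    """Whether a category subdivides the first year of life."""

    INFANT_SUB = "infant_sub"
    WHOLE_YEAR = "whole_year"


@dataclass(frozen=True)
class AgeCategory:
    """Half-open age interval [lower, upper) in years.

    Parameters
    ----------
    label : str
        Canonical label, e.g. ``"1-6 days"`` or ``"5-9 years"``.
    lower, upper : float
        Bounds in years, ``0 <= lower < upper``.
    band : Band
        ``INFANT_SUB`` for the four sub-year categories, ``WHOLE_YEAR``
        otherwise.
    """

    label: str
    lower: float
    upper: float
    band: Band = Band.WHOLE_YEAR

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper):
            raise ValueError(
                f"invalid age category {self.label!r}: need 0 <= lower < upper, "
                f"got [{self.lower}, {self.upper})"
            )

    @property
    def midpoint(self) -> float:
        """Arithmetic mean of the interval endpoints, in years."""
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        """Interval width in years."""
        return self.upper - self.lower

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper


def midpoint(category: AgeCategory) -> float:
    """Representative age of a category: the mean of its endpoints (years)."""
    return category.midpoint


#: The four infant subcategories exactly tiling the first year of life.
INFANT_CATEGORIES: tuple[AgeCategory, ...] = (
    AgeCategory("0 days", 0.0, 1.0 / DAYS_PER_YEAR, Band.INFANT_SUB),
    AgeCategory("1-6 days", 1.0 / DAYS_PER_YEAR, 7.0 / DAYS_PER_YEAR, Band.INFANT_SUB),
    AgeCategory("7-27 days", 7.0 / DAYS_PER_YEAR, 28.0 / DAYS_PER_YEAR, Band.INFANT_SUB),
    AgeCategory("28-365 days", 28.0 / DAYS_PER_YEAR, 1.0, Band.INFANT_SUB),
)

#: Alternate spellings seen in raw extracts, mapped to canonical labels.
LABEL_ALIASES: dict[str, str] = {
    "0 day": "0 days",
    "0-1 days": "0 days",
    "1–6 days": "1-6 days",
    "7–27 days": "7-27 days",
    "28–365 days": "28-365 days",
}


class AgeGrid:
    """Ordered, gapless partition of (0, upper_limit) years.

    The standard grid starts with the four infant subcategories and then
    uses (1, 5) followed by five-year bands.
    """

    def __init__(self, categories: Sequence[AgeCategory]):
        cats = sorted(categories, key=lambda c: c.lower)
        if not cats:
            raise ValueError("empty age grid")
        if cats[0].lower != 0.0:
            raise ValueError("age grid must start at age 0")
        for a, b in zip(cats, cats[1:]):
            if abs(a.upper - b.lower) > 1e-12:
                raise ValueError(
                    f"age grid gap/overlap between {a.label!r} and {b.label!r}"
                )
        labels = [c.label for c in cats]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate category labels in grid")
        self.categories: tuple[AgeCategory, ...] = tuple(cats)
        self._by_label = {c.label: c for c in cats}

    def __iter__(self) -> Iterator[AgeCategory]:
        return iter(self.categories)

    def __len__(self) -> int:
        return len(self.categories)

    def __getitem__(self, label: str) -> AgeCategory:
        key = LABEL_ALIASES.get(label, label)
        try:
            return self._by_label[key]
        except KeyError:
            raise KeyError(f"unknown age category label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return LABEL_ALIASES.get(label, label) in self._by_label

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.categories]

    @property
    def upper_limit(self) -> float:
        return self.categories[-1].upper

    @property
    def infant(self) -> list[AgeCategory]:
        return [c for c in self.categories if c.band is Band.INFANT_SUB]

    def midpoints(self) -> list[float]:
        return [c.midpoint for c in self.categories]

    def category_at(self, age: float) -> AgeCategory:
        """Category whose half-open interval contains ``age``."""
        for c in self.categories:
            if c.contains(age):
                return c
        raise ValueError(f"age {age} outside the grid (0, {self.upper_limit})")

    def restrict(self, age_range: tuple[float, float]) -> list[AgeCategory]:
        """Categories whose midpoints fall inside ``age_range`` (closed)."""
        lo, hi = age_range
        return [c for c in self.categories if lo <= c.midpoint <= hi]


def standard_grid(upper_limit: float = 15.0) -> AgeGrid:
    """Build the canonical grid: four infant bands, (1, 5), then 5-year bands.

    Parameters
    ----------
    upper_limit : float
        Upper bound in years; must be 5, 10, 15, ... (a multiple of 5).
    """
    if upper_limit < 5 or upper_limit % 5 != 0:
        raise ValueError("upper_limit must be a positive multiple of 5 years")
    cats = list(INFANT_CATEGORIES)
    cats.append(AgeCategory("1-4 years", 1.0, 5.0, Band.WHOLE_YEAR))
    lo = 5.0
    while lo < upper_limit:
        hi = lo + 5.0
        cats.append(
            AgeCategory(f"{int(lo)}-{int(hi) - 1} years", lo, hi, Band.WHOLE_YEAR)
        )
        lo = hi
    return AgeGrid(cats)
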