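"""Halley pooling: deaths and exposures from many countries and calendar
years combined into one hypothetical population.

Pooling across calendar years (Halley, 1693) and regions removes the
zero-death cells that otherwise make log-scale trajectory fitting
impossible for rarer causes: a category with zero deaths in one
country-year usually has deaths in another. Deaths and person-years are
summed over the selection; the age-specific mortality rate is the ratio

    mu_i = D_i / L_i        [per person-year]

per age category. Exposure follows the stationary-population reading of
census counts: one mean living person over a calendar year contributes
one person-year to their whole-year band, and a sub-year infant band
receives the under-1 count times the band width in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causes import CauseGroup, resolve_cause_group
from .errors import AggregationError
from .grid import AgeCategory, AgeGrid, Band

UNDER_ONE_BAND = "under-1"


@dataclass
class AggregatedATM:
    """Age trajectory of mortality for one pooled population × cause group.

    Attributes
    ----------
    population_name, cause_group : str
    grid : AgeGrid
    deaths : ndarray of int
        Pooled death sums D_i per category.
    person_years : ndarray of float
        Pooled exposures L_i per category (> 0).
    """

    population_name: str
    cause_group: str
    grid: AgeGrid
    deaths: np.ndarray
    person_years: np.ndarray
    selection: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths)
        self.person_years = np.asarray(self.person_years, dtype=float)
        n = len(self.grid)
        if len(self.deaths) != n or len(self.person_years) != n:
            raise ValueError("deaths/person_years length must match the grid")
        if (self.deaths < 0).any():
            raise ValueError("negative death counts")
        if (self.person_years <= 0).any():
            bad = [
                c.label
                for c, L in zip(self.grid, self.person_years)
                if L <= 0
            ]
            raise AggregationError(f"zero or negative person-years in {bad}")

    @property
    def rates(self) -> np.ndarray:
        """mu_i = D_i / L_i per person-year."""
        return self.deaths / self.person_years

    @property
    def midpoints(self) -> np.ndarray:
        return np.array(self.grid.midpoints())

    @property
    def usable(self) -> np.ndarray:
        """Categories eligible for log-scale fitting (D_i > 0).

        Zero-death categories are retained but flagged; log fits refuse
        them."""
        return self.deaths > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_label": self.grid.labels,
                "x": self.midpoints,
                "deaths": self.deaths,
                "person_years": self.person_years,
                "rate": self.rates,
                "usable": self.usable,
            }
        )

    def restrict(self, age_range: tuple[float, float]) -> "AggregatedATM":
        """Sub-trajectory over the categories with midpoints in range."""
        cats = self.grid.restrict(age_range)
        idx = [self.grid.labels.index(c.label) for c in cats]
        return AggregatedATM(
            self.population_name,
            self.cause_group,
            AgeGrid(cats),
            self.deaths[idx],
            self.person_years[idx],
            self.selection,
        )


def _normalise_selection(
    countries, years, pop: pd.DataFrame | None = None
) -> dict[str, list[int]]:
    """Build the explicit {country: [years]} selection.

    A plain year list is applied to every country; mismatched calendar
    coverage must be stated explicitly per country — no silent
    intersection is taken.
    """
    if isinstance(countries, dict):
        sel = {c: sorted(ys) for c, ys in countries.items()}
    else:
        countries = list(countries)
        if years is None:
            raise AggregationError(
                "explicit years are required (per-country dict or a shared list)"
            )
        sel = {c: sorted(years) for c in countries}
    if not sel or any(len(v) == 0 for v in sel.values()):
        raise AggregationError("empty country/year selection")
    return sel


def person_years(
    pop: pd.DataFrame,
    category: AgeCategory,
    countries,
    years=None,
) -> float:
    """Pooled exposure for one age category over a selection.

    Whole-year bands: sum of the band's mean population over the selected
    country-years. Infant sub-bands: the pooled under-1 population times
    the band width in years (stationary approximation).
    """
    sel = _normalise_selection(countries, years)
    band = UNDER_ONE_BAND if category.band is Band.INFANT_SUB else category.label
    total = 0.0
    for country, ys in sel.items():
        sub = pop[(pop["country"] == country) & (pop["age_band"] == band)]
        by_year = dict(zip(sub["year"], sub["count"]))
        for y in ys:
            if y not in by_year:
                raise AggregationError(
                    f"missing population record for ({country}, {y}, {band!r})"
                )
            total += float(by_year[y])
    if category.band is Band.INFANT_SUB:
        total *= category.width
    if total <= 0:
        raise AggregationError(
            f"non-positive exposure for {category.label!r} over the selection"
        )
    return total


def aggregate(
    deaths: pd.DataFrame,
    pop: pd.DataFrame,
    countries,
    years=None,
    group: CauseGroup | None = None,
    grid: AgeGrid | None = None,
    name: str | None = None,
) -> AggregatedATM:
    """Pool a selection of country-years into one trajectory.

    Parameters
    ----------
    deaths, pop : DataFrame
        Tables in the :mod:`childmort.io` layouts.
    countries : sequence of str, or dict {country: [years]}
        With a dict, per-country calendar periods may differ (the
        explicit form required when coverage is mismatched).
    years : sequence of int, optional
        Shared year list when ``countries`` is a sequence.
    group : CauseGroup
        Cause restriction; defaults to all causes.
    """
    from .causes import TOTAL

    if grid is None:
        raise AggregationError("an AgeGrid is required")
    group = group or TOTAL
    sel = _normalise_selection(countries, years)

    restricted = resolve_cause_group(group, deaths)
    mask = pd.Series(False, index=restricted.index)
    for country, ys in sel.items():
        mask |= (restricted["country"] == country) & restricted["year"].isin(ys)
    restricted = restricted[mask]
    d_by_label = restricted.groupby("age_label")["deaths"].sum()

    D = np.array([int(d_by_label.get(c.label, 0)) for c in grid])
    L = np.array([person_years(pop, c, sel) for c in grid])
    return AggregatedATM(
        population_name=name or "+".join(sorted(sel)),
        cause_group=group.name,
        grid=grid,
        deaths=D,
        person_years=L,
        selection=sel,
    )


def merge(a: AggregatedATM, b: AggregatedATM, name: str | None = None) -> AggregatedATM:
    """Exact pooling of two aggregates over disjoint selections.

    Deaths and person-years add; pooling is associative and
    order-independent.
    """
    if a.grid.labels != b.grid.labels:
        raise AggregationError("cannot merge aggregates on different grids")
    if a.cause_group != b.cause_group:
        raise AggregationError("cannot merge aggregates of different cause groups")
    overlap = {
        (c, y)
        for c, ys in a.selection.items()
        for y in ys
        if y in b.selection.get(c, [])
    }
    if overlap:
        raise AggregationError(f"overlapping selections: {sorted(overlap)[:5]}")
    sel = {c: sorted(set(a.selection.get(c, [])) | set(b.selection.get(c, [])))
           for c in set(a.selection) | set(b.selection)}
    return AggregatedATM(
        population_name=name or f"{a.population_name}+{b.population_name}",
        cause_group=a.cause_group,
        grid=a.grid,
        deaths=a.deaths + b.deaths,
        person_years=a.person_years + b.person_years,
        selection=sel,
    )


def death_share(
    total: AggregatedATM,
    part: AggregatedATM,
    age_range: tuple[float, float],
) -> float:
    """Fraction of deaths inside an age range attributable to a cause group.

    Both trajectories must be aggregated on the same population and grid;
    the share is Σ D_i(part) / Σ D_i(total) over categories whose
    midpoints fall in ``age_range``.
    """
    if total.grid.labels != part.grid.labels:
        raise AggregationError("trajectories aggregated on different grids")
    lo, hi = age_range
    idx = [i for i, c in enumerate(total.grid) if lo <= c.midpoint <= hi]
    denom = int(total.deaths[idx].sum())
    if denom == 0:
        raise AggregationError("zero total deaths in range: share undefined")
    return float(part.deaths[idx].sum()) / denom


def atm_from_counts(
    grid: AgeGrid,
    deaths,
    person_years,
    name: str = "counts",
    cause_group: str = "TOTAL",
) -> AggregatedATM:
    """Wrap pre-aggregated D_i / L_i vectors (e.g. a published counts
    table, or simulator output) as a trajectory."""
    return AggregatedATM(name, cause_group, grid, np.asarray(deaths),
                         np.asarray(person_years, dtype=float))


def atm_from_supplementary(
    supp: pd.DataFrame,
    population: str,
    cause: str,
    grid: AgeGrid,
) -> AggregatedATM:
    """Build a trajectory from the published pooled-counts table.

    The table's ``living`` column is used directly as the person-years
    denominator for every category (the published values already encode
    the exposure convention of the source analysis).
    """
    sub = supp[(supp["population"] == population) & (supp["cause"] == cause)]
    if sub.empty:
        raise AggregationError(
            f"no supplementary rows for population {population!r}, cause {cause!r}"
        )
    by_label = sub.set_index("age_label")
    missing = [c.label for c in grid if c.label not in by_label.index]
    if missing:
        raise AggregationError(f"supplementary table lacks categories {missing}")
    D = np.array([int(by_label.loc[c.label, "deaths"]) for c in grid])
    L = np.array([float(by_label.loc[c.label, "living"]) for c in grid])
    return AggregatedATM(population, cause, grid, D, L)
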