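"""Named population presets: the 25 study countries and their pooled
aggregates.

Each country entry carries the calendar period in which the ICD-10
classification and the four sub-year infant categories were both in use,
and the mean population size over that period (living persons per one
calendar year). Aggregates pool member countries' deaths and exposures;
an aggregate's size is the plain sum of its members' mean sizes.

Presets: P1 (five large western-European countries), P2 (central
Europe), P3 (Nordic countries), P14 = P1+P2+P3 (all 14 European
countries), P4 (South America), P5 (Mexico, Japan, Australia, New
Zealand, USA), P25 = P14+P4+P5.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CountryPreset:
    name: str
    years: tuple[int, int]  # inclusive calendar period
    mean_size: int  # mean living persons per calendar year

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


COUNTRIES: dict[str, CountryPreset] = {
    c.name: c
    for c in [
        CountryPreset("France", (2000, 2014), 61_466_098),
        CountryPreset("Germany", (1998, 2015), 80_892_654),
        CountryPreset("Italy", (2003, 2014), 59_026_383),
        CountryPreset("Spain", (1999, 2015), 44_137_863),
        CountryPreset("UK", (2001, 2015), 61_569_167),
        CountryPreset("Czech Republic", (1994, 2015), 10_384_837),
        CountryPreset("Austria", (2002, 2016), 8_420_447),
        CountryPreset("Hungary", (1996, 2015), 10_055_552),
        CountryPreset("Poland", (1999, 2015), 38_570_112),
        CountryPreset("Slovakia", (1996, 2014), 5_407_663),
        CountryPreset("Sweden", (1997, 2015), 9_215_809),
        CountryPreset("Norway", (1996, 2015), 4_708_433),
        CountryPreset("Denmark", (1994, 2009), 5_357_073),
        CountryPreset("Finland", (1996, 2015), 5_265_968),
        CountryPreset("Argentina", (2003, 2014), 40_916_085),
        CountryPreset("Brazil", (2006, 2015), 196_482_134),
        CountryPreset("Peru", (1999, 2015), 28_032_803),
        CountryPreset("Venezuela", (1996, 2013), 26_147_140),
        CountryPreset("Chile", (1997, 2015), 16_109_643),
        CountryPreset("Colombia", (1997, 2013), 42_606_241),
        CountryPreset("Mexico", (1998, 2012), 108_139_515),
        CountryPreset("Japan", (1995, 2015), 126_809_629),
        CountryPreset("Australia", (1998, 2015), 20_616_599),
        CountryPreset("New Zealand", (2000, 2013), 4_094_611),
        CountryPreset("USA", (1999, 2010), 291_683_111),
    ]
}

AGGREGATES: dict[str, tuple[str, ...]] = {
    "P1": ("France", "Germany", "Italy", "Spain", "UK"),
    "P2": ("Czech Republic", "Austria", "Hungary", "Poland", "Slovakia"),
    "P3": ("Sweden", "Norway", "Denmark", "Finland"),
    "P4": ("Argentina", "Brazil", "Peru", "Venezuela", "Chile", "Colombia"),
    "P5": ("Mexico", "Japan", "Australia", "New Zealand", "USA"),
}
AGGREGATES["P14"] = AGGREGATES["P1"] + AGGREGATES["P2"] + AGGREGATES["P3"]
AGGREGATES["P25"] = AGGREGATES["P14"] + AGGREGATES["P4"] + AGGREGATES["P5"]


def preset_members(name: str) -> list[str]:
    """Country list of a preset; a bare country name is its own preset."""
    if name in AGGREGATES:
        return list(AGGREGATES[name])
    if name in COUNTRIES:
        return [name]
    raise KeyError(f"undefined population preset {name!r}")


def preset_selection(name: str) -> dict[str, list[int]]:
    """Explicit {country: [years]} selection for a preset."""
    return {c: COUNTRIES[c].year_list for c in preset_members(name)}


def pooled_size(name: str) -> int:
    """Mean size of a pooled population: sum of member mean sizes."""
    return sum(COUNTRIES[c].mean_size for c in preset_members(name))
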