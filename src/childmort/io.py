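"""Readers and writers for the tabular inputs and outputs.

Two tidy CSV dialects feed the pipeline (UTF-8, ``.`` decimal separator):

* death counts — header ``country,year,cause,age_label,deaths``, one row
  per (country, year, ICD-10 chapter or code, age category);
* population counts — header ``country,year,age_band,count`` where
  ``age_band`` is either ``under-1`` or a whole-year grid label, and
  ``count`` is the mean number of living persons over the year.

Loading enforces the study's eligibility rule: infant deaths must arrive
split into the four sub-year categories; a country-year reported with a
coarser infant band (e.g. ``0-365 days``) is rejected by name. Deaths
reported in single-year labels (``"1 years"`` … ``"4 years"``) are summed
into the containing whole-year band.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import pandas as pd
import yaml

from .causes import CauseGroup
from .errors import EligibilityError, FormatError, ValidationError
from .grid import LABEL_ALIASES, AgeGrid, Band

logger = logging.getLogger(__name__)

DEATH_COLUMNS = ["country", "year", "cause", "age_label", "deaths"]
POPULATION_COLUMNS = ["country", "year", "age_band", "count"]

#: Infant labels coarser than the four required subcategories.
_COARSE_INFANT_LABELS = {
    "0-365 days", "0–365 days", "under-1", "under 1", "under 1 year",
    "<1 year", "0 years", "0 year",
}
_SINGLE_YEAR_RE = re.compile(r"^(\d+) years?$")


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def _canonical_age_label(label: str, grid: AgeGrid) -> str | None:
    """Map a raw label to a grid label; single-year labels map to their
    containing whole-year band. None if the label is not on the grid."""
    label = label.strip()
    label = LABEL_ALIASES.get(label, label)
    if label in grid:
        return grid[label].label
    m = _SINGLE_YEAR_RE.match(label)
    if m:
        age = int(m.group(1))
        try:
            cat = grid.category_at(age + 0.5)
        except ValueError:
            return None
        if cat.band is Band.WHOLE_YEAR:
            return cat.label
    return None


def load_death_counts(path: str | Path, grid: AgeGrid) -> pd.DataFrame:
    """Load and validate a tidy death-count table.

    Returns a DataFrame with the canonical columns, age labels mapped
    onto the grid, duplicates (after single-year folding) summed, and
    (country, year, cause, age_label) unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"country": str, "cause": str, "age_label": str})
    if df.empty:
        logger.warning("%s: empty death-count file", path)
        return pd.DataFrame(columns=DEATH_COLUMNS)
    _require_columns(df, DEATH_COLUMNS, path)
    df = df[DEATH_COLUMNS].copy()

    if (df["deaths"] < 0).any():
        bad = df[df["deaths"] < 0].head()
        raise ValidationError(f"{path}: negative death counts, e.g.\n{bad}")
    if not (df["deaths"] == df["deaths"].astype(int)).all():
        raise ValidationError(f"{path}: non-integer death counts")
    df["deaths"] = df["deaths"].astype(int)
    df["year"] = df["year"].astype(int)

    raw_labels = df["age_label"].str.strip()
    coarse = raw_labels.isin(_COARSE_INFANT_LABELS)
    if coarse.any():
        pairs = sorted(
            set(zip(df.loc[coarse, "country"], df.loc[coarse, "year"]))
        )
        raise EligibilityError(
            "infant deaths not split into the four sub-year categories for "
            + ", ".join(f"{c} {y}" for c, y in pairs)
        )

    df["age_label"] = raw_labels.map(lambda s: _canonical_age_label(s, grid))
    unknown = df["age_label"].isna()
    if unknown.any():
        labels = sorted(set(raw_labels[unknown]))
        logger.warning("%s: dropping records with unknown age labels %s", path, labels)
        df = df[~unknown]

    df = (
        df.groupby(["country", "year", "cause", "age_label"], as_index=False)["deaths"]
        .sum()
    )
    return df[DEATH_COLUMNS]


def write_death_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[DEATH_COLUMNS].to_csv(path, index=False)


def load_population(path: str | Path) -> pd.DataFrame:
    """Load a census-style population table (mean living persons per year)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"country": str, "age_band": str})
    if df.empty:
        logger.warning("%s: empty population file", path)
        return pd.DataFrame(columns=POPULATION_COLUMNS)
    _require_columns(df, POPULATION_COLUMNS, path)
    df = df[POPULATION_COLUMNS].copy()
    if (df["count"] < 0).any():
        raise ValidationError(f"{path}: negative population counts")
    df["year"] = df["year"].astype(int)
    df["age_band"] = df["age_band"].str.strip()
    return df


def write_population(df: pd.DataFrame, path: str | Path) -> None:
    df[POPULATION_COLUMNS].to_csv(path, index=False)


ATM_COLUMNS = [
    "population", "cause_group", "age_label", "x_years",
    "deaths", "person_years", "rate_per_1000py",
]


def write_atm_table(atm, path: str | Path, scale: float = 1000.0) -> None:
    """Write an aggregated trajectory as CSV (rates per 1000 person-years)."""
    df = atm.to_frame()
    out = pd.DataFrame(
        {
            "population": atm.population_name,
            "cause_group": atm.cause_group,
            "age_label": df["age_label"],
            "x_years": df["x"],
            "deaths": df["deaths"],
            "person_years": df["person_years"],
            "rate_per_1000py": df["rate"] * scale,
        }
    )
    out.to_csv(path, index=False)


def load_cause_groups(path: str | Path) -> dict[str, CauseGroup]:
    """Load cause-group definitions from YAML or JSON.

    The file maps a group name to a list of chapter numerals and/or
    ICD-10 code ranges, e.g. ``CACNS: [Q00-Q07]``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping name -> member list")
    groups: dict[str, CauseGroup] = {}
    for name, members in data.items():
        chapters = frozenset(m for m in members if "-" not in m)
        ranges = tuple(m for m in members if "-" in m)
        groups[name] = CauseGroup(name, chapters=chapters, code_ranges=ranges)
    return groups


SUPPLEMENTARY_COLUMNS = ["population", "cause", "age_label", "deaths", "living"]


def load_supplementary_counts(path: str | Path) -> pd.DataFrame:
    """Load the pre-aggregated counts table of the source study.

    Expected layout: a tidy CSV with header
    ``population,cause,age_label,deaths,living`` giving, for each named
    population and ICD-10 chapter, the pooled death sum D_i and the
    pooled exposure L_i (person-years) per age category — i.e. the
    spreadsheet supplement converted to CSV. The ``living`` values are
    used directly as person-years denominators.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary counts file not found at {path}; it is not bundled "
            "with this package — convert the published spreadsheet to the tidy "
            "CSV layout documented in childmort.io.load_supplementary_counts"
        )
    df = pd.read_csv(path, dtype={"population": str, "cause": str, "age_label": str})
    _require_columns(df, SUPPLEMENTARY_COLUMNS, path)
    return df[SUPPLEMENTARY_COLUMNS]


def convert_raw_who_dump(path: str | Path) -> pd.DataFrame:  # pragma: no cover
    """Converter stub for the raw fixed-column WHO mortality dump.

    Parsing the historical fixed-width dialect (with its many age-format
    codes) is out of scope; prepare the tidy CSV documented in
    :func:`load_death_counts` instead, keeping only country-years whose
    infant deaths use the four sub-year categories.
    """
    raise NotImplementedError(
        "raw WHO fixed-column dumps are not parsed; supply the tidy CSV "
        "layout (country,year,cause,age_label,deaths) instead"
    )
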