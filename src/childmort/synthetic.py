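"""Synthetic multi-country mortality datasets with known hazard truths.

The generator emits death-count and population tables in exactly the
tidy layouts the readers consume, so simulated data flow through the
full pipeline (load → pool → fit → test) unchanged. For every country,
calendar year, cause and age category the expected count is

    lambda = profile(x_i) · L_i

with L_i the stationary exposure (band population × width for the
sub-year infant bands, band population for whole-year bands) and the
observed count Poisson(lambda). Rates are far below one per person-year
in every band except possibly the first day of life, so Poisson count
noise is the natural choice; a binomial switch is available for the
first-day band. A truth record carrying every lambda and every profile
parameter is emitted beside the data — oracle tests read it instead of
re-deriving the truth.

Hazard profiles mirror the qualitative shapes of child mortality:
inverse (all-cause), bending (infection-like "other diseases"),
constant (external causes), neoplasm-like (declining in infancy, then
age-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import AgeGrid, Band, standard_grid
from .halley import UNDER_ONE_BAND


# -- hazard profiles ---------------------------------------------------------


@dataclass(frozen=True)
class InverseProfile:
    """mu(x) = c / x; log–log slope exactly −1."""

    c: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValidationError("c must be positive")

    def __call__(self, x: float) -> float:
        if x <= 0:
            raise ValidationError("inverse profile undefined at x <= 0")
        return self.c / x

    def params(self) -> dict:
        return {"kind": "inverse", "c": self.c}


@dataclass(frozen=True)
class PowerProfile:
    """mu(x) = c · x^gamma; the free-slope generalisation."""

    c: float
    gamma: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValidationError("c must be positive")

    def __call__(self, x: float) -> float:
        if x <= 0:
            raise ValidationError("power profile undefined at x <= 0")
        return self.c * x**self.gamma

    def params(self) -> dict:
        return {"kind": "power", "c": self.c, "gamma": self.gamma}


@dataclass(frozen=True)
class BendingProfile:
    """mu(x) = (mu1/x)(1 − e^(−r_max x)); flat in infancy, inverse later."""

    mu1: float
    r_max: float

    def __post_init__(self):
        if self.mu1 <= 0 or self.r_max <= 0:
            raise ValidationError("mu1 and r_max must be positive")

    def __call__(self, x: float) -> float:
        from .tcir import bending_hazard

        return float(bending_hazard(x, self.mu1, self.r_max))

    def params(self) -> dict:
        return {"kind": "bending", "mu1": self.mu1, "r_max": self.r_max}


@dataclass(frozen=True)
class ConstantProfile:
    """mu(x) = m; age-independent."""

    m: float

    def __post_init__(self):
        if self.m < 0:
            raise ValidationError("m must be non-negative")

    def __call__(self, x: float) -> float:
        return self.m

    def params(self) -> dict:
        return {"kind": "constant", "m": self.m}


@dataclass(frozen=True)
class NeoplasmProfile:
    """Inverse decline during the first year, constant afterwards."""

    c_infant: float
    m_const: float

    def __post_init__(self):
        if self.c_infant <= 0 or self.m_const <= 0:
            raise ValidationError("parameters must be positive")

    def __call__(self, x: float) -> float:
        return self.c_infant / x if x < 1.0 else self.m_const

    def params(self) -> dict:
        return {"kind": "neoplasm", "c_infant": self.c_infant,
                "m_const": self.m_const}


# -- dataset specification ---------------------------------------------------


@dataclass(frozen=True)
class CountrySpec:
    """One synthetic country: band populations held constant over years."""

    name: str
    populations: Mapping[str, float]  # band label (or "under-1") -> mean count
    years: tuple[int, int]  # inclusive

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full dataset specification: countries × years × cause profiles."""

    countries: Sequence[CountrySpec]
    causes: Mapping[str, object]  # cause name -> hazard profile
    grid: AgeGrid = field(default_factory=lambda: standard_grid(15))
    seed: int = 0
    binomial_first_day: bool = False

    def __post_init__(self):
        if not self.countries or not self.causes:
            raise ValidationError("need at least one country and one cause")
        for c in self.countries:
            for v in c.populations.values():
                if v <= 0:
                    raise ValidationError(f"non-positive population in {c.name}")


def _band_of(category, grid: AgeGrid) -> str:
    return UNDER_ONE_BAND if category.band is Band.INFANT_SUB else category.label


def _exposure(country: CountrySpec, category, grid: AgeGrid) -> float:
    band = _band_of(category, grid)
    try:
        count = float(country.populations[band])
    except KeyError:
        raise ValidationError(
            f"country {country.name!r} lacks population band {band!r}"
        ) from None
    if category.band is Band.INFANT_SUB:
        return count * category.width
    return count


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one dataset; returns (death table, population table, truth).

    The truth record stores the seed, each profile's parameters and
    every per-cell expected count lambda. TOTAL is never drawn: it is
    the sum of the cause components, so conservation holds by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    death_rows: list[tuple] = []
    pop_rows: list[tuple] = []
    truth_lambda: list[dict] = []

    for country in spec.countries:
        for band in country.populations:
            for year in country.year_list:
                pop_rows.append(
                    (country.name, year, band, country.populations[band])
                )
        for year in country.year_list:
            for cause, profile in spec.causes.items():
                for cat in spec.grid:
                    L = _exposure(country, cat, spec.grid)
                    lam = profile(cat.midpoint) * L
                    if not np.isfinite(lam):
                        raise ValidationError(
                            f"profile {cause!r} undefined at x = {cat.midpoint}"
                        )
                    if (
                        spec.binomial_first_day
                        and cat.band is Band.INFANT_SUB
                        and cat.lower == 0.0
                    ):
                        n_at_risk = int(round(L / cat.width))
                        p = min(1.0, profile(cat.midpoint) * cat.width)
                        d = int(rng.binomial(n_at_risk, p))
                    else:
                        d = int(rng.poisson(lam))
                    death_rows.append(
                        (country.name, year, cause, cat.label, d)
                    )
                    truth_lambda.append(
                        {
                            "country": country.name,
                            "year": year,
                            "cause": cause,
                            "age_label": cat.label,
                            "lam": lam,
                        }
                    )

    deaths = pd.DataFrame(
        death_rows, columns=["country", "year", "cause", "age_label", "deaths"]
    )
    pop = pd.DataFrame(pop_rows, columns=["country", "year", "age_band", "count"])
    truth = {
        "seed": spec.seed,
        "profiles": {name: p.params() for name, p in spec.causes.items()},
        "lambda": truth_lambda,
    }
    return deaths, pop, truth


def default_band_populations(
    grid: AgeGrid, band_population: float = 1_000_000.0
) -> dict[str, float]:
    """Stationary mean populations: ``band_population`` persons per year
    of age, so a five-year band holds five times the under-1 count."""
    bands = {UNDER_ONE_BAND: band_population}
    for cat in grid:
        if cat.band is Band.WHOLE_YEAR:
            bands[cat.label] = band_population * cat.width
    return bands


def single_country_spec(
    profile,
    cause: str = "XVIII",
    band_population: float = 1_000_000.0,
    years: tuple[int, int] = (2000, 2000),
    grid: AgeGrid | None = None,
    seed: int = 0,
) -> SyntheticSpec:
    """Smallest useful spec: one country, one cause profile."""
    grid = grid or standard_grid(15)
    country = CountrySpec("Synthia", default_band_populations(grid, band_population),
                          years)
    return SyntheticSpec([country], {cause: profile}, grid=grid, seed=seed)


def study_like_spec(seed: int = 0, band_population: float = 1_000_000.0,
                    n_countries: int = 5) -> SyntheticSpec:
    """Multi-country spec with the qualitative cause mix of child
    mortality: dominant inverse congenital mortality (chapter XVII),
    bending infection-like mortality (chapter I), neoplasms (II) that
    decline in infancy then go flat, and small constant external causes
    (XX). Levels give an all-cause rate near 6e-4 per person-year at age
    one. The implied all-cause trajectory is close to, but by
    construction slightly shallower than, the inverse proportion
    (noiseless log–log slope ≈ −0.96 over birth to 10 years): the flat
    components lift the oldest categories.
    """
    grid = standard_grid(15)
    causes = {
        "XVII": InverseProfile(c=5.0e-4),
        "I": BendingProfile(mu1=8.0e-5, r_max=40.0),
        "II": NeoplasmProfile(c_infant=2.0e-5, m_const=1.5e-5),
        "XX": ConstantProfile(m=1.0e-5),
    }
    countries = [
        CountrySpec(
            f"Country{k}",
            default_band_populations(grid, band_population),
            (2000, 2009),
        )
        for k in range(n_countries)
    ]
    return SyntheticSpec(countries, causes, grid=grid, seed=seed)


# -- recovery experiments ----------------------------------------------------


def recovery_experiment(
    spec: SyntheticSpec,
    n_replicates: int,
    seed: int,
    age_range: tuple[float, float] = (0.0, 10.0),
    ci_level: float = 0.95,
) -> dict:
    """Repeatedly generate → pool → fit → test, against the known truth.

    Requires a single cause profile. Reports bias/RMSE of the slope,
    CI coverage of the true slope (when the profile family has one:
    inverse → −1, power → gamma, constant → 0), coverage of mu1 for
    the inverse family, and the fraction of replicates rejecting the
    inverse-proportion null H0: gamma = −1.
    """
    from .causes import TOTAL
    from .halley import aggregate
    from .trajectory import LogLogTrajectory

    if len(spec.causes) != 1:
        raise ValidationError("recovery experiment needs a single profile family")
    (profile,) = spec.causes.values()
    p = profile.params()
    truth_gamma = {"inverse": -1.0, "power": p.get("gamma"), "constant": 0.0}.get(
        p["kind"]
    )
    truth_mu1 = p.get("c") if p["kind"] in ("inverse", "power") else None

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]

    gammas = np.empty(n_replicates)
    covered = np.zeros(n_replicates, dtype=bool)
    covered_mu1 = np.zeros(n_replicates, dtype=bool)
    rejected = np.zeros(n_replicates, dtype=bool)
    mu1s = np.empty(n_replicates)

    selection = {c.name: c.year_list for c in spec.countries}
    for i, rs in enumerate(rep_seeds):
        rep_spec = SyntheticSpec(
            spec.countries, spec.causes, grid=spec.grid, seed=rs,
            binomial_first_day=spec.binomial_first_day,
        )
        deaths, pop, _ = generate_dataset(rep_spec)
        atm = aggregate(deaths, pop, selection, group=TOTAL, grid=spec.grid,
                        name="replicate")
        res = LogLogTrajectory.from_atm(atm, age_range).fit(
            ci_level=ci_level, scale=1.0
        )
        inv = res.test_inverse()
        gammas[i] = res.gamma
        mu1s[i] = res.mu1_level
        rejected[i] = inv.rejected
        if truth_gamma is not None:
            covered[i] = res.ci_lower <= truth_gamma <= res.ci_upper
        if truth_mu1 is not None:
            half = res.ci_upper - res.gamma  # same t multiplier for both params
            se_ratio = half / res.se_gamma if res.se_gamma > 0 else 0.0
            b0 = res.ln_mu1
            se_b0 = float(res._ols.bse[0])
            covered_mu1[i] = (
                b0 - se_ratio * se_b0 <= np.log(truth_mu1) <= b0 + se_ratio * se_b0
            )

    out = {
        "n_replicates": n_replicates,
        "mean_gamma": float(gammas.mean()),
        "reject_rate": float(rejected.mean()),
        "gammas": gammas,
    }
    if truth_gamma is not None:
        out.update(
            truth_gamma=truth_gamma,
            bias_gamma=float(gammas.mean() - truth_gamma),
            rmse_gamma=float(np.sqrt(np.mean((gammas - truth_gamma) ** 2))),
            coverage_gamma=float(covered.mean()),
        )
    if truth_mu1 is not None:
        out.update(
            truth_mu1=truth_mu1,
            bias_mu1_rel=float(mu1s.mean() / truth_mu1 - 1.0),
            coverage_mu1=float(covered_mu1.mean()),
        )
    return out
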