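"""Log–log model selection for the age trajectory of mortality.

The decline of child mortality with age is assessed in three stages on
the (ln x, ln mu) pairs of an aggregated trajectory over a stated age
range (0–10 years for all-cause mortality):

1. *curvature* — a quadratic least-squares fit; if the quadratic
   coefficient is not significantly non-zero (alpha = 0.05) the decline
   is taken as linear in log–log coordinates;
2. *two-parameter line* — OLS of ln mu on ln x, giving the slope gamma
   and the level ln(mu1) at x = 1 year, with a t-based confidence
   interval for gamma and the adjusted R²;
3. *inverse proportion* — the one-parameter nested model
   mu(x) = mu1 / x (slope fixed at −1) compared with the line by the
   F-test

       F = (RSS_inverse − RSS_linear) / (RSS_linear / (n − 2)),

   F ~ F(1, n − 2) under H0: gamma = −1. Rb² = 1 − RSS_inverse/TSS is
   the share of log-scale variance the inverse law alone explains.

Side checks: a zero-slope t-test (age independence, used for neoplasms
after the first year) and a rank-based test that residuals carry no age
trend.

All fits are ordinary least squares (statsmodels); the significance
level is 0.05 throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .grid import AgeCategory
from .halley import AggregatedATM

ALPHA = 0.05


def loglog_points(
    atm: AggregatedATM, age_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """(ln x_i, ln mu_i) for the categories with midpoints in range.

    Every category in range must have at least one death — a zero rate
    has no logarithm and signals that more pooling is needed.
    """
    cats = atm.grid.restrict(age_range)
    if not cats:
        raise InsufficientDataError(f"no categories with midpoints in {age_range}")
    idx = [atm.grid.labels.index(c.label) for c in cats]
    D = atm.deaths[idx]
    if (D == 0).any():
        bad = [cats[i].label for i in range(len(cats)) if D[i] == 0]
        raise ValidationError(
            f"zero-death categories in range {age_range}: {bad}; "
            "pool more years/countries before log-scale fitting"
        )
    x = atm.midpoints[idx]
    mu = atm.rates[idx]
    if len(x) < 3:
        raise InsufficientDataError(
            f"need at least 3 categories in range, got {len(x)}"
        )
    return np.log(x), np.log(mu)


def _check_abscissae(lnx: np.ndarray) -> None:
    if np.ptp(lnx) == 0:
        raise ValidationError("identical abscissae: slope not identifiable")


@dataclass
class CurvatureTest:
    """Quadratic-term significance in the log–log quadratic fit."""

    quad_coef: float
    p_quad: float
    p_linear: float

    @property
    def rejected(self) -> bool:
        """True if log–log linearity is rejected at alpha = 0.05."""
        return self.p_quad < ALPHA


@dataclass
class InverseTest:
    """Nested comparison of the inverse proportion against the free line."""

    rss_linear: float
    rss_inverse: float
    F_stat: float
    p_value: float
    rb2: float
    df_denom: int

    @property
    def rejected(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class SlopeTest:
    """t-test of H0: gamma = gamma0 in the two-parameter fit."""

    slope: float
    gamma0: float
    t_stat: float
    p_value: float

    @property
    def rejected(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class ResidualIndependenceTest:
    """Rank correlation between fit residuals and ln age."""

    rho: float
    p_value: float
    method: str

    @property
    def rejected(self) -> bool:
        return self.p_value < ALPHA


class LogLogTrajectory:
    """Two-parameter log–log model of a mortality trajectory.

    Parameters
    ----------
    lnx, lnmu : array_like
        Natural logs of category midpoints (years) and of mortality
        rates (per person-year).

    Use :meth:`from_atm` to build the model directly from an aggregated
    trajectory restricted to an age range.
    """

    def __init__(self, lnx, lnmu):
        self.lnx = np.asarray(lnx, dtype=float)
        self.lnmu = np.asarray(lnmu, dtype=float)
        if self.lnx.shape != self.lnmu.shape or self.lnx.ndim != 1:
            raise ValueError("lnx and lnmu must be 1-D arrays of equal length")
        if len(self.lnx) < 3:
            raise InsufficientDataError("need n >= 3 points")
        _check_abscissae(self.lnx)
        self.nobs = len(self.lnx)

    @classmethod
    def from_atm(
        cls, atm: AggregatedATM, age_range: tuple[float, float] = (0.0, 10.0)
    ) -> "LogLogTrajectory":
        lnx, lnmu = loglog_points(atm, age_range)
        return cls(lnx, lnmu)

    @classmethod
    def from_rates(cls, x, mu) -> "LogLogTrajectory":
        x = np.asarray(x, dtype=float)
        mu = np.asarray(mu, dtype=float)
        if (x <= 0).any() or (mu <= 0).any():
            raise ValidationError("ages and rates must be positive for logs")
        return cls(np.log(x), np.log(mu))

    def fit(self, ci_level: float = 0.95, scale: float = 1000.0) -> "LogLogTrajectoryResults":
        """OLS fit of ln mu = ln(mu1) + gamma · ln x."""
        X = sm.add_constant(self.lnx)
        res = sm.OLS(self.lnmu, X).fit()
        return LogLogTrajectoryResults(self, res, ci_level=ci_level, scale=scale)

    def test_curvature(self) -> CurvatureTest:
        """Quadratic least squares; is the quadratic term non-zero?"""
        if self.nobs < 4:
            raise InsufficientDataError(
                "curvature test needs n >= 4 (a residual degree of freedom)"
            )
        X = np.column_stack([np.ones(self.nobs), self.lnx, self.lnx**2])
        if np.linalg.matrix_rank(X) < 3:
            raise ValidationError("collinear abscissae: quadratic not identifiable")
        res = sm.OLS(self.lnmu, X).fit()
        return CurvatureTest(
            quad_coef=float(res.params[2]),
            p_quad=float(res.pvalues[2]),
            p_linear=float(res.pvalues[1]),
        )


class LogLogTrajectoryResults:
    """Fitted two-parameter log–log line with the downstream tests.

    Attributes
    ----------
    gamma : float
        Fitted slope (−1 is the inverse proportion).
    ln_mu1 : float
        Intercept: log rate (per person-year) at age 1 year.
    se_gamma, ci_lower, ci_upper : float
        Standard error and t-based interval for gamma.
    r2, r2_adj : float
        Plain and adjusted coefficients of determination.
    scale : float
        Reporting scale for mu1 (default per 1000 person-years).
    """

    def __init__(self, model: LogLogTrajectory, olsres, ci_level: float, scale: float):
        self.model = model
        self._ols = olsres
        self.ci_level = ci_level
        self.scale = scale
        self.nobs = model.nobs
        self.ln_mu1 = float(olsres.params[0])
        self.gamma = float(olsres.params[1])
        self.se_gamma = float(olsres.bse[1])
        ci = olsres.conf_int(alpha=1 - ci_level)
        self.ci_lower, self.ci_upper = float(ci[1][0]), float(ci[1][1])
        self.r2 = float(olsres.rsquared)
        self.r2_adj = float(olsres.rsquared_adj)
        self.residuals = np.asarray(olsres.resid)
        self.rss = float(self.residuals @ self.residuals)
        self.df_resid = self.nobs - 2

    @property
    def mu1_level(self) -> float:
        """mu1 on the reporting scale (rate at age 1 × scale)."""
        return math.exp(self.ln_mu1) * self.scale

    def predict(self, x) -> np.ndarray:
        """Fitted rate (per person-year) at ages ``x`` in years."""
        x = np.asarray(x, dtype=float)
        return np.exp(self.ln_mu1 + self.gamma * np.log(x))

    # -- nested / side tests -------------------------------------------------

    def test_inverse(self) -> InverseTest:
        """F-test of H0: gamma = −1 via the nested inverse-proportion fit."""
        lnx, lnmu = self.model.lnx, self.model.lnmu
        n = self.nobs
        # one-parameter LS: ln mu1 is the mean of (ln mu_i + ln x_i)
        ln_mu1_inv = float(np.mean(lnmu + lnx))
        resid_inv = lnmu - (ln_mu1_inv - lnx)
        rss_inv = float(resid_inv @ resid_inv)
        rss_lin = self.rss
        tss = float(np.sum((lnmu - lnmu.mean()) ** 2))
        rb2 = 1.0 - rss_inv / tss if tss > 0 else 1.0
        if rss_lin <= 1e-300:
            # perfect two-parameter fit: guard the 0/0 and 1/0 cases
            if rss_inv - rss_lin <= 1e-300:
                F, p = 0.0, 1.0
            else:
                F, p = math.inf, 0.0
        else:
            F = (rss_inv - rss_lin) / (rss_lin / (n - 2))
            p = float(stats.f.sf(F, 1, n - 2))
        return InverseTest(
            rss_linear=rss_lin,
            rss_inverse=rss_inv,
            F_stat=F,
            p_value=p,
            rb2=rb2,
            df_denom=n - 2,
        )

    def inverse_mu1(self) -> float:
        """mu1 of the one-parameter inverse fit, on the reporting scale."""
        ln_mu1_inv = float(np.mean(self.model.lnmu + self.model.lnx))
        return math.exp(ln_mu1_inv) * self.scale

    def test_slope(self, gamma0: float = 0.0) -> SlopeTest:
        """Two-sided t-test of H0: gamma = gamma0."""
        if self.se_gamma == 0:
            t = 0.0 if self.gamma == gamma0 else math.inf
            p = 1.0 if self.gamma == gamma0 else 0.0
        else:
            t = (self.gamma - gamma0) / self.se_gamma
            p = float(2 * stats.t.sf(abs(t), self.df_resid))
        return SlopeTest(slope=self.gamma, gamma0=gamma0, t_stat=t, p_value=p)

    def test_zero_slope(self) -> SlopeTest:
        """Age-independence check: H0: gamma = 0."""
        return self.test_slope(0.0)

    def test_residual_independence(self, model: str = "linear") -> ResidualIndependenceTest:
        """Are the residuals free of an age trend?"""
        if model == "linear":
            resid = self.residuals
        elif model == "inverse":
            lnx, lnmu = self.model.lnx, self.model.lnmu
            ln_mu1_inv = float(np.mean(lnmu + lnx))
            resid = lnmu - (ln_mu1_inv - lnx)
        else:
            raise ValueError("model must be 'linear' or 'inverse'")
        return residual_independence(self.model.lnx, resid)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        inv = self.test_inverse()
        lines = [
            "Log-log mortality trajectory (OLS)",
            "=" * 46,
            f"n points            {self.nobs:>10d}",
            f"slope gamma         {self.gamma:>10.3f}",
            f"  {int(self.ci_level*100)}% CI            [{self.ci_lower:.2f}, {self.ci_upper:.2f}]",
            f"  se(gamma)         {self.se_gamma:>10.4f}",
            f"level mu1           {self.mu1_level:>10.1f}  (per {self.scale:g} person-years)",
            f"R2 adj              {self.r2_adj:>10.4f}",
            "-" * 46,
            "Inverse proportion mu(x) = mu1/x (H0: gamma = -1)",
            f"  Rb2               {inv.rb2:>10.4f}",
            f"  F(1,{inv.df_denom})            {inv.F_stat:>10.3f}",
            f"  p value           {inv.p_value:>10.2f}"
            + ("   rejected" if inv.rejected else "   not rejected"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Log–log scatter with the fitted line and the inverse law."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lnx = self.model.lnx
        xs = np.exp(np.linspace(lnx.min(), lnx.max(), 100))
        ax.loglog(np.exp(lnx), np.exp(self.model.lnmu) * self.scale, "o",
                  label="observed")
        ax.loglog(xs, self.predict(xs) * self.scale, "-",
                  label=f"fit, $\\gamma$={self.gamma:.3f}")
        ax.loglog(xs, self.inverse_mu1() / xs, "--", label="inverse $\\mu_1/x$")
        ax.set_xlabel("age (years)")
        ax.set_ylabel(f"mortality rate per {self.scale:g} person-years")
        ax.legend()
        return ax


def residual_independence(
    lnx: np.ndarray, resid: np.ndarray, n_perm_exact: int = 8
) -> ResidualIndependenceTest:
    """Spearman rank correlation of residuals with ln age.

    For n <= ``n_perm_exact`` the p-value is computed by full
    permutation enumeration (the asymptotic Spearman null is unreliable
    at the n = 6 of the standard grid). Degenerate all-equal residuals
    (a perfect fit) return p = 1.
    """
    lnx = np.asarray(lnx, dtype=float)
    resid = np.asarray(resid, dtype=float)
    n = len(resid)
    if n < 4:
        raise InsufficientDataError("residual independence test needs n >= 4")
    if np.allclose(resid, resid[0]):
        return ResidualIndependenceTest(rho=0.0, p_value=1.0, method="degenerate")
    rho, p_asym = stats.spearmanr(lnx, resid)
    if n <= n_perm_exact:
        r_ranks = stats.rankdata(resid)
        x_ranks = stats.rankdata(lnx)

        def _rho(perm):
            return abs(np.corrcoef(x_ranks, perm)[0, 1])

        obs = _rho(r_ranks)
        count = total = 0
        for perm in itertools.permutations(r_ranks):
            total += 1
            if _rho(np.array(perm)) >= obs - 1e-12:
                count += 1
        return ResidualIndependenceTest(
            rho=float(rho), p_value=count / total, method="permutation"
        )
    return ResidualIndependenceTest(rho=float(rho), p_value=float(p_asym),
                                    method="asymptotic")


def find_minimum(atm: AggregatedATM) -> AgeCategory:
    """Age category at which the trajectory reaches its minimum rate.

    Ties break toward the younger category. All-zero rates are a
    degenerate input.
    """
    if len(atm.grid) < 2:
        raise InsufficientDataError("minimum detection needs >= 2 categories")
    rates = atm.rates
    if (rates == 0).all():
        raise ValidationError("all rates zero: minimum undefined")
    return atm.grid.categories[int(np.argmin(rates))]


# -- Table-style reporting ---------------------------------------------------

REPORT_COLUMNS = [
    "population", "years", "size", "slope", "lower", "upper",
    "level_mu1", "r2_adj", "rb2", "p_inverse",
]


def trajectory_row(
    atm: AggregatedATM,
    age_range: tuple[float, float] = (0.0, 10.0),
    ci_level: float = 0.95,
    scale: float = 1000.0,
    size: float = float("nan"),
    years: str = "",
) -> dict:
    """One report row: slope, interval, level, R² adj, Rb², inverse-test p."""
    res = LogLogTrajectory.from_atm(atm, age_range).fit(ci_level=ci_level, scale=scale)
    inv = res.test_inverse()
    return {
        "population": atm.population_name,
        "years": years,
        "size": size,
        "slope": res.gamma,
        "lower": res.ci_lower,
        "upper": res.ci_upper,
        "level_mu1": res.mu1_level,
        "r2_adj": res.r2_adj,
        "rb2": inv.rb2,
        "p_inverse": inv.p_value,
    }


def table1_report(
    atms,
    age_range: tuple[float, float] = (0.0, 10.0),
    ci_level: float = 0.95,
    scale: float = 1000.0,
    sizes: dict[str, float] | None = None,
    rendered: bool = False,
) -> pd.DataFrame:
    """Report table over several populations.

    Parameters
    ----------
    atms : iterable of AggregatedATM or mapping name -> AggregatedATM
    sizes : optional mapping population name -> mean population size.
    rendered : bool
        If True, round to the conventional printed precision (3 decimals
        for the slope, 2 for the interval and p, 4 for R², 1 for the
        level).
    """
    if isinstance(atms, dict):
        items = atms.items()
    else:
        items = [(a.population_name, a) for a in atms]
    sizes = sizes or {}
    rows = [
        trajectory_row(a, age_range, ci_level, scale,
                       size=sizes.get(name, float("nan")))
        for name, a in items
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if rendered:
        df = df.assign(
            slope=df["slope"].round(3),
            lower=df["lower"].round(2),
            upper=df["upper"].round(2),
            level_mu1=df["level_mu1"].round(1),
            r2_adj=df["r2_adj"].round(4),
            rb2=df["rb2"].round(4),
            p_inverse=df["p_inverse"].round(2),
        )
    return df
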