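import numpy as np
import pytest

from childmort import standard_grid
from childmort.synthetic import (
    CountrySpec,
    InverseProfile,
    SyntheticSpec,
    default_band_populations,
    generate_dataset,
)


@pytest.fixture(scope="session")
def grid10():
    return standard_grid(10)


@pytest.fixture(scope="session")
def grid15():
    return standard_grid(15)


@pytest.fixture(scope="session")
def inverse_dataset(grid15):
    """One synthetic country under an exact inverse hazard, with truth."""
    spec = SyntheticSpec(
        [CountrySpec("Synthia", default_band_populations(grid15, 1e6), (2000, 2001))],
        {"XVIII": InverseProfile(c=6e-4)},
        grid=grid15,
        seed=20260929,
    )
    deaths, pop, truth = generate_dataset(spec)
    return spec, deaths, pop, truth


def ols_oracle(X, y):
    """Independent normal-equations OLS: beta, residuals, RSS, se(beta).

    Deliberately avoids statsmodels: explicit solve of X'X beta = X'y and
    the classical variance formula.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = len(y) - X.shape[1]
    if df > 0:
        cov = np.linalg.inv(XtX) * (rss / df)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(X.shape[1], np.nan)
    return beta, resid, rss, se
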