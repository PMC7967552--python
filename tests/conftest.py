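import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import alcpolicy as ap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def econ() -> ap.EconomicSeries:
    """Published annual income/alcohol-price indices, 2007-2019 (2010 = 100)."""
    return ap.load_lithuania_economy()


@pytest.fixture(scope="session")
def events() -> list[ap.PolicyEvent]:
    """The 21 curated policy events, 2001-2019."""
    return ap.load_lithuania_timeline()


@pytest.fixture(scope="session")
def window() -> ap.StudyWindow:
    """Jan 2000 - Dec 2019 monthly study window, 24/24 pre/post minimum."""
    return ap.StudyWindow.from_strings("2000-01", "2019-12")


@pytest.fixture(scope="session")
def assignments(events, econ, window) -> list[ap.TierAssignment]:
    return ap.classify(events, econ, window)


def icc_oracle(x: np.ndarray) -> float:
    """Brute-force ICC(2,1) from the two-way ANOVA interaction decomposition.

    Coded independently of the implementation: residual sum of squares is
    accumulated cell-by-cell from the additive decomposition rather than
    by subtracting sums of squares.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
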