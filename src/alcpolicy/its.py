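"""Interrupted time series design checks and segmented regression.

The evaluation design compares the observed post-intervention trend of a
monthly outcome (e.g. litres of pure alcohol per capita, or deaths) with
the counterfactual trend projected from pre-intervention data, while
controlling for economic covariates (inflation, unemployment, GDP).

Design matrix: intercept, linear time, 11 month-of-year indicators
(December is the reference month), one column per covariate, and per
intervention either a 0/1 step from the enactment month (*abrupt*
effect) or a linear ramp rising from 1/L to 1 over ``lag_months = L``
months and staying at 1 (*lagged* effect, part of the impact immediate,
the rest accruing).

Residual AR(1) autocorrelation is handled by iterative quasi-differencing
(Cochrane-Orcutt): estimate rho from OLS residuals, transform
``y*_t = y_t - rho y_{t-1}`` (likewise each regressor), refit, and
iterate to convergence (tolerance 1e-6 on rho, at most 50 iterations).
Coefficients stay on the original outcome scale; intervals use the t
distribution with the transformed model's residual degrees of freedom.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tiers import ScoreSeries, StudyWindow

__all__ = [
    "EffectShape",
    "MonthlySeries",
    "InterventionSpec",
    "DesignCheck",
    "DesignReport",
    "EffectEstimate",
    "ITSFit",
    "check_design",
    "build_design_matrix",
    "fit_its",
    "read_series_csv",
    "write_series_csv",
]


class EffectShape(str, enum.Enum):
    ABRUPT = "abrupt"
    LAGGED = "lagged"


@dataclass(frozen=True)
class MonthlySeries:
    """Consecutive monthly outcome values with aligned named covariates."""

    months: pd.PeriodIndex
    values: np.ndarray
    covariates: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __init__(self, months, values, covariates: Mapping | None = None):
        months = pd.PeriodIndex(months, freq="M")
        values = np.asarray(values, dtype=float)
        covariates = {k: np.asarray(v, dtype=float) for k, v in (covariates or {}).items()}
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "covariates", covariates)
        self._validate()

    def _validate(self) -> None:
        if len(self.months) == 0:
            raise ValueError("empty series")
        if not (np.diff(self.months.asi8) == 1).all():
            raise ValueError("months must be consecutive")
        if len(self.values) != len(self.months):
            raise ValueError("values length does not match months")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        for name, v in self.covariates.items():
            if len(v) != len(self.months) or not np.isfinite(v).all():
                raise ValueError(f"covariate {name!r} misaligned or non-finite")

    def __len__(self) -> int:
        return len(self.months)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"month": self.months.astype(str), "value": self.values})
        for name, v in self.covariates.items():
            frame[name] = v
        return frame


@dataclass(frozen=True)
class InterventionSpec:
    """A dated intervention with an abrupt (step) or lagged (ramp) effect shape."""

    date: pd.Period
    shape: EffectShape = EffectShape.ABRUPT
    lag_months: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "date", pd.Period(self.date, freq="M"))
        object.__setattr__(self, "shape", EffectShape(self.shape))
        if self.shape is EffectShape.LAGGED:
            if self.lag_months is None or self.lag_months < 1:
                raise ValueError("lag_months >= 1 required for a lagged effect")
        elif self.lag_months is not None:
            raise ValueError("lag_months only applies to lagged effects")

    @property
    def name(self) -> str:
        suffix = f"_lag{self.lag_months}" if self.shape is EffectShape.LAGGED else ""
        return f"{self.shape.value}_{self.date}{suffix}"

    def column(self, months: pd.PeriodIndex) -> np.ndarray:
        offset = months.asi8 - pd.Period(self.date, freq="M").ordinal
        if self.shape is EffectShape.ABRUPT:
            return (offset >= 0).astype(float)
        return np.clip((offset + 1) / self.lag_months, 0.0, 1.0)


@dataclass(frozen=True)
class DesignCheck:
    intervention: str
    pre_months: int
    post_months: int
    pre_ok: bool
    post_ok: bool

    @property
    def ok(self) -> bool:
        return self.pre_ok and self.post_ok


@dataclass(frozen=True)
class DesignReport:
    checks: tuple[DesignCheck, ...]
    n_total: int
    total_ok: bool
    advisory: str

    @property
    def all_ok(self) -> bool:
        return all(c.ok for c in self.checks)


def check_design(
    series: MonthlySeries,
    specs: Sequence[InterventionSpec],
    window: StudyWindow | None = None,
) -> DesignReport:
    """Report pre/post month counts per intervention and a total-length advisory.

    ``window`` supplies ``min_pre``/``min_post`` (24/24 by default) and
    the recommended 50-100 total time points; counts are taken from the
    actual series months.
    """
    min_pre = window.min_pre if window else 24
    min_post = window.min_post if window else 24
    lo = window.recommended_total_min if window else 50
    hi = window.recommended_total_max if window else 100
    n = len(series)
    checks = []
    for spec in specs:
        offset = pd.Period(spec.date, freq="M").ordinal - series.months[0].ordinal
        pre = int(np.clip(offset, 0, n))
        post = int(np.clip(n - offset, 0, n))
        checks.append(
            DesignCheck(spec.name, pre, post, pre >= min_pre, post >= min_post)
        )
    if n < lo:
        advisory = f"series has {n} time points, below the recommended minimum of {lo}"
        total_ok = False
    elif n > hi:
        advisory = f"series has {n} time points, above the recommended {hi}; power is ample"
        total_ok = True
    else:
        advisory = f"series has {n} time points, within the recommended {lo}-{hi}"
        total_ok = True
    return DesignReport(tuple(checks), n, total_ok, advisory)


def build_design_matrix(
    series: MonthlySeries,
    specs: Sequence[InterventionSpec] = (),
    score: ScoreSeries | None = None,
    seasonal: bool = True,
) -> pd.DataFrame:
    """Segmented-regression design matrix for the series.

    Columns: ``const``, ``time`` (0-based month counter), month-of-year
    indicators ``m01``-``m11`` (December reference), one column per
    covariate, one step/ramp column per intervention, and optionally the
    cumulative policy score as a single exposure column.
    """
    months = series.months
    data: dict[str, np.ndarray] = {
        "const": np.ones(len(months)),
        "time": np.arange(len(months), dtype=float),
    }
    if seasonal:
        moy = months.month
        for m in range(1, 12):
            data[f"m{m:02d}"] = (moy == m).astype(float)
    for name, cov in series.covariates.items():
        data[name] = cov
    for spec in specs:
        if spec.name in data:
            raise ValueError(f"duplicate intervention column {spec.name!r}")
        data[spec.name] = spec.column(months)
    if score is not None:
        aligned = score.series.reindex(months)
        if aligned.isna().any():
            raise ValueError("score series does not cover the outcome months")
        data["policy_score"] = aligned.to_numpy()
    X = pd.DataFrame(data, index=months)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix (e.g. two interventions in the same month)")
    return X


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class ITSFit:
    """Segmented-regression results with optional AR(1) error correction."""

    effects: Mapping[str, EffectEstimate]
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    rho: float
    converged: bool
    n_iter: int
    resid_acf1: float
    n_obs: int
    alpha: float = 0.05

    @property
    def trend(self) -> float:
        return float(self.params["time"])

    @property
    def seasonal(self) -> pd.Series:
        return self.params[[c for c in self.params.index if c.startswith("m") and c[1:].isdigit()]]


def _lag1_autocorr(resid: np.ndarray, scale: float = 1.0) -> float:
    # residuals at float-noise level (near-exact fit): no estimable autocorrelation
    if np.sqrt(np.mean(resid**2)) <= 1e-10 * max(1.0, scale):
        return 0.0
    denom = float(resid[:-1] @ resid[:-1])
    return float(resid[1:] @ resid[:-1]) / denom


def fit_its(
    series: MonthlySeries,
    specs: Sequence[InterventionSpec] = (),
    score: ScoreSeries | None = None,
    ar1: bool = True,
    alpha: float = 0.05,
    seasonal: bool = True,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> ITSFit:
    """Fit the segmented regression, optionally with Cochrane-Orcutt AR(1).

    Either ``specs`` (one step/ramp per intervention) or ``score`` (the
    cumulative policy score as a single exposure) — or both — define the
    policy terms whose coefficients are reported as effects.
    """
    X = build_design_matrix(series, specs, score=score, seasonal=seasonal)
    y = series.values
    effect_names = [s.name for s in specs] + (["policy_score"] if score is not None else [])

    res = sm.OLS(y, X).fit()
    rho, n_iter, converged = 0.0, 0, True
    if ar1:
        converged = False
        y_scale = float(np.sqrt(np.mean(y**2)))
        for n_iter in range(1, max_iter + 1):
            resid = y - X.to_numpy() @ res.params.to_numpy()
            rho_new = float(np.clip(_lag1_autocorr(resid, y_scale), -0.999, 0.999))
            if abs(rho_new - rho) < tol:
                rho = rho_new
                converged = True
                break
            rho = rho_new
            Xs = X.iloc[1:].to_numpy() - rho * X.iloc[:-1].to_numpy()
            ys = y[1:] - rho * y[:-1]
            res = sm.OLS(ys, pd.DataFrame(Xs, columns=X.columns)).fit()
        if not converged:
            warnings.warn(
                f"AR(1) iteration did not converge after {max_iter} iterations "
                f"(last rho = {rho:.6f}); returning last iterate",
                RuntimeWarning,
            )

    ci = res.conf_int(alpha)
    ci.columns = ["low", "high"]
    effects = {
        name: EffectEstimate(
            estimate=float(res.params[name]),
            se=float(res.bse[name]),
            ci_low=float(ci.loc[name, "low"]),
            ci_high=float(ci.loc[name, "high"]),
            p_value=float(res.pvalues[name]),
        )
        for name in effect_names
    }
    return ITSFit(
        effects=effects,
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        rho=rho,
        converged=converged,
        n_iter=n_iter,
        resid_acf1=_lag1_autocorr(np.asarray(res.resid)),
        n_obs=len(series),
        alpha=alpha,
    )


def read_series_csv(path: str | Path) -> MonthlySeries:
    """Read ``month,value[,covariate...]`` CSV (month as YYYY-MM)."""
    frame = pd.read_csv(path)
    if "month" not in frame.columns or "value" not in frame.columns:
        raise ValueError("series CSV must have 'month' and 'value' columns")
    months = pd.PeriodIndex(frame["month"].astype(str), freq="M")
    covs = {
        c: frame[c].to_numpy(dtype=float)
        for c in frame.columns
        if c not in ("month", "value")
    }
    return MonthlySeries(months, frame["value"].to_numpy(dtype=float), covs)


def write_series_csv(series: MonthlySeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)
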