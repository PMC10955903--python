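"""Seasonally-adjusted single-group interrupted time-series regression.

Monthly counts N_T are regressed by ordinary least squares on

    N_T = a0 + a1*T + a2*(T - Tb) * 1{T >= Tb} + sum_m b_m * 1{month(T)=m} + e_T

with T a running month counter, Tb the fixed breakpoint (the pandemic
outbreak month in the reference analysis), a0 the level at T=0 in the
reference calendar month, a1 the long-term trend, a2 the post-breakpoint
trend variation (post-period slope = a1 + a2), and b_m calendar-month
effects.  The slope-change regressor is 0 at the breakpoint month itself.

Identifiability: the printed model with an intercept and all 12 month
dummies is rank-deficient, so one reference month — the series' first
calendar month — is dropped and absorbed into a0.  a1 and a2 are invariant
to that choice.  95% CIs are the normal-approximation estimate ± 1.96·SE on
classical (non-robust) standard errors; heteroskedasticity/autocorrelation-
robust errors are available behind a flag for sensitivity work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

from .series import MonthlySeries

Z95 = 1.96

MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")

#: 14 model parameters (a0, a1, a2 + 11 month dummies)
N_PARAMS = 14
MIN_MONTHS = 26


def build_design_matrix(n_months: int,
                        breakpoint_index: int,
                        start_month_of_year: int = 8,
                        seasonal: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix of the segmented seasonal model.

    Columns: intercept, T, slope-change term, and (when ``seasonal``) one
    indicator per calendar month except the reference month
    ``start_month_of_year``.  Raises if the requested matrix is rank
    deficient (e.g. too few months to separate trend from seasonality),
    naming the offending columns.
    """
    if not 0 < breakpoint_index < n_months:
        raise ValueError(
            f"breakpoint index {breakpoint_index} must lie strictly inside "
            f"(0, {n_months})"
        )
    t = np.arange(n_months, dtype=float)
    cols = [np.ones(n_months), t, np.maximum(t - breakpoint_index, 0.0)]
    names = ["alpha0", "alpha1", "alpha2"]
    if seasonal:
        months = (start_month_of_year - 1 + np.arange(n_months)) % 12 + 1
        for m in range(1, 13):
            if m == start_month_of_year:
                continue  # reference month absorbed by the intercept
            cols.append((months == m).astype(float))
            names.append(f"beta_{MONTH_NAMES[m - 1]}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        deficient = _deficient_columns(X, names)
        raise ValueError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"linearly dependent columns involve: {deficient}"
        )
    return X, names


def _deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


@dataclass
class ITSFit:
    """OLS fit of the segmented seasonal model for one stratum."""

    stratum: str
    breakpoint_index: int
    params: dict[str, float]
    se: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float
    nobs: int
    seasonal: bool = True
    robust: str | None = None
    param_names: list[str] = field(default_factory=list)

    @property
    def alpha0(self) -> float:
        return self.params["alpha0"]

    @property
    def alpha1(self) -> float:
        return self.params["alpha1"]

    @property
    def alpha2(self) -> float:
        return self.params["alpha2"]

    @property
    def seasonal_effects(self) -> dict[str, float]:
        return {k: v for k, v in self.params.items() if k.startswith("beta_")}

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "breakpoint_index": self.breakpoint_index,
            "params": self.params,
            "se": self.se,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "r_squared": self.r_squared,
            "nobs": self.nobs,
            "robust": self.robust,
        }


def fit_its(series: MonthlySeries,
            seasonal: bool = True,
            robust: str | None = None,
            min_months: int = MIN_MONTHS) -> ITSFit:
    """Fit the segmented model to one monthly series by OLS.

    ``robust`` may be ``"HAC"`` for Newey–West standard errors (sensitivity
    option); the default reproduces plain OLS standard errors.
    """
    n = len(series)
    if n < min_months:
        raise ValueError(f"series of length {n} too short (need >= {min_months})")
    X, names = build_design_matrix(
        n, series.breakpoint_index, series.start_month_of_year, seasonal=seasonal
    )
    model = sm.OLS(series.counts, X)
    if robust == "HAC":
        res = model.fit(cov_type="HAC", cov_kwds={"maxlags": 3})
    elif robust is None:
        res = model.fit()
    else:
        raise ValueError(f"unknown robust option {robust!r}")
    params = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    ci = {k: (params[k] - Z95 * se[k], params[k] + Z95 * se[k]) for k in names}
    return ITSFit(
        stratum=series.stratum,
        breakpoint_index=series.breakpoint_index,
        params=params,
        se=se,
        conf_int=ci,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        r_squared=float(res.rsquared),
        nobs=n,
        seasonal=seasonal,
        robust=robust,
        param_names=names,
    )


@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    durbin_watson: float
    lag1_autocorr: float


def residual_diagnostics(fit: ITSFit) -> ResidualDiagnostics:
    """Residual series with Durbin–Watson and lag-1 autocorrelation.

    No automatic decision is taken; DW near 2 is consistent with
    uncorrelated errors.
    """
    r = fit.residuals
    dw = float(durbin_watson(r))
    r0 = r - r.mean()
    denom = float(r0 @ r0)
    lag1 = float(r0[1:] @ r0[:-1] / denom) if denom > 0 else 0.0
    return ResidualDiagnostics(residuals=r, durbin_watson=dw, lag1_autocorr=lag1)
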