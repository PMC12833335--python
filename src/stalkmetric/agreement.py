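"""Method-agreement statistics between manual and point-cloud diameters.

Implements the accuracy-evaluation suite used to compare caliper
measurements ``y`` with pipeline predictions ``yhat``: MAPE/MAE/RMSE/R²,
ordinary least-squares regression with confidence and prediction bands,
residuals, a paired-samples t-test, and Bland–Altman limits of agreement.

All formulas are computed directly from their definitions; Student-t
quantiles and tail probabilities come from :mod:`scipy.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AgreementMetrics",
    "RegressionBands",
    "PairedTResult",
    "BlandAltmanResult",
    "AgreementReport",
    "agreement_metrics",
    "regression_with_intervals",
    "paired_t_test",
    "bland_altman",
    "build_agreement_report",
]


class AgreementMetrics(NamedTuple):
    """MAPE (%), MAE, RMSE (measurement units) and coefficient of determination."""

    mape: float
    mae: float
    rmse: float
    r2: float


def _paired(y, yhat, min_n: int) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} paired samples, got {y.size}")
    return y, yhat


def agreement_metrics(y, yhat) -> AgreementMetrics:
    """Error metrics of predictions ``yhat`` against reference values ``y``.

    MAPE uses the reference value as denominator and is reported in percent;
    it is undefined when any ``y_i`` is zero. R² is undefined for constant
    ``y``.
    """
    y, yhat = _paired(y, yhat, 2)
    if np.any(y == 0):
        raise ValueError("MAPE is undefined when a reference value is zero")
    err = yhat - y
    mape = float(np.mean(np.abs(err) / np.abs(y)) * 100.0)
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 is undefined for constant reference values")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return AgreementMetrics(mape=mape, mae=mae, rmse=rmse, r2=r2)


@dataclass(frozen=True)
class RegressionBands:
    """OLS line with per-``x0`` confidence and prediction half-widths.

    ``ci_half`` bounds the regression mean at each grid point; ``pi_half``
    bounds a new observation and is strictly wider everywhere (it carries the
    extra ``1 +`` term under the square root).
    """

    slope: float
    intercept: float
    s: float                       # residual standard error, sqrt(SSE/(n-2))
    xbar: float
    sxx: float
    n: int
    alpha: float
    t_crit: float
    x0: np.ndarray
    y0: np.ndarray
    ci_half: np.ndarray
    pi_half: np.ndarray


def regression_with_intervals(x, y, alpha: float = 0.05, grid_size: int = 100) -> RegressionBands:
    """Least-squares line of ``y`` on ``x`` with CI and PI bands.

    The half-widths at a point ``x0`` are::

        CI: t_{alpha/2, n-2} * s * sqrt(1/n + (x0 - xbar)^2 / Sxx)
        PI: t_{alpha/2, n-2} * s * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx)

    evaluated on a uniform grid spanning ``[min x, max x]``.
    """
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    n = x.size
    xbar = float(x.mean())
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    s = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    t_crit = float(stats.t.ppf(1 - alpha / 2, df=n - 2))
    x0 = np.linspace(x.min(), x.max(), grid_size)
    y0 = intercept + slope * x0
    lever = 1.0 / n + (x0 - xbar) ** 2 / sxx
    ci_half = t_crit * s * np.sqrt(lever)
    pi_half = t_crit * s * np.sqrt(1.0 + lever)
    return RegressionBands(slope=slope, intercept=intercept, s=s, xbar=xbar, sxx=sxx,
                           n=n, alpha=alpha, t_crit=t_crit, x0=x0, y0=y0,
                           ci_half=ci_half, pi_half=pi_half)


class PairedTResult(NamedTuple):
    """Paired t-test of the differences ``d_i = y_i - yhat_i``."""

    t: float
    p: float
    dbar: float
    sd: float
    significant: bool              # True when p <= 0.05


def paired_t_test(y, yhat) -> PairedTResult:
    """Two-sided paired-samples t-test, ``t = dbar / (sd / sqrt(n))``.

    ``p > 0.05`` is interpreted as no statistically significant difference
    between the two measurement methods. When the differences have zero
    spread but a nonzero mean, ``t`` is signed infinity and ``p`` is 0.
    """
    y, yhat = _paired(y, yhat, 2)
    d = y - yhat
    n = d.size
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if dbar == 0:
            return PairedTResult(t=0.0, p=1.0, dbar=0.0, sd=0.0, significant=False)
        return PairedTResult(t=float(np.sign(dbar)) * np.inf, p=0.0, dbar=dbar, sd=0.0,
                             significant=True)
    t = dbar / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=float(t), p=p, dbar=dbar, sd=sd, significant=p <= 0.05)


class BlandAltmanResult(NamedTuple):
    """Bland–Altman limits of agreement of ``yhat - y`` differences."""

    mean_diff: float
    loa_low: float
    loa_high: float
    fraction_within: float


def bland_altman(y, yhat, k: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman analysis; the difference is predicted minus manual.

    A positive mean difference therefore indicates overestimation by the
    point-cloud method. Limits are ``mean +- k * sd`` (95% for the default
    ``k = 1.96``); ``fraction_within`` counts differences inside the closed
    limit interval.
    """
    y, yhat = _paired(y, yhat, 2)
    d = yhat - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = mean_diff - k * sd
    loa_high = mean_diff + k * sd
    within = float(np.mean((d >= loa_low) & (d <= loa_high)))
    return BlandAltmanResult(mean_diff=mean_diff, loa_low=loa_low, loa_high=loa_high,
                             fraction_within=within)


@dataclass(frozen=True)
class AgreementReport:
    """Complete agreement analysis of one diameter axis."""

    n: int
    y: np.ndarray
    yhat: np.ndarray
    metrics: AgreementMetrics
    residuals: np.ndarray          # e_i = y_i - yhat_i
    regression: Optional[RegressionBands]
    t_test: PairedTResult
    bland_altman: BlandAltmanResult

    def to_dict(self) -> dict:
        reg = self.regression
        return {
            "n": self.n,
            "mape_percent": self.metrics.mape,
            "mae": self.metrics.mae,
            "rmse": self.metrics.rmse,
            "r2": self.metrics.r2,
            "slope": None if reg is None else reg.slope,
            "intercept": None if reg is None else reg.intercept,
            "t_stat": self.t_test.t,
            "p_value": self.t_test.p,
            "mean_diff": self.bland_altman.mean_diff,
            "loa_low": self.bland_altman.loa_low,
            "loa_high": self.bland_altman.loa_high,
            "fraction_within_loa": self.bland_altman.fraction_within,
        }


def build_agreement_report(y, yhat, alpha: float = 0.05) -> AgreementReport:
    """Run the full agreement suite for one axis (manual vs predicted)."""
    y, yhat = _paired(y, yhat, 2)
    metrics = agreement_metrics(y, yhat)
    regression = None
    if y.size >= 3 and np.ptp(y) > 0:
        regression = regression_with_intervals(y, yhat, alpha=alpha)
    return AgreementReport(
        n=y.size,
        y=y,
        yhat=yhat,
        metrics=metrics,
        residuals=y - yhat,
        regression=regression,
        t_test=paired_t_test(y, yhat),
        bland_altman=bland_altman(y, yhat),
    )
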