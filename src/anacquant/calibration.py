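"""External-standard calibration: OLS fit and significance statistics.

The calibration line ``y = a*x + b`` (peak area against concentration in
ug/mL) is fitted by ordinary least squares with every replicate injection
entering as its own point.  The dispersion statistics use the determinant
form of the normal equations:

    s_y^2 = sum(d_i^2) / (n - 2)            residual variance
    D     = n * sum(x_i^2) - (sum x_i)^2    determinant of X'X (times n)
    s_a^2 = s_y^2 * n / D                   slope variance
    s_b^2 = s_y^2 * sum(x_i^2) / D          intercept variance

Coefficient significance is judged by two-sided Student t tests,
t = |coef| / s_coef against the quantile at n-2 degrees of freedom, and the
regression as a whole by the F test F = MS_reg / MS_res with (1, n-2)
degrees of freedom; for a straight-line fit F equals t_a^2 identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationLevel",
    "CalibrationFit",
    "fit_line",
    "regression_dispersions",
    "coefficient_significance",
    "regression_f_test",
    "invert",
    "calibrate",
    "t_statistic",
    "f_from_t",
]


@dataclass(frozen=True)
class CalibrationLevel:
    """One concentration level with its replicate peak areas."""

    concentration: float  # ug/mL
    areas: "tuple[float, ...]"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        areas = tuple(float(a) for a in self.areas)
        if len(areas) < 1:
            raise ValueError("at least one replicate area is required")
        object.__setattr__(self, "areas", areas)


@dataclass
class CalibrationFit:
    """A fitted calibration line plus its significance statistics.

    Populated in stages: :func:`fit_line` fills the OLS part,
    :func:`regression_dispersions` the dispersions, and
    :func:`coefficient_significance` / :func:`regression_f_test` the tests.
    ``float('inf')`` is the sentinel for an exact fit (zero dispersion with a
    nonzero coefficient).
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    x: np.ndarray
    y: np.ndarray
    residuals: np.ndarray
    x_min: float
    x_max: float
    degenerate: bool = False  # n == 2: zero residual df, stats refused

    s_y: Optional[float] = None
    s_a: Optional[float] = None
    s_b: Optional[float] = None
    determinant: Optional[float] = None

    confidence: Optional[float] = None
    t_slope: Optional[float] = None
    t_intercept: Optional[float] = None
    t_critical: Optional[float] = None
    slope_significant: Optional[bool] = None
    intercept_significant: Optional[bool] = None

    f_stat: Optional[float] = None
    f_critical: Optional[float] = None
    regression_significant: Optional[bool] = None

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {k: _clean(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFit":
        d = dict(d)
        for key in ("x", "y", "residuals"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


class InvertedConcentration(NamedTuple):
    concentration: float  # ug/mL
    extrapolated: bool  # outside the fitted level range


def fit_line(levels: Sequence[CalibrationLevel]) -> CalibrationFit:
    """Ordinary least squares over all replicate points.

    Each replicate is one ``(x, y)`` point, so ``n`` counts injections, not
    levels.  Rejects fewer than two distinct concentrations (the determinant
    of the normal equations vanishes).
    """
    x = np.array([lv.concentration for lv in levels for _ in lv.areas], dtype=float)
    y = np.array([a for lv in levels for a in lv.areas], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("at least two distinct concentrations required (D = 0)")
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n=n,
        x=x,
        y=y,
        residuals=resid,
        x_min=float(x.min()),
        x_max=float(x.max()),
        degenerate=(n == 2),
    )


def regression_dispersions(fit: CalibrationFit) -> CalibrationFit:
    """Residual SD, determinant and coefficient SDs (in place, returned)."""
    if fit.n < 3 or fit.degenerate:
        raise ValueError("dispersions need n >= 3 (n - 2 residual degrees of freedom)")
    x = fit.x
    s_y2 = float(np.sum(fit.residuals**2)) / (fit.n - 2)
    d = fit.n * float(np.sum(x**2)) - float(np.sum(x)) ** 2
    if d <= 0:
        raise ValueError("degenerate design: determinant D <= 0")
    fit.s_y = math.sqrt(s_y2)
    fit.determinant = d
    fit.s_a = math.sqrt(s_y2 * fit.n / d)
    fit.s_b = math.sqrt(s_y2 * float(np.sum(x**2)) / d)
    return fit


def t_statistic(coefficient: float, sd: float) -> float:
    """t = |coefficient| / SD; infinite for an exact fit (SD = 0, coef != 0)."""
    if sd == 0.0:
        return 0.0 if coefficient == 0.0 else math.inf
    return abs(coefficient) / sd


def f_from_t(t_slope: float) -> float:
    """Straight-line identity: regression F equals the slope t squared."""
    return t_slope * t_slope


def coefficient_significance(fit: CalibrationFit, confidence: float = 0.95) -> CalibrationFit:
    """Two-sided t tests on slope and intercept at ``confidence``."""
    if fit.s_a is None or fit.s_b is None:
        raise ValueError("call regression_dispersions first")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    fit.confidence = confidence
    fit.t_slope = t_statistic(fit.slope, fit.s_a)
    fit.t_intercept = t_statistic(fit.intercept, fit.s_b)
    fit.t_critical = float(stats.t.ppf(1 - (1 - confidence) / 2, fit.n - 2))
    fit.slope_significant = fit.t_slope > fit.t_critical
    fit.intercept_significant = fit.t_intercept > fit.t_critical
    return fit


def regression_f_test(fit: CalibrationFit, confidence: float = 0.95) -> CalibrationFit:
    """Regression F test with (1, n-2) degrees of freedom."""
    if fit.s_y is None:
        raise ValueError("call regression_dispersions first")
    ss_res = float(np.sum(fit.residuals**2))
    ss_tot = float(np.sum((fit.y - fit.y.mean()) ** 2))
    ss_reg = ss_tot - ss_res
    if ss_res == 0.0:
        fit.f_stat = math.inf
    else:
        fit.f_stat = (ss_reg / 1.0) / (ss_res / (fit.n - 2))
    fit.f_critical = float(stats.f.ppf(confidence, 1, fit.n - 2))
    fit.regression_significant = fit.f_stat > fit.f_critical
    return fit


def invert(fit: CalibrationFit, area: float) -> InvertedConcentration:
    """Inverse prediction: concentration for a measured peak area.

    Flags the result as extrapolated when it falls outside the fitted
    concentration range.
    """
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    conc = (area - fit.intercept) / fit.slope
    extrapolated = not (fit.x_min <= conc <= fit.x_max)
    return InvertedConcentration(float(conc), extrapolated)


def calibrate(levels: Sequence[CalibrationLevel], confidence: float = 0.95) -> CalibrationFit:
    """Convenience chain: fit, dispersions, t tests and F test."""
    fit = fit_line(levels)
    regression_dispersions(fit)
    coefficient_significance(fit, confidence)
    regression_f_test(fit, confidence)
    return fit
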