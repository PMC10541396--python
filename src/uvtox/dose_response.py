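"""Potency estimation by inverse prediction from effect-dose regressions.

The effect-dose relationship is fitted by ordinary least squares in one of
three parameterisations:

``linear``        E = a + b C
``logarithmic``   E = a + b ln C          (C > 0)
``gamma_loglog``  log10 Γ = a + b log10 C (Microtox basic-test route;
                  the EC50 is the concentration where Γ = 1)

An ECx/LCx/ICx is the concentration at which the fitted effect equals x
(default 50%); estimates falling outside the tested concentration range
are returned censored, carrying the violated bound rather than an
extrapolated point value.  Fit quality is gated by the coefficient of
determination against a critical value derived from the two-sided
Student-t quantile,

    r²_crit = t²_{1−α/2, df} / (t²_{1−α/2, df} + df),

the R² above which the Pearson correlation of a df-degrees-of-freedom fit
is significant at level α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from uvtox.endpoint_processing import EffectPoint, GammaPoint
from uvtox.errors import DegenerateDesignError, DomainError, NoResponseError

MODELS = ("linear", "logarithmic", "gamma_loglog")
DF_CONVENTIONS = ("standard", "total")


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit of effect (or log gamma) against (transformed) dose."""

    model: str
    intercept: float
    slope: float
    r_squared: float
    n_points: int
    critical_r_squared: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.r_squared >= self.critical_r_squared


@dataclass(frozen=True)
class PotencyEstimate:
    """An ECx/LCx/ICx with its fitted model and censoring status.

    ``censored`` is ``"none"`` for an in-range point estimate; otherwise
    ``"above_max_tested"`` / ``"below_min_tested"`` and ``value`` carries
    the violated bound (the max or min tested concentration), not the
    extrapolated number.  ``inverted`` flags fits whose effect decreases
    with dose.
    """

    kind: str  # EC | LC | IC
    level: float
    value: float
    fit: RegressionFit | None
    censored: str = "none"
    extrapolated_value: float | None = None
    inverted: bool = False
    exposure_time: float | None = None
    time_unit: str | None = None
    compound: str | None = None
    organism: str | None = None
    endpoint: str | None = None
    conc_unit: str = "mg_per_L"


def critical_r_squared(df: int, alpha: float = 0.05) -> float:
    """Critical R² for Pearson-correlation significance at level ``alpha``."""
    if df < 1:
        raise DomainError("df must be >= 1")
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t * t / (t * t + df))


def _df_for(n: int, convention: str) -> int:
    if convention not in DF_CONVENTIONS:
        raise DomainError(f"unknown df convention {convention!r}")
    # "total" keeps df equal to the number of points, the only convention
    # under which the reported critical value 0.77 at n = 3 arises; the
    # standard residual df for a two-parameter line is n - 2.
    return n if convention == "total" else max(n - 2, 1)


def _ols(x: np.ndarray, y: np.ndarray, model: str, convention: str,
         alpha: float) -> RegressionFit:
    if len(x) < 2:
        raise DegenerateDesignError("need >= 2 points for a fit")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all design points identical")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2) if np.ptp(y) > 0 else 1.0
    return RegressionFit(
        model=model,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=r2,
        n_points=len(x),
        critical_r_squared=critical_r_squared(_df_for(len(x), convention), alpha),
        alpha=alpha,
    )


def fit_effect_dose(points: Sequence[EffectPoint], model: str = "linear",
                    df_convention: str = "standard",
                    alpha: float = 0.05) -> RegressionFit:
    """OLS of percent effect on concentration (linear) or ln C (logarithmic).

    Zero concentrations are controls and are excluded; the logarithmic
    model requires strictly positive doses in any case.
    """
    if model not in {"linear", "logarithmic"}:
        raise DomainError(f"unknown model {model!r}")
    pts = [p for p in points if p.concentration > 0]
    if len({p.concentration for p in pts}) < 2:
        raise DegenerateDesignError(
            "need >= 2 distinct positive concentrations")
    c = np.array([p.concentration for p in pts], dtype=float)
    e = np.array([p.effect_pct for p in pts], dtype=float)
    x = np.log(c) if model == "logarithmic" else c
    return _ols(x, e, model, df_convention, alpha)


def estimate_ecx(fit: RegressionFit, x: float = 50.0,
                 tested_range: tuple[float, float] | None = None,
                 kind: str = "EC", **meta) -> PotencyEstimate:
    """Invert a fitted effect-dose line at effect level ``x``.

    linear:       C = (x − a)/b
    logarithmic:  C = exp((x − a)/b)

    With ``tested_range`` = (min, max tested concentration), estimates
    outside the range come back censored at the violated bound.
    """
    if fit.slope == 0:
        raise DomainError("slope is zero: no dose dependence")
    inverted = fit.slope < 0
    q = (x - fit.intercept) / fit.slope
    value = math.exp(q) if fit.model == "logarithmic" else q
    censored = "none"
    extrapolated = None
    if tested_range is not None:
        lo, hi = tested_range
        if value > hi:
            censored, extrapolated, value = "above_max_tested", value, hi
        elif value < lo:
            censored, extrapolated, value = "below_min_tested", value, lo
    if censored == "none" and value <= 0:
        raise DomainError(
            f"non-positive potency estimate ({value:g}); inverted or "
            "out-of-domain fit — supply tested_range to censor instead")
    return PotencyEstimate(kind=kind, level=x, value=float(value), fit=fit,
                           censored=censored, extrapolated_value=extrapolated,
                           inverted=inverted, **meta)


def fit_gamma_loglog(points: Sequence[GammaPoint],
                     df_convention: str = "standard", alpha: float = 0.05,
                     tested_range: tuple[float, float] | None = None,
                     **meta) -> tuple[RegressionFit, PotencyEstimate]:
    """Microtox basic-test estimation: OLS of log10 Γ on log10 C.

    The EC50 is the concentration at which the fitted Γ equals 1:
    EC50 = 10^(−a/b).  Points with Γ = 0 (no response or stimulation)
    carry no information in log space and are dropped.
    """
    usable = [p for p in points if p.gamma > 0]
    if not usable:
        raise NoResponseError("all gamma values are zero: no response")
    if len({p.concentration for p in usable}) < 2:
        raise DegenerateDesignError(
            "need >= 2 distinct concentrations with gamma > 0")
    x = np.log10([p.concentration for p in usable])
    y = np.log10([p.gamma for p in usable])
    fit = _ols(np.asarray(x), np.asarray(y), "gamma_loglog",
               df_convention, alpha)
    if fit.slope == 0:
        raise DomainError("zero slope in log-log space: no dose dependence")
    ec50 = 10.0 ** (-fit.intercept / fit.slope)
    censored = "none"
    extrapolated = None
    if tested_range is not None:
        lo, hi = tested_range
        if ec50 > hi:
            censored, extrapolated, ec50 = "above_max_tested", ec50, hi
        elif ec50 < lo:
            censored, extrapolated, ec50 = "below_min_tested", ec50, lo
    est = PotencyEstimate(kind="EC", level=50.0, value=float(ec50), fit=fit,
                          censored=censored, extrapolated_value=extrapolated,
                          inverted=fit.slope < 0, **meta)
    return fit, est


def fit_time_trend(times: Sequence[float], effects: Sequence[float],
                   flat_band: float = 0.01, df_convention: str = "standard",
                   alpha: float = 0.05) -> tuple[RegressionFit, str]:
    """Toxicity dynamics: OLS of effect on exposure time.

    Returns the fit and a direction label; slopes within ``flat_band``
    (percent effect per minute) of zero are called flat.
    """
    if len(times) != len(effects):
        raise DomainError("times and effects must have equal length")
    fit = _ols(np.asarray(times, dtype=float), np.asarray(effects, dtype=float),
               "linear", df_convention, alpha)
    if abs(fit.slope) < flat_band:
        direction = "flat"
    else:
        direction = "increasing" if fit.slope > 0 else "decreasing"
    return fit, direction


def select_model(linear: RegressionFit | None,
                 logarithmic: RegressionFit | None) -> RegressionFit:
    """Pick the better-determined of the two fits; ties go to linear."""
    if linear is None and logarithmic is None:
        raise DomainError("both fits degenerate")
    if linear is None:
        return logarithmic
    if logarithmic is None:
        return linear
    return logarithmic if logarithmic.r_squared > linear.r_squared else linear


def fit_potency(points: Sequence[EffectPoint], x: float = 50.0,
                kind: str = "EC", df_convention: str = "standard",
                alpha: float = 0.05, **meta) -> PotencyEstimate:
    """Convenience pipeline: fit both models, select, invert at level x.

    The tested range for censoring is taken from the supplied points.
    """
    fits = {}
    for model in ("linear", "logarithmic"):
        try:
            fits[model] = fit_effect_dose(points, model, df_convention, alpha)
        except (DegenerateDesignError, DomainError):
            fits[model] = None
    chosen = select_model(fits["linear"], fits["logarithmic"])
    concs = [p.concentration for p in points if p.concentration > 0]
    return estimate_ecx(chosen, x, (min(concs), max(concs)), kind, **meta)
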