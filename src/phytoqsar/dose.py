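"""Percentage-inhibition computation and log-logistic IC50 fitting.

Enzyme-inhibition assays report absorbances; inhibition follows as
``(A_blank - A_test) / A_blank * 100``. IC50 is estimated by nonlinear
least squares of inhibition against log10(concentration) using the
four-parameter logistic

    y = bottom + (top - bottom) / (1 + 10 ** ((logIC50 - log c) * hill))

or its normalized two-parameter variant with bottom fixed at 0 and top at
100 (the convention of normalized-percentage-inhibition plots). Fitting
uses multistart initialization over the tested concentration quantiles and
a small grid of Hill slopes, so convergence does not depend on a lucky
first guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datasets import ConfigurationError, DatasetValidationError

__all__ = ["percent_inhibition", "DoseResponseFit", "fit_ic50", "ic50_summary"]

_MODELS = ("four_param_logistic", "normalized_two_param")


def percent_inhibition(abs_blank: float, abs_test: float) -> float:
    """Inhibition (%) from blank and test absorbances; scale free in the
    common absorbance units."""
    if abs_blank <= 0:
        raise ConfigurationError(f"blank absorbance must be positive, got {abs_blank}")
    return (abs_blank - abs_test) / abs_blank * 100.0


@dataclass
class DoseResponseFit:
    """A fitted log-logistic inhibition curve."""

    ic50: float
    ic50_se: float
    hill: float
    hill_se: float
    top: float
    bottom: float
    model: str
    residual_ss: float
    residual_sd: float
    n_points: int
    flags: list[str] = field(default_factory=list)


def _logistic(log_c: np.ndarray, log_ic50: float, hill: float, top: float, bottom: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - log_c) * hill))


def fit_ic50(
    concentrations: np.ndarray,
    inhibition: np.ndarray,
    model: str = "normalized_two_param",
    rescale_span: bool = False,
) -> DoseResponseFit:
    """Fit an IC50 from (concentration, mean % inhibition) pairs.

    Requires >= 4 distinct positive concentrations. ``rescale_span``
    min-max rescales the inhibition values to span [0, 100] before the
    normalized fit (one reading of "normalized" curves; off by default).
    Returns the estimate with its asymptotic standard error (delta method on
    log10 IC50), the Hill slope, and diagnostic flags: ``negative_hill`` for
    curves that fall with concentration and ``ic50_outside_tested_range``
    when the estimate extrapolates beyond the tested concentrations.
    """
    if model not in _MODELS:
        raise ConfigurationError(f"unknown model {model!r}; choose from {_MODELS}")
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if c.shape != y.shape:
        raise ConfigurationError("concentrations and inhibition must have equal length")
    if np.any(c <= 0):
        raise DatasetValidationError("concentrations must be strictly positive")
    if np.unique(c).size < 4:
        raise ConfigurationError("need at least 4 distinct concentrations")
    if rescale_span:
        lo, hi = y.min(), y.max()
        if hi == lo:
            raise DatasetValidationError("flat response: cannot rescale span")
        y = (y - lo) / (hi - lo) * 100.0
    log_c = np.log10(c)

    if model == "normalized_two_param":
        def func(x, log_ic50, hill):
            return _logistic(x, log_ic50, hill, 100.0, 0.0)
        extra0: list[float] = []
    else:
        def func(x, log_ic50, hill, top, bottom):
            return _logistic(x, log_ic50, hill, top, bottom)
        extra0 = [float(y.max()), float(y.min())]

    starts = []
    for q in (0.25, 0.5, 0.75):
        for hill0 in (0.5, 1.0, 2.0):
            starts.append([float(np.quantile(log_c, q)), hill0] + extra0)
    best = None
    best_rss = math.inf
    for p0 in starts:
        try:
            popt, pcov = curve_fit(func, log_c, y, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - func(log_c, *popt)) ** 2))
        if rss < best_rss:
            best, best_rss = (popt, pcov), rss
    if best is None:
        raise RuntimeError("IC50 fit did not converge from any start")
    popt, pcov = best
    log_ic50, hill = float(popt[0]), float(popt[1])
    top, bottom = (float(popt[2]), float(popt[3])) if model == "four_param_logistic" else (100.0, 0.0)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    ic50 = 10.0**log_ic50
    # delta method: d(10^x)/dx = ln(10) * 10^x
    ic50_se = float(math.log(10.0) * ic50 * perr[0])
    dof = max(y.size - len(popt), 1)
    flags = []
    if hill < 0:
        flags.append("negative_hill")
    if not (c.min() <= ic50 <= c.max()):
        flags.append("ic50_outside_tested_range")
    return DoseResponseFit(
        ic50=ic50,
        ic50_se=ic50_se,
        hill=hill,
        hill_se=float(perr[1]),
        top=top,
        bottom=bottom,
        model=model,
        residual_ss=best_rss,
        residual_sd=math.sqrt(best_rss / dof),
        n_points=int(y.size),
        flags=flags,
    )


def ic50_summary(fits: list[DoseResponseFit] | list[float]) -> tuple[float, float]:
    """Mean and sample SD of replicate IC50 determinations (>= 2 required)."""
    values = [f.ic50 if isinstance(f, DoseResponseFit) else float(f) for f in fits]
    if len(values) < 2:
        raise ConfigurationError("need at least 2 replicate fits")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))
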