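"""Sigmoidal kinetic models for cumulative biogas production.

Two three-parameter saturating models are fitted to cumulative specific
yield curves by bounded nonlinear least squares:

modified Gompertz
    CBP(t) = B * exp(-exp(Rb * e * (lag - t) / B + 1))

Logistic
    CBP(t) = B / (1 + exp(4 * Rb * (lag - t) / B + 2))

with B the ultimate production potential (mL/g VS), Rb the maximum
production rate (mL/g VS/day) and lag the lag phase (days).  Both curves
are strictly increasing in t, approach B as t -> inf, and have their
inflection (maximum slope Rb) after the lag; at t = lag the Gompertz curve
passes through B*exp(-e) and the Logistic through B/(1+e^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticModelParams",
    "KineticFit",
    "gompertz_predict",
    "logistic_predict",
    "fit_model",
    "goodness_of_fit",
    "adjusted_r_squared",
]

logger = logging.getLogger(__name__)

_MODELS = ("gompertz", "logistic")


@dataclass(frozen=True)
class KineticModelParams:
    """Parameters of one sigmoidal model."""

    model: str
    B: float
    Rb: float
    lag: float

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.B <= 0 or self.Rb <= 0:
            raise ValueError("B and Rb must be positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")

    def predict(self, t):
        fn = gompertz_predict if self.model == "gompertz" else logistic_predict
        return fn(self, t)


@dataclass(frozen=True)
class KineticFit:
    """Fitted parameters plus goodness-of-fit statistics."""

    params: KineticModelParams | None
    r_squared: float
    adj_r_squared: float
    rmse_percent: float
    n_points: int
    converged: bool
    predicted_final: float
    message: str = ""


def gompertz_predict(params: KineticModelParams, t) -> np.ndarray | float:
    """Modified-Gompertz cumulative production at time(s) t (days)."""
    t = np.asarray(t, dtype=float)
    out = params.B * np.exp(-np.exp(params.Rb * math.e * (params.lag - t) / params.B + 1.0))
    return float(out) if out.ndim == 0 else out


def logistic_predict(params: KineticModelParams, t) -> np.ndarray | float:
    """Logistic cumulative production at time(s) t (days)."""
    t = np.asarray(t, dtype=float)
    out = params.B / (1.0 + np.exp(4.0 * params.Rb * (params.lag - t) / params.B + 2.0))
    return float(out) if out.ndim == 0 else out


def goodness_of_fit(
    observed,
    predicted,
    rmse_normalization: str = "mean",
) -> tuple[float, float]:
    """Coefficient of determination and normalised RMSE in percent.

    R^2 = 1 - SS_res/SS_tot.  RMSE(%) divides the root-mean-square error by
    the mean of the observations (default), their max, or their final value.
    Zero variance in the observations makes R^2 undefined (returned as nan
    with a warning).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    resid = observed - predicted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("observed series has zero variance; R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    denominators = {
        "mean": observed.mean(),
        "max": observed.max(),
        "final": observed[-1],
    }
    try:
        denom = denominators[rmse_normalization]
    except KeyError:
        raise ValueError("rmse_normalization must be 'mean', 'max' or 'final'") from None
    rmse = math.sqrt(ss_res / observed.size)
    rmse_pct = float("nan") if denom == 0 else rmse / denom * 100.0
    return r2, rmse_pct


def adjusted_r_squared(r2: float, n: int, n_params: int = 3) -> float:
    if n - n_params - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _curve(model: str):
    if model == "gompertz":
        return lambda t, B, Rb, lag: B * np.exp(-np.exp(Rb * math.e * (lag - t) / B + 1.0))
    return lambda t, B, Rb, lag: B / (1.0 + np.exp(4.0 * Rb * (lag - t) / B + 2.0))


def fit_model(
    days,
    yields,
    model: str = "gompertz",
    day_cutoff: float | None = None,
    rmse_normalization: str = "mean",
) -> KineticFit:
    """Fit one sigmoidal model to a cumulative yield curve.

    Bounded least squares (B > 0, Rb > 0, lag >= 0) initialised at
    B0 = 1.05 * max(yield), Rb0 = steepest finite-difference slope, lag0 = 0.
    ``day_cutoff`` restricts the fit to days <= cutoff (e.g. the steep early
    window).  Non-convergence or degenerate input is reported via
    ``converged=False`` rather than raised.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    days = np.asarray(days, dtype=float)
    yields = np.asarray(yields, dtype=float)
    if day_cutoff is not None:
        keep = days <= day_cutoff
        days, yields = days[keep], yields[keep]
    n = days.size
    if n < 4:
        raise ValueError("at least 4 points are required to fit 3 parameters")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(yields < 0):
        raise ValueError("yields must be non-negative")

    ymax = float(yields.max())
    if ymax <= 0:
        return KineticFit(
            params=None,
            r_squared=float("nan"),
            adj_r_squared=float("nan"),
            rmse_percent=float("nan"),
            n_points=n,
            converged=False,
            predicted_final=0.0,
            message="all-zero yields; nothing to fit",
        )

    slopes = np.diff(yields) / np.diff(days)
    rb0 = max(float(slopes.max()), 1e-6)
    p0 = (1.05 * ymax, rb0, 0.0)
    tiny = 1e-12
    try:
        popt, _ = curve_fit(
            _curve(model),
            days,
            yields,
            p0=p0,
            bounds=([tiny, tiny, 0.0], [np.inf, np.inf, np.inf]),
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-10,
            maxfev=10_000,
        )
        params = KineticModelParams(model, float(popt[0]), float(popt[1]), float(popt[2]))
        converged, message = True, ""
    except (RuntimeError, ValueError) as exc:
        logger.warning("%s fit failed: %s", model, exc)
        return KineticFit(
            params=None,
            r_squared=float("nan"),
            adj_r_squared=float("nan"),
            rmse_percent=float("nan"),
            n_points=n,
            converged=False,
            predicted_final=float("nan"),
            message=str(exc),
        )

    predicted = params.predict(days)
    r2, rmse_pct = goodness_of_fit(yields, predicted, rmse_normalization)
    return KineticFit(
        params=params,
        r_squared=r2,
        adj_r_squared=adjusted_r_squared(r2, n),
        rmse_percent=rmse_pct,
        n_points=n,
        converged=converged,
        predicted_final=float(params.predict(days[-1])),
        message=message,
    )
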