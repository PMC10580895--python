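"""Closed-form batch-fermentation kinetics.

The model is the classical trio used for growth-associated product
formation on a single limiting substrate:

* logistic biomass growth,  dX/dt = mu_max * X * (1 - X/Xmax);
* growth-associated product formation (Luedeking-Piret with beta = 0),
  dP/dt = alpha * dX/dt, whose integral is the line P = alpha*X + K;
* substrate consumption with a maintenance term,
  -dS/dt = (1/Y_xs) dX/dt + (1/Y_ps) dP/dt + Ke*X.

Everything here is the analytic solution of those equations; parameter
estimation from data lives in :mod:`fermkin.fitting`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, SubstrateExhaustionWarning, ValidationError

__all__ = [
    "KineticParameters",
    "TimeCourse",
    "DerivedRates",
    "biomass_growth_rate",
    "biomass_at",
    "linearized_logistic",
    "product_at",
    "product_rate",
    "substrate_at",
    "yps_from_alpha",
    "derived_rates",
]


@dataclass(frozen=True)
class KineticParameters:
    """Parameter set for one batch fermentation.

    Units: concentrations in g/l, rates in 1/h, yields in g/g.

    ``k_int`` is the integration constant of the product line
    (P = alpha*X + k_int); ``p0`` is the observed initial product
    concentration and is kept separate because a fitted line need not
    pass exactly through (x0, p0).
    """

    x0: float
    xmax: float
    mu_max: float
    y_xs: float = math.nan
    alpha: float = 0.0
    k_int: float = 0.0
    y_ps: float = math.nan
    ke: float = 0.0
    s0: float = math.nan
    p0: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValidationError(f"mu_max must be > 0, got {self.mu_max}")
        if not 0 < self.x0 < self.xmax:
            # x0 == xmax is rejected rather than treated as constant growth
            raise ValidationError(
                f"require 0 < x0 < xmax, got x0={self.x0}, xmax={self.xmax}"
            )
        for name in ("y_xs", "alpha", "k_int", "y_ps", "ke", "s0", "p0"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    def _require(self, *names: str) -> None:
        for name in names:
            if math.isnan(getattr(self, name)):
                raise ValidationError(f"parameter {name!r} is required but unset")


@dataclass(frozen=True)
class TimeCourse:
    """Ordered observations (t, X, P[, S]) of one batch run.

    ``t`` in hours, concentrations in g/l. ``s`` may be None when the
    substrate series was not measured.
    """

    t: np.ndarray
    x: np.ndarray
    p: np.ndarray
    s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        p = np.asarray(self.p, dtype=float)
        s = None if self.s is None else np.asarray(self.s, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "s", s)
        if t.ndim != 1 or len(t) == 0:
            raise ValidationError("time grid must be a non-empty 1-d array")
        if len(x) != len(t) or len(p) != len(t) or (s is not None and len(s) != len(t)):
            raise ValidationError("all series must share the time grid length")
        if np.any(t < 0):
            raise ValidationError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        for name, arr in (("biomass", x), ("product", p), ("substrate", s)):
            if arr is not None and np.any(arr[~np.isnan(arr)] < 0):
                raise ValidationError(f"{name} values must be >= 0")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.t, "biomass_g_l": self.x, "product_g_l": self.p}
        if self.s is not None:
            data["substrate_g_l"] = self.s
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DerivedRates:
    """Volumetric (Q, g/l/h) and specific (q, per g dry wt per h) rate and
    yield summaries for one run; fields are None when not computable."""

    q_x_vol: Optional[float] = None
    q_p_vol: Optional[float] = None
    q_s_vol: Optional[float] = None
    q_x_spec: Optional[float] = None
    q_p_spec: Optional[float] = None
    q_s_spec: Optional[float] = None
    y_px: Optional[float] = None


def biomass_growth_rate(x: float, params: KineticParameters) -> float:
    """Logistic growth rate mu_max * x * (1 - x/xmax) in g/l/h."""
    x = float(x)
    if x < 0 or x > params.xmax:
        raise DomainError(f"biomass must lie in [0, xmax={params.xmax}], got {x}")
    return params.mu_max * x * (1.0 - x / params.xmax)


def biomass_at(t, params: KineticParameters):
    """Explicit logistic solution X(t).

    Evaluated in the overflow-safe form
    ``xmax / (1 + ((xmax - x0)/x0) * exp(-mu_max * t))``, which equals
    ``x0 * exp(mu_max t) / (1 - (x0/xmax)(1 - exp(mu_max t)))``.
    Accepts a scalar or array of times (hours, >= 0).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    ratio = (params.xmax - params.x0) / params.x0
    out = params.xmax / (1.0 + ratio * np.exp(-params.mu_max * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def linearized_logistic(x, params: KineticParameters):
    """Log-ratio transform ln(x / (xmax - x)) of the logistic curve.

    Plotted against t this is a straight line with slope mu_max and
    intercept ln(x0 / (xmax - x0)); it is the transform used to
    linearize the growth model for graphical estimation.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0) or np.any(x_arr >= params.xmax):
        raise DomainError(
            f"biomass must lie strictly inside (0, xmax={params.xmax}) "
            "for the log-ratio transform"
        )
    out = np.log(x_arr / (params.xmax - x_arr))
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def product_at(x, params: KineticParameters):
    """Product concentration from the integrated growth-associated model,
    P = alpha * X + K."""
    x_arr = np.asarray(x, dtype=float)
    out = params.alpha * x_arr + params.k_int
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def product_rate(dxdt, params: KineticParameters):
    """Growth-associated product formation rate alpha * dX/dt (g/l/h)."""
    out = params.alpha * np.asarray(dxdt, dtype=float)
    return float(out) if np.isscalar(dxdt) or out.ndim == 0 else out


def _log_integral_biomass(t_arr: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Integral of X over [0, t]: (xmax/mu_max) * ln((xmax - x0 + x0 e^{mu t}) / xmax).

    Written with logaddexp so large mu_max*t cannot overflow.
    """
    mu, x0, xmax = params.mu_max, params.x0, params.xmax
    # ln(xmax - x0 + x0 e^{mu t}) = logaddexp(ln(xmax - x0), ln(x0) + mu t)
    log_num = np.logaddexp(math.log(xmax - x0), math.log(x0) + mu * t_arr)
    return (xmax / mu) * (log_num - math.log(xmax))


def substrate_at(t, params: KineticParameters, *, warn_exhaustion: bool = True):
    """Substrate concentration S(t) from the integrated balance.

    S(t) = s0 - (1/y_xs + alpha/y_ps) * (X(t) - x0)
              - ke * (xmax/mu_max) * ln((xmax - x0 + x0 e^{mu_max t}) / xmax)

    i.e. the analytic integral of the consumption balance using the
    closed-form integral of the logistic curve.  If the parameters imply
    S < 0 before the last requested time, a
    :class:`SubstrateExhaustionWarning` carrying the exhaustion time is
    issued (values are returned un-clipped).
    """
    params._require("y_xs", "s0")
    if params.alpha > 0:
        params._require("y_ps")
    if params.y_xs <= 0:
        raise DomainError("y_xs must be > 0 for substrate computations")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")

    coeff = 1.0 / params.y_xs
    if params.alpha > 0:
        if params.y_ps <= 0:
            raise DomainError("y_ps must be > 0 when alpha > 0")
        coeff += params.alpha / params.y_ps

    def _s(tv):
        tv = np.asarray(tv, dtype=float)
        growth_term = coeff * (biomass_at(tv, params) - params.x0)
        maint_term = params.ke * _log_integral_biomass(tv, params)
        return params.s0 - growth_term - maint_term

    out = _s(t_arr)
    if warn_exhaustion and np.any(out < 0):
        t_end = float(t_arr[np.argmax(out < 0)])
        # S(t) is strictly decreasing, so a single bracketed root exists
        t_zero = brentq(lambda tv: float(_s(tv)), 0.0, t_end) if _s(0.0) > 0 else 0.0
        warnings.warn(
            SubstrateExhaustionWarning(
                f"substrate exhausted at t = {t_zero:.4g} h, before the "
                f"requested time {t_arr[-1]:.4g} h",
                exhaustion_time=t_zero,
            ),
            stacklevel=2,
        )
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def yps_from_alpha(params: KineticParameters) -> float:
    """Product-on-substrate yield implied by the growth-associated model,
    Y_p/s = alpha * Y_x/s.

    Exposed as a consistency check: a reported Y_p/s that disagrees with
    this product indicates internally inconsistent parameter estimates.
    """
    params._require("y_xs")
    return params.alpha * params.y_xs


def derived_rates(tc: TimeCourse, qs_vol: Optional[float] = None) -> DerivedRates:
    """Volumetric and specific rate/yield summaries for one run.

    Conventions (the field's usual peak-based definitions):
    volumetric product rate Qp = peak product / time of peak product;
    volumetric biomass rate Qx = peak biomass / time of peak biomass;
    specific rates q = Q / peak biomass; Y_p/x = peak product / peak
    biomass.  The volumetric substrate rate is not derivable from
    concentrations alone and is taken from ``qs_vol`` when supplied
    (its specific counterpart is qs_vol / peak biomass).
    """
    if len(tc) < 2:
        raise ValidationError("derived rates need at least 2 observations")
    i_x = int(np.nanargmax(tc.x))
    i_p = int(np.nanargmax(tc.p))
    x_peak = float(tc.x[i_x])
    p_peak = float(tc.p[i_p])
    t_x = float(tc.t[i_x])
    t_p = float(tc.t[i_p])

    q_x_vol = x_peak / t_x if t_x > 0 else None
    q_p_vol = p_peak / t_p if t_p > 0 else None
    has_biomass = x_peak > 0

    return DerivedRates(
        q_x_vol=q_x_vol,
        q_p_vol=q_p_vol,
        q_s_vol=qs_vol,
        q_x_spec=(q_x_vol / x_peak) if (q_x_vol is not None and has_biomass) else None,
        q_p_spec=(q_p_vol / x_peak) if (q_p_vol is not None and has_biomass) else None,
        q_s_spec=(qs_vol / x_peak) if (qs_vol is not None and has_biomass) else None,
        y_px=(p_peak / x_peak) if has_biomass else None,
    )
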