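"""Parameter estimation from time-course data and model validation.

Estimators:

* :func:`fit_logistic` — x0, xmax, mu_max of the logistic growth curve,
  either by nonlinear least squares on concentrations (default) or by the
  classical log-ratio linearization with the carrying capacity profiled
  over a grid;
* :func:`fit_product_line` — alpha and the integration constant K of the
  growth-associated product line P = alpha*X + K, by OLS;
* :func:`fit_luedeking_piret` — alpha and beta of the two-term product
  model dP/dt = alpha dX/dt + beta X, from finite-difference rates, with
  Gaden's class (I growth-associated / II mixed / III non-growth) assigned
  by a 2-standard-error rule;
* :func:`fit_substrate` — Y_x/s and the maintenance coefficient Ke from
  an observed substrate series, holding the growth and product parameters
  fixed and tying Y_p/s = alpha * Y_x/s.

Validation helpers compute the signed percentage error
(experimental - calculated)/experimental * 100 per time point and both
signed-mean and mean-absolute summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Tuple

import numpy as np
from scipy import optimize

from .errors import AlignmentError, DomainError, FitError, SingularFitError, ValidationError
from .kinetics import KineticParameters, TimeCourse, biomass_at, substrate_at
from .utils import round_half_up

__all__ = [
    "KineticFitResult",
    "LuedekingPiretFit",
    "ErrorReport",
    "fit_logistic",
    "fit_product_line",
    "fit_luedeking_piret",
    "fit_substrate",
    "percentage_error",
    "error_report",
    "compare_time_courses",
]


@dataclass(frozen=True)
class KineticFitResult:
    """Result of a kinetic-parameter estimation.

    ``params`` carries the estimated subset (unestimated fields keep their
    defaults); ``se`` maps parameter names to standard errors where the
    method provides them.
    """

    params: KineticParameters
    residual_sse: float
    method: Literal["linearized", "nonlinear"]
    converged: bool
    message: str = ""
    se: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class LuedekingPiretFit:
    alpha_hat: float
    beta_hat: float
    alpha_se: float
    beta_se: float
    gaden_class: Literal["I", "II", "III"]
    residual_sse: float = math.nan


@dataclass(frozen=True)
class ErrorReport:
    """Per-time signed percentage errors between an experimental and a
    calculated series, with both summary conventions."""

    t: np.ndarray
    experimental: np.ndarray
    calculated: np.ndarray
    errors: np.ndarray  # signed percent

    @property
    def signed_mean(self) -> float:
        return float(np.mean(self.errors))

    @property
    def mean_absolute(self) -> float:
        return float(np.mean(np.abs(self.errors)))

    def rounded(self, decimals: int = 2) -> np.ndarray:
        """Errors rounded half-up for display, matching printed tables."""
        return np.array([round_half_up(e, decimals) for e in self.errors])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.t,
                "experimental_g_l": self.experimental,
                "calculated_g_l": self.calculated,
                "error_percent": self.errors,
            }
        )


def percentage_error(experimental: float, calculated: float) -> float:
    """Signed percentage error (experimental - calculated)/experimental * 100."""
    if experimental == 0:
        raise DomainError("percentage error undefined for experimental = 0")
    return (experimental - calculated) / experimental * 100.0


def error_report(t, experimental, calculated) -> ErrorReport:
    """Row-wise signed percentage errors for one aligned series pair.

    Rows with experimental = 0 have no defined percentage error; they are
    dropped with a warning (the report errors out only if no row is left).
    """
    import warnings

    t = np.asarray(t, dtype=float)
    e = np.asarray(experimental, dtype=float)
    c = np.asarray(calculated, dtype=float)
    if not (len(t) == len(e) == len(c)):
        raise AlignmentError("series lengths differ")
    mask = e != 0
    if not np.any(mask):
        raise DomainError("percentage error undefined: all experimental values are 0")
    if not np.all(mask):
        warnings.warn(
            f"dropped {int((~mask).sum())} row(s) with experimental = 0 "
            "(percentage error undefined there)",
            stacklevel=2,
        )
    t, e, c = t[mask], e[mask], c[mask]
    return ErrorReport(t=t, experimental=e, calculated=c, errors=(e - c) / e * 100.0)


def compare_time_courses(tc_exp: TimeCourse, tc_calc: TimeCourse) -> Dict[str, ErrorReport]:
    """Error reports for every series two runs share, on a common grid.

    Returns reports keyed ``biomass``/``product``/``substrate``; raises
    :class:`AlignmentError` when the time grids differ.
    """
    if len(tc_exp) != len(tc_calc) or not np.allclose(tc_exp.t, tc_calc.t):
        raise AlignmentError("experimental and calculated time grids differ")
    out = {
        "biomass": error_report(tc_exp.t, tc_exp.x, tc_calc.x),
        "product": error_report(tc_exp.t, tc_exp.p, tc_calc.p),
    }
    if tc_exp.s is not None and tc_calc.s is not None:
        out["substrate"] = error_report(tc_exp.t, tc_exp.s, tc_calc.s)
    return out


# ---------------------------------------------------------------------------
# logistic growth


def _check_growth_data(tc: TimeCourse) -> None:
    if len(tc) < 3:
        raise ValidationError("logistic fitting needs at least 3 points")
    if np.any(tc.x <= 0):
        raise ValidationError("logistic fitting needs strictly positive biomass")
    if np.ptp(tc.x) == 0:
        raise FitError("biomass series is constant; growth rate not identifiable")


def _linearized_at_xmax(t: np.ndarray, x: np.ndarray, xmax: float):
    """OLS of ln(x/(xmax-x)) on t; returns (mu, x0, sse in log-ratio space)."""
    z = np.log(x / (xmax - x))
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    mu, intercept = float(coef[0]), float(coef[1])
    resid = z - A @ coef
    x0 = xmax / (1.0 + math.exp(-intercept))
    return mu, x0, float(resid @ resid)


def _fit_logistic_linearized(tc: TimeCourse) -> KineticFitResult:
    t, x = tc.t, tc.x
    xobs = float(np.max(x))
    # profile xmax on a grid just above the largest observation, then
    # polish the best grid point with a bounded scalar search
    grid = np.linspace(xobs * (1.0 + 1e-9), 3.0 * xobs, 200)
    sses = np.array([_linearized_at_xmax(t, x, xm)[2] for xm in grid])
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda xm: _linearized_at_xmax(t, x, xm)[2],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10 * xobs},
    )
    xmax = float(res.x)
    mu, x0, sse = _linearized_at_xmax(t, x, xmax)
    if mu <= 0:
        raise FitError(
            f"linearized fit gave non-positive mu_max ({mu:.4g}); biomass "
            "series is not growth-dominated"
        )
    params = KineticParameters(x0=x0, xmax=xmax, mu_max=mu)
    return KineticFitResult(
        params=params,
        residual_sse=sse,
        method="linearized",
        converged=bool(res.success),
        message="log-ratio SSE minimized over profiled xmax",
    )


def _fit_logistic_nonlinear(tc: TimeCourse) -> KineticFitResult:
    t, x = tc.t, tc.x

    def model(tv, x0, xmax, mu):
        ratio = (xmax - x0) / x0
        return xmax / (1.0 + ratio * np.exp(-mu * tv))

    # starting point: first observation, a capacity just above the data,
    # and the slope of the linearized fit at that capacity
    x0_start = float(x[0])
    xmax_start = 1.05 * float(np.max(x))
    mu_start, _, _ = _linearized_at_xmax(t, x, xmax_start)
    if not mu_start > 0:
        mu_start = 0.1
    try:
        popt, pcov = optimize.curve_fit(
            model,
            t,
            x,
            p0=[x0_start, xmax_start, mu_start],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message varies
        raise FitError(f"nonlinear logistic fit did not converge: {exc}") from exc
    x0, xmax, mu = (float(v) for v in popt)
    if not (0 < x0 < xmax) or mu <= 0:
        raise FitError(
            f"nonlinear logistic fit converged to invalid parameters "
            f"(x0={x0:.4g}, xmax={xmax:.4g}, mu_max={mu:.4g})"
        )
    resid = x - model(t, *popt)
    se = np.sqrt(np.diag(pcov))
    params = KineticParameters(x0=x0, xmax=xmax, mu_max=mu)
    return KineticFitResult(
        params=params,
        residual_sse=float(resid @ resid),
        method="nonlinear",
        converged=True,
        message="Levenberg-Marquardt on concentration residuals",
        se={"x0": float(se[0]), "xmax": float(se[1]), "mu_max": float(se[2])},
    )


def fit_logistic(
    tc: TimeCourse, method: Literal["linearized", "nonlinear"] = "nonlinear"
) -> KineticFitResult:
    """Estimate (x0, xmax, mu_max) from a biomass series.

    ``nonlinear`` (default) minimizes squared error in concentration
    space; ``linearized`` minimizes it in log-ratio space with the
    carrying capacity profiled over a grid between max(X) and 3 max(X)
    and then polished locally.
    """
    _check_growth_data(tc)
    if method == "nonlinear":
        return _fit_logistic_nonlinear(tc)
    if method == "linearized":
        return _fit_logistic_linearized(tc)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# product


def fit_product_line(tc: TimeCourse) -> Tuple[float, float, Dict[str, float]]:
    """OLS of product on biomass: slope alpha, intercept K.

    Returns ``(alpha, k_int, diagnostics)`` where diagnostics carry the
    standard errors, R^2 and residual SSE of the line.
    """
    if len(tc) < 3:
        raise ValidationError("product-line fitting needs at least 3 points")
    x, p = tc.x, tc.p
    if np.ptp(x) == 0:
        raise SingularFitError("zero variance in biomass; product line is singular")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, p, rcond=None)
    alpha, k_int = float(coef[0]), float(coef[1])
    resid = p - A @ coef
    sse = float(resid @ resid)
    n = len(x)
    dof = n - 2
    s2 = sse / dof if dof > 0 else math.nan
    sxx = float(np.sum((x - x.mean()) ** 2))
    sst = float(np.sum((p - p.mean()) ** 2))
    diagnostics = {
        "alpha_se": math.sqrt(s2 / sxx) if dof > 0 else math.nan,
        "k_int_se": math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)) if dof > 0 else math.nan,
        "r_squared": 1.0 - sse / sst if sst > 0 else 1.0,
        "residual_sse": sse,
    }
    return alpha, k_int, diagnostics


def _central_differences(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """dy/dt at interior points, (y[i+1]-y[i-1])/(t[i+1]-t[i-1])."""
    return (y[2:] - y[:-2]) / (t[2:] - t[:-2])


def fit_luedeking_piret(tc: TimeCourse) -> LuedekingPiretFit:
    """Two-term product-formation fit dP/dt = alpha dX/dt + beta X.

    Rates come from central finite differences on interior points; the
    two-predictor regression has no intercept.  Gaden's class is assigned
    by a 2-standard-error rule: class I when beta is indistinguishable
    from zero but alpha is not, class III for the reverse, class II
    otherwise.
    """
    if len(tc) < 4:
        raise ValidationError(
            "Luedeking-Piret fitting needs at least 4 points (2 interior)"
        )
    t, x, p = tc.t, tc.x, tc.p
    dxdt = _central_differences(t, x)
    dpdt = _central_differences(t, p)
    x_int = x[1:-1]
    A = np.column_stack([dxdt, x_int])
    if np.linalg.matrix_rank(A) < 2:
        raise SingularFitError("dX/dt and X are collinear on the interior points")
    coef, *_ = np.linalg.lstsq(A, dpdt, rcond=None)
    resid = dpdt - A @ coef
    sse = float(resid @ resid)
    dof = len(dpdt) - 2
    s2 = sse / dof if dof > 0 else math.nan
    cov = s2 * np.linalg.inv(A.T @ A)
    alpha_hat, beta_hat = float(coef[0]), float(coef[1])
    alpha_se, beta_se = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))

    alpha_sig = abs(alpha_hat) > 2.0 * alpha_se
    beta_sig = abs(beta_hat) > 2.0 * beta_se
    if alpha_sig and not beta_sig:
        gaden = "I"
    elif beta_sig and not alpha_sig:
        gaden = "III"
    else:
        gaden = "II"
    return LuedekingPiretFit(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        alpha_se=alpha_se,
        beta_se=beta_se,
        gaden_class=gaden,
        residual_sse=sse,
    )


# ---------------------------------------------------------------------------
# substrate


def fit_substrate(
    tc: TimeCourse,
    growth_params: KineticParameters,
    product_params: Tuple[float, float],
) -> Tuple[float, float, Dict[str, float]]:
    """Estimate (Y_x/s, Ke) from an observed substrate series.

    Growth parameters (x0, xmax, mu_max) and the product line
    (alpha, k_int) are held fixed; Y_p/s is tied to alpha * Y_x/s so the
    balance has exactly two free parameters.  Nonlinear least squares on
    the closed-form S(t).
    """
    if tc.s is None:
        raise ValidationError(
            "substrate not observed: the time course has no substrate series"
        )
    mask = ~np.isnan(tc.s)
    if mask.sum() < 3:
        raise ValidationError("substrate fitting needs at least 3 observed points")
    t, s = tc.t[mask], tc.s[mask]
    alpha, k_int = product_params
    # the balance is anchored at t = 0; use the known initial substrate
    # when available, otherwise fall back to the first observation
    if not math.isnan(growth_params.s0):
        s0 = growth_params.s0
    elif t[0] == 0:
        s0 = float(s[0])
    else:
        raise ValidationError(
            "initial substrate unknown: set s0 on the growth parameters or "
            "include a t = 0 observation"
        )

    def make_params(y_xs: float, ke: float) -> KineticParameters:
        return KineticParameters(
            x0=growth_params.x0,
            xmax=growth_params.xmax,
            mu_max=growth_params.mu_max,
            y_xs=y_xs,
            alpha=alpha,
            k_int=k_int,
            y_ps=alpha * y_xs if alpha > 0 else math.nan,
            ke=ke,
            s0=s0,
        )

    def residuals(theta):
        y_xs, ke = theta
        pred = substrate_at(t, make_params(y_xs, ke), warn_exhaustion=False)
        return np.atleast_1d(pred) - s

    res = optimize.least_squares(
        residuals,
        x0=[1.0, 1e-3],
        bounds=([1e-8, 0.0], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise FitError(f"substrate fit did not converge: {res.message}")
    y_xs, ke = (float(v) for v in res.x)
    diagnostics = {
        "residual_sse": float(res.fun @ res.fun),
        "s0": s0,
        "y_ps_tied": alpha * y_xs,
        "n_points": int(mask.sum()),
    }
    return y_xs, ke, diagnostics
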