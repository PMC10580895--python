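"""Seeded synthetic-data generators.

Produce time courses and DOE response tables with exactly the statistical
structure the estimators in :mod:`fermkin.fitting` and
:mod:`fermkin.doe` assume, so every fitting stage can be exercised and
calibrated without laboratory data:

* :func:`simulate_time_course` — closed-form logistic biomass, a product
  series anchored at the initial product concentration via the
  growth-associated line, and the analytic substrate balance, with
  multiplicative lognormal noise (concentrations are strictly positive;
  default 5% relative scale);
* :func:`simulate_design` — a quadratic surface over coded factors plus
  additive Gaussian replicate error (default sigma 0.852 g/l, the
  residual scale of the reference fermentation design).

All randomness flows through one ``numpy.random.default_rng(seed)``
generator per call; identical seeds give byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .doe import DesignTable, Factor, Term, TermSpec
from .errors import SubstrateExhaustionWarning, ValidationError
from .kinetics import KineticParameters, TimeCourse, biomass_at, substrate_at

__all__ = ["NoiseSpec", "simulate_time_course", "simulate_design", "DEFAULT_DAY_GRID_H"]

# the reference study sampled at 3, 5, 7, 9, 11 and 13 days
DEFAULT_DAY_GRID_H = tuple(24.0 * d for d in (3, 5, 7, 9, 11, 13))


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise description for the generators.

    ``multiplicative_lognormal``: each value v becomes
    v * exp(scale*z - scale^2/2) with z ~ N(0,1), so E[obs] = v and
    ``scale`` is approximately the relative SD.  ``additive_gaussian``:
    v + N(0, scale) with ``scale`` in g/l, clipped at zero.
    """

    kind: str = "multiplicative_lognormal"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValidationError("noise scale must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0:
            return values.copy()
        if self.kind == "multiplicative_lognormal":
            z = rng.standard_normal(values.shape)
            out = values * np.exp(self.scale * z - 0.5 * self.scale**2)
        else:
            out = values + rng.normal(0.0, self.scale, size=values.shape)
        return np.clip(out, 0.0, None)


def simulate_time_course(
    params: KineticParameters,
    times: Sequence[float] = DEFAULT_DAY_GRID_H,
    noise: Optional[NoiseSpec] = None,
) -> TimeCourse:
    """Forward-simulate one batch run on the given hour grid.

    Biomass follows the closed-form logistic curve, product the
    growth-associated line anchored at p0
    (P(t) = p0 + alpha*(X(t) - x0)), and substrate the analytic balance
    when y_xs/s0 are set (re-issuing any exhaustion warning as a
    truncation warning, with negative predictions clipped to 0).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be non-empty and strictly increasing")
    x = np.atleast_1d(biomass_at(t, params))
    p = params.p0 + params.alpha * (x - params.x0)
    s = None
    if not np.isnan(params.y_xs) and not np.isnan(params.s0):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", SubstrateExhaustionWarning)
            s = np.atleast_1d(substrate_at(t, params))
        for w in caught:
            if isinstance(w.message, SubstrateExhaustionWarning):
                warnings.warn(
                    SubstrateExhaustionWarning(
                        "simulated substrate series truncated at zero: " + str(w.message),
                        exhaustion_time=w.message.exhaustion_time,
                    ),
                    stacklevel=2,
                )
        s = np.clip(s, 0.0, None)

    if noise is not None and noise.scale > 0:
        rng = np.random.default_rng(noise.seed)
        x = noise.apply(x, rng)
        p = noise.apply(p, rng)
        if s is not None:
            s = noise.apply(s, rng)
    return TimeCourse(t=t, x=x, p=p, s=s)


def simulate_design(
    factors: Sequence[Factor],
    coefficients: Dict[Union[str, Term], float],
    sigma: float = 0.852,
    seed: int = 0,
    layout: Optional[np.ndarray] = None,
    n_center_replicates: int = 0,
) -> DesignTable:
    """Simulate a DOE response table over a coded quadratic surface.

    ``coefficients`` maps terms (Term objects or strings like "X2*X4")
    to coded-unit coefficients.  ``layout`` gives natural-unit levels,
    one row per run; when omitted, the layout of the packaged reference
    design (22 three-level runs) is used, optionally extended with
    ``n_center_replicates`` extra all-center runs.  The response is the
    surface value plus N(0, sigma) noise, truncated just above zero so
    the table remains valid.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    factors = tuple(factors)
    terms = TermSpec(
        [Term.parse(t) if isinstance(t, str) else t for t in coefficients]
    )
    coef = np.array([coefficients[k] for k in coefficients], dtype=float)

    if layout is None:
        from .datasets import load_reference_design

        ref = load_reference_design()
        if tuple(f.name for f in ref.factors) != tuple(f.name for f in factors):
            raise ValidationError(
                "default layout requires the reference factor set; pass an "
                "explicit layout for other factors"
            )
        layout = ref.levels
    layout = np.asarray(layout, dtype=float)
    if n_center_replicates > 0:
        centers = np.array([[f.center for f in factors]] * n_center_replicates)
        layout = np.vstack([layout, centers])

    n = layout.shape[0]
    coded = {f.name: f.code(layout[:, j]) for j, f in enumerate(factors)}
    X = np.column_stack([t.column(coded, n) for t in terms])
    rng = np.random.default_rng(seed)
    y = X @ coef
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=n)
    y = np.maximum(y, 1e-6)  # DesignTable requires positive responses
    return DesignTable(
        run_ids=np.arange(1, n + 1),
        levels=layout,
        response=y,
        factors=factors,
    )
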