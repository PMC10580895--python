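"""Coded-factor quadratic response surfaces for process optimization.

Implements the response-surface-methodology workflow for a multi-factor
fermentation design: code natural factor levels onto [-1, +1], build a
model matrix over intercept / linear / two-way interaction / quadratic
terms, fit by ordinary least squares, summarize each term (estimate,
standard error, 95% CI, t ratio) and each effect (Type-III drop-one sum
of squares, F ratio), transform p-values to LogWorth (-log10 p) with an
optional Benjamini-Hochberg FDR adjustment, select terms by backward
elimination, and locate the predicted optimum by grid search over the
coded cube.

The OLS arithmetic is written out against the closed-form normal
equations so that it can be cross-checked independently (e.g. against
statsmodels) in the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, FitError, SingularFitError, ValidationError, RangeWarning

__all__ = [
    "Factor",
    "Term",
    "TermSpec",
    "DesignTable",
    "RSFit",
    "code_levels",
    "build_design_matrix",
    "fit_ols",
    "logworth",
    "fdr_adjust",
    "select_terms",
    "optimize_surface",
]


@dataclass(frozen=True)
class Factor:
    """One design factor with its natural-unit range.

    Coding maps low -> -1, center -> 0, high -> +1.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValidationError(
                f"factor {self.name!r}: high ({self.high}) must exceed low ({self.low})"
            )

    @property
    def center(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    def code(self, x):
        return (np.asarray(x, dtype=float) - self.center) / self.half_range

    def decode(self, c):
        return np.asarray(c, dtype=float) * self.half_range + self.center


def code_levels(x, factor: Factor):
    """Code natural levels to [-1, +1]; out-of-range values warn."""
    coded = factor.code(x)
    if np.any(np.abs(np.atleast_1d(coded)) > 1.0 + 1e-12):
        warnings.warn(
            RangeWarning(
                f"level(s) outside the design range [{factor.low}, {factor.high}] "
                f"of factor {factor.name!r}"
            ),
            stacklevel=2,
        )
    return float(coded) if np.ndim(x) == 0 else coded


@dataclass(frozen=True)
class Term:
    """One model term: intercept, linear, interaction or quadratic.

    ``factors`` holds 0, 1 or 2 factor names; interactions are stored in
    sorted order so X2*X4 and X4*X2 compare equal.
    """

    kind: str  # "intercept" | "linear" | "interaction" | "quadratic"
    factors: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = {"intercept": 0, "linear": 1, "interaction": 2, "quadratic": 1}
        if self.kind not in expected:
            raise ValidationError(f"unknown term kind {self.kind!r}")
        if len(self.factors) != expected[self.kind]:
            raise ValidationError(f"term kind {self.kind!r} takes {expected[self.kind]} factor(s)")
        if self.kind == "interaction":
            if self.factors[0] == self.factors[1]:
                raise ValidationError("self-interaction should be a quadratic term")
            object.__setattr__(self, "factors", tuple(sorted(self.factors)))

    @classmethod
    def parse(cls, text: str) -> "Term":
        """Parse "X1", "X2*X4", "X4^2" or "X4*X4" (the latter two equal)."""
        text = text.strip()
        if text.lower() in ("1", "intercept"):
            return cls("intercept")
        if "^" in text:
            base, power = text.split("^")
            if power.strip() != "2":
                raise ValidationError(f"only squared terms supported, got {text!r}")
            return cls("quadratic", (base.strip(),))
        if "*" in text:
            a, b = (s.strip() for s in text.split("*"))
            if a == b:
                return cls("quadratic", (a,))
            return cls("interaction", (a, b))
        return cls("linear", (text,))

    def __str__(self) -> str:
        if self.kind == "intercept":
            return "Intercept"
        if self.kind == "linear":
            return self.factors[0]
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return "*".join(self.factors)

    def column(self, coded: Dict[str, np.ndarray], n: int) -> np.ndarray:
        if self.kind == "intercept":
            return np.ones(n)
        cols = [coded[f] for f in self.factors]
        if self.kind == "linear":
            return cols[0]
        if self.kind == "quadratic":
            return cols[0] ** 2
        return cols[0] * cols[1]


class TermSpec:
    """Ordered, duplicate-free list of model terms."""

    def __init__(self, terms: Iterable[Union[Term, str]]):
        parsed: List[Term] = []
        for t in terms:
            term = Term.parse(t) if isinstance(t, str) else t
            if term in parsed:
                raise ValidationError(f"duplicate term {term}")
            parsed.append(term)
        self.terms: Tuple[Term, ...] = tuple(parsed)

    @classmethod
    def full_quadratic(cls, factors: Sequence[Factor]) -> "TermSpec":
        """Intercept + all linear, two-way interaction and quadratic terms."""
        names = [f.name for f in factors]
        terms: List[Term] = [Term("intercept")]
        terms += [Term("linear", (n,)) for n in names]
        terms += [Term("interaction", (a, b)) for a, b in itertools.combinations(names, 2)]
        terms += [Term("quadratic", (n,)) for n in names]
        return cls(terms)

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other) -> bool:
        return isinstance(other, TermSpec) and self.terms == other.terms

    def __repr__(self) -> str:
        return f"TermSpec([{', '.join(str(t) for t in self.terms)}])"

    def labels(self) -> List[str]:
        return [str(t) for t in self.terms]

    def without(self, term: Term) -> "TermSpec":
        return TermSpec([t for t in self.terms if t != term])


@dataclass(frozen=True)
class DesignTable:
    """DOE runs: run ids, natural-unit factor levels, and a response.

    ``levels`` is (n_runs, n_factors) in natural units, column order
    matching ``factors``. Run ids need not be contiguous.
    """

    run_ids: np.ndarray
    levels: np.ndarray
    response: np.ndarray
    factors: Tuple[Factor, ...]

    def __post_init__(self) -> None:
        run_ids = np.asarray(self.run_ids)
        levels = np.asarray(self.levels, dtype=float)
        response = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "run_ids", run_ids)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "factors", tuple(self.factors))
        n, k = levels.shape
        if len(run_ids) != n or len(response) != n:
            raise ValidationError("run ids, levels and response must align")
        if k != len(self.factors):
            raise ValidationError("level columns must match the factor list")
        if len(np.unique(run_ids)) != n:
            raise ValidationError("duplicate run ids")
        if np.any(response <= 0):
            raise ValidationError("responses must be > 0")
        for j, f in enumerate(self.factors):
            col = levels[:, j]
            if np.any(col < f.low - 1e-9) or np.any(col > f.high + 1e-9):
                warnings.warn(
                    RangeWarning(
                        f"factor {f.name!r} has levels outside [{f.low}, {f.high}]"
                    ),
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.run_ids)

    def coded(self) -> Dict[str, np.ndarray]:
        return {f.name: f.code(self.levels[:, j]) for j, f in enumerate(self.factors)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=[f.name for f in self.factors])
        df.insert(0, "run", self.run_ids)
        df["response"] = self.response
        return df


@dataclass(frozen=True)
class RSFit:
    """Fitted response surface.

    Term-level statistics are aligned with ``terms``; the effect ANOVA
    (Type-III drop-one sums of squares) covers every non-intercept term.
    """

    terms: TermSpec
    factors: Tuple[Factor, ...]
    params: np.ndarray
    bse: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    rmse: float
    r_squared: float
    f_model: float
    p_model: float
    df_resid: int
    n_obs: int
    fitted: np.ndarray
    residuals: np.ndarray
    anova: pd.DataFrame  # term, df, ss, f_ratio, p_value, logworth, fdr_logworth

    def term_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms.labels(),
                "estimate": self.params,
                "std_error": self.bse,
                "lower_95": self.ci_lower,
                "upper_95": self.ci_upper,
                "t_ratio": self.tvalues,
                "p_value": self.pvalues,
            }
        )

    def predict(self, coded: Dict[str, np.ndarray]) -> np.ndarray:
        n = len(next(iter(coded.values())))
        X = np.column_stack([t.column(coded, n) for t in self.terms])
        return X @ self.params


def build_design_matrix(
    dt: DesignTable, terms: TermSpec, factors: Optional[Sequence[Factor]] = None
) -> pd.DataFrame:
    """Model matrix over coded levels; one named column per term."""
    factors = tuple(factors) if factors is not None else dt.factors
    known = {f.name for f in factors}
    for term in terms:
        for name in term.factors:
            if name not in known:
                raise ValidationError(f"term {term} references unknown factor {name!r}")
    coded = {f.name: f.code(dt.levels[:, j]) for j, f in enumerate(dt.factors)}
    n = len(dt)
    data = {str(t): t.column(coded, n) for t in terms}
    return pd.DataFrame(data, index=dt.run_ids)


def _find_aliased(X: np.ndarray, labels: Sequence[str]) -> List[str]:
    """Columns that are linearly dependent on the columns before them."""
    aliased, kept = [], []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(labels[j])
    return aliased


def fit_ols(
    matrix: Union[pd.DataFrame, np.ndarray],
    y: np.ndarray,
    terms: Optional[TermSpec] = None,
    factors: Sequence[Factor] = (),
) -> RSFit:
    """Ordinary least squares with the full response-surface report.

    Standard errors use the unbiased residual variance SSE/(n-p); the
    whole-model F compares against the intercept-only model; per-effect
    Type-III sums of squares come from refitting with each term dropped.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [f"c{j}" for j in range(X.shape[1])]
    if terms is None:
        terms = TermSpec([Term.parse(lbl) for lbl in labels])
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValidationError(f"need at least {p + 1} runs to fit {p} terms, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError(
            "model matrix is rank deficient; aliased terms: "
            + ", ".join(_find_aliased(X, labels))
        )

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    df_resid = n - p
    mse = sse / df_resid
    rmse = math.sqrt(mse)
    bse = np.sqrt(np.diag(XtX_inv) * mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / np.where(bse > 0, bse, 1.0), np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tcrit = stats.t.ppf(0.975, df_resid)
    ci_lo = beta - tcrit * bse
    ci_hi = beta + tcrit * bse

    sst = float(np.sum((y - y.mean()) ** 2))
    has_intercept = any(t.kind == "intercept" for t in terms)
    ss_model = sst - sse if has_intercept else float(fitted @ fitted)
    df_model = p - 1 if has_intercept else p
    if df_model > 0 and mse > 0:
        f_model = (ss_model / df_model) / mse
        p_model = float(stats.f.sf(f_model, df_model, df_resid))
    else:
        f_model, p_model = math.nan, math.nan
    r_squared = 1.0 - sse / sst if sst > 0 else 1.0

    # Type-III (drop-one) effect sums of squares
    rows = []
    for j, term in enumerate(terms):
        if term.kind == "intercept":
            continue
        X_red = np.delete(X, j, axis=1)
        beta_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        resid_red = y - X_red @ beta_red
        ss_term = float(resid_red @ resid_red) - sse
        f_ratio = (ss_term / 1.0) / mse if mse > 0 else math.inf
        p_val = float(stats.f.sf(f_ratio, 1, df_resid)) if mse > 0 else 0.0
        rows.append((str(term), 1, ss_term, f_ratio, p_val))
    if rows:
        anova = pd.DataFrame(rows, columns=["term", "df", "ss", "f_ratio", "p_value"])
        # exact fits give p = 0; floor them so the log/FDR transforms stay finite
        p_safe = np.clip(anova["p_value"].to_numpy(), 1e-300, 1.0)
        anova["logworth"] = -np.log10(p_safe)
        anova["fdr_p"] = fdr_adjust(p_safe)
        anova["fdr_logworth"] = -np.log10(anova["fdr_p"])
    else:
        anova = pd.DataFrame(
            columns=["term", "df", "ss", "f_ratio", "p_value", "logworth", "fdr_p", "fdr_logworth"]
        )

    return RSFit(
        terms=terms,
        factors=tuple(factors),
        params=beta,
        bse=bse,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        tvalues=tvals,
        pvalues=pvals,
        rmse=rmse,
        r_squared=r_squared,
        f_model=float(f_model),
        p_model=p_model,
        df_resid=df_resid,
        n_obs=n,
        fitted=fitted,
        residuals=resid,
        anova=anova,
    )


def logworth(p: float) -> float:
    """-log10(p); the significance scale used in effect screening plots."""
    if not 0 < p <= 1:
        raise DomainError(f"p-value must lie in (0, 1], got {p}")
    return -math.log10(p)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def select_terms(
    dt: DesignTable,
    full_terms: TermSpec,
    alpha_stay: float = 0.05,
) -> TermSpec:
    """Backward elimination on term p-values.

    Iteratively drops the non-intercept term with the largest p-value
    until every remaining term has p <= ``alpha_stay`` (ties broken by
    term-list order).  If the full model is not estimable on the design
    (rank deficient or no residual degree of freedom), the start point
    falls back to intercept + main effects and a warning is issued.
    """
    y = dt.response
    terms = full_terms

    def estimable(ts: TermSpec) -> bool:
        X = build_design_matrix(dt, ts).to_numpy()
        return X.shape[0] > X.shape[1] and np.linalg.matrix_rank(X) == X.shape[1]

    if not estimable(terms):
        fallback = TermSpec(
            [t for t in full_terms if t.kind in ("intercept", "linear")]
        )
        warnings.warn(
            "full model not estimable on this design; starting backward "
            "elimination from intercept + main effects",
            stacklevel=2,
        )
        terms = fallback
        if not estimable(terms):
            raise FitError("even the main-effects model is not estimable")

    while True:
        fit = fit_ols(build_design_matrix(dt, terms), y, terms=terms, factors=dt.factors)
        candidates = [
            (j, t) for j, t in enumerate(terms) if t.kind != "intercept"
        ]
        if not candidates:
            break
        j_worst, t_worst = max(candidates, key=lambda jt: fit.pvalues[jt[0]])
        if fit.pvalues[j_worst] <= alpha_stay:
            break
        terms = terms.without(t_worst)
        if len(terms) == 0:
            break
    return terms


def optimize_surface(
    fit: RSFit,
    factors: Optional[Sequence[Factor]] = None,
    grid_points_per_factor: int = 11,
) -> Tuple[Dict[str, float], float]:
    """Grid-search maximum of the fitted surface over the coded cube.

    Evaluates the surface on a full factorial grid of
    ``grid_points_per_factor`` levels per factor spanning [-1, +1] and
    returns the natural-unit settings of the argmax and the predicted
    response.  Deterministic: ties resolve to the first grid point in
    row-major order.
    """
    factors = tuple(factors) if factors is not None else fit.factors
    if not factors:
        raise ValidationError("optimize_surface needs the factor definitions")
    axes = [np.linspace(-1.0, 1.0, grid_points_per_factor) for _ in factors]
    mesh = np.meshgrid(*axes, indexing="ij")
    coded = {f.name: m.ravel() for f, m in zip(factors, mesh)}
    pred = fit.predict(coded)
    i = int(np.argmax(pred))
    settings = {f.name: float(f.decode(coded[f.name][i])) for f in factors}
    return settings, float(pred[i])
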