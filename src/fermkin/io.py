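"""Delimited-text readers and writers for all package formats.

Dialect: comma-separated, UTF-8, "." decimal separator, mandatory header
row; tab-separated input is accepted on read.  Writers prepend comment
lines (``# key: value``) stamping the package version and, where
relevant, the RNG seed; readers skip ``#`` lines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .doe import DesignTable, Factor, TermSpec
from .errors import ValidationError
from .fitting import ErrorReport
from .kinetics import KineticParameters, TimeCourse

__all__ = [
    "RunConfig",
    "read_time_course",
    "write_time_course",
    "read_design_table",
    "write_design_table",
    "read_params",
    "write_params",
    "read_factor_config",
    "write_error_report",
]

PARAM_KEYS = ("x0", "xmax", "mu_max", "y_xs", "alpha", "k_int", "y_ps", "ke", "s0", "p0")

_TC_COLUMNS = {"time_h", "time_d", "biomass_g_l", "product_g_l", "substrate_g_l"}
_DESIGN_COLUMNS = ("run", "ph", "temperature_c", "oil_g", "agitation_rpm", "time_d", "response_g_l")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline invocation."""

    inputs: Dict[str, Path] = field(default_factory=dict)
    method: str = "nonlinear"
    fdr_method: str = "fdr_bh"
    alpha_stay: float = 0.05
    grid_points: int = 11
    seed: int = 0
    out_dir: Path = Path(".")
    verbosity: int = 0

    def validate(self) -> "RunConfig":
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise ValidationError(f"input {name!r} not found: {path}")
        if self.method not in ("linearized", "nonlinear"):
            raise ValidationError(f"unknown fit method {self.method!r}")
        if not 0 < self.alpha_stay <= 1:
            raise ValidationError("alpha_stay must lie in (0, 1]")
        return self


def _read_delimited(path) -> pd.DataFrame:
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValidationError(f"{path}: file is empty or not delimited text") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return df


def _header_lines(seed: Optional[int] = None, **extra) -> str:
    lines = [f"# fermkin: v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines += [f"# {k}: {v}" for k, v in extra.items()]
    return "\n".join(lines) + "\n"


def read_time_course(path: Union[str, Path]) -> TimeCourse:
    """Read a time course; ``time_d`` columns are converted to hours.

    Rows out of time order are sorted with a warning; negative values or
    unknown columns raise a :class:`ValidationError` naming the problem.
    """
    df = _read_delimited(path)
    unknown = set(df.columns) - _TC_COLUMNS
    if unknown:
        raise ValidationError(f"{path}: unknown columns {sorted(unknown)}")
    if "time_h" in df.columns:
        t = df["time_h"].to_numpy(float)
    elif "time_d" in df.columns:
        t = df["time_d"].to_numpy(float) * 24.0
    else:
        raise ValidationError(f"{path}: missing time column (time_h or time_d)")
    for col in ("biomass_g_l", "product_g_l"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
        bad = df.index[df[col] < 0].tolist()
        if bad:
            raise ValidationError(f"{path}: negative {col} in rows {bad}")
    order = np.argsort(t, kind="stable")
    if not np.array_equal(order, np.arange(len(t))):
        warnings.warn(f"{path}: rows were not time-ordered; sorted on read", stacklevel=2)
    if np.any(np.diff(t[order]) <= 0):
        raise ValidationError(f"{path}: duplicate or non-increasing times")
    s = df["substrate_g_l"].to_numpy(float)[order] if "substrate_g_l" in df.columns else None
    return TimeCourse(
        t=t[order],
        x=df["biomass_g_l"].to_numpy(float)[order],
        p=df["product_g_l"].to_numpy(float)[order],
        s=s,
    )


def write_time_course(tc: TimeCourse, path: Union[str, Path], seed: Optional[int] = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(seed=seed))
        tc.to_frame().to_csv(fh, index=False, float_format="%.12g")


def read_design_table(path: Union[str, Path], factors: Sequence[Factor]) -> DesignTable:
    """Read a DOE table with the fixed design schema.

    Column order: run, ph, temperature_c, oil_g, agitation_rpm, time_d,
    response_g_l; factor columns map positionally onto ``factors``.
    Duplicate run ids raise; out-of-range levels warn (inside
    DesignTable validation).
    """
    df = _read_delimited(path)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    level_cols = list(_DESIGN_COLUMNS[1:-1])
    if len(level_cols) != len(factors):
        raise ValidationError("factor list does not match the design schema")
    return DesignTable(
        run_ids=df["run"].to_numpy(),
        levels=df[level_cols].to_numpy(float),
        response=df["response_g_l"].to_numpy(float),
        factors=tuple(factors),
    )


def write_design_table(dt: DesignTable, path: Union[str, Path], seed: Optional[int] = None) -> None:
    path = Path(path)
    df = pd.DataFrame(dt.levels, columns=list(_DESIGN_COLUMNS[1:-1]))
    df.insert(0, "run", dt.run_ids)
    df["response_g_l"] = dt.response
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(seed=seed))
        df.to_csv(fh, index=False, float_format="%.12g")


def read_params(path: Union[str, Path]) -> KineticParameters:
    """Read a kinetic parameter set from flat key-value JSON."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    unknown = set(raw) - set(PARAM_KEYS)
    if unknown:
        raise ValidationError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return KineticParameters(**raw)


def write_params(params: KineticParameters, path: Union[str, Path]) -> None:
    data = {k: getattr(params, k) for k in PARAM_KEYS}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def read_factor_config(path: Union[str, Path]):
    """Read factor definitions and term lists from YAML or JSON.

    Returns ``(factors, term_specs)`` where ``term_specs`` maps variant
    names to :class:`TermSpec` objects (key ``initial`` holds the full
    starting model when present).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    factors = tuple(Factor(**f) for f in raw["factors"])
    specs: Dict[str, TermSpec] = {}
    for name, terms in raw.get("term_variants", {}).items():
        specs[name] = TermSpec(terms)
    if "initial_terms" in raw:
        specs["initial"] = TermSpec(raw["initial_terms"])
    return factors, specs


def write_error_report(
    reports: Dict[str, ErrorReport], path: Union[str, Path], json_path: Optional[Union[str, Path]] = None
) -> None:
    """Write per-series error tables plus a JSON summary block.

    The delimited table mirrors the published validation layout: one
    block of (time, experimental, calculated, error%) columns per
    series.
    """
    frames = []
    summary = {}
    for name, rep in reports.items():
        df = rep.to_frame().rename(
            columns={
                "experimental_g_l": f"{name}_experimental_g_l",
                "calculated_g_l": f"{name}_calculated_g_l",
                "error_percent": f"{name}_error_percent",
            }
        )
        frames.append(df.set_index("time_h"))
        summary[name] = {
            "signed_mean_percent": rep.signed_mean,
            "mean_absolute_percent": rep.mean_absolute,
        }
    merged = pd.concat(frames, axis=1).reset_index()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines())
        merged.to_csv(fh, index=False, float_format="%.12g")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
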