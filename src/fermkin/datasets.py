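"""Access to the packaged reference fixtures (see ``data/README.md``)."""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import pandas as pd

from .doe import DesignTable, Factor, TermSpec
from .kinetics import KineticParameters, TimeCourse

__all__ = [
    "reference_factors",
    "term_variants",
    "initial_terms",
    "load_reference_params",
    "load_reference_design",
    "load_reference_validation",
    "load_surface_activity",
]


def _data_path(name: str):
    return resources.files("fermkin.data").joinpath(name)


def reference_factors() -> Tuple[Factor, ...]:
    """The five design factors of the reference optimization."""
    factors, _ = _factor_config()
    return factors


def term_variants() -> Dict[str, TermSpec]:
    """Selected-term readings: ``text_variant`` and ``table_variant``."""
    _, specs = _factor_config()
    return {k: v for k, v in specs.items() if k != "initial"}


def initial_terms() -> TermSpec:
    """The full 21-term initial model of the reference design."""
    _, specs = _factor_config()
    return specs["initial"]


def _factor_config():
    from .io import read_factor_config

    with resources.as_file(_data_path("factors.yaml")) as path:
        return read_factor_config(path)


def load_reference_params() -> KineticParameters:
    """Kinetic parameter set of the reference fermentation."""
    from .io import read_params

    with resources.as_file(_data_path("reference_kinetics.json")) as path:
        return read_params(path)


def load_reference_design() -> DesignTable:
    """The 22 printed runs of the reference optimization design."""
    from .io import read_design_table

    with resources.as_file(_data_path("reference_design.csv")) as path:
        return read_design_table(path, reference_factors())


def load_reference_validation() -> Tuple[TimeCourse, TimeCourse, pd.DataFrame]:
    """Experimental and model-calculated series of the validation table.

    Returns ``(experimental, calculated, frame)`` where ``frame`` also
    carries the published per-row error columns (as printed, including
    the known 1.56-vs-1.50 rounding discrepancy at 168 h).
    """
    with resources.as_file(_data_path("reference_validation.csv")) as path:
        df = pd.read_csv(path)
    exp = TimeCourse(
        t=df["time_h"].to_numpy(float),
        x=df["biomass_experimental_g_l"].to_numpy(float),
        p=df["product_experimental_g_l"].to_numpy(float),
    )
    calc = TimeCourse(
        t=df["time_h"].to_numpy(float),
        x=df["biomass_calculated_g_l"].to_numpy(float),
        p=df["product_calculated_g_l"].to_numpy(float),
    )
    return exp, calc, df


def load_surface_activity() -> pd.DataFrame:
    """Replicate summaries of the surface-activity assays."""
    with resources.as_file(_data_path("surface_activity.csv")) as path:
        return pd.read_csv(path)
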