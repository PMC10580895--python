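"""Surface-activity arithmetic and replicate summaries.

These are the small descriptive computations that accompany a
biosurfactant screening campaign: the 24-hour emulsification index,
fold improvement of a yield over a reference, and mean +/- SD summaries
of replicate measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .utils import round_half_up

__all__ = ["ReplicateSummary", "emulsification_index", "fold_change", "summarize_replicates"]


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    n: int


def emulsification_index(emulsion_height: float, total_height: float) -> float:
    """E24: emulsion layer height as a percentage of total liquid height."""
    if total_height <= 0:
        raise DomainError("total height must be > 0")
    if emulsion_height < 0 or emulsion_height > total_height:
        raise DomainError(
            "emulsion height must lie between 0 and the total height "
            f"(got {emulsion_height} of {total_height})"
        )
    return emulsion_height / total_height * 100.0


def fold_change(value: float, reference: float, decimals: int = 2) -> float:
    """value / reference, rounded half-up to ``decimals`` places."""
    if reference <= 0:
        raise DomainError("reference must be > 0")
    return round_half_up(value / reference, decimals)


def summarize_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Arithmetic mean and sample (n-1) standard deviation; sd = 0 for n = 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("need at least one measurement")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return ReplicateSummary(mean=float(np.mean(arr)), sd=sd, n=int(arr.size))
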