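"""Competition-assay fitness and growth-curve (AUC) computations.

Relative fitness follows the serial-transfer competition convention of
long-term evolution experiments: two strains are mixed, propagated with a
1:100 transfer into fresh medium every 24 h, and plated at the start and end.
The relative fitness of A versus B is the ratio of the natural logs of each
competitor's *realized growth* — its net fold-expansion over the whole
competition, counting the regrowth after each transfer:

    growth_X = final_density_X * dilution**(days - 1) / initial_density_X
    w        = ln(growth_A) / ln(growth_B)

so ``w = 1`` is neutrality and ``w > 1`` means A outgrew B.

Plate-reader growth curves are summarised by the trapezoidal area under the
OD600 curve (AUC) over the recorded window; growth of a strain relative to a
reference is the ratio of their AUCs, and the no-epistasis expectation for a
multi-mutant is the product of the single-mutant relative growths (the same
multiplicative null used for competition fitness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CompetitionRecord",
    "GrowthCurve",
    "relative_fitness",
    "realized_growth",
    "auc",
    "relative_growth",
    "expected_growth",
]


@dataclass(frozen=True)
class CompetitionRecord:
    """Initial/final plate densities (CFU/mL) of two competitors.

    ``dilution`` is the fold-transfer into fresh medium between days (default
    1:100); densities are measured at the start of day 1 and the end of the
    final day, so realized growth multiplies the final density by
    ``dilution**(days-1)`` to account for the intermediate transfers.
    """

    initial_density_A: float
    final_density_A: float
    initial_density_B: float
    final_density_B: float
    days: int = 3
    dilution: float = 100.0

    def __post_init__(self) -> None:
        for name in ("initial_density_A", "final_density_A", "initial_density_B", "final_density_B"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not self.dilution > 1:
            raise ValueError("dilution must be > 1 (fold-transfer per day)")


def realized_growth(initial: float, final: float, days: int, dilution: float) -> float:
    """Net fold-expansion of one competitor over the competition."""
    return final * dilution ** (days - 1) / initial


def relative_fitness(rec: CompetitionRecord) -> float:
    """Relative fitness w = ln(realized growth A) / ln(realized growth B).

    Antisymmetric under competitor exchange (w -> 1/w).  Raises if either
    competitor's realized growth is <= 1, where the log ratio is undefined or
    degenerate (a competitor that failed to net-expand).
    """
    g_a = realized_growth(rec.initial_density_A, rec.final_density_A, rec.days, rec.dilution)
    g_b = realized_growth(rec.initial_density_B, rec.final_density_B, rec.days, rec.dilution)
    if g_b <= 1:
        raise ValueError(
            f"competitor B realized growth {g_b:.4g} <= 1; relative fitness undefined"
        )
    if g_a <= 1:
        raise ValueError(
            f"competitor A realized growth {g_a:.4g} <= 1; relative fitness undefined"
        )
    return math.log(g_a) / math.log(g_b)


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series (times in hours, strictly increasing)."""

    times: tuple[float, ...]
    od_values: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od_values, dtype=float)
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "od_values", tuple(od))
        if t.size != od.size:
            raise ValueError("times and od_values differ in length")
        if t.size < 2:
            raise ValueError("a growth curve needs at least 2 timepoints")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD values must be non-negative")


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the OD curve (OD·hours) over the recorded window."""
    return float(np.trapezoid(curve.od_values, curve.times))


def relative_growth(auc_strain: float, auc_reference: float) -> float:
    """AUC of a strain divided by the AUC of the reference (ancestor)."""
    if not auc_reference > 0:
        raise ValueError("reference AUC must be positive")
    return auc_strain / auc_reference


def expected_growth(singles: Sequence[float]) -> float:
    """Multiplicative no-epistasis expectation: product of single-mutant
    relative growths.  Observed-vs-expected comparisons reuse the same
    propagated-SD t-test as fitness epistasis (see :mod:`epiland.epistasis`)."""
    singles = list(singles)
    if not singles:
        raise ValueError("expected_growth requires at least one single-mutant ratio")
    return float(np.prod(singles))
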