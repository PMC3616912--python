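"""Phenotype-microarray (Biolog-style) differential-respiration screen.

A phenotype microarray reports respiration in each well as a kinetic curve of
tetrazolium dye reduction.  Per-environment activity is summarised by the
average height ``h`` of the kinetic response curve (time-weighted mean
signal).  Two strains are called differential in an environment when the
absolute difference of their mean heights exceeds ``k`` standard deviations
of the replicate heights — conjunctively for *both* strains by default
(``|mean_A - mean_B| > k·sd_A`` and ``> k·sd_B``), the most conservative
reading; the multiplier ``k`` (default 3) and the conjunctive/disjunctive
choice are configurable.  A differential call is a *gain* of function for the
first (evolved) strain when its mean height is the larger, otherwise a *loss*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["KineticCurve", "ScreenCall", "curve_height", "differential_call", "screen_summary"]


@dataclass(frozen=True)
class KineticCurve:
    """One well's respiration signal over time (arbitrary dye-reduction units)."""

    times: tuple[float, ...]
    signal: tuple[float, ...]
    strain: str = ""
    environment: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "signal", tuple(s))
        if t.size != s.size:
            raise ValueError("times and signal differ in length")
        if t.size < 2:
            raise ValueError("a kinetic curve needs at least 2 timepoints")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("signal must be non-negative")


@dataclass(frozen=True)
class ScreenCall:
    """Differential-respiration verdict for one environment.

    ``verdict`` is "gain" iff the call is differential and the evolved strain
    (A) has the larger mean height; "loss" iff differential with A lower;
    otherwise "none".  ``degenerate`` flags calls where a zero replicate SD
    collapsed the threshold so any nonzero difference would trigger.
    """

    environment: str
    h_A: float
    h_B: float
    sd_A: float
    sd_B: float
    verdict: str
    degenerate: bool = False

    @property
    def differential(self) -> bool:
        return self.verdict != "none"


def curve_height(curve: KineticCurve) -> float:
    """Average height h of a kinetic curve: trapezoidal integral / window length."""
    t = np.asarray(curve.times)
    s = np.asarray(curve.signal)
    return float(np.trapezoid(s, t) / (t[-1] - t[0]))


def differential_call(
    h_reps_A: Sequence[float],
    h_reps_B: Sequence[float],
    environment: str = "",
    sd_multiplier: float = 3.0,
    rule: str = "conjunctive",
) -> ScreenCall:
    """Call differential respiration between strain A (evolved) and B (ancestor).

    ``rule="conjunctive"`` requires the mean difference to exceed
    ``sd_multiplier`` times the replicate SD of *each* strain;
    ``"disjunctive"`` requires it for either strain.  Raising the multiplier
    monotonically shrinks the differential set.
    """
    a = np.asarray(list(h_reps_A), dtype=float)
    b = np.asarray(list(h_reps_B), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each strain needs at least one replicate height")
    if rule not in ("conjunctive", "disjunctive"):
        raise ValueError(f"unknown rule {rule!r}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1)) if a.size > 1 else 0.0
    sd_b = float(b.std(ddof=1)) if b.size > 1 else 0.0
    diff = abs(mean_a - mean_b)
    exceeds = [diff > sd_multiplier * sd_a, diff > sd_multiplier * sd_b]
    differential = all(exceeds) if rule == "conjunctive" else any(exceeds)
    degenerate = differential and diff > 0 and (sd_a == 0.0 or sd_b == 0.0)
    if differential and diff > 0:
        verdict = "gain" if mean_a > mean_b else "loss"
    else:
        verdict = "none"
    return ScreenCall(
        environment=environment,
        h_A=mean_a,
        h_B=mean_b,
        sd_A=sd_a,
        sd_B=sd_b,
        verdict=verdict,
        degenerate=degenerate,
    )


def screen_summary(calls: Iterable[ScreenCall]) -> dict:
    """Tally a screen: totals and per-category environment lists."""
    gains, losses = [], []
    total = 0
    for call in calls:
        total += 1
        if call.verdict == "gain":
            gains.append(call.environment)
        elif call.verdict == "loss":
            losses.append(call.environment)
    return {
        "n_environments": total,
        "differential": len(gains) + len(losses),
        "gains": len(gains),
        "losses": len(losses),
        "gain_environments": gains,
        "loss_environments": losses,
    }


def screen_from_table(
    df: pd.DataFrame,
    strain_evolved: str,
    strain_ancestor: str,
    sd_multiplier: float = 3.0,
    rule: str = "conjunctive",
) -> list[ScreenCall]:
    """Run the screen on a long table (strain,environment,replicate,time_h,signal)."""
    required = {"strain", "environment", "replicate", "time_h", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table is missing columns {sorted(missing)}")
    calls = []
    for env, env_df in df.groupby("environment", sort=True):
        heights: dict[str, list[float]] = {strain_evolved: [], strain_ancestor: []}
        for (strain, _rep), rep_df in env_df.groupby(["strain", "replicate"], sort=True):
            if strain not in heights:
                continue
            rep_df = rep_df.sort_values("time_h")
            curve = KineticCurve(
                tuple(rep_df["time_h"]), tuple(rep_df["signal"]), strain=str(strain),
                environment=str(env),
            )
            heights[strain].append(curve_height(curve))
        calls.append(
            differential_call(
                heights[strain_evolved],
                heights[strain_ancestor],
                environment=str(env),
                sd_multiplier=sd_multiplier,
                rule=rule,
            )
        )
    return calls
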