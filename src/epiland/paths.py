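"""Mutational-path accessibility, per-step effects, and fitness peaks.

The genotype space over L loci is an L-dimensional hypercube whose directed
edges add one mutation at a time.  An ordering of the L mutations defines a
path of L steps from the ancestor to the full mutant; there are L! such
orderings (120 for L = 5).  A path is *selectively accessible* when every
step increases fitness, so that natural selection could traverse it one
beneficial substitution at a time.  Two accessibility modes are provided:

* ``"mean"`` (default): the mean fitness must strictly increase at every
  step; ties count as inaccessible.
* ``"significant"``: every step must be *significantly* beneficial at level
  alpha under the per-edge t-test (optionally corrected over all edges).

Per-edge statistics mirror the epistasis machinery: delta_w is the difference
of genotype means, its SD combines the two replicate SDs in quadrature,
t = delta_w / sd_delta with df = min(n_from, n_to) - 1, and edges are
classified beneficial/deleterious/neutral at alpha after the chosen
multiple-comparison correction (Bonferroni over the L * 2^(L-1) edges by
default).  Peaks are genotypes whose mean fitness is not exceeded by any
Hamming-distance-1 neighbour.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import LandscapeSummary, LocusSet, MutationSet

__all__ = [
    "MutationalPath",
    "enumerate_paths",
    "is_accessible",
    "count_accessible",
    "step_effects",
    "peaks",
    "paths_report",
    "to_dot",
]


@dataclass(frozen=True)
class MutationalPath:
    """One ordering of the loci and its genotype chain (length L+1)."""

    ordering: tuple[str, ...]
    chain: tuple[MutationSet, ...]

    def __post_init__(self) -> None:
        for k, g in enumerate(self.chain):
            if g.size != k:
                raise ValueError("chain element k must carry exactly k mutations")


def enumerate_paths(loci: LocusSet) -> list[MutationalPath]:
    """All L! orderings of the loci, lexicographic in locus (fixation) order."""
    out = []
    for ordering in itertools.permutations(loci.loci):
        chain = [loci.ancestor()]
        for locus in ordering:
            chain.append(chain[-1].add(locus))
        out.append(MutationalPath(tuple(ordering), tuple(chain)))
    return out


def _edge_stats(
    landscape: LandscapeSummary, env: str, g_from: MutationSet, g_to: MutationSet
) -> tuple[float, float, float, int, float]:
    """(delta_w, sd_delta, t, df, p) for one directed edge."""
    m_from, sd_from, n_from = landscape.cell(env, g_from)
    m_to, sd_to, n_to = landscape.cell(env, g_to)
    delta = m_to - m_from
    sd_delta = math.hypot(sd_from, sd_to)
    df = min(n_from, n_to) - 1
    if sd_delta > 0 and df >= 1:
        t = delta / sd_delta
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        t, p = float("nan"), float("nan")
    return delta, sd_delta, t, df, float(p)


def step_effects(
    landscape: LandscapeSummary,
    env: str,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """All L*2^(L-1) directed single-mutation edges with tests and verdicts.

    Columns: from, to, locus_added, delta_w, sd_delta, t, df, p, p_adj,
    classification (beneficial/deleterious/neutral at alpha after correction;
    "none" disables correction).
    """
    if not landscape.is_complete(env):
        raise ValueError(f"landscape for {env!r} is incomplete; step effects need all 2^L genotypes")
    loci = landscape.loci
    rows = []
    for g in loci.all_genotypes():
        for locus in loci.loci:
            if locus in g:
                continue
            g_to = g.add(locus)
            delta, sd_delta, t, df, p = _edge_stats(landscape, env, g, g_to)
            rows.append(
                {
                    "environment": env,
                    "from": g.label,
                    "to": g_to.label,
                    "locus_added": locus,
                    "delta_w": delta,
                    "sd_delta": sd_delta,
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    m = len(table)
    if correction == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * m, 1.0)
    elif correction == "none":
        table["p_adj"] = table["p"]
    else:
        from statsmodels.stats.multitest import multipletests

        if correction != "bh":
            raise ValueError(f"unknown correction {correction!r}")
        finite = table["p"].notna()
        adj = np.full(m, np.nan)
        adj[finite.to_numpy()] = multipletests(table.loc[finite, "p"], method="fdr_bh")[1]
        table["p_adj"] = adj
    sig = table["p_adj"] < alpha
    table["classification"] = np.where(
        sig & (table["delta_w"] > 0),
        "beneficial",
        np.where(sig & (table["delta_w"] < 0), "deleterious", "neutral"),
    )
    return table


def is_accessible(
    path: MutationalPath,
    landscape: LandscapeSummary,
    env: str,
    mode: str = "mean",
    alpha: float = 0.05,
) -> bool:
    """Whether every step of the path increases fitness (see module docstring).

    ``mode="significant"`` uses per-step uncorrected t-tests at ``alpha``; for
    the corrected analysis combine :func:`step_effects` with
    :func:`paths_report`.
    """
    if mode not in ("mean", "significant"):
        raise ValueError(f"unknown accessibility mode {mode!r}")
    for g_from, g_to in zip(path.chain, path.chain[1:]):
        delta, sd_delta, t, df, p = _edge_stats(landscape, env, g_from, g_to)
        if mode == "mean":
            if not delta > 0:
                return False
        else:
            if not (delta > 0 and np.isfinite(p) and p < alpha):
                return False
    return True


def count_accessible(
    landscape: LandscapeSummary, env: str, mode: str = "mean", alpha: float = 0.05
) -> int:
    """Number of the L! orderings that are selectively accessible."""
    if not landscape.is_complete(env):
        raise ValueError(f"landscape for {env!r} is incomplete")
    paths = enumerate_paths(landscape.loci)
    return sum(is_accessible(p, landscape, env, mode, alpha) for p in paths)


def paths_report(
    landscape: LandscapeSummary, env: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-ordering accessibility verdicts and the first blocking step.

    Columns: environment, ordering, accessible_mean, accessible_significant,
    first_blocking_step (1-based index of the first non-increasing step under
    the mean criterion; empty if accessible).
    """
    rows = []
    for path in enumerate_paths(landscape.loci):
        first_block = ""
        acc_mean = True
        acc_sig = True
        for k, (g_from, g_to) in enumerate(zip(path.chain, path.chain[1:]), start=1):
            delta, _, _, _, p = _edge_stats(landscape, env, g_from, g_to)
            if acc_mean and not delta > 0:
                acc_mean = False
                first_block = str(k)
            if not (delta > 0 and np.isfinite(p) and p < alpha):
                acc_sig = False
        rows.append(
            {
                "environment": env,
                "ordering": "".join(path.ordering),
                "accessible_mean": acc_mean,
                "accessible_significant": acc_sig,
                "first_blocking_step": first_block,
            }
        )
    return pd.DataFrame(rows)


def peaks(landscape: LandscapeSummary, env: str) -> dict:
    """Local and global fitness maxima of the landscape in one environment.

    A local maximum has mean fitness >= every Hamming-1 neighbour (both
    adding and removing a mutation); the global maximum is the argmax of the
    mean, with ties reported as sets of genotype labels.
    """
    if not landscape.is_complete(env):
        raise ValueError(f"landscape for {env!r} is incomplete")
    loci = landscape.loci
    local = []
    best = -math.inf
    global_set: list[str] = []
    for g in loci.all_genotypes():
        w = landscape.w_mean(env, g)
        neighbours = [MutationSet(g.mask ^ (1 << i), loci) for i in range(loci.size)]
        if all(w >= landscape.w_mean(env, nb) for nb in neighbours):
            local.append(g.label)
        if w > best + 1e-15:
            best = w
            global_set = [g.label]
        elif abs(w - best) <= 1e-15:
            global_set.append(g.label)
    return {"local_maxima": local, "global_maximum": global_set}


def to_dot(landscape: LandscapeSummary, env: str, alpha: float = 0.05,
           correction: str = "bonferroni") -> str:
    """Graphviz DOT rendering of the hypercube with edge classifications."""
    edges = step_effects(landscape, env, alpha=alpha, correction=correction)
    styles = {"beneficial": "solid", "deleterious": "dashed", "neutral": "dotted"}
    lines = [f'digraph landscape {{', f'  label="{env}";']
    for g in landscape.loci.all_genotypes():
        lines.append(f'  "{g.label}" [label="{g.label}\\nw={landscape.w_mean(env, g):.3f}"];')
    for _, row in edges.iterrows():
        style = styles[row["classification"]]
        lines.append(f'  "{row["from"]}" -> "{row["to"]}" [style={style}];')
    lines.append("}")
    return "\n".join(lines)
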