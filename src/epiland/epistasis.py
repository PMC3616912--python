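"""Epistasis against the multiplicative null: decomposition, errors, tests.

The null model of no interaction says the relative fitness of a combination
of mutations is the product of the single-mutant fitnesses,

    w_exp(g) = prod_i w_i          for the loci i present in g,

and *absolute epistasis* is the deviation of the observed genotype fitness
from that expectation,

    eps(g) = w_obs(g) - w_exp(g),

with the sign carrying meaning (positive = synergistic for beneficial
mutations, negative = antagonistic).  Uncertainty is propagated through the
product: the relative errors of the singles combine (in quadrature by
default, root-sum-of-squares; optionally as a plain sum) to give sd_exp, and
the uncertainty of eps combines sd_obs and sd_exp the same way.  Significance
uses t = eps / sd_eps with df = n_reps - 1.

*Net higher-order epistasis* isolates interactions among three or more
mutations that are not explained by their constituent lower-order
interactions.  It is defined recursively (inclusion-exclusion): the net
interaction of a pair is its absolute epistasis; for |g| >= 3,

    eps_HO(g) = eps(g) - sum_{B subset g, 2 <= |B| < |g|} eps_net(B),

which makes the decomposition exact and order-independent — any genotype's
observed fitness is its multiplicative expectation plus the sum of the net
interaction terms of all its subsets.

Landscape-level summaries: mean epistasis across multi-mutation genotypes
(one-sample t-test), the diminishing-returns correlation between epistasis
and expected fitness with a standard-major-axis (model II) line, and
focal-mutation stratified analyses (group t-test, ANCOVA drop-term F-tests,
per-stratum correlations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import LandscapeSummary, MutationSet, subsets

__all__ = [
    "expected_fitness",
    "absolute_epistasis",
    "epistasis_sd",
    "epistasis_test",
    "net_higher_order",
    "epistasis_table",
    "mean_epistasis",
    "diminishing_returns_fit",
    "focal_mutation_analysis",
    "MeanEpistasis",
    "DiminishingReturnsFit",
    "FocalMutationReport",
]


def _combine(parts: Sequence[float], method: str) -> float:
    if method == "quadrature":
        return math.sqrt(sum(p * p for p in parts))
    if method == "linear":
        return sum(abs(p) for p in parts)
    raise ValueError(f"unknown error-propagation method {method!r}")


def expected_fitness(
    singles: Mapping[str, tuple[float, float]], method: str = "quadrature"
) -> tuple[float, float]:
    """Multiplicative-null expected fitness and its propagated SD.

    ``singles`` maps each required locus to its single-mutant (w_mean, w_sd).
    sd_exp = w_exp * combine(sd_i / w_i) where combine is root-sum-of-squares
    ("quadrature", default) or a plain sum of relative errors ("linear").
    """
    if not singles:
        raise ValueError("no single-mutant fitnesses supplied")
    w_exp = 1.0
    rel_errors = []
    for locus, (mean, sd) in singles.items():
        if not mean > 0:
            raise ValueError(f"single-mutant fitness for locus {locus!r} must be positive")
        if sd < 0:
            raise ValueError(f"negative SD for locus {locus!r}")
        w_exp *= mean
        rel_errors.append(sd / mean)
    return w_exp, w_exp * _combine(rel_errors, method)


def absolute_epistasis(w_obs: float, singles: Mapping[str, tuple[float, float]]) -> float:
    """eps = w_obs - prod(singles); the sign distinguishes synergy from antagonism."""
    w_exp, _ = expected_fitness(singles)
    return w_obs - w_exp


def epistasis_sd(sd_obs: float, sd_exp: float, method: str = "quadrature") -> float:
    """Propagated SD of eps from the SDs of observed and expected fitness."""
    if sd_obs < 0 or sd_exp < 0:
        raise ValueError("SDs must be non-negative")
    return _combine([sd_obs, sd_exp], method)


def epistasis_test(eps: float, sd_eps: float, n_reps: int) -> tuple[float, int, float]:
    """Two-sided t-test of eps against 0: t = eps/sd_eps, df = n_reps - 1.

    Raises on sd_eps = 0 (degenerate: callers should flag the record instead
    of reporting p = 0) and on n_reps < 2 (no df).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    if not sd_eps > 0:
        raise ValueError("sd_eps must be positive (zero SD is degenerate, flag it)")
    df = n_reps - 1
    t = eps / sd_eps
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p)


# ---------------------------------------------------------------------------
# higher-order decomposition
# ---------------------------------------------------------------------------

def _abs_eps_from_means(landscape: LandscapeSummary, env: str, g: MutationSet) -> float:
    w_obs = landscape.w_mean(env, g)
    w_exp = 1.0
    for s in g.singletons():
        w_exp *= landscape.w_mean(env, s)
    return w_obs - w_exp


def net_higher_order(landscape: LandscapeSummary, env: str, g: MutationSet) -> float:
    """Net interaction term eps_net(g) of the inclusion-exclusion decomposition.

    For |g| = 2 this is the pair's absolute epistasis; for |g| >= 3 it is the
    genotype's absolute epistasis minus the net terms of all proper subsets
    with >= 2 mutations.  Requires every subset of ``g`` (including singles)
    to be present in the landscape for ``env``.
    """
    if g.size < 2:
        raise ValueError("net higher-order epistasis is defined for >= 2 mutations")

    memo: dict[int, float] = {}

    def eps_net(sub: MutationSet) -> float:
        if sub.mask in memo:
            return memo[sub.mask]
        val = _abs_eps_from_means(landscape, env, sub)
        if sub.size > 2:
            val -= sum(eps_net(b) for b in subsets(sub, 2))
        memo[sub.mask] = val
        return val

    return eps_net(g)


# ---------------------------------------------------------------------------
# per-landscape epistasis report
# ---------------------------------------------------------------------------

def epistasis_table(
    landscape: LandscapeSummary,
    env: str,
    method: str = "quadrature",
    alpha: float = 0.05,
    correction: str = "none",
    min_mutations: int = 2,
) -> pd.DataFrame:
    """One epistasis record per genotype with >= ``min_mutations`` mutations.

    Columns: environment, genotype, n_mut, w_obs, sd_obs, w_exp, sd_exp, eps,
    sd_eps, t, df, p, p_adj, significant, degenerate, eps_higher.  ``p_adj``
    applies the requested multiple-testing correction ("none", "bonferroni",
    "bh"); ``eps_higher`` is the net higher-order term (equal to eps for
    pairs, NaN if a subset genotype is missing).
    """
    rows = []
    for g in landscape.genotypes(env):
        if g.size < min_mutations:
            continue
        w_obs, sd_obs, n = landscape.cell(env, g)
        singles = landscape.single_mutants(env, g)
        w_exp, sd_exp = expected_fitness(singles, method)
        eps = w_obs - w_exp
        sd_eps = epistasis_sd(sd_obs, sd_exp, method)
        degenerate = not sd_eps > 0 or n < 2
        if degenerate:
            t = df = p = float("nan")
        else:
            t, df, p = epistasis_test(eps, sd_eps, n)
        try:
            eps_ho = net_higher_order(landscape, env, g) if g.size >= 2 else float("nan")
        except KeyError:
            eps_ho = float("nan")
        rows.append(
            {
                "environment": env,
                "genotype": g.label,
                "n_mut": g.size,
                "w_obs": w_obs,
                "sd_obs": sd_obs,
                "w_exp": w_exp,
                "sd_exp": sd_exp,
                "eps": eps,
                "sd_eps": sd_eps,
                "t": t,
                "df": df,
                "p": p,
                "degenerate": degenerate,
            }
        )
        rows[-1]["eps_higher"] = eps_ho
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = _adjust_p(table["p"].to_numpy(), correction)
    table["significant"] = table["p_adj"] < alpha
    return table


def _adjust_p(p: np.ndarray, correction: str) -> np.ndarray:
    if correction == "none":
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    methods = {"bonferroni": "bonferroni", "bh": "fdr_bh"}
    if correction not in methods:
        raise ValueError(f"unknown correction {correction!r}")
    finite = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if finite.any():
        out[finite] = multipletests(p[finite], method=methods[correction])[1]
    return out


# ---------------------------------------------------------------------------
# landscape-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanEpistasis:
    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    n: int


def mean_epistasis(eps_values: Sequence[float], ci: float = 0.95) -> MeanEpistasis:
    """One-sample t-test of the epistasis values against 0, with a t-based CI."""
    x = np.asarray(list(eps_values), dtype=float)
    if x.size < 2:
        raise ValueError("mean epistasis needs at least 2 genotypes")
    m = float(x.mean())
    sd = x.std(ddof=1)
    if sd == 0.0:
        # degenerate: identical values; t is 0 (no deviation) or unbounded
        t = 0.0 if m == 0.0 else math.copysign(math.inf, m)
        p = 1.0 if m == 0.0 else 0.0
        return MeanEpistasis(mean=m, ci_low=m, ci_high=m, t=t, df=x.size - 1, p=p, n=x.size)
    res = stats.ttest_1samp(x, 0.0)
    sem = sd / math.sqrt(x.size)
    half = stats.t.ppf(0.5 + ci / 2, x.size - 1) * sem
    return MeanEpistasis(
        mean=m, ci_low=m - half, ci_high=m + half,
        t=float(res.statistic), df=x.size - 1, p=float(res.pvalue), n=x.size,
    )


@dataclass(frozen=True)
class DiminishingReturnsFit:
    """Correlation of epistasis with expected fitness, plus a model-II line.

    A negative ``pearson_r`` is the diminishing-returns signature: epistasis
    becomes more antagonistic as the expected fitness of a genotype rises.
    The standard major axis (SMA) slope is sign(r) * sd_y / sd_x — symmetric
    in x and y, appropriate when both carry error.
    """

    environment: str
    scale: str
    pearson_r: float
    p_value: float
    sma_slope: float
    sma_intercept: float
    n_genotypes: int


def diminishing_returns_fit(
    records: pd.DataFrame, scale: str = "absolute", environment: str = ""
) -> DiminishingReturnsFit:
    """Fit the epistasis-vs-expected-fitness relationship on an epistasis table.

    ``scale`` selects y = eps ("absolute") or y = eps / w_exp ("relative").
    """
    if scale not in ("absolute", "relative"):
        raise ValueError(f"unknown epistasis scale {scale!r}")
    x = records["w_exp"].to_numpy(dtype=float)
    y = records["eps"].to_numpy(dtype=float)
    if scale == "relative":
        y = y / x
    if x.size < 3:
        raise ValueError("diminishing-returns fit needs at least 3 genotypes")
    if np.isclose(x.std(ddof=1), 0) or np.isclose(y.std(ddof=1), 0):
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = stats.pearsonr(x, y)
    slope = math.copysign(y.std(ddof=1) / x.std(ddof=1), r)
    intercept = float(y.mean() - slope * x.mean())
    env = environment or (records["environment"].iloc[0] if "environment" in records else "")
    return DiminishingReturnsFit(
        environment=str(env), scale=scale, pearson_r=float(r), p_value=float(p),
        sma_slope=float(slope), sma_intercept=intercept, n_genotypes=int(x.size),
    )


@dataclass(frozen=True)
class FocalMutationReport:
    """Stratified epistasis analysis by presence/absence of one mutation.

    Combines (a) a pooled-variance two-sample t-test of mean epistasis with vs
    without the mutation, (b) an ANCOVA ``eps ~ w_exp * has_mutation`` with
    F-tests for dropping the interaction and the main-effect terms, and (c)
    per-stratum correlations of epistasis with expected fitness.
    """

    locus: str
    n_with: int
    n_without: int
    mean_eps_with: float
    mean_eps_without: float
    t_group: float
    df_group: int
    p_group: float
    f_interaction: float
    p_interaction: float
    f_mutation: float
    p_mutation: float
    r_with: float
    r_without: float


def focal_mutation_analysis(records: pd.DataFrame, locus: str) -> FocalMutationReport:
    """Test whether one focal mutation shapes the epistasis/expected-fitness pattern.

    ``records`` is an epistasis table (needs genotype, eps, w_exp columns);
    strata are genotypes containing vs lacking the single-character ``locus``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = records[["genotype", "eps", "w_exp"]].copy()
    d["has"] = d["genotype"].str.contains(locus, regex=False).astype(int)
    with_g = d[d["has"] == 1]
    without_g = d[d["has"] == 0]
    if len(with_g) < 2 or len(without_g) < 2:
        raise ValueError(f"stratum for locus {locus!r} has fewer than 2 genotypes")

    t_res = stats.ttest_ind(with_g["eps"], without_g["eps"], equal_var=True)
    df_group = len(d) - 2

    full = smf.ols("eps ~ w_exp * has", data=d).fit()
    no_interaction = smf.ols("eps ~ w_exp + has", data=d).fit()
    no_mutation = smf.ols("eps ~ w_exp + w_exp:has", data=d).fit()
    cmp_int = sm.stats.anova_lm(no_interaction, full)
    cmp_mut = sm.stats.anova_lm(no_mutation, full)

    def _stratum_r(sub: pd.DataFrame) -> float:
        if len(sub) < 3 or np.isclose(sub["w_exp"].std(ddof=1), 0):
            return float("nan")
        return float(stats.pearsonr(sub["w_exp"], sub["eps"])[0])

    return FocalMutationReport(
        locus=locus,
        n_with=len(with_g),
        n_without=len(without_g),
        mean_eps_with=float(with_g["eps"].mean()),
        mean_eps_without=float(without_g["eps"].mean()),
        t_group=float(t_res.statistic),
        df_group=df_group,
        p_group=float(t_res.pvalue),
        f_interaction=float(cmp_int["F"].iloc[1]),
        p_interaction=float(cmp_int["Pr(>F)"].iloc[1]),
        f_mutation=float(cmp_mut["F"].iloc[1]),
        p_mutation=float(cmp_mut["Pr(>F)"].iloc[1]),
        r_with=_stratum_r(with_g),
        r_without=_stratum_r(without_g),
    )
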