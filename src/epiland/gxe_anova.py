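"""Full-factorial G x E ANOVA and class-level variance partitioning.

Replicate-level fitness observations over all 2^L genotypes in one or two
environments are decomposed by a fixed-effects linear model whose factors are
the L mutation indicators plus (when two environments are present) the
environment, with *all* interaction orders: 2^(L+1) - 1 = 63 non-intercept
terms for L = 5 and two environments (a "six-way" ANOVA).

Factors are effect-coded (+1 mutant / -1 wild-type, +1 / -1 for the two
environments), so on a balanced design the term columns are mutually
orthogonal and each term's sum of squares is well defined independently of
fitting order.  Sums of squares are computed sequentially via a QR
decomposition with terms ordered by ascending interaction order; on balanced
data this reproduces the orthogonal decomposition exactly, and on unbalanced
data it is a documented Type-I (sequential) analysis, flagged with a warning.

Terms are classified by biological meaning — G (one locus), GxG (two or more
loci), E (environment alone), GxE (one locus x environment), GxGxE (two or
more loci x environment) — and the variance partition reports each class's
share of the *total* sum of squares (fractions, summing to 1 with the
residual), the scale on which "GxGxE explains ~8% of fitness variance"
statements are made.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import LocusSet, parse_genotype

__all__ = ["FactorialTerm", "AnovaTable", "build_design", "anova", "variance_partition"]

ENV_FACTOR = "E"


@dataclass(frozen=True)
class FactorialTerm:
    """One model term: a (possibly empty) locus subset, optionally x environment."""

    loci: tuple[str, ...]
    includes_environment: bool

    @property
    def order(self) -> int:
        return len(self.loci) + (1 if self.includes_environment else 0)

    @property
    def label(self) -> str:
        parts = list(self.loci) + ([ENV_FACTOR] if self.includes_environment else [])
        return ":".join(parts)

    @property
    def term_class(self) -> str:
        k = len(self.loci)
        if self.includes_environment:
            if k == 0:
                return "E"
            return "GxE" if k == 1 else "GxGxE"
        return "G" if k == 1 else "GxG"


@dataclass
class AnovaTable:
    """Per-term df/SS/MS/F/p plus residual and total sums of squares."""

    terms: pd.DataFrame  # columns: term, class, df, SS, MS, F, p
    ss_residual: float
    df_residual: int
    ss_total: float
    balanced: bool

    @property
    def df_model(self) -> int:
        return int(self.terms["df"].sum())

    @property
    def ss_model(self) -> float:
        return float(self.terms["SS"].sum())

    def overall_f(self) -> tuple[float, int, int, float]:
        """Whole-model F test: (F, df_model, df_residual, p)."""
        ms_model = self.ss_model / self.df_model
        ms_res = self.ss_residual / self.df_residual
        f = ms_model / ms_res
        p = float(stats.f.sf(f, self.df_model, self.df_residual))
        return f, self.df_model, self.df_residual, p


def _prepare(df: pd.DataFrame, loci: LocusSet) -> pd.DataFrame:
    required = {"environment", "genotype", "w"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observations are missing columns {sorted(missing)}")
    d = df.copy()
    masks = d["genotype"].map(lambda s: parse_genotype(str(s), loci).mask)
    for i, locus in enumerate(loci.loci):
        d[f"_code_{locus}"] = np.where((masks.to_numpy() >> i) & 1, 1.0, -1.0)
    return d


def build_design(
    df: pd.DataFrame, loci: LocusSet | None = None
) -> tuple[np.ndarray, np.ndarray, list[FactorialTerm]]:
    """Effect-coded full-factorial design matrix (with leading intercept).

    Returns (X, y, terms) where ``terms`` matches the non-intercept columns,
    ordered by ascending interaction order then label.  One environment drops
    the E factor; two environments code it +/-1; more than two are not
    supported by the +/-1 coding and raise.
    """
    loci = loci or LocusSet()
    d = _prepare(df, loci)
    envs = sorted(d["environment"].unique())
    if len(envs) > 2:
        raise ValueError(
            f"effect-coded factorial supports 1 or 2 environments, got {len(envs)}: {envs}"
        )
    factors: dict[str, np.ndarray] = {
        locus: d[f"_code_{locus}"].to_numpy() for locus in loci.loci
    }
    if len(envs) == 2:
        factors[ENV_FACTOR] = np.where(d["environment"] == envs[1], 1.0, -1.0)

    terms: list[FactorialTerm] = []
    names = list(loci.loci) + ([ENV_FACTOR] if len(envs) == 2 else [])
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            terms.append(
                FactorialTerm(
                    loci=tuple(c for c in combo if c != ENV_FACTOR),
                    includes_environment=ENV_FACTOR in combo,
                )
            )
    terms.sort(key=lambda t: (t.order, t.label))

    n = len(d)
    X = np.ones((n, 1 + len(terms)))
    for j, term in enumerate(terms, start=1):
        col = np.ones(n)
        for locus in term.loci:
            col = col * factors[locus]
        if term.includes_environment:
            col = col * factors[ENV_FACTOR]
        X[:, j] = col
    y = d["w"].to_numpy(dtype=float)
    return X, y, terms


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["environment", "genotype"]).size()
    return counts.nunique() == 1


def anova(df: pd.DataFrame, loci: LocusSet | None = None) -> AnovaTable:
    """Fit the full-factorial model and return the ANOVA table.

    ``df`` holds replicate-level rows (environment, genotype, w).  Requires
    at least one cell with >= 2 replicates so a residual exists.
    """
    loci = loci or LocusSet()
    balanced = _is_balanced(df)
    if not balanced:
        warnings.warn(
            "unbalanced design: sums of squares are sequential (Type I) in "
            "ascending interaction order",
            stacklevel=2,
        )
    X, y, terms = build_design(df, loci)
    n, p = X.shape
    if n <= p:
        raise ValueError("zero residual degrees of freedom; need replicate observations")
    # Sequential SS through QR: column j's increment in explained SS.
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ y
    ss_seq = proj**2
    ss_terms = ss_seq[1:]  # drop intercept
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_model = float(ss_terms.sum())
    ss_res = float(y @ y - np.sum(proj**2))
    df_res = n - p
    ms_res = ss_res / df_res
    rows = []
    for term, ss in zip(terms, ss_terms):
        ms = ss  # df = 1 for every two-level term
        f = ms / ms_res if ms_res > 0 else float("inf")
        pval = float(stats.f.sf(f, 1, df_res)) if np.isfinite(f) else 0.0
        rows.append(
            {"term": term.label, "class": term.term_class, "df": 1,
             "SS": float(ss), "MS": float(ms), "F": float(f), "p": pval}
        )
    table = AnovaTable(
        terms=pd.DataFrame(rows),
        ss_residual=ss_res,
        df_residual=df_res,
        ss_total=ss_total,
        balanced=balanced,
    )
    if abs(ss_model + ss_res - ss_total) > 1e-6 * max(ss_total, 1.0):
        warnings.warn("SS decomposition does not conserve total SS to tolerance", stacklevel=2)
    return table


def variance_partition(table: AnovaTable) -> pd.DataFrame:
    """Fraction of total SS per interaction class (G, GxG, E, GxE, GxGxE, residual).

    Fractions sum to 1.  This is a raw sum-of-squares share, not a
    variance-component estimate.
    """
    classes = ["G", "GxG", "E", "GxE", "GxGxE"]
    ss_by_class = table.terms.groupby("class")["SS"].sum()
    rows = []
    for cls in classes:
        ss = float(ss_by_class.get(cls, 0.0))
        rows.append({"class": cls, "SS": ss, "fraction": ss / table.ss_total})
    rows.append(
        {"class": "residual", "SS": table.ss_residual,
         "fraction": table.ss_residual / table.ss_total}
    )
    return pd.DataFrame(rows)
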