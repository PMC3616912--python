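"""Synthetic landscapes and assay data with known ground truth.

The generator inverts the analysis model: a true landscape is specified by
per-environment single-mutant multiplicative factors and planted net
interaction coefficients eps_net(B) for chosen subsets B (|B| >= 2), and each
genotype's true fitness is

    w_true(g) = prod_{i in g} w_i  +  sum_{B subseteq g, |B| >= 2} eps_net(B),

exactly the decomposition the epistasis module recovers.  Replicate
measurements add Gaussian noise on the fitness scale (the scale the t-tests
operate on), truncated to stay positive by resampling.  Competition plate
counts, logistic OD600 growth curves and phenotype-microarray kinetic curves
are generated by inverting the corresponding assay formulas, so round-trips
through :mod:`epiland.assays` and :mod:`epiland.biolog` recover the planted
quantities.

The default specification mirrors the study design this package reimplements:
L = 5 loci (r, t, s, g, p) in fixation order; three environments — the
original selection environment plus one raising and one lowering the fitness
of the full mutant — with the published single-mutant fitness factors in each;
5 replicate assays per genotype; measurement noise SD 0.03 on relative
fitness.  Pairwise interactions follow a diminishing-returns rule
eps_net(pair) = -c_env (w_exp(pair) - 1), with an additional antagonistic
pair (t, g) planted only in the fitness-raising environment, so GxG, GxE and
GxGxE structure are all present by construction.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard
from scipy.optimize import brentq

from .landscape import (
    FitnessObservation,
    LandscapeSummary,
    LocusSet,
    MutationSet,
    parse_genotype,
)

__all__ = [
    "LandscapeSpec",
    "default_spec",
    "gxgxe_spec",
    "true_fitness",
    "true_landscape",
    "simulate_fitness_table",
    "simulate_competitions",
    "simulate_growth_curves",
    "simulate_biolog",
    "simulate_assays",
    "planted_variance_fractions",
]

# Single-mutant fitness factors (1 + published per-environment fitness gain)
# for the five mutations in fixation order.
SELECTION_SINGLES = {"r": 1.015, "t": 1.133, "s": 1.094, "g": 1.05, "p": 1.00}
ENV_UP_SINGLES = {"r": 1.00, "t": 1.22, "s": 1.06, "g": 1.04, "p": 1.12}
ENV_DOWN_SINGLES = {"r": 1.005, "t": 1.13, "s": 0.92, "g": 1.01, "p": 0.99}


@dataclass(frozen=True)
class LandscapeSpec:
    """Ground truth for a simulated multi-environment fitness landscape.

    ``singles`` maps environment -> locus -> multiplicative fitness factor;
    ``interactions`` maps environment -> genotype label (|B| >= 2, canonical
    order) -> planted net interaction coefficient eps_net(B).
    """

    loci: LocusSet = field(default_factory=LocusSet)
    environments: tuple[str, ...] = ("selection", "env_up", "env_down")
    singles: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)
    n_reps: int = 5
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for env in self.environments:
            if env not in self.singles:
                raise ValueError(f"no single-mutant effects specified for {env!r}")
            missing = set(self.loci.loci) - set(self.singles[env])
            if missing:
                raise ValueError(f"missing single effects for loci {sorted(missing)} in {env!r}")


def _diminishing_returns_pairs(
    loci: LocusSet, singles: dict[str, float], c: float
) -> dict[str, float]:
    """eps_net(pair) = -c (w_exp(pair) - 1) for every pair of loci."""
    out = {}
    for a, b in itertools.combinations(loci.loci, 2):
        pair = parse_genotype(a + b, loci)
        out[pair.label] = -c * (singles[a] * singles[b] - 1.0)
    return out


def default_spec(n_reps: int = 5, noise_sd: float = 0.03) -> LandscapeSpec:
    """The study-like default: 5 loci x 3 environments, diminishing returns,
    plus one environment-specific antagonistic pair (t,g in env_up, -0.2)."""
    loci = LocusSet()
    singles = {
        "selection": dict(SELECTION_SINGLES),
        "env_up": dict(ENV_UP_SINGLES),
        "env_down": dict(ENV_DOWN_SINGLES),
    }
    # weak antagonism: per-pair deviations of a few percent, so the summed
    # epistasis of the full mutant stays small against its ~30-50% fitness gain
    strength = {"selection": 0.1, "env_up": 0.08, "env_down": 0.15}
    interactions = {
        env: _diminishing_returns_pairs(loci, singles[env], strength[env])
        for env in singles
    }
    interactions["env_up"][parse_genotype("tg", loci).label] = -0.2
    return LandscapeSpec(
        loci=loci,
        environments=("selection", "env_up", "env_down"),
        singles=singles,
        interactions=interactions,
        n_reps=n_reps,
        noise_sd=noise_sd,
    )


def true_fitness(spec: LandscapeSpec, env: str, g: MutationSet) -> float:
    """Noise-free fitness of one genotype: product of singles + planted terms."""
    w = 1.0
    for locus in g.present:
        w *= spec.singles[env][locus]
    for label, eps in spec.interactions.get(env, {}).items():
        b = parse_genotype(label, spec.loci)
        if b.issubset(g):
            w += eps
    if not w > 0:
        raise ValueError(f"spec implies non-positive fitness {w:.4g} for {g.label} in {env}")
    return w


def true_landscape(spec: LandscapeSpec) -> LandscapeSummary:
    """The exact landscape (w_sd = 0, n = 1 per cell) implied by the spec."""
    cells = {}
    for env in spec.environments:
        for g in spec.loci.all_genotypes():
            cells[(env, g.mask)] = (true_fitness(spec, env, g), 0.0, 1)
    return LandscapeSummary(spec.loci, cells)


def simulate_fitness_table(spec: LandscapeSpec, seed: int) -> list[FitnessObservation]:
    """Replicate observations: w_true + N(0, noise_sd), resampled to stay > 0."""
    rng = np.random.default_rng(seed)
    out = []
    for env in spec.environments:
        for g in spec.loci.all_genotypes():
            w_true = true_fitness(spec, env, g)
            for rep in range(1, spec.n_reps + 1):
                w = w_true + rng.normal(0.0, spec.noise_sd) if spec.noise_sd else w_true
                while w <= 0:
                    w = w_true + rng.normal(0.0, spec.noise_sd)
                out.append(FitnessObservation(env, g, rep, float(w)))
    return out


def fitness_table_frame(observations) -> pd.DataFrame:
    """Observations as the tidy CSV frame the pipeline reads."""
    return pd.DataFrame(
        [
            {
                "environment": o.environment,
                "genotype": o.genotype.label,
                "replicate": o.replicate,
                "w": o.w,
            }
            for o in observations
        ]
    )


# ---------------------------------------------------------------------------
# assay-level generators
# ---------------------------------------------------------------------------

def simulate_competitions(
    spec: LandscapeSpec,
    seed: int,
    days: int = 3,
    dilution: float = 100.0,
    initial_density: float = 1e5,
) -> pd.DataFrame:
    """Competition plate counts whose log-ratio fitness equals the target w.

    The ancestor competitor realizes ``dilution**days`` net fold-expansion
    (full regrowth after each 1:dilution transfer); the focal strain's final
    density is chosen so that the realized-growth log ratio equals the
    per-replicate target fitness (w_true plus measurement noise).  With
    noise_sd = 0 the round trip through ``assays.relative_fitness`` is exact.
    """
    rng = np.random.default_rng(seed)
    growth_b = dilution**days
    rows = []
    for env in spec.environments:
        for g in spec.loci.all_genotypes():
            w_true = true_fitness(spec, env, g)
            for rep in range(1, spec.n_reps + 1):
                w = w_true + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
                while w <= 0:
                    w = w_true + rng.normal(0.0, spec.noise_sd)
                growth_a = growth_b**w
                rows.append(
                    {
                        "strain_A": g.label,
                        "strain_B": "anc",
                        "environment": env,
                        "replicate": rep,
                        "A0": initial_density,
                        "Af": growth_a * initial_density / dilution ** (days - 1),
                        "B0": initial_density,
                        "Bf": growth_b * initial_density / dilution ** (days - 1),
                        "days": days,
                        "dilution": dilution,
                    }
                )
    return pd.DataFrame(rows)


def simulate_growth_curves(
    spec: LandscapeSpec,
    seed: int,
    env: str | None = None,
    strains: list[str] | None = None,
    n_reps: int = 12,
    hours: float = 24.0,
    step_h: float = 0.25,
    carrying_od: float = 1.0,
    rate_per_h: float = 0.8,
) -> pd.DataFrame:
    """Logistic OD600 curves whose AUC ratios encode the true relative growth.

    Each strain's curve is a logistic with carrying capacity scaled by its
    true fitness (initial OD a fixed 1% of capacity, so the curve is an exact
    scalar multiple of the ancestor's and the AUC ratio equals the capacity
    ratio).  Replicates perturb the capacity multiplicatively by the spec
    noise.  Long format: strain, replicate, time_h, od.
    """
    rng = np.random.default_rng(seed)
    env = env or spec.environments[0]
    if strains is None:
        strains = ["anc"] + [l for l in spec.loci.loci] + ["gp", spec.loci.full().label]
    t = np.arange(0.0, hours + step_h / 2, step_h)
    shape = 1.0 / (1.0 + (1.0 / 0.01 - 1.0) * np.exp(-rate_per_h * t))
    rows = []
    for strain in strains:
        g = parse_genotype(strain, spec.loci)
        target = true_fitness(spec, env, g) if g.size else 1.0
        for rep in range(1, n_reps + 1):
            k = carrying_od * target
            if spec.noise_sd:
                k *= max(1.0 + rng.normal(0.0, spec.noise_sd), 1e-3)
            od = k * shape
            rows.extend(
                {"strain": strain, "environment": env, "replicate": rep,
                 "time_h": float(ti), "od": float(oi)}
                for ti, oi in zip(t, od)
            )
    return pd.DataFrame(rows)


def simulate_biolog(
    seed: int,
    n_wells: int = 96,
    n_gains: int = 10,
    n_losses: int = 3,
    gain_fold: float = 2.0,
    loss_fold: float = 0.5,
    n_reps: int = 2,
    baseline_height: float = 70.0,
    rep_jitter: float = 0.01,
    hours: float = 48.0,
    step_h: float = 0.25,
) -> pd.DataFrame:
    """Kinetic respiration curves with planted gains/losses of function.

    Wells are labelled env_000... Planted wells scale the evolved strain's
    curve by ``gain_fold``/``loss_fold`` — large enough to exceed the 3-SD
    rule given the small replicate jitter — while in unplanted wells the
    evolved curves are copies of the ancestor's, so the screen's differential
    count equals the planted count by construction.  Long format:
    strain, environment, replicate, time_h, signal.
    """
    if n_gains + n_losses > n_wells:
        raise ValueError("more planted calls than wells")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, hours + step_h / 2, step_h)
    # saturating (Monod-style) respiration curve shape, mean height ~= 1
    shape = 1.0 - np.exp(-t / (hours / 4))
    shape /= np.trapezoid(shape, t) / (t[-1] - t[0])
    wells = [f"env_{i:03d}" for i in range(n_wells)]
    planted = rng.permutation(n_wells)
    gain_wells = {wells[i] for i in planted[:n_gains]}
    loss_wells = {wells[i] for i in planted[n_gains : n_gains + n_losses]}
    rows = []
    for well in wells:
        base = baseline_height * (0.5 + rng.random())  # well-to-well variation
        anc_scales = base * (1.0 + rng.normal(0.0, rep_jitter, size=n_reps))
        if well in gain_wells:
            evo_scales = anc_scales * gain_fold
        elif well in loss_wells:
            evo_scales = anc_scales * loss_fold
        else:
            evo_scales = anc_scales  # identical curves -> zero mean difference
        for strain, scales in (("ancestor", anc_scales), ("evolved", evo_scales)):
            for rep, scale in enumerate(scales, start=1):
                signal = scale * shape
                rows.extend(
                    {"strain": strain, "environment": well, "replicate": rep,
                     "time_h": float(ti), "signal": float(si)}
                    for ti, si in zip(t, signal)
                )
    return pd.DataFrame(rows)


def simulate_assays(spec: LandscapeSpec, seed: int) -> dict[str, pd.DataFrame]:
    """All raw assay tables for a spec: competitions, growth curves, Biolog."""
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=3)
    return {
        "competitions": simulate_competitions(spec, int(child[0])),
        "growth_curves": simulate_growth_curves(spec, int(child[1])),
        "biolog": simulate_biolog(int(child[2])),
    }


# ---------------------------------------------------------------------------
# Walsh-spectrum oracle for planted variance structure
# ---------------------------------------------------------------------------

def planted_variance_fractions(spec: LandscapeSpec, environments: tuple[str, str]) -> dict[str, float]:
    """Class-level SS fractions of the noise-free landscape over two environments.

    Computed by a Walsh (Hadamard) transform of the 2^(L+1) cell means in
    +/-1 coding — an independent spectral route to the same quantity the
    effect-coded ANOVA estimates, used as the oracle for planted-fraction
    calibration and recovery tests.  Fractions are shares of the total
    (non-intercept) SS of the cell means.
    """
    L = spec.loci.size
    n_factors = L + 1
    size = 2**n_factors
    y = np.empty(size)
    for idx in range(size):
        mask = idx & ((1 << L) - 1)
        env = environments[(idx >> L) & 1]
        y[idx] = true_fitness(spec, env, MutationSet(mask, spec.loci))
    # Row r of a Sylvester Hadamard matrix is the +/-1 character chi_r;
    # coefficient k's SS share is H[k] . y squared / size, intercept excluded.
    H = hadamard(size)
    coeffs = H @ y / size
    ss = size * coeffs**2
    fractions = {"G": 0.0, "GxG": 0.0, "E": 0.0, "GxE": 0.0, "GxGxE": 0.0}
    total = 0.0
    for k in range(1, size):
        loci_bits = bin(k & ((1 << L) - 1)).count("1")
        has_env = bool(k >> L & 1)
        if has_env:
            cls = "E" if loci_bits == 0 else ("GxE" if loci_bits == 1 else "GxGxE")
        else:
            cls = "G" if loci_bits == 1 else "GxG"
        fractions[cls] += ss[k]
        total += ss[k]
    return {cls: val / total for cls, val in fractions.items()}


def gxgxe_spec(
    target_fraction: float = 0.08,
    n_reps: int = 5,
    noise_sd: float = 0.03,
) -> LandscapeSpec:
    """A two-environment spec whose planted GxGxE share of model SS equals
    ``target_fraction``.

    Singles are identical in both environments (no planted E or GxE beyond the
    aliasing of the environment-flipped pair term), and a single pair (t, g)
    carries +d in one environment and -d in the other; d is calibrated by
    root-finding against the Walsh-spectrum oracle.
    """
    loci = LocusSet()
    singles = dict(SELECTION_SINGLES)
    envs = ("env_A", "env_B")

    def build(d: float) -> LandscapeSpec:
        base = _diminishing_returns_pairs(loci, singles, 0.5)
        inter_a = dict(base)
        inter_b = dict(base)
        tg = parse_genotype("tg", loci).label
        inter_a[tg] = base[tg] + d
        inter_b[tg] = base[tg] - d
        return LandscapeSpec(
            loci=loci,
            environments=envs,
            singles={e: dict(singles) for e in envs},
            interactions={"env_A": inter_a, "env_B": inter_b},
            n_reps=n_reps,
            noise_sd=noise_sd,
        )

    def objective(d: float) -> float:
        return planted_variance_fractions(build(d), envs)["GxGxE"] - target_fraction

    # upper bracket keeps every implied w_true positive for the default singles
    d_star = brentq(objective, 1e-6, 0.6, xtol=1e-12)
    return build(d_star)
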