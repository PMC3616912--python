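"""Genotype labels, subset combinatorics, and fitness-table I/O.

A fitness landscape over ``L`` named loci assigns a relative fitness ``w``
(measured against a common ancestor, so ``w = 1`` is neutrality) to each of
the ``2^L`` genotypes formed by every subset of the mutations.  Genotypes are
written as strings of single-character locus labels in a fixed order — by
convention the order in which the mutations fixed during the source
population's evolution (default ``r, t, s, g, p``) — so the triple carrying
the first three mutations is always ``"rts"``, never ``"srt"``.  The ancestor
(no mutations) is written with the token ``"anc"``.

This module defines the locus/genotype types, parsing and formatting between
label conventions (letter strings and bitstrings), proper-subset enumeration
used by the epistasis decomposition, and the tidy-CSV reader plus
per-(environment, genotype) summariser that every downstream statistic
consumes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ANCESTOR_TOKEN",
    "LocusSet",
    "MutationSet",
    "FitnessObservation",
    "LandscapeSummary",
    "parse_genotype",
    "format_genotype",
    "subsets",
    "load_fitness_table",
    "summarize",
]

#: Label used for the genotype with no mutations (the shared ancestor).
ANCESTOR_TOKEN = "anc"


@dataclass(frozen=True)
class LocusSet:
    """An ordered collection of single-character locus labels.

    The order is fixed for the lifetime of an analysis and determines both the
    canonical genotype string (present loci listed in this order) and the bit
    positions of the mask representation (bit ``i`` ⇔ ``loci[i]``).
    """

    loci: tuple[str, ...] = ("r", "t", "s", "g", "p")

    def __post_init__(self) -> None:
        if isinstance(self.loci, str) or not isinstance(self.loci, tuple):
            object.__setattr__(self, "loci", tuple(self.loci))
        if len(self.loci) < 1:
            raise ValueError("a LocusSet needs at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError(f"duplicate locus labels in {self.loci!r}")
        for label in self.loci:
            if len(label) != 1:
                raise ValueError(f"locus labels must be single characters, got {label!r}")
            if label in "01":
                raise ValueError("locus labels '0'/'1' would be ambiguous with bitstrings")

    @property
    def size(self) -> int:
        return len(self.loci)

    def index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}; known loci are {''.join(self.loci)}") from None

    def all_genotypes(self) -> list["MutationSet"]:
        """Every subset of the loci, ordered by (size, canonical label)."""
        out = [MutationSet(mask, self) for mask in range(2 ** self.size)]
        out.sort(key=lambda g: (g.size, g.label))
        return out

    def full(self) -> "MutationSet":
        return MutationSet((1 << self.size) - 1, self)

    def ancestor(self) -> "MutationSet":
        return MutationSet(0, self)


@dataclass(frozen=True)
class MutationSet:
    """A subset of the loci of a :class:`LocusSet`, stored as a bit mask.

    Bit ``i`` of ``mask`` is set iff locus ``i`` (in fixation order) is
    mutated.  The canonical string form lists present loci in locus order;
    the empty set renders as :data:`ANCESTOR_TOKEN`.
    """

    mask: int
    loci: LocusSet = field(default_factory=LocusSet)

    def __post_init__(self) -> None:
        if not 0 <= self.mask < (1 << self.loci.size):
            raise ValueError(f"mask {self.mask} out of range for {self.loci.size} loci")

    @property
    def size(self) -> int:
        """Number of mutations present."""
        return self.mask.bit_count()

    @property
    def label(self) -> str:
        """Canonical genotype label ('rts' style, or the ancestor token)."""
        if self.mask == 0:
            return ANCESTOR_TOKEN
        return "".join(l for i, l in enumerate(self.loci.loci) if self.mask >> i & 1)

    @property
    def bitstring(self) -> str:
        return "".join("1" if self.mask >> i & 1 else "0" for i in range(self.loci.size))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    def __contains__(self, locus: str) -> bool:
        return bool(self.mask >> self.loci.index(locus) & 1)

    @property
    def present(self) -> tuple[str, ...]:
        return tuple(l for i, l in enumerate(self.loci.loci) if self.mask >> i & 1)

    def add(self, locus: str) -> "MutationSet":
        return MutationSet(self.mask | (1 << self.loci.index(locus)), self.loci)

    def issubset(self, other: "MutationSet") -> bool:
        return self.mask & other.mask == self.mask

    def singletons(self) -> list["MutationSet"]:
        """The single-mutation genotypes for each locus present, in locus order."""
        return [MutationSet(1 << i, self.loci) for i in range(self.loci.size) if self.mask >> i & 1]


def parse_genotype(label: str, loci: LocusSet | None = None) -> MutationSet:
    """Parse a genotype label into a canonical :class:`MutationSet`.

    Accepts the ancestor token, a 0/1 bitstring of length ``L`` (leftmost bit
    = first locus), or a string of present locus characters in any order.
    Round-trips with :func:`format_genotype`.
    """
    loci = loci or LocusSet()
    label = label.strip()
    if label == ANCESTOR_TOKEN:
        return MutationSet(0, loci)
    if not label:
        raise ValueError("empty genotype label (use the ancestor token for no mutations)")
    if set(label) <= {"0", "1"}:
        if len(label) != loci.size:
            raise ValueError(
                f"bitstring {label!r} has length {len(label)}, expected {loci.size}"
            )
        mask = sum(1 << i for i, c in enumerate(label) if c == "1")
        return MutationSet(mask, loci)
    mask = 0
    for ch in label:
        bit = 1 << loci.index(ch)
        if mask & bit:
            raise ValueError(f"duplicate locus {ch!r} in genotype label {label!r}")
        mask |= bit
    return MutationSet(mask, loci)


def format_genotype(g: MutationSet) -> str:
    """Canonical string form of a genotype (inverse of :func:`parse_genotype`)."""
    return g.label


def subsets(g: MutationSet, min_size: int = 0) -> list[MutationSet]:
    """All *proper* subsets of ``g`` with at least ``min_size`` mutations.

    Ordered deterministically by (size, canonical label).  Used by the
    higher-order epistasis recursion, which subtracts every lower-order
    interaction term of a genotype.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    bits = [1 << i for i in range(g.loci.size) if g.mask >> i & 1]
    out: list[MutationSet] = []
    for k in range(min_size, len(bits)):  # proper subsets only: k < |g|
        for combo in itertools.combinations(bits, k):
            out.append(MutationSet(sum(combo), g.loci))
    out.sort(key=lambda s: (s.size, s.label))
    return out


@dataclass(frozen=True)
class FitnessObservation:
    """One replicate relative-fitness measurement of a genotype in an environment."""

    environment: str
    genotype: MutationSet
    replicate: int
    w: float

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(
                f"relative fitness must be positive, got w={self.w} for "
                f"{self.genotype.label} in {self.environment}"
            )


class LandscapeSummary:
    """Per-(environment, genotype) mean fitness, sample SD, and replicate count.

    This is the object all downstream statistics consume: epistasis records,
    path accessibility, peaks, and the factorial ANOVA all read genotype means
    and replicate SDs from here.  SDs use the n−1 denominator so they feed
    t-tests with df = n−1.
    """

    def __init__(
        self,
        loci: LocusSet,
        cells: Mapping[tuple[str, int], tuple[float, float, int]],
    ) -> None:
        self.loci = loci
        # (environment, mask) -> (w_mean, w_sd, n_reps)
        self._cells = dict(cells)
        for (env, mask), (mean, sd, n) in self._cells.items():
            if n < 1 or sd < 0:
                raise ValueError(f"invalid summary cell for ({env}, mask={mask})")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_observations(cls, observations: Iterable[FitnessObservation]) -> "LandscapeSummary":
        obs = list(observations)
        if not obs:
            raise ValueError("no observations")
        loci = obs[0].genotype.loci
        seen: set[tuple[str, int, int]] = set()
        grouped: dict[tuple[str, int], list[float]] = {}
        for o in obs:
            key = (o.environment, o.genotype.mask, o.replicate)
            if key in seen:
                raise ValueError(
                    f"duplicate observation key (env={o.environment!r}, "
                    f"genotype={o.genotype.label!r}, replicate={o.replicate})"
                )
            seen.add(key)
            grouped.setdefault((o.environment, o.genotype.mask), []).append(o.w)
        cells = {}
        singletons = [k for k, v in grouped.items() if len(v) == 1]
        if singletons:
            warnings.warn(
                f"{len(singletons)} (environment, genotype) cells have a single "
                "replicate; their SD is reported as 0 and no t-test is possible",
                stacklevel=2,
            )
        for key, ws in grouped.items():
            arr = np.asarray(ws, dtype=float)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            cells[key] = (float(arr.mean()), sd, int(arr.size))
        return cls(loci, cells)

    # -- access -----------------------------------------------------------
    def _key(self, environment: str, genotype: MutationSet | str) -> tuple[str, int]:
        if isinstance(genotype, str):
            genotype = parse_genotype(genotype, self.loci)
        return environment, genotype.mask

    def has(self, environment: str, genotype: MutationSet | str) -> bool:
        return self._key(environment, genotype) in self._cells

    def cell(self, environment: str, genotype: MutationSet | str) -> tuple[float, float, int]:
        key = self._key(environment, genotype)
        try:
            return self._cells[key]
        except KeyError:
            g = MutationSet(key[1], self.loci)
            raise KeyError(
                f"no fitness data for genotype {g.label!r} in environment {environment!r}"
            ) from None

    def w_mean(self, environment: str, genotype: MutationSet | str) -> float:
        return self.cell(environment, genotype)[0]

    def w_sd(self, environment: str, genotype: MutationSet | str) -> float:
        return self.cell(environment, genotype)[1]

    def n_reps(self, environment: str, genotype: MutationSet | str) -> int:
        return self.cell(environment, genotype)[2]

    @property
    def environments(self) -> list[str]:
        return sorted({env for env, _ in self._cells})

    def genotypes(self, environment: str) -> list[MutationSet]:
        out = [MutationSet(m, self.loci) for e, m in self._cells if e == environment]
        out.sort(key=lambda g: (g.size, g.label))
        return out

    def is_complete(self, environment: str) -> bool:
        """True iff all 2^L genotypes are present for the environment."""
        return len(self.genotypes(environment)) == 2 ** self.loci.size

    def single_mutants(
        self, environment: str, genotype: MutationSet | None = None
    ) -> dict[str, tuple[float, float]]:
        """(mean, sd) of each single-mutant fitness, optionally restricted to
        the loci present in ``genotype``."""
        loci = genotype.present if genotype is not None else self.loci.loci
        out = {}
        for locus in loci:
            g1 = MutationSet(1 << self.loci.index(locus), self.loci)
            mean, sd, _ = self.cell(environment, g1)
            out[locus] = (mean, sd)
        return out

    # -- export -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "environment": env,
                "genotype": MutationSet(mask, self.loci).label,
                "n_mut": MutationSet(mask, self.loci).size,
                "w_mean": mean,
                "w_sd": sd,
                "n": n,
            }
            for (env, mask), (mean, sd, n) in self._cells.items()
        ]
        df = pd.DataFrame(rows).sort_values(["environment", "n_mut", "genotype"])
        return df.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_fitness_table(path, loci: LocusSet | None = None) -> list[FitnessObservation]:
    """Read a tidy fitness CSV (environment,genotype,replicate,w) into observations.

    Rejects missing columns, unparsable genotype labels and non-positive ``w``.
    """
    loci = loci or LocusSet()
    df = pd.read_csv(path)
    required = ["environment", "genotype", "replicate", "w"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"fitness table {path} is missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        w = float(row.w)
        if not math.isfinite(w) or w <= 0:
            raise ValueError(
                f"non-positive or non-finite fitness w={row.w!r} for genotype "
                f"{row.genotype!r} in {row.environment!r}"
            )
        out.append(
            FitnessObservation(
                environment=str(row.environment),
                genotype=parse_genotype(str(row.genotype), loci),
                replicate=int(row.replicate),
                w=w,
            )
        )
    return out


def summarize(observations: Iterable[FitnessObservation]) -> LandscapeSummary:
    """Collapse replicate observations to per-cell mean/SD/n (duplicate keys error)."""
    return LandscapeSummary.from_observations(observations)
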