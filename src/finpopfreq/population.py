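"""Finite diploid populations and the scenario grids of testable parameters.

A population of ``M`` diploid individuals carries ``2M`` gene copies at a
locus.  For a focal allele the two parameters of interest are its population
frequency ``p`` (a multiple of ``1/(2M)``) and the population frequency of
homozygotes for that allele ``P`` (a multiple of ``1/M``).  Any pair must
satisfy ``max(0, 2p - 1) <= P <= p``: homozygotes cannot carry more copies
than exist, and when ``p > 1/2`` heterozygotes alone cannot absorb all
copies.

Internally both parameters are held as integer counts -- ``kp = 2*M*p``
copies and ``cP = M*P`` homozygous individuals -- so grid construction and
feasibility checks never hinge on floating-point equality.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import FeasibilityError

__all__ = [
    "PopulationSpec",
    "SampleObservation",
    "Scenario",
    "ScenarioGrid",
    "homozygosity_bounds",
    "scenario_grid",
    "feasible_p_range",
    "as_copy_count",
    "as_homozygote_count",
]

#: absolute slack allowed when snapping a float frequency onto its lattice
_LATTICE_TOL = 1e-6


def as_copy_count(p: float, M: int) -> int:
    """Snap an allele frequency onto the 1/(2M) lattice, returning 2*M*p.

    Raises :class:`FeasibilityError` if ``p`` is not (numerically) a
    multiple of ``1/(2M)`` or lies outside [0, 1].
    """
    kp = 2 * M * p
    k = int(round(kp))
    if abs(kp - k) > _LATTICE_TOL * max(1.0, abs(kp)):
        raise FeasibilityError(
            f"allele frequency {p} is not a multiple of 1/(2M) for M={M}"
        )
    if not 0 <= k <= 2 * M:
        raise FeasibilityError(f"allele frequency {p} outside [0, 1]")
    return k


def as_homozygote_count(P: float, M: int) -> int:
    """Snap a homozygote frequency onto the 1/M lattice, returning M*P."""
    cP = M * P
    c = int(round(cP))
    if abs(cP - c) > _LATTICE_TOL * max(1.0, abs(cP)):
        raise FeasibilityError(
            f"homozygote frequency {P} is not a multiple of 1/M for M={M}"
        )
    if not 0 <= c <= M:
        raise FeasibilityError(f"homozygote frequency {P} outside [0, 1]")
    return c


def homozygosity_bounds(p: float, M: int) -> tuple[float, float]:
    """Feasible range of the homozygote frequency for an allele at frequency p.

    The minimum is ``max(0, 2p - 1)``: all copies sit in heterozygotes until
    the copies outnumber the individuals, after which every surplus copy
    forces a homozygote.  The maximum is ``p`` (every carrier homozygous).
    The maximum may need rounding down to the 1/M lattice by callers when
    ``2*M*p`` is odd.
    """
    kp = as_copy_count(p, M)
    lo = max(0, kp - M) / M
    hi = kp / (2 * M)
    return lo, hi


def _check_pair(M: int, kp: int, cP: int) -> None:
    if not (0 <= kp <= 2 * M):
        raise FeasibilityError(f"copy count {kp} outside [0, {2 * M}]")
    if cP < max(0, kp - M) or 2 * cP > kp:
        raise FeasibilityError(
            f"homozygote count {cP} infeasible for copy count {kp} (M={M}): "
            f"require max(0, kp-M) <= cP <= kp/2"
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Marginal description of a finite diploid population.

    Parameters are stored as integer counts: ``allele_copies[j]`` copies of
    allele ``j`` (summing to ``2M``) and ``homozygotes[j]`` individuals
    homozygous for allele ``j``.
    """

    M: int
    allele_copies: tuple[int, ...]
    homozygotes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.M < 1:
            raise FeasibilityError("population size M must be >= 1")
        if len(self.allele_copies) < 2:
            raise FeasibilityError("need at least two alleles")
        if len(self.allele_copies) != len(self.homozygotes):
            raise FeasibilityError("allele_copies and homozygotes differ in length")
        if sum(self.allele_copies) != 2 * self.M:
            raise FeasibilityError(
                f"allele copies sum to {sum(self.allele_copies)}, expected {2 * self.M}"
            )
        if sum(self.homozygotes) > self.M:
            raise FeasibilityError("homozygote counts exceed population size")
        for kp, cP in zip(self.allele_copies, self.homozygotes):
            _check_pair(self.M, kp, cP)

    @classmethod
    def from_freqs(
        cls,
        M: int,
        allele_freqs: Sequence[float],
        homozygote_freqs: Sequence[float],
    ) -> "PopulationSpec":
        copies = tuple(as_copy_count(p, M) for p in allele_freqs)
        homs = tuple(as_homozygote_count(P, M) for P in homozygote_freqs)
        return cls(M=M, allele_copies=copies, homozygotes=homs)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_copies)

    @property
    def allele_freqs(self) -> np.ndarray:
        return np.asarray(self.allele_copies, dtype=float) / (2 * self.M)

    @property
    def homozygote_freqs(self) -> np.ndarray:
        return np.asarray(self.homozygotes, dtype=float) / self.M


@dataclass(frozen=True)
class SampleObservation:
    """A without-replacement sample of N individuals, summarised for one
    focal allele by the observed copy count ``k_obs`` (0..2N) and optionally
    by the genotype-class counts (x2 homozygotes, x1 heterozygotes, x0
    non-carriers)."""

    N: int
    k_obs: int
    x2: int | None = None
    x1: int | None = None
    x0: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise FeasibilityError("sample size N must be >= 1")
        if not 0 <= self.k_obs <= 2 * self.N:
            raise FeasibilityError(f"k_obs={self.k_obs} outside [0, {2 * self.N}]")
        counts = (self.x2, self.x1, self.x0)
        if any(c is not None for c in counts):
            if any(c is None for c in counts):
                raise FeasibilityError("give all of x2, x1, x0 or none")
            if min(counts) < 0 or sum(counts) != self.N:
                raise FeasibilityError("genotype counts must be >= 0 and sum to N")
            if 2 * self.x2 + self.x1 != self.k_obs:
                raise FeasibilityError("2*x2 + x1 must equal k_obs")

    @property
    def p_hat(self) -> float:
        """Observed sample allele frequency k_obs / (2N)."""
        return self.k_obs / (2 * self.N)


class Scenario(enum.Enum):
    """Assumed relation between allele frequency and homozygosity.

    HWE:      P = p**2  (Hardy-Weinberg equilibrium)
    MIN_HOM:  P = max(0, 2p - 1)  (minimum possible homozygosity)
    MAX_HOM:  P = p  (maximum possible homozygosity; no heterozygotes)
    UNKNOWN_HOM: P unconstrained within the feasibility bounds
    """

    HWE = "hwe"
    MIN_HOM = "minhom"
    MAX_HOM = "maxhom"
    UNKNOWN_HOM = "unknown"

    @classmethod
    def parse(cls, value: "Scenario | str") -> "Scenario":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise FeasibilityError(f"unknown scenario {value!r}") from None


@dataclass(frozen=True)
class ScenarioGrid:
    """The feasible (p, P) pairs hypothesizable under a scenario, stored as
    integer (copy count, homozygote count) pairs sorted by copy count."""

    scenario: Scenario
    M: int
    kp: np.ndarray = field(repr=False)  # copy counts, shape (n,)
    cP: np.ndarray = field(repr=False)  # homozygote counts, shape (n,)

    def __len__(self) -> int:
        return len(self.kp)

    @property
    def p_values(self) -> np.ndarray:
        return self.kp / (2 * self.M)

    @property
    def P_values(self) -> np.ndarray:
        return self.cP / self.M

    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.p_values, self.P_values))


def scenario_grid(
    scenario: Scenario | str,
    M: int,
    rule: Callable[[float], float] | None = None,
) -> ScenarioGrid:
    """Enumerate the feasible (p, P) lattice pairs for a scenario.

    HWE keeps only allele frequencies for which the implied homozygote count
    ``M*p**2`` is itself an integer (for M=1000 that is the 11 frequencies
    0, 0.1, ..., 1; for general M the set can be irregular).  MIN_HOM admits
    every p on the 1/(2M) lattice (2M+1 values), MAX_HOM every p on the 1/M
    lattice (M+1 values).  UNKNOWN_HOM enumerates every feasible (p, P)
    pair; for M=1000 that is 1,002,001 pairs.

    A user-supplied ``rule`` (p -> P) replaces the scenario's relation:
    every p on the 1/(2M) lattice whose rule(P) lands on the 1/M lattice
    within feasibility bounds is kept.
    """
    if M < 1:
        raise FeasibilityError("M must be >= 1")

    if rule is not None:
        kps, cPs = [], []
        for k in range(2 * M + 1):
            P = rule(k / (2 * M))
            c = M * P
            ci = int(round(c))
            if abs(c - ci) > _LATTICE_TOL:
                continue
            if ci < max(0, k - M) or 2 * ci > k:
                continue
            kps.append(k)
            cPs.append(ci)
        if not kps:
            raise FeasibilityError("homozygosity rule admits no feasible pair")
        return ScenarioGrid(
            Scenario.parse(scenario) if scenario is not None else Scenario.UNKNOWN_HOM,
            M,
            np.asarray(kps, dtype=np.int64),
            np.asarray(cPs, dtype=np.int64),
        )

    scenario = Scenario.parse(scenario)
    if scenario is Scenario.HWE:
        # need M*p^2 = kp^2/(4M) integral as well as kp integral
        kps = [k for k in range(2 * M + 1) if (k * k) % (4 * M) == 0]
        cPs = [(k * k) // (4 * M) for k in kps]
    elif scenario is Scenario.MIN_HOM:
        kps = list(range(2 * M + 1))
        cPs = [max(0, k - M) for k in kps]
    elif scenario is Scenario.MAX_HOM:
        kps = [2 * t for t in range(M + 1)]
        cPs = list(range(M + 1))
    elif scenario is Scenario.UNKNOWN_HOM:
        kps, cPs = [], []
        for k in range(2 * M + 1):
            lo, hi = max(0, k - M), k // 2
            kps.extend([k] * (hi - lo + 1))
            cPs.extend(range(lo, hi + 1))
    else:  # pragma: no cover
        raise FeasibilityError(f"unknown scenario {scenario!r}")

    return ScenarioGrid(
        scenario, M, np.asarray(kps, dtype=np.int64), np.asarray(cPs, dtype=np.int64)
    )


def feasible_p_range(
    M: int, N: int, k_obs: int, n_alleles: int = 2
) -> tuple[float, float]:
    """Range of population allele frequencies consistent with the sample.

    The population must hold at least the ``k_obs`` focal copies seen in the
    sample, and at least the ``2N - k_obs`` non-focal copies, so
    ``k_obs/(2M) <= p <= 1 - (2N - k_obs)/(2M)``.  Both endpoints lie on the
    1/(2M) lattice and are attainable.
    """
    if not 1 <= N <= M:
        raise FeasibilityError(f"need 1 <= N <= M, got N={N}, M={M}")
    if not 0 <= k_obs <= 2 * N:
        raise FeasibilityError(f"k_obs={k_obs} outside [0, {2 * N}]")
    if n_alleles < 2:
        raise FeasibilityError("need at least two alleles")
    return k_obs / (2 * M), 1.0 - (2 * N - k_obs) / (2 * M)
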