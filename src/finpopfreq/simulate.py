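"""Explicit finite populations and without-replacement sampling.

This is the empirical counterpart of the analytic machinery: a population
is materialised as a list of M genotypes realising requested allele and
homozygote frequencies, samples are drawn uniformly without replacement,
and confidence-interval coverage is estimated by replication.  All
randomness flows through mandatory seeds (no global state), so every run
is bit-reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FeasibilityError
from .population import PopulationSpec, SampleObservation
from .intervals import ci_known_homozygosity
from .population import Scenario

__all__ = ["ExplicitPopulation", "build_population", "draw_sample",
           "empirical_coverage"]


@dataclass(frozen=True)
class ExplicitPopulation:
    """M individuals as (allele, allele) genotype rows (unordered pairs
    stored sorted), together with the marginal spec they realise."""

    genotypes: np.ndarray = field(repr=False)  # shape (M, 2), int alleles
    spec: PopulationSpec

    @property
    def M(self) -> int:
        return len(self.genotypes)


def _derive_spec(genotypes: np.ndarray, n_alleles: int) -> PopulationSpec:
    M = len(genotypes)
    copies = np.bincount(genotypes.ravel(), minlength=n_alleles)
    hom = np.bincount(
        genotypes[genotypes[:, 0] == genotypes[:, 1], 0], minlength=n_alleles
    )
    return PopulationSpec(M, tuple(int(c) for c in copies), tuple(int(h) for h in hom))


def build_population(
    M: int,
    allele_freqs: Sequence[float],
    homozygote_freqs: Sequence[float],
    seed: int | None = None,
) -> ExplicitPopulation:
    """Construct genotypes realising the requested per-allele marginals.

    Homozygotes of each allele are placed first; leftover single copies are
    paired into heterozygotes greedily (most-remaining allele with
    second-most, ties broken by allele index), which succeeds whenever the
    marginals are jointly feasible.  The seed only shuffles the row order
    -- the derived marginals, and hence the focal-allele sampling
    distribution, do not depend on it.
    """
    spec = PopulationSpec.from_freqs(M, allele_freqs, homozygote_freqs)
    rows: list[tuple[int, int]] = []
    singles: list[tuple[int, int]] = []  # (-count, allele) heap
    for j, (kp, cP) in enumerate(zip(spec.allele_copies, spec.homozygotes)):
        rows.extend([(j, j)] * cP)
        het = kp - 2 * cP
        if het:
            singles.append((-het, j))
    heapq.heapify(singles)
    while len(singles) > 1:
        c1, a1 = heapq.heappop(singles)
        c2, a2 = heapq.heappop(singles)
        rows.append((min(a1, a2), max(a1, a2)))
        if c1 + 1:
            heapq.heappush(singles, (c1 + 1, a1))
        if c2 + 1:
            heapq.heappush(singles, (c2 + 1, a2))
    if singles:
        raise FeasibilityError(
            f"cannot pair remaining copies of allele {singles[0][1]} into "
            "heterozygotes; marginals are jointly infeasible"
        )
    genotypes = np.array(rows, dtype=np.int64)
    if seed is not None:
        genotypes = genotypes[np.random.default_rng(seed).permutation(M)]
    derived = _derive_spec(genotypes, spec.n_alleles)
    assert derived == spec, "round-trip marginal mismatch"
    return ExplicitPopulation(genotypes=genotypes, spec=spec)


def draw_sample(
    pop: ExplicitPopulation, N: int, seed: int, focal: int = 0
) -> SampleObservation:
    """Uniform without-replacement draw of N individuals; the observation
    summarises genotype classes for the focal allele."""
    if N > pop.M:
        raise FeasibilityError(f"sample size {N} exceeds population size {pop.M}")
    rng = np.random.default_rng(seed)
    rows = pop.genotypes[rng.choice(pop.M, size=N, replace=False)]
    carries = (rows == focal).sum(axis=1)
    x2 = int(np.sum(carries == 2))
    x1 = int(np.sum(carries == 1))
    return SampleObservation(N=N, k_obs=2 * x2 + x1, x2=x2, x1=x1, x0=N - x2 - x1)


def empirical_coverage(
    M: int,
    N: int,
    p: float,
    P: float,
    alpha: float,
    replicates: int,
    seed: int,
    scenario: Scenario | str = Scenario.HWE,
) -> float:
    """Monte-Carlo estimate of CI coverage at a true (p, P).

    Builds a two-allele population with the requested focal marginals,
    draws ``replicates`` independent samples, and reports the fraction of
    runs whose scenario-rule CI contains the true p.  Relaxed-alpha
    intervals count as covering only if they actually contain p.
    """
    pop = build_population(M, [p, 1 - p], [P, 1 - 2 * p + P])
    seeds = np.random.SeedSequence(seed).generate_state(replicates)
    ci_cache: dict[int, tuple[float, float]] = {}
    hits = 0
    for s in seeds:
        k_obs = draw_sample(pop, N, int(s)).k_obs
        if k_obs not in ci_cache:
            ci = ci_known_homozygosity(M, N, k_obs, alpha, scenario=scenario)
            ci_cache[k_obs] = (ci.lower, ci.upper)
        lo, hi = ci_cache[k_obs]
        hits += lo - 1e-12 <= p <= hi + 1e-12
    return hits / replicates
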