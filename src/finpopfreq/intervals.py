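"""Acceptance regions and test-inversion confidence sets for allele
frequencies.

For a hypothesized pair (p, P) the equal-tail level-``alpha`` acceptance
region for the copy count K is the interval [k_lo, k_hi] where k_lo is the
largest integer with Pr(K < k_lo) <= alpha/2 and k_hi the smallest with
Pr(K > k_hi) <= alpha/2 (tail ties broken non-strictly, i.e. toward wider
regions, preserving the >= 1-alpha coverage guarantee).  Membership of an
observation in that interval reduces to two tail statistics:

    k_obs in [k_lo, k_hi]  <=>  Pr(K <= k_obs) > alpha/2
                                and Pr(K >= k_obs) > alpha/2.

The confidence set for p given an observed copy count is the set of
feasible lattice p (under a known homozygosity rule mapping p to P) whose
acceptance region contains k_obs; the reported interval is the hull
[min, max] of that set -- conservative when the accepted set has interior
gaps.  When no candidate accepts k_obs, alpha is halved until one does and
the relaxed level is reported as ``effective_alpha``.  When the
homozygosity is unknown, the same inversion over every feasible (p, P)
lattice pair yields a joint confidence region whose coordinate projections
give intervals for p and P.

Two literature baselines are provided for comparison: the Clopper-Pearson
binomial interval (the infinite-population Hardy-Weinberg limit of the
method) and the Wald-type interval with the plug-in variance estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import FeasibilityError, ImpossibleObservationError
from .population import (
    Scenario,
    ScenarioGrid,
    as_copy_count,
    as_homozygote_count,
    feasible_p_range,
    scenario_grid,
)
from .distribution import _class_counts_int, _pmf_array

__all__ = [
    "AcceptanceRegion",
    "ConfidenceInterval",
    "ConfidenceRegion",
    "acceptance_region",
    "ci_known_homozygosity",
    "cr_unknown_homozygosity",
    "relax_alpha",
    "clopper_pearson_ci",
    "weir_wald_ci",
]

#: non-strict tail comparisons: a tail equal to alpha/2 (up to rounding)
#: keeps the boundary point inside the acceptance region
_TIE_EPS = 1e-12

_MAX_HALVINGS = 4000  # termination guard; unreachable for feasible inputs


@dataclass(frozen=True)
class AcceptanceRegion:
    """Equal-tail acceptance interval [k_lo, k_hi] for one (p, P) pair."""

    M: int
    N: int
    p: float
    P: float
    alpha: float
    k_lo: int
    k_hi: int

    def contains(self, k_obs: int) -> bool:
        return self.k_lo <= k_obs <= self.k_hi


@dataclass(frozen=True)
class ConfidenceInterval:
    """Interval [lower, upper] for an allele frequency at nominal level
    1 - alpha; ``effective_alpha`` records any tail relaxation and
    ``accepted_p`` the (possibly non-contiguous) accepted lattice values."""

    lower: float
    upper: float
    alpha: float
    effective_alpha: float
    accepted_p: np.ndarray | None = field(default=None, repr=False)
    method: str = "test-inversion"

    @property
    def length(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ConfidenceRegion:
    """Joint confidence set of (p, P) pairs with coordinate projections."""

    M: int
    N: int
    k_obs: int
    alpha: float
    effective_alpha: float
    accepted_kp: np.ndarray = field(repr=False)
    accepted_cP: np.ndarray = field(repr=False)

    @property
    def p_interval(self) -> tuple[float, float]:
        return (
            float(self.accepted_kp.min()) / (2 * self.M),
            float(self.accepted_kp.max()) / (2 * self.M),
        )

    @property
    def hom_interval(self) -> tuple[float, float]:
        return (
            float(self.accepted_cP.min()) / self.M,
            float(self.accepted_cP.max()) / self.M,
        )

    def __len__(self) -> int:
        return len(self.accepted_kp)


def _region_from_pmf(pmf: np.ndarray, alpha: float) -> tuple[int, int]:
    """Equal-tail (k_lo, k_hi) from a pmf vector over 0..2N."""
    a2 = alpha / 2 + _TIE_EPS
    low = np.concatenate(([0.0], np.cumsum(pmf)[:-1]))  # low[k] = P(K < k)
    up = np.concatenate((np.cumsum(pmf[::-1])[::-1][1:], [0.0]))  # P(K > k)
    k_lo = int(np.sum(low <= a2)) - 1
    k_hi = len(pmf) - int(np.sum(up <= a2))
    return k_lo, k_hi


def acceptance_region(
    M: int, N: int, p: float, P: float, alpha: float
) -> AcceptanceRegion:
    """Equal-tail acceptance region for the copy count under (p, P)."""
    if not 0 < alpha < 1:
        raise FeasibilityError("alpha must lie in (0, 1)")
    kp = as_copy_count(p, M)
    cP = as_homozygote_count(P, M)
    pmf = _pmf_array(M, N, kp, cP)
    k_lo, k_hi = _region_from_pmf(pmf, alpha)
    return AcceptanceRegion(M, N, kp / (2 * M), cP / M, alpha, k_lo, k_hi)


# ---------------------------------------------------------------------------
# grid inversion engine (shared with the study-design sweeps)
# ---------------------------------------------------------------------------


class _GridInversion:
    """Tail statistics for every (p, P) pair of a grid at fixed (M, N).

    Acceptance tests at any level, for any observed copy count, become
    vectorised comparisons against the cached tail matrices; the study
    design sweeps reuse one instance across all 2N+1 observations.
    """

    def __init__(self, M: int, N: int, grid: ScenarioGrid):
        self.M, self.N = M, N
        self.kp = grid.kp
        self.cP = grid.cP
        n = len(grid.kp)
        pmfs = np.empty((n, 2 * N + 1))
        for i in range(n):
            pmfs[i] = _pmf_array(M, N, int(self.kp[i]), int(self.cP[i]))
        # le[:, k] = P(K <= k); ge[:, k] = P(K >= k)
        self.le = np.cumsum(pmfs, axis=1)
        self.ge = np.cumsum(pmfs[:, ::-1], axis=1)[:, ::-1]
        # interval support limits: as alpha -> 0 the acceptance region grows
        # to [k_min, k_max], the extreme copy counts achievable in a sample
        m2, m1, m0 = self.kp * 0 + self.cP, self.kp - 2 * self.cP, M - self.kp + self.cP
        x2m = np.minimum(m2, N)
        self.k_max = 2 * x2m + np.minimum(m1, N - x2m)
        x0m = np.minimum(m0, N)
        x1m = np.minimum(m1, N - x0m)
        self.k_min = 2 * (N - x0m - x1m) + x1m

    def feasible(self, k_obs: int) -> np.ndarray:
        """Population must contain the sampled copies of both kinds."""
        return (self.kp >= k_obs) & (2 * self.M - self.kp >= 2 * self.N - k_obs)

    def attainable(self, k_obs: int) -> np.ndarray:
        return (self.k_min <= k_obs) & (k_obs <= self.k_max)

    def accepted(self, k_obs: int, alpha: float) -> np.ndarray:
        a2 = alpha / 2 + _TIE_EPS
        return (self.le[:, k_obs] > a2) & (self.ge[:, k_obs] > a2)

    def regions(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        a2 = alpha / 2 + _TIE_EPS
        # P(K < k) = le[:, k-1]; largest k with lower tail <= a2
        low = np.concatenate(
            (np.zeros((len(self.kp), 1)), self.le[:, :-1]), axis=1
        )
        up = np.concatenate(
            (self.ge[:, 1:], np.zeros((len(self.kp), 1))), axis=1
        )
        k_lo = np.sum(low <= a2, axis=1) - 1
        k_hi = 2 * self.N + 1 - np.sum(up <= a2, axis=1)
        return k_lo, k_hi

    def invert(self, k_obs: int, alpha: float) -> tuple[np.ndarray, float]:
        """Accepted-candidate mask and effective alpha after relaxation."""
        feas = self.feasible(k_obs)
        acc = feas & self.accepted(k_obs, alpha)
        eff = alpha
        if not acc.any():
            if not (feas & self.attainable(k_obs)).any():
                raise ImpossibleObservationError(
                    f"k_obs={k_obs} has zero probability under every feasible "
                    f"candidate (M={self.M}, N={self.N})"
                )
            for _ in range(_MAX_HALVINGS):
                eff /= 2
                acc = feas & self.accepted(k_obs, eff)
                if acc.any():
                    break
            else:  # pragma: no cover
                raise ImpossibleObservationError("alpha relaxation did not converge")
        return acc, eff


def _grid_for(
    M: int,
    scenario: Scenario | str | None,
    rule: Callable[[float], float] | None,
) -> ScenarioGrid:
    if rule is not None:
        return scenario_grid(scenario, M, rule=rule)
    if scenario is None:
        raise FeasibilityError("give a scenario or a homozygosity rule")
    return scenario_grid(scenario, M)


def ci_known_homozygosity(
    M: int,
    N: int,
    k_obs: int,
    alpha: float = 0.05,
    scenario: Scenario | str | None = None,
    rule: Callable[[float], float] | None = None,
) -> ConfidenceInterval:
    """Test-inversion confidence interval for p under a known homozygosity
    rule (a scenario, or an explicit map p -> P)."""
    if not 0 < alpha < 1:
        raise FeasibilityError("alpha must lie in (0, 1)")
    feasible_p_range(M, N, k_obs)  # validates M, N, k_obs
    grid = _grid_for(M, scenario, rule)
    inv = _GridInversion(M, N, grid)
    acc, eff = inv.invert(k_obs, alpha)
    sel = inv.kp[acc]
    return ConfidenceInterval(
        lower=float(sel.min()) / (2 * M),
        upper=float(sel.max()) / (2 * M),
        alpha=alpha,
        effective_alpha=eff,
        accepted_p=np.sort(sel) / (2 * M),
    )


def cr_unknown_homozygosity(
    M: int, N: int, k_obs: int, alpha: float = 0.05
) -> ConfidenceRegion:
    """Joint confidence region over every feasible (p, P) pair, for use when
    nothing is assumed about the homozygosity."""
    if not 0 < alpha < 1:
        raise FeasibilityError("alpha must lie in (0, 1)")
    feasible_p_range(M, N, k_obs)
    kps, cPs, tails = [], [], []
    for kp in range(k_obs, 2 * M - (2 * N - k_obs) + 1):
        for cP in range(max(0, kp - M), kp // 2 + 1):
            pmf = _pmf_array(M, N, kp, cP)
            le = float(np.sum(pmf[: k_obs + 1]))
            ge = float(np.sum(pmf[k_obs:]))
            kps.append(kp)
            cPs.append(cP)
            tails.append(min(le, ge))
    kps = np.asarray(kps)
    cPs = np.asarray(cPs)
    tails = np.asarray(tails)

    eff = alpha
    acc = tails > alpha / 2 + _TIE_EPS
    if not acc.any():
        if tails.max() <= 0.0:
            raise ImpossibleObservationError(
                f"k_obs={k_obs} impossible under every feasible (p, P) pair"
            )
        for _ in range(_MAX_HALVINGS):
            eff /= 2
            acc = tails > eff / 2 + _TIE_EPS
            if acc.any():
                break
    return ConfidenceRegion(
        M=M,
        N=N,
        k_obs=k_obs,
        alpha=alpha,
        effective_alpha=eff,
        accepted_kp=kps[acc],
        accepted_cP=cPs[acc],
    )


def relax_alpha(
    M: int,
    N: int,
    k_obs: int,
    alpha: float,
    candidates: Iterable[tuple[float, float]],
) -> float:
    """Halve alpha until at least one candidate (p, P) accepts k_obs.

    Returns alpha unchanged when the accepted set is already non-empty;
    raises :class:`ImpossibleObservationError` when k_obs lies outside the
    limiting acceptance interval of every candidate.
    """
    cand = [(as_copy_count(p, M), as_homozygote_count(P, M)) for p, P in candidates]
    if not cand:
        raise ImpossibleObservationError("empty candidate set")
    tails = []
    for kp, cP in cand:
        pmf = _pmf_array(M, N, kp, cP)
        tails.append(min(float(np.sum(pmf[: k_obs + 1])), float(np.sum(pmf[k_obs:]))))
    best = max(tails)
    if best <= 0.0:
        raise ImpossibleObservationError(
            f"k_obs={k_obs} has zero probability under every candidate"
        )
    eff = alpha
    for _ in range(_MAX_HALVINGS):
        if best > eff / 2 + _TIE_EPS:
            return eff
        eff /= 2
    raise ImpossibleObservationError("alpha relaxation did not converge")


# ---------------------------------------------------------------------------
# literature baselines
# ---------------------------------------------------------------------------


def clopper_pearson_ci(
    k_obs: int, n_trials: int, alpha: float = 0.05
) -> ConfidenceInterval:
    """Exact equal-tail binomial interval (Clopper-Pearson) for k_obs
    successes in n_trials Bernoulli draws; the infinite-population
    Hardy-Weinberg limit of the test-inversion interval (n_trials = 2N)."""
    if not 0 <= k_obs <= n_trials:
        raise FeasibilityError("k_obs outside [0, n_trials]")
    lower = 0.0 if k_obs == 0 else float(
        stats.beta.ppf(alpha / 2, k_obs, n_trials - k_obs + 1)
    )
    upper = 1.0 if k_obs == n_trials else float(
        stats.beta.ppf(1 - alpha / 2, k_obs + 1, n_trials - k_obs)
    )
    return ConfidenceInterval(lower, upper, alpha, alpha, method="clopper-pearson")


def weir_wald_ci(
    k_obs: int, N: int, sample_hom_freq: float, alpha: float = 0.05
) -> ConfidenceInterval:
    """Wald-type interval p_hat +/- z * s_hat with the plug-in standard
    error from the infinite-population variance (p_hat(1-p_hat) +
    (P_hat - p_hat^2)) / (2N), truncated to [0, 1].

    A large-sample approximation only; degenerates to a point at the
    boundaries (the documented pathology of Wald intervals).
    """
    p_hat = k_obs / (2 * N)
    P_hat = sample_hom_freq
    var = (p_hat * (1 - p_hat) + (P_hat - p_hat**2)) / (2 * N)
    s = math.sqrt(max(var, 0.0))
    z = float(stats.norm.ppf(1 - alpha / 2))
    return ConfidenceInterval(
        max(0.0, p_hat - z * s), min(1.0, p_hat + z * s), alpha, alpha, method="wald"
    )
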