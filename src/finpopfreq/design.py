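"""Sample-size design: worst-case confidence-interval lengths and the
minimum sample size achieving a target accuracy.

For a scenario (a known homozygosity rule) and a sample size N, the
worst-case accuracy is the maximum test-inversion CI length over every
observed copy count k_obs = 0..2N.  The minimum sample size for a target
length t is the smallest N whose worst-case length is <= t; it is located
by a coarse upward scan in steps of 10 followed by a downward walk in steps
of 1 (so the result does not depend on the scan origin, and no monotonicity
of the worst-case length in N is assumed).  A target of 0.2 (0.1) bounds
the absolute error of the midpoint estimate by 0.1 (0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import FeasibilityError
from .population import Scenario, scenario_grid
from .intervals import _GridInversion

__all__ = [
    "DesignSweepResult",
    "ci_length_profile",
    "max_ci_length",
    "min_sample_size",
    "m_sweep",
]


@dataclass(frozen=True)
class DesignSweepResult:
    """Outcome of a minimum-sample-size search."""

    M: int
    scenario: Scenario
    alpha: float
    target_length: float
    N_min: int
    maxlen_at_Nmin: float
    maxlen_below: float | None  # worst-case length at N_min - 1 (None if N_min == 1)
    reached: bool  # False when even a census cannot meet the target


def ci_length_profile(
    M: int,
    N: int,
    scenario: Scenario | str,
    alpha: float = 0.05,
    rule: Callable[[float], float] | None = None,
) -> np.ndarray:
    """CI length for every observed copy count k_obs = 0..2N.

    Entries are NaN for observations impossible under every feasible
    candidate of the scenario grid.  Acceptance tails for each grid pair are
    computed once and reused across all observations.
    """
    grid = scenario_grid(scenario, M, rule=rule)
    inv = _GridInversion(M, N, grid)
    lengths = np.full(2 * N + 1, np.nan)
    for k in range(2 * N + 1):
        feas = inv.feasible(k)
        if not (feas & inv.attainable(k)).any():
            continue
        acc, _ = inv.invert(k, alpha)
        sel = inv.kp[acc]
        lengths[k] = (sel.max() - sel.min()) / (2 * M)
    return lengths


def max_ci_length(
    M: int,
    N: int,
    scenario: Scenario | str,
    alpha: float = 0.05,
    rule: Callable[[float], float] | None = None,
) -> float:
    """Worst-case CI length over all attainable observations at sample size N."""
    return float(np.nanmax(ci_length_profile(M, N, scenario, alpha, rule=rule)))


def min_sample_size(
    M: int,
    scenario: Scenario | str,
    alpha: float = 0.05,
    target_length: float = 0.2,
    start: int = 10,
    step: int = 10,
) -> DesignSweepResult:
    """Smallest N whose worst-case CI length meets the target.

    Scans N = start, start+step, ... until the target is met, then walks
    down one N at a time while it still is; the returned N_min therefore
    satisfies maxlen(N_min) <= target and maxlen(N_min - 1) > target.
    """
    if not 0 < target_length < 1:
        raise FeasibilityError("target_length must lie in (0, 1)")
    scenario = Scenario.parse(scenario)
    cache: dict[int, float] = {}

    def maxlen(N: int) -> float:
        if N not in cache:
            cache[N] = max_ci_length(M, N, scenario, alpha)
        return cache[N]

    N = min(max(1, start), M)
    while maxlen(N) > target_length:
        if N >= M:
            return DesignSweepResult(
                M, scenario, alpha, target_length, M, maxlen(M), None, reached=False
            )
        N = min(N + step, M)
    while N > 1 and maxlen(N - 1) <= target_length:
        N -= 1
    below = maxlen(N - 1) if N > 1 else None
    return DesignSweepResult(
        M, scenario, alpha, target_length, N, maxlen(N), below, reached=True
    )


def m_sweep(
    N: int,
    scenario: Scenario | str,
    alpha: float = 0.05,
    M_list: Sequence[int] = (100, 250, 500, 750, 1000, 2500, 5000, 7500, 10000),
) -> dict[int, float]:
    """Worst-case CI length at fixed N across a range of population sizes.

    The default grid spans small to very large populations; N defaults are
    the caller's responsibility (N must not exceed the smallest M).
    """
    if N > min(M_list):
        raise FeasibilityError("N exceeds the smallest population size in M_list")
    return {int(M): max_ci_length(int(M), N, scenario, alpha) for M in M_list}
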