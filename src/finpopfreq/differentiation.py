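"""Jost's D between two populations and a confidence interval for it.

Jost's D measures allelic differentiation on the effective-number scale.
For two demes with allele-frequency vectors u and v (equal weights),

    H_S = 1 - (sum_j u_j^2 + sum_j v_j^2) / 2          (mean within-deme
                                                        expected heterozygosity)
    H_T = 1 - sum_j ((u_j + v_j) / 2)^2                 (pooled heterozygosity)
    D   = 2 * (H_T - H_S) / (1 - H_S)

D is 0 for identical frequency vectors and 1 for fully disjoint allele
sets.  Sampling uncertainty is propagated by optimisation: given a joint
confidence box for each population's allele frequencies (a Cartesian
product of per-allele intervals with a Bonferroni joint level), the
confidence interval for D is [min D, max D] over all frequency vectors in
the two boxes.  Frequencies of the listed alleles are free variables with
the remainder 1 - sum assigned to an implied final allele, so the only
extra constraint is sum <= 1 per population.  D is non-convex in the
frequencies, so the constrained optimiser is restarted from a fixed-seed
Sobol sample of the box plus its corners.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .errors import FeasibilityError
from .intervals import ConfidenceInterval

__all__ = ["JointBox", "DifferentiationResult", "jost_d",
           "bonferroni_joint_region", "d_interval"]

_SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class JointBox:
    """Cartesian product of per-allele confidence intervals for one
    population, with joint coverage >= ``joint_level`` by Bonferroni."""

    intervals: tuple[tuple[float, float], ...]
    joint_level: float

    def __post_init__(self) -> None:
        for lo, hi in self.intervals:
            if not (0.0 <= lo <= hi <= 1.0):
                raise FeasibilityError(f"interval ({lo}, {hi}) invalid")
        lo_sum = sum(lo for lo, _ in self.intervals)
        if lo_sum > 1.0 + _SIMPLEX_TOL:
            raise FeasibilityError(
                "box lies entirely outside the frequency simplex "
                f"(lower bounds sum to {lo_sum:.4f} > 1)"
            )

    @property
    def n_listed(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class DifferentiationResult:
    """Jost's D point value with optimisation-based confidence bounds."""

    D_lo: float
    D_hi: float
    joint_level: float
    D_point: float | None = None
    n_starts: int = 0
    max_constraint_violation: float = 0.0
    argmin: np.ndarray | None = field(default=None, repr=False)
    argmax: np.ndarray | None = field(default=None, repr=False)


def _check_simplex(freqs: np.ndarray, name: str) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or len(freqs) < 2:
        raise FeasibilityError(f"{name} must be a vector of >= 2 frequencies")
    if freqs.min() < -_SIMPLEX_TOL or abs(freqs.sum() - 1.0) > _SIMPLEX_TOL:
        raise FeasibilityError(f"{name} is not a frequency vector (non-negative, sum 1)")
    return np.clip(freqs, 0.0, 1.0)


def jost_d(freqs1: Sequence[float], freqs2: Sequence[float]) -> float:
    """Jost's D between two populations from full allele-frequency vectors."""
    u = _check_simplex(np.asarray(freqs1, float), "freqs1")
    v = _check_simplex(np.asarray(freqs2, float), "freqs2")
    if len(u) != len(v):
        raise FeasibilityError("frequency vectors must have equal length")
    return float(_jost_d_raw(u, v))


def _jost_d_raw(u: np.ndarray, v: np.ndarray) -> float:
    hs = 1.0 - (np.dot(u, u) + np.dot(v, v)) / 2.0
    ht = 1.0 - np.dot((u + v) / 2.0, (u + v) / 2.0)
    if hs >= 1.0 - 1e-15:  # unreachable with finitely many alleles
        return 0.0
    return 2.0 * (ht - hs) / (1.0 - hs)


def bonferroni_joint_region(
    cis: Sequence[ConfidenceInterval], joint_alpha: float
) -> JointBox:
    """Combine per-allele CIs into a joint box at level 1 - joint_alpha.

    The per-allele CIs must all have been computed at level
    1 - joint_alpha / n (uniform Bonferroni split); the final allele's
    frequency is implied by the listed ones and gets no interval of its own.
    """
    n = len(cis)
    if n == 0:
        raise FeasibilityError("need at least one per-allele interval")
    expected = joint_alpha / n
    for ci in cis:
        if abs(ci.alpha - expected) > 1e-9:
            raise FeasibilityError(
                f"per-allele alpha {ci.alpha} inconsistent with joint alpha "
                f"{joint_alpha} over {n} alleles (expected {expected})"
            )
    return JointBox(
        intervals=tuple((ci.lower, ci.upper) for ci in cis),
        joint_level=1.0 - sum(ci.alpha for ci in cis),
    )


def _full_vector(x: np.ndarray) -> np.ndarray:
    """Append the implied final allele frequency 1 - sum(x)."""
    return np.concatenate([x, [max(0.0, 1.0 - x.sum())]])


def d_interval(
    box1: JointBox,
    box2: JointBox,
    freqs1: Sequence[float] | None = None,
    freqs2: Sequence[float] | None = None,
    n_starts: int = 32,
    seed: int = 0,
) -> DifferentiationResult:
    """Constrained min/max of Jost's D over two joint confidence boxes.

    Each population's listed allele frequencies range over its box subject
    to sum <= 1; the remainder is the implied final allele.  Observed
    frequency vectors, when given, yield the point estimate ``D_point``.
    SLSQP is restarted from a Sobol sample of the joint box (fixed seed)
    plus every box corner up to 256.
    """
    if box1.n_listed != box2.n_listed:
        raise FeasibilityError("boxes must cover the same allele set")
    d1 = box1.n_listed
    lo = np.array([iv[0] for iv in box1.intervals + box2.intervals])
    hi = np.array([iv[1] for iv in box1.intervals + box2.intervals])
    bounds = list(zip(lo, hi))
    constraints = [
        {"type": "ineq", "fun": lambda x: 1.0 - x[:d1].sum()},
        {"type": "ineq", "fun": lambda x: 1.0 - x[d1:].sum()},
    ]

    def objective(x: np.ndarray) -> float:
        return _jost_d_raw(_full_vector(x[:d1]), _full_vector(x[d1:]))

    def clip_feasible(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, lo, hi)
        for sl in (slice(0, d1), slice(d1, None)):
            excess = x[sl].sum() - 1.0
            if excess > 0:  # shed the excess without leaving the box
                room = x[sl] - lo[sl]
                x[sl] -= excess * room / room.sum()
        return x

    sampler = qmc.Sobol(d=2 * d1, scramble=True, seed=seed)
    starts = [clip_feasible(lo + s * (hi - lo))
              for s in sampler.random(max(n_starts, 1))]
    if 2 ** (2 * d1) <= 256:
        for corner in itertools.product(*[(l, h) for l, h in bounds]):
            starts.append(clip_feasible(np.array(corner)))

    best = {1: (np.inf, None), -1: (np.inf, None)}
    worst_viol = 0.0
    for sign in (1, -1):
        for x0 in starts:
            res = optimize.minimize(
                lambda x: sign * objective(x),
                x0,
                method="SLSQP",
                bounds=bounds,
                constraints=constraints,
                options={"maxiter": 200, "ftol": 1e-12},
            )
            viol = max(0.0, res.x[:d1].sum() - 1.0, res.x[d1:].sum() - 1.0)
            if viol > 1e-8:
                worst_viol = max(worst_viol, viol)
                continue
            if res.fun < best[sign][0]:
                best[sign] = (res.fun, res.x.copy())
    if best[1][1] is None or best[-1][1] is None:
        raise FeasibilityError("no feasible point found in the joint boxes")

    D_lo, D_hi = float(best[1][0]), float(-best[-1][0])
    D_point = None
    if freqs1 is not None and freqs2 is not None:
        D_point = jost_d(freqs1, freqs2)
    return DifferentiationResult(
        D_lo=max(0.0, D_lo),
        D_hi=min(1.0, D_hi),
        joint_level=1.0 - ((1.0 - box1.joint_level) + (1.0 - box2.joint_level)),
        D_point=D_point,
        n_starts=len(starts),
        max_constraint_violation=worst_viol,
        argmin=best[1][1],
        argmax=best[-1][1],
    )
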