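"""Exact sampling distribution of an allele's copy count in a finite sample.

Partition the population by genotype class for the focal allele: ``m2 = M*P``
homozygotes, ``m1 = 2M(p - P)`` heterozygous carriers and
``m0 = M - m2 - m1`` non-carriers.  Drawing ``N`` individuals without
replacement makes the sampled class counts ``(x2, x1, x0)`` multivariate
hypergeometric,

    Pr(x2, x1, x0) = C(m2, x2) C(m1, x1) C(m0, x0) / C(M, N),

and the copy count ``K = 2*x2 + x1`` inherits its pmf by summing over the
feasible ``x2`` for each ``k``:

    L(k) = max(0, k - N, ceil((k - m1)/2)),
    U(k) = min(m2, floor(k/2), m0 - N + k),
    Pr(K = k) = sum_{x2=L(k)}^{U(k)} Pr(x2, k - 2*x2, N - k + x2).

An empty range (L > U) means ``k`` is infeasible and has probability zero.
The mean of the sample frequency ``p_hat = K/(2N)`` is ``p`` and its
variance carries the finite-population correction:

    Var(p_hat) = (M - N)/(M - 1) * (p(1 - p) + (P - p^2)) / (2N),

which reduces to the classic infinite-population form as M grows.

Binomial coefficients are evaluated through a cached log-factorial table and
accumulated on the probability scale (all terms are <= 1, so no overflow);
an exact :class:`fractions.Fraction` mode is available for oracle-grade
comparisons on tiny instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import FeasibilityError
from .population import as_copy_count, as_homozygote_count

__all__ = [
    "CopyCountDistribution",
    "genotype_class_counts",
    "triple_pmf",
    "x2_bounds",
    "copy_count_pmf",
    "copy_count_mean",
    "copy_count_variance",
    "copy_count_cdf",
    "brute_force_pmf",
]

# cached log-factorials: _LOG_FACT[i] = log(i!)
_LOG_FACT = np.zeros(1)


def _log_fact(n_max: int) -> np.ndarray:
    global _LOG_FACT
    if len(_LOG_FACT) <= n_max:
        from scipy.special import gammaln

        _LOG_FACT = gammaln(np.arange(max(n_max + 1, 1024)) + 1.0)
    return _LOG_FACT


def genotype_class_counts(M: int, p: float, P: float) -> tuple[int, int, int]:
    """Integer genotype-class counts (homozygotes, heterozygous carriers,
    non-carriers) implied by the marginals (p, P)."""
    kp = as_copy_count(p, M)
    cP = as_homozygote_count(P, M)
    return _class_counts_int(M, kp, cP)


def _class_counts_int(M: int, kp: int, cP: int) -> tuple[int, int, int]:
    m2 = cP
    m1 = kp - 2 * cP
    m0 = M - kp + cP
    if m1 < 0:
        raise FeasibilityError(
            f"homozygote count {cP} exceeds half the copy count {kp} (P > p)"
        )
    if m0 < 0:
        raise FeasibilityError(
            f"homozygote count {cP} below minimum {kp - M} for copy count {kp} "
            f"(P < 2p - 1)"
        )
    return m2, m1, m0


def triple_pmf(
    x2: int, x1: int, x0: int, *, M: int, N: int, p: float, P: float
) -> float:
    """Multivariate hypergeometric probability of sampling exactly
    (x2, x1, x0) individuals from the three genotype classes."""
    if min(x2, x1, x0) < 0:
        raise FeasibilityError("genotype counts must be non-negative")
    if x2 + x1 + x0 != N:
        return 0.0
    m2, m1, m0 = genotype_class_counts(M, p, P)
    if x2 > m2 or x1 > m1 or x0 > m0:
        return 0.0
    return (
        math.comb(m2, x2) * math.comb(m1, x1) * math.comb(m0, x0) / math.comb(M, N)
    )


def x2_bounds(k: int, *, M: int, N: int, p: float, P: float) -> tuple[int, int]:
    """Integer bounds (L, U) on the number of sampled homozygotes given the
    copy count ``k``; L > U means no feasible sample achieves ``k``."""
    if not 0 <= k <= 2 * N:
        raise FeasibilityError(f"k={k} outside [0, {2 * N}]")
    m2, m1, m0 = genotype_class_counts(M, p, P)
    L = max(0, k - N, math.ceil((k - m1) / 2))
    U = min(m2, k // 2, m0 - N + k)
    return L, U


@dataclass(frozen=True)
class CopyCountDistribution:
    """Exact pmf of the focal-allele copy count K over k = 0..2N."""

    M: int
    N: int
    p: float
    P: float
    pmf: np.ndarray = field(repr=False)

    @property
    def support(self) -> np.ndarray:
        return np.arange(2 * self.N + 1)

    def cdf(self, k: int) -> float:
        if k < 0:
            return 0.0
        return float(np.sum(self.pmf[: min(k, 2 * self.N) + 1]))

    def mean_freq(self) -> float:
        """pmf-weighted mean of p_hat = K/(2N)."""
        return float(np.dot(self.support, self.pmf)) / (2 * self.N)

    def var_freq(self) -> float:
        """pmf-weighted variance of p_hat."""
        mu = float(np.dot(self.support, self.pmf))
        var_k = float(np.dot((self.support - mu) ** 2, self.pmf))
        return var_k / (2 * self.N) ** 2


def _pmf_array(M: int, N: int, kp: int, cP: int) -> np.ndarray:
    """Vectorised pmf over k = 0..2N from integer parameters."""
    m2, m1, m0 = _class_counts_int(M, kp, cP)
    lf = _log_fact(max(M, 1))

    x2_vals = np.arange(min(m2, N) + 1)
    lo = np.maximum(0, N - x2_vals - m0)
    hi = np.minimum(m1, N - x2_vals)
    keep = lo <= hi
    x2_vals, lo, hi = x2_vals[keep], lo[keep], hi[keep]
    if len(x2_vals) == 0:
        raise FeasibilityError("no feasible sample composition (should not happen)")
    counts = hi - lo + 1
    total = int(counts.sum())
    x2 = np.repeat(x2_vals, counts)
    # ragged arange over each [lo, hi] row
    row_start = np.repeat(np.cumsum(counts) - counts, counts)
    x1 = np.repeat(lo, counts) + (np.arange(total) - row_start)
    x0 = N - x2 - x1

    def lc(n, x):  # log C(n, x), inputs already feasible
        return lf[n] - lf[x] - lf[n - x]

    logp = lc(m2, x2) + lc(m1, x1) + lc(m0, x0) - (lf[M] - lf[N] - lf[M - N])
    return np.bincount(2 * x2 + x1, weights=np.exp(logp), minlength=2 * N + 1)


def _pmf_exact(M: int, N: int, kp: int, cP: int) -> list[Fraction]:
    """Exact-rational pmf via the same x2-bounds reduction."""
    m2, m1, m0 = _class_counts_int(M, kp, cP)
    denom = math.comb(M, N)
    out = []
    for k in range(2 * N + 1):
        L = max(0, k - N, math.ceil((k - m1) / 2))
        U = min(m2, k // 2, m0 - N + k)
        num = sum(
            math.comb(m2, x2) * math.comb(m1, k - 2 * x2) * math.comb(m0, N - k + x2)
            for x2 in range(L, U + 1)
        )
        out.append(Fraction(num, denom))
    return out


def copy_count_pmf(
    M: int, N: int, p: float, P: float, *, exact: bool = False
) -> CopyCountDistribution:
    """Exact sampling distribution of the focal-allele copy count.

    With ``exact=True`` the pmf is computed in rational arithmetic
    (intended for oracle comparisons on tiny instances) and returned as a
    float array alongside ``.fractions``.
    """
    if not 1 <= N <= M:
        raise FeasibilityError(f"need 1 <= N <= M, got N={N}, M={M}")
    kp = as_copy_count(p, M)
    cP = as_homozygote_count(P, M)
    if exact:
        fr = _pmf_exact(M, N, kp, cP)
        dist = CopyCountDistribution(M, N, kp / (2 * M), cP / M,
                                     np.array([float(f) for f in fr]))
        object.__setattr__(dist, "fractions", fr)
        return dist
    return CopyCountDistribution(M, N, kp / (2 * M), cP / M, _pmf_array(M, N, kp, cP))


def copy_count_mean(M: int, N: int, p: float, P: float) -> float:
    """E[p_hat]; equals p exactly (sampling is unbiased)."""
    kp = as_copy_count(p, M)
    as_homozygote_count(P, M)  # feasibility check
    return kp / (2 * M)


def copy_count_variance(M: int, N: int, p: float, P: float) -> float:
    """Var(p_hat) in closed form, with finite-population correction."""
    kp = as_copy_count(p, M)
    cP = as_homozygote_count(P, M)
    _class_counts_int(M, kp, cP)  # feasibility
    if M == 1:
        return 0.0  # census of a single individual
    p_ = kp / (2 * M)
    P_ = cP / M
    fpc = (M - N) / (M - 1)
    return fpc * (p_ * (1 - p_) + (P_ - p_ * p_)) / (2 * N)


def copy_count_cdf(M: int, N: int, p: float, P: float, k: int) -> float:
    """Pr(K <= k)."""
    return copy_count_pmf(M, N, p, P).cdf(k)


def brute_force_pmf(M: int, N: int, p: float, P: float) -> CopyCountDistribution:
    """Enumeration oracle: tabulate K over every feasible genotype-class
    triple with directly counted multivariate-hypergeometric weights.

    Independent of :func:`x2_bounds`; exact rational arithmetic.  Guarded to
    tiny instances (C(M, N) <= 1e6).
    """
    if math.comb(M, N) > 10**6:
        raise FeasibilityError("instance too large for brute-force enumeration")
    kp = as_copy_count(p, M)
    cP = as_homozygote_count(P, M)
    m2, m1, m0 = _class_counts_int(M, kp, cP)
    denom = math.comb(M, N)
    acc = [Fraction(0)] * (2 * N + 1)
    for x2, x1 in itertools.product(range(N + 1), range(N + 1)):
        x0 = N - x2 - x1
        if x0 < 0 or x2 > m2 or x1 > m1 or x0 > m0:
            continue
        w = Fraction(
            math.comb(m2, x2) * math.comb(m1, x1) * math.comb(m0, x0), denom
        )
        acc[2 * x2 + x1] += w
    dist = CopyCountDistribution(M, N, kp / (2 * M), cP / M,
                                 np.array([float(f) for f in acc]))
    object.__setattr__(dist, "fractions", acc)
    return dist
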