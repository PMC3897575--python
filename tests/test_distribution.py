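"""Exact copy-count distribution against enumeration oracles and closed forms."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from finpopfreq import (
    FeasibilityError,
    brute_force_pmf,
    copy_count_cdf,
    copy_count_mean,
    copy_count_pmf,
    copy_count_variance,
    genotype_class_counts,
    scenario_grid,
    triple_pmf,
    x2_bounds,
)
from conftest import all_feasible_pairs


class TestGenotypeClassCounts:
    @pytest.mark.parametrize(
        "M, p, P, expected",
        [
            (1000, 0.5, 0.25, (250, 500, 250)),  # Hardy-Weinberg proportions
            (4, 0.5, 0.25, (1, 2, 1)),
            (1000, 0.7, 0.4, (400, 600, 0)),     # minimum homozygosity, p > 1/2
        ],
    )
    def test_examples(self, M, p, P, expected):
        assert genotype_class_counts(M, p, P) == expected

    def test_infeasible_marginals_rejected(self):
        with pytest.raises(FeasibilityError):
            genotype_class_counts(1000, 0.7, 0.2)  # below 2p - 1
        with pytest.raises(FeasibilityError):
            genotype_class_counts(10, 0.55, 0.23)  # M*P not an integer

    @given(st.integers(1, 80), st.data())
    def test_classes_recover_allele_count(self, M, data):
        kp = data.draw(st.integers(0, 2 * M))
        cP = data.draw(st.integers(max(0, kp - M), kp // 2))
        m2, m1, m0 = genotype_class_counts(M, kp / (2 * M), cP / M)
        assert m2 + m1 + m0 == M
        assert 2 * m2 + m1 == kp
        assert min(m2, m1, m0) >= 0


class TestTriplePmf:
    def test_two_heterozygotes_from_hwe_quartet(self):
        # {AA, Aa, Aa, aa}: of the C(4,2)=6 pairs, exactly one is both hets
        assert triple_pmf(0, 2, 0, M=4, N=2, p=0.5, P=0.25) == pytest.approx(1 / 6)

    def test_census_is_deterministic(self):
        assert triple_pmf(1, 2, 1, M=4, N=4, p=0.5, P=0.25) == pytest.approx(1.0)
        assert triple_pmf(2, 1, 1, M=4, N=4, p=0.5, P=0.25) == 0.0

    def test_normalisation_over_feasible_triples(self):
        total = sum(
            triple_pmf(x2, x1, 3 - x2 - x1, M=6, N=3, p=1 / 3, P=1 / 6)
            for x2 in range(4)
            for x1 in range(4 - x2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestX2Bounds:
    def test_quartet_example(self):
        assert x2_bounds(2, M=4, N=2, p=0.5, P=0.25) == (0, 1)

    def test_no_copies_forces_zero_homozygotes(self):
        # feasible variant: enough non-carriers to fill the sample
        assert x2_bounds(0, M=8, N=2, p=0.5, P=0.25) == (0, 0)

    @pytest.mark.parametrize("M", [4, 6, 9, 12])
    def test_emptiness_iff_no_feasible_triple(self, M):
        for kp, cP in all_feasible_pairs(M):
            for N in range(1, M + 1):
                m2, m1, m0 = genotype_class_counts(M, kp / (2 * M), cP / M)
                for k in range(2 * N + 1):
                    L, U = x2_bounds(k, M=M, N=N, p=kp / (2 * M), P=cP / M)
                    exists = any(
                        x2 <= m2 and k - 2 * x2 <= m1
                        and 0 <= N - k + x2 <= m0 and k - 2 * x2 >= 0
                        for x2 in range(N + 1)
                    )
                    assert (L <= U) == exists


class TestPmfAgainstOracle:
    def test_hwe_quartet_pmf(self):
        dist = copy_count_pmf(4, 2, 0.5, 0.25)
        np.testing.assert_allclose(dist.pmf, [0, 1 / 3, 1 / 3, 1 / 3, 0], atol=1e-15)

    @pytest.mark.parametrize("M", list(range(2, 13)))
    def test_exact_equality_with_enumeration_all_feasible_pairs(self, M):
        """Formula-with-bounds pmf equals direct enumeration, as rationals."""
        for kp, cP in all_feasible_pairs(M):
            for N in range(1, M + 1):
                a = copy_count_pmf(M, N, kp / (2 * M), cP / M, exact=True)
                b = brute_force_pmf(M, N, kp / (2 * M), cP / M)
                assert a.fractions == b.fractions, (M, N, kp, cP)

    def test_float_pmf_close_to_exact(self):
        for kp, cP in all_feasible_pairs(10):
            a = copy_count_pmf(10, 5, kp / 20, cP / 10)
            b = brute_force_pmf(10, 5, kp / 20, cP / 10)
            np.testing.assert_allclose(a.pmf, b.pmf, atol=1e-13)

    def test_census_and_fixed_allele_are_point_masses(self):
        census = copy_count_pmf(8, 8, 0.75, 0.5)
        assert census.pmf[12] == pytest.approx(1.0)
        absent = copy_count_pmf(50, 10, 0.0, 0.0)
        assert absent.pmf[0] == pytest.approx(1.0)


class TestMoments:
    @pytest.mark.parametrize("scenario", ["hwe", "minhom", "maxhom"])
    @pytest.mark.parametrize("N", [5, 25, 50])
    def test_mean_and_variance_closed_forms_across_grids(self, scenario, N):
        M = 50
        for kp, cP in zip(*[scenario_grid(scenario, M).kp,
                            scenario_grid(scenario, M).cP]):
            p, P = kp / (2 * M), cP / M
            dist = copy_count_pmf(M, N, p, P)
            assert abs(dist.pmf.sum() - 1.0) < 1e-12
            assert abs(dist.mean_freq() - p) < 1e-12  # unbiasedness
            assert abs(dist.var_freq() - copy_count_variance(M, N, p, P)) < 1e-12

    def test_census_variance_zero(self):
        assert copy_count_variance(40, 40, 0.3, 0.1) == 0.0
        assert copy_count_mean(40, 40, 0.3, 0.1) == pytest.approx(0.3)

    def test_variance_increases_with_homozygosity(self):
        M, N = 60, 12
        for kp in (30, 60, 84):
            p = kp / (2 * M)
            lo = max(0, kp - M) / M
            hi = (kp // 2) / M
            assert copy_count_variance(M, N, p, hi) >= copy_count_variance(
                M, N, p, lo
            )

    def test_quartet_variance(self):
        # enumerated pmf (0, 1/3, 1/3, 1/3, 0) has Var(p_hat) = 1/24
        assert copy_count_variance(4, 2, 0.5, 0.25) == pytest.approx(1 / 24)
        assert copy_count_pmf(4, 2, 0.5, 0.25).var_freq() == pytest.approx(1 / 24)


class TestCdf:
    def test_quartet_cdf(self):
        assert copy_count_cdf(4, 2, 0.5, 0.25, 2) == pytest.approx(2 / 3)

    def test_cdf_telescopes_to_pmf(self):
        dist = copy_count_pmf(20, 6, 0.4, 0.2)
        for k in range(13):
            assert dist.cdf(k) - dist.cdf(k - 1) == pytest.approx(
                dist.pmf[k], abs=1e-12
            )
        assert dist.cdf(12) == pytest.approx(1.0, abs=1e-12)


class TestLimitsAndSymmetry:
    @pytest.mark.parametrize("p", [0.1, 0.5])
    def test_binomial_limit_at_hwe(self, p):
        from scipy.stats import binom

        M, N = 10**5, 20
        dist = copy_count_pmf(M, N, p, p * p)
        tv = 0.5 * np.abs(dist.pmf - binom.pmf(np.arange(2 * N + 1), 2 * N, p)).sum()
        assert tv < 1e-3

    @pytest.mark.parametrize("M", [7, 12])
    def test_allele_relabelling_symmetry(self, M):
        # swapping the focal allele with its complement mirrors the pmf:
        # pmf(k; p, P) = pmf(2N - k; 1 - p, 1 - 2p + P)
        N = 5
        for kp, cP in all_feasible_pairs(M):
            a = copy_count_pmf(M, N, kp / (2 * M), cP / M)
            q_kp = 2 * M - kp
            q_cP = M - kp + cP
            b = copy_count_pmf(M, N, q_kp / (2 * M), q_cP / M)
            np.testing.assert_allclose(a.pmf, b.pmf[::-1], atol=1e-13)
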