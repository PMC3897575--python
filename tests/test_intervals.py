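"""Acceptance regions, test-inversion confidence sets, relaxation and baselines."""

import numpy as np
import pytest

from finpopfreq import (
    FeasibilityError,
    ImpossibleObservationError,
    acceptance_region,
    brute_force_pmf,
    ci_known_homozygosity,
    clopper_pearson_ci,
    copy_count_pmf,
    cr_unknown_homozygosity,
    relax_alpha,
    scenario_grid,
    weir_wald_ci,
)
from conftest import all_feasible_pairs


def oracle_accepts(M, N, kp, cP, k_obs, alpha):
    """Membership check recomputed from the enumeration-oracle pmf."""
    fr = brute_force_pmf(M, N, kp / (2 * M), cP / M).fractions
    le = sum(fr[: k_obs + 1])
    ge = sum(fr[k_obs:])
    return le > alpha / 2 and ge > alpha / 2


class TestAcceptanceRegion:
    def test_degenerate_distribution(self):
        reg = acceptance_region(50, 10, 0.0, 0.0, 0.05)
        assert (reg.k_lo, reg.k_hi) == (0, 0)

    def test_hwe_quartet_region(self):
        reg = acceptance_region(4, 2, 0.5, 0.25, 0.05)
        assert (reg.k_lo, reg.k_hi) == (1, 3)
        assert reg.contains(2) and not reg.contains(0)

    def test_guaranteed_coverage_across_maxhom_grid(self):
        M, N, alpha = 100, 20, 0.05
        grid = scenario_grid("maxhom", M)
        for kp, cP in zip(grid.kp, grid.cP):
            p, P = kp / (2 * M), cP / M
            reg = acceptance_region(M, N, p, P, alpha)
            mass = copy_count_pmf(M, N, p, P).pmf[reg.k_lo : reg.k_hi + 1].sum()
            assert mass >= 1 - alpha - 1e-12


class TestCiKnownHomozygosity:
    def test_census_pins_frequency(self):
        ci = ci_known_homozygosity(12, 12, 18, 0.05, scenario="maxhom")
        assert ci.lower == ci.upper == pytest.approx(0.75)

    @pytest.mark.parametrize("k_obs", range(9))
    def test_accepted_set_matches_oracle_scan(self, k_obs):
        """M=12, N=4, maximum homozygosity: compare against a scan that
        tests every lattice p using the enumeration-oracle pmf."""
        M, N, alpha = 12, 4, 0.05
        grid = scenario_grid("maxhom", M)
        expected = [
            int(kp)
            for kp, cP in zip(grid.kp, grid.cP)
            if kp >= k_obs and 2 * M - kp >= 2 * N - k_obs
            and oracle_accepts(M, N, int(kp), int(cP), k_obs, alpha)
        ]
        ci = ci_known_homozygosity(M, N, k_obs, alpha, scenario="maxhom")
        got = sorted(round(p * 2 * M) for p in ci.accepted_p)
        assert got == expected

    def test_interval_is_hull_of_accepted_set(self):
        ci = ci_known_homozygosity(100, 20, 20, 0.05, scenario="minhom")
        assert ci.lower == pytest.approx(ci.accepted_p.min())
        assert ci.upper == pytest.approx(ci.accepted_p.max())

    def test_length_shrinks_as_alpha_grows(self):
        lengths = [
            ci_known_homozygosity(100, 20, 10, a, scenario="maxhom").length
            for a in (0.01, 0.05, 0.1, 0.2)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(lengths, lengths[1:]))

    def test_maxhom_at_least_as_long_as_hwe(self):
        # matched (M, N, k_obs); p-hat = 0.5 lies on both grids
        M, N, k = 100, 20, 20
        hwe = ci_known_homozygosity(M, N, k, 0.05, scenario="hwe")
        mx = ci_known_homozygosity(M, N, k, 0.05, scenario="maxhom")
        assert mx.length >= hwe.length - 1e-12

    @pytest.mark.parametrize("scen", ["hwe", "minhom", "maxhom"])
    def test_exact_coverage_guarantee(self, scen):
        """Sum_k pmf(k | truth) * 1[p_true in CI(k)] >= 1 - alpha for every
        grid truth (the defining property of test inversion)."""
        M, N, alpha = 50, 10, 0.05
        grid = scenario_grid(scen, M)
        cis = {
            k: set(np.round(ci_known_homozygosity(
                M, N, k, alpha, scenario=scen).accepted_p * 2 * M).astype(int))
            for k in range(2 * N + 1)
        }
        for kp, cP in zip(grid.kp, grid.cP):
            p, P = kp / (2 * M), cP / M
            pmf = copy_count_pmf(M, N, p, P).pmf
            cover = sum(
                pmf[k] for k in range(2 * N + 1)
                if pmf[k] > 0 and int(kp) in cis[k]
            )
            assert cover >= 1 - alpha - 1e-10, (scen, p)


class TestConfidenceRegion:
    @pytest.mark.parametrize("k_obs", range(7))
    def test_accepted_pairs_match_exhaustive_oracle(self, k_obs):
        M, N, alpha = 6, 3, 0.05
        expected = {
            (kp, cP)
            for kp, cP in all_feasible_pairs(M)
            if kp >= k_obs and 2 * M - kp >= 2 * N - k_obs
            and oracle_accepts(M, N, kp, cP, k_obs, alpha)
        }
        cr = cr_unknown_homozygosity(M, N, k_obs, alpha)
        got = set(zip(cr.accepted_kp.tolist(), cr.accepted_cP.tolist()))
        assert got == expected

    def test_region_coverage_for_every_truth(self):
        M, N, alpha = 30, 10, 0.05
        regions = {
            k: set(
                zip(*(lambda c: (c.accepted_kp.tolist(), c.accepted_cP.tolist()))(
                    cr_unknown_homozygosity(M, N, k, alpha)
                ))
            )
            for k in range(2 * N + 1)
        }
        for kp, cP in all_feasible_pairs(M):
            pmf = copy_count_pmf(M, N, kp / (2 * M), cP / M).pmf
            cover = sum(
                pmf[k] for k in range(2 * N + 1) if (kp, cP) in regions[k]
            )
            assert cover >= 1 - alpha - 1e-10, (kp, cP)

    def test_p_projection_close_to_maxhom_interval(self):
        # unknown homozygosity is well approximated by the P = p worst case
        M, N, k = 200, 20, 20
        cr = cr_unknown_homozygosity(M, N, k, 0.05)
        ci = ci_known_homozygosity(M, N, k, 0.05, scenario="maxhom")
        lo, hi = cr.p_interval
        assert abs((hi - lo) - ci.length) <= 0.05


class TestRelaxAlpha:
    def test_noop_when_accepted_set_nonempty(self):
        grid = scenario_grid("hwe", 100)
        cand = list(zip(grid.p_values, grid.P_values))
        assert relax_alpha(100, 20, 20, 0.05, cand) == 0.05

    def test_far_tail_observation_forces_relaxation(self):
        """A lone candidate at p = 1/2 assigns probability ~1e-12 to
        k_obs = 2N; the observation is attainable yet rejected at 0.05,
        so alpha must be halved until the region stretches out to it."""
        M, N, k_obs, alpha = 100, 10, 20, 0.05
        cand = [(0.5, 0.25)]
        eff = relax_alpha(M, N, k_obs, alpha, cand)
        assert eff < alpha
        tail = copy_count_pmf(M, N, 0.5, 0.25).pmf[k_obs:].sum()
        assert 0 < tail <= 0.05 / 2 and tail > eff / 2
        # idempotence: the relaxed level is a fixed point
        assert relax_alpha(M, N, k_obs, eff, cand) == eff

    def test_ci_records_relaxed_alpha_for_sparse_rule(self):
        # rule admits only p = 1/2 (elsewhere M * rule(p) is off-lattice)
        M, N, k_obs = 100, 10, 20
        rule = lambda p: 0.25 if p == 0.5 else 0.0051
        ci = ci_known_homozygosity(M, N, k_obs, 0.05, rule=rule)
        assert ci.effective_alpha < 0.05
        assert list(ci.accepted_p) == [0.5]
        assert ci.lower == ci.upper == 0.5

    def test_impossible_observation_raises(self):
        with pytest.raises(ImpossibleObservationError):
            # single candidate with all copies fixed: k_obs = 1 unreachable
            relax_alpha(10, 5, 1, 0.05, [(0.0, 0.0)])


class TestBaselines:
    def test_clopper_pearson_boundary_cases(self):
        assert clopper_pearson_ci(0, 40).lower == 0.0
        assert clopper_pearson_ci(40, 40).upper == 1.0

    def test_inversion_matches_clopper_pearson_in_binomial_limit(self):
        """HWE with M >> N: endpoints agree within one grid step."""
        M, N, k = 10**5, 25, 20
        step = 0.01  # HWE lattice spacing at M = 1e5
        ti = ci_known_homozygosity(M, N, k, 0.05, scenario="hwe")
        cp = clopper_pearson_ci(k, 2 * N, 0.05)
        assert abs(ti.lower - cp.lower) <= step + 1e-9
        assert abs(ti.upper - cp.upper) <= step + 1e-9

    def test_wald_degenerates_at_boundary(self):
        ci = weir_wald_ci(0, 30, 0.0)
        assert ci.lower == ci.upper == 0.0

    def test_wald_symmetric_before_truncation(self):
        ci = weir_wald_ci(30, 50, 0.12)
        p_hat = 30 / 100
        assert (p_hat - ci.lower) == pytest.approx(ci.upper - p_hat, abs=1e-12)

    def test_wald_close_to_inversion_for_large_samples(self):
        # fine HWE lattice (step 0.002) so grid quantisation is negligible
        M, N = 250_000, 200
        k = N  # p_hat = 0.5
        ti = ci_known_homozygosity(M, N, k, 0.05, scenario="hwe")
        wald = weir_wald_ci(k, N, 0.25)  # HWE plug-in homozygosity
        assert abs(wald.length - ti.length) / ti.length < 0.1

    def test_alpha_validation(self):
        with pytest.raises(FeasibilityError):
            ci_known_homozygosity(10, 5, 3, 1.5, scenario="hwe")
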