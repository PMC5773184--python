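"""Variance decomposition, bootstrap CIs, scrambling tests, level comparisons."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phasevar as pv
from phasevar.circular import angular_variance
from phasevar.episodes import Episode
from phasevar.synthetic import wrapped_sigma2
from phasevar.variability import (
    abs_ddphi_summary,
    bilateral_test,
    compare_levels,
    cycle_to_cycle_variance,
    outlier_screen,
    phase_period_correlation,
    population_variance,
    repetition_test,
)


def make_episode(dphi, side="L", coord="peristaltic"):
    dphi = np.asarray(dphi, dtype=float)
    return Episode(side, coord, 0, dphi.size - 1, np.arange(dphi.size), dphi)


class TestCycleToCycleVariance:
    def test_noise_free_episode_has_zero_variance(self):
        summ = cycle_to_cycle_variance(make_episode([0.2] * 20))
        assert summ.var_phase == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery(self, rng):
        sigma = np.sqrt(wrapped_sigma2(0.001))
        vals = [
            cycle_to_cycle_variance(make_episode(rng.normal(0.2, sigma, 40) % 1)).var_phase
            for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(0.001, rel=0.1)

    def test_seven_cycle_episode_is_computed(self):
        assert cycle_to_cycle_variance(make_episode([0.2] * 7)) is not None

    def test_short_episode_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            assert cycle_to_cycle_variance(make_episode([0.2] * 5)) is None


class TestPopulationVariance:
    def test_identical_means_give_zero_and_degenerate_ci(self, rng):
        pv_res = population_variance([0.2] * 10, n_boot=200, rng=rng)
        assert pv_res.var_phase == pytest.approx(0.0, abs=1e-12)
        assert pv_res.ci_lo == pytest.approx(0.0, abs=1e-12)
        assert pv_res.ci_hi == pytest.approx(0.0, abs=1e-12)

    def test_point_estimate_is_angular_variance(self, rng):
        means = rng.uniform(0.1, 0.3, 25)
        res = population_variance(means, n_boot=100, rng=rng)
        assert res.var_phase == pytest.approx(angular_variance(means), rel=1e-12)
        assert res.ci_lo <= res.var_phase <= res.ci_hi

    def test_requires_three_animals(self, rng):
        with pytest.raises(ValueError):
            population_variance([0.1, 0.2], rng=rng)

    def test_separated_populations_have_disjoint_cis(self, rng):
        # two levels generated with variances 0.004 vs 0.002 at large n:
        # the bootstrap CIs must not overlap
        n = 400
        hi = rng.normal(0.23, np.sqrt(wrapped_sigma2(0.004)), n) % 1
        lo = rng.normal(0.13, np.sqrt(wrapped_sigma2(0.002)), n) % 1
        res_hi = population_variance(hi, n_boot=2000, rng=rng)
        res_lo = population_variance(lo, n_boot=2000, rng=rng)
        assert res_hi.var_phase > res_lo.var_phase
        assert res_hi.ci_lo > res_lo.ci_hi

    def test_percentile_method_available(self, rng):
        means = rng.uniform(0.1, 0.3, 25)
        res = population_variance(means, n_boot=500, rng=rng, method="percentile")
        assert res.method == "percentile"
        assert res.ci_lo <= res.var_phase <= res.ci_hi


class TestScramblingTests:
    def test_identical_pairs_give_midway_p(self, rng):
        vals = np.full(10, 0.2)
        res = repetition_test(vals, vals, n_scramble=500, rng=rng)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_lower == pytest.approx(0.5)

    def test_strong_animal_identity_gives_tiny_p(self, rng):
        m1, m2 = pv.generate_switch_cycle_means(
            24, sd_animal=0.06, sd_episode=0.01, rng=rng
        )
        res = repetition_test(m1, m2, n_scramble=2000, rng=rng)
        assert res.p_lower < 0.005

    def test_mirror_symmetric_sides_give_small_p(self, rng):
        left = rng.normal(0.2, 0.06, 20) % 1
        res = bilateral_test(left, left, n_scramble=2000, rng=rng)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_lower < 0.01

    def test_independent_sides_not_significant(self, rng):
        # bilateral variance equal to population variance: scrambling
        # cannot distinguish the true pairing
        ps = []
        for _ in range(20):
            left = rng.normal(0.2, 0.06, 26) % 1
            right = rng.normal(0.2, 0.06, 26) % 1
            ps.append(bilateral_test(left, right, n_scramble=500, rng=rng).p_lower)
        assert np.median(ps) > 0.1

    def test_missing_animals_dropped(self, rng):
        m1 = np.array([0.1, 0.2, 0.15, 0.18, 0.22, np.nan, 0.2])
        m2 = np.array([0.1, 0.2, 0.15, 0.18, 0.22, 0.3, 0.21])
        with pytest.warns(UserWarning, match="dropped"):
            res = repetition_test(m1, m2, n_scramble=200, rng=rng)
        assert res.n_pairs == 6

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            bilateral_test([0.1], [0.1], rng=rng)

    def test_pairing_schemes_agree_under_structure(self, rng):
        m1, m2 = pv.generate_switch_cycle_means(24, sd_animal=0.06, sd_episode=0.01, rng=rng)
        p_der = repetition_test(m1, m2, n_scramble=2000, rng=rng, pairing="derangement")
        p_ind = repetition_test(m1, m2, n_scramble=2000, rng=rng, pairing="independent")
        assert p_der.p_lower < 0.005 and p_ind.p_lower < 0.005


class TestCompareLevels:
    def test_identical_paired_groups(self):
        a = [0.1, 0.2, 0.3, 0.25]
        res = compare_levels(a, a, paired=True)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_distinct_level_means_detected(self, rng):
        # CPG-like mean 0.23 vs motor-like 0.13 at moderate spread
        a = rng.normal(0.23, 0.06, 60) % 1
        b = rng.normal(0.13, 0.045, 60) % 1
        res = compare_levels(a, b, paired=False)
        assert res.p < 0.001
        assert res.mean_a > res.mean_b

    def test_wrap_straddling_groups_handled(self, rng):
        # values on both sides of zero must not split into 0 and 1 clusters
        a = (rng.normal(0.0, 0.02, 30)) % 1
        b = (rng.normal(0.05, 0.02, 30)) % 1
        res = compare_levels(a, b)
        assert abs(res.mean_a) < 0.1 and res.mean_b < 0.15
        assert res.p < 0.001

    def test_rotation_leaves_p_unchanged(self, rng):
        a = rng.normal(0.2, 0.03, 20) % 1
        b = rng.normal(0.25, 0.03, 20) % 1
        r1 = compare_levels(a, b)
        r2 = compare_levels((a + 0.4) % 1, (b + 0.4) % 1)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_levels([0.1, 0.2], [0.1, 0.2, 0.3], paired=True)


class TestSummaries:
    def test_abs_ddphi_of_zeros(self):
        assert abs_ddphi_summary([0.0, 0.0]) == 0.0

    def test_abs_ddphi_symmetric_pair(self):
        assert abs_ddphi_summary([-0.1, 0.1]) == pytest.approx(0.1)

    def test_bilateral_vs_repetition_ratio(self, rng):
        # bilateral differences drawn with 2.5x the repetition spread show
        # the corresponding ratio of mean absolute differences
        rep = rng.normal(0.0, 0.02, 4000)
        bil = rng.normal(0.0, 0.05, 4000)
        ratio = abs_ddphi_summary(bil) / abs_ddphi_summary(rep)
        assert 2.0 < ratio < 3.0

    @given(st.lists(st.floats(-0.5, 0.5), min_size=1, max_size=20))
    def test_abs_ddphi_nonnegative(self, vals):
        assert abs_ddphi_summary(vals) >= 0.0


class TestOutlierScreen:
    def test_tight_cluster_unflagged(self):
        assert not outlier_screen([0.1, 0.11, 0.12, 0.13, 0.12]).any()

    def test_far_point_flagged(self):
        flags = outlier_screen([0.1, 0.11, 0.12, 0.13, 0.12, 0.45])
        assert flags.tolist() == [False] * 5 + [True]

    def test_three_values_rejected(self):
        with pytest.raises(ValueError):
            outlier_screen([0.1, 0.2, 0.3])


class TestPhasePeriodCorrelation:
    def test_independent_inputs_uncorrelated(self, rng):
        r, p = phase_period_correlation(rng.uniform(0.1, 0.3, 200), rng.normal(8, 1, 200))
        assert abs(r) < 0.2
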