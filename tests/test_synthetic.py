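"""Generator correctness: reproducibility, calibration, clamp and traces."""

import numpy as np
import pytest

import phasevar as pv
from phasevar.circular import angular_variance
from phasevar.synthetic import wrapped_sigma2


def measure_dphi(rec, side, level):
    a = rec.animal
    ref = pv.group_bursts(pv.SpikeTrain("r", rec.spikes[f"a{a:03d}_{side}_{level}_front"]))
    tgt = pv.group_bursts(pv.SpikeTrain("t", rec.spikes[f"a{a:03d}_{side}_{level}_rear"]))
    return pv.pair_cycles(ref, tgt, side=side, level=level)


class TestGeneratePopulation:
    def test_noise_free_measured_dphi_equals_target(self, noise_free_config):
        cfg = noise_free_config
        cfg.dphi_mean = {(lv, co): 0.2 for lv in ("cpg", "motor") for co in
                         ("peristaltic", "synchronous")}
        recordings, truth = pv.generate_population(cfg)
        for rec in recordings:
            for side in "LR":
                for level in ("cpg", "motor"):
                    ps = measure_dphi(rec, side, level)
                    assert ps.skipped.size == 0
                    np.testing.assert_allclose(ps.dphi, 0.2, atol=1e-9)

    def test_noise_free_recovery_is_cycle_exact(self, noise_free_config):
        recordings, truth = pv.generate_population(noise_free_config)
        rec = recordings[0]
        ps = measure_dphi(rec, "L", "cpg")
        tcd = truth.cycle_dphi
        tl = tcd[(tcd.animal == rec.animal) & (tcd.side == "L") & (tcd.level == "cpg")]
        lookup = dict(zip(ps.cycles.tolist(), ps.dphi.tolist()))
        for row in tl.itertuples():
            assert row.cycle in lookup
            assert lookup[row.cycle] == pytest.approx(row.dphi, abs=1e-9)

    def test_cycle_variance_matches_wrapped_normal_relation(self):
        # brute-force oracle: angular variance of a large wrapped-normal
        # sample equals the calibration target
        target = 0.002
        sigma = np.sqrt(wrapped_sigma2(target))
        rng = np.random.default_rng(0)
        sample = rng.normal(0.2, sigma, 200_000) % 1.0
        assert angular_variance(sample) == pytest.approx(target, rel=0.02)
        cfg = pv.GeneratorConfig(
            n_animals=3,
            seed=2,
            var_population=0.0,
            var_bilateral=0.0,
            var_repetition=0.0,
            var_cycle=target,
        )
        # one common target phase, so per-cycle noise is the only dispersion
        cfg.dphi_mean = {(lv, co): 0.3 for lv in ("cpg", "motor") for co in
                         ("peristaltic", "synchronous")}
        recordings, truth = pv.generate_population(cfg)
        per_episode = []
        for rec in recordings:
            ps = measure_dphi(rec, "L", "cpg")
            per_episode.append(angular_variance(ps.dphi))
        assert np.mean(per_episode) == pytest.approx(target, rel=0.25)

    def test_episode_lengths_within_configured_range(self, small_population):
        _, _, truth = small_population
        assert truth.episodes["n_cycles"].between(15, 60).all()

    def test_generation_is_bit_reproducible(self):
        cfg = pv.GeneratorConfig(n_animals=3, seed=42)
        rec_a, truth_a = pv.generate_population(cfg)
        rec_b, truth_b = pv.generate_population(pv.GeneratorConfig(n_animals=3, seed=42))
        for ra, rb in zip(rec_a, rec_b):
            for ch in ra.spikes:
                np.testing.assert_array_equal(ra.spikes[ch], rb.spikes[ch])
        assert truth_a.cycle_dphi.equals(truth_b.cycle_dphi)

    def test_sides_always_in_opposite_coordinations(self, small_population):
        _, _, truth = small_population
        piv = truth.episodes.pivot_table(
            index=["animal", "episode"], columns="side", values="coordination",
            aggfunc="first",
        )
        assert (piv["L"] != piv["R"]).all()

    def test_inconsistent_variance_components_rejected(self):
        cfg = pv.GeneratorConfig(
            var_population=0.001, var_bilateral=0.005, var_repetition=0.003
        )
        with pytest.raises(ValueError, match="inconsistent variance"):
            cfg.validate()

    def test_excessive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            wrapped_sigma2(0.06)  # > 2 rad^2

    def test_invalid_config_fields_rejected(self):
        with pytest.raises(ValueError):
            pv.GeneratorConfig(period_cv=0.5).validate()
        with pytest.raises(ValueError):
            pv.GeneratorConfig(cycles_per_episode=(10, 5)).validate()


class TestGenerateConstrictionTraces:
    def test_noise_free_mrr_at_target_offsets(self):
        cfg = pv.GeneratorConfig(seed=1, trace_snr=np.inf, period_cv=0.0, var_cycle=0.0)
        cfg.beat_dphi_mean = {"peristaltic": 0.25, "synchronous": 0.02}
        traces, truth = pv.generate_constriction_traces(cfg, n_cycles=10)
        front = truth[(truth.side == "L") & (truth.segment == "front")]["mrr_time"].to_numpy()
        rear = truth[(truth.side == "L") & (truth.segment == "rear")]["mrr_time"].to_numpy()
        np.testing.assert_allclose(rear - front[:-1], 0.25 * 8.0, atol=1e-9)
        t, y = traces["L_rear"]
        events = pv.mrr_phase_markers(t, y, smoothing=1)
        dt = t[1] - t[0]
        for e in rear:
            if t[0] + 1 < e < t[-1] - 5:
                assert np.min(np.abs(events - e)) <= dt + 1e-9

    def test_zero_amplitude_rejected(self):
        cfg = pv.GeneratorConfig(trace_amplitude=0.0)
        with pytest.raises(ValueError, match="no constriction"):
            pv.generate_constriction_traces(cfg)

    def test_undersampled_rise_rejected(self):
        cfg = pv.GeneratorConfig(trace_fs=2.0)
        with pytest.raises(ValueError, match="sampling rate too low"):
            pv.generate_constriction_traces(cfg)


class TestGenerateClampTrace:
    def test_single_spike_peak_follows_ohms_law(self):
        t, cur = pv.generate_clamp_trace(
            {"u": np.array([0.1])}, {"u": 2.0}, holding_mV=-42.0, reversal_mV=-62.0
        )
        # 2 nS * 20 mV = 40 pA at the alpha-function peak
        assert np.max(cur) == pytest.approx(40.0, rel=1e-3)

    def test_zero_conductance_gives_flat_trace(self):
        t, cur = pv.generate_clamp_trace(
            {"u": np.array([0.1, 0.5])}, {"u": 0.0}, noise_sd_pA=0.0
        )
        np.testing.assert_allclose(cur, 0.0)

    def test_overlapping_kernels_sum(self):
        t, one = pv.generate_clamp_trace({"u": np.array([0.1])}, {"u": 1.0})
        t2, two = pv.generate_clamp_trace(
            {"u": np.array([0.1, 0.1 + 1e-9])}, {"u": 1.0}, duration_s=t[-1] + 1e-6
        )
        assert np.max(two) == pytest.approx(2 * np.max(one), rel=1e-3)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pv.generate_clamp_trace({"u": np.array([0.1])}, {"u": -1.0})

    def test_holding_at_reversal_rejected(self):
        with pytest.raises(ValueError):
            pv.generate_clamp_trace(
                {"u": np.array([0.1])}, {"u": 1.0}, holding_mV=-62.0, reversal_mV=-62.0
            )


class TestSwitchCycleMeans:
    def test_null_case_is_exchangeable(self, rng):
        m1, m2 = pv.generate_switch_cycle_means(
            2000, sd_animal=0.0, sd_episode=0.05, rng=rng
        )
        # both cycles share mean and spread; the difference carries twice
        # the episode variance (no animal-level coupling to cancel)
        assert angular_variance(m1) == pytest.approx(angular_variance(m2), rel=0.2)
        d = pv.circular_mean_difference(m1, m2)
        expected = angular_variance(m1) + angular_variance(m2)
        assert angular_variance(d) == pytest.approx(expected, rel=0.15)

    def test_animal_structure_shrinks_differences(self, rng):
        m1, m2 = pv.generate_switch_cycle_means(
            2000, sd_animal=0.06, sd_episode=0.01, rng=rng
        )
        d = pv.circular_mean_difference(m1, m2)
        # within-animal differences reflect only the episode component
        assert angular_variance(d) < 0.2 * angular_variance(m1)
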