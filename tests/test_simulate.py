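"""The synthetic-data generator: samplers, noise models, grid, determinism."""

import numpy as np
import pytest

import sigcat as sc
from sigcat.simulate import (
    DEFAULT_AMPLITUDES,
    ConfigurationError,
    is_classifiable_as_truth,
)


class TestSigmoidalSampler:
    def test_distribution_moments(self):
        rng = np.random.default_rng(1)
        draws = [sc.sample_sigmoidal_params(rng) for _ in range(10_000)]
        i_max = np.median([p.I_max for p in draws])
        t_mid = np.median([p.t_mid for p in draws])
        assert i_max == pytest.approx((0.3 + 20.0) / 2.0, rel=0.02)
        assert t_mid == pytest.approx(15.0, rel=0.02)
        # tan(U[0, pi/2]) has median tan(pi/4) = 1
        assert np.median([p.a1 for p in draws]) == pytest.approx(1.0, rel=0.05)

    def test_all_slopes_positive(self):
        rng = np.random.default_rng(2)
        assert all(sc.sample_sigmoidal_params(rng).a1 > 0 for _ in range(1000))


class TestDoubleSampler:
    def test_second_midpoint_never_exceeds_27(self):
        rng = np.random.default_rng(3)
        for _ in range(2000):
            p = sc.sample_double_params(rng)
            assert p.t_mid1_prime + 1.0 <= p.t_mid2_prime <= 27.0 + 1e-9

    def test_final_asymptote_below_maximum(self):
        rng = np.random.default_rng(4)
        for _ in range(2000):
            p = sc.sample_double_params(rng)
            assert p.I_final <= 0.85 * p.I_max + 1e-12

    def test_decay_slope_range(self):
        rng = np.random.default_rng(5)
        a2 = [sc.sample_double_params(rng).a2_prime for _ in range(2000)]
        assert 0.001 <= min(a2) and max(a2) <= 40.0


class TestSampleTimes:
    def test_equidistant_grid_exact(self):
        rng = np.random.default_rng(0)
        t = sc.sample_times("equidistant", rng)
        assert len(t) == 55
        assert t[0] == 3.0 and t[-1] == 30.0
        np.testing.assert_allclose(np.diff(t), 0.5)

    @pytest.mark.parametrize("regime", sc.simulate.SAMPLING_REGIMES)
    def test_all_regimes_stay_in_window(self, regime):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = sc.sample_times(regime, rng)
            assert len(t) == 55
            assert t.min() >= 3.0 and t.max() <= 30.0
            assert np.all(np.diff(t) >= 0)

    def test_beta_center_mean(self):
        rng = np.random.default_rng(7)
        t = np.concatenate([sc.sample_times("beta_center", rng) for _ in range(200)])
        # Beta(2,2) has mean 1/2, so times average 3 + 27/2
        assert t.mean() == pytest.approx(16.5, rel=0.01)


class TestAddNoise:
    def test_additive_amplitude_zero_is_identity(self):
        rng = np.random.default_rng(0)
        y = np.linspace(0, 4, 20)
        np.testing.assert_array_equal(sc.add_noise(y, "additive", 0.0, rng), y)

    def test_additive_bounded_by_half_amplitude(self):
        rng = np.random.default_rng(1)
        y = np.linspace(0, 4, 200)
        noisy = sc.add_noise(y, "additive", 0.8, rng)
        assert np.max(np.abs(noisy - y)) <= 0.5 * 0.8 * 4.0

    def test_multiplicative_centered_amplitude_zero_is_identity(self):
        rng = np.random.default_rng(2)
        y = np.linspace(0.1, 4, 20)
        out = sc.add_noise(y, "multiplicative", 0.0, rng, "centered")
        np.testing.assert_allclose(out, y, rtol=1e-15)

    def test_multiplicative_literal_scales_by_amplitude(self):
        rng = np.random.default_rng(3)
        y = np.ones(2000)
        out = sc.add_noise(y, "multiplicative", 1.0, rng, "literal")
        # factors are 2**U[-1,1]: bounded in [1/2, 2]
        assert np.all((out >= 0.5) & (out <= 2.0))

    def test_amplitude_out_of_range_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            sc.add_noise(np.ones(5), "additive", 1.6, rng)


class TestExclusionRule:
    TIMES = 3.0 + 0.5 * np.arange(55)

    def test_well_formed_sigmoidal_is_kept(self):
        p = sc.SigmoidalParams(I_max=5.0, t_mid=14.0, a1=0.8)
        assert is_classifiable_as_truth("sigmoidal", p, self.TIMES)

    def test_rise_after_window_end_is_rejected(self):
        # midpoint near the window edge with a shallow slope: the curve
        # cannot finish rising, so by definition it fails the end-ratio gate
        p = sc.SigmoidalParams(I_max=5.0, t_mid=29.0, a1=0.3)
        assert not is_classifiable_as_truth("sigmoidal", p, self.TIMES)

    def test_tiny_amplitude_is_rejected_as_no_signal(self):
        p = sc.SigmoidalParams(I_max=0.05, t_mid=14.0, a1=0.8)
        assert not is_classifiable_as_truth("sigmoidal", p, self.TIMES)

    def test_double_without_visible_decay_is_rejected(self):
        # decay so shallow the curve never drops below 75% of its maximum
        p = sc.DoubleSigmoidalParams(
            I_max=5.0, I_final=4.5, t_mid1_prime=10.0, t_mid2_prime=25.0,
            a1_prime=1.0, a2_prime=0.005,
        )
        assert not is_classifiable_as_truth("double_sigmoidal", p, self.TIMES)

    def test_well_formed_double_is_kept(self):
        p = sc.DoubleSigmoidalParams(
            I_max=4.0, I_final=0.8, t_mid1_prime=10.0, t_mid2_prime=20.0,
            a1_prime=1.0, a2_prime=0.8,
        )
        assert is_classifiable_as_truth("double_sigmoidal", p, self.TIMES)


class TestGrid:
    def test_default_grid_cardinality(self):
        assert sc.grid_size(sc.GridSpec()) == 50 * 2 * 5 * 11 * 2

    def test_small_grid_shape_and_sample_length(self):
        grid = sc.GridSpec(
            models=("sigmoidal",), regimes=("equidistant", "uniform"),
            noise_types=("additive",), amplitudes=(0.0, 0.6),
            n_replicates=3, seed=9,
        )
        samples = sc.generate_grid(grid)
        assert len(samples) == 1 * 2 * 1 * 2 * 3 == sc.grid_size(grid)
        for s in samples:
            assert len(s.times) == 55
            assert s.clean_intensities.shape == s.noisy_intensities.shape == (55,)

    def test_fixed_seed_regenerates_bit_identically(self):
        grid = sc.GridSpec(
            models=("double_sigmoidal",), regimes=("beta_early",),
            noise_types=("multiplicative",), amplitudes=(0.45,),
            n_replicates=4, seed=17,
        )
        a = sc.generate_grid(grid)
        b = sc.generate_grid(grid)
        for x, y in zip(a, b):
            assert x.sample_id == y.sample_id
            assert x.true_params == y.true_params
            np.testing.assert_array_equal(x.times, y.times)
            np.testing.assert_array_equal(x.noisy_intensities, y.noisy_intensities)

    def test_every_retained_truth_is_classifiable(self):
        grid = sc.GridSpec(
            models=("sigmoidal", "double_sigmoidal"), regimes=("equidistant",),
            noise_types=("additive",), amplitudes=(1.5,), n_replicates=5, seed=3,
        )
        for s in sc.generate_grid(grid):
            assert is_classifiable_as_truth(s.model_kind, s.true_params, s.times)

    def test_impossible_thresholds_raise_configuration_error(self):
        cfg = sc.DecisionConfig(min_intensity_max=1e9, min_intensity_range=1e9)
        grid = sc.GridSpec(
            models=("sigmoidal",), regimes=("equidistant",),
            noise_types=("additive",), amplitudes=(0.0,), n_replicates=1,
            seed=0, decision_cfg=cfg,
        )
        with pytest.raises(ConfigurationError):
            sc.generate_grid(grid)

    def test_amplitude_ladder_is_equally_spaced(self):
        assert DEFAULT_AMPLITUDES == tuple(
            pytest.approx(0.15 * i) for i in range(11)
        )
        assert len(DEFAULT_AMPLITUDES) == 11


def test_invalid_spec_fields_rejected():
    with pytest.raises(ValueError):
        sc.SimulationSpec(model_kind="cubic")
    with pytest.raises(ValueError):
        sc.SimulationSpec(noise_amplitude=2.0)
    with pytest.raises(ValueError):
        sc.SimulationSpec(multiplicative_mode="odd")
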