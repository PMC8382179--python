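"""Linear-nonlinear spiking encoder: filter, nonlinearity, spikes, features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingsense import (EncoderParams, FiringProbability, compute_norm_constant,
                       filter_kernel, filter_strain, first_spike_features,
                       generate_spikes, nonlinearity)
from wingsense.encoding import first_spikes_from_probability


class TestFilterKernel:
    def test_peak_value_one_at_minus_tau(self):
        lags, vals = filter_kernel(EncoderParams(), dt=1e-4)
        i = np.argmin(np.abs(lags + 5e-3))
        assert vals[i] == pytest.approx(1.0)

    def test_value_at_lag_zero_matches_closed_form(self):
        lags, vals = filter_kernel(EncoderParams(), dt=1e-4)
        i = np.argmin(np.abs(lags))
        assert vals[i] == pytest.approx(np.cos(5.0) * np.exp(-25.0 / 16.0),
                                        rel=1e-12)

    def test_support_spans_three_decay_times(self):
        lags, _ = filter_kernel(EncoderParams(), dt=1e-4)
        assert lags[0] == pytest.approx(-17e-3)
        assert lags[-1] == pytest.approx(7e-3)

    def test_narrow_envelope_is_impulse_like(self):
        lags, vals = filter_kernel(EncoderParams(delta=1e-4), dt=1e-4)
        mass_near_peak = np.abs(vals[np.abs(lags + 5e-3) <= 2e-4]).sum()
        assert mass_near_peak > 0.95 * np.abs(vals).sum()

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            filter_kernel(EncoderParams(), dt=0.0)


class TestFilterStrain:
    def test_zero_strain_gives_zero_output(self):
        g = filter_strain(np.zeros((200, 3)))
        assert np.abs(g).max() == 0.0

    def test_linearity_in_scale(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(300, 4))
        g1 = filter_strain(s)
        g3 = filter_strain(3.0 * s)
        np.testing.assert_allclose(g3, 3.0 * g1, rtol=1e-10)

    def test_impulse_response_is_reversed_causal_kernel(self):
        s = np.zeros((300, 1))
        s[100, 0] = 1.0
        g = filter_strain(s)
        lags, vals = filter_kernel(EncoderParams(), 1e-4)
        causal = vals[lags <= 1e-15][::-1]
        np.testing.assert_allclose(g[100:100 + len(causal), 0], causal,
                                   atol=1e-12)
        # strictly causal up to FFT roundoff
        assert np.abs(g[:100]).max() < 1e-12


class TestNormalization:
    def test_reference_field_normalizes_to_exactly_one(self, flap_strain):
        params = EncoderParams()
        c = compute_norm_constant(flap_strain, params)
        g = filter_strain(flap_strain, params.with_norm(c))
        assert np.abs(g).max() == pytest.approx(1.0, rel=1e-6)

    def test_stiffest_wing_stays_below_one(self, flap_strain):
        from wingsense import WingParams, simulate_strain
        params = EncoderParams()
        c = compute_norm_constant(flap_strain, params)
        stiff = simulate_strain(WingParams(youngs_modulus=10e9), duration=0.2,
                                seed=0, noise=False)
        g = filter_strain(stiff, params.with_norm(c))
        assert np.abs(g).max() < 1.0

    def test_constant_invariant_to_sensor_permutation(self, flap_strain):
        params = EncoderParams()
        c = compute_norm_constant(flap_strain, params)
        from wingsense.wing import StrainField
        perm = np.random.default_rng(0).permutation(flap_strain.data.shape[1])
        shuffled = StrainField(data=flap_strain.data[:, perm],
                               dt=flap_strain.dt, grid=flap_strain.grid)
        assert compute_norm_constant(shuffled, params) == pytest.approx(c)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_norm_constant(np.zeros((100, 2)), EncoderParams())


class TestNonlinearity:
    def test_half_maximum_at_threshold(self):
        p = nonlinearity(np.array([[0.2]]), EncoderParams(beta=0.2))
        assert p.data[0, 0] == pytest.approx(0.5)

    def test_value_above_threshold_closed_form(self):
        p = nonlinearity(np.array([[0.3]]), EncoderParams(beta=0.2, alpha=50))
        assert p.data[0, 0] == pytest.approx(1.0 / (1.0 + np.exp(-5.0)))

    def test_saturates_toward_zero_and_one(self):
        p = nonlinearity(np.array([[-100.0, 100.0]]), EncoderParams())
        assert p.data[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert p.data[0, 1] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30)
    @given(g=st.floats(0.0, 0.6), dg=st.floats(1e-3, 0.1),
           beta=st.floats(0.06, 0.69), dbeta=st.floats(1e-3, 0.25))
    def test_monotone_in_g_and_antitone_in_beta(self, g, dg, beta, dbeta):
        # ranges keep alpha(g - beta) out of float64 sigmoid saturation
        lo = nonlinearity(np.array([[g]]), EncoderParams(beta=beta)).data[0, 0]
        hi = nonlinearity(np.array([[g + dg]]), EncoderParams(beta=beta)).data[0, 0]
        assert hi > lo
        raised = nonlinearity(np.array([[g]]),
                              EncoderParams(beta=min(beta + dbeta, 0.99))).data[0, 0]
        assert raised < lo

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            EncoderParams(alpha=0.0)
        with pytest.raises(ValueError):
            EncoderParams(beta=1.5)


class TestGenerateSpikes:
    def test_zero_probability_gives_empty_raster(self):
        p = FiringProbability(np.zeros((400, 3)), dt=1e-4)
        r = generate_spikes(p, seed=0)
        assert r.data.sum() == 0

    def test_certain_firing_spikes_at_refractory_cadence(self):
        p = FiringProbability(np.ones((400, 1)), dt=1e-4)
        r = generate_spikes(p, refractory=15e-3, seed=0)
        np.testing.assert_array_equal(np.where(r.data[0, :, 0])[0],
                                      [0, 150, 300])

    def test_mean_count_matches_binomial_without_refractory(self):
        n, prob = 10000, 0.3
        p = FiringProbability(np.full((n, 1), prob), dt=1e-4)
        r = generate_spikes(p, refractory=0.5e-4, n_repeats=10, seed=1)
        counts = r.data.sum(axis=(1, 2))
        sd = np.sqrt(n * prob * (1 - prob))
        assert abs(counts.mean() - n * prob) < 3 * sd / np.sqrt(10)

    def test_deterministic_given_seed(self):
        p = FiringProbability(np.full((1000, 5), 0.2), dt=1e-4)
        a = generate_spikes(p, n_repeats=3, seed=7)
        b = generate_spikes(p, n_repeats=3, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_refractory_invariant_holds_on_random_rasters(self, seed):
        rng = np.random.default_rng(seed)
        p = FiringProbability(rng.uniform(0, 1, size=(800, 4)), dt=1e-4)
        r = generate_spikes(p, refractory=15e-3, n_repeats=2, seed=seed)
        for rep in range(2):
            for j in range(4):
                isi = np.diff(np.where(r.data[rep, :, j])[0])
                assert (isi >= 150).all()

    def test_invalid_repeats_rejected(self):
        p = FiringProbability(np.zeros((10, 1)), dt=1e-4)
        with pytest.raises(ValueError):
            generate_spikes(p, n_repeats=0)


class TestFirstSpikeFeatures:
    def test_empty_raster_gives_all_zero_sentinels(self):
        p = FiringProbability(np.zeros((800, 2)), dt=1e-4)
        f = first_spike_features(generate_spikes(p, seed=0))
        assert f.data.shape == (2, 2)
        assert (f.data == 0).all()

    def test_single_spike_lands_in_correct_cell(self):
        from wingsense.encoding import SpikeRaster
        data = np.zeros((1, 1200, 3), dtype=np.uint8)
        data[0, 472, 1] = 1  # wingbeat 1, sample 72 -> 7.3 ms
        f = first_spike_features(SpikeRaster(data, dt=1e-4))
        assert f.data[1, 1] == pytest.approx(7.3)
        assert f.data.sum() == pytest.approx(7.3)

    def test_times_quantized_to_tenth_millisecond(self):
        rng = np.random.default_rng(3)
        p = FiringProbability(rng.uniform(0, 0.3, size=(1200, 6)), dt=1e-4)
        f = first_spike_features(generate_spikes(p, n_repeats=2, seed=3))
        nz = f.data[f.data > 0]
        np.testing.assert_allclose(np.round(nz * 10) / 10, nz)
        assert nz.min() > 0 and nz.max() <= 40.0

    def test_observation_count_75_beats_10_repeats_2_conditions(self):
        p = FiringProbability(np.zeros((30000, 1)), dt=1e-4)
        f = first_spike_features(generate_spikes(p, n_repeats=10, seed=0))
        assert f.n_observations == 750  # per condition; 1,500 for the pair

    def test_duration_must_divide_into_wingbeats(self):
        from wingsense.encoding import SpikeRaster
        with pytest.raises(ValueError):
            first_spike_features(SpikeRaster(np.zeros((1, 410, 1), np.uint8),
                                             dt=1e-4))


class TestFusedPath:
    def test_same_law_as_reference_path_at_constant_probability(self):
        gval, ep = 0.2, EncoderParams(beta=0.2)  # p = 0.5 exactly
        g = np.full((20000, 10), gval)
        fused = first_spikes_from_probability(g, ep, 1e-4, 0.04, 10, seed=5)
        r = generate_spikes(nonlinearity(g, ep), 15e-3, 10, seed=5)
        ref = first_spike_features(r).data
        assert fused.shape == ref.shape
        # first-spike time distributions agree (both geometric + refractory)
        assert abs(fused[fused > 0].mean() - ref[ref > 0].mean()) < 0.15
        assert abs((fused == 0).mean() - (ref == 0).mean()) < 0.01

    def test_deterministic_and_quantized(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0.15, 0.1, size=(4000, 20))
        a = first_spikes_from_probability(g, EncoderParams(), 1e-4, 0.04, 3, 9)
        b = first_spikes_from_probability(g, EncoderParams(), 1e-4, 0.04, 3, 9)
        np.testing.assert_array_equal(a, b)
        nz = a[a > 0]
        np.testing.assert_allclose(np.round(nz * 10) / 10, nz)
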