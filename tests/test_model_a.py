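"""Static-weight mean field: summand moments, identity map, fixed point."""

import math

import numpy as np
import pytest

from ratefield import (DegreeDist, DegreeModel, MeanFieldModelA, MFParamsA,
                       NeuronParams, WeightDistribution, degree_tilts,
                       evaluate_F, external_input_moments,
                       input_stats_from_weights, phi, rate_given_identity,
                       sample_rate_distribution_A, solve_homogeneous)
from ratefield.params import ConfigError


class TestWeightDistribution:
    def test_gamma_matches_target_moments(self):
        """E[w] = -0.3, Var[w] = 0.2 -> shape 0.45, scale 2/3 and signed
        raw moments from the gamma product formula."""
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        assert wd.shape == pytest.approx(0.45)
        assert wd.scale == pytest.approx(2.0 / 3.0)
        assert wd.mean == pytest.approx(-0.3)
        assert wd.var == pytest.approx(0.2)
        s, t = 0.45, 2.0 / 3.0
        assert wd.m3 == pytest.approx(-(t ** 3) * s * (s + 1) * (s + 2))
        assert wd.m4 == pytest.approx(t ** 4 * s * (s + 1) * (s + 2) * (s + 3))

    def test_sampling_moments(self, rng):
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        x = wd.sample(200_000, rng)
        assert x.mean() == pytest.approx(-0.3, abs=0.01)
        assert x.var() == pytest.approx(0.2, abs=0.02)
        assert np.all(x <= 0)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ConfigError):
            WeightDistribution.from_moments(1.0, 0.5, 0.0, 1.0)


class TestInputStats:
    def test_degenerate_weight(self):
        """w = c: (c m, c^2 s2, c^2 m, c^4 s2, c^3 s2)."""
        th = MFParamsA(10.0, 4.0)
        st = input_stats_from_weights(th, WeightDistribution.degenerate(-0.3))
        c = -0.3
        assert st.m_mu == pytest.approx(c * 10)
        assert st.s_mu2 == pytest.approx(c ** 2 * 4)
        assert st.m_sig == pytest.approx(c ** 2 * 10)
        assert st.s_sig2 == pytest.approx(c ** 4 * 4)
        assert st.c_musig == pytest.approx(c ** 3 * 4)

    def test_zero_rate_variance(self):
        """s2 = 0 leaves only the weight-heterogeneity terms."""
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        st = input_stats_from_weights(MFParamsA(10.0, 0.0), wd)
        assert st.s_mu2 == pytest.approx(wd.var * 100)
        assert st.c_musig == pytest.approx((wd.m3 - wd.m1 * wd.m2) * 100)

    def test_psd_projection(self):
        st = input_stats_from_weights(MFParamsA(5.0, 1.0),
                                      WeightDistribution.signed_gamma(-0.3, 0.2))
        S = st.sigma_matrix()
        assert np.all(np.linalg.eigvalsh(S) >= -1e-12)


class TestRateGivenIdentity:
    def test_decoupled_neuron(self, params):
        """K = 0, Y = Z = 0 gives the external-drive rate."""
        th = MFParamsA(10.0, 2.0)
        wd = WeightDistribution.degenerate(-0.3)
        ext = external_input_moments(params)
        assert rate_given_identity(th, 0, 0.0, 0.0, wd, params) == \
            pytest.approx(phi(ext.mu, ext.sigma, params), rel=1e-4)

    def test_zero_weight_independent_of_identity(self, params):
        th = MFParamsA(10.0, 2.0)
        wd = WeightDistribution.degenerate(0.0)
        vals = {rate_given_identity(th, k, y, 0.0, wd, params)
                for k in (0, 10, 40) for y in (-1.0, 0.0, 2.0)}
        assert max(vals) - min(vals) < 1e-9

    def test_monotone_in_y(self, params):
        th = MFParamsA(10.0, 2.0)
        wd = WeightDistribution.degenerate(0.2)    # excitatory
        rates = [rate_given_identity(th, 25, y, 0.0, wd, params)
                 for y in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(rates) > 0)


class TestEvaluateF:
    def test_zero_weight_no_mc_noise(self, params):
        tilt = degree_tilts(DegreeModel.fixed_in(25))
        F, se = evaluate_F(MFParamsA(5.0, 1.0), tilt,
                           WeightDistribution.degenerate(0.0), params,
                           n_mc=2000, seed=0)
        ext = external_input_moments(params)
        assert F[0] == pytest.approx(phi(ext.mu, ext.sigma, params), rel=1e-4)
        assert F[1] == pytest.approx(0.0, abs=1e-12)

    def test_homogeneous_fixed_point_is_fixed(self, params):
        """theta = (nu_hom, 0) satisfies F(theta) = theta for degenerate
        degrees and weights (no MC noise: all triplets identical)."""
        w = -0.3
        nu_h = solve_homogeneous(params, 25, w)[0]
        tilt = degree_tilts(DegreeModel.fixed_in(25))
        F, _ = evaluate_F(MFParamsA(nu_h, 0.0), tilt,
                          WeightDistribution.degenerate(w), params,
                          n_mc=2000, seed=0)
        assert F[0] == pytest.approx(nu_h, abs=1e-3)
        assert F[1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_nonnegative(self, params):
        tilt = degree_tilts(DegreeModel.independent_normal(25, 7))
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        F, _ = evaluate_F(MFParamsA(12.0, 6.0), tilt, wd, params,
                          n_mc=5000, seed=1)
        assert F[1] >= 0.0


class TestSolveThetaA:
    @pytest.mark.parametrize("w", [-0.5, -0.3, -0.1, 0.0, 0.1])
    def test_homogeneous_reduction(self, params, w):
        """Degenerate degrees + degenerate weights recover the homogeneous
        fixed point within 0.1 Hz."""
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25),
                              WeightDistribution.degenerate(w), params)
        res = mdl.fit(n_mc=10_000, seed=2)
        nu_h = solve_homogeneous(params, 25, w)[0]
        assert res.theta.m == pytest.approx(nu_h, abs=0.1)
        assert res.theta.s2 < 1e-9

    def test_zero_weight_single_iteration(self, params):
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25),
                              WeightDistribution.degenerate(0.0), params)
        res = mdl.fit(n_mc=2000, seed=3)
        assert res.info.n_iter == 1

    def test_seed_invariance(self, params):
        """Two solver runs with different MC seeds agree within combined
        standard errors."""
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25), wd, params)
        r1 = mdl.fit(n_mc=50_000, seed=4)
        r2 = mdl.fit(n_mc=50_000, seed=5)
        se = np.hypot(*(np.array([r1.info.mc_se, r2.info.mc_se])))
        assert abs(r1.theta.m - r2.theta.m) < 3 * se[0] + 1e-3
        assert abs(r1.theta.s2 - r2.theta.s2) < 3 * se[1] + 1e-3

    def test_fixed_point_contract(self, params):
        """||theta* - F(theta*)|| within 3 MC standard errors."""
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25), wd, params)
        res = mdl.fit(n_mc=100_000, seed=6)
        F, se = evaluate_F(res.theta, mdl.tilt, wd, params,
                           n_mc=100_000, seed=99)
        assert np.all(np.abs(F - res.theta.as_array()) <= 3 * se + 1e-3)

    def test_summary_mentions_convergence(self, params):
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25),
                              WeightDistribution.degenerate(-0.2), params)
        s = mdl.fit(n_mc=5000, seed=7).summary()
        assert "presynaptic rate mean" in s and "True" in s


class TestReconstruction:
    def test_rates_within_physical_bounds(self, params):
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25), wd, params)
        res = mdl.fit(n_mc=20_000, seed=8)
        s = res.sample_rates(n=20_000)
        assert np.all(s > 0) and np.all(s <= params.nu_max)

    def test_degenerate_network_point_mass(self, params):
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25),
                              WeightDistribution.degenerate(-0.3), params)
        res = mdl.fit(n_mc=5000, seed=9)
        s = res.sample_rates(n=5000)
        assert s.std() < 1e-6

    def test_fixed_in_sample_reproduces_theta(self, params):
        """With fixed in-degrees the presynaptic and network rate laws
        coincide, so the sample must reproduce theta*."""
        wd = WeightDistribution.signed_gamma(-0.3, 0.2)
        mdl = MeanFieldModelA(DegreeModel.fixed_in(25), wd, params)
        res = mdl.fit(n_mc=100_000, seed=10)
        s = res.sample_rates(n=200_000)
        se_m = s.std() / math.sqrt(s.size)
        assert abs(s.mean() - res.theta.m) < 3 * se_m + 0.02
        assert s.var() == pytest.approx(res.theta.s2, rel=0.03)
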