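"""Plastic mean field: equilibrium kernel, scalar rate equation, fixed point,
rate/weight reconstruction and its self-consistency."""

import numpy as np
import pytest

from ratefield import (DegreeModel, MeanFieldModelB, MFParamsB, NeuronParams,
                       SeparableKernel, degree_tilts, equilibrium_weight,
                       evaluate_G, external_input_moments, phi,
                       solve_homogeneous, solve_rate_scalar)
from ratefield.model_b import solve_rates_batch


@pytest.fixture(scope="module")
def params_b() -> NeuronParams:
    return NeuronParams(nu_ext=8.0)


class TestEquilibriumWeight:
    def test_zero_presynaptic_rate(self):
        k = SeparableKernel(g0=0.1)
        assert equilibrium_weight(0.0, 10.0, k) == 0.0

    def test_equal_rates_saturate_at_g0(self):
        """w*(nu, nu) = g0 nu^2/(nu^2 + eps) -> g0 when nu^2 >> eps."""
        k = SeparableKernel(g0=0.1, eps=1e-3)
        nu = 10.0  # Hz -> 0.01 ms^-1, nu^2 = 1e-4 << eps
        expect = 0.1 * 1e-4 / (1e-4 + 1e-3)
        assert equilibrium_weight(nu, nu, k) == pytest.approx(expect)
        hi = 3000.0  # 3 ms^-1: far above eps scale
        assert equilibrium_weight(hi, hi, k) == pytest.approx(0.1, rel=1e-3)

    def test_small_eps_limit(self):
        k = SeparableKernel(g0=0.2, eps=1e-12)
        assert equilibrium_weight(6.0, 3.0, k) == \
            pytest.approx(0.2 * 6.0 / 3.0, rel=1e-6)

    def test_inhibitory_sign(self):
        k = SeparableKernel(g0=0.1, sign=-1)
        assert equilibrium_weight(10.0, 10.0, k) < 0


class TestScalarRateEquation:
    def test_zero_theta_gives_external_rate(self, params_b):
        th = MFParamsB(0.0, 0.0, 0.0, 0.0, 0.0)
        k = SeparableKernel(g0=0.1)
        ext = external_input_moments(params_b)
        nu = solve_rate_scalar(th, 25, 0.0, 0.0, k, params_b)
        assert nu == pytest.approx(phi(ext.mu, ext.sigma, params_b), abs=1e-3)

    def test_residual_contract(self, params_b):
        th = MFParamsB(1e-4, 1e-11, 4e-7, 1e-15, 0.0)
        k = SeparableKernel(g0=0.1)
        nu = solve_rate_scalar(th, 25, 0.0, 0.0, k, params_b, tol=1e-6)
        # re-substitute
        from ratefield.model_b import _residual_rates
        import numpy as _np
        A = _np.array([25 * th.m_mu])
        B = _np.array([25 * th.m_sig])
        r = _residual_rates(_np.array([nu / 1000.0]), A, B, k, params_b,
                            external_input_moments(params_b))[0]
        assert abs(r) * 1000.0 < 1e-5

    def test_batch_agrees_with_dense_grid_oracle(self, params_b):
        """Batch solver vs a brute-force 100k-point scan on random draws."""
        rng = np.random.default_rng(0)
        k = SeparableKernel(g0=0.1)
        th = MFParamsB(1.2e-4, 8e-11, 4.4e-7, 2.2e-15, 4e-13)
        n = 40
        K = rng.integers(5, 60, n)
        Y = rng.normal(0, np.sqrt(th.s_mu2), n)
        Z = rng.normal(0, np.sqrt(th.s_sig2), n)
        fast = solve_rates_batch(th, K, Y, Z, k, params_b)
        from ratefield.model_b import _residual_rates
        ext = external_input_moments(params_b)
        for i in range(n):
            grid = np.linspace(0.0, 0.5, 100_001)
            A = np.array([K[i] * th.m_mu + np.sqrt(K[i]) * Y[i]])
            B = np.array([K[i] * th.m_sig + np.sqrt(K[i]) * Z[i]])
            r = _residual_rates(grid[:, None], A, B, k, params_b, ext)[:, 0]
            j = int(np.argmax(r >= 0))
            lo, hi = grid[j - 1], grid[j]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                rm = _residual_rates(np.array([mid]), A, B, k, params_b, ext)[0]
                lo, hi = (mid, hi) if rm < 0 else (lo, mid)
            assert fast[i] == pytest.approx(1000.0 * 0.5 * (lo + hi), abs=1e-3)


class TestEvaluateG:
    def test_zero_gain_kernel(self, params_b):
        tilt = degree_tilts(DegreeModel.fixed_in(25))
        G, _ = evaluate_G(MFParamsB(0, 0, 0, 0, 0), tilt,
                          SeparableKernel(g0=0.0), params_b, n_mc=2000, seed=0)
        assert np.allclose(G, 0.0)

    def test_degenerate_homogeneous_moments(self, params_b):
        """Fixed degrees + zero-variance theta: variances vanish and the
        means are the summand values at the homogeneous rate."""
        k = SeparableKernel(g0=0.1)
        tilt = degree_tilts(DegreeModel.fixed_in(25))
        from ratefield.model_b import homogeneous_theta0
        th0 = homogeneous_theta0(tilt, k, params_b)
        G, _ = evaluate_G(th0, tilt, k, params_b, n_mc=2000, seed=1)
        assert G[1] == pytest.approx(0.0, abs=1e-15)
        assert G[3] == pytest.approx(0.0, abs=1e-20)
        assert G[0] == pytest.approx(th0.m_mu, rel=1e-3)
        assert G[2] == pytest.approx(th0.m_sig, rel=1e-3)

    def test_variances_nonnegative(self, params_b):
        tilt = degree_tilts(DegreeModel.independent_normal(25, 7))
        G, _ = evaluate_G(MFParamsB(1.2e-4, 8e-11, 4.4e-7, 2.2e-15, 0.0),
                          tilt, SeparableKernel(g0=0.1), params_b,
                          n_mc=5000, seed=2)
        assert G[1] >= 0 and G[3] >= 0


class TestFixedPoint:
    @pytest.mark.parametrize("g0", [0.05, 0.1, 0.2])
    def test_homogeneous_reduction(self, params_b, g0):
        """Fixed degrees: the heterogeneous solver lands on the homogeneous
        plastic fixed point within 0.1 Hz."""
        k = SeparableKernel(g0=g0)
        nu_h = solve_homogeneous(params_b, 25, k.weight_homogeneous_hz)[0]
        mdl = MeanFieldModelB(DegreeModel.fixed_in(25), k, params_b)
        res = mdl.fit(n_mc=10_000, seed=3)
        rates = res.sample_rates(n=5000)
        assert rates.mean() == pytest.approx(nu_h, abs=0.1)
        assert rates.std() < 1e-6

    def test_zero_gain_theta_zero(self, params_b):
        mdl = MeanFieldModelB(DegreeModel.fixed_in(25),
                              SeparableKernel(g0=1e-12), params_b)
        res = mdl.fit(n_mc=5000, seed=4)
        ext = external_input_moments(params_b)
        assert res.sample_rates(n=2000).mean() == \
            pytest.approx(phi(ext.mu, ext.sigma, params_b), abs=0.05)

    def test_fixed_point_contract(self, params_b):
        mdl = MeanFieldModelB(DegreeModel.independent_normal(25, 7),
                              SeparableKernel(g0=0.1), params_b)
        res = mdl.fit(n_mc=50_000, seed=5)
        G, se = evaluate_G(res.theta, mdl.tilt, mdl.kernel, params_b,
                           n_mc=50_000, seed=77)
        assert np.all(np.abs(G - res.theta.as_array())
                      <= 3 * se + 1e-3 * abs(res.theta.m_mu))


@pytest.fixture(scope="module")
def fitted(params_b):
    mdl = MeanFieldModelB(DegreeModel.independent_normal(25, 7),
                          SeparableKernel(g0=0.1), params_b)
    return mdl.fit(n_mc=50_000, seed=6)


class TestReconstruction:
    def test_rates_bounded(self, fitted, params_b):
        s = fitted.sample_rates(n=20_000)
        assert np.all(s > 0) and np.all(s <= params_b.nu_max)

    def test_weights_positive_for_excitatory_kernel(self, fitted):
        w = fitted.sample_weights(n=20_000)
        assert np.all(w >= 0)

    def test_degenerate_network_point_masses(self, params_b):
        k = SeparableKernel(g0=0.1)
        mdl = MeanFieldModelB(DegreeModel.fixed_in(25), k, params_b)
        res = mdl.fit(n_mc=5000, seed=7)
        r = res.sample_rates(n=3000)
        w = res.sample_weights(n=3000)
        assert r.std() < 1e-6 and w.std() < 1e-9
        nu = r.mean()
        assert w.mean() == pytest.approx(
            equilibrium_weight(nu, nu, k), rel=1e-4)

    def test_self_consistency_of_reconstruction(self, fitted, params_b):
        """Moments of (g_pre(nu) nu, g_pre(nu)^2 nu) over a presyn-tilted
        rate sample reproduce theta* within 3 s.e. (closes the loop)."""
        from ratefield.model_b import _identity_rates, _summand_moments
        rng = np.random.default_rng(123)
        nu = _identity_rates(fitted.theta, fitted.model.tilt.presyn,
                             fitted.model.kernel, params_b, 100_000, rng)
        M, se = _summand_moments(nu, fitted.model.kernel)
        assert np.all(np.abs(M - fitted.theta.as_array())
                      <= 3 * se + 3 * np.asarray(fitted.info.mc_se))
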