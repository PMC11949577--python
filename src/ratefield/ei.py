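"""Two-population (E-I) extension of the plastic mean-field theory.

Each neuron receives inputs from every presynaptic population Q through its
own in-degree K_Q; the per-edge summand moments theta_Q = (m_mu, s_mu2,
m_sig, s_sig2, c_musig)_Q are a property of the presynaptic population
alone.  The scalar rate equation of a neuron with identity
X = {(K_Q, Y_Q, Z_Q)} sums population blocks inside the input moments:

    mu(nu)     = tau g_post(nu) * sum_Q sign_Q (K_Q m_mu_Q + sqrt(K_Q) Y_Q) + mu_ext
    sigma2(nu) = tau g_post(nu)^2 * [sum_Q (K_Q m_sig_Q + sqrt(K_Q) Z_Q)]_+ + sigma2_ext

with the inhibitory rule entering with the opposite sign (and the same
Oja-like g_post).  The implementation assumes the block in-degree laws are
independent of the individual out-degrees, so the presynaptic in-degree
laws are unbiased -- the regime of the networks studied here (independent
normal E degrees, fixed I in-degrees with emergent out-degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .degrees import DegreeModel, degree_tilts
from .kernels import SeparableKernel
from .model_a import ConvergenceError, FixedPointInfo, RATE_FLOOR
from .model_b import MFParamsB, _summand_moments
from .params import ConfigError, NeuronParams
from .transfer import external_input_moments, phi_vec

__all__ = ["MeanFieldModelEI", "MeanFieldResultsEI", "solve_rates_batch_ei"]


def solve_rates_batch_ei(thetas: dict[str, MFParamsB],
                         K: dict[str, np.ndarray],
                         Y: dict[str, np.ndarray], Z: dict[str, np.ndarray],
                         kernels: dict[str, SeparableKernel],
                         p: NeuronParams, n_grid: int = 400,
                         n_bisect: int = 52) -> np.ndarray:
    """Smallest-root scalar rate equation with per-population input blocks.

    All dict arguments are keyed by presynaptic population.  Rates in Hz.
    """
    pops = list(thetas)
    A = {}
    B = {}
    n = None
    for q in pops:
        Kq = np.asarray(K[q], dtype=float)
        sq = np.sqrt(Kq)
        A[q] = Kq * thetas[q].m_mu + sq * np.asarray(Y[q])
        B[q] = Kq * thetas[q].m_sig + sq * np.asarray(Z[q])
        n = A[q].size
    ext = external_input_moments(p)
    g_post = kernels[pops[0]].g_post      # common postsynaptic factor

    def residual(nu_ms, idx=None):
        gp = g_post(nu_ms)
        acc_mu = 0.0
        acc_sig = 0.0
        for q in pops:
            aq = A[q] if idx is None else A[q][idx]
            bq = B[q] if idx is None else B[q][idx]
            acc_mu = acc_mu + kernels[q].sign * aq
            acc_sig = acc_sig + bq
        mu = p.tau * gp * acc_mu + ext.mu
        sig2 = np.maximum(p.tau * gp * gp * acc_sig, 0.0) + ext.sigma2
        return nu_ms - phi_vec(mu, np.sqrt(sig2), p) / 1000.0

    nu_max = 1.0 / p.tau_ref if p.tau_ref > 0 else 0.6
    grid = np.linspace(0.0, nu_max, n_grid)
    lo = np.zeros(n)
    hi = np.full(n, nu_max)
    found = np.zeros(n, dtype=bool)
    active = np.arange(n)
    block = 16
    k = 1
    while k < n_grid and active.size:
        ks = grid[k:k + block]
        r = residual(ks[:, None], idx=active)
        nonneg = r >= 0.0
        any_hit = nonneg.any(axis=0)
        first = np.argmax(nonneg, axis=0)
        hit = active[any_hit]
        jf = first[any_hit]
        hi[hit] = ks[jf]
        lo[hit] = grid[k - 1 + jf]
        found[hit] = True
        active = active[~any_hit]
        k += block
    lo[~found] = grid[-2]
    idx_all = np.arange(n)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        r = residual(mid, idx=idx_all)
        neg = r < 0.0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi) * 1000.0


class MeanFieldModelEI:
    """Plastic mean-field model with excitatory and inhibitory populations.

    Parameters
    ----------
    degree_models : dict pre_pop -> DegreeModel
        In-degree law of inputs *from* pre_pop (assumed identical for every
        postsynaptic population, as in symmetric E-I networks).
    kernels : dict pre_pop -> SeparableKernel
        Equilibrium kernels; the inhibitory one carries sign = -1.
    params : NeuronParams or dict pop -> NeuronParams
        Neuron parameters (shared across populations when a single set is
        given; the theory below assumes statistically equivalent
        populations and uses the first set for the scalar equation).
    """

    def __init__(self, degree_models: dict[str, DegreeModel],
                 kernels: dict[str, SeparableKernel], params):
        if set(degree_models) != set(kernels):
            raise ConfigError("degree_models and kernels must share keys")
        self.pops = sorted(degree_models)
        self.degree_models = degree_models
        self.kernels = kernels
        self.params = params if isinstance(params, NeuronParams) \
            else params[self.pops[0]]
        self.tilts = {q: degree_tilts(m) for q, m in degree_models.items()}

    # -- fixed point --------------------------------------------------------
    def _draws(self, n_mc: int, rng: np.random.Generator):
        return {q: (rng.random(n_mc), rng.standard_normal(n_mc),
                    rng.standard_normal(n_mc)) for q in self.pops}

    def _identities(self, thetas, draws, tilted: bool):
        K, Y, Z = {}, {}, {}
        for q in self.pops:
            u, g1, g2 = draws[q]
            law = self.tilts[q].presyn if tilted else self.tilts[q].network
            K[q] = law.sample_from_uniforms(u)
            a, b, d = thetas[q].chol()
            Y[q] = a * g1
            Z[q] = b * g1 + d * g2
        return K, Y, Z

    def evaluate_G(self, thetas: dict[str, MFParamsB], n_mc: int, draws
                   ) -> tuple[dict, dict]:
        """One map evaluation: presynaptic-tilted identities -> rates ->
        summand moments per presynaptic population.

        With statistically equivalent populations the rate law is shared, so
        a single rate sample feeds every population's g_pre moments."""
        K, Y, Z = self._identities(thetas, draws, tilted=True)
        nu = solve_rates_batch_ei(thetas, K, Y, Z, self.kernels, self.params)
        G, se = {}, {}
        for q in self.pops:
            G[q], se[q] = _summand_moments(nu, self.kernels[q])
        return G, se

    def fit(self, damping: float = 0.5, tol: float = 1e-3, max_iter: int = 60,
            n_mc: int = 50_000, seed: int = 0) -> "MeanFieldResultsEI":
        rng = np.random.default_rng(seed)
        draws = self._draws(n_mc, rng)
        # zero-variance start at the external-drive rate
        ext = external_input_moments(self.params)
        nu0 = float(phi_vec(ext.mu, ext.sigma, self.params)) / 1000.0
        thetas = {}
        for q in self.pops:
            gp = float(self.kernels[q].g_pre(nu0))
            thetas[q] = MFParamsB(gp * nu0, 0.0, gp * gp * nu0, 0.0, 0.0)
        traj = []
        for it in range(1, max_iter + 1):
            G, se = self.evaluate_G(thetas, n_mc, draws)
            ok = True
            new_thetas = {}
            resid = {}
            for q in self.pops:
                cur = thetas[q].as_array()
                new = (1.0 - damping) * cur + damping * G[q]
                resid[q] = G[q] - cur
                rel = np.abs(new - cur) / np.maximum(
                    np.abs(cur), 1e-3 * max(abs(cur[0]), 1e-12))
                new_thetas[q] = MFParamsB.from_array(new)
                if not (np.all(rel < tol)
                        and np.all(np.abs(resid[q]) <= 3.0 * se[q] + 1e-15)):
                    ok = False
            traj.append(np.concatenate([new_thetas[q].as_array()
                                        for q in self.pops]))
            thetas = new_thetas
            if ok:
                info = FixedPointInfo(True, it,
                                      np.concatenate([resid[q] for q in self.pops]),
                                      np.concatenate([se[q] for q in self.pops]),
                                      np.array(traj))
                return MeanFieldResultsEI(self, thetas, info, n_mc, seed)
        raise ConvergenceError(
            f"E-I fixed point not converged after {max_iter} iterations",
            trajectory=np.array(traj))


@dataclass
class MeanFieldResultsEI:
    model: MeanFieldModelEI
    thetas: dict[str, MFParamsB]
    info: FixedPointInfo
    n_mc: int
    seed: int

    def sample_rates(self, n: int = 100_000, seed: int | None = None) -> np.ndarray:
        """Rate sample of a random network neuron (identities from the
        untilted block in-degree laws)."""
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        draws = self.model._draws(n, rng)
        K, Y, Z = self.model._identities(self.thetas, draws, tilted=False)
        nu = solve_rates_batch_ei(self.thetas, K, Y, Z, self.model.kernels,
                                  self.model.params)
        return np.clip(nu, RATE_FLOOR, self.model.params.nu_max)

    def sample_weights(self, pre_pop: str, n: int = 100_000,
                       seed: int | None = None) -> np.ndarray:
        """Equilibrium weights of synapses from ``pre_pop``: the post
        endpoint's in-degree from pre_pop is size-biased, all other block
        degrees are unbiased; the pre endpoint uses unbiased laws."""
        rng = np.random.default_rng(self.seed + 3 if seed is None else seed)
        m = self.model
        kern = m.kernels[pre_pop]

        def rates(postsyn_bias: bool) -> np.ndarray:
            draws = m._draws(n, rng)
            K, Y, Z = m._identities(self.thetas, draws, tilted=False)
            if postsyn_bias:
                u = rng.random(n)
                K[pre_pop] = m.tilts[pre_pop].postsyn.sample_from_uniforms(u)
            return solve_rates_batch_ei(self.thetas, K, Y, Z, m.kernels,
                                        m.params)

        nu_pre = rates(postsyn_bias=False)
        nu_post = rates(postsyn_bias=True)
        return kern.sign * kern.g_pre(nu_pre / 1000.0) \
            * kern.g_post(nu_post / 1000.0)

    def summary(self, n_sample: int = 30_000) -> str:
        rates = self.sample_rates(n=n_sample)
        lines = ["Mean-field fixed point -- E-I plastic network",
                 "=" * 50]
        for q in self.model.pops:
            t = self.thetas[q]
            lines.append(f"theta[{q}]: m_mu={t.m_mu:.4e}  s_mu2={t.s_mu2:.4e}  "
                         f"m_sig={t.m_sig:.4e}")
        lines += [
            f"iterations                   {self.info.n_iter}",
            f"residual norm                {self.info.residual_norm:.3e}",
            f"network rate mean / sd       {rates.mean():.4f} / {rates.std():.4f} Hz",
        ]
        for q in self.model.pops:
            w = self.sample_weights(q, n=n_sample)
            lines.append(f"weights from {q}: mean {w.mean():+.5f} sd {w.std():.5f} mV")
        return "\n".join(lines)
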