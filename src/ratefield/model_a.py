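"""Mean-field theory for heterogeneous networks with static weights (Model A).

The unknowns are the mean and variance of the firing rate of a *presynaptic*
neuron, theta = (m, s2).  Given theta, the per-edge summands (w nu, w^2 nu)
have moments fixed by the weight distribution,

    m_mu  = E[w] m                 s_mu2 = E[w^2] s2 + Var[w] m^2
    m_sig = E[w^2] m               s_sig2 = E[w^4] s2 + Var[w^2] m^2
    c     = E[w^3] s2 + (E[w^3] - E[w] E[w^2]) m^2,

and by the CLT the input sums of a neuron with in-degree K are bivariate
normal with mean K (m_mu, m_sig) and covariance K Sigma.  A neuron's rate
is then a deterministic function of its identity triplet X = (K, Y, Z):

    nu(theta, X) = phi(mu, sigma),
    mu     = tau (K m_mu  + sqrt(K) Y) + mu_ext,
    sigma2 = tau (K m_sig + sqrt(K) Z) + sigma2_ext,

and self-consistency requires theta to equal the mean/variance of
nu(theta, X) with K drawn from the *presynaptic* (tilted) in-degree law.
The fixed point is found by damped Picard iteration on a Monte-Carlo
estimate of that map with common random numbers; the network rate
distribution is reconstructed afterwards with K from the untilted law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .degrees import DegreeDist, DegreeModel, DegreeTilt, degree_tilts
from .params import ConfigError, NeuronParams
from .transfer import external_input_moments, phi_vec
from .weights import WeightDistribution

__all__ = [
    "MFParamsA",
    "InputStatsA",
    "input_stats_from_weights",
    "rate_given_identity",
    "evaluate_F",
    "solve_theta_A",
    "sample_rate_distribution_A",
    "MeanFieldModelA",
    "MeanFieldResultsA",
    "ConvergenceError",
    "FixedPointInfo",
]

#: reconstruction support (Hz): avoids degenerate zero-rate artifacts downstream
RATE_FLOOR = 1e-4


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


@dataclass(frozen=True)
class MFParamsA:
    """Mean m (Hz) and variance s2 (Hz^2) of a presynaptic neuron's rate."""

    m: float
    s2: float

    def __post_init__(self):
        if self.s2 < 0:
            raise ConfigError("rate variance must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.s2])


@dataclass(frozen=True)
class InputStatsA:
    """Moments of the per-edge summands (w nu, w^2 nu)."""

    m_mu: float
    s_mu2: float
    m_sig: float
    s_sig2: float
    c_musig: float

    def sigma_matrix(self) -> np.ndarray:
        """2x2 covariance of (w nu, w^2 nu), with the off-diagonal shrunk to
        the PSD boundary if Monte-Carlo noise pushed it past."""
        c = self.c_musig
        bound = math.sqrt(max(self.s_mu2 * self.s_sig2, 0.0))
        c = max(-bound, min(bound, c))
        return np.array([[self.s_mu2, c], [c, self.s_sig2]])


def input_stats_from_weights(theta: MFParamsA, wd: WeightDistribution) -> InputStatsA:
    """Exact per-edge summand moments for independent weight and rate."""
    m, s2 = theta.m, theta.s2
    e1, e2, e3, e4 = wd.m1, wd.m2, wd.m3, wd.m4
    return InputStatsA(
        m_mu=e1 * m,
        s_mu2=e2 * s2 + wd.var * m * m,
        m_sig=e2 * m,
        s_sig2=e4 * s2 + wd.var_w2 * m * m,
        c_musig=e3 * s2 + (e3 - e1 * e2) * m * m,
    )


def _rates_from_triplets(stats: InputStatsA, K, g1, g2, p: NeuronParams
                         ) -> np.ndarray:
    """Vectorised Eq-of-state: rate of a neuron with identity (K, Y, Z).

    (g1, g2) are the *standardised* Gaussian coordinates; the correlated
    fluctuations (Y, Z) ~ N(0, Sigma) are produced internally via the
    Cholesky factor of Sigma(theta), so a degenerate Sigma (e.g. w == 0)
    makes the rate independent of the identity fluctuations.
    """
    ext = external_input_moments(p)
    tau_s = p.tau / 1000.0
    K = np.asarray(K, dtype=float)
    sqk = np.sqrt(K)
    Y, Z = _correlated_yz(stats, np.asarray(g1, dtype=float),
                          np.asarray(g2, dtype=float))
    mu = tau_s * (K * stats.m_mu + sqk * Y) + ext.mu
    # the CLT fluctuation can drive the recurrent variance negative at small
    # K; floor it at zero (the external part always remains)
    rec = tau_s * (K * stats.m_sig + sqk * Z)
    sigma2 = np.maximum(rec, 0.0) + ext.sigma2
    return phi_vec(mu, np.sqrt(sigma2), p)


def rate_given_identity(theta: MFParamsA, K: int, y: float, z: float,
                        wd: WeightDistribution, p: NeuronParams) -> float:
    """Rate (Hz) of one neuron with identity (K, y, z), the fluctuations in
    standardised coordinates (scaled by chol(Sigma(theta)) internally)."""
    stats = input_stats_from_weights(theta, wd)
    return float(_rates_from_triplets(stats, [K], [y], [z], p)[0])


@dataclass
class _CRNDraws:
    """Common random numbers reused across Picard iterations."""

    u_k: np.ndarray       # uniforms for the in-degree inverse cdf
    g1: np.ndarray        # standard normal pair, correlated via chol(Sigma)
    g2: np.ndarray

    @classmethod
    def make(cls, n: int, rng: np.random.Generator) -> "_CRNDraws":
        return cls(u_k=rng.random(n), g1=rng.standard_normal(n),
                   g2=rng.standard_normal(n))


def _correlated_yz(stats: InputStatsA, g1, g2) -> tuple[np.ndarray, np.ndarray]:
    s = stats.sigma_matrix()
    a = math.sqrt(max(s[0, 0], 0.0))
    if a > 0:
        b = s[0, 1] / a
        c2 = max(s[1, 1] - b * b, 0.0)
        c = math.sqrt(c2)
    else:
        b = 0.0
        c = math.sqrt(max(s[1, 1], 0.0))
    return a * g1, b * g1 + c * g2


def evaluate_F(theta: MFParamsA, tilt: DegreeTilt, wd: WeightDistribution,
               p: NeuronParams, n_mc: int = 100_000,
               seed: int | np.random.Generator | _CRNDraws = 0,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the self-consistency map F(theta) = (F_m, F_s2).

    K is drawn from the presynaptic (tilted) in-degree law and (Y, Z) from
    N(0, Sigma(theta)).  Returns (F, se) with the standard errors of both
    components.
    """
    if n_mc < 1000:
        raise ConfigError("n_mc must be >= 1000")
    if isinstance(seed, _CRNDraws):
        draws = seed
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        draws = _CRNDraws.make(n_mc, rng)
    stats = input_stats_from_weights(theta, wd)
    K = tilt.presyn.sample_from_uniforms(draws.u_k)
    nu = _rates_from_triplets(stats, K, draws.g1, draws.g2, p)
    n = nu.size
    f_m = float(nu.mean())
    dev = nu - f_m
    f_s2 = float(dev @ dev) / n
    se_m = math.sqrt(f_s2 / n)
    m4 = float((dev ** 4).mean())
    se_s2 = math.sqrt(max(m4 - f_s2 ** 2, 0.0) / n)
    return np.array([f_m, f_s2]), np.array([se_m, se_s2])


@dataclass
class FixedPointInfo:
    """Convergence diagnostics of the damped Picard iteration."""

    converged: bool
    n_iter: int
    residual: np.ndarray
    mc_se: np.ndarray
    trajectory: np.ndarray

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residual))


def solve_theta_A(tilt: DegreeTilt, wd: WeightDistribution, p: NeuronParams,
                  theta0: MFParamsA | None = None, damping: float = 0.5,
                  tol: float = 1e-3, max_iter: int = 100,
                  n_mc: int = 100_000, seed: int = 0,
                  ) -> tuple[MFParamsA, FixedPointInfo]:
    """Solve theta = F(theta) by damped Picard iteration with common random
    numbers.  Converged when the relative update is below ``tol`` and the
    residual is within 3 Monte-Carlo standard errors."""
    if not (0 < damping <= 1):
        raise ConfigError("damping must be in (0, 1]")
    rng = np.random.default_rng(seed)
    draws = _CRNDraws.make(n_mc, rng)
    if theta0 is None:
        ext = external_input_moments(p)
        nu0 = float(phi_vec(ext.mu, ext.sigma, p))
        theta = MFParamsA(nu0, 0.0)
    else:
        theta = theta0
    traj = [theta.as_array()]
    for it in range(1, max_iter + 1):
        F, se = evaluate_F(theta, tilt, wd, p, n_mc=n_mc, seed=draws)
        cur = theta.as_array()
        new = (1.0 - damping) * cur + damping * F
        resid = F - cur
        traj.append(new)
        rel = np.abs(new - cur) / np.maximum(np.abs(cur), 1e-6)
        theta = MFParamsA(float(new[0]), float(max(new[1], 0.0)))
        if np.all(rel < tol) and np.all(np.abs(resid) <= 3.0 * se + 1e-12):
            info = FixedPointInfo(True, it, resid, se, np.array(traj))
            return theta, info
    raise ConvergenceError(
        f"Model A fixed point not converged after {max_iter} iterations",
        trajectory=np.array(traj))


def sample_rate_distribution_A(theta: MFParamsA, network_in: DegreeDist,
                               wd: WeightDistribution, p: NeuronParams,
                               n: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """Reconstruct the network rate distribution: K from the *untilted*
    network in-degree law, (Y, Z) from N(0, Sigma(theta))."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    stats = input_stats_from_weights(theta, wd)
    K = network_in.sample(n, rng)
    nu = _rates_from_triplets(stats, K, rng.standard_normal(n),
                              rng.standard_normal(n), p)
    return np.clip(nu, RATE_FLOOR, p.nu_max)


# ---------------------------------------------------------------------------
# model / results presentation
# ---------------------------------------------------------------------------

class MeanFieldModelA:
    """Mean-field model of a static-weight heterogeneous LIF network.

    Parameters
    ----------
    degree_model : DegreeModel
        Joint in-/out-degree law of the connectivity scaffold.
    weight_dist : WeightDistribution
        Per-synapse weight law (i.i.d. across synapses).
    params : NeuronParams
        Single-population neuron and external-drive parameters.
    """

    def __init__(self, degree_model: DegreeModel, weight_dist: WeightDistribution,
                 params: NeuronParams):
        self.degree_model = degree_model
        self.weight_dist = weight_dist
        self.params = params
        self.tilt = degree_tilts(degree_model)

    def fit(self, damping: float = 0.5, tol: float = 1e-3, max_iter: int = 100,
            n_mc: int = 100_000, seed: int = 0,
            theta0: MFParamsA | None = None) -> "MeanFieldResultsA":
        theta, info = solve_theta_A(self.tilt, self.weight_dist, self.params,
                                    theta0=theta0, damping=damping, tol=tol,
                                    max_iter=max_iter, n_mc=n_mc, seed=seed)
        return MeanFieldResultsA(self, theta, info, n_mc=n_mc, seed=seed)


@dataclass
class MeanFieldResultsA:
    """Fitted Model A fixed point with reconstruction helpers."""

    model: MeanFieldModelA
    theta: MFParamsA
    info: FixedPointInfo
    n_mc: int
    seed: int

    @property
    def presyn_rate_mean(self) -> float:
        return self.theta.m

    @property
    def presyn_rate_sd(self) -> float:
        return math.sqrt(self.theta.s2)

    def input_stats(self) -> InputStatsA:
        return input_stats_from_weights(self.theta, self.model.weight_dist)

    def sample_rates(self, n: int = 1_000_000, seed: int | None = None) -> np.ndarray:
        """Network (untilted) firing-rate sample in Hz."""
        return sample_rate_distribution_A(
            self.theta, self.model.tilt.network, self.model.weight_dist,
            self.model.params, n=n,
            seed=self.seed + 1 if seed is None else seed)

    def summary(self) -> str:
        t = self.theta
        i = self.info
        lines = [
            "Mean-field fixed point -- Model A (static weights)",
            "=" * 52,
            f"presynaptic rate mean m      {t.m:12.4f} Hz",
            f"presynaptic rate var  s2     {t.s2:12.4f} Hz^2",
            f"presynaptic rate s.d.        {math.sqrt(t.s2):12.4f} Hz",
            f"iterations                   {i.n_iter:12d}",
            f"residual ||theta - F||       {i.residual_norm:12.3e}",
            f"MC standard errors           ({i.mc_se[0]:.3e}, {i.mc_se[1]:.3e})",
            f"converged                    {str(i.converged):>12s}",
        ]
        return "\n".join(lines)
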