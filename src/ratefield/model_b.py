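"""Mean-field theory for plastic heterogeneous networks (Model B).

At equilibrium every weight is a separable function of the pre- and
postsynaptic rates, w = sign * g_pre(nu_pre) * g_post(nu_post), so the
per-edge input summands seen by any postsynaptic neuron,

    v_j = ( g_pre(nu_j) nu_j,  g_pre(nu_j)^2 nu_j ),

are a *network* property: their mean vector and covariance matrix form the
five mean-field unknowns theta = (m_mu, s_mu2, m_sig, s_sig2, c_musig).
Given theta, a neuron with identity X = (K, Y, Z) has a rate solving the
scalar equation

    nu = phi( mu(nu), sigma(nu) ),
    mu(nu)     = tau sign g_post(nu) (K m_mu  + sqrt(K) Y) + mu_ext,
    sigma2(nu) = tau g_post(nu)^2    (K m_sig + sqrt(K) Z) + sigma2_ext,

denoted Phi(theta, X); the smallest non-negative root is taken (continuity
with the g0 -> 0 limit).  Self-consistency sets theta equal to the moments
of v over presynaptic neurons, i.e. with K drawn from the tilted in-degree
law -- a five-dimensional fixed point solved by damped Picard iteration on
Monte-Carlo estimates with common random numbers.

Internal rate unit is ms^-1 (so eps keeps its ms^-2 unit); all public
rates are Hz.  theta therefore carries mV ms^-2 / mV^2 ms^-3 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .degrees import DegreeDist, DegreeModel, DegreeTilt, degree_tilts
from .kernels import SeparableKernel, equilibrium_weight
from .model_a import ConvergenceError, FixedPointInfo, RATE_FLOOR
from .params import ConfigError, NeuronParams
from .transfer import external_input_moments, phi_vec, solve_homogeneous

__all__ = [
    "MFParamsB",
    "solve_rate_scalar",
    "solve_rates_batch",
    "evaluate_G",
    "solve_theta_B",
    "sample_rate_distribution_B",
    "sample_weight_distribution_B",
    "MeanFieldModelB",
    "MeanFieldResultsB",
]


@dataclass(frozen=True)
class MFParamsB:
    """Moments of the per-edge summands (g_pre(nu) nu, g_pre(nu)^2 nu)."""

    m_mu: float
    s_mu2: float
    m_sig: float
    s_sig2: float
    c_musig: float

    def __post_init__(self):
        if self.s_mu2 < 0 or self.s_sig2 < 0:
            raise ConfigError("variances must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_mu, self.s_mu2, self.m_sig,
                         self.s_sig2, self.c_musig])

    @classmethod
    def from_array(cls, a) -> "MFParamsB":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(max(a[1], 0.0)), float(a[2]),
                   float(max(a[3], 0.0)), float(a[4]))

    def chol(self) -> tuple[float, float, float]:
        """Cholesky factors of the PSD-projected covariance of (v_mu, v_sig)."""
        bound = math.sqrt(max(self.s_mu2 * self.s_sig2, 0.0))
        c = max(-bound, min(bound, self.c_musig))
        a = math.sqrt(max(self.s_mu2, 0.0))
        if a > 0:
            b = c / a
            d = math.sqrt(max(self.s_sig2 - b * b, 0.0))
        else:
            b, d = 0.0, math.sqrt(max(self.s_sig2, 0.0))
        return a, b, d


def _residual_rates(nu_ms, A, B, kernel: SeparableKernel, p: NeuronParams,
                    ext) -> np.ndarray:
    """nu - phi(mu(nu), sigma(nu)) in ms^-1, vectorised over samples."""
    gp = kernel.g_post(nu_ms)
    mu = p.tau * kernel.sign * gp * A + ext.mu
    rec = p.tau * gp * gp * B
    sig2 = np.maximum(rec, 0.0) + ext.sigma2
    return nu_ms - phi_vec(mu, np.sqrt(sig2), p) / 1000.0


def solve_rates_batch(theta: MFParamsB, K, Y, Z, kernel: SeparableKernel,
                      p: NeuronParams, n_grid: int = 400,
                      n_bisect: int = 52) -> np.ndarray:
    """Smallest non-negative root of the scalar rate equation, vectorised.

    Scans the rate grid over [0, 1/tau_ref] in blocks, keeping only samples
    whose first sign change has not yet been found (the residual at nu = 0
    is -phi <= 0, and at the refractory bound it is >= 0, so a bracket
    always exists), then refines by bisection.  Rates returned in Hz.
    """
    K = np.asarray(K, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    sqk = np.sqrt(K)
    A = K * theta.m_mu + sqk * Y
    B = K * theta.m_sig + sqk * Z
    ext = external_input_moments(p)
    n = A.size
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
        r = _residual_rates(ks[:, None], A[active], B[active], kernel, p, ext)
        nonneg = r >= 0.0
        any_hit = nonneg.any(axis=0)
        first = np.argmax(nonneg, axis=0)
        hit_idx = active[any_hit]
        jf = first[any_hit]
        hi[hit_idx] = ks[jf]
        lo[hit_idx] = grid[k + jf - 1] if np.isscalar(jf) else grid[k - 1 + jf]
        found[hit_idx] = True
        active = active[~any_hit]
        k += block
    # anything left unbracketed sits at the refractory bound by construction
    lo[~found] = grid[-2]

    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        r = _residual_rates(mid, A, B, kernel, p, ext)
        neg = r < 0.0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi) * 1000.0


def solve_rate_scalar(theta: MFParamsB, K: float, Y: float, Z: float,
                      kernel: SeparableKernel, p: NeuronParams,
                      n_grid: int = 400, tol: float = 1e-6,
                      return_all: bool = False):
    """Scalar rate equation Phi(theta, X): full 400-point scan of
    [0, 1/tau_ref] with every sign change refined by bisection to
    ``|residual| < tol`` Hz.  Returns the smallest root (Hz), or the sorted
    list of all roots when ``return_all``."""
    sqk = math.sqrt(K)
    A = np.array([K * theta.m_mu + sqk * Y])
    B = np.array([K * theta.m_sig + sqk * Z])
    ext = external_input_moments(p)
    nu_max = 1.0 / p.tau_ref if p.tau_ref > 0 else 0.6
    grid = np.linspace(0.0, nu_max, n_grid)
    res = np.array([_residual_rates(np.array([g]), A, B, kernel, p, ext)[0]
                    for g in grid])
    roots = []
    for i in range(n_grid - 1):
        if res[i] == 0.0:
            roots.append(grid[i])
        if res[i] * res[i + 1] < 0:
            lo, hi = grid[i], grid[i + 1]
            flo = res[i]
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                fm = _residual_rates(np.array([mid]), A, B, kernel, p, ext)[0]
                if abs(fm) * 1000.0 < tol:
                    break
                if flo * fm < 0:
                    hi = mid
                else:
                    lo, flo = mid, fm
            roots.append(mid)
    if res[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        raise RuntimeError("no root of the scalar rate equation found")
    roots = sorted(1000.0 * r for r in roots)
    return roots if return_all else roots[0]


# ---------------------------------------------------------------------------
# self-consistency map and fixed point
# ---------------------------------------------------------------------------

def _summand_moments(nu_hz: np.ndarray, kernel: SeparableKernel
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Five-vector of moments of (g_pre(nu) nu, g_pre(nu)^2 nu) plus s.e."""
    nu = nu_hz / 1000.0
    gpre = kernel.g_pre(nu)
    a = gpre * nu
    b = gpre * gpre * nu
    n = a.size
    ma, mb = float(a.mean()), float(b.mean())
    da, db = a - ma, b - mb
    va = float(da @ da) / n
    vb = float(db @ db) / n
    cab = float(da @ db) / n
    se = np.array([
        math.sqrt(va / n),
        math.sqrt(max(float((da ** 4).mean()) - va ** 2, 0.0) / n),
        math.sqrt(vb / n),
        math.sqrt(max(float((db ** 4).mean()) - vb ** 2, 0.0) / n),
        math.sqrt(max(float(((da * db - cab) ** 2).mean()), 0.0) / n),
    ])
    return np.array([ma, va, mb, vb, cab]), se


def evaluate_G(theta: MFParamsB, tilt: DegreeTilt, kernel: SeparableKernel,
               p: NeuronParams, n_mc: int = 100_000,
               seed: int | np.random.Generator = 0,
               draws: tuple | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the five-component map G(theta) and its s.e.

    K from the presynaptic (tilted) in-degree law, (Y, Z) ~ N(0, Sigma(theta)).
    """
    if n_mc < 1000:
        raise ConfigError("n_mc must be >= 1000")
    if draws is None:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        draws = (rng.random(n_mc), rng.standard_normal(n_mc),
                 rng.standard_normal(n_mc))
    u_k, g1, g2 = draws
    K = tilt.presyn.sample_from_uniforms(u_k)
    a, b, d = theta.chol()
    Y = a * g1
    Z = b * g1 + d * g2
    nu = solve_rates_batch(theta, K, Y, Z, kernel, p)
    return _summand_moments(nu, kernel)


def solve_theta_B(tilt: DegreeTilt, kernel: SeparableKernel, p: NeuronParams,
                  theta0: MFParamsB | None = None, damping: float = 0.5,
                  tol: float = 1e-3, max_iter: int = 60,
                  n_mc: int = 100_000, seed: int = 0,
                  ) -> tuple[MFParamsB, FixedPointInfo]:
    """Damped Picard iteration on theta = G(theta) with common random
    numbers; converged when the relative update is below ``tol`` and the
    residual is within 3 MC standard errors componentwise."""
    if not (0 < damping <= 1):
        raise ConfigError("damping must be in (0, 1]")
    rng = np.random.default_rng(seed)
    draws = (rng.random(n_mc), rng.standard_normal(n_mc),
             rng.standard_normal(n_mc))
    if theta0 is None:
        theta = homogeneous_theta0(tilt, kernel, p)
    else:
        theta = theta0
    traj = [theta.as_array()]
    scale = max(abs(theta.m_mu), 1e-12)
    for it in range(1, max_iter + 1):
        G, se = evaluate_G(theta, tilt, kernel, p, n_mc=n_mc, draws=draws)
        cur = theta.as_array()
        new = (1.0 - damping) * cur + damping * G
        resid = G - cur
        traj.append(new)
        rel = np.abs(new - cur) / np.maximum(np.abs(cur), 1e-3 * scale)
        theta = MFParamsB.from_array(new)
        if np.all(rel < tol) and np.all(np.abs(resid) <= 3.0 * se + 1e-15):
            return theta, FixedPointInfo(True, it, resid, se, np.array(traj))
    raise ConvergenceError(
        f"Model B fixed point not converged after {max_iter} iterations",
        trajectory=np.array(traj))


def homogeneous_theta0(tilt: DegreeTilt, kernel: SeparableKernel,
                       p: NeuronParams) -> MFParamsB:
    """Zero-variance initialisation from the homogeneous plastic network:
    the smallest homogeneous root at the mean degree."""
    roots = solve_homogeneous(p, tilt.mean_degree, kernel.weight_homogeneous_hz)
    if roots:
        nu = roots[0] / 1000.0
    else:
        ext = external_input_moments(p)
        nu = float(phi_vec(ext.mu, ext.sigma, p)) / 1000.0
    gp = float(kernel.g_pre(nu))
    return MFParamsB(gp * nu, 0.0, gp * gp * nu, 0.0, 0.0)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _identity_rates(theta: MFParamsB, dist: DegreeDist, kernel, p,
                    n: int, rng: np.random.Generator) -> np.ndarray:
    K = dist.sample(n, rng)
    a, b, d = theta.chol()
    g1 = rng.standard_normal(n)
    g2 = rng.standard_normal(n)
    return solve_rates_batch(theta, K, a * g1, b * g1 + d * g2, kernel, p)


def sample_rate_distribution_B(theta: MFParamsB, network_in: DegreeDist,
                               kernel: SeparableKernel, p: NeuronParams,
                               n: int = 200_000, seed: int = 0) -> np.ndarray:
    """Network rate sample (Hz): K from the untilted in-degree law."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    nu = _identity_rates(theta, network_in, kernel, p, n, rng)
    return np.clip(nu, RATE_FLOOR, p.nu_max)


def sample_weight_distribution_B(theta: MFParamsB, tilt: DegreeTilt,
                                 kernel: SeparableKernel, p: NeuronParams,
                                 n: int = 200_000, seed: int = 0) -> np.ndarray:
    """Equilibrium weight sample (mV) over random edges.

    The postsynaptic endpoint's in-degree is size-biased (k P(k) / <K>) and
    the presynaptic endpoint's is tilted through the conditional mean
    out-degree; the two identities are independent given the tilted laws.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    nu_pre = _identity_rates(theta, tilt.presyn, kernel, p, n, rng)
    nu_post = _identity_rates(theta, tilt.postsyn, kernel, p, n, rng)
    return equilibrium_weight(nu_pre, nu_post, kernel)


# ---------------------------------------------------------------------------
# model / results presentation
# ---------------------------------------------------------------------------

class MeanFieldModelB:
    """Mean-field model of a plastic heterogeneous LIF network.

    Parameters
    ----------
    degree_model : DegreeModel
    kernel : SeparableKernel
        Equilibrium plasticity kernel (default Oja-like).
    params : NeuronParams
    """

    def __init__(self, degree_model: DegreeModel, kernel: SeparableKernel,
                 params: NeuronParams):
        self.degree_model = degree_model
        self.kernel = kernel
        self.params = params
        self.tilt = degree_tilts(degree_model)

    def fit(self, damping: float = 0.5, tol: float = 1e-3, max_iter: int = 60,
            n_mc: int = 100_000, seed: int = 0,
            theta0: MFParamsB | None = None) -> "MeanFieldResultsB":
        theta, info = solve_theta_B(self.tilt, self.kernel, self.params,
                                    theta0=theta0, damping=damping, tol=tol,
                                    max_iter=max_iter, n_mc=n_mc, seed=seed)
        return MeanFieldResultsB(self, theta, info, n_mc=n_mc, seed=seed)


@dataclass
class MeanFieldResultsB:
    """Fitted Model B fixed point with rate/weight reconstruction."""

    model: MeanFieldModelB
    theta: MFParamsB
    info: FixedPointInfo
    n_mc: int
    seed: int

    def sample_rates(self, n: int = 200_000, seed: int | None = None) -> np.ndarray:
        return sample_rate_distribution_B(
            self.theta, self.model.tilt.network, self.model.kernel,
            self.model.params, n=n,
            seed=self.seed + 1 if seed is None else seed)

    def sample_weights(self, n: int = 200_000, seed: int | None = None) -> np.ndarray:
        return sample_weight_distribution_B(
            self.theta, self.model.tilt, self.model.kernel, self.model.params,
            n=n, seed=self.seed + 2 if seed is None else seed)

    def summary(self, n_sample: int = 50_000) -> str:
        t = self.theta
        i = self.info
        rates = self.sample_rates(n=n_sample)
        weights = self.sample_weights(n=n_sample)
        lines = [
            "Mean-field fixed point -- Model B (plastic weights)",
            "=" * 55,
            f"theta  m_mu                  {t.m_mu:14.6e} mV ms^-2",
            f"       s_mu2                 {t.s_mu2:14.6e}",
            f"       m_sig                 {t.m_sig:14.6e} mV^2 ms^-3",
            f"       s_sig2                {t.s_sig2:14.6e}",
            f"       c_musig               {t.c_musig:14.6e}",
            f"iterations                   {i.n_iter:8d}",
            f"residual ||theta - G||       {i.residual_norm:14.3e}",
            f"converged                    {str(i.converged):>8s}",
            "-" * 55,
            f"network rate mean / sd       {rates.mean():9.4f} / {rates.std():.4f} Hz",
            f"edge weight mean / sd        {weights.mean():9.5f} / {weights.std():.5f} mV",
        ]
        return "\n".join(lines)
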