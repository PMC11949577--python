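"""LIF transfer function (first-passage / Siegert rate) and input moments.

The stationary rate of an LIF neuron driven by Gaussian white-noise input
with integrated-input mean ``mu`` (mV) and variance ``sigma**2`` (mV^2)
over one membrane time constant is

    phi(mu, sigma)^-1 = tau_ref + tau * sqrt(pi) *
        Int_{(v_reset-mu)/sigma}^{(v_theta-mu)/sigma} exp(u^2) erfc(-u) du.

Naive evaluation of ``exp(u**2) * erfc(-u)`` overflows exactly where deeply
sub-threshold rates must still come out finite, so the integrand is split
into the scaled complementary error function (``erfcx``, bounded) and a
``2*exp(u**2)`` part whose antiderivative is ``sqrt(pi)*erfi``; for upper
limits beyond the range of ``erfi`` the rate is evaluated in log space from
the asymptotic expansion.

Two implementations are provided:

``phi``
    scalar, adaptive-quadrature accuracy (relative error <= 1e-8); used by
    the homogeneous fixed-point solver and wherever a single high-accuracy
    value is needed.
``phi_vec``
    vectorised, backed by a precomputed antiderivative table of ``erfcx``
    (absolute error ~1e-6 on the inverse rate, i.e. relative rate error
    below ~1e-4); used inside the Monte-Carlo mean-field solvers where
    millions of evaluations per iteration are required.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence, Union

import numpy as np
from scipy import integrate, special

from .params import ConfigError, NeuronParams

__all__ = [
    "phi",
    "phi_vec",
    "deterministic_rate",
    "external_input_moments",
    "homogeneous_input_moments",
    "solve_homogeneous",
    "InputMoments",
]

_SQRT_PI = math.sqrt(math.pi)
#: below this sigma (mV) the diffusion integral degenerates and the
#: deterministic-LIF closed form is used instead
SIGMA_SWITCH = 1e-6
#: upper integration limit beyond which the log-space asymptotic branch is
#: used (erfi overflows near 26.6; rates there are < 1e-25 Hz anyway)
_B_ASYMPTOTIC = 25.0


class InputMoments:
    """Mean ``mu`` (mV) and variance ``sigma2`` (mV^2) of the integrated input."""

    __slots__ = ("mu", "sigma2")

    def __init__(self, mu: float, sigma2: float):
        if sigma2 < 0:
            raise ConfigError("input variance must be >= 0")
        self.mu = float(mu)
        self.sigma2 = float(sigma2)

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    def __iter__(self):
        return iter((self.mu, self.sigma2))

    def __repr__(self) -> str:  # pragma: no cover
        return f"InputMoments(mu={self.mu:.6g}, sigma2={self.sigma2:.6g})"


# ---------------------------------------------------------------------------
# integrand pieces
# ---------------------------------------------------------------------------

def _g(u):
    """Bounded part of exp(u^2)*erfc(-u): erfcx(-u) for u<=0, -erfcx(u) for u>0."""
    u = np.asarray(u, dtype=float)
    return np.where(u <= 0.0, special.erfcx(-u), -special.erfcx(u))


# Antiderivative table G(x) = Int_0^x g(u) du on [_X_LO, _X_HI]; linear
# interpolation plus asymptotic log tails beyond the edges.
_X_LO, _X_HI = -60.0, 8.0
_TABLE_STEP = 0.0025
_table_x: np.ndarray | None = None
_table_G: np.ndarray | None = None


def _build_table() -> None:
    # g jumps from +1 to -1 at u = 0 (the 2*exp(u^2) part absorbs the step),
    # so the two branches are integrated separately and joined at G(0) = 0.
    global _table_x, _table_G
    n_neg = int(round(-_X_LO / _TABLE_STEP))
    n_pos = int(round(_X_HI / _TABLE_STEP))
    x_neg = np.linspace(_X_LO, 0.0, n_neg + 1)
    x_pos = np.linspace(0.0, _X_HI, n_pos + 1)
    G_neg = integrate.cumulative_trapezoid(special.erfcx(-x_neg), x_neg, initial=0.0)
    G_neg -= G_neg[-1]
    G_pos = integrate.cumulative_trapezoid(-special.erfcx(x_pos), x_pos, initial=0.0)
    _table_x = np.concatenate([x_neg, x_pos[1:]])
    _table_G = np.concatenate([G_neg, G_pos[1:]])


def _erfcx_tail(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Int_lo^hi erfcx(u) du for lo >= ~8, from the asymptotic series."""
    return (np.log(hi / lo) + 0.25 / hi**2 - 0.25 / lo**2) / _SQRT_PI


# Dawson-function table on [0, _X_HI]: sqrt(pi)*erfi(x) = 2*dawsn(x)*exp(x^2)
_table_D: np.ndarray | None = None
_INV_STEP = 1.0 / _TABLE_STEP


def _build_dawson_table() -> None:
    global _table_D
    n = int(round(_X_HI / _TABLE_STEP))
    _table_D = special.dawsn(np.linspace(0.0, _X_HI, n + 1))


def _lerp(x: np.ndarray, x0: float, table: np.ndarray) -> np.ndarray:
    """Linear interpolation on a uniform grid (x assumed pre-clipped)."""
    pos = (x - x0) * _INV_STEP
    i = pos.astype(np.intp)
    np.clip(i, 0, table.size - 2, out=i)
    frac = pos - i
    lo = table[i]
    return lo + frac * (table[i + 1] - lo)


def _G_vec(x: np.ndarray) -> np.ndarray:
    if _table_x is None:
        _build_table()
    xc = np.clip(x, _X_LO, _X_HI)
    out = _lerp(xc, _X_LO, _table_G)
    hi = x > _X_HI
    if np.any(hi):
        out[hi] -= _erfcx_tail(np.full(np.count_nonzero(hi), _X_HI), x[hi])
    lo = x < _X_LO
    if np.any(lo):
        # g(u) = erfcx(-u) > 0 for u < 0
        out[lo] -= _erfcx_tail(np.full(np.count_nonzero(lo), -_X_LO), -x[lo])
    return out


def _sqrtpi_erfi_vec(x: np.ndarray) -> np.ndarray:
    """sqrt(pi)*erfi(x) for 0 <= x <= _X_HI via the Dawson table."""
    if _table_D is None:
        _build_dawson_table()
    return 2.0 * _lerp(x, 0.0, _table_D) * np.exp(x * x)


# ---------------------------------------------------------------------------
# deterministic (noise-free) limit
# ---------------------------------------------------------------------------

def deterministic_rate(mu: float, p: NeuronParams) -> float:
    """Noise-free LIF rate (Hz): 0 below threshold, else the closed form
    ``1 / (tau_ref + tau * ln((mu - v_reset)/(mu - v_theta)))``."""
    if mu <= p.v_theta:
        return 0.0
    inv_ms = p.tau_ref + p.tau * math.log((mu - p.v_reset) / (mu - p.v_theta))
    return 1000.0 / inv_ms


def _log_rate_asymptotic(b: float, tau: float) -> float:
    """log of the rate (in ms^-1) for upper limit b >> 1 (deeply sub-threshold)."""
    corr = 1.0 + 0.5 / b**2 + 0.75 / b**4
    return -(b * b) - math.log(tau * _SQRT_PI * corr / b)


def phi(mu: float, sigma: float, p: NeuronParams) -> float:
    """Siegert transfer function: stationary LIF rate in Hz.

    Parameters
    ----------
    mu, sigma : float
        Mean (mV) and standard deviation (mV) of the input integrated over
        one membrane time constant.
    p : NeuronParams
        Provides tau, v_theta, v_reset, tau_ref.
    """
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if sigma < SIGMA_SWITCH:
        return deterministic_rate(mu, p)
    a = (p.v_reset - mu) / sigma
    b = (p.v_theta - mu) / sigma
    if b > _B_ASYMPTOTIC:
        # tau_ref is utterly negligible against exp(b^2) here
        log_rate_ms = _log_rate_asymptotic(b, p.tau)
        try:
            return 1000.0 * math.exp(log_rate_ms)
        except OverflowError:  # pragma: no cover
            return 0.0
    # bounded erfcx part, split at the kink u = 0; far-left tail analytic
    i_g = 0.0
    if a < _X_LO:
        hi_end = min(b, _X_LO)
        i_g += float(_erfcx_tail(np.asarray(-hi_end), np.asarray(-a)))
        a = hi_end
    pieces = []
    if a < 0.0:
        pieces.append((a, min(b, 0.0)))
    if b > 0.0:
        pieces.append((max(a, 0.0), b))
    for lo, hi in pieces:
        val, _ = integrate.quad(lambda u: float(_g(u)), lo, hi,
                                epsabs=1e-14, epsrel=1e-11, limit=200)
        i_g += val
    bp, ap = max(b, 0.0), max(a, 0.0)
    i_exp = _SQRT_PI * (special.erfi(bp) - special.erfi(ap))
    inv_ms = p.tau_ref + p.tau * _SQRT_PI * (i_exp + i_g)
    return 1000.0 / inv_ms


def phi_vec(mu, sigma, p: NeuronParams) -> np.ndarray:
    """Vectorised Siegert rate (Hz); see :func:`phi` for conventions."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    mu, sigma = np.broadcast_arrays(mu, sigma)
    out = np.empty(mu.shape, dtype=float)

    det = sigma < SIGMA_SWITCH
    if np.any(det):
        md = mu[det]
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = p.tau_ref + p.tau * np.log((md - p.v_reset) / (md - p.v_theta))
        out[det] = np.where(md > p.v_theta, 1000.0 / inv, 0.0)

    st = ~det
    if np.any(st):
        s = sigma[st]
        a = (p.v_reset - mu[st]) / s
        b = (p.v_theta - mu[st]) / s
        rates = np.empty(a.shape, dtype=float)

        big = b > _X_HI
        if np.any(big):
            bb = b[big]
            corr = 1.0 + 0.5 / bb**2 + 0.75 / bb**4
            with np.errstate(under="ignore"):
                rates[big] = 1000.0 * np.exp(-bb * bb) * bb / (p.tau * _SQRT_PI * corr)

        reg = ~big
        if np.any(reg):
            ar, br = a[reg], b[reg]
            i_g = _G_vec(br) - _G_vec(ar)
            i_exp = (_sqrtpi_erfi_vec(np.maximum(br, 0.0))
                     - _sqrtpi_erfi_vec(np.maximum(ar, 0.0)))
            inv_ms = p.tau_ref + p.tau * _SQRT_PI * (i_exp + i_g)
            rates[reg] = 1000.0 / inv_ms
        out[st] = rates
    return out


# ---------------------------------------------------------------------------
# input-moment assembly
# ---------------------------------------------------------------------------

def external_input_moments(p: NeuronParams) -> InputMoments:
    """Moments of the external Poisson drive integrated over tau:
    ``mu_ext = tau*K_ext*w_ext*nu_ext`` and ``sigma2_ext = tau*K_ext*w_ext^2*nu_ext``."""
    tau_s = p.tau / 1000.0
    mu = tau_s * p.k_ext * p.w_ext * p.nu_ext
    s2 = tau_s * p.k_ext * p.w_ext**2 * p.nu_ext
    return InputMoments(mu, s2)


def homogeneous_input_moments(
    nu: float,
    K: float,
    w: Union[float, Callable[[float], float]],
    p: NeuronParams,
) -> InputMoments:
    """Input moments of a neuron in a homogeneous network firing at ``nu`` Hz.

    ``w`` is either a fixed weight (mV) or a rate-dependent equilibrium
    kernel ``w(nu)`` (the plastic, Model-B variant).
    """
    if nu < 0:
        raise ConfigError("rate must be >= 0")
    w_val = w(nu) if callable(w) else w
    tau_s = p.tau / 1000.0
    ext = external_input_moments(p)
    mu = tau_s * K * w_val * nu + ext.mu
    s2 = tau_s * K * w_val**2 * nu + ext.sigma2
    return InputMoments(mu, s2)


def solve_homogeneous(
    p: NeuronParams,
    K: float,
    w: Union[float, Callable[[float], float]],
    n_grid: int = 2000,
    tol: float = 1e-6,
) -> list[float]:
    """All self-consistent rates of the homogeneous network, sorted ascending.

    Scans ``nu - phi(mu(nu), sigma(nu))`` on a grid over [0, 1/tau_ref] and
    refines every sign change by bisection to ``|residual| < tol`` Hz.
    Returns an empty list when no sign change is found.
    """

    def resid(nu: float) -> float:
        m = homogeneous_input_moments(nu, K, w, p)
        return nu - phi(m.mu, m.sigma, p)

    grid = np.linspace(0.0, p.nu_max, n_grid)
    vals = np.array([resid(v) for v in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        f0, f1 = vals[i], vals[i + 1]
        if f0 == 0.0:
            roots.append(grid[i])
            continue
        if f0 * f1 < 0:
            lo, hi, flo = grid[i], grid[i + 1], f0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                fm = resid(mid)
                if abs(fm) < tol:
                    break
                if flo * fm < 0:
                    hi = mid
                else:
                    lo, flo = mid, fm
            roots.append(mid)
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # dedupe near-identical roots from adjacent brackets
    out: list[float] = []
    for r in sorted(roots):
        if not out or r - out[-1] > 1e-6 * max(1.0, out[-1]):
            out.append(float(r))
    return out
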