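"""Statistics of the spike trace of a Poisson neuron.

The trace R(t) decays exponentially with time constant tau_p and jumps by 1
at every spike of its neuron.  For Poisson firing at rate nu the stationary
law of R depends only on the dimensionless rate-memory product

    alpha = tau_p * nu,

and its density satisfies the delay ODE

    r * rho'(r) = (alpha - 1) * rho(r) - alpha * rho(r - 1),

an exponentially filtered Poisson (shot-noise) process with cumulants
kappa_n = alpha / n.  On [0, 1) the shifted term vanishes and the density
is exactly proportional to r**(alpha - 1); beyond r = 1 the equation is
marched interval by interval using the exact integrating factor

    rho(r) = r**(alpha-1) * [ rho(n) * n**(1-alpha)
                              - alpha * Int_n^r u**(-alpha) rho(u-1) du ],

with the integral accumulated by Simpson's rule on a grid aligned so that
rho(u - 1) is available at the nodes without interpolation.  The analytic
first interval handles the r -> 0 singularity for alpha < 1, and a running
rescale (with per-interval log offsets) keeps the march in floating-point
range for large alpha, where the unnormalised solution spans hundreds of
orders of magnitude.

The tau_p-normalised trace nu_hat = R / tau_p estimates the firing rate;
its coefficient of variation at stationarity is 1 / sqrt(2 * alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .params import ConfigError

__all__ = [
    "TraceDensity",
    "TraceMoments",
    "stationary_trace_density",
    "stationary_trace_moments",
    "transient_trace_moments",
    "trace_cv",
    "simulate_trace_ensemble",
    "trace_from_spikes",
]


@dataclass
class TraceMoments:
    """Mean and centred moments of the trace R.

    ``central[n]`` holds <R_n> for n = 0..n_max (so ``central[0] = 1`` and
    ``central[1] = 0``).  ``time`` is in ms, with ``inf`` for stationarity.
    """

    alpha: float
    mean: float
    central: np.ndarray
    time: float = math.inf

    @property
    def var(self) -> float:
        return float(self.central[2])

    @property
    def cv(self) -> float:
        return math.sqrt(self.var) / self.mean if self.mean > 0 else math.nan

    @property
    def skewness(self) -> float:
        return float(self.central[3] / self.central[2] ** 1.5)


def stationary_trace_moments(alpha: float, n_max: int = 4) -> TraceMoments:
    """Stationary moments from the exact recursion
    ``<R> = alpha``, ``<R_n> = (alpha/n) * (1 + sum_{k=2}^{n-2} C(n,k) <R_k>)``.
    """
    if alpha <= 0:
        raise ConfigError("alpha must be > 0")
    if n_max < 2:
        raise ConfigError("n_max must be >= 2")
    central = np.zeros(n_max + 1)
    central[0] = 1.0
    for n in range(2, n_max + 1):
        acc = 1.0
        for k in range(2, n - 1):
            acc += math.comb(n, k) * central[k]
        central[n] = alpha / n * acc
    return TraceMoments(alpha=alpha, mean=alpha, central=central)


def transient_trace_moments(
    alpha: float,
    tau_p: float,
    t: float,
    initial: TraceMoments | None = None,
    n_max: int = 4,
    rtol: float = 1e-10,
) -> TraceMoments:
    """Moments at time ``t`` (ms) from the coupled moment ODEs.

    The system, in units of s = t/tau_p, is
    ``d<R>/ds = -<R> + alpha`` and
    ``d<R_n>/ds = -n <R_n> + alpha (1 + sum_{k=2}^{n-2} C(n,k) <R_k>)``.
    ``initial=None`` starts from R = 0 (all moments zero).
    """
    if t < 0:
        raise ConfigError("t must be >= 0")
    if initial is None:
        y0 = np.zeros(n_max)          # [mean, m2, ..., m_nmax]
    else:
        y0 = np.concatenate([[initial.mean], initial.central[2:n_max + 1]])

    def rhs(_s, y):
        dy = np.empty_like(y)
        dy[0] = -y[0] + alpha
        for n in range(2, n_max + 1):
            acc = 1.0
            for k in range(2, n - 1):
                acc += math.comb(n, k) * y[k - 1]
            dy[n - 1] = -n * y[n - 1] + alpha * acc
        return dy

    if t == 0:
        y = y0
    else:
        sol = integrate.solve_ivp(rhs, (0.0, t / tau_p), y0, method="Radau",
                                  rtol=rtol, atol=1e-12)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"moment ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
    central = np.zeros(n_max + 1)
    central[0] = 1.0
    central[2:] = y[1:]
    return TraceMoments(alpha=alpha, mean=float(y[0]), central=central, time=t)


def trace_cv(alpha: float) -> float:
    """Stationary coefficient of variation of the trace, 1/sqrt(2*alpha)."""
    if alpha <= 0:
        raise ConfigError("alpha must be > 0")
    return 1.0 / math.sqrt(2.0 * alpha)


# ---------------------------------------------------------------------------
# stationary density
# ---------------------------------------------------------------------------

@dataclass
class TraceDensity:
    """Stationary density of the trace R at rate-memory product ``alpha``.

    ``grid``/``values`` hold the normalised density on [0, r_max].  On the
    first unit interval the density is exactly ``coeff0 * r**(alpha-1)``
    (``values[0]`` is inf for alpha < 1); quadrature helpers treat that
    piece analytically.
    """

    alpha: float
    grid: np.ndarray
    values: np.ndarray
    coeff0: float                  # normalised coefficient of r**(alpha-1) on [0,1)
    step: float
    _cdf: np.ndarray = field(default=None, repr=False)

    def moment(self, n: int) -> float:
        """Raw moment E[R^n] by analytic-first-interval + trapezoid quadrature."""
        a = self.alpha
        head = self.coeff0 / (a + n)                    # Int_0^1 r^n c r^(a-1) dr
        i1 = int(round(1.0 / self.step))
        r, v = self.grid[i1:], self.values[i1:]
        return head + float(np.trapezoid(v * r ** n, r))

    @property
    def mass(self) -> float:
        a = self.alpha
        i1 = int(round(1.0 / self.step))
        return self.coeff0 / a + float(np.trapezoid(self.values[i1:], self.grid[i1:]))

    def mean(self) -> float:
        return self.moment(1)

    def var(self) -> float:
        m = self.moment(1)
        return self.moment(2) - m * m

    def central_moment(self, n: int) -> float:
        m = self.mean()
        i1 = int(round(1.0 / self.step))
        r, v = self.grid[i1:], self.values[i1:]
        tail = float(np.trapezoid(v * (r - m) ** n, r))
        # analytic piece integrated numerically in s = r**alpha to absorb the
        # singularity: r = s**(1/alpha), dr = s**(1/alpha-1)/alpha ds
        s = np.linspace(0.0, 1.0, 2001)[1:]
        r0 = s ** (1.0 / self.alpha)
        head = self.coeff0 / self.alpha * float(
            np.trapezoid((r0 - m) ** n, s))
        return head + tail

    def cdf(self, x) -> np.ndarray:
        """Distribution function of R, vectorised."""
        if self._cdf is None:
            i1 = int(round(1.0 / self.step))
            c = np.zeros_like(self.grid)
            with np.errstate(invalid="ignore"):
                c[: i1 + 1] = self.coeff0 / self.alpha * self.grid[: i1 + 1] ** self.alpha
            inc = integrate.cumulative_trapezoid(self.values[i1:], self.grid[i1:])
            c[i1 + 1:] = c[i1] + inc
            self._cdf = c
        x = np.asarray(x, dtype=float)
        lo = x < 1.0
        out = np.interp(x, self.grid, self._cdf)
        if np.any(lo):
            xl = np.clip(x[lo], 0.0, None)
            out[lo] = self.coeff0 / self.alpha * xl ** self.alpha
        return np.clip(out, 0.0, 1.0)

    def rate_density(self, tau_p: float) -> tuple[np.ndarray, np.ndarray]:
        """Density of the normalised trace nu_hat = R/tau_p in Hz:
        returns (rates_Hz, density_per_Hz)."""
        scale = tau_p / 1000.0
        return self.grid / scale, self.values * scale


def stationary_trace_density(
    alpha: float,
    step: float = 1.0 / 400,
    r_max: float | None = None,
) -> TraceDensity:
    """Solve the stationary delay ODE for the trace density.

    Parameters
    ----------
    alpha : float
        Rate-memory product tau_p * nu (> 0).
    step : float
        Grid spacing; must put at least 200 points on every unit interval.
    r_max : float, optional
        Truncation radius.  Default ``alpha + 12*sqrt(alpha/2) + 2`` keeps
        the discarded tail mass far below 1e-8.
    """
    if alpha <= 0:
        raise ConfigError("alpha must be > 0")
    n_per = int(round(1.0 / step))
    if n_per < 200:
        raise ConfigError("step too coarse: need >= 200 points per unit interval")
    if r_max is None:
        r_max = alpha + 12.0 * math.sqrt(alpha / 2.0) + 2.0
    n_int = max(2, int(math.ceil(r_max)))
    h = 1.0 / n_per

    # interval arrays (n_per+1 points each, endpoints shared) and log offsets
    vals = np.empty((n_int, n_per + 1))
    log_off = np.zeros(n_int)

    r0 = np.linspace(0.0, 1.0, n_per + 1)
    with np.errstate(divide="ignore"):
        vals[0] = r0 ** (alpha - 1.0)
    if alpha < 1.0:
        vals[0, 0] = np.inf

    for j in range(1, n_int):
        # scaled integrating factor: with q = r/j in [1, 1+1/j],
        #   rho(r) = q**(alpha-1) * [rho(j) - (alpha/j) * Qhat(r)],
        #   Qhat(r) = Int_j^r (u/j)**(-alpha) rho(u-1) du,
        # so every power stays within floating-point range for any alpha
        q = 1.0 + r0 / j
        prev = vals[j - 1]
        with np.errstate(under="ignore"):
            w = q ** (-alpha) * prev        # integrand of the shifted term
        Q = np.empty(n_per + 1)
        Q[0] = 0.0
        if j == 1:
            # the shifted term is exactly s^(a-1) (1+s)^(-a) with s = u-1
            # (singular at s=0 for a < 1, non-smooth for non-integer a);
            # product integration -- smooth factor linear per cell, the
            # s^(a-1) weight integrated exactly -- is uniformly O(h^2)
            s = r0
            f = (1.0 + s) ** (-alpha)
            i1 = np.diff(s ** alpha) / alpha                 # Int s^(a-1)
            i2 = np.diff(s ** (alpha + 1.0)) / (alpha + 1.0)  # Int s^a
            cells = f[:-1] * i1 + (f[1:] - f[:-1]) / h * (i2 - s[:-1] * i1)
            Q[1:] = np.cumsum(cells)
        else:
            Q[1:] = integrate.cumulative_simpson(w, dx=h)
        with np.errstate(under="ignore"):
            ynew = q ** (alpha - 1.0) * (prev[-1] - alpha / j * Q)
        np.clip(ynew, 0.0, None, out=ynew)   # guard tiny negative round-off in the tail
        m = ynew.max()
        log_off[j] = log_off[j - 1]
        if m > 1e100 or (0.0 < m < 1e-100):
            ynew /= m
            log_off[j] += math.log(m)
        vals[j] = ynew

    # assemble on a common scale (two-stage multiply: each stage stays in range)
    with np.errstate(divide="ignore"):
        peak_log = np.array([
            (np.log(np.max(np.where(np.isfinite(v), v, 0.0))) if np.any(v > 0) else -np.inf)
            + lo for v, lo in zip(vals, log_off)
        ])
    ref = float(np.max(peak_log[np.isfinite(peak_log)]))
    with np.errstate(under="ignore"):
        for j in range(n_int):
            f = log_off[j] - ref
            if f < -1480.0:
                vals[j] = np.zeros(n_per + 1)
            else:
                half = math.exp(0.5 * f)
                vals[j] = vals[j] * half * half

    grid = np.concatenate([np.linspace(j, j + 1, n_per + 1)[:-1] for j in range(n_int)]
                          + [[float(n_int)]])
    dens = np.concatenate([vals[j][:-1] for j in range(n_int)] + [[vals[-1][-1]]])

    coeff0 = math.exp(log_off[0] - ref) if log_off[0] - ref > -700 else 0.0
    td = TraceDensity(alpha=alpha, grid=grid, values=dens, coeff0=coeff0, step=h)
    mass = td.mass
    if not (mass > 0 and np.isfinite(mass)):
        raise RuntimeError("density march failed to produce finite mass")
    td.values = dens / mass
    td.coeff0 = coeff0 / mass
    td._cdf = None
    mean = td.mean()
    if abs(mean - alpha) > 5e-3 * alpha:
        raise RuntimeError(
            f"density resolution failure: mean {mean:.6g} vs alpha {alpha:.6g}")
    return td


# ---------------------------------------------------------------------------
# Monte-Carlo ensemble and closed-form trajectory
# ---------------------------------------------------------------------------

def simulate_trace_ensemble(
    nu: float,
    tau_p: float,
    n_traj: int,
    t_end: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Samples of the normalised trace nu_hat(t_end) (Hz) over independent
    Poisson trajectories starting from R(0) = 0.

    Each trajectory draws a Poisson spike train of rate ``nu`` (Hz) on
    [0, t_end] (ms) and evaluates R(t_end) = sum_k exp(-(t_end - t_k)/tau_p)
    in closed form.
    """
    if n_traj < 1 or t_end < 0:
        raise ConfigError("need n_traj >= 1 and t_end >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if nu == 0 or t_end == 0:
        return np.zeros(n_traj)
    lam = nu * t_end / 1000.0
    counts = rng.poisson(lam, n_traj)
    total = int(counts.sum())
    times = rng.uniform(0.0, t_end, total)
    idx = np.repeat(np.arange(n_traj), counts)
    with np.errstate(under="ignore"):
        contrib = np.exp(-(t_end - times) / tau_p)
    R = np.bincount(idx, weights=contrib, minlength=n_traj)
    return R / tau_p * 1000.0


def trace_from_spikes(spike_times: np.ndarray, tau_p: float, t_eval: np.ndarray,
                      r0: float = 0.0, t0: float = 0.0) -> np.ndarray:
    """Closed-form trace R(t) for a known spike train (times in ms)."""
    spike_times = np.asarray(spike_times, dtype=float)
    t_eval = np.asarray(t_eval, dtype=float)
    out = r0 * np.exp(-(t_eval - t0) / tau_p)
    for tk in spike_times:
        with np.errstate(under="ignore"):
            out = out + np.where(t_eval >= tk, np.exp(-(t_eval - tk) / tau_p), 0.0)
    return out
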