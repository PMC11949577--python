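"""Separable equilibrium kernels of the trace-driven plasticity rule.

At equilibrium (reliable traces) every weight factorises as

    w* = sign * g_pre(nu_pre) * g_post(nu_post),

with the default Oja-like pair g_pre(nu) = g0 * nu  (mV) and
g_post(nu) = nu / (nu**2 + eps)  (ms).  Rates are handled internally in
ms^-1 so that eps keeps its natural ms^-2 unit; the public entry points
take Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import ConfigError, PlasticityRule

__all__ = ["SeparableKernel", "equilibrium_weight"]


@dataclass(frozen=True)
class SeparableKernel:
    """Equilibrium weight map w* = sign * g_pre(nu_pre) * g_post(nu_post).

    Custom ``g_pre``/``g_post`` callables must accept rates in ms^-1
    (vectorised); the defaults implement the Oja-like rule.
    """

    g0: float = 0.1
    eps: float = 1e-3
    sign: int = 1
    g_pre_fn: Callable | None = None
    g_post_fn: Callable | None = None

    def __post_init__(self):
        if self.g0 < 0 or self.eps <= 0:
            raise ConfigError("need g0 >= 0 and eps > 0")
        if self.sign not in (-1, 1):
            raise ConfigError("sign must be +1 or -1")

    @classmethod
    def from_rule(cls, rule: PlasticityRule) -> "SeparableKernel":
        return cls(g0=rule.g0, eps=rule.eps, sign=rule.sign)

    def g_pre(self, nu_ms):
        """Presynaptic factor (mV); nu in ms^-1."""
        if self.g_pre_fn is not None:
            return self.g_pre_fn(nu_ms)
        return self.g0 * np.asarray(nu_ms, dtype=float)

    def g_post(self, nu_ms):
        """Postsynaptic factor (ms); nu in ms^-1."""
        nu = np.asarray(nu_ms, dtype=float)
        if self.g_post_fn is not None:
            return self.g_post_fn(nu)
        return nu / (nu * nu + self.eps)

    def weight(self, nu_pre_ms, nu_post_ms):
        return self.sign * self.g_pre(nu_pre_ms) * self.g_post(nu_post_ms)

    def weight_homogeneous_hz(self, nu_hz: float) -> float:
        """w(nu) for a homogeneous network, rates in Hz (for the scalar
        fixed-point interface of the transfer module)."""
        nu = nu_hz / 1000.0
        return float(self.weight(nu, nu))


def equilibrium_weight(nu_pre_hz, nu_post_hz, kernel: SeparableKernel):
    """Equilibrium weight (mV) for pre/post rates given in Hz."""
    nu_pre = np.asarray(nu_pre_hz, dtype=float) / 1000.0
    nu_post = np.asarray(nu_post_hz, dtype=float) / 1000.0
    if np.any(nu_pre < 0) or np.any(nu_post < 0):
        raise ConfigError("rates must be >= 0")
    out = kernel.weight(nu_pre, nu_post)
    return float(out) if out.ndim == 0 else out
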