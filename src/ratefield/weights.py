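"""Static synaptic-weight distributions (Model A).

Only the first four raw moments enter the mean-field equations; sampling is
needed to build microscopic networks.  The signed-gamma family covers the
inhibitory networks of interest: w = sign * Gamma(shape, scale) with
shape * scale = |E[w]| and shape * scale**2 = Var[w].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigError

__all__ = ["WeightDistribution"]


@dataclass(frozen=True)
class WeightDistribution:
    """First four raw moments of the per-synapse weight (mV^n), plus an
    optional sampler for microscopic runs."""

    kind: str
    m1: float
    m2: float
    m3: float
    m4: float
    shape: float = 0.0
    scale: float = 0.0
    sign: int = 1

    def __post_init__(self):
        if self.m2 < self.m1 ** 2 - 1e-12:
            raise ConfigError("E[w^2] >= E[w]^2 violated")
        if self.m4 < self.m2 ** 2 - 1e-12:
            raise ConfigError("E[w^4] >= E[w^2]^2 violated")
        for v in (self.m1, self.m2, self.m3, self.m4):
            if not np.isfinite(v):
                raise ConfigError("weight moments must be finite")

    # -- constructors -------------------------------------------------------
    @classmethod
    def degenerate(cls, c: float) -> "WeightDistribution":
        return cls("degenerate", c, c ** 2, c ** 3, c ** 4)

    @classmethod
    def signed_gamma(cls, mean: float, var: float) -> "WeightDistribution":
        """Gamma law carrying the sign of ``mean``; ``var`` > 0."""
        if var <= 0 or mean == 0:
            raise ConfigError("signed gamma needs mean != 0 and var > 0")
        sign = 1 if mean > 0 else -1
        am = abs(mean)
        scale = var / am
        shape = am * am / var
        # raw gamma moments: E[x^n] = scale^n * shape (shape+1) ... (shape+n-1)
        raw = [1.0]
        for i in range(4):
            raw.append(raw[-1] * scale * (shape + i))
        return cls("signed-gamma", sign * raw[1], raw[2], sign * raw[3], raw[4],
                   shape=shape, scale=scale, sign=sign)

    @classmethod
    def from_moments(cls, m1: float, m2: float, m3: float, m4: float
                     ) -> "WeightDistribution":
        return cls("moments", m1, m2, m3, m4)

    # -- queries ------------------------------------------------------------
    def raw_moment(self, n: int) -> float:
        return (self.m1, self.m2, self.m3, self.m4)[n - 1]

    @property
    def mean(self) -> float:
        return self.m1

    @property
    def var(self) -> float:
        return self.m2 - self.m1 ** 2

    @property
    def var_w2(self) -> float:
        """Var[w^2]."""
        return self.m4 - self.m2 ** 2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "degenerate":
            return np.full(n, self.m1)
        if self.kind == "signed-gamma":
            return self.sign * rng.gamma(self.shape, self.scale, n)
        raise ConfigError("a moments-only weight law cannot be sampled")
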