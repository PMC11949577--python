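"""Parameter containers shared across the simulator and the mean-field solvers.

Units are fixed package-wide: time in ms, voltage in mV, rates in Hz.
The plasticity kernel works internally with rates in ms^-1 (so that the
homeostatic constant ``eps`` carries its natural unit of ms^-2); every
public function accepts and returns Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ConfigError(ValueError):
    """Raised when a parameter set or run configuration is invalid."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron and its external Poisson drive.

    Attributes
    ----------
    tau : float
        Membrane time constant (ms).
    v_theta, v_reset : float
        Firing threshold and post-spike reset voltage (mV).
    tau_ref : float
        Absolute refractory period (ms); the voltage is clamped at
        ``v_reset`` and synaptic input is discarded during this window.
    delay : float
        Spike transmission delay of this neuron's outgoing synapses (ms).
    k_ext : int
        Number of independent external Poisson sources per neuron.
    w_ext : float
        Synaptic weight of every external source (mV).
    nu_ext : float
        Rate of each external source (Hz).
    """

    tau: float = 20.0
    v_theta: float = 20.0
    v_reset: float = 10.0
    tau_ref: float = 2.0
    delay: float = 1.0
    k_ext: int = 1000
    w_ext: float = 0.14
    nu_ext: float = 8.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigError("membrane time constant tau must be > 0")
        if self.v_theta <= self.v_reset:
            raise ConfigError("v_theta must exceed v_reset")
        if self.tau_ref < 0 or self.k_ext < 0 or self.nu_ext < 0:
            raise ConfigError("tau_ref, k_ext and nu_ext must be >= 0")
        if self.w_ext < 0:
            raise ConfigError("w_ext must be >= 0")

    @property
    def nu_max(self) -> float:
        """Refractory-limited maximal firing rate (Hz)."""
        return 1000.0 / self.tau_ref if self.tau_ref > 0 else float("inf")

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PlasticityRule:
    """Trace-driven Hebbian rule with multiplicative homeostasis.

    The weight of a synapse from neuron j onto neuron i follows

        dw/dt = sign * g0 * nu_j * nu_i - (nu_i**2 + eps) * w

    where ``nu`` denotes the tau_p-normalised spike trace (ms^-1).  With
    reliable traces the equilibrium is the separable kernel
    ``w* = sign * g0 * nu_pre * nu_post / (nu_post**2 + eps)``.

    ``sign`` is +1 for the excitatory rule and -1 for the inhibitory one
    (identical form, opposite sign).  Excitatory weights are floored at 0
    and inhibitory weights capped at 0 during the transient.
    """

    g0: float = 0.1         # Hebbian gain (mV)
    eps: float = 1e-3       # homeostatic constant (ms^-2)
    tau_p: float = 5000.0   # trace time constant (ms)
    sign: int = 1

    def __post_init__(self) -> None:
        if self.g0 <= 0 or self.eps <= 0 or self.tau_p <= 0:
            raise ConfigError("g0, eps and tau_p must all be > 0")
        if self.sign not in (-1, 1):
            raise ConfigError("sign must be +1 or -1")


@dataclass(frozen=True)
class SimConfig:
    """Clock-driven simulation settings (times in ms)."""

    dt: float = 0.1
    t_sim: float = 10_000.0
    t_burn: float = 0.0
    dt_w: float = 1.0            # weight-update interval
    seed: int = 0
    record_spikes: bool = True
    trace_sample_every: float | None = None   # ms between trace snapshots
    voltage_probe: tuple[int, ...] = field(default_factory=tuple)
    weight_probe: tuple[int, ...] = field(default_factory=tuple)  # edge ids

    def __post_init__(self) -> None:
        if not (0 < self.dt <= self.dt_w <= self.t_sim):
            raise ConfigError("need 0 < dt <= dt_w <= t_sim")
        if self.t_burn < 0 or self.t_burn >= self.t_sim:
            raise ConfigError("need 0 <= t_burn < t_sim")
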