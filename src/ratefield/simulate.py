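"""Clock-driven microscopic simulation of the LIF network.

Delta-pulse synapses make the subthreshold dynamics exactly integrable:
between pulses the voltage decays by exp(-dt/tau) per step, and pulses are
delivered at step boundaries (delays rounded to whole steps).  The external
drive is statistically exact: one Poisson count per neuron per step with
intensity K_ext * nu_ext * dt.  Each neuron carries a spike trace that
decays by exp(-dt/tau_p) per step and jumps by 1 at the neuron's own
spikes; when plasticity is enabled the edge weights advance by forward
Euler every dt_w using the current tau_p-normalised traces:

    w += dt_w * (sign * g0 * nu_pre * nu_post - (nu_post**2 + eps) * w),

with excitatory-rule weights floored at 0 and inhibitory-rule weights
capped at 0.  Refractory neurons are clamped at the reset voltage and
discard all input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degrees import NetworkScaffold
from .params import ConfigError, NeuronParams, PlasticityRule, SimConfig
from .transfer import external_input_moments, phi

__all__ = [
    "SpikeRecord",
    "SimResult",
    "simulate",
    "empirical_rates",
    "population_rate_timeseries",
    "default_initial_weights",
    "synchrony_fano",
]


@dataclass
class SpikeRecord:
    """Ordered spike events: parallel arrays of times (ms) and neuron ids."""

    times: np.ndarray
    neurons: np.ndarray
    n_neurons: int
    t_end: float

    def __post_init__(self):
        if np.any(np.diff(self.times) < 0):
            raise ConfigError("spike times must be non-decreasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def for_neuron(self, i: int) -> np.ndarray:
        return self.times[self.neurons == i]

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_ms": self.times, "neuron": self.neurons}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, n_neurons: int, t_end: float) -> "SpikeRecord":
        df = pd.read_csv(path)
        return cls(df["t_ms"].to_numpy(float), df["neuron"].to_numpy(np.int64),
                   n_neurons, t_end)


@dataclass
class SimResult:
    """Output of one microscopic run."""

    record: SpikeRecord
    weights_final: np.ndarray          # per scaffold edge, mV
    rates: np.ndarray                  # per-neuron empirical rate (Hz), post burn-in
    scaffold: NetworkScaffold
    trace_times: np.ndarray | None = None
    trace_samples: np.ndarray | None = None   # (n_samples, n_neurons) nu_hat in Hz
    voltage_times: np.ndarray | None = None
    voltage_samples: np.ndarray | None = None
    weight_times: np.ndarray | None = None
    weight_samples: np.ndarray | None = None  # (n_samples, len(weight_probe))
    config: SimConfig | None = None

    def weights_to_csv(self, path) -> None:
        pd.DataFrame({"pre": self.scaffold.pre, "post": self.scaffold.post,
                      "w_mV": self.weights_final}).to_csv(path, index=False)


def empirical_rates(rec: SpikeRecord, window: tuple[float, float],
                    n_neurons: int | None = None) -> np.ndarray:
    """Per-neuron firing rate (Hz) from spike counts in (t0, t1]."""
    t0, t1 = window
    if t1 <= t0:
        raise ConfigError("window must satisfy t1 > t0")
    n = n_neurons if n_neurons is not None else rec.n_neurons
    sel = (rec.times > t0) & (rec.times <= t1)
    counts = np.bincount(rec.neurons[sel], minlength=n)
    return counts * (1000.0 / (t1 - t0))


def population_rate_timeseries(rec: SpikeRecord, bin_ms: float,
                               neurons: np.ndarray | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous population rate (Hz) in consecutive bins."""
    if bin_ms <= 0:
        raise ConfigError("bin must be > 0")
    if neurons is None:
        times = rec.times
        n_pop = rec.n_neurons
    else:
        mask = np.isin(rec.neurons, neurons)
        times = rec.times[mask]
        n_pop = len(neurons)
    n_bins = max(1, int(math.ceil(rec.t_end / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts * (1000.0 / (bin_ms * n_pop))


def synchrony_fano(rec: SpikeRecord, bin_ms: float = 3.0,
                   t_start: float = 0.0) -> float:
    """Fano factor of binned population spike counts.

    Near 1 for asynchronous Poisson-like firing; large values flag
    population synchrony (the regime where the mean-field theory breaks).
    """
    sel = rec.times > t_start
    n_bins = max(1, int((rec.t_end - t_start) / bin_ms))
    counts, _ = np.histogram(rec.times[sel],
                             bins=np.linspace(t_start, rec.t_end, n_bins + 1))
    m = counts.mean()
    return float(counts.var() / m) if m > 0 else 0.0


def default_initial_weights(scaffold: NetworkScaffold, rule: PlasticityRule,
                            params) -> np.ndarray:
    """Equilibrium weights at the external-drive-only rate estimate,
    w0 = sign * g0 * nu0^2 / (nu0^2 + eps); shortens the transient without
    changing the fixed point."""
    p_by = _params_per_neuron(scaffold, params)
    w = np.empty(scaffold.n_edges)
    for pop in np.unique(scaffold.labels):
        p = p_by[pop]
        ext = external_input_moments(p)
        nu0 = phi(ext.mu, ext.sigma, p) / 1000.0   # ms^-1
        sel = scaffold.labels[scaffold.pre] == pop
        sign = rule.sign if not isinstance(rule, dict) else rule[pop].sign
        g0 = rule.g0 if not isinstance(rule, dict) else rule[pop].g0
        eps = rule.eps if not isinstance(rule, dict) else rule[pop].eps
        w[sel] = sign * g0 * nu0 * nu0 / (nu0 * nu0 + eps)
    return w


def _params_per_neuron(scaffold: NetworkScaffold, params) -> dict[str, NeuronParams]:
    if isinstance(params, NeuronParams):
        return {pop: params for pop in np.unique(scaffold.labels)}
    missing = set(np.unique(scaffold.labels)) - set(params)
    if missing:
        raise ConfigError(f"missing NeuronParams for populations {missing}")
    return dict(params)


def simulate(
    scaffold: NetworkScaffold,
    initial_weights: np.ndarray | float,
    params,
    rule: PlasticityRule | dict[str, PlasticityRule] | None = None,
    cfg: SimConfig = SimConfig(),
    forced_rates: np.ndarray | None = None,
) -> SimResult:
    """Integrate the network dynamics.

    Parameters
    ----------
    scaffold : NetworkScaffold
    initial_weights : array (one per edge) or scalar, in mV.
    params : NeuronParams or dict population -> NeuronParams.
    rule : PlasticityRule, dict pre-population -> PlasticityRule, or None
        (static weights, Model A).
    cfg : SimConfig
    forced_rates : optional per-neuron rates (Hz); when given, neurons fire
        as independent Poisson processes at these rates instead of
        integrating their voltage (used to probe the plasticity dynamics
        with clamped rates; refractoriness does not apply).
    """
    n = scaffold.n
    dt = cfg.dt
    n_steps = int(round(cfg.t_sim / dt))
    rng = np.random.default_rng(cfg.seed)
    p_by = _params_per_neuron(scaffold, params)
    pops = list(p_by)

    w = np.asarray(initial_weights, dtype=float)
    if w.ndim == 0:
        w = np.full(scaffold.n_edges, float(w))
    if w.shape != (scaffold.n_edges,):
        raise ConfigError("initial_weights must give one value per edge")
    w = w.copy()

    # per-neuron parameter arrays
    tau = np.empty(n)
    v_theta = np.empty(n)
    v_reset = np.empty(n)
    ref_steps = np.empty(n, dtype=np.int64)
    delay_steps = np.empty(n, dtype=np.int64)
    lam_ext = np.empty(n)
    w_ext = np.empty(n)
    for pop in pops:
        p = p_by[pop]
        m = scaffold.labels == pop
        tau[m] = p.tau
        v_theta[m] = p.v_theta
        v_reset[m] = p.v_reset
        # a neuron spiking at step s is next eligible at step s + ref + 1,
        # so min ISI = (ref + 1) * dt = tau_ref exactly
        ref_steps[m] = max(0, int(round(p.tau_ref / dt)) - 1)
        delay_steps[m] = max(1, int(round(p.delay / dt)))
        lam_ext[m] = p.k_ext * p.nu_ext * dt / 1000.0
        w_ext[m] = p.w_ext
    decay = np.exp(-dt / tau)
    uniform_lam = float(lam_ext[0]) if np.all(lam_ext == lam_ext[0]) else None

    # plasticity setup
    plastic = rule is not None
    if plastic:
        rule_by = rule if isinstance(rule, dict) else {pop: rule for pop in pops}
        pre_labels = scaffold.labels[scaffold.pre]
        sign_e = np.empty(scaffold.n_edges)
        g0_e = np.empty(scaffold.n_edges)
        eps_e = np.empty(scaffold.n_edges)
        tau_p_n = np.empty(n)
        for pop in pops:
            r = rule_by[pop]
            sign_e[pre_labels == pop] = r.sign
            g0_e[pre_labels == pop] = r.g0
            eps_e[pre_labels == pop] = r.eps
            tau_p_n[scaffold.labels == pop] = r.tau_p
        trace_decay = np.exp(-dt / tau_p_n)
        exc_e = sign_e > 0
        w_step = int(round(cfg.dt_w / dt))
        # traces start at the stationary mean of the external-drive-only rate
        R = np.empty(n)
        for pop in pops:
            p = p_by[pop]
            ext = external_input_moments(p)
            nu0 = phi(ext.mu, ext.sigma, p)
            R[scaffold.labels == pop] = rule_by[pop].tau_p * nu0 / 1000.0
    elif cfg.trace_sample_every is not None:
        raise ConfigError("trace recording requires a plasticity rule")

    # out-edge CSR ordered by presynaptic neuron
    order = np.argsort(scaffold.pre, kind="stable")
    edge_of = order
    tgt = scaffold.post[order]
    out_ptr = np.searchsorted(scaffold.pre[order], np.arange(n + 1))

    ring_len = int(delay_steps.max()) + 1
    buf = np.zeros((ring_len, n))

    v = v_reset + (v_theta - v_reset) * rng.random(n)
    refrac = np.zeros(n, dtype=np.int64)

    forced = forced_rates is not None
    if forced:
        p_force = np.asarray(forced_rates, dtype=float) * dt / 1000.0

    spike_t: list[np.ndarray] = []
    spike_i: list[np.ndarray] = []
    tr_t, tr_v = [], []
    vt_t, vt_v = [], []
    wt_t, wt_v = [], []
    tr_every = (int(round(cfg.trace_sample_every / dt))
                if cfg.trace_sample_every else 0)
    probe = np.asarray(cfg.voltage_probe, dtype=np.int64)
    w_probe = np.asarray(cfg.weight_probe, dtype=np.int64)
    if w_probe.size and not plastic:
        raise ConfigError("weight recording requires a plasticity rule")

    for step in range(n_steps):
        row = step % ring_len
        inp = buf[row]
        if forced:
            spk = np.flatnonzero(rng.random(n) < p_force)
        else:
            if uniform_lam is not None:
                ext_counts = rng.poisson(uniform_lam, n)
            else:
                ext_counts = rng.poisson(lam_ext)
            active = refrac == 0
            v[active] = v[active] * decay[active] + (
                w_ext[active] * ext_counts[active] + inp[active])
            np.subtract(refrac, 1, out=refrac, where=~active)
            spk = np.flatnonzero(active & (v >= v_theta))
            if spk.size:
                v[spk] = v_reset[spk]
                refrac[spk] = ref_steps[spk]
        inp[:] = 0.0
        if plastic:
            R *= trace_decay
            if spk.size:
                R[spk] += 1.0
        if spk.size:
            # deliver pulses after each pre-neuron's delay
            for j in spk:
                lo, hi = out_ptr[j], out_ptr[j + 1]
                if hi > lo:
                    drow = (step + delay_steps[j]) % ring_len
                    np.add.at(buf[drow], tgt[lo:hi], w[edge_of[lo:hi]])
            if cfg.record_spikes:
                spike_t.append(np.full(spk.size, (step + 1) * dt))
                spike_i.append(spk.astype(np.int64))
        if plastic and (step + 1) % w_step == 0:
            nu_hat = R / tau_p_n
            dw = sign_e * g0_e * nu_hat[scaffold.pre] * nu_hat[scaffold.post] \
                - (nu_hat[scaffold.post] ** 2 + eps_e) * w
            w += cfg.dt_w * dw
            np.maximum(w, 0.0, out=w, where=exc_e)
            np.minimum(w, 0.0, out=w, where=~exc_e)
        if tr_every and (step + 1) % tr_every == 0:
            tr_t.append((step + 1) * dt)
            tr_v.append(1000.0 * R / tau_p_n)
            if w_probe.size:
                wt_t.append((step + 1) * dt)
                wt_v.append(w[w_probe].copy())
        if probe.size:
            vt_t.append((step + 1) * dt)
            vt_v.append(v[probe].copy())
        if step % 256 == 0 and not np.all(np.isfinite(v)):
            raise RuntimeError(f"non-finite voltage at t = {(step+1)*dt:.3f} ms")

    times = np.concatenate(spike_t) if spike_t else np.empty(0)
    ids = np.concatenate(spike_i) if spike_i else np.empty(0, np.int64)
    rec = SpikeRecord(times=times, neurons=ids, n_neurons=n, t_end=cfg.t_sim)
    rates = empirical_rates(rec, (cfg.t_burn, cfg.t_sim)) if cfg.record_spikes \
        else np.full(n, np.nan)
    return SimResult(
        record=rec, weights_final=w, rates=rates, scaffold=scaffold,
        trace_times=np.array(tr_t) if tr_t else None,
        trace_samples=np.array(tr_v) if tr_v else None,
        voltage_times=np.array(vt_t) if vt_t else None,
        voltage_samples=np.array(vt_v) if vt_v else None,
        weight_times=np.array(wt_t) if wt_t else None,
        weight_samples=np.array(wt_v) if wt_v else None,
        config=cfg)
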