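"""Config-driven experiment harness: theory-vs-simulation comparisons.

A run config is a declarative mapping (usually loaded from YAML) selecting
an experiment kind and its parameters; each runner builds the synthetic
network, runs the microscopic simulation, solves the corresponding
mean-field system and emits a ComparisonReport with summary statistics,
distribution distances and pass/fail flags against configurable
tolerances.  Reports serialise to JSON and reproduce bit-for-bit from
their embedded config and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import yaml
from scipy import stats as sps

from . import __version__
from .degrees import DegreeDist, DegreeModel, build_multipop_scaffold, build_scaffold
from .ei import MeanFieldModelEI
from .kernels import SeparableKernel
from .model_a import MeanFieldModelA
from .model_b import MeanFieldModelB
from .params import ConfigError, NeuronParams, PlasticityRule, SimConfig
from .simulate import default_initial_weights, simulate, synchrony_fano
from .trace import simulate_trace_ensemble, stationary_trace_density
from .weights import WeightDistribution

log = logging.getLogger("ratefield")

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "run_trace_experiment",
    "run_model_a_experiment",
    "run_model_b_experiment",
    "run_experiment",
    "distribution_distance",
]

_KINDS = ("trace", "model-a", "model-b", "ei-model-b")

DEFAULT_TOLERANCES = {
    "mean_rate_rel": 0.05,
    "sd_rate_rel": 0.15,
    "rate_wasserstein_rel": 0.10,
    "mean_rate_rel_b": 0.10,
    "mean_weight_rel": 0.10,
    "weight_wasserstein_rel": 0.15,
    "trace_ks": 0.015,
    "synchrony_fano": 5.0,
}


def distribution_distance(sample_a, sample_b) -> tuple[float, float]:
    """(Kolmogorov-Smirnov, Wasserstein-1) distances between two samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("samples must be non-empty")
    ks = float(sps.ks_2samp(a, b).statistic)
    w1 = float(sps.wasserstein_distance(a, b))
    return ks, w1


# ---------------------------------------------------------------------------
# config parsing
# ---------------------------------------------------------------------------

def _degree_model_from(cfg: dict) -> DegreeModel:
    kind = cfg.get("kind")
    if kind == "fixed-in":
        return DegreeModel.fixed_in(int(cfg["k"]))
    if kind == "independent-normal":
        return DegreeModel.independent_normal(float(cfg["mu_k"]),
                                              float(cfg["sigma_k"]))
    if kind == "independent":
        return DegreeModel.independent(
            DegreeDist.from_pmf({int(k): float(v)
                                 for k, v in cfg["in_pmf"].items()}),
            DegreeDist.from_pmf({int(k): float(v)
                                 for k, v in cfg["out_pmf"].items()}))
    if kind == "joint":
        return DegreeModel.joint_table(cfg["k_in"], cfg["k_out"], cfg["p"])
    raise ConfigError(f"unknown degree model kind {kind!r}")


def _weights_from(cfg: dict) -> WeightDistribution:
    kind = cfg.get("kind")
    if kind == "degenerate":
        return WeightDistribution.degenerate(float(cfg["value"]))
    if kind == "signed-gamma":
        return WeightDistribution.signed_gamma(float(cfg["mean"]),
                                               float(cfg["var"]))
    if kind == "moments":
        return WeightDistribution.from_moments(*(float(cfg[f"m{i}"])
                                                 for i in (1, 2, 3, 4)))
    raise ConfigError(f"unknown weight distribution kind {kind!r}")


def _neuron_from(cfg: dict) -> NeuronParams:
    return NeuronParams(**cfg)


@dataclass
class RunConfig:
    """Validated experiment configuration."""

    kind: str
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kind = d.get("kind")
        if kind not in _KINDS:
            raise ConfigError(f"experiment kind must be one of {_KINDS}")
        return cls(kind=kind, seed=int(d.get("seed", 0)), raw=dict(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def tolerances(self) -> dict:
        tol = dict(DEFAULT_TOLERANCES)
        tol.update(self.raw.get("tolerances", {}))
        return tol


@dataclass
class ComparisonReport:
    """Theory-vs-simulation summary; serialisable round-trip."""

    kind: str
    config_hash: str
    seed: int
    version: str
    theory: dict
    empirical: dict
    distances: dict
    checks: dict
    flags: dict = field(default_factory=dict)
    histograms: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "ComparisonReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _histogram(sample: np.ndarray, n_bins: int = 60) -> dict:
    counts, edges = np.histogram(sample, bins=n_bins)
    return {"edges": edges.tolist(), "counts": counts.tolist()}


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

def run_trace_experiment(cfg: RunConfig) -> ComparisonReport:
    """Stationary trace density vs a Monte-Carlo ensemble observed at
    t = 5 tau_p (trajectories started from R = 0)."""
    if cfg.kind != "trace":
        raise ConfigError("config kind must be 'trace'")
    r = cfg.raw
    nu = float(r.get("nu", 5.0))
    tau_p = float(r.get("tau_p", 10_000.0))
    n_traj = int(r.get("n_traj", 50_000))
    t_end = float(r.get("t_end_tau_p", 5.0)) * tau_p
    tol = cfg.tolerances()
    theory: dict[str, Any] = {"alpha": tau_p * nu / 1000.0}
    empirical: dict[str, Any] = {}
    distances: dict[str, Any] = {}
    checks: dict[str, Any] = {}
    flags: dict[str, Any] = {}
    hists: dict[str, Any] = {}
    if nu == 0.0:
        flags["degenerate_zero_rate"] = True
        ens = simulate_trace_ensemble(nu, tau_p, n_traj, t_end, seed=cfg.seed)
        empirical["all_zero"] = bool(np.all(ens == 0.0))
        checks["degenerate_ensemble_zero"] = empirical["all_zero"]
    else:
        alpha = tau_p * nu / 1000.0
        dens = stationary_trace_density(alpha)
        ens_hz = simulate_trace_ensemble(nu, tau_p, n_traj, t_end, seed=cfg.seed)
        ens_R = ens_hz * tau_p / 1000.0
        ks = float(sps.ks_1samp(ens_R, dens.cdf).statistic)
        theory["mean_rate"] = nu
        theory["cv"] = float(1.0 / np.sqrt(2 * alpha))
        empirical["mean_rate"] = float(ens_hz.mean())
        empirical["cv"] = float(ens_hz.std() / ens_hz.mean())
        distances["ks"] = ks
        checks["ks"] = ks < tol["trace_ks"]
        checks["mean"] = abs(empirical["mean_rate"] - nu) / nu < 0.01
        hists["nu_hat"] = _histogram(ens_hz)
    return ComparisonReport(kind=cfg.kind, config_hash=cfg.hash(),
                            seed=cfg.seed, version=__version__,
                            theory=theory, empirical=empirical,
                            distances=distances, checks=checks,
                            flags=flags, histograms=hists)


def _sim_cfg(r: dict, seed: int) -> SimConfig:
    s = r.get("sim", {})
    return SimConfig(dt=float(s.get("dt", 0.1)),
                     t_sim=float(s.get("t_sim", 60_000.0)),
                     t_burn=float(s.get("t_burn", 10_000.0)),
                     dt_w=float(s.get("dt_w", 1.0)),
                     seed=seed)


def run_model_a_experiment(cfg: RunConfig) -> ComparisonReport:
    """Static-weight network: microsim vs the two-parameter mean field."""
    if cfg.kind != "model-a":
        raise ConfigError("config kind must be 'model-a'")
    r = cfg.raw
    n = int(r.get("n", 1000))
    dm = _degree_model_from(r["network"])
    wd = _weights_from(r["weights"])
    p = _neuron_from(r.get("neuron", {}))
    sol = r.get("solver", {})
    tol = cfg.tolerances()
    rng = np.random.default_rng(cfg.seed)

    log.info("model-a: building scaffold N=%d and simulating", n)
    sc = build_scaffold(n, dm, seed=rng)
    w = wd.sample(sc.n_edges, rng) if wd.kind != "degenerate" \
        else np.full(sc.n_edges, wd.mean)
    sim = simulate(sc, w, p, cfg=_sim_cfg(r, cfg.seed + 1))

    log.info("model-a: solving the mean-field fixed point")
    mdl = MeanFieldModelA(dm, wd, p)
    res = mdl.fit(n_mc=int(sol.get("n_mc", 100_000)),
                  damping=float(sol.get("damping", 0.5)),
                  seed=cfg.seed + 2)
    th_rates = res.sample_rates(n=int(sol.get("n_reconstruct", 500_000)))

    ks, w1 = distribution_distance(th_rates, sim.rates)
    emp_sd = float(sim.rates.std())
    theory = {"theta_m": res.theta.m, "theta_s2": res.theta.s2,
              "rate_mean": float(th_rates.mean()), "rate_sd": float(th_rates.std())}
    empirical = {"rate_mean": float(sim.rates.mean()), "rate_sd": emp_sd,
                 "fano": synchrony_fano(sim.record, t_start=sim.config.t_burn)}
    distances = {"rate_ks": ks, "rate_w1": w1}
    checks = {
        "mean_rate": abs(theory["rate_mean"] - empirical["rate_mean"])
        <= tol["mean_rate_rel"] * empirical["rate_mean"],
        "sd_rate": abs(theory["rate_sd"] - emp_sd) <= tol["sd_rate_rel"] * emp_sd,
        "wasserstein": w1 <= tol["rate_wasserstein_rel"] * emp_sd,
    }
    hists = {"rates_sim": _histogram(sim.rates),
             "rates_theory": _histogram(th_rates)}
    return ComparisonReport(kind=cfg.kind, config_hash=cfg.hash(), seed=cfg.seed,
                            version=__version__, theory=theory,
                            empirical=empirical, distances=distances,
                            checks=checks, histograms=hists)


def run_model_b_experiment(cfg: RunConfig) -> ComparisonReport:
    """Plastic network: microsim to quasi-equilibrium vs the five-parameter
    mean field (single population or E-I)."""
    if cfg.kind not in ("model-b", "ei-model-b"):
        raise ConfigError("config kind must be 'model-b' or 'ei-model-b'")
    r = cfg.raw
    p = _neuron_from(r.get("neuron", {}))
    pl = r.get("plasticity", {})
    g0 = float(pl.get("g0", 0.1))
    eps = float(pl.get("eps", 1e-3))
    tau_p = float(pl.get("tau_p", 5000.0))
    sol = r.get("solver", {})
    tol = cfg.tolerances()
    scfg = _sim_cfg(r, cfg.seed + 1)
    if scfg.t_sim < 5 * tau_p:
        log.warning("t_sim = %.0f ms < 5 tau_p: equilibrium may not be reached",
                    scfg.t_sim)
    flags: dict[str, Any] = {}

    if cfg.kind == "model-b":
        n = int(r.get("n", 1000))
        dm = _degree_model_from(r["network"])
        sc = build_scaffold(n, dm, seed=cfg.seed)
        rule = PlasticityRule(g0=g0, eps=eps, tau_p=tau_p)
        kern = SeparableKernel(g0=g0, eps=eps)
        w0 = default_initial_weights(sc, rule, p)
        log.info("model-b: simulating N=%d for %.0f ms", n, scfg.t_sim)
        sim = simulate(sc, w0, p, rule=rule, cfg=scfg)
        sim_w = sim.weights_final
        if g0 > 0:
            mdl = MeanFieldModelB(dm, kern, p)
            res = mdl.fit(n_mc=int(sol.get("n_mc", 100_000)),
                          damping=float(sol.get("damping", 0.5)),
                          seed=cfg.seed + 2)
            nrec = int(sol.get("n_reconstruct", 200_000))
            th_rates = res.sample_rates(n=nrec)
            th_w = res.sample_weights(n=nrec)
        else:
            # g_pre == 0: weights collapse, rates are external-drive only
            from .transfer import external_input_moments, phi
            ext = external_input_moments(p)
            th_rates = np.full(10_000, phi(ext.mu, ext.sigma, p))
            th_w = np.zeros(10_000)
    else:
        sizes = {q: int(v) for q, v in r.get("sizes", {"E": 1000, "I": 1000}).items()}
        dms = {q: _degree_model_from(c) for q, c in r["networks"].items()}
        models = {(post, pre): dms[pre] for post in sizes for pre in sizes}
        sc = build_multipop_scaffold(sizes, models, seed=cfg.seed)
        rules = {"E": PlasticityRule(g0=g0, eps=eps, tau_p=tau_p, sign=1),
                 "I": PlasticityRule(g0=g0, eps=eps, tau_p=tau_p, sign=-1)}
        kerns = {"E": SeparableKernel(g0=g0, eps=eps, sign=1),
                 "I": SeparableKernel(g0=g0, eps=eps, sign=-1)}
        w0 = default_initial_weights(sc, rules, p)
        log.info("ei-model-b: simulating N=%d for %.0f ms", sc.n, scfg.t_sim)
        sim = simulate(sc, w0, p, rule=rules, cfg=scfg)
        sim_w = sim.weights_final[sc.labels[sc.pre] == "E"]
        mdl = MeanFieldModelEI(dms, kerns, p)
        res = mdl.fit(n_mc=int(sol.get("n_mc", 50_000)), seed=cfg.seed + 2)
        nrec = int(sol.get("n_reconstruct", 100_000))
        th_rates = res.sample_rates(n=nrec)
        th_w = res.sample_weights("E", n=nrec)

    # equilibration check: population rate drift across the last two quarters
    q3 = empirical_mean_rate(sim, 0.5, 0.75)
    q4 = empirical_mean_rate(sim, 0.75, 1.0)
    drift = abs(q4 - q3) / max(q4, 1e-9)
    if drift > 0.05:
        flags["not_equilibrated"] = True
    fano = synchrony_fano(sim.record, t_start=scfg.t_burn)
    synchronous = fano > tol["synchrony_fano"]
    if synchronous:
        flags["synchronous_regime"] = True

    ks_r, w1_r = distribution_distance(th_rates, sim.rates)
    _, w1_w = distribution_distance(th_w, sim_w)
    emp_w_sd = float(np.std(sim_w))
    theory = {"rate_mean": float(th_rates.mean()), "rate_sd": float(th_rates.std()),
              "weight_mean": float(th_w.mean()), "weight_sd": float(th_w.std())}
    empirical = {"rate_mean": float(sim.rates.mean()),
                 "rate_sd": float(sim.rates.std()),
                 "weight_mean": float(np.mean(sim_w)), "weight_sd": emp_w_sd,
                 "fano": fano, "rate_drift": drift}
    distances = {"rate_ks": ks_r, "rate_w1": w1_r, "weight_w1": w1_w}
    if synchronous:
        # outside the theory's validity: record distances, do not judge
        checks = {"regime_flagged": True}
    else:
        checks = {
            "mean_rate": abs(theory["rate_mean"] - empirical["rate_mean"])
            <= tol["mean_rate_rel_b"] * max(empirical["rate_mean"], 1e-9),
            "mean_weight": abs(theory["weight_mean"] - empirical["weight_mean"])
            <= tol["mean_weight_rel"] * max(abs(empirical["weight_mean"]), 1e-12),
            "weight_wasserstein": (w1_w <= tol["weight_wasserstein_rel"] * emp_w_sd
                                   if emp_w_sd > 0 else w1_w < 1e-9),
        }
    hists = {"rates_sim": _histogram(sim.rates), "rates_theory": _histogram(th_rates),
             "weights_sim": _histogram(np.asarray(sim_w)),
             "weights_theory": _histogram(th_w)}
    return ComparisonReport(kind=cfg.kind, config_hash=cfg.hash(), seed=cfg.seed,
                            version=__version__, theory=theory,
                            empirical=empirical, distances=distances,
                            checks=checks, flags=flags, histograms=hists)


def empirical_mean_rate(sim, frac0: float, frac1: float) -> float:
    t0 = sim.config.t_sim * frac0
    t1 = sim.config.t_sim * frac1
    sel = (sim.record.times > t0) & (sim.record.times <= t1)
    return float(sel.sum() * 1000.0 / ((t1 - t0) * sim.record.n_neurons))


def run_experiment(cfg: RunConfig) -> ComparisonReport:
    if cfg.kind == "trace":
        return run_trace_experiment(cfg)
    if cfg.kind == "model-a":
        return run_model_a_experiment(cfg)
    return run_model_b_experiment(cfg)
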