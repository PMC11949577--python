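"""Joint in-/out-degree models, configuration-model scaffolds and degree tilts.

The connectivity scaffold is a fixed directed graph drawn from an ensemble
characterised by a joint in-/out-degree law: each neuron's degree pair is an
independent draw.  Three model kinds are supported:

* ``fixed-in`` - every neuron receives exactly k inputs chosen uniformly at
  random among the other neurons; out-degrees are emergent (binomial).
* ``independent`` - in- and out-degrees drawn independently from marginal
  pmfs; wiring by directed stub matching.
* ``joint`` - an explicit joint pmf over (k_in, k_out) pairs, allowing
  in/out correlations; wiring by stub matching.

The in-degree law seen across the endpoints of a random edge is *tilted*
relative to the network law: the postsynaptic endpoint is size-biased,
``k P(k) / <K>``, and the presynaptic endpoint is biased through the
conditional mean out-degree, ``<K_out | K_in = m> P(m) / <K>`` (unbiased
exactly when individual in- and out-degrees are independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import ConfigError

__all__ = [
    "DegreeDist",
    "DegreeModel",
    "DegreeTilt",
    "NetworkScaffold",
    "sample_degree_sequence",
    "build_scaffold",
    "build_multipop_scaffold",
    "degree_tilts",
    "empirical_tilt_check",
]

_PMF_TOL = 1e-9


@dataclass(frozen=True)
class DegreeDist:
    """A pmf over non-negative integer degrees."""

    ks: np.ndarray
    ps: np.ndarray

    def __post_init__(self):
        ks = np.asarray(self.ks, dtype=np.int64)
        ps = np.asarray(self.ps, dtype=float)
        if ks.ndim != 1 or ks.shape != ps.shape or ks.size == 0:
            raise ConfigError("degree pmf needs matching 1-d support and weights")
        if np.any(ks < 0):
            raise ConfigError("degree support must be non-negative integers")
        if np.any(ps < 0) or abs(ps.sum() - 1.0) > _PMF_TOL:
            raise ConfigError("degree pmf must be non-negative and sum to 1")
        object.__setattr__(self, "ks", ks)
        object.__setattr__(self, "ps", ps)

    @classmethod
    def fixed(cls, k: int) -> "DegreeDist":
        return cls(np.array([int(k)]), np.array([1.0]))

    @classmethod
    def discretized_normal(cls, mu: float, sigma: float,
                           min_degree: int = 1) -> "DegreeDist":
        """Normal law rounded to the nearest integer, truncated below
        ``min_degree`` and renormalised."""
        if sigma <= 0:
            return cls.fixed(max(int(round(mu)), min_degree))
        hi = int(math.ceil(mu + 10 * sigma))
        ks = np.arange(min_degree, hi + 1)
        ps = (stats.norm.cdf(ks + 0.5, mu, sigma)
              - stats.norm.cdf(ks - 0.5, mu, sigma))
        tot = ps.sum()
        if tot <= 0:
            raise ConfigError("discretized normal has no mass above min_degree")
        keep = ps > 0
        return cls(ks[keep], ps[keep] / tot)

    @classmethod
    def from_pmf(cls, pmf: dict[int, float]) -> "DegreeDist":
        ks = np.array(sorted(pmf), dtype=np.int64)
        ps = np.array([pmf[int(k)] for k in ks], dtype=float)
        return cls(ks, ps / 1.0)

    def mean(self) -> float:
        return float(self.ks @ self.ps)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.ks, size=n, p=self.ps)

    def sample_from_uniforms(self, u: np.ndarray) -> np.ndarray:
        """Inverse-cdf sampling from given uniforms (for common random numbers)."""
        cdf = np.cumsum(self.ps)
        cdf[-1] = 1.0
        return self.ks[np.searchsorted(cdf, u, side="right").clip(0, self.ks.size - 1)]

    def pmf_dict(self) -> dict[int, float]:
        return {int(k): float(p) for k, p in zip(self.ks, self.ps)}


@dataclass(frozen=True)
class DegreeModel:
    """Joint in-/out-degree specification for one population pair.

    ``kind`` is one of ``fixed-in`` (out-degree emergent from uniform
    incoming wiring), ``independent`` (independent marginals, stub
    matching) or ``joint`` (explicit joint pmf table, stub matching).
    """

    kind: str
    in_dist: DegreeDist | None = None
    out_dist: DegreeDist | None = None
    joint: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None  # (kin, kout, p)

    def __post_init__(self):
        if self.kind == "fixed-in":
            if self.in_dist is None:
                raise ConfigError("fixed-in model needs an in-degree pmf")
        elif self.kind == "independent":
            if self.in_dist is None or self.out_dist is None:
                raise ConfigError("independent model needs both marginals")
            if abs(self.in_dist.mean() - self.out_dist.mean()) > \
                    1e-6 * max(1.0, self.in_dist.mean()):
                raise ConfigError(
                    "in- and out-degree means must match for a closed network")
        elif self.kind == "joint":
            if self.joint is None:
                raise ConfigError("joint model needs a (kin, kout, p) table")
            kin, kout, p = (np.asarray(a) for a in self.joint)
            if not (kin.shape == kout.shape == p.shape) or kin.ndim != 1:
                raise ConfigError("joint table must be three matching 1-d arrays")
            if np.any(p < 0) or abs(p.sum() - 1.0) > _PMF_TOL:
                raise ConfigError("joint pmf must be non-negative and sum to 1")
            if abs(float(kin @ p) - float(kout @ p)) > 1e-6 * max(1.0, float(kin @ p)):
                raise ConfigError("joint law must have equal in- and out-degree means")
            object.__setattr__(self, "joint", (kin.astype(np.int64),
                                               kout.astype(np.int64), p.astype(float)))
        else:
            raise ConfigError(f"unknown degree model kind {self.kind!r}")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def fixed_in(cls, k: int) -> "DegreeModel":
        return cls("fixed-in", in_dist=DegreeDist.fixed(k))

    @classmethod
    def fixed_in_dist(cls, in_dist: DegreeDist) -> "DegreeModel":
        return cls("fixed-in", in_dist=in_dist)

    @classmethod
    def independent(cls, in_dist: DegreeDist, out_dist: DegreeDist | None = None
                    ) -> "DegreeModel":
        return cls("independent", in_dist=in_dist,
                   out_dist=out_dist if out_dist is not None else in_dist)

    @classmethod
    def independent_normal(cls, mu: float, sigma: float) -> "DegreeModel":
        d = DegreeDist.discretized_normal(mu, sigma)
        return cls("independent", in_dist=d, out_dist=d)

    @classmethod
    def joint_table(cls, kin, kout, p) -> "DegreeModel":
        return cls("joint", joint=(np.asarray(kin), np.asarray(kout), np.asarray(p)))

    # -- marginals and conditionals ----------------------------------------
    @property
    def in_marginal(self) -> DegreeDist:
        if self.kind in ("fixed-in", "independent"):
            return self.in_dist
        kin, _, p = self.joint
        ks = np.unique(kin)
        ps = np.array([p[kin == k].sum() for k in ks])
        return DegreeDist(ks, ps / ps.sum())

    def mean_degree(self) -> float:
        m = self.in_marginal.mean()
        if m <= 0:
            raise ConfigError("mean degree must be > 0")
        return m

    def cond_mean_out_given_in(self) -> dict[int, float]:
        """<K_out | K_in = m> per in-degree value m in the support."""
        if self.kind == "fixed-in":
            # out-degrees emerge from uniform wiring, independent of k_in
            m = self.in_marginal.mean()
            return {int(k): m for k in self.in_marginal.ks}
        if self.kind == "independent":
            m = self.out_dist.mean()
            return {int(k): m for k in self.in_dist.ks}
        kin, kout, p = self.joint
        out = {}
        for k in np.unique(kin):
            sel = kin == k
            w = p[sel]
            out[int(k)] = float((kout[sel] @ w) / w.sum())
        return out


@dataclass(frozen=True)
class DegreeTilt:
    """Network in-degree law and its edge-endpoint-conditioned tilts."""

    network: DegreeDist
    presyn: DegreeDist
    postsyn: DegreeDist
    mean_degree: float
    cond_mean_out: dict[int, float]


def degree_tilts(model: DegreeModel) -> DegreeTilt:
    """Closed-form edge-endpoint in-degree laws.

    postsyn pmf(k) = k P(k) / <K>;  presyn pmf(m) = <K_out|K_in=m> P(m) / <K>.
    """
    net = model.in_marginal
    mean_k = model.mean_degree()
    post_w = net.ks * net.ps
    post = DegreeDist(net.ks, post_w / post_w.sum())
    cond = model.cond_mean_out_given_in()
    pre_w = np.array([cond[int(k)] for k in net.ks]) * net.ps
    pre = DegreeDist(net.ks, pre_w / pre_w.sum())
    return DegreeTilt(network=net, presyn=pre, postsyn=post,
                      mean_degree=mean_k, cond_mean_out=cond)


# ---------------------------------------------------------------------------
# sampling and wiring
# ---------------------------------------------------------------------------

def sample_degree_sequence(model: DegreeModel, n: int,
                           seed: int | np.random.Generator = 0
                           ) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw N i.i.d. degree pairs.  Returns (k_in, k_out); k_out is None for
    ``fixed-in`` models where out-degrees are emergent."""
    if n < 1:
        raise ConfigError("need n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model.kind == "fixed-in":
        return model.in_dist.sample(n, rng), None
    if model.kind == "independent":
        return model.in_dist.sample(n, rng), model.out_dist.sample(n, rng)
    kin, kout, p = model.joint
    idx = rng.choice(kin.size, size=n, p=p)
    return kin[idx], kout[idx]


def _repair_sums(model: DegreeModel, kin: np.ndarray, kout: np.ndarray,
                 rng: np.random.Generator, max_resample: int) -> tuple[np.ndarray, np.ndarray]:
    """Make sum(k_in) == sum(k_out) by resampling single nodes; a finite
    sample from the ensemble-level law has no reason to balance exactly."""
    kin, kout = kin.copy(), kout.copy()
    n = kin.size
    for _ in range(max_resample):
        if kin.sum() == kout.sum():
            return kin, kout
        i = int(rng.integers(n))
        ki, ko = sample_degree_sequence(model, 1, rng)
        kin[i] = ki[0]
        kout[i] = ko[0]
    # last resort: spread the residual difference in +-1 steps over random
    # nodes (an O(sqrt(N)/N) perturbation of the out-marginal)
    diff = int(kin.sum() - kout.sum())
    while diff != 0:
        i = int(rng.integers(n))
        if diff > 0:
            kout[i] += 1
            diff -= 1
        elif kout[i] > 0:
            kout[i] -= 1
            diff += 1
    return kin, kout


@dataclass
class NetworkScaffold:
    """Fixed binary directed connectivity: edge list plus realized degrees.

    ``pre[e] -> post[e]`` for every directed edge e.  ``labels`` assigns a
    population name to every neuron (a single population by default).
    """

    n: int
    pre: np.ndarray
    post: np.ndarray
    labels: np.ndarray = None

    def __post_init__(self):
        if self.labels is None:
            self.labels = np.zeros(self.n, dtype="<U8")
            self.labels[:] = "all"
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ConfigError("pre/post arrays must match")
        if self.n_edges:
            if self.pre.min() < 0 or max(self.pre.max(), self.post.max()) >= self.n:
                raise ConfigError("edge endpoint out of range")
            if np.any(self.pre == self.post):
                raise ConfigError("self-loops are not allowed")
            codes = self.pre * self.n + self.post
            if np.unique(codes).size != codes.size:
                raise ConfigError("duplicate edges are not allowed")

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)

    def in_degrees(self, pre_pop: str | None = None) -> np.ndarray:
        sel = slice(None) if pre_pop is None else (self.labels[self.pre] == pre_pop)
        return np.bincount(self.post[sel], minlength=self.n)

    def out_degrees(self, post_pop: str | None = None) -> np.ndarray:
        sel = slice(None) if post_pop is None else (self.labels[self.post] == post_pop)
        return np.bincount(self.pre[sel], minlength=self.n)

    def population(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.labels == name)

    def to_csv(self, path) -> None:
        pd.DataFrame({"pre": self.pre, "post": self.post}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n: int | None = None,
                 labels: np.ndarray | None = None) -> "NetworkScaffold":
        df = pd.read_csv(path)
        pre = df["pre"].to_numpy(np.int64)
        post = df["post"].to_numpy(np.int64)
        if n is None:
            n = int(max(pre.max(), post.max())) + 1
        return cls(n=n, pre=pre, post=post, labels=labels)


def _wire_fixed_in(kin: np.ndarray, n: int, rng: np.random.Generator,
                   offset_pre: int = 0, offset_post: int = 0,
                   exclude_self: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Uniform incoming-neighbour wiring: each node i picks k_in[i] distinct
    sources among the other nodes."""
    pres, posts = [], []
    for i, k in enumerate(kin):
        k = int(k)
        if k == 0:
            continue
        limit = n - 1 if exclude_self else n
        if k > limit:
            raise ConfigError(f"in-degree {k} >= available sources {limit}")
        src = rng.choice(n - 1, size=k, replace=False) if exclude_self \
            else rng.choice(n, size=k, replace=False)
        if exclude_self:
            src = np.where(src >= i, src + 1, src)
        pres.append(src)
        posts.append(np.full(k, i, dtype=np.int64))
    if not pres:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return (np.concatenate(pres) + offset_pre,
            np.concatenate(posts) + offset_post)


def _resolve_conflicts(pre: np.ndarray, post: np.ndarray, n_post: int,
                       forbid_self: bool, rng: np.random.Generator,
                       max_rounds: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Repair a stub pairing in place: re-shuffle conflicting (duplicate or
    self-loop) stubs against each other, falling back to targeted edge swaps
    when only a couple of stubborn conflicts remain."""
    for _ in range(max_rounds):
        codes = pre * n_post + post
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        dup = np.zeros(codes.size, dtype=bool)
        dup[order[1:]] = sorted_codes[1:] == sorted_codes[:-1]
        bad = dup | (pre == post) if forbid_self else dup
        n_bad = int(bad.sum())
        if n_bad == 0:
            return pre, post
        if n_bad <= 2:
            # tiny conflict sets cannot fix themselves by re-shuffling:
            # swap each with a random partner edge
            existing = set(codes.tolist())
            for j in np.flatnonzero(bad):
                for _ in range(2000):
                    k = int(rng.integers(codes.size))
                    p1, q1 = pre[j], post[k]
                    p2, q2 = pre[k], post[j]
                    if forbid_self and (p1 == q1 or p2 == q2):
                        continue
                    c1, c2 = p1 * n_post + q1, p2 * n_post + q2
                    if c1 == c2:
                        continue
                    others = existing - {int(codes[j]), int(codes[k])}
                    if c1 in others or c2 in others:
                        continue
                    post[j], post[k] = post[k], post[j]
                    break
                else:  # pragma: no cover
                    raise RuntimeError("stub matching: final swap failed")
                codes = pre * n_post + post
                existing = set(codes.tolist())
            continue
        idx = np.flatnonzero(bad)
        sub = pre[idx]
        rng.shuffle(sub)
        pre[idx] = sub
    raise RuntimeError(f"stub matching failed after {max_rounds} rounds")


def _stub_match(kin: np.ndarray, kout: np.ndarray, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Directed configuration-model wiring with rejection of self-loops and
    duplicate edges."""
    if kin.sum() != kout.sum():
        raise ConfigError("stub matching needs equal stub totals")
    post = np.repeat(np.arange(kin.size), kin)
    pre = np.repeat(np.arange(kout.size), kout)
    rng.shuffle(pre)
    return _resolve_conflicts(pre, post, kin.size, True, rng)


def build_scaffold(n: int, degrees, seed: int | np.random.Generator = 0,
                   max_resample_factor: int = 20) -> NetworkScaffold:
    """Generate a simple directed graph realizing a degree model or sequence.

    ``degrees`` is a DegreeModel, or a pair (k_in, k_out-or-None) of length-n
    arrays.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(degrees, DegreeModel):
        kin, kout = sample_degree_sequence(degrees, n, rng)
        if kout is not None:
            kin, kout = _repair_sums(degrees, kin, kout, rng,
                                     max_resample_factor * n)
        model = degrees
    else:
        kin, kout = degrees
        kin = np.asarray(kin, dtype=np.int64)
        kout = None if kout is None else np.asarray(kout, dtype=np.int64)
        model = None
    if kin.size != n:
        raise ConfigError("degree sequence length must equal n")
    if kin.max(initial=0) >= n:
        raise ConfigError("an in-degree >= N cannot be wired without multi-edges")
    if kout is None:
        pre, post = _wire_fixed_in(kin, n, rng)
    else:
        if kin.sum() != kout.sum():
            raise ConfigError("in-/out-degree sums must match for stub matching")
        pre, post = _stub_match(kin, kout, rng)
    sc = NetworkScaffold(n=n, pre=pre, post=post)
    realized = sc.in_degrees()
    if not np.array_equal(realized, kin):
        raise RuntimeError("wiring failed to realize the in-degree sequence")
    return sc


def build_multipop_scaffold(sizes: dict[str, int],
                            models: dict[tuple[str, str], DegreeModel],
                            seed: int | np.random.Generator = 0) -> NetworkScaffold:
    """Wire each (post_pop <- pre_pop) block independently from its own model.

    ``models`` maps (post_pop, pre_pop) to the degree model of that block;
    in-degree there counts inputs from pre_pop only.  Cross-population
    blocks allow i == j node indices trivially (different neurons).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pops = list(sizes)
    offsets, labels, off = {}, [], 0
    for p in pops:
        offsets[p] = off
        labels.extend([p] * sizes[p])
        off += sizes[p]
    n_tot = off
    pres, posts = [], []
    for (post_pop, pre_pop), model in models.items():
        n_post, n_pre = sizes[post_pop], sizes[pre_pop]
        same = post_pop == pre_pop
        kin, kout = sample_degree_sequence(model, n_post, rng)
        if kout is None:
            if same:
                pre, post = _wire_fixed_in(kin, n_post, rng,
                                           offsets[pre_pop], offsets[post_pop])
            else:
                # choose k sources uniformly in the other population
                pre_l, post_l = [], []
                for i, k in enumerate(kin):
                    k = int(k)
                    if k > n_pre:
                        raise ConfigError("block in-degree exceeds source population")
                    src = rng.choice(n_pre, size=k, replace=False)
                    pre_l.append(src + offsets[pre_pop])
                    post_l.append(np.full(k, i + offsets[post_pop], np.int64))
                pre = np.concatenate(pre_l) if pre_l else np.empty(0, np.int64)
                post = np.concatenate(post_l) if post_l else np.empty(0, np.int64)
        else:
            if not same:
                kout_seq = sample_degree_sequence(model, n_pre, rng)[1]
                d = int(kin.sum() - kout_seq.sum())
                while d != 0:  # +-1 repair on the source side
                    i = int(rng.integers(n_pre))
                    if d > 0:
                        kout_seq[i] += 1
                        d -= 1
                    elif kout_seq[i] > 0:
                        kout_seq[i] -= 1
                        d += 1
                post_b = np.repeat(np.arange(n_post), kin)
                pre_b = np.repeat(np.arange(n_pre), kout_seq)
                rng.shuffle(pre_b)
                # cross-block duplicates only (self-loops impossible)
                pre_b, post_b = _resolve_conflicts(pre_b, post_b, n_post,
                                                   False, rng)
                pre = pre_b + offsets[pre_pop]
                post = post_b + offsets[post_pop]
            else:
                kin, kout = _repair_sums(model, kin, kout, rng, 20 * n_post)
                pre_b, post_b = _stub_match(kin, kout, rng)
                pre = pre_b + offsets[pre_pop]
                post = post_b + offsets[post_pop]
        pres.append(pre)
        posts.append(post)
    return NetworkScaffold(n=n_tot, pre=np.concatenate(pres),
                           post=np.concatenate(posts),
                           labels=np.array(labels, dtype="<U8"))


def empirical_tilt_check(scaffold: NetworkScaffold,
                         pre_pop: str | None = None,
                         post_pop: str | None = None
                         ) -> tuple[dict[int, int], dict[int, int], bool]:
    """Observed in-degree histograms over edges, for the pre endpoint and the
    post endpoint.  Returns (presyn_hist, postsyn_hist, empty_flag)."""
    sel = np.ones(scaffold.n_edges, dtype=bool)
    if pre_pop is not None:
        sel &= scaffold.labels[scaffold.pre] == pre_pop
    if post_pop is not None:
        sel &= scaffold.labels[scaffold.post] == post_pop
    pre, post = scaffold.pre[sel], scaffold.post[sel]
    if pre.size == 0:
        return {}, {}, True
    kin = scaffold.in_degrees(pre_pop=pre_pop)
    pre_h = pd.Series(kin[pre]).value_counts().sort_index()
    post_h = pd.Series(kin[post]).value_counts().sort_index()
    return ({int(k): int(v) for k, v in pre_h.items()},
            {int(k): int(v) for k, v in post_h.items()}, False)
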