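"""Degree models, scaffold generation and edge-endpoint tilts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ratefield import (DegreeDist, DegreeModel, NetworkScaffold,
                       build_multipop_scaffold, build_scaffold, degree_tilts,
                       empirical_tilt_check, sample_degree_sequence)
from ratefield.params import ConfigError


class TestDegreeDist:
    def test_normalization_enforced(self):
        with pytest.raises(ConfigError):
            DegreeDist(np.array([1, 2]), np.array([0.5, 0.6]))

    def test_discretized_normal_truncation(self):
        d = DegreeDist.discretized_normal(25.0, 7.0)
        assert d.ks.min() >= 1
        assert abs(d.ps.sum() - 1.0) < 1e-9
        assert d.mean() == pytest.approx(25.0, abs=0.1)

    def test_point_mass_at_zero_is_valid(self):
        """An isolated-node sequence (all in-degrees 0) is legal."""
        kin, kout = sample_degree_sequence(DegreeModel.fixed_in(0), 10, seed=0)
        assert np.all(kin == 0) and kout is None
        sc = build_scaffold(10, (kin, None), seed=0)
        assert sc.n_edges == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.dictionaries(st.integers(1, 60), st.floats(0.01, 1.0),
                           min_size=1, max_size=8))
    def test_tilt_pmfs_normalized(self, pmf):
        """Both tilted laws are proper pmfs for any valid degree model."""
        tot = sum(pmf.values())
        d = DegreeDist.from_pmf({k: v / tot for k, v in pmf.items()})
        t = degree_tilts(DegreeModel.independent(d, d))
        assert abs(t.postsyn.ps.sum() - 1.0) < 1e-9
        assert abs(t.presyn.ps.sum() - 1.0) < 1e-9
        # size-bias identity: sum_k post(k) <K> / k = 1
        assert np.sum(t.postsyn.ps * t.mean_degree / t.postsyn.ks) == \
            pytest.approx(1.0, abs=1e-9)


class TestSampling:
    def test_fixed_in(self):
        kin, kout = sample_degree_sequence(DegreeModel.fixed_in(25), 1000, seed=1)
        assert np.all(kin == 25) and kout is None

    def test_normal_marginals_mean(self):
        m = DegreeModel.independent_normal(25.0, 7.0)
        kin, kout = sample_degree_sequence(m, 100_000, seed=2)
        se = kin.std() / np.sqrt(kin.size)
        assert abs(kin.mean() - m.in_dist.mean()) < 3 * se
        assert kin.min() >= 1

    def test_determinism(self):
        m = DegreeModel.independent_normal(25.0, 7.0)
        a = sample_degree_sequence(m, 500, seed=9)
        b = sample_degree_sequence(m, 500, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestScaffold:
    def test_fixed_in_invariants(self):
        sc = build_scaffold(1000, DegreeModel.fixed_in(25), seed=3)
        kin = sc.in_degrees()
        assert np.all(kin == 25)
        assert not np.any(sc.pre == sc.post)
        codes = sc.pre * sc.n + sc.post
        assert np.unique(codes).size == codes.size
        assert sc.n_edges == kin.sum() == sc.out_degrees().sum()

    def test_forced_complete_graph(self):
        """N=3 with in-degrees (2,2,2): the complete digraph is forced."""
        sc = build_scaffold(3, (np.array([2, 2, 2]), None), seed=0)
        edges = set(zip(sc.pre.tolist(), sc.post.tolist()))
        assert edges == {(i, j) for i in range(3) for j in range(3) if i != j}

    def test_out_degrees_binomial(self):
        """Uniform incoming wiring makes out-degrees Binomial(N-1, K/(N-1));
        chi-square over pooled repetitions."""
        n, k = 1000, 25
        pooled = []
        for seed in range(6):
            sc = build_scaffold(n, DegreeModel.fixed_in(k), seed=seed)
            pooled.append(sc.out_degrees())
        obs = np.concatenate(pooled)
        dist = stats.binom(n - 1, k / (n - 1))
        lo, hi = int(dist.ppf(1e-4)), int(dist.ppf(1 - 1e-4))
        edges = np.arange(lo, hi + 2) - 0.5
        counts, _ = np.histogram(obs, bins=edges)
        probs = np.diff(dist.cdf(edges))
        keep = probs * obs.size > 5
        p = stats.chisquare(counts[keep],
                            probs[keep] / probs[keep].sum() * counts[keep].sum()).pvalue
        assert p > 0.01

    def test_stub_matching_realizes_sequence(self):
        m = DegreeModel.independent_normal(25.0, 7.0)
        sc = build_scaffold(800, m, seed=4)
        assert not np.any(sc.pre == sc.post)
        codes = sc.pre * sc.n + sc.post
        assert np.unique(codes).size == codes.size

    def test_degree_too_large_rejected(self):
        with pytest.raises(ConfigError):
            build_scaffold(10, (np.full(10, 10), None), seed=0)

    def test_determinism(self):
        a = build_scaffold(300, DegreeModel.fixed_in(10), seed=5)
        b = build_scaffold(300, DegreeModel.fixed_in(10), seed=5)
        assert np.array_equal(a.pre, b.pre) and np.array_equal(a.post, b.post)

    def test_csv_roundtrip(self, tmp_path):
        sc = build_scaffold(50, DegreeModel.fixed_in(5), seed=6)
        path = tmp_path / "edges.csv"
        sc.to_csv(path)
        sc2 = NetworkScaffold.from_csv(path, n=50)
        assert np.array_equal(np.sort(sc.pre * 50 + sc.post),
                              np.sort(sc2.pre * 50 + sc2.post))


class TestTilts:
    def test_postsyn_size_bias_closed_form(self):
        """pmf {10: .5, 30: .5} -> postsyn {10: .25, 30: .75} (<K> = 20)."""
        d = DegreeDist.from_pmf({10: 0.5, 30: 0.5})
        t = degree_tilts(DegreeModel.independent(d, DegreeDist.fixed(20)))
        assert t.postsyn.pmf_dict() == pytest.approx({10: 0.25, 30: 0.75})

    def test_independent_presyn_unbiased(self):
        d = DegreeDist.from_pmf({10: 0.5, 30: 0.5})
        t = degree_tilts(DegreeModel.independent(d, DegreeDist.fixed(20)))
        assert t.presyn.pmf_dict() == pytest.approx({10: 0.5, 30: 0.5})

    def test_correlated_presyn_biased(self):
        """k_out = k_in on {10, 30} tilts the presynaptic law to {.25, .75}."""
        m = DegreeModel.joint_table([10, 30], [10, 30], [0.5, 0.5])
        t = degree_tilts(m)
        assert t.presyn.pmf_dict() == pytest.approx({10: 0.25, 30: 0.75})

    def test_fixed_in_postsyn_point_mass(self):
        sc = build_scaffold(200, DegreeModel.fixed_in(10), seed=7)
        pre_h, post_h, empty = empirical_tilt_check(sc)
        assert not empty
        assert set(post_h) == {10}

    def test_single_edge(self):
        sc = NetworkScaffold(n=2, pre=np.array([0]), post=np.array([1]))
        pre_h, post_h, empty = empirical_tilt_check(sc)
        assert not empty
        assert sum(pre_h.values()) == sum(post_h.values()) == 1

    def test_empty_edge_set_flag(self):
        sc = NetworkScaffold(n=3, pre=np.empty(0, int), post=np.empty(0, int))
        assert empirical_tilt_check(sc)[2] is True

    def test_empirical_matches_theory_joint_model(self):
        """~1e5 generated edges reproduce both closed-form tilts
        (chi-square p > 0.01)."""
        m = DegreeModel.joint_table([10, 30], [10, 30], [0.5, 0.5])
        t = degree_tilts(m)
        sc = build_scaffold(5000, m, seed=8)
        pre_h, post_h, _ = empirical_tilt_check(sc)
        for hist, law in ((pre_h, t.presyn), (post_h, t.postsyn)):
            tot = sum(hist.values())
            obs = np.array([hist.get(int(k), 0) for k in law.ks])
            exp = law.ps * tot
            assert stats.chisquare(obs, exp).pvalue > 0.01


class TestMultipop:
    def test_ei_blocks(self):
        sizes = {"E": 300, "I": 300}
        dm_e = DegreeModel.independent_normal(12.0, 3.0)
        dm_i = DegreeModel.fixed_in(12)
        models = {(po, pr): (dm_e if pr == "E" else dm_i)
                  for po in sizes for pr in sizes}
        sc = build_multipop_scaffold(sizes, models, seed=9)
        assert sc.n == 600
        kin_i = sc.in_degrees(pre_pop="I")
        assert np.all(kin_i == 12)
        codes = sc.pre * sc.n + sc.post
        assert np.unique(codes).size == codes.size
        assert not np.any(sc.pre == sc.post)
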