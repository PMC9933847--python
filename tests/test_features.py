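"""Diffusion, weighted-path and ring features against independent oracles."""

import networkx as nx
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from netpu.features import (assemble_features, balanced_diffusion, heat_diffusion,
                            netring, netshort, ring_partition)
from netpu.network import Network, SeedSet

from conftest import random_connected, random_seedset


class TestHeatDiffusion:
    def test_two_node_closed_form(self):
        """Single edge: spectral solution ((1+e^{-2t})/2, (1-e^{-2t})/2)."""
        net = Network.from_edges([("a", "b")])
        seeds = SeedSet(members=("a",), scores={"a": 1.0})
        for t in (0.01, 0.5, 3.0):
            z = heat_diffusion(net, seeds, t).z
            expected = np.array([(1 + np.exp(-2 * t)) / 2, (1 - np.exp(-2 * t)) / 2])
            assert z == pytest.approx(expected, abs=1e-10)

    def test_small_t_recovers_initial_condition(self, path_net, path_seed_one):
        z = heat_diffusion(path_net, path_seed_one, 1e-9).z
        assert z == pytest.approx(path_seed_one.score_vector(path_net), abs=1e-7)

    def test_long_time_limit_is_uniform(self):
        """On a connected graph the heat kernel relaxes to mean(z0)."""
        net = random_connected(12, 0.3, seed=5)
        seeds = random_seedset(net, 3, seed=5)
        z = heat_diffusion(net, seeds, 1e3).z
        total = sum(seeds.scores.values())
        assert z == pytest.approx(np.full(net.n, total / net.n), abs=1e-6)

    @pytest.mark.parametrize("rng_seed", range(10))
    def test_mass_conserved_random_graphs(self, rng_seed):
        net = random_connected(30, 0.12, seed=rng_seed)
        seeds = random_seedset(net, 5, seed=rng_seed)
        z = heat_diffusion(net, seeds, 0.7).z
        assert z.sum() == pytest.approx(sum(seeds.scores.values()), abs=1e-8)
        assert (z >= -1e-12).all()

    @pytest.mark.parametrize("rng_seed", range(3))
    def test_matches_ode_integration_oracle(self, rng_seed):
        """expm action agrees with direct integration of z' = -Lz."""
        net = random_connected(20, 0.15, seed=100 + rng_seed)
        seeds = random_seedset(net, 4, seed=rng_seed)
        A = net.adjacency().toarray()
        L = np.diag(A.sum(1)) - A
        z0 = seeds.score_vector(net)
        sol = solve_ivp(lambda _, z: -L @ z, (0, 0.4), z0, rtol=1e-10, atol=1e-12)
        z = heat_diffusion(net, seeds, 0.4).z
        assert z == pytest.approx(sol.y[:, -1], abs=1e-6)


class TestBalancedDiffusion:
    def test_uniform_is_fixed_point(self):
        """The all-ones vector is in the null space of I - K^{-1}A."""
        net = random_connected(15, 0.2, seed=2)
        seeds = SeedSet(members=net.nodes, scores={g: 0.5 for g in net.nodes})
        z = balanced_diffusion(net, seeds, 2.0).z
        assert z == pytest.approx(np.full(net.n, 0.5), abs=1e-9)

    @pytest.mark.parametrize("rng_seed", range(10))
    def test_degree_weighted_conservation(self, rng_seed):
        net = random_connected(20, 0.15, seed=rng_seed)
        seeds = random_seedset(net, 4, seed=rng_seed)
        k = net.degrees()
        z0 = seeds.score_vector(net)
        z = balanced_diffusion(net, seeds, 0.9).z
        assert (k * z).sum() == pytest.approx((k * z0).sum(), abs=1e-8)

    def test_equals_heat_on_degree_regular_pair(self):
        """Single edge has K = I, so both Laplacians coincide."""
        net = Network.from_edges([("a", "b")])
        seeds = SeedSet(members=("a",), scores={"a": 0.8})
        zh = heat_diffusion(net, seeds, 0.6).z
        zb = balanced_diffusion(net, seeds, 0.6).z
        assert zb == pytest.approx(zh, abs=1e-12)


class TestNetShort:
    def test_path_all_seeds_equals_harmonic(self, path_net):
        """Uniform unit scores make every edge weight 1: NS_1 = 1 + 1/2 + 1/3."""
        seeds = SeedSet(members=path_net.nodes, scores={g: 1.0 for g in path_net.nodes})
        ns = netshort(path_net, seeds)
        assert ns["1"] == pytest.approx(11 / 6, abs=1e-12)

    @pytest.mark.parametrize("rng_seed", range(5))
    def test_uniform_scores_match_scaled_harmonic_oracle(self, rng_seed):
        """With uniform normalized score u the measure is u * harmonic centrality."""
        net = random_connected(20, 0.15, seed=rng_seed)
        seeds = SeedSet(members=net.nodes, scores={g: 0.6 for g in net.nodes})
        u = 1.0  # scores all equal -> s~ = s/maxS = 1
        ns = netshort(net, seeds)
        harm = nx.harmonic_centrality(net.to_graph())
        for g in net.nodes:
            assert ns[g] == pytest.approx(u * harm[g], abs=1e-12)

    def test_star_center_dominates_leaves(self):
        net = Network.from_edges([("c", f"l{i}") for i in range(5)])
        seeds = SeedSet(members=net.nodes, scores={g: 0.7 for g in net.nodes})
        ns = netshort(net, seeds)
        assert all(ns["c"] > ns[f"l{i}"] for i in range(5))

    def test_nonseed_penalization_default(self, path_net):
        """Non-seeds get normalized score penalization * minS / maxS."""
        seeds = SeedSet(members=("1",), scores={"1": 0.8})
        # lone seed: minS = maxS, so non-seed s~ = 0.5; edge 3-4 costs 2/(0.5+0.5)=2
        ns = netshort(path_net, seeds, penalization=0.5)
        # check via brute force with those weights
        g = nx.Graph()
        s = {"1": 1.0, "2": 0.5, "3": 0.5, "4": 0.5}
        for u, v in [("1", "2"), ("2", "3"), ("3", "4")]:
            g.add_edge(u, v, weight=2 / (s[u] + s[v]))
        for node in path_net.nodes:
            d = nx.single_source_dijkstra_path_length(g, node)
            expected = sum(1 / d[o] for o in d if o != node)
            assert ns[node] == pytest.approx(expected, abs=1e-12)

    def test_zero_penalization_rejected(self, path_net, path_seed_one):
        with pytest.raises(ValueError):
            netshort(path_net, path_seed_one, penalization=0.0)


class TestRingPartition:
    def test_path_levels(self, path_net, path_seed_one):
        rings = ring_partition(path_net, path_seed_one)
        assert list(rings.level) == [0, 1, 2, 3]
        assert rings.max_level == 3

    def test_all_seeds_degenerate(self, path_net):
        seeds = SeedSet(members=path_net.nodes, scores={g: 1.0 for g in path_net.nodes})
        rings = ring_partition(path_net, seeds)
        assert rings.max_level == 0 and (rings.level == 0).all()

    @pytest.mark.parametrize("rng_seed", range(5))
    def test_equals_min_over_per_seed_bfs(self, rng_seed):
        net = random_connected(30, 0.1, seed=rng_seed)
        seeds = random_seedset(net, 3, seed=rng_seed)
        rings = ring_partition(net, seeds)
        g = net.to_graph()
        for i, node in enumerate(net.nodes):
            expected = min(nx.shortest_path_length(g, s, node) for s in seeds.members)
            assert rings.level[i] == expected

    @pytest.mark.parametrize("rng_seed", range(5))
    def test_adjacent_levels_differ_by_at_most_one(self, rng_seed):
        net = random_connected(25, 0.1, seed=50 + rng_seed)
        seeds = random_seedset(net, 2, seed=rng_seed)
        level = ring_partition(net, seeds).level
        for e in net.edges:
            u, v = tuple(e)
            assert abs(level[net.index[u]] - level[net.index[v]]) <= 1


class TestNetRing:
    def test_path_fixture_hand_recursion(self, path_net, path_seed_one):
        """Ring-by-ring hand computation on the 4-path with one unit seed."""
        r = netring(path_net, path_seed_one, mixing=0.5)
        assert [r[g] for g in "1234"] == pytest.approx([0.5, 1.75, 2.875, 3.875], abs=1e-12)

    @pytest.mark.parametrize("rng_seed", range(10))
    def test_rank_bounds(self, rng_seed):
        """Non-seeds lie in [l, l+1]; seeds in [0, 1]."""
        net = random_connected(25, 0.12, seed=rng_seed)
        seeds = random_seedset(net, 4, seed=rng_seed)
        rings = ring_partition(net, seeds)
        r = netring(net, seeds, rings)
        seed_set = set(seeds.members)
        for i, g in enumerate(net.nodes):
            if g in seed_set:
                assert 0.0 <= r[g] <= 1.0
            else:
                l = rings.level[i]
                assert l - 1e-12 <= r[g] <= l + 1 + 1e-12

    @pytest.mark.parametrize("rng_seed", range(5))
    def test_nonseed_neighbors_split_between_rings(self, rng_seed):
        """|O_i| + |lower-ring neighbors| = degree, for every non-seed."""
        net = random_connected(25, 0.12, seed=7 + rng_seed)
        seeds = random_seedset(net, 3, seed=rng_seed)
        rings = ring_partition(net, seeds)
        A = net.adjacency()
        for i, g in enumerate(net.nodes):
            l = rings.level[i]
            if l == 0:
                continue
            nb = A.indices[A.indptr[i]:A.indptr[i + 1]]
            lower = (rings.level[nb] == l - 1).sum()
            other = (rings.level[nb] != l - 1).sum()
            assert lower + other == net.degrees()[i]
            assert lower >= 1  # a ring-l node always touches ring l-1

    def test_inconsistent_rings_rejected(self, path_net, path_seed_one):
        from netpu.features import RingPartition

        bad = RingPartition(level=np.array([1, 1, 2, 3]))  # seed not at level 0
        with pytest.raises(ValueError):
            netring(path_net, path_seed_one, bad)


class TestAssembleFeatures:
    def test_full_path_fixture(self, path_net, path_seed_one):
        F = assemble_features(path_net, path_seed_one)
        assert F.X.shape == (4, 4)
        assert F.order == path_net.nodes
        assert (F.X >= 0).all() and (F.X <= 1).all()
        for j in range(4):
            assert F.X[:, j].min() == pytest.approx(0.0)
            assert F.X[:, j].max() == pytest.approx(1.0)

    def test_netring_inverted_by_default(self, path_net, path_seed_one):
        """After the flip the seed-adjacent end of the path scores highest."""
        F = assemble_features(path_net, path_seed_one)
        col = dict(zip(F.order, F.X[:, list(F.columns).index("netring")]))
        assert col["1"] == 1.0 and col["4"] == 0.0
        F_raw = assemble_features(path_net, path_seed_one, invert_netring=False)
        raw = dict(zip(F_raw.order, F_raw.X[:, list(F_raw.columns).index("netring")]))
        assert raw["1"] == 0.0 and raw["4"] == 1.0

    def test_constant_column_warns_and_zeroes(self, caplog):
        from netpu.features import _minmax

        with caplog.at_level("WARNING", logger="netpu.features"):
            out = _minmax(np.array([5.0, 5.0, 5.0]), "x")
        assert (out == 0).all()
        assert any("constant" in r.message for r in caplog.records)

    def test_minmax_three_points(self):
        from netpu.features import _minmax

        assert _minmax(np.array([2.0, 4.0, 6.0]), "x") == pytest.approx([0, 0.5, 1])
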