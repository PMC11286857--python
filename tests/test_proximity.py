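"""Closest-distance proximity, permutation z-scores, unit scaling, separation."""

import itertools

import numpy as np
import pytest

import syndrumnet as sn
from tests.test_network import floyd_warshall


def mod(net, genes, name="m"):
    return sn.build_module(genes, net, name)


def brute_closest(dist, q, a):
    return sum(min(dist[(x, y)] for x in q) for y in a) / len(a)


def brute_separation(dist, a, b):
    def within(genes):
        if len(genes) == 1:
            return 0.0
        return sum(min(dist[(g, h)] for h in genes if h != g) for g in genes) / len(genes)

    d_ab = (
        sum(min(dist[(x, y)] for y in b) for x in a)
        + sum(min(dist[(y, x)] for x in a) for y in b)
    ) / (len(a) + len(b))
    return d_ab - (within(a) + within(b)) / 2.0


class TestClosestDistance:
    def test_worked_example(self, path_net):
        q = mod(path_net, {"a", "c"}, "Q")
        a = mod(path_net, {"e", "f"}, "A")
        assert sn.closest_distance(path_net, q, a) == pytest.approx(2.0)

    def test_swapped_arguments_worked_example(self, path_net):
        q = mod(path_net, {"e", "f"}, "Q")
        a = mod(path_net, {"a", "c"}, "A")
        assert sn.closest_distance(path_net, q, a) == pytest.approx(2.0)

    def test_subset_gives_zero(self, path_net):
        q = mod(path_net, {"a", "b", "c"}, "Q")
        a = mod(path_net, {"a", "c"}, "A")
        assert sn.closest_distance(path_net, q, a) == 0.0

    def test_zero_iff_subset(self, path_net):
        q = mod(path_net, {"a", "b"}, "Q")
        a = mod(path_net, {"b", "c"}, "A")
        assert sn.closest_distance(path_net, q, a) > 0.0

    def test_matches_brute_force_oracle(self, random_net):
        dist = floyd_warshall(random_net.nodes, list(random_net.graph.edges))
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = set(rng.choice(random_net.nodes, size=4, replace=False))
            a = set(rng.choice(random_net.nodes, size=5, replace=False))
            got = sn.closest_distance(random_net, mod(random_net, q), mod(random_net, a))
            assert got == pytest.approx(brute_closest(dist, q, a))


class TestProximityZ:
    def test_z_consistent_with_null_moments(self, random_net):
        bins = sn.build_degree_bins(random_net, min_bin_size=10)
        q = mod(random_net, set(random_net.nodes[:4]), "Q")
        a = mod(random_net, set(random_net.nodes[10:14]), "A")
        res = sn.proximity_z(random_net, q, a, bins, n_perm=50, rng_seed=0)
        assert res.z == pytest.approx((res.d_observed - res.mu) / res.sigma)
        assert res.sigma > 0 and res.n_perm == 50

    def test_fixed_seed_reproducible(self, random_net):
        bins = sn.build_degree_bins(random_net, min_bin_size=10)
        q = mod(random_net, set(random_net.nodes[:4]), "Q")
        a = mod(random_net, set(random_net.nodes[5:9]), "A")
        r1 = sn.proximity_z(random_net, q, a, bins, n_perm=20, rng_seed=9)
        r2 = sn.proximity_z(random_net, q, a, bins, n_perm=20, rng_seed=9)
        assert r1 == r2

    def test_degenerate_null_flagged(self):
        # complete graph: every inter-gene distance is 1, so the null is constant
        import networkx as nx

        net = sn.MolecularNetwork(nx.complete_graph(6))
        net = sn.MolecularNetwork(
            nx.relabel_nodes(net.graph, {i: f"k{i}" for i in range(6)})
        )
        bins = sn.build_degree_bins(net, min_bin_size=6)
        # whole-node-set modules: every resample reproduces the node set, d is constant
        q = mod(net, set(net.nodes), "Q")
        a = mod(net, set(net.nodes), "A")
        with pytest.warns(UserWarning, match="degenerate"):
            res = sn.proximity_z(net, q, a, bins, n_perm=10, rng_seed=0)
        assert res.degenerate and res.z == 0.0

    def test_planted_drug_modules_have_negative_z(self, small_bench):
        """Planted drug modules sit near the disease module, so their
        proximity z should be negative across seeds."""
        bins = sn.build_degree_bins(small_bench.net, min_bin_size=100)
        for seed in range(10):
            res = sn.proximity_z(
                small_bench.net,
                small_bench.disease_module,
                small_bench.drug_modules[small_bench.planted_drugs[seed % 4]],
                bins,
                n_perm=30,
                rng_seed=seed,
            )
            assert res.z < 0


class TestScaleToUnit:
    def test_three_point_example(self):
        out = sn.scale_to_unit({"a": -2.0, "b": 0.0, "c": 2.0})
        assert out == {"a": 1.0, "b": 0.5, "c": 0.0}

    def test_two_drug_endpoints(self):
        out = sn.scale_to_unit({"capsaicin": -7.72, "fasudil": -4.16})
        assert out == {"capsaicin": 1.0, "fasudil": 0.0}

    def test_bounded_and_antimonotone(self):
        rng = np.random.default_rng(0)
        z = {f"d{i}": float(v) for i, v in enumerate(rng.standard_normal(50))}
        out = sn.scale_to_unit(z)
        assert all(0.0 <= v <= 1.0 for v in out.values())
        order_z = sorted(z, key=z.get)
        order_p = sorted(out, key=out.get, reverse=True)
        assert order_z == order_p

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            sn.scale_to_unit({"a": 1.0, "b": 1.0})

    def test_single_value_error(self):
        with pytest.raises(ValueError):
            sn.scale_to_unit({"a": 1.0})


class TestSeparation:
    def test_adjacent_singletons(self):
        net = sn.load_network([("a", "b"), ("b", "c")])
        res = sn.separation(net, mod(net, {"a"}, "A"), mod(net, {"b"}, "B"))
        assert res.d_aa == 0.0 and res.d_bb == 0.0
        assert res.d_ab == 1.0 and res.s == 1.0

    def test_identical_singletons_give_zero(self):
        net = sn.load_network([("a", "b")])
        res = sn.separation(net, mod(net, {"a"}, "A"), mod(net, {"a"}, "B"))
        assert res.s == 0.0

    def test_symmetric(self, random_net):
        a = mod(random_net, set(random_net.nodes[:5]), "A")
        b = mod(random_net, set(random_net.nodes[8:12]), "B")
        assert sn.separation(random_net, a, b).s == pytest.approx(
            sn.separation(random_net, b, a).s
        )

    def test_invariant_definition(self, random_net):
        a = mod(random_net, set(random_net.nodes[:6]), "A")
        b = mod(random_net, set(random_net.nodes[4:9]), "B")  # overlapping modules
        res = sn.separation(random_net, a, b)
        assert res.s == pytest.approx(res.d_ab - (res.d_aa + res.d_bb) / 2.0)

    def test_matches_brute_force_oracle(self, random_net):
        dist = floyd_warshall(random_net.nodes, list(random_net.graph.edges))
        rng = np.random.default_rng(11)
        for _ in range(15):
            a = set(rng.choice(random_net.nodes, size=5, replace=False))
            b = set(rng.choice(random_net.nodes, size=4, replace=False))
            got = sn.separation(random_net, mod(random_net, a), mod(random_net, b))
            assert got.s == pytest.approx(brute_separation(dist, a, b))

    def test_pairwise_matches_per_pair(self, random_net):
        mods = {
            "m1": mod(random_net, set(random_net.nodes[:5]), "m1"),
            "m2": mod(random_net, set(random_net.nodes[5:9]), "m2"),
            "m3": mod(random_net, set(random_net.nodes[9:15]), "m3"),
        }
        pairwise = sn.pairwise_separation(random_net, mods)
        for (a, b), res in pairwise.items():
            direct = sn.separation(random_net, mods[a], mods[b])
            assert res.s == pytest.approx(direct.s)
            assert res.d_ab == pytest.approx(direct.d_ab)
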