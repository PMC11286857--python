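"""PRINCE-style propagation: normalisation, fixed point, priors, expansion."""

import networkx as nx
import numpy as np
import pytest

import syndrumnet as sn


def net_from_edges(edges):
    return sn.load_network(edges)


def closed_form(net, prior, alpha):
    """Direct linear solve F* = (1 - alpha)(I - alpha W')^{-1} Y."""
    w = sn.normalize_adjacency(net).toarray()
    y = np.zeros(len(net))
    for g, v in prior.items():
        y[net.nodes.index(g)] = v
    f = (1 - alpha) * np.linalg.solve(np.eye(len(net)) - alpha * w, y)
    return {g: f[i] for i, g in enumerate(net.nodes)}


class TestNormalizeAdjacency:
    def test_single_edge(self):
        net = net_from_edges([("a", "b")])
        w = sn.normalize_adjacency(net).toarray()
        assert w[0, 1] == pytest.approx(1.0) and w[1, 0] == pytest.approx(1.0)

    def test_triangle(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        w = sn.normalize_adjacency(net).toarray()
        off = w[np.nonzero(w)]
        assert np.allclose(off, 0.5)

    def test_star_with_three_leaves(self):
        net = net_from_edges([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        w = sn.normalize_adjacency(net).toarray()
        hub = net.nodes.index("hub")
        for leaf in ("l1", "l2", "l3"):
            assert w[hub, net.nodes.index(leaf)] == pytest.approx(1 / np.sqrt(3))

    def test_spectral_radius_at_most_one(self, random_net):
        w = sn.normalize_adjacency(random_net).toarray()
        assert np.max(np.abs(np.linalg.eigvals(w))) <= 1.0 + 1e-9


class TestPropagate:
    def test_alpha_to_zero_limit_returns_prior(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        prior = {"a": 1.0, "c": 0.25}
        res = sn.propagate(net, prior, sn.PropagationConfig(alpha=1e-9))
        assert res.scores["a"] == pytest.approx(1.0, abs=1e-6)
        assert res.scores["c"] == pytest.approx(0.25, abs=1e-6)
        assert res.scores["b"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_matches_closed_form_on_random_graphs(self, alpha):
        rng = np.random.default_rng(17)
        for trial in range(5):
            while True:
                g = nx.gnp_random_graph(
                    int(rng.integers(8, 31)), 0.25, seed=int(rng.integers(2**31))
                )
                if nx.is_connected(g) and g.number_of_nodes() > 2:
                    break
            net = sn.MolecularNetwork(nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes}))
            seeds = list(net.nodes)[:3]
            prior = {s: 1.0 for s in seeds}
            cfg = sn.PropagationConfig(alpha=alpha, tol=1e-9, max_iter=5000)
            res = sn.propagate(net, prior, cfg)
            exact = closed_form(net, prior, alpha)
            diff = max(abs(res.scores[g] - exact[g]) for g in net.nodes)
            assert res.converged and diff < 10 * cfg.tol

    def test_symmetric_graph_symmetric_prior_symmetric_scores(self):
        net = net_from_edges([("a", "b"), ("b", "c")])  # path symmetric about b
        res = sn.propagate(net, {"a": 1.0, "c": 1.0}, sn.PropagationConfig())
        assert res.scores["a"] == pytest.approx(res.scores["c"])

    def test_monotone_in_prior(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        base = sn.propagate(net, {"a": 1.0}, sn.PropagationConfig())
        raised = sn.propagate(net, {"a": 1.0, "c": 0.5}, sn.PropagationConfig())
        for g in net.nodes:
            assert raised.scores[g] >= base.scores[g] - 1e-12

    def test_all_zero_prior_errors(self):
        net = net_from_edges([("a", "b")])
        with pytest.raises(ValueError, match="all-zero"):
            sn.propagate(net, {"a": 0.0}, sn.PropagationConfig())

    def test_non_convergence_warns(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        with pytest.warns(UserWarning, match="converge"):
            res = sn.propagate(net, {"a": 1.0}, sn.PropagationConfig(tol=1e-12, max_iter=2))
        assert not res.converged


class TestBuildPrior:
    def test_no_similar_entities_is_indicator(self, path_net):
        mod = sn.build_module({"a", "b"}, path_net, "m")
        assert sn.build_prior(mod) == {"a": 1.0, "b": 1.0}

    def test_max_rule_over_similar_entities(self, path_net):
        mod = sn.build_module({"a"}, path_net, "m")
        d1 = sn.build_module({"c"}, path_net, "d1")
        d2 = sn.build_module({"c", "d"}, path_net, "d2")
        prior = sn.build_prior(mod, [(d1, 0.4), (d2, 0.7)])
        assert prior["c"] == pytest.approx(0.7)
        assert prior["d"] == pytest.approx(0.7)

    def test_own_membership_dominates(self, path_net):
        mod = sn.build_module({"a"}, path_net, "m")
        other = sn.build_module({"a", "b"}, path_net, "o")
        prior = sn.build_prior(mod, [(other, 0.9)])
        assert prior["a"] == 1.0

    def test_sum_aggregation(self, path_net):
        mod = sn.build_module({"a"}, path_net, "m")
        d1 = sn.build_module({"c"}, path_net, "d1")
        d2 = sn.build_module({"c"}, path_net, "d2")
        prior = sn.build_prior(mod, [(d1, 0.4), (d2, 0.3)], agg="sum")
        assert prior["c"] == pytest.approx(0.7)

    def test_out_of_range_similarity_errors(self, path_net):
        mod = sn.build_module({"a"}, path_net, "m")
        other = sn.build_module({"b"}, path_net, "o")
        with pytest.raises(ValueError, match="0, 1"):
            sn.build_prior(mod, [(other, 1.5)])


class TestExpandModule:
    def test_k_zero_is_identity(self, path_net):
        mod = sn.build_module({"b"}, path_net, "m")
        scores = sn.propagate(path_net, {"b": 1.0}, sn.PropagationConfig())
        out = sn.expand_module(mod, scores, path_net, sn.PropagationConfig(expansion_k=0))
        assert out.genes_on_network == {"b"}

    def test_chain_admits_both_neighbours(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        mod = sn.build_module({"b"}, net, "m")
        scores = sn.propagate(net, {"b": 1.0}, sn.PropagationConfig())
        out = sn.expand_module(mod, scores, net, sn.PropagationConfig(expansion_k=2))
        assert out.genes_on_network == {"a", "b", "c"}

    def test_no_prior_variant_admits_all_neighbours(self, path_net):
        mod = sn.build_module({"b"}, path_net, "m")
        out = sn.expand_module(mod, None, path_net, sn.PropagationConfig())
        assert out.genes_on_network == {"a", "b", "c", "f"}

    def test_size_invariant(self, random_net):
        mod = sn.build_module(set(random_net.nodes[:4]), random_net, "m")
        scores = sn.propagate(
            random_net, {g: 1.0 for g in mod.genes_on_network}, sn.PropagationConfig()
        )
        candidates = set()
        for g in mod.genes_on_network:
            candidates.update(random_net.graph.neighbors(g))
        candidates -= mod.genes_on_network
        for k in (0, 2, 10, 100):
            out = sn.expand_module(
                mod, scores, random_net, sn.PropagationConfig(expansion_k=k)
            )
            assert len(out) == len(mod) + min(k, len(candidates))

    def test_no_neighbours_warns_and_returns_unchanged(self):
        net = net_from_edges([("a", "b")])
        mod = sn.build_module({"a", "b"}, net, "m")
        with pytest.warns(UserWarning, match="no neighbour"):
            out = sn.expand_module(mod, None, net, sn.PropagationConfig())
        assert out.genes_on_network == {"a", "b"}
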