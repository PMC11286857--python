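"""Shared fixtures: toy graphs and session-scoped synthetic benchmarks."""

import numpy as np
import pytest

import syndrumnet as sn


@pytest.fixture()
def path_net():
    """5-node path a-b-c-d-e plus a pendant f on b (spec-style toy graph)."""
    return sn.load_network(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "f")]
    )


@pytest.fixture(scope="session")
def random_net():
    """Connected 30-node random graph for oracle comparisons."""
    import networkx as nx

    rng = np.random.default_rng(42)
    while True:
        g = nx.gnp_random_graph(30, 0.12, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    return sn.MolecularNetwork(g)


@pytest.fixture(scope="session")
def small_bench():
    """Reduced planted benchmark for unit-level structural checks."""
    cfg = sn.SynthConfig(
        n_genes=600,
        disease_module_size=30,
        drug_module_size=15,
        n_planted_drugs=4,
        n_decoy_drugs=8,
        rng_seed=7,
    )
    return sn.generate_benchmark(cfg)


@pytest.fixture(scope="session")
def bench():
    """Reference planted benchmark at the study-condition defaults."""
    return sn.generate_benchmark(rng_seed=0)
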