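"""Molecular interaction network: loading, giant component, distances, degree-matched sampling.

The undirected gene–gene interaction graph is the backbone for every
network-based measure in this package (closest-distance proximity, module
separation, propagation). Nodes are opaque gene identifiers (strings);
edges are unweighted and undirected. All shortest-path machinery works in
hop units on the giant component, so distances are always finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularNetwork",
    "DegreeBins",
    "load_network",
    "giant_component",
    "shortest_path_lengths",
    "build_degree_bins",
    "degree_matched_sample",
]


class MolecularNetwork:
    """Undirected, simple (no self-loops, no multi-edges) gene interaction graph.

    Wraps a :class:`networkx.Graph` and lazily caches a CSR adjacency matrix
    plus a node index for fast multi-source BFS via scipy's csgraph routines.
    """

    def __init__(self, graph: nx.Graph):
        if nx.number_of_selfloops(graph):
            raise ValueError("network must not contain self-loops")
        self.graph = graph
        self._nodes: list[str] = sorted(graph.nodes)
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._nodes)}
        self._adjacency: csr_matrix | None = None

    # -- basic container protocol -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return self._nodes

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self._index)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def index_of(self, genes: Iterable[str]) -> np.ndarray:
        """Integer indices for *genes*; raises listing any gene not on the network."""
        missing = [g for g in genes if g not in self._index]
        if missing:
            raise KeyError(f"genes absent from network: {sorted(missing)[:10]}")
        return np.fromiter((self._index[g] for g in genes), dtype=np.intp)

    @property
    def adjacency(self) -> csr_matrix:
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self.graph, nodelist=self._nodes, format="csr", dtype=np.float64
            )
        return self._adjacency

    def min_distances_from(self, sources: Iterable[str]) -> np.ndarray:
        """Hop distance from the nearest of *sources* to every node (multi-source BFS)."""
        idx = self.index_of(sources)
        if idx.size == 0:
            raise ValueError("source set is empty")
        return dijkstra(self.adjacency, unweighted=True, indices=idx, min_only=True)

    def distances_from(self, sources: Sequence[str]) -> np.ndarray:
        """Matrix of hop distances, one row per source, columns in ``nodes`` order."""
        idx = self.index_of(sources)
        dist = dijkstra(self.adjacency, unweighted=True, indices=idx)
        return np.atleast_2d(dist)

    def is_connected(self) -> bool:
        return len(self) > 0 and nx.is_connected(self.graph)


@dataclass(frozen=True)
class DegreeBins:
    """Partition of network nodes into degree-similar groups.

    Exact-degree groups are merged upward (ascending degree) until every bin
    holds at least ``min_bin_size`` nodes, the standard construction for
    degree-preserving null models of proximity measures.
    """

    bins: tuple[tuple[str, ...], ...]
    min_bin_size: int
    _gene_to_bin: Mapping[str, int] = field(repr=False, hash=False, compare=False, default=None)

    def bin_of(self, gene: str) -> int:
        return self._gene_to_bin[gene]

    def members(self, bin_id: int) -> tuple[str, ...]:
        return self.bins[bin_id]


def load_network(edge_table, *, header: str | bool = "auto") -> MolecularNetwork:
    """Build a network from two-column edge records.

    Parameters
    ----------
    edge_table
        Either an iterable of ``(gene_a, gene_b)`` pairs, or a path to a
        TSV/CSV file with two columns (``#`` comment lines ignored, header
        optional).
    header
        Only used for file input: ``"auto"`` skips a first line whose fields
        look like column names; ``True``/``False`` force the choice.

    Self-loops and duplicated (unordered) edges are removed; the node and
    edge counts of the cleaned graph are logged.
    """
    if isinstance(edge_table, (str, bytes)) or hasattr(edge_table, "__fspath__"):
        pairs = _read_edge_file(edge_table, header=header)
    else:
        pairs = list(edge_table)
    if not pairs:
        raise ValueError("empty edge input")
    g = nx.Graph()
    n_self, n_dup = 0, 0
    for a, b in pairs:
        a, b = str(a).strip(), str(b).strip()
        if not a or not b:
            raise ValueError(f"malformed edge record: {(a, b)!r}")
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError("no valid edges after removing self-loops/duplicates")
    logger.info(
        "loaded network: %d nodes, %d edges (%d self-loops, %d duplicates removed)",
        g.number_of_nodes(), g.number_of_edges(), n_self, n_dup,
    )
    return MolecularNetwork(g)


_HEADER_TOKENS = {
    "source", "target", "gene_a", "gene_b", "genea", "geneb", "node1", "node2",
    "from", "to", "protein1", "protein2", "gene1", "gene2", "a", "b",
}


def _read_edge_file(path, *, header: str | bool = "auto") -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected two columns, got {line!r}")
            a, b = fields[0].strip(), fields[1].strip()
            if first_data_line:
                first_data_line = False
                skip = header is True or (
                    header == "auto" and a.lower() in _HEADER_TOKENS and b.lower() in _HEADER_TOKENS
                )
                if skip:
                    continue
            if not a or not b:
                raise ValueError(f"line {lineno}: empty gene identifier in {line!r}")
            pairs.append((a, b))
    return pairs


def giant_component(net: MolecularNetwork) -> MolecularNetwork:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken deterministically by the
    lexicographically smallest member gene.
    """
    if len(net) == 0:
        raise ValueError("empty network")
    components = [frozenset(c) for c in nx.connected_components(net.graph)]
    best = max(components, key=lambda c: (len(c), min(c)))
    if len(best) == len(net):
        return net
    sub = net.graph.subgraph(best).copy()
    logger.info("giant component: %d of %d nodes retained", len(best), len(net))
    return MolecularNetwork(sub)


def shortest_path_lengths(
    net: MolecularNetwork, sources: Iterable[str], targets: Iterable[str]
) -> dict[tuple[str, str], int]:
    """Hop distances for every (source, target) pair.

    All genes must be present on the network (error lists the offenders).
    Symmetric in the sense that d(s, t) equals d(t, s).
    """
    sources = sorted(set(sources))
    targets = sorted(set(targets))
    t_idx = net.index_of(targets)
    dist = net.distances_from(sources)
    out: dict[tuple[str, str], int] = {}
    for i, s in enumerate(sources):
        row = dist[i, t_idx]
        if np.isinf(row).any():
            raise ValueError(f"no finite path from {s} to some targets (disconnected graph?)")
        for t, d in zip(targets, row):
            out[(s, t)] = int(d)
    return out


def build_degree_bins(net: MolecularNetwork, min_bin_size: int = 100) -> DegreeBins:
    """Group nodes by degree, merging adjacent degree groups until each bin
    has at least ``min_bin_size`` members (the last bin absorbs any small tail)."""
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    by_degree: dict[int, list[str]] = {}
    for g in net.nodes:
        by_degree.setdefault(net.degree(g), []).append(g)
    bins: list[list[str]] = []
    current: list[str] = []
    for d in sorted(by_degree):
        current.extend(sorted(by_degree[d]))
        if len(current) >= min_bin_size:
            bins.append(current)
            current = []
    if current:
        if bins:
            bins[-1].extend(current)
        else:
            bins.append(current)
    gene_to_bin = {g: i for i, members in enumerate(bins) for g in members}
    return DegreeBins(
        bins=tuple(tuple(m) for m in bins),
        min_bin_size=min_bin_size,
        _gene_to_bin=gene_to_bin,
    )


def degree_matched_sample(
    net: MolecularNetwork,
    template: Iterable[str],
    bins: DegreeBins,
    rng: np.random.Generator | int,
) -> frozenset[str]:
    """Random gene set matching *template* in size and (binned) degree.

    For each degree bin, as many genes as the template holds in that bin are
    drawn uniformly without replacement from the bin's members.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    template = sorted(set(template))
    net.index_of(template)  # validates membership
    needed: dict[int, int] = {}
    for g in template:
        b = bins.bin_of(g)
        needed[b] = needed.get(b, 0) + 1
    sample: list[str] = []
    for b in sorted(needed):
        members = bins.members(b)
        k = needed[b]
        if k > len(members):
            raise ValueError(
                f"degree bin {b} has {len(members)} genes but template needs {k}; "
                "increase min_bin_size"
            )
        chosen = rng.choice(len(members), size=k, replace=False)
        sample.extend(members[i] for i in chosen)
    return frozenset(sample)
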