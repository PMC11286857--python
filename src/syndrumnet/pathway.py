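"""Pathway-level mode-of-action analytics.

Over-representation of a gene set in user-supplied pathway collections
(one-sided hypergeometric), coverage of a disease's enriched pathways by a
drug pair's enriched pathways, significance of the largest connected
component formed by module genes inside a pathway subgraph, and
fold-change-based DEG filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "enrich",
    "pathway_coverage",
    "lcc_zscore",
    "deg_filter",
]


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets over a background universe (e.g. KEGG-style pathways
    read from GMT)."""

    pathways: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        sets = {str(k): frozenset(v) for k, v in self.pathways.items()}
        universe = frozenset(self.universe)
        stray = set().union(*sets.values()) - universe if sets else set()
        if stray:
            raise ValueError(f"pathway genes outside universe: {sorted(stray)[:5]}")
        object.__setattr__(self, "pathways", sets)
        object.__setattr__(self, "universe", universe)

    def __len__(self) -> int:
        return len(self.pathways)


def enrich(
    genes: Iterable[str], pathways: PathwayCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    P(X >= overlap) for drawing ``len(query)`` genes from the universe
    where the pathway marks its members as successes. Genes outside the
    universe are dropped with a warning. No multiplicity correction is
    applied; ``significant`` flags raw p < alpha.
    """
    query = frozenset(genes)
    if not query:
        raise ValueError("empty query gene set")
    outside = query - pathways.universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query genes outside the universe")
        query = query & pathways.universe
        if not query:
            raise ValueError("no query genes remain inside the universe")
    n_universe = len(pathways.universe)
    n_query = len(query)
    rows = []
    for pid, members in sorted(pathways.pathways.items()):
        overlap = len(query & members)
        # P(X >= overlap) with X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        rows.append(
            {
                "pathway": pid,
                "pathway_size": len(members),
                "overlap": overlap,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)


def pathway_coverage(target_pathways: Iterable[str], drug_pathways_union: Iterable[str]) -> float:
    """Fraction of the target's enriched pathways also enriched for the drug
    pair: |target ∩ union| / |target|. Monotone in the union."""
    target = set(target_pathways)
    if not target:
        raise ValueError("empty target pathway set")
    return len(target & set(drug_pathways_union)) / len(target)


def lcc_zscore(
    net: MolecularNetwork,
    pathway_genes: Iterable[str],
    module_genes: Iterable[str],
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> tuple[int, float]:
    """Size and significance of the largest connected component formed by
    module genes inside a pathway's induced subgraph.

    The null draws ``n_perm`` uniform same-size gene sets from the pathway
    genes (degree matching is unnecessary at pathway scale) and
    standardises the observed LCC size. Returns (lcc_size, z); z is NaN
    when the module misses the pathway entirely or the null is degenerate.
    The conventional significance cutoff is z > 1.95.
    """
    pathway_genes = sorted(set(pathway_genes) & net.node_set)
    if not pathway_genes:
        raise ValueError("pathway has no genes on the network")
    sub = net.graph.subgraph(pathway_genes)
    inside = sorted(set(module_genes) & set(pathway_genes))
    if not inside:
        return 0, float("nan")
    obs = _lcc_size(sub, inside)
    rng = np.random.default_rng(int(rng_seed))
    k = len(inside)
    null = np.empty(n_perm)
    pool = np.array(pathway_genes)
    for i in range(n_perm):
        draw = pool[rng.choice(len(pool), size=k, replace=False)]
        null[i] = _lcc_size(sub, draw)
    sigma = null.std(ddof=0)
    if sigma == 0.0:
        warnings.warn("degenerate LCC null (sigma = 0)")
        return obs, float("nan")
    return obs, float((obs - null.mean()) / sigma)


def _lcc_size(subgraph: nx.Graph, genes) -> int:
    induced = subgraph.subgraph(genes)
    if induced.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(induced))


def deg_filter(table: Mapping[str, float], threshold: float = 1.0) -> frozenset[str]:
    """Differentially expressed genes: |log2 fold change| >= threshold
    (boundary included)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = set()
    for gene, fc in table.items():
        fc = float(fc)
        if not np.isfinite(fc):
            raise ValueError(f"non-finite log2FC for {gene}")
        if abs(fc) >= threshold:
            out.add(gene)
    return frozenset(out)
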