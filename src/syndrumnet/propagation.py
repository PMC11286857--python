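"""PRINCE-style network propagation with prior knowledge.

Seed/prior scores diffuse over the symmetrically normalised network,
F_t = alpha * W' F_{t-1} + (1 - alpha) * Y, where W' = D^{-1/2} W D^{-1/2}
and Y encodes membership of the entity's own module (1) plus
similarity-weighted membership of related entities' modules. The fixed
point ranks candidate genes; module expansion admits top-scoring network
neighbours of the current module. A no-prior variant admits all
neighbours.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix, diags

from .modules import GeneModule
from .network import MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "PropagationScores",
    "normalize_adjacency",
    "propagate",
    "build_prior",
    "expand_module",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Free parameters of the propagation and expansion steps.

    alpha
        Mixing weight in (0, 1) between network smoothing and the prior:
        higher alpha diffuses farther from the seeds.
    tol, max_iter
        Convergence threshold on the max absolute score change, and the
        iteration cap.
    expansion_k
        Number of neighbour candidates admitted per module; ``None`` means
        "as many as the module has genes".
    prior_agg
        How similarity evidence from several related entities combines for
        a gene outside the entity's own module: strongest single source
        (``"max"``, the PRINCE heuristic) or additive (``"sum"``).
    """

    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    expansion_k: int | None = None
    prior_agg: str = "max"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.prior_agg not in ("max", "sum"):
            raise ValueError("prior_agg must be 'max' or 'sum'")


@dataclass(frozen=True)
class PropagationScores:
    """Per-gene stationary scores plus convergence diagnostics."""

    scores: Mapping[str, float]
    converged: bool
    n_iter: int

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.scores.get(gene, default)


def normalize_adjacency(net: MolecularNetwork) -> csr_matrix:
    """Symmetric normalisation W' = D^{-1/2} W D^{-1/2}.

    Spectral radius is at most 1 on a connected graph; isolated nodes
    (impossible after giant-component extraction) raise an error.
    """
    adj = net.adjacency
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if (deg == 0).any():
        raise ValueError("isolated node: normalisation undefined")
    d_inv_sqrt = diags(1.0 / np.sqrt(deg))
    return (d_inv_sqrt @ adj @ d_inv_sqrt).tocsr()


def propagate(
    net: MolecularNetwork,
    prior: Mapping[str, float],
    cfg: PropagationConfig = PropagationConfig(),
    norm_adj: csr_matrix | None = None,
) -> PropagationScores:
    """Iterate F = alpha * W' F + (1 - alpha) * Y to its fixed point.

    The prior must be non-negative and not all-zero. Passing a
    pre-computed ``norm_adj`` avoids re-normalising when many entities
    propagate over the same network.
    """
    y = np.zeros(len(net))
    for gene, v in prior.items():
        if v < 0:
            raise ValueError(f"negative prior value for {gene}")
        if gene in net:
            y[net.index_of([gene])[0]] = float(v)
    if not y.any():
        raise ValueError("prior is all-zero on the network")
    w = normalize_adjacency(net) if norm_adj is None else norm_adj
    f = y.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        f_new = cfg.alpha * (w @ f) + (1.0 - cfg.alpha) * y
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"propagation did not converge in {cfg.max_iter} iterations")
    scores = {g: float(f[i]) for i, g in enumerate(net.nodes)}
    return PropagationScores(scores=scores, converged=converged, n_iter=n_iter)


def build_prior(
    entity: GeneModule,
    similar_entities: Sequence[tuple[GeneModule, float]] = (),
    agg: str = "max",
) -> dict[str, float]:
    """Prior knowledge vector: 1 on the entity's own module genes; for other
    genes, the (max or sum, per *agg*) similarity of related entities whose
    module contains the gene; 0 elsewhere. Own membership dominates."""
    prior: dict[str, float] = {}
    for other, sim in similar_entities:
        if not (0.0 <= sim <= 1.0):
            raise ValueError(f"similarity for {other.entity_id} outside [0, 1]")
        for g in other.genes_on_network:
            if agg == "sum":
                prior[g] = prior.get(g, 0.0) + sim
            else:
                prior[g] = max(prior.get(g, 0.0), sim)
    for g in entity.genes_on_network:
        prior[g] = 1.0
    return prior


def expand_module(
    module: GeneModule,
    scores: PropagationScores | None,
    net: MolecularNetwork,
    cfg: PropagationConfig = PropagationConfig(),
) -> GeneModule:
    """Grow a module with its top-scoring network neighbours.

    Candidates are the direct network neighbours of the current module
    genes. With propagation scores, the ``expansion_k`` best candidates are
    admitted (default k = module size), ties broken by gene id; without
    scores (the no-prior "neighbours" variant) every candidate is admitted.
    Original genes are always retained.
    """
    base = module.genes_on_network
    candidates = set()
    for g in base:
        candidates.update(net.graph.neighbors(g))
    candidates -= base
    if not candidates:
        warnings.warn(f"{module.entity_id}: no neighbour candidates; module unchanged")
        return module
    if scores is None:
        admitted = candidates
    else:
        k = len(base) if cfg.expansion_k is None else cfg.expansion_k
        ranked = sorted(candidates, key=lambda g: (-scores.get(g), g))
        admitted = set(ranked[: max(k, 0)])
    new_genes = base | admitted
    return GeneModule(
        entity_id=module.entity_id,
        genes=module.genes | frozenset(admitted),
        genes_on_network=frozenset(new_genes),
    )
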