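"""Network-based proximity and separation between gene modules.

Two related distance measures drive the prediction:

* closest-distance proximity d(Q, A) = (1/|A|) sum over a in A of the
  shortest-path distance from a to the nearest gene of Q, standardised
  against a degree-matched permutation null into a z-score, then
  sign-inverted and min-max scaled into P in [0, 1] across a drug
  collection;
* module separation s_AB = <d_AB> - (<d_AA> + <d_BB>)/2, positive when two
  modules occupy distinct network neighbourhoods.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .modules import GeneModule
from .network import DegreeBins, MolecularNetwork, degree_matched_sample

logger = logging.getLogger(__name__)

__all__ = [
    "ProximityResult",
    "SeparationResult",
    "closest_distance",
    "proximity_z",
    "scale_to_unit",
    "separation",
    "pairwise_separation",
]


@dataclass(frozen=True)
class ProximityResult:
    """Observed closest distance with its permutation-null summary."""

    d_observed: float
    mu: float
    sigma: float
    z: float
    n_perm: int
    degenerate: bool = False  # sigma == 0, z forced to 0


@dataclass(frozen=True)
class SeparationResult:
    d_aa: float
    d_bb: float
    d_ab: float
    s: float


def _as_gene_set(module) -> frozenset[str]:
    if isinstance(module, GeneModule):
        return module.genes_on_network
    return frozenset(module)


def _closest_distance_sets(net: MolecularNetwork, q: frozenset[str], a: frozenset[str]) -> float:
    dist = net.min_distances_from(q)
    vals = dist[net.index_of(a)]
    if np.isinf(vals).any():
        raise ValueError("infinite distance encountered; run giant_component first")
    return float(vals.mean())


def closest_distance(net: MolecularNetwork, query: GeneModule, other) -> float:
    """Mean over *other*'s genes of the hop distance to the nearest gene of
    *query*. Asymmetric: averages over the second argument, minimises over
    the first. Zero iff the second module is a subset of the first."""
    q, a = _as_gene_set(query), _as_gene_set(other)
    if not q or not a:
        raise ValueError("modules must be non-empty on the network")
    return _closest_distance_sets(net, q, a)


def proximity_z(
    net: MolecularNetwork,
    query: GeneModule,
    other,
    bins: DegreeBins,
    n_perm: int = 100,
    rng_seed: int = 0,
) -> ProximityResult:
    """Standardise d(Q, A) against a degree-matched permutation null.

    Each repetition independently resamples BOTH gene sets, matching the
    size and degree-bin profile of the originals, and recomputes the
    closest distance. z = (d_obs - mu) / sigma over ``n_perm`` repetitions.
    Permutation streams derive from ``rng_seed`` by counter offset, so a
    fixed seed is bit-reproducible and results do not depend on evaluation
    order across module pairs.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    q, a = _as_gene_set(query), _as_gene_set(other)
    if not q or not a:
        raise ValueError("modules must be non-empty on the network")
    d_obs = _closest_distance_sets(net, q, a)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng([int(rng_seed), i])
        q_rand = degree_matched_sample(net, q, bins, rng)
        a_rand = degree_matched_sample(net, a, bins, rng)
        null[i] = _closest_distance_sets(net, q_rand, a_rand)
    mu = float(null.mean())
    sigma = float(null.std(ddof=0))
    if sigma == 0.0:
        warnings.warn("degenerate permutation null (sigma = 0); z set to 0")
        return ProximityResult(d_obs, mu, 0.0, 0.0, n_perm, degenerate=True)
    return ProximityResult(d_obs, mu, sigma, (d_obs - mu) / sigma, n_perm)


def scale_to_unit(z_values: Mapping[str, float]) -> dict[str, float]:
    """Sign-invert z-scores and min-max scale them into [0, 1].

    Computed across one collection (e.g. all drugs for a query disease):
    the most negative z maps to 1, the most positive to 0.
    """
    if len(z_values) < 2:
        raise ValueError("need at least two values to scale")
    neg = {k: -float(v) for k, v in z_values.items()}
    lo, hi = min(neg.values()), max(neg.values())
    if hi == lo:
        raise ValueError("all z-values identical; scaling undefined")
    return {k: (v - lo) / (hi - lo) for k, v in neg.items()}


def separation(net: MolecularNetwork, mod_a: GeneModule, mod_b: GeneModule) -> SeparationResult:
    """Topological separation of two modules.

    <d_AA> averages, over each gene of A, the distance to the nearest
    *other* gene of A (0 for a singleton module); <d_AB> averages, over all
    genes of the union, the distance to the nearest gene of the opposite
    set, with genes shared by both modules contributing 0.
    s_AB = <d_AB> - (<d_AA> + <d_BB>)/2; symmetric in A and B.
    """
    a, b = _as_gene_set(mod_a), _as_gene_set(mod_b)
    if not a or not b:
        raise ValueError("modules must be non-empty on the network")
    d_aa = _mean_within(net, a)
    d_bb = _mean_within(net, b)
    d_ab = _mean_between(net, a, b)
    s = d_ab - (d_aa + d_bb) / 2.0
    return SeparationResult(d_aa=d_aa, d_bb=d_bb, d_ab=d_ab, s=s)


def pairwise_separation(
    net: MolecularNetwork, modules: Mapping[str, GeneModule]
) -> dict[tuple[str, str], SeparationResult]:
    """Separation for every unordered module pair.

    Equivalent to calling :func:`separation` per pair, but each module's
    nearest-distance array and within-module mean are computed once, so the
    cost is linear rather than quadratic in the collection size.
    """
    names = sorted(modules)
    gene_sets = {n: _as_gene_set(modules[n]) for n in names}
    for n in names:
        if not gene_sets[n]:
            raise ValueError(f"module {n} is empty on the network")
    idx = {n: net.index_of(sorted(gene_sets[n])) for n in names}
    dmin = {n: net.min_distances_from(gene_sets[n]) for n in names}
    d_within = {n: _mean_within(net, gene_sets[n]) for n in names}
    out: dict[tuple[str, str], SeparationResult] = {}
    for a, b in itertools.combinations(names, 2):
        vals_a = dmin[b][idx[a]]
        vals_b = dmin[a][idx[b]]
        total = np.concatenate([vals_a, vals_b])
        if np.isinf(total).any():
            raise ValueError("infinite between-module distance; run giant_component first")
        d_ab = float(total.sum() / (len(gene_sets[a]) + len(gene_sets[b])))
        s = d_ab - (d_within[a] + d_within[b]) / 2.0
        out[(a, b)] = SeparationResult(d_aa=d_within[a], d_bb=d_within[b], d_ab=d_ab, s=s)
    return out


def _mean_within(net: MolecularNetwork, genes: frozenset[str]) -> float:
    if len(genes) == 1:
        return 0.0
    ordered = sorted(genes)
    dist = net.distances_from(ordered)  # |genes| x n_nodes
    cols = net.index_of(ordered)
    mat = dist[:, cols]
    np.fill_diagonal(mat, np.inf)  # exclude self
    nearest = mat.min(axis=1)
    if np.isinf(nearest).any():
        raise ValueError("infinite within-module distance; run giant_component first")
    return float(nearest.mean())


def _mean_between(net: MolecularNetwork, a: frozenset[str], b: frozenset[str]) -> float:
    dist_to_b = net.min_distances_from(b)
    dist_to_a = net.min_distances_from(a)
    vals_a = dist_to_b[net.index_of(sorted(a))]  # a-genes -> nearest b
    vals_b = dist_to_a[net.index_of(sorted(b))]  # b-genes -> nearest a
    total = np.concatenate([vals_a, vals_b])
    if np.isinf(total).any():
        raise ValueError("infinite between-module distance; run giant_component first")
    # shared genes appear in both passes with distance 0, as required
    return float(total.sum() / (len(a) + len(b)))
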