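"""Similarity layers: transcriptional cosine, chemical weighted Jaccard,
and network-based disease similarity.

Three independent notions of likeness feed the prediction:

* cosine correlation between expression signatures on a shared gene set
  (transcriptional correlation C);
* generalized (weighted) Jaccard on chemical fingerprint count vectors
  (structural drug similarity R(A, B));
* sign-inverted, unit-scaled proximity z between a query disease module and
  other diseases' gene sets (network-based disease similarity R(Q, a)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .modules import ExpressionSignature, GeneModule
from .network import DegreeBins, MolecularNetwork
from .proximity import proximity_z, scale_to_unit

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintVector",
    "SimilarityMatrix",
    "cosine_correlation",
    "weighted_jaccard",
    "fingerprint_similarity_matrix",
    "disease_similarity",
]

DEFAULT_MIN_OVERLAP = 3


@dataclass(frozen=True)
class FingerprintVector:
    """Sparse non-negative feature counts for one drug (e.g. substructure
    fingerprints read from file)."""

    drug_id: str
    counts: Mapping[str, float]

    def __post_init__(self):
        cleaned = {str(f): float(c) for f, c in self.counts.items() if c != 0}
        if any(c < 0 for c in cleaned.values()):
            raise ValueError(f"{self.drug_id}: negative fingerprint count")
        if not cleaned:
            raise ValueError(f"{self.drug_id}: all-zero fingerprint")
        object.__setattr__(self, "counts", cleaned)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric entity-by-entity similarity with unit diagonal."""

    ids: tuple[str, ...]
    values: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityMatrix":
        if not np.allclose(df.to_numpy(), df.to_numpy().T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        return cls(ids=tuple(df.index), values=df)

    def get(self, a: str, b: str) -> float:
        return float(self.values.at[a, b])


def cosine_correlation(
    sig1: ExpressionSignature,
    sig2: ExpressionSignature,
    genes: Iterable[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Cosine of the two raw signature value vectors restricted to *genes*.

    No centering is applied (cosine, not Pearson). Only genes with a value
    in BOTH signatures count toward the overlap; below ``min_overlap`` the
    correlation is undefined and NaN is returned with a warning (callers
    score such pairs with C = 0 and a flag).
    """
    genes = sorted(set(genes))
    shared = [g for g in genes if g in sig1.values.index and g in sig2.values.index]
    if len(shared) < min_overlap:
        warnings.warn(
            f"cosine undefined: {len(shared)} overlapping genes "
            f"(< min_overlap={min_overlap}) between {sig1.entity_id} and {sig2.entity_id}"
        )
        return float("nan")
    x = sig1.values.loc[shared].to_numpy()
    y = sig2.values.loc[shared].to_numpy()
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0.0 or ny_ == 0.0:
        warnings.warn(
            f"cosine undefined: zero vector on overlap between "
            f"{sig1.entity_id} and {sig2.entity_id}"
        )
        return float("nan")
    return float(np.dot(x, y) / (nx_ * ny_))


def weighted_jaccard(x: FingerprintVector, y: FingerprintVector) -> float:
    """Generalized Jaccard: sum of elementwise minima over sum of maxima
    across the feature union. 1 for identical vectors, 0 for disjoint
    supports, scale-invariant under joint positive rescaling."""
    features = set(x.counts) | set(y.counts)
    num = sum(min(x.counts.get(f, 0.0), y.counts.get(f, 0.0)) for f in features)
    den = sum(max(x.counts.get(f, 0.0), y.counts.get(f, 0.0)) for f in features)
    if den == 0.0:
        raise ValueError("both fingerprints are all-zero")
    return num / den


def fingerprint_similarity_matrix(fps: Sequence[FingerprintVector]) -> SimilarityMatrix:
    """All-pairs weighted-Jaccard similarity for a drug collection."""
    ids = [fp.drug_id for fp in fps]
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = weighted_jaccard(fps[i], fps[j])
    df = pd.DataFrame(mat, index=ids, columns=ids)
    return SimilarityMatrix(ids=tuple(ids), values=df)


def disease_similarity(
    net: MolecularNetwork,
    query: GeneModule,
    others: Sequence[GeneModule],
    bins: DegreeBins,
    n_perm: int = 100,
    rng_seed: int = 0,
) -> pd.Series:
    """Network-based similarity of a query disease to other diseases.

    Proximity z(Q, a) between the query's module and each other disease's
    gene set is computed with the degree-matched permutation null, then
    sign-inverted and min-max scaled across the disease collection: the
    closest disease maps to 1, the farthest to 0.
    """
    if len(others) < 2:
        raise ValueError("need at least two other diseases to scale similarities")
    z = {}
    for k, other in enumerate(others):
        res = proximity_z(net, query, other, bins, n_perm=n_perm, rng_seed=_sub_seed(rng_seed, k))
        z[other.entity_id] = res.z
    scaled = scale_to_unit(z)
    return pd.Series(scaled).sort_index()


def _sub_seed(seed: int, k: int) -> int:
    # independent per-entity permutation streams derived from one seed
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(k,)).generate_state(1)[0] % (2**31))
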