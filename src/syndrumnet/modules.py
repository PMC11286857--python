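"""Disease and drug modules built from gene lists and expression signatures.

A *module* is the set of genes characterising one entity (a disease's
susceptibility genes, or a drug's response genes) mapped onto the molecular
interaction network. Drug response genes are the top fraction of most
up-regulated plus most down-regulated genes of the drug's expression
signature (5% each side by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .network import MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = ["ExpressionSignature", "GeneModule", "top_fraction_genes", "build_module"]


@dataclass(frozen=True)
class ExpressionSignature:
    """Signed differential-expression values (fold change or characteristic
    score) for one entity, keyed by gene."""

    entity_id: str
    values: pd.Series  # gene -> signed float
    kind: str = "drug"  # "disease" | "drug"

    def __post_init__(self):
        v = self.values.astype(float)
        if v.index.has_duplicates:
            raise ValueError(f"{self.entity_id}: duplicate genes in signature")
        if not np.isfinite(v.to_numpy()).all():
            raise ValueError(f"{self.entity_id}: non-finite signature values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def nonzero_genes(self) -> frozenset[str]:
        """Genes with a non-zero score (the characteristic-score convention
        for disease-specific genes)."""
        v = self.values
        return frozenset(v.index[v != 0.0])


@dataclass(frozen=True)
class GeneModule:
    """A named gene set together with its network-mapped subset."""

    entity_id: str
    genes: frozenset[str]
    genes_on_network: frozenset[str] = field(default=None)

    def __post_init__(self):
        if self.genes_on_network is None:
            object.__setattr__(self, "genes_on_network", self.genes)
        if not self.genes_on_network <= self.genes:
            raise ValueError("genes_on_network must be a subset of genes")

    def __len__(self) -> int:
        return len(self.genes_on_network)


def top_fraction_genes(sig: ExpressionSignature, fraction: float = 0.05) -> frozenset[str]:
    """Union of the most up- and most down-regulated genes of a signature.

    Takes the ``floor(fraction * N)`` genes with the largest strictly
    positive values and the same number with the most negative values
    (N = signature size). Genes scoring exactly zero are never selected.
    Ties at a cutoff are resolved by lexicographic gene id so the result is
    deterministic. If one sign class has fewer genes than requested, all of
    that class are taken with a warning.
    """
    if not (0.0 < fraction < 0.5):
        raise ValueError("fraction must lie in (0, 0.5)")
    v = sig.values
    if (v == 0.0).all():
        raise ValueError(f"{sig.entity_id}: all-zero signature")
    k = int(np.floor(fraction * len(v)))
    if k == 0:
        return frozenset()
    # sort by (value, gene id): descending value for positives, ascending for negatives
    order = sorted(v.items(), key=lambda kv: (-kv[1], kv[0]))
    pos = [g for g, x in order if x > 0]
    order_neg = sorted(v.items(), key=lambda kv: (kv[1], kv[0]))
    neg = [g for g, x in order_neg if x < 0]
    if len(pos) < k or len(neg) < k:
        warnings.warn(
            f"{sig.entity_id}: only {len(pos)} positive / {len(neg)} negative genes "
            f"for a cutoff of {k} per sign; taking all available"
        )
    return frozenset(pos[:k]) | frozenset(neg[:k])


def build_module(genes: Iterable[str], net: MolecularNetwork, entity_id: str) -> GeneModule:
    """Map a gene set onto the network, recording both the raw set and the
    network-restricted subset. Errors if no gene lies on the network."""
    genes = frozenset(str(g) for g in genes)
    on_net = frozenset(g for g in genes if g in net)
    dropped = len(genes) - len(on_net)
    if not on_net:
        raise ValueError(f"{entity_id}: no module gene is present on the network")
    if dropped:
        logger.info("%s: dropped %d/%d genes absent from network", entity_id, dropped, len(genes))
    return GeneModule(entity_id=entity_id, genes=genes, genes_on_network=on_net)
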