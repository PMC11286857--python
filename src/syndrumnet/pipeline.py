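"""End-to-end orchestration: network -> modules -> similarity -> propagation
-> proximity/separation -> scoring -> evaluation.

Two modes are runnable on the same inputs:

* ``syndrum`` — no propagation: transcriptional correlations use the raw
  overlap between the disease module and each drug module (often below the
  minimum overlap, in which case C is 0 and flagged);
* ``syndrumnet`` — with propagation: disease and drug modules are expanded
  by PRINCE-style propagation (disease-similarity and chemical-similarity
  priors) before correlations are computed on the enlarged overlaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .modules import ExpressionSignature, GeneModule
from .network import MolecularNetwork, build_degree_bins
from .propagation import PropagationConfig, build_prior, expand_module, normalize_adjacency, propagate
from .proximity import pairwise_separation, proximity_z, scale_to_unit
from .scoring import auc, rank_pairs
from .similarity import (
    FingerprintVector,
    cosine_correlation,
    disease_similarity,
    fingerprint_similarity_matrix,
)
from .synthdata import SynthBenchmark

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_benchmark"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of one prediction run."""

    mode: str = "syndrumnet"  # "syndrum" | "syndrumnet"
    n_perm: int = 100
    min_bin_size: int = 100
    min_overlap: int = 3
    separation_sign: str = "positive"
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("syndrum", "syndrumnet"):
            raise ValueError("mode must be 'syndrum' or 'syndrumnet'")


@dataclass(frozen=True)
class PipelineResult:
    ranked: pd.DataFrame
    z: Mapping[str, float]
    p: Mapping[str, float]
    c: Mapping[str, float]
    auc: float | None


def run_pipeline(
    net: MolecularNetwork,
    disease_module: GeneModule,
    disease_signature: ExpressionSignature,
    drug_modules: Mapping[str, GeneModule],
    drug_signatures: Mapping[str, ExpressionSignature],
    cfg: PipelineConfig = PipelineConfig(),
    fingerprints: Mapping[str, FingerprintVector] | None = None,
    aux_disease_modules: Sequence[GeneModule] = (),
    synergy_labels: set[frozenset[str]] | None = None,
) -> PipelineResult:
    """Score and rank every unordered drug pair for one query disease.

    Proximity z-scores (degree-matched permutation null), unit-scaled
    proximities P, pairwise separations and transcriptional correlations C
    are combined into the T + P + C prediction score; when known-synergy
    labels are supplied the ranking's ROC AUC is reported as well.
    """
    drugs = sorted(drug_modules)
    if len(drugs) < 2:
        raise ValueError("need at least two drugs")
    bins = build_degree_bins(net, min_bin_size=cfg.min_bin_size)

    # --- proximity of each drug to the query disease -----------------------------
    z: dict[str, float] = {}
    for k, d in enumerate(drugs):
        res = proximity_z(
            net, disease_module, drug_modules[d], bins,
            n_perm=cfg.n_perm, rng_seed=_stream(cfg.rng_seed, 1, k),
        )
        z[d] = res.z
    p = scale_to_unit(z)

    # --- pairwise separation ------------------------------------------------------
    s = {pair: res.s for pair, res in pairwise_separation(net, drug_modules).items()}

    # --- transcriptional correlations ----------------------------------------------
    if cfg.mode == "syndrum":
        q_mod = disease_module
        expanded = dict(drug_modules)
    else:
        q_mod, expanded = _propagate_modules(
            net, disease_module, drug_modules, cfg, fingerprints, aux_disease_modules
        )
    c: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undefined-overlap warnings are per-pair noise
        for d in drugs:
            overlap = q_mod.genes_on_network & expanded[d].genes_on_network
            c[d] = cosine_correlation(
                disease_signature, drug_signatures[d], overlap, min_overlap=cfg.min_overlap
            )

    ranked = rank_pairs(drugs, z, p, c, s, separation_sign=cfg.separation_sign)
    auc_val = None
    if synergy_labels:
        scores = {
            frozenset({r.drug_a, r.drug_b}): r.score for r in ranked.itertuples()
        }
        auc_val = auc(scores, {frozenset(pair) for pair in synergy_labels})
    return PipelineResult(ranked=ranked, z=z, p=p, c=c, auc=auc_val)


def _propagate_modules(
    net: MolecularNetwork,
    disease_module: GeneModule,
    drug_modules: Mapping[str, GeneModule],
    cfg: PipelineConfig,
    fingerprints: Mapping[str, FingerprintVector] | None,
    aux_disease_modules: Sequence[GeneModule],
):
    """Expand the disease module (disease-similarity prior) and every drug
    module (chemical-similarity prior) by network propagation."""
    w = normalize_adjacency(net)
    bins = build_degree_bins(net, min_bin_size=cfg.min_bin_size)

    # disease prior from network-based similarity to auxiliary diseases
    similar_diseases: list[tuple[GeneModule, float]] = []
    if len(aux_disease_modules) >= 2:
        sims = disease_similarity(
            net, disease_module, list(aux_disease_modules), bins,
            n_perm=cfg.n_perm, rng_seed=_stream(cfg.rng_seed, 2, 0),
        )
        by_id = {m.entity_id: m for m in aux_disease_modules}
        similar_diseases = [(by_id[i], float(v)) for i, v in sims.items()]
    prior_q = build_prior(disease_module, similar_diseases, agg=cfg.propagation.prior_agg)
    scores_q = propagate(net, prior_q, cfg.propagation, norm_adj=w)
    q_expanded = expand_module(disease_module, scores_q, net, cfg.propagation)

    # drug priors from chemical fingerprint similarity
    sim_matrix = None
    if fingerprints:
        ordered = [fingerprints[d] for d in sorted(fingerprints)]
        sim_matrix = fingerprint_similarity_matrix(ordered)
    expanded: dict[str, GeneModule] = {}
    for d, module in drug_modules.items():
        similar_drugs: list[tuple[GeneModule, float]] = []
        if sim_matrix is not None and d in sim_matrix.values.index:
            for other, other_module in drug_modules.items():
                if other == d or other not in sim_matrix.values.index:
                    continue
                sim = sim_matrix.get(d, other)
                if sim > 0:
                    similar_drugs.append((other_module, min(sim, 1.0)))
        prior = build_prior(module, similar_drugs, agg=cfg.propagation.prior_agg)
        scores = propagate(net, prior, cfg.propagation, norm_adj=w)
        expanded[d] = expand_module(module, scores, net, cfg.propagation)
    return q_expanded, expanded


def run_benchmark(
    bench: SynthBenchmark, cfg: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Run the pipeline on a planted synthetic benchmark, evaluating the
    ranking against the planted synergy labels."""
    return run_pipeline(
        bench.net,
        bench.disease_module,
        bench.disease_signature,
        bench.drug_modules,
        bench.drug_signatures,
        cfg,
        fingerprints=bench.fingerprints,
        aux_disease_modules=bench.aux_disease_modules,
        synergy_labels=set(bench.synergy_labels),
    )


def _stream(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31)
    )
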