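"""Synthetic fixtures with planted synergy structure.

The generator emulates, at desk scale, the statistical structure the
prediction method exploits on real data:

* a connected preferential-attachment gene network with a heavy-tailed
  degree distribution standing in for the interactome;
* a disease module planted as a breadth-first neighbourhood of a seed
  node, so its genes are topologically localised;
* planted "synergistic" drug modules: mutually disjoint sub-neighbourhoods
  adjacent to the disease module (hence low proximity z to the disease and
  positive pairwise separation), arranged on a ring so that consecutive
  planted drugs form the labelled synergistic pairs; decoy drug modules
  are uniform random gene sets;
* dense expression signatures over the full gene universe, amplified on
  the owning module's genes (so the top-fraction rule approximately
  recovers a planted module); planted drug signatures mix the disease
  field at correlation rho, decoys are independent noise;
* chemical fingerprints in which partner drugs share feature blocks;
* Hill-curve dose-response plates whose combination wells sit on the Loewe
  additivity line (additive pairs) or beat the Bliss expectation by a
  factor 1 - epsilon (synergistic pairs).

All randomness flows from a single seed; each artifact draws from its own
counter-offset sub-stream, so any piece regenerates identically on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .modules import ExpressionSignature, GeneModule, build_module
from .network import MolecularNetwork
from .similarity import FingerprintVector
from .synergy import DoseResponseCurve, DoseResponsePlate

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SynthBenchmark", "generate_network", "plant_modules_and_signatures", "generate_plate", "generate_benchmark"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the planted benchmark.

    Defaults define the reference benchmark used throughout the test
    suite: a 2,000-gene network, an 80-gene disease module, 10 planted
    drugs (40 genes each) whose consecutive ring pairs are the 10 labelled
    synergistic combinations, 40 decoy drugs, and disease-drug signature
    correlation rho = 0.6.
    """

    n_genes: int = 2000
    attachment_m: int = 2
    disease_module_size: int = 80
    drug_module_size: int = 40
    n_planted_drugs: int = 10
    n_decoy_drugs: int = 40
    disease_overlap_fraction: float = 0.05  # of drug module taken from the disease module
    n_aux_diseases: int = 4
    aux_shared_fraction: float = 0.6
    rho: float = 0.6
    noise_sd: float = 1.0
    ec50_range: tuple[float, float] = (0.1, 10.0)
    hill_slope_range: tuple[float, float] = (1.0, 3.0)
    bliss_excess: float = 0.3
    plate_noise_sd: float = 0.03
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        for frac in (self.disease_overlap_fraction, self.aux_shared_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.disease_module_size >= self.n_genes / 4 or self.drug_module_size >= self.n_genes / 4:
            raise ValueError("module sizes must be < n_genes / 4")


@dataclass(frozen=True)
class SynthBenchmark:
    """Complete planted fixture: network, modules, signatures, fingerprints,
    known-synergy labels."""

    config: SynthConfig
    net: MolecularNetwork
    disease_module: GeneModule
    disease_signature: ExpressionSignature
    aux_disease_modules: tuple[GeneModule, ...]
    drug_modules: Mapping[str, GeneModule]
    drug_signatures: Mapping[str, ExpressionSignature]
    fingerprints: Mapping[str, FingerprintVector]
    synergy_labels: frozenset[frozenset[str]]
    planted_drugs: tuple[str, ...]
    decoy_drugs: tuple[str, ...]

    @property
    def drugs(self) -> tuple[str, ...]:
        return self.planted_drugs + self.decoy_drugs


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *key])


def generate_network(cfg: SynthConfig) -> MolecularNetwork:
    """Connected preferential-attachment graph with heavy-tailed degrees.

    Node labels are zero-padded gene identifiers ("g0000", ...); a fixed
    seed yields an identical edge list across runs.
    """
    rng = _sub_rng(cfg.rng_seed, 0)
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment_m, seed=int(rng.integers(2**31)))
    width = len(str(cfg.n_genes - 1))
    mapping = {i: f"g{i:0{width}d}" for i in g.nodes}
    return MolecularNetwork(nx.relabel_nodes(g, mapping))


def _bfs_order(graph: nx.Graph, start: str) -> list[str]:
    """Deterministic BFS visit order (neighbours explored in sorted order)."""
    seen = {start}
    order = [start]
    frontier = [start]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node)):
                if nb not in seen:
                    seen.add(nb)
                    order.append(nb)
                    nxt.append(nb)
        frontier = nxt
    return order


def _grow_module(graph: nx.Graph, anchor: str, size: int, blocked: set[str]) -> list[str]:
    """Collect the *size* non-blocked nodes nearest to *anchor* in BFS order.

    The search traverses blocked nodes without collecting them, so the
    module stays localised around the anchor even when its immediate
    neighbourhood is already claimed.
    """
    if anchor in blocked:
        raise ValueError("anchor is blocked")
    seen = {anchor}
    picked = [anchor]
    frontier = [anchor]
    while frontier and len(picked) < size:
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node)):
                if nb in seen:
                    continue
                seen.add(nb)
                nxt.append(nb)
                if nb not in blocked:
                    picked.append(nb)
                    if len(picked) >= size:
                        return picked
        frontier = nxt
    if len(picked) < size:
        raise ValueError(
            f"infeasible geometry: cannot grow a module of size {size} from {anchor}"
        )
    return picked


def plant_modules_and_signatures(net: MolecularNetwork, cfg: SynthConfig) -> SynthBenchmark:
    """Plant the disease module, drug modules, signatures, fingerprints and
    synergy labels on an existing network. See the module docstring for the
    construction."""
    graph = net.graph
    nodes = net.nodes

    # --- disease module: BFS neighbourhood of the highest-degree node -----------
    seed_node = max(nodes, key=lambda g: (net.degree(g), g))
    disease_genes = _bfs_order(graph, seed_node)[: cfg.disease_module_size]
    disease_set = set(disease_genes)
    disease_module = build_module(disease_genes, net, "disease_Q")

    # --- planted drug modules: disjoint shells around the disease module --------
    rng_mod = _sub_rng(cfg.rng_seed, 1)
    shell = sorted({nb for g in disease_genes for nb in graph.neighbors(g)} - disease_set)
    rng_mod.shuffle(shell)
    n_overlap = int(round(cfg.disease_overlap_fraction * cfg.drug_module_size))
    overlap_pool = list(disease_genes)
    rng_mod.shuffle(overlap_pool)
    if cfg.n_planted_drugs * n_overlap > len(overlap_pool):
        raise ValueError("infeasible geometry: overlap demand exceeds the disease module")

    planted: dict[str, GeneModule] = {}
    used: set[str] = set(disease_set)
    shell_iter = iter(shell)
    for i in range(cfg.n_planted_drugs):
        overlap_genes = [overlap_pool.pop() for _ in range(n_overlap)]
        anchor = next((a for a in shell_iter if a not in used), None)
        if anchor is None:
            raise ValueError("infeasible geometry: disease shell exhausted")
        grown = _grow_module(graph, anchor, cfg.drug_module_size - n_overlap, blocked=used)
        used.update(grown)
        name = f"planted_{i:02d}"
        planted[name] = build_module(set(grown) | set(overlap_genes), net, name)

    # --- decoy drug modules: uniform random gene sets ----------------------------
    decoys: dict[str, GeneModule] = {}
    for i in range(cfg.n_decoy_drugs):
        rng_d = _sub_rng(cfg.rng_seed, 2, i)
        genes = rng_d.choice(len(nodes), size=cfg.drug_module_size, replace=False)
        name = f"decoy_{i:02d}"
        decoys[name] = build_module({nodes[j] for j in genes}, net, name)

    # --- synergy labels: ring over the planted drugs ------------------------------
    planted_ids = tuple(sorted(planted))
    labels = frozenset(
        frozenset({planted_ids[i], planted_ids[(i + 1) % len(planted_ids)]})
        for i in range(len(planted_ids))
    )

    # --- signatures: dense latent fields, amplified on the entity's module --------
    # Every gene carries a differential-expression value (signatures from
    # expression assays are dense); a module's own genes are amplified so
    # the top-fraction rule approximately recovers the planted module.
    # Planted drug fields mix the disease field at correlation rho, so the
    # cosine on any sizeable shared gene set reflects rho; decoy fields are
    # independent noise.
    rng_sig = _sub_rng(cfg.rng_seed, 3)
    amp = 3.0
    disease_field = rng_sig.standard_normal(len(nodes))
    disease_values = pd.Series(disease_field, index=nodes)
    disease_values.loc[disease_genes] *= amp
    disease_signature = ExpressionSignature("disease_Q", disease_values, kind="disease")

    drug_modules = {**planted, **decoys}
    drug_signatures: dict[str, ExpressionSignature] = {}
    for k, (name, module) in enumerate(sorted(drug_modules.items())):
        rng_s = _sub_rng(cfg.rng_seed, 4, k)
        noise = cfg.noise_sd * rng_s.standard_normal(len(nodes))
        if name in planted:
            field = cfg.rho * disease_field + np.sqrt(max(0.0, 1.0 - cfg.rho**2)) * noise
        else:
            field = noise
        values = pd.Series(field, index=nodes)
        values.loc[sorted(module.genes_on_network)] *= amp
        drug_signatures[name] = ExpressionSignature(name, values, kind="drug")

    # --- fingerprints: partner drugs share pair-specific feature blocks -----------
    fingerprints: dict[str, FingerprintVector] = {}
    rng_fp = _sub_rng(cfg.rng_seed, 5)
    block = 20
    pair_features = {
        i: {f"pair{i:02d}_{j:02d}": float(rng_fp.integers(1, 5)) for j in range(block)}
        for i in range(len(planted_ids))
    }
    for idx, name in enumerate(planted_ids):
        counts = {f"priv_{name}_{j:02d}": float(rng_fp.integers(1, 5)) for j in range(block)}
        counts.update(pair_features[idx])  # pair (idx, idx+1)
        counts.update(pair_features[(idx - 1) % len(planted_ids)])  # pair (idx-1, idx)
        fingerprints[name] = FingerprintVector(name, counts)
    for name in sorted(decoys):
        counts = {f"priv_{name}_{j:02d}": float(rng_fp.integers(1, 5)) for j in range(2 * block)}
        fingerprints[name] = FingerprintVector(name, counts)

    # --- auxiliary diseases for the similarity prior -------------------------------
    aux: list[GeneModule] = []
    for i in range(cfg.n_aux_diseases):
        rng_a = _sub_rng(cfg.rng_seed, 6, i)
        size = cfg.disease_module_size
        if i < cfg.n_aux_diseases // 2:
            # near-duplicate: shares a fraction of the query module
            n_shared = int(round(cfg.aux_shared_fraction * size))
            shared = list(rng_a.choice(disease_genes, size=n_shared, replace=False))
            rest_pool = [g for g in nodes if g not in disease_set]
            rest = list(rng_a.choice(rest_pool, size=size - n_shared, replace=False))
            genes = shared + rest
        else:
            genes = [nodes[j] for j in rng_a.choice(len(nodes), size=size, replace=False)]
        aux.append(build_module(genes, net, f"aux_disease_{i:02d}"))

    return SynthBenchmark(
        config=cfg,
        net=net,
        disease_module=disease_module,
        disease_signature=disease_signature,
        aux_disease_modules=tuple(aux),
        drug_modules=drug_modules,
        drug_signatures=drug_signatures,
        fingerprints=fingerprints,
        synergy_labels=labels,
        planted_drugs=planted_ids,
        decoy_drugs=tuple(sorted(decoys)),
    )


def generate_benchmark(cfg: SynthConfig | None = None, **overrides) -> SynthBenchmark:
    """Network plus planted structure in one call."""
    if cfg is None:
        cfg = SynthConfig(**overrides)
    elif overrides:
        cfg = SynthConfig(**{**asdict(cfg), **overrides})
    net = generate_network(cfg)
    return plant_modules_and_signatures(net, cfg)


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

def _hill_survival(conc: np.ndarray | float, ec50: float, slope: float) -> np.ndarray | float:
    return 1.0 / (1.0 + (np.asarray(conc, float) / ec50) ** slope)


def _loewe_additive_survival(c_a, ec_a, h_a, c_b, ec_b, h_b) -> float:
    """Survival of a combination lying exactly on the Loewe additivity line."""

    def toxic_unit(u: float) -> float:
        ecu_a = ec_a * (u / (1.0 - u)) ** (1.0 / h_a)
        ecu_b = ec_b * (u / (1.0 - u)) ** (1.0 / h_b)
        return c_a / ecu_a + c_b / ecu_b - 1.0

    u = brentq(toxic_unit, 1e-9, 1.0 - 1e-9)
    return 1.0 - u


def generate_plate(
    cfg: SynthConfig,
    pair_is_synergistic: bool,
    rng_seed: int | None = None,
    drug_a: str = "drugA",
    drug_b: str = "drugB",
) -> DoseResponsePlate:
    """Hill-curve plate for one drug pair.

    Single-drug wells follow Hill survival curves (EC50 log-uniform in
    ``ec50_range``, slope uniform in ``hill_slope_range``) over a 7-point
    twofold dilution series centred on each EC50, with Gaussian measurement
    noise. Combination wells pair matched dilution steps; an additive pair
    sits on the Loewe additivity line (the concentration-addition null),
    while a synergistic pair's survival is the Bliss prediction times
    (1 - ``bliss_excess``), i.e. it beats independent action by a planted
    margin. A fixed seed reproduces the plate bit for bit.
    """
    rng = _sub_rng(cfg.rng_seed if rng_seed is None else rng_seed, 7)
    lo, hi = cfg.ec50_range
    ec = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=2)
    slopes = rng.uniform(*cfg.hill_slope_range, size=2)
    curves = {}
    for name, e, h in zip((drug_a, drug_b), ec, slopes):
        conc = e * 2.0 ** np.arange(-3, 4)
        surv = _hill_survival(conc, e, h)
        surv = np.clip(surv + rng.normal(0.0, cfg.plate_noise_sd, size=conc.size), 0.0, 1.4)
        curves[name] = DoseResponseCurve(
            drug_id=name,
            concentrations=tuple(conc),
            survival=tuple(surv),
            n_replicates=3,
        )
    combos = []
    for k in (-1, 0, 1):
        c_a = float(ec[0] * 2.0**k)
        c_b = float(ec[1] * 2.0**k)
        if pair_is_synergistic:
            bliss = _hill_survival(c_a, ec[0], slopes[0]) * _hill_survival(c_b, ec[1], slopes[1])
            surv = float(bliss) * (1.0 - cfg.bliss_excess)
        else:
            surv = _loewe_additive_survival(c_a, ec[0], slopes[0], c_b, ec[1], slopes[1])
        surv = float(np.clip(surv + rng.normal(0.0, cfg.plate_noise_sd), 0.0, 1.4))
        combos.append((drug_a, c_a, drug_b, c_b, surv))
    return DoseResponsePlate(curves=curves, combinations=tuple(combos))
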