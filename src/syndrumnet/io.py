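"""Plain-text readers and writers: GMT gene sets, signature/fingerprint/plate
TSVs, and the bundled published validation table. Everything is TSV or GMT
for auditability; no binary intermediates."""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .modules import ExpressionSignature
from .similarity import FingerprintVector
from .synergy import DoseResponseCurve, DoseResponsePlate

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_signature",
    "write_signature",
    "read_fingerprints",
    "write_fingerprints",
    "read_plate",
    "write_plate",
    "load_cml_validation",
]


def read_gmt(path) -> dict[str, frozenset[str]]:
    """GMT: one gene set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(set(map(str, sets[name]))))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gene_list(path) -> frozenset[str]:
    """One gene per line; blank lines and ``#`` comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return frozenset(genes)


def read_signature(path, entity_id: str | None = None, kind: str = "drug") -> ExpressionSignature:
    """Signature TSV with columns ``gene`` and ``value`` (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, value)")
    first_val = df.iloc[0, 1]
    try:
        float(first_val)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    values = pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str).to_numpy()
    )
    eid = entity_id or Path(path).stem
    return ExpressionSignature(entity_id=eid, values=values, kind=kind)


def write_signature(sig: ExpressionSignature, path) -> None:
    df = pd.DataFrame({"gene": sig.values.index, "value": sig.values.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_fingerprints(path) -> list[FingerprintVector]:
    """Fingerprint TSV with columns ``drug``, ``feature``, ``count``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"drug", "feature", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    fps = []
    for drug, grp in df.groupby("drug", sort=True):
        counts = dict(zip(grp["feature"].astype(str), grp["count"].astype(float)))
        fps.append(FingerprintVector(drug_id=str(drug), counts=counts))
    return fps


def write_fingerprints(fps: Sequence[FingerprintVector], path) -> None:
    rows = [
        {"drug": fp.drug_id, "feature": f, "count": c}
        for fp in fps
        for f, c in sorted(fp.counts.items())
    ]
    pd.DataFrame(rows, columns=["drug", "feature", "count"]).to_csv(path, sep="\t", index=False)


def read_plate(single_path, combo_path) -> DoseResponsePlate:
    """Dose-response plate from two TSVs.

    ``single_path``: columns ``drug``, ``concentration``, ``survival``
    (replicate rows allowed; survival as a percentage). ``combo_path``:
    columns ``drug_a``, ``conc_a``, ``drug_b``, ``conc_b``, ``survival``.
    """
    single = pd.read_csv(single_path, sep="\t", comment="#")
    curves = {}
    for drug, grp in single.groupby("drug", sort=True):
        agg = grp.groupby("concentration")["survival"].agg(["mean", "std", "count"]).sort_index()
        curves[str(drug)] = DoseResponseCurve(
            drug_id=str(drug),
            concentrations=tuple(agg.index.astype(float)),
            survival=tuple(agg["mean"].to_numpy() / 100.0),
            sd=tuple(np.nan_to_num(agg["std"].to_numpy()) / 100.0),
            n_replicates=int(agg["count"].max()),
        )
    combos = pd.read_csv(combo_path, sep="\t", comment="#")
    combinations = tuple(
        (str(r.drug_a), float(r.conc_a), str(r.drug_b), float(r.conc_b), float(r.survival) / 100.0)
        for r in combos.itertuples()
    )
    return DoseResponsePlate(curves=curves, combinations=combinations)


def write_plate(plate: DoseResponsePlate, single_path, combo_path) -> None:
    rows = [
        {"drug": c.drug_id, "concentration": conc, "survival": 100.0 * s}
        for c in plate.curves.values()
        for conc, s in zip(c.concentrations, c.survival)
    ]
    pd.DataFrame(rows).to_csv(single_path, sep="\t", index=False)
    combo_rows = [
        {"drug_a": a, "conc_a": ca, "drug_b": b, "conc_b": cb, "survival": 100.0 * s}
        for a, ca, b, cb, s in plate.combinations
    ]
    pd.DataFrame(combo_rows, columns=["drug_a", "conc_a", "drug_b", "conc_b", "survival"]).to_csv(
        combo_path, sep="\t", index=False
    )


def load_cml_validation() -> pd.DataFrame:
    """Bundled table of the top-20 predicted CML drug pairs with their
    published network statistics and K562 in-vitro validation results
    (WST-8 assay survival ratios, CA and IA synergy scores; missing values
    mark pairs excluded from the wet-lab panel)."""
    ref = importlib.resources.files("syndrumnet.data").joinpath("cml_k562_validation.tsv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")
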