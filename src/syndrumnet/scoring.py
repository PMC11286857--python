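"""SyndrumNET prediction score: topology + proximity + transcriptional correlation.

For a query disease Q and an unordered drug pair (A, B) the score is
T + P + C where

* T in {0, 2} rewards the Complementary Exposure topology (class II): both
  drug modules overlap the disease neighbourhood (z_QA < 0 and z_QB < 0)
  while being mutually separated on the network;
* P = (P_QA + P_QB)/2 averages the unit-scaled proximities;
* C = (|C_QA| + |C_QB|)/2 averages absolute transcriptional correlations.

Ranked pair tables are evaluated against known-synergy labels by ROC AUC
(Mann-Whitney form; ties count one half).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureClass",
    "PairScore",
    "classify_exposure",
    "t_score",
    "p_score",
    "c_score",
    "prediction_score",
    "rank_pairs",
    "auc",
]


class ExposureClass(Enum):
    """Topological classes of a (disease, drug A, drug B) triple, determined
    by the signs of (z_QA < 0, z_QB < 0, separated). The drug pair is
    unordered, so "exactly one z negative" is a single configuration."""

    I = "overlapping exposure"        # both z < 0, modules overlapping
    II = "complementary exposure"     # both z < 0, modules separated
    III = "single exposure, separated"
    IV = "single exposure, overlapping"
    V = "non-exposure, separated"
    VI = "non-exposure, overlapping"


@dataclass(frozen=True)
class PairScore:
    drug_a: str
    drug_b: str
    exposure_class: ExposureClass
    t: float
    p: float
    c: float

    @property
    def total(self) -> float:
        return self.t + self.p + self.c


def classify_exposure(
    z_qa: float, z_qb: float, s_ab: float, separation_sign: str = "positive"
) -> ExposureClass:
    """Assign the topological class of a disease/drug-pair triple.

    ``separation_sign`` states which sign of s_AB counts as "separated
    drug modules" for class II; the default ``"positive"`` follows the
    separation measure's construction (positive s = distinct
    neighbourhoods). ``"negative"`` inverts the convention.
    """
    if not all(map(math.isfinite, (z_qa, z_qb, s_ab))):
        raise ValueError("classification requires finite z_QA, z_QB, s_AB")
    if separation_sign not in ("positive", "negative"):
        raise ValueError("separation_sign must be 'positive' or 'negative'")
    separated = bool(s_ab > 0) if separation_sign == "positive" else bool(s_ab < 0)
    n_close = int(z_qa < 0) + int(z_qb < 0)  # int(): numpy bools do not add
    if n_close == 2:
        return ExposureClass.II if separated else ExposureClass.I
    if n_close == 1:
        return ExposureClass.III if separated else ExposureClass.IV
    return ExposureClass.V if separated else ExposureClass.VI


def t_score(cls: ExposureClass) -> float:
    """Network-based localisation score: 2 for Complementary Exposure
    (class II), 0 for every other class."""
    return 2.0 if cls is ExposureClass.II else 0.0


def p_score(p_qa: float, p_qb: float) -> float:
    """Mean unit-scaled proximity of the two drugs to the query disease."""
    for v in (p_qa, p_qb):
        if not (0.0 <= v <= 1.0):
            raise ValueError("scaled proximities must lie in [0, 1]")
    return (p_qa + p_qb) / 2.0


def c_score(c_qa: float, c_qb: float) -> float:
    """Mean absolute transcriptional correlation; NaN inputs (undefined
    correlations) contribute 0."""
    vals = []
    for v in (c_qa, c_qb):
        if math.isnan(v):
            vals.append(0.0)
            continue
        if not (-1.0 <= v <= 1.0):
            raise ValueError("correlations must lie in [-1, 1]")
        vals.append(abs(v))
    return sum(vals) / 2.0


def prediction_score(t: float, p: float, c: float) -> float:
    """Total prediction score T + P + C (range [0, 4])."""
    return t + p + c


def rank_pairs(
    drugs: Iterable[str],
    z: Mapping[str, float],
    p: Mapping[str, float],
    c: Mapping[str, float],
    s: Mapping[tuple[str, str], float],
    separation_sign: str = "positive",
) -> pd.DataFrame:
    """Score and rank all unordered drug pairs for one query disease.

    ``z``, ``p``, ``c`` map each drug to its proximity z-score, scaled
    proximity and transcriptional correlation (NaN allowed for undefined
    C); ``s`` maps unordered pairs (either key order accepted) to their
    separation. Rows are sorted by descending total score, ties broken by
    (drug A, drug B) lexicographic order, so the table is independent of
    input ordering.
    """
    drugs = sorted(set(drugs))
    if len(drugs) < 2:
        raise ValueError("need at least two drugs")
    rows = []
    for a, b in itertools.combinations(drugs, 2):
        s_ab = s.get((a, b), s.get((b, a)))
        if s_ab is None:
            raise KeyError(f"missing separation for pair ({a}, {b})")
        cls = classify_exposure(z[a], z[b], s_ab, separation_sign=separation_sign)
        t_val = t_score(cls)
        p_val = p_score(p[a], p[b])
        c_val = c_score(c.get(a, float("nan")), c.get(b, float("nan")))
        rows.append(
            {
                "drug_a": a,
                "drug_b": b,
                "z_qa": z[a],
                "z_qb": z[b],
                "s_ab": s_ab,
                "p_qa": p[a],
                "p_qb": p[b],
                "c_qa": c.get(a, float("nan")),
                "c_qb": c.get(b, float("nan")),
                "exposure_class": cls.name,
                "T": t_val,
                "P": p_val,
                "C": c_val,
                "score": prediction_score(t_val, p_val, c_val),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["score", "drug_a", "drug_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def auc(scores: Mapping, positives: Iterable) -> float:
    """ROC AUC of a score table against a positive set.

    Computed in the Mann-Whitney form: the probability that a uniformly
    random positive outscores a uniformly random negative, ties counting
    one half. ``scores`` maps items (e.g. frozenset drug pairs) to real
    scores; ``positives`` is the subset of items with known synergy.
    """
    positives = set(positives)
    items = list(scores)
    labels = np.array([it in positives for it in items])
    n_pos = int(labels.sum())
    n_neg = len(items) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    vals = np.array([float(scores[it]) for it in items])
    ranks = rankdata(vals)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[labels].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
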