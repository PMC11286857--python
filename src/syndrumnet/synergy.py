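"""Experimental synergy statistics: Bliss independent action and Loewe
concentration addition from cell-survival dose-response data.

Effects are fractions of growth inhibition, e = 1 - survival. Under Bliss
independence two non-interacting drugs with single-agent effects v and w
combine to CI_mix = 1 - (1 - v)(1 - w); an observed combined effect above
CI_mix indicates synergy. Under Loewe additivity the toxic unit
TU = C_a / EC_u^A + C_b / EC_u^B equals 1 for a purely additive pair at the
combination's observed effect level u; TU < 1 indicates synergy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseCurve",
    "DoseResponsePlate",
    "SynergyScores",
    "bliss_ci",
    "ec_u",
    "effect_at",
    "loewe_tu",
    "score_plate",
    "classify_and_summarize",
    "summarize_printed_scores",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Single-drug concentration-survival measurements.

    Concentrations must be positive and strictly increasing; survival
    fractions lie in [0, 1.5] (values above 1 indicate stimulation and are
    flagged with a warning).
    """

    drug_id: str
    concentrations: tuple[float, ...]
    survival: tuple[float, ...]  # mean survival fraction per concentration
    sd: tuple[float, ...] | None = None
    n_replicates: int = 1

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if c.size != s.size or c.size < 2:
            raise ValueError(f"{self.drug_id}: need >= 2 matched (conc, survival) points")
        if (c <= 0).any() or (np.diff(c) <= 0).any():
            raise ValueError(f"{self.drug_id}: concentrations must be positive, strictly increasing")
        if (s < 0).any() or (s > 1.5).any():
            raise ValueError(f"{self.drug_id}: survival fractions outside [0, 1.5]")
        if (s > 1.0).any():
            warnings.warn(f"{self.drug_id}: survival > 100% (stimulation) observed")

    def effects(self) -> np.ndarray:
        """Inhibition effects 1 - survival; stimulation clamps to effect 0."""
        return np.clip(1.0 - np.asarray(self.survival, float), 0.0, 1.0)


@dataclass(frozen=True)
class DoseResponsePlate:
    """Single-drug curves plus combination wells from one assay."""

    curves: dict[str, DoseResponseCurve]
    combinations: tuple[tuple[str, float, str, float, float], ...]
    # (drug_a, conc_a, drug_b, conc_b, combined mean survival fraction)


@dataclass(frozen=True)
class SynergyScores:
    """Per-combination synergy statistics under both reference models."""

    drug_a: str
    drug_b: str
    ca: float          # Loewe toxic unit (NaN when u is outside a curve's range)
    ia_ci: float       # Bliss-expected combined effect CI_mix
    observed_effect: float
    excess_over_bliss: float

    @property
    def ca_synergistic(self) -> bool:
        return bool(self.ca < 1.0)

    @property
    def ia_synergistic(self) -> bool:
        return bool(self.excess_over_bliss > 0.0)


def bliss_ci(v: float, w: float) -> float:
    """Bliss-expected combined effect 1 - (1 - v)(1 - w) for single-agent
    effect fractions v, w in [0, 1]. Symmetric, monotone, bounded in [0, 1]."""
    for e in (v, w):
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"effect fraction {e} outside [0, 1]")
    return 1.0 - (1.0 - v) * (1.0 - w)


def _isotonic_effects(curve: DoseResponseCurve) -> np.ndarray:
    """Effects made non-decreasing in concentration (pool-adjacent-violators),
    warning when cleanup changes anything."""
    e = curve.effects().copy()
    if (np.diff(e) >= 0).all():
        return e
    warnings.warn(f"{curve.drug_id}: non-monotone dose-response; isotonic cleanup applied")
    # pool adjacent violators with equal weights
    vals = list(e)
    weights = [1.0] * len(vals)
    blocks = []
    for v, w in zip(vals, weights):
        blocks.append([v, w])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            v2, w2 = blocks.pop()
            v1, w1 = blocks.pop()
            blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    out = []
    for v, w in blocks:
        out.extend([v] * int(round(w)))
    return np.array(out)


def ec_u(curve: DoseResponseCurve, u: float) -> float:
    """Concentration producing effect fraction *u*, interpolated log-linearly
    between bracketing measured points.

    *u* must lie within the observed effect range (no extrapolation); a
    measured effect returns its measured concentration (smallest, if the
    cleaned curve is flat there).
    """
    e = _isotonic_effects(curve)
    c = np.asarray(curve.concentrations, float)
    if not (e.min() <= u <= e.max()):
        raise ValueError(
            f"{curve.drug_id}: effect {u:.3f} outside observed range "
            f"[{e.min():.3f}, {e.max():.3f}]"
        )
    log_c = np.log10(c)
    # leftmost bracketing: first index with effect >= u
    hi = int(np.searchsorted(e, u, side="left"))
    if e[hi] == u:
        return float(c[hi])
    lo = hi - 1
    frac = (u - e[lo]) / (e[hi] - e[lo])
    return float(10 ** (log_c[lo] + frac * (log_c[hi] - log_c[lo])))


def effect_at(curve: DoseResponseCurve, conc: float) -> float:
    """Effect fraction at *conc*, log-linearly interpolated on the cleaned
    curve (inverse of :func:`ec_u` at measured points)."""
    e = _isotonic_effects(curve)
    c = np.asarray(curve.concentrations, float)
    if not (c.min() <= conc <= c.max()):
        raise ValueError(f"{curve.drug_id}: concentration {conc} outside measured range")
    return float(np.interp(np.log10(conc), np.log10(c), e))


def loewe_tu(c_a: float, c_b: float, ec_u_a: float, ec_u_b: float) -> float:
    """Toxic unit C_a/EC_u^A + C_b/EC_u^B. Linear in each concentration."""
    if ec_u_a <= 0 or ec_u_b <= 0:
        raise ValueError("EC values must be positive")
    if c_a < 0 or c_b < 0:
        raise ValueError("concentrations must be non-negative")
    return c_a / ec_u_a + c_b / ec_u_b


def score_plate(plate: DoseResponsePlate) -> list[SynergyScores]:
    """Bliss and Loewe statistics for every combination well of a plate.

    For each well: single-agent effects v, w are interpolated from the
    drugs' curves at the well's concentrations; CI_mix = bliss_ci(v, w);
    the observed combined effect u sets the Loewe reference level, and
    TU = C_a/EC_u^A + C_b/EC_u^B. When u falls outside a drug's observed
    effect range the toxic unit is undefined (NaN, flagged).
    """
    out = []
    for drug_a, c_a, drug_b, c_b, surv in plate.combinations:
        curve_a, curve_b = plate.curves[drug_a], plate.curves[drug_b]
        v = effect_at(curve_a, c_a)
        w = effect_at(curve_b, c_b)
        ci = bliss_ci(v, w)
        observed = float(np.clip(1.0 - surv, 0.0, 1.0))
        try:
            tu = loewe_tu(c_a, c_b, ec_u(curve_a, observed), ec_u(curve_b, observed))
        except ValueError:
            warnings.warn(
                f"({drug_a}, {drug_b}): combined effect {observed:.3f} outside a "
                "single-drug curve range; CA score undefined"
            )
            tu = float("nan")
        out.append(
            SynergyScores(
                drug_a=drug_a,
                drug_b=drug_b,
                ca=tu,
                ia_ci=ci,
                observed_effect=observed,
                excess_over_bliss=observed - ci,
            )
        )
    return out


def classify_and_summarize(scores: Sequence[SynergyScores]) -> dict[str, float]:
    """Fraction of combinations called synergistic under each model.

    CA call: TU < 1 (strict; TU exactly 1 is additive). IA call: observed
    combined effect exceeds the Bliss expectation. Fractions are reported
    as percentages rounded to one decimal. Combinations with an undefined
    CA score are excluded from the CA denominator.
    """
    if not scores:
        raise ValueError("no synergy scores to summarise")
    ca_defined = [s for s in scores if not np.isnan(s.ca)]
    ca_frac = (
        100.0 * sum(s.ca_synergistic for s in ca_defined) / len(ca_defined)
        if ca_defined
        else float("nan")
    )
    ia_frac = 100.0 * sum(s.ia_synergistic for s in scores) / len(scores)
    return {
        "n": len(scores),
        "ca_synergy_percent": round(ca_frac, 1),
        "ia_synergy_percent": round(ia_frac, 1),
    }


def summarize_printed_scores(
    ca_scores: Sequence[float], ia_scores: Sequence[float]
) -> dict[str, float]:
    """Synergy fractions from already-tabulated CA/IA score columns.

    Applies the tabulated decision rules directly: CA (toxic unit) < 1 and
    IA score >= 1. NaN entries (combinations not assayed) are dropped.
    """
    ca = np.asarray([c for c in ca_scores if not np.isnan(c)], float)
    ia = np.asarray([i for i in ia_scores if not np.isnan(i)], float)
    if ca.size == 0 or ia.size == 0:
        raise ValueError("no scores supplied")
    return {
        "n_ca": int(ca.size),
        "n_ia": int(ia.size),
        "ca_synergy_percent": round(100.0 * float((ca < 1.0).mean()), 1),
        "ia_synergy_percent": round(100.0 * float((ia >= 1.0).mean()), 1),
    }
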