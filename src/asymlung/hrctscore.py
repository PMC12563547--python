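"""Extent-weighted HRCT lung injury score (modified Ichikado system).

Readers report, per lung region, the percentage of the region occupied by each
radiological pattern grade. The late-fibrotic honeycombing grade is excluded
and the two traction-bronchiectasis grades are merged into a single
``bronchodilatation`` grade, leaving four ordinal grades with default weights
normal=1, ground-glass=2, consolidation=3, bronchodilatation=4.

A region scores ``Σ weight(grade) × extent_percent(grade)`` (100 = fully
normal, 400 = fully bronchodilatated under the defaults); a lung side scores
the arithmetic mean of its regions. Recruitability of a side is indexed by the
expiratory-hold minus inspiratory-hold score difference: a positive delta means
the side looks more injured at expiration than inspiration, i.e. it is
recruitable by inspiratory pressure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WEIGHTS",
    "GRADES",
    "RegionPattern",
    "HRCTSideScore",
    "region_score",
    "side_score",
    "recruitability",
    "score_table",
    "recruitability_table",
]

GRADES = ("normal", "ground_glass", "consolidation", "bronchodilatation")
DEFAULT_WEIGHTS: dict[str, float] = {
    "normal": 1, "ground_glass": 2, "consolidation": 3, "bronchodilatation": 4,
}
EXTENT_SUM_TOL = 0.5  # percent

EXTENT_COLUMNS = {
    "normal_pct": "normal",
    "ggo_pct": "ground_glass",
    "consolidation_pct": "consolidation",
    "bronchodil_pct": "bronchodilatation",
}


@dataclass(frozen=True)
class RegionPattern:
    animal_id: str
    lung_side: str          # "left" | "right"
    hold: str               # "expiratory" | "inspiratory"
    region_id: str
    extents: Mapping[str, float]  # grade -> percent of region area


@dataclass(frozen=True)
class HRCTSideScore:
    animal_id: str
    lung_side: str
    hold: str
    score: float
    n_regions: int


def region_score(extents: Mapping[str, float],
                 weights: Mapping[str, float] | None = None,
                 tol: float = EXTENT_SUM_TOL) -> float:
    """Extent-weighted score of one region.

    >>> region_score({"normal": 40, "consolidation": 60})
    220.0
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    unknown = set(extents) - set(weights)
    if unknown:
        raise ValueError(f"unknown pattern grade(s): {sorted(unknown)}")
    vals = np.asarray(list(extents.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError("extents must be non-negative")
    total = vals.sum()
    if abs(total - 100.0) > tol:
        raise ValueError(f"extents sum to {total}, expected 100 ± {tol}")
    return float(sum(weights[g] * p for g, p in extents.items()))


def side_score(regions: Sequence[RegionPattern],
               weights: Mapping[str, float] | None = None) -> HRCTSideScore:
    """Mean region score for one animal/side/hold."""
    if len(regions) == 0:
        raise ValueError("at least one region is required")
    keys = {(r.animal_id, r.lung_side, r.hold) for r in regions}
    if len(keys) != 1:
        raise ValueError(f"regions mix animal/side/hold keys: {sorted(keys)}")
    animal_id, lung_side, hold = next(iter(keys))
    scores = [region_score(r.extents, weights) for r in regions]
    return HRCTSideScore(animal_id, lung_side, hold,
                         float(np.mean(scores)), len(regions))


def recruitability(exp_score: HRCTSideScore, insp_score: HRCTSideScore) -> float:
    """Expiratory minus inspiratory hold score (positive = recruitable)."""
    if (exp_score.animal_id, exp_score.lung_side) != (
            insp_score.animal_id, insp_score.lung_side):
        raise ValueError("scores belong to different animal/side")
    if exp_score.hold != "expiratory" or insp_score.hold != "inspiratory":
        raise ValueError("expected one expiratory and one inspiratory score")
    return exp_score.score - insp_score.score


def score_table(df: pd.DataFrame,
                weights: Mapping[str, float] | None = None,
                tol: float = EXTENT_SUM_TOL) -> pd.DataFrame:
    """Per animal/side/hold scores from a long per-region extent table.

    Expects columns ``animal_id, lung_side, hold, region_id`` plus the extent
    percentage columns ``normal_pct, ggo_pct, consolidation_pct,
    bronchodil_pct``.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    missing = [c for c in EXTENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing extent columns: {missing}")
    ext = df[list(EXTENT_COLUMNS)].to_numpy(dtype=float)
    if (ext < 0).any():
        raise ValueError("extents must be non-negative")
    sums = ext.sum(axis=1)
    bad = np.abs(sums - 100.0) > tol
    if bad.any():
        raise ValueError(
            f"{bad.sum()} region(s) have extents not summing to 100 ± {tol}")
    w = np.array([weights[EXTENT_COLUMNS[c]] for c in EXTENT_COLUMNS])
    work = df[["animal_id", "lung_side", "hold"]].copy()
    work["region_score"] = ext @ w
    g = work.groupby(["animal_id", "lung_side", "hold"], sort=True)["region_score"]
    out = g.mean().rename("score").reset_index()
    out["n_regions"] = g.count().values
    return out


def recruitability_table(side_scores: pd.DataFrame) -> pd.DataFrame:
    """Expiratory − inspiratory score per animal/side from a side-score table."""
    wide = side_scores.pivot_table(index=["animal_id", "lung_side"],
                                   columns="hold", values="score")
    if not {"expiratory", "inspiratory"}.issubset(wide.columns):
        raise ValueError("need both expiratory and inspiratory hold scores")
    wide = wide.dropna(subset=["expiratory", "inspiratory"])
    out = wide.reset_index()
    out["recruitability"] = out["expiratory"] - out["inspiratory"]
    return out[["animal_id", "lung_side", "expiratory", "inspiratory",
                "recruitability"]]
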