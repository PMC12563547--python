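"""Semi-quantitative histological lung injury scoring (LIS).

Per high-power field, a pathologist records neutrophil counts in the alveolar
and interstitial space and the degree of alveolar septal thickening. Counts are
binned to category points (none → 0, 1–5 → 1, >5 → 2; thickening <2× → 0,
2–4× → 1, >4× → 2) and combined with fixed weights.

Two score variants are provided:

* modified LIS (early exudative injury; hyaline membranes and proteinaceous
  debris omitted): per-field weighted sum ``20·A + 14·B + 2·C``. The default
  ``per_field_100`` denominator keeps the original 100-point per-field
  normalization, giving the documented range 0 (minimal) to 0.72 (severe).
  A literal ``per_field_72`` mode (maximum 1.0) is selectable.
* original five-component score: ``20·A + 14·B + 7·C_hyaline + 7·D_debris +
  2·E_septal`` over n_fields × 100, range 0–1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FieldObservation",
    "LISResult",
    "categorize_field",
    "modified_lis",
    "ats_lis",
    "score_fields_table",
    "side_comparison",
]

logger = logging.getLogger(__name__)

MODIFIED_WEIGHTS = (20, 14, 2)          # alveolar, interstitial, septal
ATS_WEIGHTS = (20, 14, 7, 7, 2)         # alveolar, interstitial, hyaline, debris, septal
DEFAULT_N_FIELDS = 20                   # fields read per sample by convention

_POINTS = (0, 1, 2)


@dataclass(frozen=True)
class FieldObservation:
    """Category points for one high-power field.

    ``a``: alveolar-space neutrophils, ``b``: interstitial neutrophils,
    ``c``: septal thickening; optional ``hyaline`` / ``debris`` points are
    required only for the original five-component score.
    """

    a: int
    b: int
    c: int
    hyaline: int | None = None
    debris: int | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) not in _POINTS:
                raise ValueError(f"{name} points must be one of {_POINTS}")
        for name in ("hyaline", "debris"):
            v = getattr(self, name)
            if v is not None and v not in _POINTS:
                raise ValueError(f"{name} points must be one of {_POINTS}")


@dataclass(frozen=True)
class LISResult:
    score: float
    n_fields: int
    variant: str                 # "modified" | "ats_original"
    denominator_mode: str        # "per_field_100" | "per_field_72"


def _bin_count(count: int) -> int:
    if count < 0 or count != int(count):
        raise ValueError(f"count must be a non-negative integer, got {count}")
    if count == 0:
        return 0
    return 1 if count <= 5 else 2


def _bin_fold(fold: float) -> int:
    # 2x and 4x thickening read as inclusive bin ends: [0,2) -> 0, [2,4] -> 1, (4,inf) -> 2
    if fold < 0 or not np.isfinite(fold):
        raise ValueError(f"thickening fold must be finite and >= 0, got {fold}")
    if fold < 2:
        return 0
    return 1 if fold <= 4 else 2


def categorize_field(alveolar_neutrophils: int, interstitial_neutrophils: int,
                     septal_thickening_fold: float) -> FieldObservation:
    """Bin raw per-field observations to category points.

    >>> categorize_field(7, 5, 3.0)
    FieldObservation(a=2, b=1, c=1, hyaline=None, debris=None)
    """
    return FieldObservation(
        a=_bin_count(alveolar_neutrophils),
        b=_bin_count(interstitial_neutrophils),
        c=_bin_fold(septal_thickening_fold),
    )


def modified_lis(fields: list[FieldObservation] | list[tuple[int, int, int]],
                 denominator_mode: str = "per_field_100") -> LISResult:
    """Three-component lung injury score over a set of fields.

    ``per_field_100`` (default) divides the per-field sum 20a+14b+2c by 100 per
    field, giving the documented 0–0.72 range; ``per_field_72`` divides by 72.
    """
    if len(fields) == 0:
        raise ValueError("at least one field is required")
    if denominator_mode == "per_field_100":
        denom = 100
    elif denominator_mode == "per_field_72":
        denom = 72
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    total = 0.0
    for f in fields:
        if not isinstance(f, FieldObservation):
            f = FieldObservation(*f)
        total += (MODIFIED_WEIGHTS[0] * f.a + MODIFIED_WEIGHTS[1] * f.b
                  + MODIFIED_WEIGHTS[2] * f.c)
    return LISResult(score=total / (len(fields) * denom),
                     n_fields=len(fields), variant="modified",
                     denominator_mode=denominator_mode)


def ats_lis(fields: list[FieldObservation]) -> LISResult:
    """Original five-component score (range 0–1); requires hyaline and debris
    points on every field."""
    if len(fields) == 0:
        raise ValueError("at least one field is required")
    total = 0.0
    for f in fields:
        if not isinstance(f, FieldObservation):
            f = FieldObservation(*f)
        if f.hyaline is None or f.debris is None:
            raise ValueError(
                "hyaline and debris points are required for the original score")
        total += (ATS_WEIGHTS[0] * f.a + ATS_WEIGHTS[1] * f.b
                  + ATS_WEIGHTS[2] * f.hyaline + ATS_WEIGHTS[3] * f.debris
                  + ATS_WEIGHTS[4] * f.c)
    return LISResult(score=total / (len(fields) * 100),
                     n_fields=len(fields), variant="ats_original",
                     denominator_mode="per_field_100")


def score_fields_table(df: pd.DataFrame,
                       denominator_mode: str = "per_field_100") -> pd.DataFrame:
    """Per animal-side-sample modified LIS from a long per-field table.

    Accepts either raw columns (``alveolar_neutrophils``,
    ``interstitial_neutrophils``, ``septal_thickening_fold``) or pre-binned
    ``a, b, c`` points, keyed by ``animal_id, lung_side, sample_id``.
    """
    keys = ["animal_id", "lung_side", "sample_id"]
    missing = [c for c in keys if c not in df.columns]
    if missing:
        raise ValueError(f"missing key columns: {missing}")
    work = df.copy()
    if not {"a", "b", "c"}.issubset(work.columns):
        work["a"] = work["alveolar_neutrophils"].map(_bin_count)
        work["b"] = work["interstitial_neutrophils"].map(_bin_count)
        work["c"] = work["septal_thickening_fold"].map(_bin_fold)
    denom = 100 if denominator_mode == "per_field_100" else 72
    work["_pts"] = (MODIFIED_WEIGHTS[0] * work["a"]
                    + MODIFIED_WEIGHTS[1] * work["b"]
                    + MODIFIED_WEIGHTS[2] * work["c"])
    g = work.groupby(keys, sort=True)["_pts"]
    out = (g.sum() / (g.count() * denom)).rename("lis").reset_index()
    out["n_fields"] = g.count().values
    return out


def side_comparison(per_sample: pd.DataFrame,
                    value_col: str = "lis") -> pd.DataFrame:
    """Paired left-vs-right table, one row per animal.

    Samples within one animal-side are averaged first (the three-samples-per
    -site convention), then sides are paired. Animals missing one side are
    excluded with a logged warning.
    """
    if not {"animal_id", "lung_side", value_col}.issubset(per_sample.columns):
        raise ValueError("need animal_id, lung_side and value columns")
    per_side = (per_sample.groupby(["animal_id", "lung_side"], sort=True)[value_col]
                .mean().unstack("lung_side"))
    incomplete = per_side.index[per_side.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("excluding unpaired animals: %s", list(incomplete))
        warnings.warn(f"excluding unpaired animals: {list(incomplete)}",
                      stacklevel=2)
        per_side = per_side.dropna()
    out = per_side.rename(columns={"left": "left", "right": "right"}).reset_index()
    out["diff"] = out["left"] - out["right"]
    return out
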