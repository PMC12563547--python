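"""Derived respiratory mechanics and transpulmonary-pressure-guided PEEP titration.

Static hold-maneuver readings (airway and esophageal pressures) are turned into
the derived quantities used to compare ventilation strategies:

* driving pressure            ``ΔP    = P_plat − PEEP``
* end-expiratory TPP          ``TPP_exp  = PEEP − P_ES,exp``
* end-inspiratory TPP         ``TPP_insp = P_plat − P_ES,insp``
* transpulmonary driving p.   ``ΔP_L  = TPP_insp − TPP_exp``
* mechanical power            ``MP = 0.098 · RR · V_T · (P_peak − 0.5·(P_plat − PEEP))``
* quasi-static compliance     ``C_RS ≈ V_T / ΔP``

All pressures are in cmH₂O, tidal volume enters in mL and is converted to litres
only inside the mechanical-power formula (0.098 J per L·cmH₂O). The
device-reported compliance, when present, is carried through untouched and never
conflated with the quasi-static V_T/ΔP estimate.

The titration rule models hourly PEEP adjustment toward a slightly positive
end-expiratory transpulmonary pressure: if the current TPP_exp lies outside the
target band, PEEP is set directly to the esophageal pressure plus the band
midpoint, rounded to the ventilator step and clamped to the allowed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "VentilatorReading",
    "DerivedMechanics",
    "TitrationPolicy",
    "TitrationStep",
    "derive_mechanics",
    "derive_table",
    "titrate_peep",
    "run_titration_series",
]

#: mechanical-power conversion factor, J per (L · cmH₂O) per breath
_MP_FACTOR = 0.098

DERIVED_COLUMNS = [
    "delta_p",
    "tpp_exp",
    "tpp_insp",
    "delta_p_l",
    "mech_power_j_min",
    "crs_quasistatic",
]


class ValidationError(ValueError):
    """Raised when an input violates a physical/physiological invariant."""


@dataclass(frozen=True)
class VentilatorReading:
    """One static hold-maneuver measurement set for one animal and timepoint.

    Pressures in cmH₂O, tidal volume in mL, respiratory rate in breaths/min,
    FiO₂ as a fraction. ``crs_reported`` and ``resistance_reported`` are
    device-calculated values carried as pass-through inputs.
    """

    animal_id: str
    timepoint: str
    p_peak: float
    p_plat: float
    peep: float
    p_es_insp: float
    p_es_exp: float
    tidal_volume: float
    resp_rate: float
    fio2: float = 0.5
    crs_reported: float | None = None
    resistance_reported: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite([self.p_peak, self.p_plat, self.peep,
                            self.p_es_insp, self.p_es_exp,
                            self.tidal_volume, self.resp_rate]).all():
            raise ValidationError("non-finite pressure/volume/rate value")
        if self.peep < 0:
            raise ValidationError(f"peep must be >= 0, got {self.peep}")
        if self.p_plat < self.peep:
            raise ValidationError(
                f"p_plat ({self.p_plat}) must be >= peep ({self.peep})")
        if self.p_peak < self.p_plat:
            raise ValidationError(
                f"p_peak ({self.p_peak}) must be >= p_plat ({self.p_plat})")
        if self.tidal_volume <= 0:
            raise ValidationError(
                f"tidal_volume must be > 0, got {self.tidal_volume}")
        if self.resp_rate <= 0:
            raise ValidationError(f"resp_rate must be > 0, got {self.resp_rate}")
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValidationError(f"fio2 must be in [0.21, 1.0], got {self.fio2}")


@dataclass(frozen=True)
class DerivedMechanics:
    """All derived quantities for one reading. ``crs_quasistatic`` is None
    (undefined) when the driving pressure is zero."""

    delta_p: float
    tpp_exp: float
    tpp_insp: float
    delta_p_l: float
    mech_power: float
    crs_quasistatic: float | None


def derive_mechanics(reading: VentilatorReading) -> DerivedMechanics:
    """Compute every derived mechanics quantity from one hold-maneuver reading.

    >>> r = VentilatorReading("p1", "t6", p_peak=30.3, p_plat=17.5, peep=5.0,
    ...                       p_es_insp=13.3, p_es_exp=7.6,
    ...                       tidal_volume=310, resp_rate=25.3)
    >>> round(derive_mechanics(r).tpp_exp, 1)
    -2.6
    """
    delta_p = reading.p_plat - reading.peep
    tpp_exp = reading.peep - reading.p_es_exp
    tpp_insp = reading.p_plat - reading.p_es_insp
    delta_p_l = tpp_insp - tpp_exp
    vt_l = reading.tidal_volume / 1000.0
    mech_power = _MP_FACTOR * reading.resp_rate * vt_l * (
        reading.p_peak - 0.5 * (reading.p_plat - reading.peep))
    crs = reading.tidal_volume / delta_p if delta_p > 0 else None
    return DerivedMechanics(delta_p, tpp_exp, tpp_insp, delta_p_l,
                            mech_power, crs)


def derive_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived-mechanics columns to a tidy per-animal/timepoint table.

    Expects columns ``p_peak, p_plat, peep, p_es_insp, p_es_exp,
    tidal_volume_ml, resp_rate`` (extra columns are passed through).
    """
    required = ["p_peak", "p_plat", "peep", "p_es_insp", "p_es_exp",
                "tidal_volume_ml", "resp_rate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    out = df.copy()
    out["delta_p"] = out["p_plat"] - out["peep"]
    out["tpp_exp"] = out["peep"] - out["p_es_exp"]
    out["tpp_insp"] = out["p_plat"] - out["p_es_insp"]
    out["delta_p_l"] = out["tpp_insp"] - out["tpp_exp"]
    out["mech_power_j_min"] = (_MP_FACTOR * out["resp_rate"]
                               * out["tidal_volume_ml"] / 1000.0
                               * (out["p_peak"] - 0.5 * out["delta_p"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        crs = out["tidal_volume_ml"] / out["delta_p"]
    out["crs_quasistatic"] = crs.where(out["delta_p"] > 0, np.nan)
    return out


@dataclass(frozen=True)
class TitrationPolicy:
    """Target band and ventilator constraints for TPP_exp-guided titration."""

    target_low: float = 0.0
    target_high: float = 3.0
    peep_min: float = 4.0
    peep_max: float = 24.0
    rounding_step: float = 1.0

    def __post_init__(self) -> None:
        if not self.target_low < self.target_high:
            raise ValidationError("target_low must be < target_high")
        if not self.peep_min < self.peep_max:
            raise ValidationError("peep_min must be < peep_max")
        if self.rounding_step <= 0:
            raise ValidationError("rounding_step must be > 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.target_low + self.target_high)


def _round_step(x: float, step: float) -> float:
    # round to nearest multiple of step, ties away from zero
    q = x / step
    r = math.floor(q + 0.5) if q >= 0 else math.ceil(q - 0.5)
    return r * step


def titrate_peep(current_peep: float, p_es_exp: float,
                 policy: TitrationPolicy = TitrationPolicy()) -> float:
    """One hourly titration decision.

    Leaves PEEP unchanged when the observed TPP_exp already sits inside the
    target band; otherwise sets it to ``p_es_exp + band midpoint``, rounded to
    the ventilator step (ties away from zero) and clamped to the allowed range.
    """
    if not policy.peep_min <= current_peep <= policy.peep_max:
        raise ValidationError(
            f"current_peep {current_peep} outside [{policy.peep_min}, {policy.peep_max}]")
    tpp_exp = current_peep - p_es_exp
    if policy.target_low <= tpp_exp <= policy.target_high:
        return current_peep
    target = p_es_exp + policy.midpoint
    target = _round_step(target, policy.rounding_step)
    return min(max(target, policy.peep_min), policy.peep_max)


@dataclass(frozen=True)
class TitrationStep:
    step: int
    peep: float
    p_es_exp: float
    tpp_exp: float


def run_titration_series(
    initial_peep: float,
    esophageal_response: Callable[[float], float],
    n_steps: int,
    policy: TitrationPolicy = TitrationPolicy(),
) -> list[TitrationStep]:
    """Apply the hourly titration rule repeatedly against a chest-wall response.

    ``esophageal_response`` maps the currently applied PEEP to the expiratory
    esophageal pressure it produces (the response contract). Each trace entry
    records the PEEP applied at that step and the TPP_exp observed under it;
    the next step's PEEP is the titration decision. Deterministic given inputs.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    peep = float(initial_peep)
    trace: list[TitrationStep] = []
    for k in range(n_steps):
        p_es = float(esophageal_response(peep))
        if not np.isfinite(p_es):
            raise ValidationError(f"non-finite esophageal response at step {k}")
        trace.append(TitrationStep(k, peep, p_es, peep - p_es))
        peep = titrate_peep(peep, p_es, policy)
    return trace
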