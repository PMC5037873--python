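"""Steady-state masses and derived kinetic parameters.

Given fitted fractional transfer coefficients and the plasma retinol pool
M(5) (mean plasma [12C]retinol concentration x plasma volume), the tracee
steady state of the plasma/stores exchange yields the storage pool M(6),
the disposal rate DR (irreversible vitamin A loss, umol/d) and fractional
catabolic rates.  Residence times come from the negative inverse of the
exchange-compartment matrix

    A = [[-L65,  L56        ],
         [ L65, -(L56+L106)]]

whose first column of -A^(-1) gives T(5,5) and T(6,5), the mean total time
a tracer molecule spends in plasma and in stores after entering plasma.
Recycling metrics and the time to plasma (TTP50%) follow the standard
definitions: v(5) = T(5,5)/t1/2(5) - 1 recycles, tt(5) = T(6,5)/v(5), and
TTP50% is the time at which half of the absorbed dose has made its first
arrival in the plasma compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    ArmSolution,
    RetinolArmParams,
    SubjectParams,
    ValidationError,
)

__all__ = [
    "KineticSummary",
    "steady_state",
    "half_life",
    "residence_times",
    "recycling",
    "ttp50",
    "days_of_stores",
    "summarize_subject",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class KineticSummary:
    """Per-subject kinetic report.  Units noted per field."""

    M5: float              # umol, plasma retinol pool
    M6: float              # umol, extravascular stores (traced mass)
    DR: float              # umol/d, disposal rate
    FCR65: float           # 1/d, fraction of stores lost irreversibly per day
    FCR55: float           # 1/d, disposal rate relative to the plasma pool
    thalf5: float          # hours, plasma retinol half-life
    thalf6: float          # days, stores half-life
    T55: float             # days, plasma residence time
    T65: float             # days, stores residence time
    TSYS: float            # days, T55 + T65
    v5: float              # dimensionless recycling number
    tt5: float             # days, recycling time
    TTP50: float           # hours, time for 50% of absorbed dose to reach plasma
    days_of_stores: float  # days, M6 / DR
    dietary_input_U1: float  # umol/d, DR/0.75 (steady-state extrapolation)


def steady_state(arm: RetinolArmParams, M5: float):
    """Tracee steady state of the plasma/stores exchange.

    Returns (M6, DR, FCR65, FCR55).  Flux balance on the stores compartment
    gives M6 = L65*M5/(L56+L106); DR = L106*M6.
    """
    if not (M5 > 0):
        raise ValidationError("M5 must be positive")
    if arm.L106 <= 0:
        raise ValidationError("L106 must be positive for a finite steady state")
    M6 = arm.L65 * M5 / (arm.L56 + arm.L106)
    DR = arm.L106 * M6
    return M6, DR, DR / M6, DR / M5


def half_life(rates_out) -> float:
    """ln 2 / sum of exit rates (days), for the rates leaving one compartment."""
    total = float(np.sum(np.asarray(rates_out, dtype=float)))
    if total <= 0:
        raise ValidationError("sum of exit rates must be positive")
    return math.log(2.0) / total


def residence_times(arm: RetinolArmParams):
    """(T55, T65, TSYS) in days from the negative exchange-matrix inverse."""
    if arm.L106 <= 0:
        raise ValidationError("L106 must be positive (finite residence times)")
    A = np.array([[-arm.L65, arm.L56],
                  [arm.L65, -(arm.L56 + arm.L106)]])
    T = -np.linalg.inv(A)
    T55, T65 = T[0, 0], T[1, 0]
    return float(T55), float(T65), float(T55 + T65)


def recycling(T55: float, T65: float, thalf5_days: float):
    """Recycling number v(5) and recycling time tt(5) (days).

    ``thalf5_days`` is the plasma half-life in DAYS.
    """
    if thalf5_days <= 0:
        raise ValidationError("plasma half-life must be positive")
    v5 = T55 / thalf5_days - 1.0
    if v5 <= 0:
        raise ValidationError("no recycling (T55 <= t1/2); tt(5) undefined")
    return v5, T65 / v5


def ttp50(params: SubjectParams, arm: str = "C10") -> float:
    """Time (hours) for 50% of the absorbed tracer to first reach plasma."""
    return ArmSolution(params, arm).ttp50() * HOURS_PER_DAY


def days_of_stores(M6: float, DR: float) -> float:
    """Model-predicted days of vitamin A stores: M6 / DR."""
    if not (DR > 0):
        raise ValidationError("disposal rate must be positive")
    if M6 < 0:
        raise ValidationError("M6 must be >= 0")
    return M6 / DR


def summarize_subject(params: SubjectParams, M5: float) -> KineticSummary:
    """Full kinetic report for one subject from fitted parameters and M(5)."""
    r = params.retinol_arm
    M6, DR, FCR65, FCR55 = steady_state(r, M5)
    th5_d = half_life([r.L65])
    th6_d = half_life([r.L56, r.L106])
    T55, T65, TSYS = residence_times(r)
    v5, tt5 = recycling(T55, T65, th5_d)
    return KineticSummary(
        M5=M5, M6=M6, DR=DR, FCR65=FCR65, FCR55=FCR55,
        thalf5=th5_d * HOURS_PER_DAY, thalf6=th6_d,
        T55=T55, T65=T65, TSYS=TSYS, v5=v5, tt5=tt5,
        TTP50=ttp50(params),
        days_of_stores=days_of_stores(M6, DR),
        dietary_input_U1=DR / 0.75,
    )
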