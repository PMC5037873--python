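"""Preprocessing and quality screening of plasma tracer curves.

Converts raw plasma tracer concentrations to fraction-of-dose (FD) curves
and screens subjects with six exclusion rules mirroring the published
cohort's criteria: missing critical samples, negative FD after background
subtraction, a positive terminal slope, converging or diverging isotope
curves, and an abnormally high [13C10]retinol peak.

FD(t) = (concentration(t) - background) x plasma volume / dose, where
plasma volume (L) = 0.0435 L/kg x body weight (kg).  Negative FD values are
preserved (not clamped) so that screening can see them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import TracerCurve, ValidationError

__all__ = [
    "SubjectRecord",
    "QCConfig",
    "QCVerdict",
    "REASON_CODES",
    "plasma_volume",
    "fd_from_concentration",
    "rae_dose",
    "isomer_amounts_from_mass",
    "screen_subject",
    "PLASMA_VOLUME_PER_KG",
    "BETA_CAROTENE_MW",
    "RETINOL_MW",
]

PLASMA_VOLUME_PER_KG = 0.0435  # L plasma per kg body weight
BETA_CAROTENE_MW = 546.8       # g/mol, also alpha-carotene (isomer)
RETINOL_MW = 286.5             # g/mol

REASON_CODES = (
    "MISSING_CRITICAL",
    "NEGATIVE_FD",
    "POSITIVE_TERMINAL_SLOPE",
    "CURVES_CONVERGE",
    "CURVES_DIVERGE",
    "ABNORMAL_PEAK",
)


@dataclass(frozen=True)
class SubjectRecord:
    """Identity and dosing anchor data for one subject."""

    subject_id: str
    body_weight: float            # kg
    mean_plasma_retinol: float    # umol/L, mean [12C]retinol over the study
    dose_retinol: float           # umol [13C10]retinyl acetate
    dose_bc_alltrans: float       # umol all-trans beta-carotene
    dose_bc_cis: float            # umol cis beta-carotene
    dose_bc_alpha: float          # umol alpha-carotene

    def __post_init__(self):
        if not (self.body_weight > 0):
            raise ValidationError("body_weight must be positive")
        if not (self.mean_plasma_retinol > 0):
            raise ValidationError("mean_plasma_retinol must be positive")
        for f in ("dose_retinol", "dose_bc_alltrans", "dose_bc_cis", "dose_bc_alpha"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")

    @property
    def plasma_volume(self) -> float:
        return plasma_volume(self.body_weight)

    @property
    def dose_carotene_rae(self) -> float:
        """Carotene dose in umol retinol activity equivalents."""
        return rae_dose(self.dose_bc_alltrans, self.dose_bc_cis, self.dose_bc_alpha)

    @property
    def plasma_pool(self) -> float:
        """Plasma retinol pool M(5), umol."""
        return self.mean_plasma_retinol * self.plasma_volume


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for subject screening.

    ``slope_floor`` is an absolute lower bound (1/d) a slope must also clear
    to count as significant: with a 3-point terminal window the OLS slope SE
    has a single degree of freedom and is too noisy to act as the only gate.
    """

    critical_times: tuple = (0.25, 0.5, 2.0, 14.0)  # 6 h, 12 h, 2 d, 14 d
    terminal_window: tuple = (2.0, 14.0)            # [lo, hi] days, inclusive
    slope_nse: float = 2.0                          # SE multiples
    slope_floor: float = 0.05                       # 1/d
    peak_bound: float = 0.30                        # max plausible peak FD (C10)
    negative_tol: float = 1e-6                      # FD below -tol flags
    time_match_tol: float = 1e-6                    # d, schedule matching


@dataclass(frozen=True)
class QCVerdict:
    subject_id: str
    included: bool
    reason_codes: tuple = ()

    def __post_init__(self):
        if self.included != (len(self.reason_codes) == 0):
            raise ValidationError("included must equal 'no reason codes'")
        for rc in self.reason_codes:
            if rc not in REASON_CODES:
                raise ValidationError(f"unknown reason code {rc!r}")


def plasma_volume(body_weight: float) -> float:
    """Estimated plasma volume (L) from body weight (kg)."""
    if not (body_weight > 0) or not math.isfinite(body_weight):
        raise ValidationError("body_weight must be a positive finite number")
    return PLASMA_VOLUME_PER_KG * body_weight


def fd_from_concentration(times, conc, pv: float, dose: float,
                          background=0.0, label: str = "C10") -> TracerCurve:
    """Fraction-of-dose curve from plasma tracer concentrations.

    Parameters
    ----------
    times : array, days
    conc : array, umol/L plasma tracer concentration
    pv : plasma volume, L
    dose : administered tracer dose, umol
    background : scalar or array, umol/L analytical background subtracted
        from every sample.  Negative FD values are preserved for QC.
    """
    if not (dose > 0):
        raise ValidationError("dose must be positive")
    if not (pv > 0):
        raise ValidationError("plasma volume must be positive")
    conc = np.asarray(conc, dtype=float)
    fd = (conc - np.asarray(background, dtype=float)) * pv / dose
    return TracerCurve(label, np.asarray(times, dtype=float), fd)


def rae_dose(dose_bc_alltrans: float, dose_bc_cis: float,
             dose_bc_alpha: float) -> float:
    """Retinol-activity-equivalent content of a carotenoid dose (umol RAE).

    All-trans beta-carotene can yield at most 2 retinol molecules; cis-beta-
    carotene and alpha-carotene yield at most 1.
    """
    for v in (dose_bc_alltrans, dose_bc_cis, dose_bc_alpha):
        if v < 0:
            raise ValidationError("isomer doses must be >= 0")
    return 2.0 * dose_bc_alltrans + dose_bc_cis + dose_bc_alpha


def isomer_amounts_from_mass(mass_mg: float, frac_alltrans: float,
                             frac_cis: float, frac_alpha: float,
                             mw: float = BETA_CAROTENE_MW) -> tuple:
    """Molar isomer amounts (umol) of a carotene dose given its mass (mg)
    and isomeric composition (mass fractions)."""
    if mass_mg < 0:
        raise ValidationError("mass must be >= 0")
    total = frac_alltrans + frac_cis + frac_alpha
    if total > 1.0 + 1e-9 or min(frac_alltrans, frac_cis, frac_alpha) < 0:
        raise ValidationError("isomer fractions must be >= 0 and sum to <= 1")
    umol_per_mg = 1000.0 / mw
    return (mass_mg * frac_alltrans * umol_per_mg,
            mass_mg * frac_cis * umol_per_mg,
            mass_mg * frac_alpha * umol_per_mg)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _window_points(curve: TracerCurve, lo: float, hi: float):
    mask = (curve.times >= lo - 1e-9) & (curve.times <= hi + 1e-9)
    return curve.times[mask], curve.fd[mask]


def _log_slope(t, y):
    """OLS slope and its SE of log(y) vs t; requires all y > 0."""
    ly = np.log(y)
    n = t.size
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    slope = np.sum((t - tbar) * (ly - ly.mean())) / sxx
    resid = ly - (ly.mean() + slope * (t - tbar))
    dof = n - 2
    se = math.sqrt(np.sum(resid**2) / dof / sxx) if dof > 0 else 0.0
    return slope, se


def _significant(slope: float, se: float, cfg: QCConfig) -> bool:
    return abs(slope) > max(cfg.slope_nse * se, cfg.slope_floor)


def screen_subject(curve_c10: TracerCurve, curve_c5: TracerCurve,
                   config: QCConfig | None = None,
                   subject_id: str = "") -> QCVerdict:
    """Apply the six exclusion rules, in order, stopping at the first hit.

    Order: missing critical time points; negative FD; positive terminal
    slope (either curve); converging / diverging curves (slope of
    log(fd_C5/fd_C10) over the terminal window: positive = curves approach
    on the semilog plot = converge, negative = diverge); abnormally high
    [13C10]retinol peak.
    """
    cfg = config or QCConfig()

    def verdict(*codes):
        return QCVerdict(subject_id, not codes, tuple(codes))

    # 1 - critical time points present in both curves
    for tc in cfg.critical_times:
        for curve in (curve_c10, curve_c5):
            if not np.any(np.isclose(curve.times, tc, atol=cfg.time_match_tol)):
                return verdict("MISSING_CRITICAL")

    lo, hi = cfg.terminal_window
    t10, y10 = _window_points(curve_c10, lo, hi)
    t5, y5 = _window_points(curve_c5, lo, hi)
    if t10.size < 2 or t5.size < 2 or not np.array_equal(t10, t5):
        return verdict("MISSING_CRITICAL")

    # 2 - negative FD after background subtraction (from first critical time)
    t_first = min(cfg.critical_times)
    for curve in (curve_c10, curve_c5):
        mask = curve.times >= t_first - 1e-9
        if np.any(curve.fd[mask] < -cfg.negative_tol):
            return verdict("NEGATIVE_FD")

    # 3 - positive terminal slope on either curve
    if np.any(y10 <= 0) or np.any(y5 <= 0):
        return verdict("NEGATIVE_FD")
    for t, y in ((t10, y10), (t5, y5)):
        slope, se = _log_slope(t, y)
        if slope > 0 and _significant(slope, se, cfg):
            return verdict("POSITIVE_TERMINAL_SLOPE")

    # 4/5 - converging or diverging isotope curves
    slope, se = _log_slope(t10, y5 / y10)
    if _significant(slope, se, cfg):
        return verdict("CURVES_CONVERGE" if slope > 0 else "CURVES_DIVERGE")

    # 6 - abnormally high C10 peak
    if np.max(curve_c10.fd) > cfg.peak_bound:
        return verdict("ABNORMAL_PEAK")

    return verdict()
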