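"""Dual-arm linear compartmental model of whole-body retinol kinetics.

The model describes plasma appearance of labeled retinol after a single oral
bolus of either [13C10]retinyl acetate (the "retinol arm") or [13C10]beta-
carotene (the "carotene arm", observed as [13C5]retinol).  Each arm is a
chain:

    gut (1/11) -> enterocyte (2/12) -> transport delay (3/13)
      -> liver (4/14) -> plasma (5/15) <-> stores (6/16) -> irreversible loss

with a direct enterocyte-to-plasma shunt (portal/chylomicron-surface uptake)
and first-order fractional transfer coefficients L(I,J) in units of 1/day.
The delay element is a pure transport delay: its output is its input shifted
by the delay time DT.  Both arms share the plasma/stores exchange
coefficients L(6,5), L(5,6) and the irreversible-loss coefficient L(10,6).

Retinol absorption efficiency is fixed at 75%, i.e. the unabsorbed loss from
the gut is L(0,1) = L(2,1)/3.  In the carotene arm the unconverted fraction
is governed by a dimensionless proportionality constant P(11) through
L(0,11) = P(11) x L(12,11), so the fraction of the carotene dose that is
absorbed and converted to retinol is 1/(1 + P(11)).

All simulated quantities are fractions of the oral dose (FD, dimensionless)
and all times are in days.  Because the system is linear and the delayed
signal is the output of an autonomous upstream block, the solution is
computed exactly: the state at any time is assembled from two augmented
matrix exponentials (one for the direct enterocyte-to-plasma route, one for
the delayed route, evaluated at t - DT), so accuracy is limited only by
floating point, with no step-size control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

__all__ = [
    "RetinolArmParams",
    "CaroteneArmParams",
    "SubjectParams",
    "TracerCurve",
    "ArmSolution",
    "COHORT_MEANS",
    "COHORT_SDS",
    "mean_params",
    "simulate_fd",
    "cumulative_plasma_arrival",
    "mass_balance",
    "RETINOL_ABSORBED_FRACTION",
    "ValidationError",
]

#: fraction of the retinol dose absorbed; L(0,1) = L(2,1)/3 makes this exact
RETINOL_ABSORBED_FRACTION = 0.75

#: published cohort means of the model parameters (n = 30 healthy young adults)
COHORT_MEANS = {
    "L21": 24.2, "L52": 0.114, "DT3": 0.113, "L54": 2.98,
    "L65": 5.50, "L56": 0.169, "L106": 0.0599,
    "L1512": 0.110, "DT13": 0.152, "L1514": 1.43, "P11": 10.9,
}

#: published cohort SDs, same source as :data:`COHORT_MEANS`
COHORT_SDS = {
    "L21": 39.0, "L52": 0.191, "DT3": 0.0442, "L54": 5.18,
    "L65": 2.11, "L56": 0.108, "L106": 0.0231,
    "L1512": 0.205, "DT13": 0.0327, "L1514": 0.872, "P11": 5.54,
}


class ValidationError(ValueError):
    """Raised when model inputs violate their physical constraints."""


def _check_nonneg(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite, got {v!r}")
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class RetinolArmParams:
    """Free coefficients of the retinyl-acetate arm (per day; DT3 in days).

    Derived, constrained coefficients: L01 = L21/3 (unabsorbed loss, fixing
    absorption at 75%) and L32 = L21.
    """

    L21: float
    L52: float
    DT3: float
    L54: float
    L65: float   # plasma -> stores
    L56: float   # stores -> plasma
    L106: float  # irreversible loss from stores

    def __post_init__(self):
        _check_nonneg(self, ("L21", "L52", "DT3", "L54", "L65", "L56", "L106"))

    @property
    def L01(self) -> float:
        return self.L21 / 3.0

    @property
    def L32(self) -> float:
        return self.L21

    @property
    def absorbed_fraction(self) -> float:
        return RETINOL_ABSORBED_FRACTION


@dataclass(frozen=True)
class CaroteneArmParams:
    """Free coefficients of the beta-carotene arm.

    ``P11`` is the dimensionless non-conversion constant: L011 = P11 x L1211.
    The gut/enterocyte forward coefficients are shared with the retinol arm
    (L1211 = L1312 = L21), as are the plasma/stores exchange coefficients;
    explicit shared values may be supplied for cross-validation and are
    checked against the retinol arm on :class:`SubjectParams` construction.
    """

    P11: float
    L1512: float
    DT13: float
    L1514: float
    # optional explicit copies of the shared coefficients (None = mirrored)
    L1615: float | None = None
    L1516: float | None = None
    L2016: float | None = None

    def __post_init__(self):
        _check_nonneg(self, ("P11", "L1512", "DT13", "L1514"))

    @property
    def converted_fraction(self) -> float:
        """Fraction of the carotene dose absorbed and converted to retinol."""
        return 1.0 / (1.0 + self.P11)


@dataclass(frozen=True)
class SubjectParams:
    """Both arms of one subject's model, with shared-coefficient checks."""

    retinol_arm: RetinolArmParams
    carotene_arm: CaroteneArmParams

    def __post_init__(self):
        r, c = self.retinol_arm, self.carotene_arm
        for explicit, shared, names in (
            (c.L1615, r.L65, "L1615/L65"),
            (c.L1516, r.L56, "L1516/L56"),
            (c.L2016, r.L106, "L2016/L106"),
        ):
            if explicit is not None and not math.isclose(
                explicit, shared, rel_tol=1e-9, abs_tol=1e-12
            ):
                raise ValidationError(
                    f"shared coefficients mismatch between arms: {names} "
                    f"({explicit!r} != {shared!r})"
                )


@dataclass(frozen=True)
class TracerCurve:
    """Time-ordered fraction-of-dose observations or predictions.

    Observed curves may be slightly negative before QC (background
    subtraction); model predictions are nonnegative.
    """

    label: str  # "C10" or "C5"
    times: np.ndarray  # days, strictly increasing, >= 0
    fd: np.ndarray     # dimensionless fraction of dose

    def __post_init__(self):
        if self.label not in ("C10", "C5"):
            raise ValidationError(f"label must be 'C10' or 'C5', got {self.label!r}")
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.fd, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValidationError("times and fd must be 1-D arrays of equal length")
        if t.size and t[0] < 0:
            raise ValidationError("times must be nonnegative")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fd", y)

    def at(self, t: float, atol: float = 1e-9) -> float:
        """FD value at time ``t`` (must be a sampled time point)."""
        idx = np.nonzero(np.isclose(self.times, t, atol=atol))[0]
        if idx.size == 0:
            raise ValidationError(f"time {t} d is not a sampled time point")
        return float(self.fd[idx[0]])


# ---------------------------------------------------------------------------
# internal arm description: both arms map onto one generic chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ArmChain:
    gut_fwd: float    # gut -> enterocyte (L21 = L1211)
    gut_loss: float   # unabsorbed loss  (L01 or L011)
    direct: float     # enterocyte -> plasma shunt (L52 or L1512)
    DT: float         # transport delay (d)
    hep: float        # liver -> plasma (L54 or L1514)
    L65: float
    L56: float
    L106: float

    @property
    def absorbed_fraction(self) -> float:
        tot = self.gut_fwd + self.gut_loss
        if tot == 0.0:
            raise ValidationError("gut outflow is zero; no dose ever absorbed")
        return self.gut_fwd / tot


def _arm_chain(params: SubjectParams, arm: str) -> _ArmChain:
    r = params.retinol_arm
    if arm == "C10":
        return _ArmChain(r.L21, r.L01, r.L52, r.DT3, r.L54, r.L65, r.L56, r.L106)
    if arm == "C5":
        c = params.carotene_arm
        return _ArmChain(
            r.L21, c.P11 * r.L21, c.L1512, c.DT13, c.L1514, r.L65, r.L56, r.L106
        )
    raise ValidationError(f"arm must be 'C10' or 'C5', got {arm!r}")


def _phi(x):
    """(1 - exp(-x)) / x, stable near 0; x >= 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    out = -np.expm1(-xs) / xs
    return np.where(small, 1.0 - x / 2.0 + x * x / 6.0, out)


class ArmSolution:
    """Exact solution of one arm for a unit oral bolus at t = 0.

    The gut/enterocyte pair has the closed form

        q_gut(t) = exp(-a t),                      a = gut_fwd + gut_loss
        q_ent(t) = gut_fwd * (exp(-a t) - exp(-b t)) / (b - a),
                                                   b = gut_fwd + direct

    The downstream states are assembled from two augmented linear
    subsystems, each solved with a matrix exponential:

    * the direct route (enterocyte -> plasma shunt), evaluated at t;
    * the delayed route (enterocyte -> delay -> liver -> plasma),
      evaluated at t - DT and zero before the delay elapses.

    Both subsystems carry integrator rows for cumulative first-pass plasma
    arrival, cumulative irreversible loss from stores, and the running FD
    time-integral (AUC).
    """

    # state indices within each augmented subsystem
    _Q5, _Q6, _Q4, _ARR, _LOSS, _AUC = 0, 1, 2, 3, 4, 5

    def __init__(self, params: SubjectParams, arm: str):
        self.params = params
        self.arm = arm
        self.chain = ch = _arm_chain(params, arm)
        self._a = ch.gut_fwd + ch.gut_loss
        self._b = ch.gut_fwd + ch.direct

        # direct route: states (z1, z2, q5, q6, arr, loss, auc)
        M1 = np.zeros((7, 7))
        M1[0, 0] = -self._a
        M1[1, 0] = ch.gut_fwd
        M1[1, 1] = -self._b
        M1[2, 1] = ch.direct
        M1[2, 2] = -ch.L65
        M1[2, 3] = ch.L56
        M1[3, 2] = ch.L65
        M1[3, 3] = -(ch.L56 + ch.L106)
        M1[4, 1] = ch.direct          # cumulative first-pass arrival
        M1[5, 3] = ch.L106            # cumulative loss from stores
        M1[6, 2] = 1.0                # cumulative FD integral
        self._M1 = M1

        # delayed route: states (z1, z2, q4, q5, q6, arr, loss, auc),
        # started at t = DT with the enterocyte history replayed from 0
        M2 = np.zeros((8, 8))
        M2[0, 0] = -self._a
        M2[1, 0] = ch.gut_fwd
        M2[1, 1] = -self._b
        M2[2, 1] = ch.gut_fwd         # delay output L32 * q_ent(t - DT)
        M2[2, 2] = -ch.hep
        M2[3, 2] = ch.hep
        M2[3, 3] = -ch.L65
        M2[3, 4] = ch.L56
        M2[4, 3] = ch.L65
        M2[4, 4] = -(ch.L56 + ch.L106)
        M2[5, 2] = ch.hep
        M2[6, 4] = ch.L106
        M2[7, 3] = 1.0
        self._M2 = M2

    # -- closed-form upstream states ------------------------------------
    def q_gut(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-self._a * t)

    def q_ent(self, t):
        # (exp(-a t) - exp(-b t)) / (b - a) = exp(-min t) * t * phi(|b-a| t)
        t = np.asarray(t, dtype=float)
        tpos = np.where(t > 0.0, t, 0.0)
        m = min(self._a, self._b)
        d = abs(self._b - self._a)
        out = self.chain.gut_fwd * tpos * np.exp(-m * tpos) * _phi(d * tpos)
        return np.where(t <= 0.0, 0.0, out)

    def _int_q_ent(self, t):
        """Integral of q_ent from 0 to t (closed form, degenerate-safe)."""
        t = np.asarray(t, dtype=float)
        a, b = self._a, self._b
        if a <= 0.0:
            return np.zeros_like(t)
        tpos = np.where(t > 0.0, t, 0.0)
        if abs(b - a) > 1e-8 * max(a, b):
            fa = -np.expm1(-a * tpos) / a
            fb = -np.expm1(-b * tpos) / b if b > 0 else tpos
            val = self.chain.gut_fwd * (fa - fb) / (b - a)
        else:
            # limit b -> a of (f(a) - f(b)) / (b - a) = -f'(a)
            e = np.exp(-a * tpos)
            val = self.chain.gut_fwd * (1.0 - e - a * tpos * e) / a**2
        return np.where(t <= 0.0, 0.0, val)

    def delay_output(self, t):
        """Inflow to the liver compartment: gut_fwd * q_ent(t - DT)."""
        t = np.asarray(t, dtype=float)
        return self.chain.gut_fwd * self.q_ent(t - self.chain.DT)

    def delay_content(self, t):
        """Tracer in transit inside the delay element at time t."""
        t = np.asarray(t, dtype=float)
        ch = self.chain
        return ch.gut_fwd * (self._int_q_ent(t) - self._int_q_ent(t - ch.DT))

    # -- downstream states via matrix exponentials ----------------------
    def _eval(self, t):
        """Rows: q4, q5, q6, cum_arrival, cum_loss6, cum_fd at each time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValidationError("times must be nonnegative")
        out = np.zeros((6, t.size))
        x1 = np.zeros(7)
        x1[0] = 1.0
        x2 = np.zeros(8)
        x2[0] = 1.0
        DT = self.chain.DT
        for j, tj in enumerate(t):
            if tj == 0.0:
                continue
            s1 = expm(self._M1 * tj) @ x1
            q5, q6, arr, loss, auc = s1[2], s1[3], s1[4], s1[5], s1[6]
            q4 = 0.0
            s = tj - DT
            if s > 0.0:
                s2 = expm(self._M2 * s) @ x2
                q4 = s2[2]
                q5 += s2[3]
                q6 += s2[4]
                arr += s2[5]
                loss += s2[6]
                auc += s2[7]
            out[:, j] = (q4, q5, q6, arr, loss, auc)
        return out

    def fd(self, t):
        """Fraction of dose in the plasma compartment."""
        val = self._eval(t)[1]
        val = np.where((val < 0) & (val > -1e-12), 0.0, val)
        return val if np.ndim(t) else float(val[0])

    def states(self, t) -> dict:
        q = self._eval(t)
        sq = lambda v: v if np.ndim(t) else float(v[0])
        ta = np.atleast_1d(t)
        return {
            "gut": sq(self.q_gut(ta)),
            "enterocyte": sq(self.q_ent(ta)),
            "delay": sq(self.delay_content(ta)),
            "liver": sq(q[0]),
            "plasma": sq(q[1]),
            "stores": sq(q[2]),
            "cum_arrival": sq(q[3]),
            "cum_loss_stores": sq(q[4]),
            "cum_fd": sq(q[5]),
        }

    def arrival_fraction(self, t):
        """Cumulative FIRST-PASS plasma arrival / absorbed fraction.

        Nondecreasing, 0 at t = 0 and -> 1 as t -> infinity: every absorbed
        molecule eventually reaches plasma (both enterocyte exits lead
        there), and recycled returns from stores are deliberately excluded.
        """
        val = self._eval(t)[3] / self.chain.absorbed_fraction
        return val if np.ndim(t) else float(val[0])

    def auc_fd(self, t):
        """Integral of FD from 0 to t (days)."""
        val = self._eval(t)[5]
        return val if np.ndim(t) else float(val[0])

    def mass_residual(self, t):
        """|total tracer accounted for - 1| at time t (conservation check)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        q = self._eval(t_arr)
        ch = self.chain
        a = self._a
        cum_loss_gut = (ch.gut_loss / a) * -np.expm1(-a * t_arr) if a > 0 else 0.0
        total = (
            self.q_gut(t_arr) + self.q_ent(t_arr) + self.delay_content(t_arr)
            + q[0] + q[1] + q[2] + q[4] + cum_loss_gut
        )
        val = np.abs(total - 1.0)
        return val if np.ndim(t) else float(val[0])

    def ttp50(self, t_hint: float = 10.0) -> float:
        """Time (days) at which half of the absorbed tracer has first
        reached plasma; root of arrival_fraction(t) = 0.5."""
        f = lambda t: self.arrival_fraction(t) - 0.5
        hi = t_hint
        for _ in range(20):
            if f(hi) > 0:
                break
            hi *= 2.0
        else:  # pragma: no cover
            raise ValidationError("arrival fraction never reaches 0.5")
        return brentq(f, 0.0, hi, xtol=1e-6 / 24.0)  # 0.01 h in days


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def mean_params() -> SubjectParams:
    """Subject parameters at the published cohort means."""
    m = COHORT_MEANS
    return SubjectParams(
        RetinolArmParams(m["L21"], m["L52"], m["DT3"], m["L54"],
                         m["L65"], m["L56"], m["L106"]),
        CaroteneArmParams(m["P11"], m["L1512"], m["DT13"], m["L1514"]),
    )


def _times_array(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a nonempty 1-D array")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be nonnegative and strictly increasing")
    return t


def simulate_fd(params: SubjectParams, arm: str, times) -> TracerCurve:
    """Model-predicted fraction-of-dose curve for a unit oral bolus."""
    t = _times_array(times)
    sol = ArmSolution(params, arm)
    return TracerCurve(arm, t, np.asarray(sol.fd(t)))


def cumulative_plasma_arrival(params: SubjectParams, arm: str, t_grid) -> np.ndarray:
    """Cumulative first-pass plasma arrival, as a fraction of the ABSORBED dose."""
    t = _times_array(t_grid)
    sol = ArmSolution(params, arm)
    return np.asarray(sol.arrival_fraction(t))


def mass_balance(params: SubjectParams, arm: str, t):
    """Conservation residual |sum of compartments + losses - 1| at time(s) t."""
    sol = ArmSolution(params, arm)
    val = sol.mass_residual(np.atleast_1d(np.asarray(t, dtype=float)))
    return val if np.ndim(t) else float(val[0])
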