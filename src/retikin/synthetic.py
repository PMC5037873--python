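"""Synthetic cohort generator.

Emulates the published study design so that every pipeline stage is
testable without the (undeposited) raw plasma data: 30 subjects sampled at
0, 2, 4, 6, 8, 10, 12 h and 1, 2, 7, 14 d after dosing, per-subject model
parameters dispersed around the published cohort means/SDs, and ~5%
proportional measurement noise.

Parameters are drawn independently from lognormal distributions
moment-matched to the published arithmetic mean m and SD s
(sigma^2 = ln(1 + (s/m)^2), mu = ln m - sigma^2/2); lognormal rather than
truncated normal because several published CVs exceed 1 (e.g. L(2,1):
24.2 +/- 39.0), which would make normal draws frequently negative.  Delay
times are capped at 1 d.  An optional correlation matrix (Gaussian copula
on the lognormal z-scores) is accepted for sensitivity studies; the default
is independence, since no between-parameter covariance was published.

What the generator does NOT emulate: assay background/absolute detection
noise on the earliest samples (noise is purely proportional), diurnal
tracee variation, and within-subject correlation of measurement errors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    COHORT_MEANS,
    COHORT_SDS,
    CaroteneArmParams,
    RetinolArmParams,
    SubjectParams,
    TracerCurve,
    ValidationError,
    simulate_fd,
)
from .qc import QCConfig, SubjectRecord

__all__ = [
    "PopulationConfig",
    "SyntheticCohort",
    "STUDY_SCHEDULE",
    "STUDY_DOSES",
    "sample_parameters",
    "generate_subject_curves",
    "generate_cohort",
    "inject_anomaly",
    "inject_standard_anomalies",
    "ANOMALY_PLAN",
    "write_cohort",
]

#: sampling schedule, days: 0, 2..12 h, then 1, 2, 7, 14 d
STUDY_SCHEDULE = tuple(
    [0.0] + [h / 24.0 for h in (2, 4, 6, 8, 10, 12)] + [1.0, 2.0, 7.0, 14.0]
)

#: administered doses, umol: retinyl acetate; all-trans, cis, alpha carotene
STUDY_DOSES = {
    "dose_retinol": 2.954,
    "dose_bc_alltrans": 3.237,
    "dose_bc_cis": 0.366,
    "dose_bc_alpha": 0.055,
}

_PARAM_ORDER = tuple(COHORT_MEANS)

#: anomaly proportions of the source study's excluded subjects
ANOMALY_PLAN = (
    ("MISSING_CRITICAL", 1),
    ("NEGATIVE_FD", 3),
    ("POSITIVE_TERMINAL_SLOPE", 3),
    ("CURVES_CONVERGE", 3),
    ("CURVES_DIVERGE", 1),
    ("ABNORMAL_PEAK", 4),
)


@dataclass(frozen=True)
class PopulationConfig:
    n_subjects: int = 30
    seed: int = 0
    parameter_means: dict = field(default_factory=lambda: dict(COHORT_MEANS))
    parameter_sds: dict = field(default_factory=lambda: dict(COHORT_SDS))
    body_weight_mean: float = 65.2       # kg
    body_weight_sd: float = 10.0
    plasma_retinol_mean: float = 1.53    # umol/L
    plasma_retinol_sd: float = 0.27
    plasma_retinol_range: tuple = (1.13, 2.32)
    noise_cv: float = 0.05
    schedule: tuple = STUDY_SCHEDULE
    doses: dict = field(default_factory=lambda: dict(STUDY_DOSES))
    dt_cap: float = 1.0                  # d, upper cap for delay draws
    correlation: object = None           # optional z-score correlation matrix

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        sched = np.asarray(self.schedule, dtype=float)
        if np.any(np.diff(sched) <= 0):
            raise ValidationError("schedule must be strictly increasing")
        for k, s in self.parameter_sds.items():
            if s < 0:
                raise ValidationError(f"SD of {k} must be >= 0")
            if self.parameter_means.get(k, 0.0) == 0.0 and s > 0:
                raise ValidationError(f"{k}: zero mean with nonzero SD")


@dataclass(frozen=True)
class SyntheticCohort:
    config: PopulationConfig
    subjects: tuple          # SubjectRecord per subject
    true_params: tuple       # SubjectParams per subject
    curves: tuple            # (TracerCurve C10, TracerCurve C5) per subject


def _lognormal_moments(m: float, s: float):
    sigma2 = np.log1p((s / m) ** 2)
    return np.log(m) - sigma2 / 2.0, np.sqrt(sigma2)


def _draw_matrix(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    """n_subjects x n_params matrix of lognormal draws (column order
    :data:`_PARAM_ORDER`), optionally copula-correlated."""
    n, k = config.n_subjects, len(_PARAM_ORDER)
    if config.correlation is not None:
        C = np.asarray(config.correlation, dtype=float)
        if C.shape != (k, k):
            raise ValidationError(f"correlation must be {k}x{k}")
        z = rng.multivariate_normal(np.zeros(k), C, size=n, method="cholesky")
    else:
        z = rng.standard_normal((n, k))
    out = np.empty((n, k))
    for j, name in enumerate(_PARAM_ORDER):
        m = config.parameter_means[name]
        s = config.parameter_sds[name]
        if s == 0.0 or m == 0.0:
            out[:, j] = m
        else:
            mu, sigma = _lognormal_moments(m, s)
            out[:, j] = np.exp(mu + sigma * z[:, j])
    return out


def _params_from_row(row: dict, dt_cap: float) -> SubjectParams:
    return SubjectParams(
        RetinolArmParams(row["L21"], row["L52"], min(row["DT3"], dt_cap),
                         row["L54"], row["L65"], row["L56"], row["L106"]),
        CaroteneArmParams(row["P11"], row["L1512"],
                          min(row["DT13"], dt_cap), row["L1514"]),
    )


def sample_parameters(config: PopulationConfig,
                      rng: np.random.Generator | None = None) -> list:
    """Per-subject SubjectParams drawn from the moment-matched population."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mat = _draw_matrix(config, rng)
    return [
        _params_from_row(dict(zip(_PARAM_ORDER, mat[i])), config.dt_cap)
        for i in range(config.n_subjects)
    ]


def _sample_subjects(config: PopulationConfig, rng: np.random.Generator):
    """Body weights (lognormal) and truncated-normal plasma retinol."""
    mu, sigma = _lognormal_moments(config.body_weight_mean, config.body_weight_sd)
    weights = np.exp(mu + sigma * rng.standard_normal(config.n_subjects))
    lo, hi = config.plasma_retinol_range
    retinol = np.empty(config.n_subjects)
    for i in range(config.n_subjects):
        while True:
            v = rng.normal(config.plasma_retinol_mean, config.plasma_retinol_sd)
            if lo <= v <= hi:
                retinol[i] = v
                break
    return [
        SubjectRecord(subject_id=f"S{i+1:03d}", body_weight=float(weights[i]),
                      mean_plasma_retinol=float(retinol[i]), **config.doses)
        for i in range(config.n_subjects)
    ]


def generate_subject_curves(params: SubjectParams, config: PopulationConfig,
                            rng: np.random.Generator):
    """Noisy FD curve pair for one subject at the study schedule.

    Each positive model FD is multiplied by mean-1 lognormal noise with
    CV = noise_cv; the t = 0 sample stays exactly 0.
    """
    sched = np.asarray(config.schedule, dtype=float)
    out = []
    for arm in ("C10", "C5"):
        clean = simulate_fd(params, arm, sched)
        fd = clean.fd.copy()
        if config.noise_cv > 0:
            sigma2 = np.log1p(config.noise_cv**2)
            noise = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), fd.size))
            pos = fd > 0
            fd[pos] = fd[pos] * noise[pos]
        out.append(TracerCurve(arm, sched, fd))
    return tuple(out)


def generate_cohort(config: PopulationConfig | None = None) -> SyntheticCohort:
    """Full reproducible cohort: subjects, true parameters, noisy curves."""
    config = config or PopulationConfig()
    rng = np.random.default_rng(config.seed)
    params = sample_parameters(config, rng)
    subjects = _sample_subjects(config, rng)
    curves = tuple(generate_subject_curves(p, config, rng) for p in params)
    return SyntheticCohort(config, tuple(subjects), tuple(params), curves)


# ---------------------------------------------------------------------------
# anomaly injection (for QC screening fixtures)
# ---------------------------------------------------------------------------

def _window_mask(times, qc: QCConfig):
    lo, hi = qc.terminal_window
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def _window_log_slope(curve: TracerCurve, qc: QCConfig) -> float:
    m = _window_mask(curve.times, qc)
    t, y = curve.times[m], curve.fd[m]
    ly = np.log(y)
    tbar = t.mean()
    return float(np.sum((t - tbar) * (ly - ly.mean())) / np.sum((t - tbar) ** 2))


def _set_window_slope(curve: TracerCurve, qc: QCConfig,
                      slope: float) -> TracerCurve:
    """Replace terminal-window points with an exact log-linear segment of
    the given slope, anchored at the realized first window value.  The
    zero-residual segment makes the OLS slope SE vanish, so the intended
    screening outcome is deterministic."""
    m = _window_mask(curve.times, qc)
    fd = curve.fd.copy()
    t = curve.times[m]
    fd[m] = fd[m][0] * np.exp(slope * (t - t[0]))
    return TracerCurve(curve.label, curve.times, fd)


def inject_anomaly(curves, kind: str, qc_config: QCConfig | None = None):
    """Deterministically perturb a clean curve pair so screening flags
    exactly ``kind``.

    Perturbations are chosen not to co-trigger earlier rules: convergence
    is induced by steepening the C10 curve DOWN toward C5 (log-ratio slope
    about +3x the significance floor), divergence by steepening C5 down;
    both leave each curve's own terminal slope negative.
    """
    qc = qc_config or QCConfig()
    c10, c5 = curves
    if kind == "MISSING_CRITICAL":
        drop = max(qc.critical_times)
        keep10 = ~np.isclose(c10.times, drop, atol=qc.time_match_tol)
        keep5 = ~np.isclose(c5.times, drop, atol=qc.time_match_tol)
        return (TracerCurve("C10", c10.times[keep10], c10.fd[keep10]),
                TracerCurve("C5", c5.times[keep5], c5.fd[keep5]))
    if kind == "NEGATIVE_FD":
        fd = c10.fd.copy()
        fd[-2] = -10.0 * qc.negative_tol
        return TracerCurve("C10", c10.times, fd), c5
    if kind == "POSITIVE_TERMINAL_SLOPE":
        return _set_window_slope(c10, qc, 3.0 * qc.slope_floor), c5
    if kind == "CURVES_CONVERGE":
        s5 = _window_log_slope(c5, qc)
        return (_set_window_slope(c10, qc, s5 - 3.0 * qc.slope_floor),
                _set_window_slope(c5, qc, s5))
    if kind == "CURVES_DIVERGE":
        s10 = _window_log_slope(c10, qc)
        return (_set_window_slope(c10, qc, s10),
                _set_window_slope(c5, qc, s10 - 3.0 * qc.slope_floor))
    if kind == "ABNORMAL_PEAK":
        scale = 1.2 * qc.peak_bound / float(np.max(c10.fd))
        return TracerCurve("C10", c10.times, c10.fd * max(scale, 1.0)), c5
    raise ValidationError(f"unknown anomaly kind {kind!r}")


def make_qc_fixture(seed: int = 0, qc_config: QCConfig | None = None,
                    n_subjects: int = 45, config: PopulationConfig | None = None):
    """45-subject screening fixture: a cohort of subjects that screen clean,
    with anomalies then injected in the source study's proportions.

    Under the full published parameter dispersion a minority of genuine
    draws fail screening on their own (very slow hepatic release makes the
    two curves genuinely non-parallel; low plasma turnover pushes the peak
    over the plausibility bound) — exactly the kind of real subject the
    source study excluded.  To make the fixture isolate the screening
    logic, subjects are drawn from the population and only those whose
    clean noisy curves pass screening are kept, before injection.

    Returns (records, curves, expected reason code per subject or None).
    """
    from .qc import screen_subject

    qc = qc_config or QCConfig()
    base_cfg = config or PopulationConfig()
    pool_cfg = dataclasses.replace(base_cfg, n_subjects=4 * n_subjects, seed=seed)
    pool = generate_cohort(pool_cfg)
    keep = [
        i for i in range(pool_cfg.n_subjects)
        if screen_subject(*pool.curves[i], qc).included
    ][:n_subjects]
    if len(keep) < n_subjects:
        raise ValidationError("population rejects too many subjects; "
                              "enlarge the candidate pool")
    cohort = SyntheticCohort(
        pool_cfg,
        tuple(pool.subjects[i] for i in keep),
        tuple(pool.true_params[i] for i in keep),
        tuple(pool.curves[i] for i in keep),
    )
    curves, expected = inject_standard_anomalies(cohort, qc)
    return cohort.subjects, curves, expected


def inject_standard_anomalies(cohort: SyntheticCohort,
                              qc_config: QCConfig | None = None):
    """Perturb the first 15 subjects following the source study's exclusion
    proportions (:data:`ANOMALY_PLAN`); returns (curves list, expected
    reason code per subject, None for clean)."""
    qc = qc_config or QCConfig()
    expected = []
    for kind, count in ANOMALY_PLAN:
        expected.extend([kind] * count)
    expected.extend([None] * (len(cohort.curves) - len(expected)))
    curves = [
        inject_anomaly(pair, kind, qc) if kind is not None else pair
        for pair, kind in zip(cohort.curves, expected)
    ]
    return curves, expected


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir, mode: str = "conc",
                 curves=None) -> dict:
    """Write subjects.csv, curves.csv, truth.csv and a config echo JSON.

    ``mode='conc'`` writes plasma concentrations (umol/L; FD x dose / plasma
    volume, zero background) exercising the preprocessing stage;
    ``mode='fd'`` writes FD values directly.  ``curves`` overrides the
    cohort's own curves (e.g. after anomaly injection).
    """
    if mode not in ("conc", "fd"):
        raise ValidationError("mode must be 'conc' or 'fd'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = cohort.curves if curves is None else curves

    pd.DataFrame([dataclasses.asdict(s) for s in cohort.subjects]).to_csv(
        out / "subjects.csv", index=False)

    rows = []
    for rec, (c10, c5) in zip(cohort.subjects, curves):
        times = c10.times
        fd5_lookup = dict(zip(c5.times, c5.fd))
        for t, y10 in zip(times, c10.fd):
            y5 = fd5_lookup.get(t, np.nan)
            if mode == "fd":
                rows.append({"subject_id": rec.subject_id, "time_d": t,
                             "fd_c10": y10, "fd_c5": y5})
            else:
                pv = rec.plasma_volume
                rows.append({
                    "subject_id": rec.subject_id, "time_d": t,
                    "conc_c10_umol_L": y10 * rec.dose_retinol / pv,
                    "conc_c5_umol_L": y5 * rec.dose_carotene_rae / pv,
                })
    pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)

    truth_rows = []
    for rec, p in zip(cohort.subjects, cohort.true_params):
        r, c = p.retinol_arm, p.carotene_arm
        truth_rows.append({
            "subject_id": rec.subject_id,
            "L21": r.L21, "L52": r.L52, "DT3": r.DT3, "L54": r.L54,
            "L65": r.L65, "L56": r.L56, "L106": r.L106,
            "L1512": c.L1512, "DT13": c.DT13, "L1514": c.L1514, "P11": c.P11,
        })
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)

    echo = dataclasses.asdict(cohort.config)
    echo["schedule"] = list(echo["schedule"])
    echo["plasma_retinol_range"] = list(echo["plasma_retinol_range"])
    echo["mode"] = mode
    (out / "generate_config.json").write_text(json.dumps(echo, indent=2))
    return {"subjects": out / "subjects.csv", "curves": out / "curves.csv",
            "truth": out / "truth.csv"}
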