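"""Pipeline orchestration: preprocess -> QC -> fit -> summarize -> bioefficacy.

Input files (CSV):

* ``subjects.csv`` — one row per subject with the SubjectRecord fields
  (subject_id, body_weight, mean_plasma_retinol, dose_retinol,
  dose_bc_alltrans, dose_bc_cis, dose_bc_alpha).
* ``curves.csv`` — long format: subject_id, time_d, then either
  conc_c10_umol_L / conc_c5_umol_L (mode="conc") or fd_c10 / fd_c5
  (mode="fd").  In concentration mode the t = 0 sample of each analyte is
  used as its background and FD = (conc - background) x plasma volume /
  dose; the [13C5]retinol dose is the carotene dose in retinol activity
  equivalents.

Outputs: qc.csv, params.csv, summary.csv, bioefficacy.csv and report.json
(cohort means +/- SDs, per-subject exclusions, collected warnings).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .bioefficacy import (
    BioefficacyResult,
    graphical_bioefficacy,
    isotope_ratio,
    model_based_bioefficacy,
    rae_ratio_text,
)
from .fitting import FitConfig, fit_subject
from .model import TracerCurve
from .qc import QCConfig, SubjectRecord, fd_from_concentration, screen_subject
from .summary import summarize_subject

__all__ = ["RunConfig", "PipelineError", "load_subjects", "load_curves",
           "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised for malformed inputs or an empty post-QC cohort."""


class QCSettings(BaseModel):
    critical_times: list[float] = [0.25, 0.5, 2.0, 14.0]
    terminal_window: list[float] = [2.0, 14.0]
    slope_nse: float = 2.0
    slope_floor: float = 0.05
    peak_bound: float = 0.30
    negative_tol: float = 1e-6

    def to_config(self) -> QCConfig:
        return QCConfig(critical_times=tuple(self.critical_times),
                        terminal_window=tuple(self.terminal_window),
                        slope_nse=self.slope_nse, slope_floor=self.slope_floor,
                        peak_bound=self.peak_bound,
                        negative_tol=self.negative_tol)


class FitSettings(BaseModel):
    weight_fsd: float = 0.05
    fsd_flag: float = 0.5
    max_nfev: int = 5000
    ftol: float = 1e-10
    xtol: float = 1e-10

    def to_config(self) -> FitConfig:
        return FitConfig(weight_fsd=self.weight_fsd, fsd_flag=self.fsd_flag,
                         max_nfev=self.max_nfev, ftol=self.ftol,
                         xtol=self.xtol)


class BioSettings(BaseModel):
    truncation_day: float = 14.0
    isotope_ratio_day: float = 2.0


class RunConfig(BaseModel):
    """Run configuration; JSON-serializable, CLI flags may override."""

    subjects_csv: str
    curves_csv: str
    out_dir: str = "."
    mode: str = Field("conc", pattern="^(conc|fd)$")
    seed: int = 0
    qc: QCSettings = QCSettings()
    fit: FitSettings = FitSettings()
    bioefficacy: BioSettings = BioSettings()


def _read_csv(path, required_cols) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"input file not found: {p}")
    try:
        df = pd.read_csv(p)
    except Exception as exc:
        raise PipelineError(f"cannot parse {p}: {exc}") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise PipelineError(f"{p}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise PipelineError(f"{p}: no data rows")
    return df


def load_subjects(path) -> dict:
    """subject_id -> SubjectRecord."""
    cols = ["subject_id", "body_weight", "mean_plasma_retinol", "dose_retinol",
            "dose_bc_alltrans", "dose_bc_cis", "dose_bc_alpha"]
    df = _read_csv(path, cols)
    out = {}
    for i, row in df.iterrows():
        try:
            rec = SubjectRecord(
                subject_id=str(row["subject_id"]),
                **{c: float(row[c]) for c in cols[1:]})
        except Exception as exc:
            raise PipelineError(f"{path} row {i + 2}: {exc}") from exc
        out[rec.subject_id] = rec
    return out


def load_curves(path, subjects: dict, mode: str = "conc") -> dict:
    """subject_id -> (TracerCurve C10, TracerCurve C5)."""
    if mode == "conc":
        cols = ["subject_id", "time_d", "conc_c10_umol_L", "conc_c5_umol_L"]
    else:
        cols = ["subject_id", "time_d", "fd_c10", "fd_c5"]
    df = _read_csv(path, cols)
    out = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        sid = str(sid)
        if sid not in subjects:
            log.warning("curves for unknown subject %s skipped", sid)
            continue
        grp = grp.sort_values("time_d")
        t = grp["time_d"].to_numpy(dtype=float)
        try:
            if mode == "fd":
                pair = (TracerCurve("C10", t, grp["fd_c10"].to_numpy(float)),
                        TracerCurve("C5", t, grp["fd_c5"].to_numpy(float)))
            else:
                rec = subjects[sid]
                pair = []
                for col, dose, label in (
                    ("conc_c10_umol_L", rec.dose_retinol, "C10"),
                    ("conc_c5_umol_L", rec.dose_carotene_rae, "C5"),
                ):
                    conc = grp[col].to_numpy(dtype=float)
                    bg = conc[t == 0.0][0] if np.any(t == 0.0) else 0.0
                    pair.append(fd_from_concentration(
                        t, conc, rec.plasma_volume, dose, bg, label))
                pair = tuple(pair)
        except Exception as exc:
            raise PipelineError(f"{path}, subject {sid}: {exc}") from exc
        out[sid] = tuple(pair)
    return out


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.INFO)
        self.messages = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def _fmt(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, stages=("qc", "fit", "summary",
                                            "bioefficacy")) -> dict:
    """Execute the pipeline and write per-stage CSVs plus report.json."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qc_cfg = config.qc.to_config()
    fit_cfg = config.fit.to_config()

    collector = _WarningCollector()
    root = logging.getLogger("retikin")
    root.addHandler(collector)
    root.setLevel(min(root.level or logging.INFO, logging.INFO))
    try:
        subjects = load_subjects(config.subjects_csv)
        curves = load_curves(config.curves_csv, subjects, config.mode)

        report = {"n_subjects": len(subjects), "config": config.model_dump()}

        # --- QC -----------------------------------------------------------
        verdicts = {}
        for sid, rec in subjects.items():
            if sid not in curves:
                from .qc import QCVerdict
                verdicts[sid] = QCVerdict(sid, False, ("MISSING_CRITICAL",))
                continue
            verdicts[sid] = screen_subject(*curves[sid], qc_cfg, subject_id=sid)
        qc_df = pd.DataFrame(
            [{"subject_id": s, "included": v.included,
              "reason_codes": ";".join(v.reason_codes)}
             for s, v in verdicts.items()])
        _fmt(qc_df, out_dir / "qc.csv")
        included = [s for s, v in verdicts.items() if v.included]
        report["n_included"] = len(included)
        report["excluded"] = {s: list(v.reason_codes)
                              for s, v in verdicts.items() if not v.included}
        if "fit" not in stages:
            return _finish(report, out_dir, collector, root)
        if not included:
            raise PipelineError("empty cohort: every subject failed QC")

        # --- fitting ------------------------------------------------------
        fits = {}
        rows = []
        for sid in included:
            c10, c5 = curves[sid]
            params, f10, f5 = fit_subject(c10, c5, config=fit_cfg)
            fits[sid] = (params, f10, f5)
            for fr in (f10, f5):
                for name, fsd in fr.fsd.items():
                    rows.append({
                        "subject_id": sid, "parameter": name,
                        "estimate": getattr(fr.params, name), "fsd": fsd,
                        "flag": ("poorly_identified"
                                 if name in fr.poorly_identified else ""),
                        "converged": fr.converged,
                    })
            if not (f10.converged and f5.converged):
                log.warning("fit did not converge for subject %s", sid)
        _fmt(pd.DataFrame(rows), out_dir / "params.csv")
        if "summary" not in stages:
            return _finish(report, out_dir, collector, root)

        # --- kinetic summary ----------------------------------------------
        sum_rows = []
        for sid in included:
            params, _, _ = fits[sid]
            ks = summarize_subject(params, subjects[sid].plasma_pool)
            row = {"subject_id": sid}
            row.update(dataclasses.asdict(ks))
            sum_rows.append(row)
        sum_df = pd.DataFrame(sum_rows)
        _fmt(sum_df, out_dir / "summary.csv")
        report["kinetics"] = {
            c: {"mean": float(sum_df[c].mean()), "sd": float(sum_df[c].std())}
            for c in sum_df.columns if c != "subject_id"}
        if "bioefficacy" not in stages:
            return _finish(report, out_dir, collector, root)

        # --- bioefficacy ----------------------------------------------------
        bio_rows = []
        for sid in included:
            params, _, _ = fits[sid]
            c10, c5 = curves[sid]
            mb = model_based_bioefficacy(params)
            res = BioefficacyResult(
                subject_id=sid,
                model_based=mb,
                graphical=graphical_bioefficacy(
                    c10, c5, config.bioefficacy.truncation_day),
                isotope_ratio_d2=isotope_ratio(
                    c10, c5, config.bioefficacy.isotope_ratio_day),
                rae_ratio_text=rae_ratio_text(mb),
            )
            bio_rows.append(dataclasses.asdict(res))
        bio_df = pd.DataFrame(bio_rows)
        _fmt(bio_df, out_dir / "bioefficacy.csv")
        report["bioefficacy"] = {}
        for c in ("model_based", "graphical", "isotope_ratio_d2"):
            v = bio_df[c]
            report["bioefficacy"][c] = {
                "mean": float(v.mean()), "sd": float(v.std()),
                "cv": float(v.std() / v.mean()),
                "range": [float(v.min()), float(v.max())],
            }
        return _finish(report, out_dir, collector, root)
    finally:
        root.removeHandler(collector)


def _finish(report: dict, out_dir: Path, collector, root) -> dict:
    report["warnings"] = list(collector.messages)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, default=float))
    return report
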