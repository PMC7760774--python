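"""End-to-end pipeline: simulate -> process -> QC -> fit -> reliability.

Mechanizes the study flow (each athlete completes a 3-min all-out field
test plus a ramp GXT with a supramaximal verification bout), producing a
cohort table, a fitted prediction model and a reliability report as one
seeded, reproducible run.
"""
from __future__ import annotations

import json
import logging
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allout import compute_allout
from .config import GeneratorConfig
from .data import MPH_TO_MPS
from .gxt import process_gxt, process_verification
from .qc import apply_qc
from .regression import ModelFit, compare_observed_predicted, fit_stepwise, fitted_values
from .reliability import reliability_report
from .synthetic import (
    calibrate_sex_cs_distributions,
    design_protocol_for,
    render_allout_trace,
    render_gxt_series,
    render_pacing_violation,
    sample_athletes,
)

log = logging.getLogger("critspeed")

#: versioned cohort-table schema (speed columns carry a unit suffix)
COHORT_SCHEMA_VERSION = 1
COHORT_COLUMNS = (
    "id",
    "sex",
    "mass_kg",
    "cs",
    "s150",
    "dprime",
    "vo2max_ramp",
    "vo2max_vp",
    "get_vo2",
    "fifty_delta",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, athlete_ids=()):
        self.stage = stage
        self.athlete_ids = list(athlete_ids)
        suffix = f" (athletes: {self.athlete_ids})" if self.athlete_ids else ""
        super().__init__(f"[{stage}] {message}{suffix}")


@dataclass
class RunReport:
    config: dict
    counts: dict
    qc_summary: dict
    model: dict
    comparison: dict
    reliability: dict
    seed: int
    version: str = __version__
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; columns tagged `_mph` convert to m/s on load."""
    df = pd.read_csv(path)
    for col in list(df.columns):
        if col.endswith("_mph"):
            df[col[:-4] + "_mps"] = df[col] * MPH_TO_MPS
            df = df.drop(columns=[col])
    missing = [c for c in ("id", "cs") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    if df["id"].duplicated().any():
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"duplicate athlete ids: {dupes}")
    return df


def simulate_cohort(config: GeneratorConfig) -> tuple[GeneratorConfig, pd.DataFrame, list]:
    """Stages simulate + process-3mt + process-gxt; returns the measured table."""
    t0 = _time.perf_counter()
    if not config.is_calibrated:
        config = calibrate_sex_cs_distributions(config)
    truths = sample_athletes(config)
    if not truths:
        raise StageError("simulate", "cohort is empty (n_athletes = 0)")
    log.info("calibrated + sampled %d athletes in %.1fs", len(truths), _time.perf_counter() - t0)

    rows = []
    for truth in truths:
        if truth.is_pacing_violator:
            trace = render_pacing_violation(truth, config)
        else:
            trace = render_allout_trace(truth, config)
        allout = compute_allout(trace)

        protocol = design_protocol_for(truth)
        gas = render_gxt_series(truth, protocol, config)
        try:
            gxt = process_gxt(gas, protocol)
        except ValueError as exc:
            raise StageError("process-gxt", str(exc), [truth.id]) from exc
        vp = process_verification(gxt.vo2max, gas)
        rows.append(
            {
                "id": truth.id,
                "sex": truth.sex,
                "mass_kg": truth.mass_kg,
                "cs": allout.cs,
                "s150": allout.s150,
                "dprime": allout.dprime,
                "vo2max_ramp": gxt.vo2max,
                "vo2max_vp": vp.vp_vo2max,
                "get_vo2": gxt.get_vo2,
                "fifty_delta": gxt.fifty_delta,
                "true_cs": truth.true_cs,
                "true_vo2max": truth.true_vo2max,
                "injected_pacing": truth.is_pacing_violator,
                "injected_vp": truth.is_vp_violator,
            }
        )
    return config, pd.DataFrame(rows), truths


def run_full(config: GeneratorConfig, outdir=None, seed: int | None = None) -> tuple[RunReport, pd.DataFrame]:
    """Execute the whole pipeline on a simulated cohort.

    Writes cohort.csv, report.json and summary.txt under ``outdir`` when
    given. Stage outputs are pure functions of config + seed; a rerun
    with the same config produces byte-identical files.
    """
    if seed is not None:
        config = config.replace(seed=seed)
    config.validate()
    timings = {}
    t0 = _time.perf_counter()
    config, measured, _ = simulate_cohort(config)
    timings["simulate+process"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    valid, excluded, qc_summary = apply_qc(measured)
    timings["qc"] = _time.perf_counter() - t0
    if len(valid) < 5:
        raise StageError(
            "fit", f"only {len(valid)} valid athletes after QC; need >= 5",
            valid["id"].tolist(),
        )

    t0 = _time.perf_counter()
    model_frame = valid.rename(columns={"vo2max_ramp": "vo2max"})
    fit = fit_stepwise(model_frame)
    comparison = compare_observed_predicted(model_frame, fit)
    rel = reliability_report(
        model_frame["vo2max"].to_numpy(float), fitted_values(model_frame, fit)
    )
    timings["fit+reliability"] = _time.perf_counter() - t0

    cohort = pd.concat([valid, excluded]).sort_values("id").reset_index(drop=True)
    cohort["predicted_vo2max"] = np.nan
    cohort.loc[~cohort["qc_excluded"], "predicted_vo2max"] = fitted_values(
        cohort[~cohort["qc_excluded"]], fit
    )
    report = RunReport(
        config=config.to_dict(),
        counts={
            "n_input": qc_summary["n_input"],
            "n_valid": qc_summary["n_valid"],
            "n_excluded": qc_summary["n_excluded"],
        },
        qc_summary=qc_summary,
        model=fit.to_dict(),
        comparison=comparison,
        reliability=rel.to_dict(),
        seed=config.seed,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir / "cohort.csv")
        report.to_json(outdir / "report.json")
        (outdir / "summary.txt").write_text(summarize(report))
    return report, cohort


def summarize(report: RunReport) -> str:
    m = report.model
    c = report.comparison
    r = report.reliability
    q = report.qc_summary
    lines = [
        f"critspeed v{report.version}  (seed {report.seed})",
        f"cohort: {q['n_input']} simulated, {q['n_valid']} valid, "
        f"{q['n_excluded']} excluded "
        f"(pacing {q['by_reason']['pacing']}, verification {q['by_reason']['verification']}, "
        f"both {q['by_reason']['both']})",
        f"model: VO2max = {m['coef_cs']:.3f}*CS + {m['coef_sex']:.3f}*sex + "
        f"{m['intercept']:.3f}  (SEE {m['see']:.2f} mL/kg/min, "
        f"R2 model1 {m['r2_model1']:.3f}, model2 {m['r2_model2']:.3f}, n={m['n']})",
        f"observed vs predicted: {c['mean_observed']:.2f} +/- {c['sd_observed']:.2f} "
        f"vs {c['mean_predicted']:.2f} +/- {c['sd_predicted']:.2f} "
        f"(t={c['t']:.3f}, p={c['p']:.3f})",
        f"reliability: TE {r['te']:.2f} mL/kg/min "
        f"(95% CI {r['ci_te_lower']:.2f}-{r['ci_te_upper']:.2f}), "
        f"CV {r['cv_percent']:.2f}%, ICC {r['icc']:.3f}, r {r['pearson_r']:.3f}",
    ]
    return "\n".join(lines) + "\n"


def setup_logging(json_lines: bool = False, level=logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _JsonFormatter(logging.Formatter):
            def format(self, record):
                return json.dumps(
                    {"level": record.levelname, "msg": record.getMessage()}
                )

        handler.setFormatter(_JsonFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
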