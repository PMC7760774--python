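"""Cohort quality-control screens.

Two exclusion rules:

* pacing: a 3MT-derived CS deviating by >= 3.5% from the GXT-derived
  50% delta marks a paced (held-back) all-out effort; the boundary value
  itself fails. The deviation is taken relative to the 50% delta, the
  GXT-derived reference.
* verification: the ramp and verification-bout VO2max must agree within
  3% (inclusive) for the ramp value to count as a true maximum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PACING_THRESHOLD = 0.035  # deviation >= this fails
VP_THRESHOLD = 0.03  # deviation <= this passes

REASONS = ("none", "pacing", "verification", "both")


@dataclass
class QCFlags:
    pacing_pass: bool
    pacing_deviation: float
    vp_pass: bool
    vp_deviation: float

    @property
    def excluded(self) -> bool:
        return not (self.pacing_pass and self.vp_pass)

    @property
    def reason(self) -> str:
        if self.pacing_pass and self.vp_pass:
            return "none"
        if not self.pacing_pass and not self.vp_pass:
            return "both"
        return "pacing" if not self.pacing_pass else "verification"


def pacing_check(cs: float, fifty_delta: float) -> tuple[bool, float]:
    """Pass iff |CS - 50%delta| / 50%delta < 3.5% (boundary fails)."""
    if cs <= 0 or fifty_delta <= 0:
        raise ValueError("cs and fifty_delta must be positive")
    deviation = abs(cs - fifty_delta) / fifty_delta
    return deviation < PACING_THRESHOLD, deviation


def vp_check(result) -> tuple[bool, float]:
    """Pass iff the ramp/verification relative difference is <= 3% (inclusive).

    Accepts either a :class:`~critspeed.gxt.VerificationResult` or the
    relative difference itself; mirrors the acceptance rule applied by
    ``process_verification``, re-exposed here for cohort bookkeeping.
    """
    deviation = getattr(result, "relative_difference", result)
    if deviation < 0:
        raise ValueError("vp deviation must be >= 0")
    return deviation <= VP_THRESHOLD, deviation


REQUIRED_COLUMNS = ("id", "cs", "fifty_delta", "vo2max_ramp", "vo2max_vp")


def apply_qc(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Partition a cohort table into valid and excluded athletes.

    ``cohort`` needs columns id, cs, fifty_delta, vo2max_ramp and
    vo2max_vp. Returns (valid, excluded, summary); the union of the two
    frames is the input in its original order, annotated with QC columns.
    Rows with missing values are reported by id rather than dropped.
    """
    missing_cols = set(REQUIRED_COLUMNS) - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {sorted(missing_cols)}")
    incomplete = cohort[
        cohort[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    ]["id"].tolist()
    if incomplete:
        raise ValueError(f"incomplete records for athlete ids: {incomplete}")

    out = cohort.copy()
    rows = []
    for _, rec in cohort.iterrows():
        p_pass, p_dev = pacing_check(rec["cs"], rec["fifty_delta"])
        vp_dev = abs(rec["vo2max_ramp"] - rec["vo2max_vp"]) / rec["vo2max_ramp"]
        v_pass, v_dev = vp_check(vp_dev)
        rows.append(QCFlags(p_pass, p_dev, v_pass, v_dev))
    out["pacing_pass"] = [f.pacing_pass for f in rows]
    out["pacing_deviation"] = [f.pacing_deviation for f in rows]
    out["vp_pass"] = [f.vp_pass for f in rows]
    out["vp_deviation"] = [f.vp_deviation for f in rows]
    out["qc_excluded"] = [f.excluded for f in rows]
    out["qc_reason"] = [f.reason for f in rows]

    valid = out[~out["qc_excluded"]].copy()
    excluded = out[out["qc_excluded"]].copy()
    reason_counts = {r: int((out["qc_reason"] == r).sum()) for r in REASONS}
    summary = {
        "n_input": int(len(out)),
        "n_valid": int(len(valid)),
        "n_excluded": int(len(excluded)),
        "by_reason": reason_counts,
        "dual_violations": reason_counts["both"],
    }
    return valid, excluded, summary
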