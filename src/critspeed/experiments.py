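"""Cohort-scale recovery experiments.

Each experiment regenerates a synthetic cohort from scratch under the
calibrated default configuration, pushes it through the measurement
pipeline (all-out trace synthesis, then CS extraction), and measures how
well the fitted prediction model recovers the generating parameters.
These are the computations behind the package's headline checks:
coefficient/SEE recovery at large n and the pooled CS-VO2max
correlation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .allout import compute_allout
from .config import GeneratorConfig
from .qc import apply_qc
from .regression import fit_stepwise
from .reliability import pearson_r
from .synthetic import (
    calibrate_sex_cs_distributions,
    render_allout_trace,
    sample_athletes,
)


def calibrated_default_config(seed: int) -> GeneratorConfig:
    """Default generator configuration, calibrated, with the given seed."""
    return calibrate_sex_cs_distributions(GeneratorConfig(seed=int(seed) % (2**31)))


def extract_cs_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Sample athletes, render all-out traces, extract CS from each.

    Returns a frame with extracted ``cs`` (and ``s150``/``dprime``)
    alongside each athlete's sex and observed VO2max (the generated
    value, which carries the model's residual error).
    """
    truths = sample_athletes(config)
    rows = np.empty((len(truths), 3))
    for i, truth in enumerate(truths):
        result = compute_allout(render_allout_trace(truth, config))
        rows[i] = (result.cs, result.s150, result.dprime)
    return pd.DataFrame(
        {
            "id": [t.id for t in truths],
            "sex": [t.sex for t in truths],
            "cs": rows[:, 0],
            "s150": rows[:, 1],
            "dprime": rows[:, 2],
            "true_cs": [t.true_cs for t in truths],
            "true_dprime": [t.true_dprime for t in truths],
            "vo2max": [t.true_vo2max for t in truths],
        }
    )


def coefficient_recovery(seed: int, n: int = 50_000) -> dict:
    """End-to-end parameter recovery: trace synthesis -> CS extraction -> OLS.

    Fits observed VO2max on pipeline-extracted CS and sex for ``n``
    athletes and reports the recovered coefficients and SEE.
    """
    config = calibrated_default_config(seed).replace(n_athletes=n)
    cohort = extract_cs_cohort(config)
    fit = fit_stepwise(cohort)
    return {
        "coef_cs": fit.coef_cs,
        "coef_sex": fit.coef_sex,
        "intercept": fit.intercept,
        "see": fit.see,
        "r2_model1": fit.r2_model1,
        "n": n,
        "median_cs_error": float(
            np.median(np.abs(cohort["cs"] - cohort["true_cs"]))
        ),
    }


def correlation_recovery(seed: int, n: int = 10_000) -> dict:
    """Pooled Pearson correlation of extracted CS with observed VO2max."""
    config = calibrated_default_config(seed).replace(n_athletes=n)
    cohort = extract_cs_cohort(config)
    r, p = pearson_r(cohort["cs"].to_numpy(), cohort["vo2max"].to_numpy())
    return {"r": r, "p": p, "n": n}


def qc_fixture(seed: int = 1, n: int = 37, n_pacing: int = 9, n_vp: int = 3) -> dict:
    """The cohort-screening fixture: injected violators through the full run.

    Simulates ``n`` athletes of whom the first ``n_pacing`` pace the
    all-out test and the next ``n_vp`` blow the verification bout, runs
    every test through the measurement pipeline and the QC screens, and
    returns the exclusion summary.
    """
    from .pipeline import simulate_cohort

    config = GeneratorConfig(
        n_athletes=n,
        n_pacing_violators=n_pacing,
        n_vp_violators=n_vp,
        seed=seed,
    )
    _, measured, _ = simulate_cohort(config)
    _, _, summary = apply_qc(measured)
    return summary
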