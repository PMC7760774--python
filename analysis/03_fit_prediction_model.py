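#!/usr/bin/env python
"""Fit the stepwise VO2max ~ CS + sex prediction model on the valid cohort.

CS (the hypothesis variable) enters first; sex enters when its partial
t-test clears p < 0.05. Writes the coefficient table and model summary
to results/model_fit.json.
"""
import json
from pathlib import Path

import pandas as pd

from critspeed.regression import compare_observed_predicted, fit_stepwise

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort_qc.csv")
    valid = cohort[~cohort["qc_excluded"]].rename(columns={"vo2max_ramp": "vo2max"})
    fit = fit_stepwise(valid)
    comparison = compare_observed_predicted(valid, fit)
    out = {"fit": fit.to_dict(), "observed_vs_predicted": comparison}
    (RESULTS / "model_fit.json").write_text(json.dumps(out, indent=2))
    print(
        f"VO2max = {fit.coef_cs:.3f}*CS + {fit.coef_sex:.3f}*sex + {fit.intercept:.3f} "
        f"(SEE {fit.see:.2f}, R2 {fit.r2_model2:.3f}, n={fit.n})"
    )
    print(
        f"observed vs fitted: t={comparison['t']:.3f}, p={comparison['p']:.3f} "
        "(zero by construction for an intercept model)"
    )


if __name__ == "__main__":
    main()
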