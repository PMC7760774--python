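#!/usr/bin/env python
"""Agreement between observed and model-predicted VO2max.

Computes typical error, CV%, ICC(3,1), Pearson r and the paired t on the
valid cohort, plus the degrees-of-freedom reconciliation that converts
the model SEE to a typical error. Writes results/reliability.json.
"""
import json
from pathlib import Path

import pandas as pd

from critspeed.regression import fit_stepwise, fitted_values
from critspeed.reliability import reliability_report, te_from_see

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort_qc.csv")
    valid = cohort[~cohort["qc_excluded"]].rename(columns={"vo2max_ramp": "vo2max"})
    fit = fit_stepwise(valid)
    observed = valid["vo2max"].to_numpy(float)
    predicted = fitted_values(valid, fit)
    rep = reliability_report(observed, predicted)
    te_see = te_from_see(fit.see, fit.n, len(fit.included_terms))
    out = rep.to_dict() | {"te_from_see": te_see}
    (RESULTS / "reliability.json").write_text(json.dumps(out, indent=2))
    print(
        f"TE {rep.te:.2f} mL/kg/min (from SEE: {te_see:.2f}; "
        f"95% CI {rep.ci_te_lower:.2f}-{rep.ci_te_upper:.2f}), "
        f"CV {rep.cv_percent:.2f}%, ICC {rep.icc:.3f}, r {rep.pearson_r:.3f}"
    )


if __name__ == "__main__":
    main()
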