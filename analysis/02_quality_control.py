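#!/usr/bin/env python
"""Screen the measured cohort for pacing and verification failures.

Applies the two exclusion rules (CS within 3.5% of 50% delta; ramp and
verification VO2max within 3%) to the table from 01_simulate_cohort.py.
Writes the annotated cohort and a JSON exclusion summary.
"""
import json
from pathlib import Path

import pandas as pd

from critspeed.qc import apply_qc

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort_measurements.csv")
    valid, excluded, summary = apply_qc(cohort)
    annotated = pd.concat([valid, excluded]).sort_values("id")
    annotated.to_csv(RESULTS / "cohort_qc.csv", index=False)
    (RESULTS / "qc_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"{summary['n_valid']} valid / {summary['n_excluded']} excluded "
        f"(pacing {summary['by_reason']['pacing']}, "
        f"verification {summary['by_reason']['verification']}, "
        f"both {summary['by_reason']['both']})"
    )


if __name__ == "__main__":
    main()
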