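#!/usr/bin/env python
"""Build, trim, combine and calibrate the survey weights.

Runs the full weighting pipeline on the simulated cohort: per-sweep mini
weights (response, timely, (re)infection) and envisioned-population
weights, median + 3×IQR trimming, longitudinal combination by
month-of-test cohort, and calibration to the census margins.  Writes the
weight files and prints a Table-3-style summary (N, median, IQR per
weight): response weights are large (~1/response rate), timely and
(re)infection weights hover just above 1, and the combined longitudinal
weights are their products.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from cohortweights.io import (
    read_cohort,
    read_margins,
    write_weightset_csv,
)
from cohortweights.pipeline import PipelineConfig, run_weight_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def summarise(name: str, values: pd.Series) -> str:
    v = values.dropna()
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return f"{name:>32} {len(v):>6} {med:>9.2f} {q1:>8.2f}-{q3:<8.2f}"


def main() -> None:
    warnings.filterwarnings("ignore")
    cohort = read_cohort(RESULTS / "cohort.csv")
    margins = read_margins(RESULTS / "census_margins.csv")
    result = run_weight_pipeline(cohort, margins, PipelineConfig())

    write_weightset_csv(result.weightsets, RESULTS / "weights.csv")
    combined = result.combined.copy()
    combined["w_census_trimmed"] = result.calibrated
    combined.reset_index().to_csv(RESULTS / "combined_weights.csv",
                                  index=False)
    result.ratios.to_csv(RESULTS / "calibration_ratios.csv", index=False)

    print(f"{'survey weight':>32} {'N':>6} {'median':>9} {'IQR':>17}")
    for sweep in (3, 6, 12):
        frame = result.weightsets[sweep].frame
        for col, label in (("w_response", "Response"),
                           ("w_timely", "Timely response"),
                           ("w_reinfection", "(Re)infection"),
                           ("w_envisioned", "Envisioned population")):
            print(summarise(f"{label} {sweep}m", frame[col]))
            print(summarise(f"Trimmed {label.lower()} {sweep}m",
                            frame[f"{col}_trimmed"]))
    print(summarise("Combined longitudinal", combined["w_combined"]))
    print(summarise("Trimmed combined", combined["w_combined_trimmed"]))
    print(summarise("Census-calibrated (trimmed)",
                    combined["w_census_trimmed"]))
    print(f"\nWrote weights.csv, combined_weights.csv, "
          f"calibration_ratios.csv to {RESULTS}")


if __name__ == "__main__":
    main()
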