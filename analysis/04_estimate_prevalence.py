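#!/usr/bin/env python
"""Weighted and unweighted symptom prevalences over the longitudinal
analytic sample.

Estimates tiredness and shortness-of-breath prevalence at 0, 6 and 12
months by index test status — unweighted, weighted to the target
population (combined weights, trimmed) and weighted to the general
population (census-calibrated) — plus prevalence by time of first
report.  The generator's latent symptom states give the envisioned-
population truth for comparison, something no real study observes.
"""

import warnings
from pathlib import Path

from cohortweights.estimation import first_report_table, pipeline_estimates, weighted_prevalence
from cohortweights.io import read_cohort, read_margins, write_results
from cohortweights.pipeline import PipelineConfig, run_weight_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    warnings.filterwarnings("ignore")
    cohort = read_cohort(RESULTS / "cohort.csv")
    margins = read_margins(RESULTS / "census_margins.csv")
    config = PipelineConfig()
    result = run_weight_pipeline(cohort, margins, config)

    estimates = pipeline_estimates(cohort, result, config)
    write_results(estimates, RESULTS / "prevalence_estimates.csv")

    wide = estimates[estimates["group"] != "All"].pivot_table(
        index=["symptom", "group", "timepoint"], columns="variant",
        values="value")[["unweighted", "target_trimmed", "census_trimmed"]]
    truth = {
        (sym, grp, t): weighted_prevalence(
            cohort.loc[cohort["index_status"] == grp, f"true_{sym}_{t}"])
        for sym in ("tired", "breathless")
        for grp in ("Negative", "Positive")
        for t in (0, 6, 12)
    }
    wide["envisioned_truth"] = [truth[k] for k in wide.index]
    print("Prevalence (%) by symptom, index status and months post-test:")
    print(wide.round(2).to_string())

    for symptom in ("tired", "breathless"):
        table = first_report_table(
            cohort, result.combined["w_combined_trimmed"], symptom)
        table.to_csv(RESULTS / f"first_report_{symptom}.csv", index=False)
        print(f"\n{symptom}: weighted % by time of first report")
        print(table.round(2).to_string(index=False))
    print(f"\nWrote prevalence_estimates.csv and first_report_*.csv "
          f"to {RESULTS}")


if __name__ == "__main__":
    main()
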