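#!/usr/bin/env python
"""Fit the nine conditional-probability models (3 stages × 3 sweeps).

For each sweep this selects the minimum-AIC functional forms for age and
IMD, then runs forward (p < 0.157) / backward (p >= 0.200 removes)
stepwise refinement around the forced design covariates.  Model reports
and the form-search log go to results/; the printed table summarises
selected forms, stepwise picks, separation drops and C-statistics
(discrimination is expectedly modest for the response models, which can
only use the design covariates).
"""

import warnings
from pathlib import Path

from cohortweights.forms import search_log_frame
from cohortweights.io import read_cohort, write_model_report
from cohortweights.pipeline import PipelineConfig, fit_sweep_models

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    warnings.filterwarnings("ignore")
    cohort = read_cohort(RESULTS / "cohort.csv")
    config = PipelineConfig()

    print(f"{'sweep':>5} {'stage':>11} {'n':>6} {'C':>7}  forms / "
          "selected / dropped")
    logs = []
    for sweep in config.sweeps:
        models, forms, search_logs = fit_sweep_models(cohort, sweep, config)
        logs.extend(search_logs)
        for stage, model in models.items():
            write_model_report(model, RESULTS / f"model_{stage}_{sweep}m.csv")
            age = forms.get((sweep, stage, "age_years"))
            imd = forms.get((sweep, stage, "imd_decile"))
            print(f"{sweep:>4}m {stage:>11} {model.n_used:>6} "
                  f"{model.c_statistic:>7.4f}  "
                  f"age={age.label() if age else '-'} "
                  f"imd={imd.label() if imd else '-'} | "
                  f"selected={model.selected_candidates or '-'} | "
                  f"dropped={model.dropped_for_separation or '-'}")
    import pandas as pd

    pd.concat([search_log_frame(r) for r in logs],
              ignore_index=True).to_csv(RESULTS / "form_search_log.csv",
                                        index=False)
    print(f"\nWrote model_*_*.csv and form_search_log.csv to {RESULTS}")


if __name__ == "__main__":
    main()
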