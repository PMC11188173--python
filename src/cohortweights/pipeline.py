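"""End-to-end weight construction: functional forms → propensity models →
mini weights → trimming → longitudinal combination → census calibration.

:func:`run_weight_pipeline` is the one entry point the analysis scripts,
the bootstrap and the CLI all share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_design, required_columns
from .forms import FormSpec, select_form_by_aic
from .modelfit import c_statistic, fit_logit
from .selection import (
    FittedPropensityModel,
    build_model_spec,
    design_terms,
    outcome_column,
    stepwise_select,
)
from .weights import TrimConfig, WeightSet, calibrate_to_census, combine_longitudinal, compute_sweep_weights

log = logging.getLogger(__name__)

CONTINUOUS_DESIGN_VARS = ("age_years", "imd_decile")


@dataclass
class PipelineConfig:
    """Which stages of the weighting machinery to run and how."""

    sweeps: tuple[int, ...] = (3, 6, 12)
    stages: tuple[str, ...] = ("respond", "timely", "reinfected")
    #: AIC search over the functional-form menu for age and IMD; if False
    #: both enter linearly
    select_forms: bool = True
    #: stepwise refinement of candidate predictors; if False only the
    #: forced design covariates are fitted
    stepwise: bool = True
    interactions: bool = True
    questionnaire: bool = True
    longitudinal: bool = True
    calibrate: bool = True
    jan_mar_component: str = "response_only"
    trim: TrimConfig = field(default_factory=TrimConfig)

    def __post_init__(self) -> None:
        if self.longitudinal and not {6, 12} <= set(self.sweeps):
            raise ValueError("longitudinal weights need sweeps 6 and 12")


@dataclass
class PipelineResult:
    models: dict[int, dict[str, FittedPropensityModel | None]]
    forms: dict[tuple[int, str, str], FormSpec]
    weightsets: dict[int, WeightSet]
    combined: pd.DataFrame | None = None
    exclusions: pd.DataFrame | None = None
    calibrated: pd.Series | None = None
    calibrated_untrimmed: pd.Series | None = None
    ratios: pd.DataFrame | None = None
    #: per-sweep calibrated envisioned weights (single-sweep analyses)
    sweep_calibrated: dict[int, pd.Series] = field(default_factory=dict)
    form_search_logs: list = field(default_factory=list)


def _risk_set(cohort: pd.DataFrame, sweep: int, stage: str) -> pd.DataFrame:
    if stage == "respond":
        return cohort[cohort[f"available_{sweep}m"].astype(bool)]
    if stage == "timely":
        return cohort[cohort[f"responded_{sweep}m"] == 1]
    if stage == "reinfected":
        return cohort[cohort[f"timely_{sweep}m"] == 1]
    raise ValueError(f"unknown stage {stage!r}")


def select_model_forms(
    data: pd.DataFrame,
    outcome_col: str,
    include_index_status: bool,
) -> tuple[dict[str, FormSpec], list]:
    """Minimum-AIC functional forms for age then IMD, selected
    sequentially (the later search uses the earlier winner in its
    baseline)."""
    forms: dict[str, FormSpec] = {}
    logs = []
    chosen_age: FormSpec | None = None
    for var in CONTINUOUS_DESIGN_VARS:
        baseline = [
            t
            for t in design_terms(
                age_form=chosen_age, include_index_status=include_index_status
            )
            if var not in t.required_columns()
        ]
        needed = sorted(required_columns(baseline) | {var, outcome_col})
        sub = data.dropna(subset=[c for c in needed if c in data.columns])
        best, records = select_form_by_aic(sub, outcome_col, baseline, var)
        forms[var] = best
        logs.append(records)
        if var == "age_years":
            chosen_age = best
    return forms, logs


def fit_sweep_models(
    cohort: pd.DataFrame,
    sweep: int,
    config: PipelineConfig,
) -> tuple[dict[str, FittedPropensityModel | None],
           dict[tuple[int, str, str], FormSpec], list]:
    """Fit the (up to three) conditional-probability models at one sweep."""
    models: dict[str, FittedPropensityModel | None] = {}
    forms: dict[tuple[int, str, str], FormSpec] = {}
    search_logs: list = []
    for stage in ("respond", "timely", "reinfected"):
        if stage not in config.stages:
            models[stage] = None
            continue
        data = _risk_set(cohort, sweep, stage)
        ycol = outcome_column(stage, sweep)
        include_index = not (stage == "reinfected" and sweep == 3)

        age_form = imd_form = None
        if config.select_forms:
            chosen, logs = select_model_forms(data, ycol, include_index)
            age_form, imd_form = chosen["age_years"], chosen["imd_decile"]
            forms[(sweep, stage, "age_years")] = age_form
            forms[(sweep, stage, "imd_decile")] = imd_form
            search_logs.extend(logs)

        spec = build_model_spec(
            sweep,
            stage,
            age_form=age_form,
            imd_form=imd_form,
            interactions=config.interactions,
            questionnaire=config.questionnaire,
        )
        if not config.stepwise:
            spec.candidate_terms = []
        models[stage] = stepwise_select(data, ycol, spec, sweep)
        log.info(
            "sweep %sm %s model: n=%d, C=%.4f, selected=%s, dropped=%s",
            sweep, stage, models[stage].n_used, models[stage].c_statistic,
            models[stage].selected_candidates,
            models[stage].dropped_for_separation,
        )
    return models, forms, search_logs


def refit_models(
    cohort: pd.DataFrame,
    models: dict[int, dict[str, FittedPropensityModel | None]],
) -> dict[int, dict[str, FittedPropensityModel | None]]:
    """Re-estimate coefficients of already-specified models on new data
    (bootstrap replications keep the full-data term selection)."""
    out: dict[int, dict[str, FittedPropensityModel | None]] = {}
    for sweep, stage_models in models.items():
        out[sweep] = {}
        for stage, model in stage_models.items():
            if model is None:
                out[sweep][stage] = None
                continue
            data = _risk_set(cohort, sweep, stage)
            ycol = outcome_column(stage, sweep)
            needed = sorted(required_columns(model.terms) | {ycol})
            data = data.dropna(subset=needed)
            y = data[ycol].to_numpy(dtype=float)
            X, _ = build_design(data, model.terms)
            X = np.column_stack([np.ones(len(data)), X])
            res = fit_logit(y, X)
            probs = 1.0 / (1.0 + np.exp(-(X @ res.params)))
            out[sweep][stage] = FittedPropensityModel(
                outcome=model.outcome,
                sweep=sweep,
                terms=model.terms,
                coefficients=np.asarray(res.params),
                standard_errors=np.asarray(res.bse),
                column_names=model.column_names,
                c_statistic=c_statistic(probs, y),
                dropped_for_separation=model.dropped_for_separation,
                n_used=len(data),
                selected_candidates=model.selected_candidates,
            )
    return out


def run_weight_pipeline(
    cohort: pd.DataFrame,
    margins: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
    prefit_models: dict[int, dict[str, FittedPropensityModel | None]] | None = None,
) -> PipelineResult:
    """Fit models (unless ``prefit_models`` are supplied for coefficient
    refits), compute per-sweep weight sets, combine longitudinally and
    calibrate to census margins, as enabled in ``config``."""
    if config.calibrate and margins is None:
        raise ValueError("calibration requested but no census margins given")

    if prefit_models is not None:
        models = refit_models(cohort, prefit_models)
        forms: dict = {}
        logs: list = []
    else:
        models, forms, logs = {}, {}, []
        for sweep in config.sweeps:
            m, f, sl = fit_sweep_models(cohort, sweep, config)
            models[sweep] = m
            forms.update(f)
            logs.extend(sl)

    weightsets = {
        sweep: compute_sweep_weights(cohort, models[sweep], sweep, config.trim)
        for sweep in config.sweeps
    }
    result = PipelineResult(
        models=models, forms=forms, weightsets=weightsets,
        form_search_logs=logs,
    )

    if config.longitudinal:
        combined, exclusions = combine_longitudinal(
            weightsets, cohort, config.trim, config.jan_mar_component)
        result.combined = combined
        result.exclusions = exclusions
        if config.calibrate:
            result.calibrated, result.ratios = calibrate_to_census(
                combined["w_combined_trimmed"], cohort, margins)
            result.calibrated_untrimmed, _ = calibrate_to_census(
                combined["w_combined"], cohort, margins)
    elif config.calibrate:
        for sweep in config.sweeps:
            cal, ratios = calibrate_to_census(
                weightsets[sweep].frame["w_envisioned_trimmed"],
                cohort, margins)
            result.sweep_calibrated[sweep] = cal
            result.ratios = ratios
    return result
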