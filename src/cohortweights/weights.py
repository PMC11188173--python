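"""From fitted conditional probabilities to final survey weights.

The weighting is sequential: at each sweep the analytic sample (timely,
non-(re)infected responders) is re-weighted back to the *envisioned
population* by the product of three mini weights, each the reciprocal of
one conditional retention probability:

* ``w_response``    = 1 / Pr(responded | envisioned)
* ``w_timely``      = 1 / Pr(timely | responded)
* ``w_reinfection`` = 1 / Pr(not (re)infected | timely)  — the retained
  group at this stage is the non-(re)infected, so the retention
  probability is the complement of the modelled (re)infection risk
* ``w_envisioned``  = the product of the three

Weights are trimmed at median + k×IQR (k = 3 by default) and rescaled to
preserve their sum; longitudinal target-population weights multiply
untrimmed per-sweep components and are trimmed once at the end; final
weights can be calibrated to external census margins by per-cell ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import required_columns
from .selection import FittedPropensityModel
from .synthetic import age_band_label

STAGES = ("respond", "timely", "reinfected")


def mini_weight(p_retained):
    """Reciprocal of a conditional retention probability."""
    p = np.asarray(p_retained, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("retention probabilities must lie in (0, 1]")
    out = 1.0 / p
    return float(out) if np.isscalar(p_retained) else out


@dataclass(frozen=True)
class TrimConfig:
    """Weight-trimming rule: cap at median + k × IQR, then rescale all
    weights by a common factor so the sum is unchanged."""

    k: float = 3.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("trim constant k must be positive")


@dataclass
class TrimMetadata:
    cutoff: float
    k: float
    rescale_factor: float
    n_capped: int


def trim_weights(weights, config: TrimConfig = TrimConfig()
                 ) -> tuple[np.ndarray, TrimMetadata]:
    """Cap extreme weights and restore the original sum.

    Quartiles use linear-interpolation quantiles (the package's fixed
    convention).  The returned sum equals the input sum to 1e-9 relative.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot trim an empty weight vector")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    q1, med, q3 = np.quantile(w, [0.25, 0.5, 0.75], method="linear")
    cutoff = med + config.k * (q3 - q1)
    capped = np.minimum(w, cutoff)
    factor = w.sum() / capped.sum()
    return capped * factor, TrimMetadata(
        cutoff=float(cutoff), k=config.k, rescale_factor=float(factor),
        n_capped=int((w > cutoff).sum()))


@dataclass
class WeightSet:
    """Per-person weights for one sweep.

    ``frame`` is indexed by person id with columns ``w_response``,
    ``w_timely``, ``w_reinfection``, ``w_envisioned`` (NaN where the
    person is outside the relevant risk set or excluded), their
    ``*_trimmed`` variants, and the boolean
    ``excluded_missing_covariates``.
    """

    sweep: int
    frame: pd.DataFrame
    trim_metadata: dict[str, TrimMetadata] = field(default_factory=dict)

    def weights(self, kind: str = "w_envisioned", trimmed: bool = False
                ) -> pd.Series:
        col = f"{kind}_trimmed" if trimmed else kind
        return self.frame[col].dropna()


def compute_sweep_weights(
    cohort: pd.DataFrame,
    models: dict[str, FittedPropensityModel | None],
    sweep: int,
    trim: TrimConfig = TrimConfig(),
) -> WeightSet:
    """Assign the three mini weights and the envisioned-population weight
    at one sweep.

    ``models`` maps stage name to its fitted model; a ``None`` entry means
    that stage's retention probability is taken as 1 (used by reduced
    simulation designs).  Persons inside a stage's risk set but with
    missing values on that stage's model covariates are flagged
    ``excluded_missing_covariates`` and receive no weight.
    """
    for stage, model in models.items():
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if model is not None and model.sweep != sweep:
            raise ValueError(
                f"model for stage {stage!r} was fitted at sweep "
                f"{model.sweep}, not {sweep}")

    s = sweep
    envisioned = cohort[f"available_{s}m"].fillna(False).astype(bool)
    responded = cohort[f"responded_{s}m"] == 1
    timely = cohort[f"timely_{s}m"] == 1
    analytic = timely & (cohort[f"reinfected_{s}m"] == 0)

    frame = pd.DataFrame(index=cohort["id"].to_numpy())
    frame.index.name = "id"
    for col in ("w_response", "w_timely", "w_reinfection", "w_envisioned"):
        frame[col] = np.nan
    excluded = np.zeros(len(cohort), dtype=bool)

    def stage_probs(stage: str, risk: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        """(probability of retention for risk rows, complete-row mask)."""
        model = models.get(stage)
        if model is None:
            return np.ones(int(risk.sum())), np.ones(int(risk.sum()), bool)
        req = sorted(required_columns(model.terms))
        sub = cohort.loc[risk]
        complete = sub[req].notna().all(axis=1).to_numpy() if req else \
            np.ones(len(sub), bool)
        p = np.full(len(sub), np.nan)
        if complete.any():
            pr = model.predict(sub.loc[complete])
            p[complete] = pr if stage != "reinfected" else 1.0 - pr
        return p, complete

    # response stage: modelled over the envisioned population, weight
    # assigned to responders
    p, _ = stage_probs("respond", envisioned)
    w = np.full(len(cohort), np.nan)
    w[envisioned.to_numpy()] = 1.0 / p
    excluded |= responded.to_numpy() & np.isnan(w)
    frame.loc[responded.to_numpy(), "w_response"] = w[responded.to_numpy()]

    p, _ = stage_probs("timely", responded)
    w = np.full(len(cohort), np.nan)
    w[responded.to_numpy()] = 1.0 / p
    excluded |= timely.to_numpy() & np.isnan(w)
    frame.loc[timely.to_numpy(), "w_timely"] = w[timely.to_numpy()]

    p, _ = stage_probs("reinfected", timely)
    w = np.full(len(cohort), np.nan)
    w[timely.to_numpy()] = 1.0 / p
    excluded |= analytic.to_numpy() & np.isnan(w)
    frame.loc[analytic.to_numpy(), "w_reinfection"] = w[analytic.to_numpy()]

    frame["w_envisioned"] = (frame["w_response"] * frame["w_timely"]
                             * frame["w_reinfection"])
    frame["excluded_missing_covariates"] = excluded

    meta: dict[str, TrimMetadata] = {}
    ws = WeightSet(sweep=sweep, frame=frame, trim_metadata=meta)
    for col in ("w_response", "w_timely", "w_reinfection", "w_envisioned"):
        defined = frame[col].notna()
        frame[f"{col}_trimmed"] = np.nan
        if defined.any():
            trimmed, md = trim_weights(frame.loc[defined, col].to_numpy(), trim)
            frame.loc[defined, f"{col}_trimmed"] = trimmed
            meta[col] = md
    return ws


JAN_MAR = ("2021-01", "2021-02", "2021-03")
OCT_DEC = ("2020-10", "2020-11", "2020-12")


def combine_longitudinal(
    weightsets: dict[int, WeightSet],
    cohort: pd.DataFrame,
    trim: TrimConfig = TrimConfig(),
    jan_mar_component: str = "response_only",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-sweep weights into longitudinal target-population
    weights (target: everyone envisioned at the 6-month sweep).

    Inclusion and components by month-of-test cohort:

    * January–March 2021 testers must have completed the 3-month
      questionnaire (which carries their baseline symptom report) and be in
      the 6- and 12-month analytic samples; their weight multiplies the
      untrimmed 3-month response mini weight (or, with
      ``jan_mar_component="envisioned"``, the full 3-month envisioned
      weight) by the untrimmed 6- and 12-month envisioned weights.
    * October–December 2020 testers must be in the 6- and 12-month
      analytic samples; their weight multiplies the untrimmed 6- and
      12-month envisioned weights.
    * September-2020 testers have no 6-month sweep and are excluded.

    The combined weight is trimmed once.  Returns ``(combined,
    exclusions)``: the first indexed by id with ``w_combined`` and
    ``w_combined_trimmed``, the second listing excluded persons and why.
    """
    if jan_mar_component not in ("response_only", "envisioned"):
        raise ValueError(f"unknown jan_mar_component {jan_mar_component!r}")
    for s in (6, 12):
        if s not in weightsets:
            raise ValueError(f"longitudinal combination needs sweep {s} weights")

    month = cohort["month_of_test"]
    ids = cohort["id"].to_numpy()
    w6 = weightsets[6].frame["w_envisioned"].reindex(ids).to_numpy()
    w12 = weightsets[12].frame["w_envisioned"].reindex(ids).to_numpy()

    component3_col = ("w_response" if jan_mar_component == "response_only"
                      else "w_envisioned")

    combined = np.full(len(cohort), np.nan)
    reasons: list[tuple[int, str]] = []

    jan_mar = month.isin(JAN_MAR).to_numpy()
    oct_dec = month.isin(OCT_DEC).to_numpy()
    sep = ~jan_mar & ~oct_dec

    if jan_mar.any():
        if 3 not in weightsets:
            raise ValueError("January–March testers need sweep-3 weights")
        w3 = weightsets[3].frame[component3_col].reindex(ids).to_numpy()
        resp3 = (cohort["responded_3m"] == 1).to_numpy()
    for i in np.flatnonzero(jan_mar | oct_dec):
        if jan_mar[i]:
            if not resp3[i]:
                reasons.append((ids[i], "no 3-month questionnaire"))
                continue
            if np.isnan(w3[i]):
                reasons.append((ids[i], "no 3-month weight"))
                continue
        if np.isnan(w6[i]):
            reasons.append((ids[i], "not in 6-month analytic sample"))
            continue
        if np.isnan(w12[i]):
            reasons.append((ids[i], "not in 12-month analytic sample"))
            continue
        combined[i] = (w3[i] if jan_mar[i] else 1.0) * w6[i] * w12[i]
    for i in np.flatnonzero(sep):
        reasons.append((ids[i], "no 6-month sweep for month of test"))

    out = pd.DataFrame({"w_combined": combined}, index=ids)
    out.index.name = "id"
    defined = out["w_combined"].notna()
    out["w_combined_trimmed"] = np.nan
    if defined.any():
        trimmed, md = trim_weights(out.loc[defined, "w_combined"].to_numpy(),
                                   trim)
        out.loc[defined, "w_combined_trimmed"] = trimmed
        out.attrs["trim_metadata"] = md
    exclusions = pd.DataFrame(reasons, columns=["id", "reason"])
    return out, exclusions


def census_cells(cohort: pd.DataFrame) -> pd.Series:
    """Sex × age-band × region calibration cell of each person."""
    bands = cohort["age_years"].map(age_band_label)
    return (cohort["sex"].astype(str) + "|" + bands + "|"
            + cohort["region"].astype(str))


def calibrate_to_census(
    weights: pd.Series,
    cohort: pd.DataFrame,
    margins: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Multiply weights by per-cell census-to-sample ratios.

    ``weights`` is indexed by person id (NaN or absent = not in the
    weighted sample); ``margins`` has columns sex, age_band, region,
    count.  After calibration each occupied cell's weighted total equals
    its census count.  An occupied cell missing from the margins is an
    error; a census cell with no weighted sample is reported with a
    warning (that stratum is unrepresentable).
    """
    margin_key = (margins["sex"].astype(str) + "|"
                  + margins["age_band"].astype(str) + "|"
                  + margins["region"].astype(str))
    if margin_key.duplicated().any():
        raise ValueError("duplicate cells in census margins")
    margin_counts = pd.Series(margins["count"].to_numpy(), index=margin_key)
    if (margin_counts < 0).any():
        raise ValueError("census margin counts must be non-negative")

    cells = census_cells(cohort).to_numpy()
    cell_by_id = pd.Series(cells, index=cohort["id"].to_numpy())
    w = weights.dropna()
    sample_cells = cell_by_id.reindex(w.index)
    totals = w.groupby(sample_cells).sum()

    missing = sorted(set(totals.index) - set(margin_counts.index))
    if missing:
        raise ValueError(f"occupied sample cells absent from margins: {missing}")
    empty = margin_counts.index[(margin_counts > 0)
                                & ~margin_counts.index.isin(totals.index)]
    if len(empty):
        warnings.warn(
            f"{len(empty)} census cells have no weighted sample and cannot "
            "be represented", stacklevel=2)

    ratios = margin_counts.reindex(totals.index) / totals
    calibrated = w * ratios.reindex(sample_cells).to_numpy()
    ratio_frame = pd.DataFrame({
        "cell": totals.index,
        "weighted_total": totals.to_numpy(),
        "margin": margin_counts.reindex(totals.index).to_numpy(),
        "ratio": ratios.to_numpy(),
    })
    parts = ratio_frame["cell"].str.split("|", expand=True)
    ratio_frame[["sex", "age_band", "region"]] = parts
    return calibrated, ratio_frame.drop(columns="cell")
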