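"""Weighted prevalence estimation, sample accounting and the bootstrap.

Prevalences are Hájek-style weighted proportions, reported as
percentages.  The bootstrap resamples *persons from the envisioned
population* with replacement and reruns model fitting and weight
construction inside every replication, so the resulting percentile
intervals propagate the uncertainty of the estimated weights — treating
weights as known would overstate precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .design import build_design, required_columns
from .modelfit import FitError, fit_logit
from .pipeline import PipelineConfig, PipelineResult, run_weight_pipeline
from .synthetic import SWEEP_TIMEPOINT
from .weights import trim_weights

log = logging.getLogger(__name__)

SYMPTOM_NAMES = ("tired", "breathless")
GROUPS = ("Negative", "Positive", "All")
TIMEPOINTS = (0, 6, 12)


def weighted_prevalence(indicators, weights=None) -> float:
    """100 × Σ(w·I) / Σw; with ``weights=None`` every w is 1."""
    y = np.asarray(indicators, dtype=float)
    if y.size == 0:
        raise ValueError("empty group: no rows to estimate a prevalence from")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape:
        raise ValueError("indicators and weights differ in length")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return float(100.0 * (w * y).sum() / total)


def _group_mask(cohort: pd.DataFrame, group: str) -> np.ndarray:
    if group == "All":
        return np.ones(len(cohort), dtype=bool)
    return (cohort["index_status"] == group).to_numpy()


def _prevalence_rows(
    cohort: pd.DataFrame,
    weight_variants: dict[str, pd.Series],
    symptoms,
    groups,
    timepoints,
) -> pd.DataFrame:
    """Tidy prevalence table over every symptom × group × timepoint ×
    weight variant.  Each variant's Series is indexed by person id; NaN or
    missing ids are outside that variant's weighted sample."""
    ids = cohort["id"].to_numpy()
    rows = []
    for variant, wser in weight_variants.items():
        w_all = wser.reindex(ids).to_numpy() if wser is not None else np.ones(
            len(ids))
        for symptom in symptoms:
            for t in timepoints:
                obs = cohort[f"obs_{symptom}_{t}"].to_numpy(dtype=float)
                for group in groups:
                    m = (_group_mask(cohort, group) & ~np.isnan(w_all)
                         & ~np.isnan(obs))
                    if not m.any():
                        continue
                    rows.append({
                        "symptom": symptom, "timepoint": t, "group": group,
                        "variant": variant,
                        "value": weighted_prevalence(obs[m], w_all[m]),
                        "n": int(m.sum()),
                    })
    return pd.DataFrame(rows)


def pipeline_estimates(
    cohort: pd.DataFrame,
    result: PipelineResult,
    config: PipelineConfig,
    symptoms=SYMPTOM_NAMES,
    groups=GROUPS,
    timepoints=TIMEPOINTS,
) -> pd.DataFrame:
    """Prevalence table for a fitted pipeline.

    Longitudinal runs report the unweighted, target-population (combined,
    trimmed and untrimmed) and census-calibrated variants over the
    longitudinal analytic sample.  Single-sweep runs report unweighted and
    envisioned-population variants per sweep at the sweep's matching
    timepoint.
    """
    if config.longitudinal and result.combined is not None:
        base = result.combined["w_combined"]
        in_sample = base.dropna()
        variants: dict[str, pd.Series | None] = {
            # unweighted over the same analytic sample
            "unweighted": pd.Series(1.0, index=in_sample.index),
            "target": base,
            "target_trimmed": result.combined["w_combined_trimmed"],
        }
        if result.calibrated is not None:
            variants["census_trimmed"] = result.calibrated
            variants["census"] = result.calibrated_untrimmed
        return _prevalence_rows(cohort, variants, symptoms, groups, timepoints)

    frames = []
    for sweep, ws in result.weightsets.items():
        t = SWEEP_TIMEPOINT[sweep]
        base = ws.frame["w_envisioned"]
        variants = {
            "unweighted": pd.Series(1.0, index=base.dropna().index),
            "envisioned": base,
            "envisioned_trimmed": ws.frame["w_envisioned_trimmed"],
        }
        if sweep in result.sweep_calibrated:
            variants["census_trimmed"] = result.sweep_calibrated[sweep]
        sub = _prevalence_rows(cohort, variants, symptoms, groups, (t,))
        sub["sweep"] = sweep
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def first_report_table(
    cohort: pd.DataFrame,
    weights: pd.Series,
    symptom: str,
) -> pd.DataFrame:
    """Weighted prevalence by the earliest timepoint of symptom report.

    Persons are classified by the first of 0/6/12 months at which they
    report the symptom ("never" otherwise); percentages use the supplied
    longitudinal weights, and the cumulative column at each timepoint is
    the weighted share who have ever reported by then.
    """
    w = weights.dropna()
    sub = cohort.set_index("id").loc[w.index]
    obs = np.column_stack([
        sub[f"obs_{symptom}_{t}"].to_numpy(dtype=float) for t in TIMEPOINTS])
    if np.isnan(obs).any():
        keep = ~np.isnan(obs).any(axis=1)
        obs, w = obs[keep], w[keep]
    first = np.full(len(w), -1)
    for j in range(len(TIMEPOINTS) - 1, -1, -1):
        first[obs[:, j] == 1] = TIMEPOINTS[j]
    wsum = w.to_numpy().sum()
    rows, cum = [], 0.0
    for t in TIMEPOINTS:
        pct = 100.0 * w.to_numpy()[first == t].sum() / wsum
        cum += pct
        rows.append({"first_report": str(t), "percent": pct,
                     "cumulative_percent": cum})
    rows.append({"first_report": "never",
                 "percent": 100.0 * w.to_numpy()[first == -1].sum() / wsum,
                 "cumulative_percent": 100.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample accounting


def retention_percentage(analytic: int, envisioned: int) -> int:
    """Analytic-over-envisioned share, rounded to the nearest integer."""
    if analytic > envisioned:
        raise ValueError("analytic sample exceeds the envisioned population")
    if envisioned <= 0:
        raise ValueError("envisioned population must be positive")
    return int(np.floor(100.0 * analytic / envisioned + 0.5))


def sample_accounting(flows: pd.DataFrame) -> pd.DataFrame:
    """Flow table with retention percentages.

    ``flows`` needs columns sweep, envisioned, responded, timely,
    analytic; the four counts must be non-increasing along the nesting.
    """
    required = ["sweep", "envisioned", "responded", "timely", "analytic"]
    missing = [c for c in required if c not in flows.columns]
    if missing:
        raise ValueError(f"flow table lacks columns {missing}")
    out = flows.copy()
    for _, row in out.iterrows():
        chain = [row["envisioned"], row["responded"], row["timely"],
                 row["analytic"]]
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise ValueError(
                f"counts increase along the nesting at sweep {row['sweep']}")
    out["retention_pct"] = [
        retention_percentage(int(a), int(e))
        for a, e in zip(out["analytic"], out["envisioned"])
    ]
    return out


def flow_counts(cohort: pd.DataFrame, sweeps=(3, 6, 12)) -> pd.DataFrame:
    """Observed per-sweep nested stage counts of a cohort table."""
    rows = []
    for s in sweeps:
        envisioned = int(cohort[f"available_{s}m"].astype(bool).sum())
        responded = int((cohort[f"responded_{s}m"] == 1).sum())
        timely = int((cohort[f"timely_{s}m"] == 1).sum())
        analytic = int(((cohort[f"timely_{s}m"] == 1)
                        & (cohort[f"reinfected_{s}m"] == 0)).sum())
        rows.append({"sweep": s, "envisioned": envisioned,
                     "responded": responded, "timely": timely,
                     "analytic": analytic})
    return sample_accounting(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapConfig:
    """Percentile bootstrap over persons in the envisioned population."""

    replications: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    #: resample within index-status strata (matched-at-invitation designs)
    stratify_by_index: bool = False
    #: repeat the functional-form search inside each replication (the
    #: default keeps the full-data forms and refits coefficients only)
    refit_forms: bool = False
    #: repeat stepwise selection inside each replication
    refit_stepwise: bool = False
    max_dropped_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def _resample_indices(rng, cohort: pd.DataFrame, stratify: bool) -> np.ndarray:
    n = len(cohort)
    if not stratify:
        return rng.integers(0, n, n)
    idx = []
    for _, grp in cohort.groupby("index_status", sort=True):
        pos = cohort.index.get_indexer(grp.index)
        idx.append(pos[rng.integers(0, len(pos), len(pos))])
    return np.concatenate(idx)


def _fast_path_applicable(cohort, margins, config: PipelineConfig,
                          bconfig: BootstrapConfig) -> bool:
    if (config.longitudinal or config.calibrate or margins is not None
            or len(config.sweeps) != 1 or config.stages != ("respond",)
            or bconfig.refit_forms or bconfig.refit_stepwise):
        return False
    return True


def bootstrap_prevalence(
    cohort: pd.DataFrame,
    margins: pd.DataFrame | None,
    config: PipelineConfig,
    bconfig: BootstrapConfig,
    symptoms=SYMPTOM_NAMES,
    groups=GROUPS,
    timepoints=TIMEPOINTS,
) -> pd.DataFrame:
    """Point estimates with percentile confidence bounds.

    The full-data pipeline is run once for the point estimates (and, by
    default, to fix functional forms and selected terms); each replication
    then resamples persons with replacement, refits the models and
    recomputes weights and prevalences.  Replications in which any model
    cannot be fitted (e.g. a one-class outcome) are dropped and counted;
    more than ``max_dropped_fraction`` dropped is an error.  A fixed seed
    reproduces the intervals exactly.
    """
    full = run_weight_pipeline(cohort, margins, config)
    point = pipeline_estimates(cohort, full, config, symptoms, groups,
                               timepoints)
    keys = ["symptom", "timepoint", "group", "variant"] + (
        ["sweep"] if "sweep" in point.columns else [])

    rng = np.random.default_rng(bconfig.seed)
    if _fast_path_applicable(cohort, margins, config, bconfig):
        reps, dropped = _fast_single_stage_reps(
            cohort, full, config, bconfig, rng, symptoms, groups, timepoints)
    else:
        reps, dropped = _general_reps(
            cohort, margins, full, config, bconfig, rng, symptoms, groups,
            timepoints, keys)

    if dropped > bconfig.max_dropped_fraction * bconfig.replications:
        raise RuntimeError(
            f"{dropped}/{bconfig.replications} bootstrap replications failed")

    alpha = (1.0 - bconfig.ci_level) / 2.0
    out = point.set_index(keys)
    lo = pd.Series(np.nan, index=out.index)
    hi = pd.Series(np.nan, index=out.index)
    nrep = pd.Series(0, index=out.index)
    for key, values in reps.items():
        v = np.asarray(values)
        if key in out.index and len(v):
            lo[key] = np.quantile(v, alpha)
            hi[key] = np.quantile(v, 1.0 - alpha)
            nrep[key] = len(v)
    out["ci_low"] = lo
    out["ci_high"] = hi
    out["n_replications"] = nrep
    out.attrs["dropped_replications"] = dropped
    return out.reset_index()


def _general_reps(cohort, margins, full, config, bconfig, rng, symptoms,
                  groups, timepoints, keys):
    reps: dict[tuple, list[float]] = {}
    dropped = 0
    refit_all = bconfig.refit_forms or bconfig.refit_stepwise
    rep_config = config
    if refit_all:
        from dataclasses import replace as _replace
        rep_config = _replace(config, select_forms=bconfig.refit_forms,
                              stepwise=bconfig.refit_stepwise)
    for _ in range(bconfig.replications):
        idx = _resample_indices(rng, cohort, bconfig.stratify_by_index)
        boot = cohort.iloc[idx].reset_index(drop=True)
        boot = boot.assign(id=np.arange(len(boot)))
        try:
            res = run_weight_pipeline(
                boot, margins, rep_config,
                prefit_models=None if refit_all else full.models)
            est = pipeline_estimates(boot, res, config, symptoms, groups,
                                     timepoints)
        except (FitError, ValueError, RuntimeError) as exc:
            log.warning("bootstrap replication dropped: %s", exc)
            dropped += 1
            continue
        for _, row in est.iterrows():
            key = tuple(row[k] for k in keys)
            reps.setdefault(key, []).append(row["value"])
    return reps, dropped


def _fast_single_stage_reps(cohort, full, config, bconfig, rng, symptoms,
                            groups, timepoints):
    """Array-based replication loop for the reduced one-model design
    (single sweep, response stage only, no calibration).  Produces the
    same estimator as the general path, just without per-replication
    DataFrame construction."""
    (sweep,) = config.sweeps
    t_sweep = SWEEP_TIMEPOINT[sweep]
    timepoints = tuple(t for t in timepoints if t == t_sweep) or (t_sweep,)
    model = full.models[sweep]["respond"]

    req = sorted(required_columns(model.terms))
    complete = cohort[req].notna().all(axis=1).to_numpy() if req else \
        np.ones(len(cohort), bool)
    if not complete.all():
        raise RuntimeError("fast bootstrap path requires complete covariates")
    X_all, _ = build_design(cohort, model.terms)
    X_all = np.column_stack([np.ones(len(cohort)), X_all])
    avail = cohort[f"available_{sweep}m"].astype(bool).to_numpy()
    responded = (cohort[f"responded_{sweep}m"] == 1).to_numpy()
    analytic = ((cohort[f"timely_{sweep}m"] == 1)
                & (cohort[f"reinfected_{sweep}m"] == 0)).to_numpy()
    obs = {
        s: cohort[f"obs_{s}_{t_sweep}"].to_numpy(dtype=float)
        for s in symptoms
    }
    gmask = {g: _group_mask(cohort, g) for g in groups}

    reps: dict[tuple, list[float]] = {}
    dropped = 0
    for _ in range(bconfig.replications):
        idx = _resample_indices(rng, cohort, bconfig.stratify_by_index)
        a = avail[idx]
        rows = idx[a]
        y = responded[rows].astype(float)
        try:
            res = fit_logit(y, X_all[rows])
        except FitError:
            dropped += 1
            continue
        p = special.expit(X_all[rows] @ res.params)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        in_analytic = analytic[rows]
        w = 1.0 / p[in_analytic]
        wt, _ = trim_weights(w, config.trim)
        arows = rows[in_analytic]
        for s in symptoms:
            yobs = obs[s][arows]
            ok = ~np.isnan(yobs)
            for g in groups:
                m = gmask[g][arows] & ok
                if not m.any():
                    continue
                for variant, ww in (("unweighted", None),
                                    ("envisioned", w),
                                    ("envisioned_trimmed", wt)):
                    val = weighted_prevalence(
                        yobs[m], None if ww is None else ww[m])
                    key = (s, t_sweep, g, variant, sweep)
                    reps.setdefault(key, []).append(val)
    return reps, dropped
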