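"""Propensity-model specification and stepwise refinement.

Three conditional-probability logistic models are fitted per sweep:

* ``respond``    — Pr(responding | envisioned to take part)
* ``timely``     — Pr(responding timely | responded)
* ``reinfected`` — Pr((re)infected | timely response)

Each model forces the design covariates used for matching (sex, age,
region, index SARS-CoV-2 status, IMD — age and IMD under their selected
functional forms) and refines a candidate list by forward (p < 0.157) /
backward (p >= 0.200 removes) stepwise selection on joint Wald tests per
term block.  The response model's candidates are all two-way interactions
of the design covariates (no questionnaire data exists for
non-responders); the timely and (re)infection models consider current
questionnaire measures.  The index-status exception: a test-positive
person cannot be reinfected within 3 months of the positive episode, so
index status is excluded from the 3-month (re)infection model entirely.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    CategoricalTerm,
    FormTerm,
    InteractionTerm,
    NumericTerm,
    Term,
    build_design,
    freeze_terms,
    required_columns,
    term_slices,
)
from .forms import FormSpec
from .modelfit import FitError, c_statistic, fit_logit, wald_block_p

log = logging.getLogger(__name__)

OUTCOMES = ("respond", "timely", "reinfected")

#: separation heuristics on the logit scale — far outside any plausible
#: effect in this design
SEPARATION_COEF = 15.0
SEPARATION_SE = 100.0


@dataclass
class StepwiseConfig:
    """Forward/backward stepwise settings for one propensity model."""

    forced_terms: list[Term]
    candidate_terms: list[Term]
    p_enter: float = 0.157
    p_remove: float = 0.200
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.p_enter < 1 and 0 < self.p_remove < 1):
            raise ValueError("stepwise thresholds must lie in (0, 1)")
        forced = {t.name for t in self.forced_terms}
        cand = {t.name for t in self.candidate_terms}
        if forced & cand:
            raise ValueError(f"terms both forced and candidate: {forced & cand}")


@dataclass
class FittedPropensityModel:
    """One fitted conditional-probability model."""

    outcome: str
    sweep: int
    terms: list[Term]  # frozen; order matches the coefficient blocks
    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    column_names: list[str]
    c_statistic: float
    dropped_for_separation: list[str]
    n_used: int
    selected_candidates: list[str] = field(default_factory=list)
    search_log: list[dict] = field(default_factory=list)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(data, self.terms)
        return np.column_stack([np.ones(len(data)), X])

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted probabilities, clipped into the open interval (0, 1)."""
        eta = self.design(data) @ self.coefficients
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["(intercept)"] + self.column_names,
                "estimate": self.coefficients,
                "se": self.standard_errors,
            }
        )


def outcome_column(outcome: str, sweep: int) -> str:
    if outcome == "respond":
        return f"responded_{sweep}m"
    if outcome == "timely":
        return f"timely_{sweep}m"
    if outcome == "reinfected":
        return f"reinfected_{sweep}m"
    raise ValueError(f"unknown outcome {outcome!r}")


def design_terms(
    age_form: FormSpec | None = None,
    imd_form: FormSpec | None = None,
    include_index_status: bool = True,
) -> list[Term]:
    """The forced design-covariate terms (matching variables)."""
    age = FormTerm(age_form) if age_form else NumericTerm("age_years")
    imd = FormTerm(imd_form) if imd_form else NumericTerm("imd_decile")
    terms: list[Term] = [CategoricalTerm("sex"), age, CategoricalTerm("region")]
    if include_index_status:
        terms.append(CategoricalTerm("index_status"))
    terms.append(imd)
    return terms


def questionnaire_candidates(sweep: int) -> list[Term]:
    """Current-questionnaire measures eligible for the timely and
    (re)infection models."""
    s = sweep
    return [
        CategoricalTerm("ethnicity"),
        CategoricalTerm(f"vacc_{s}m"),
        NumericTerm(f"phealth_{s}m"),
        NumericTerm(f"lonely_{s}m"),
        NumericTerm(f"nsympt_{s}m"),
        NumericTerm(f"swemws_{s}m"),
        NumericTerm(f"eqvas_{s}m"),
        NumericTerm(f"eq5dy_{s}m"),
        NumericTerm(f"sdq_{s}m"),
        NumericTerm(f"cfs_{s}m"),
    ]


def build_model_spec(
    sweep: int,
    outcome: str,
    age_form: FormSpec | None = None,
    imd_form: FormSpec | None = None,
    interactions: bool = True,
    questionnaire: bool = True,
) -> StepwiseConfig:
    """Model architecture for one (sweep, outcome) pair.

    ``interactions``/``questionnaire`` switch off the candidate sets for
    reduced (e.g. simulation-study) configurations; the forced design
    covariates are unaffected.
    """
    if sweep not in (3, 6, 12):
        raise ValueError(f"unknown sweep {sweep!r}")
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")

    include_index = not (outcome == "reinfected" and sweep == 3)
    forced = design_terms(age_form, imd_form, include_index_status=include_index)

    candidates: list[Term] = []
    if outcome == "respond":
        if interactions:
            candidates = [
                InteractionTerm(a, b) for a, b in itertools.combinations(forced, 2)
            ]
    elif questionnaire:
        candidates = questionnaire_candidates(sweep)
    return StepwiseConfig(forced_terms=forced, candidate_terms=candidates)


# ---------------------------------------------------------------------------
# separation handling


def _categorical_separation(
    data: pd.DataFrame, y: np.ndarray, term: Term
) -> bool:
    """True if any level of a categorical term perfectly predicts ``y``."""
    if not isinstance(term, CategoricalTerm):
        return False
    values = data[term.column].astype(str).to_numpy()
    for lv in pd.unique(values):
        sub = y[values == lv]
        if len(sub) > 0 and (sub.min() == 1 or sub.max() == 0):
            return True
    return False


def drop_perfect_predictors(
    data: pd.DataFrame,
    outcome: str,
    terms: Sequence[Term],
) -> tuple[list[Term], list[str]]:
    """Remove variables that perfectly predict the outcome.

    Detection is two-stage: (i) any categorical level whose outcome is
    constant; (ii) a converged fit with a coefficient beyond ±15 on the
    logit scale or a standard error beyond 100, both far outside plausible
    effects here.  Offending variables are removed and reported, and the
    check repeats until the remaining fit is clean.
    """
    y = data[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome!r} is constant; no model possible")

    kept = list(terms)
    dropped: list[str] = []

    changed = True
    while changed:
        changed = False
        for t in list(kept):
            if _categorical_separation(data, y, t):
                kept.remove(t)
                dropped.append(t.name)
                changed = True

    while kept:
        X, _ = build_design(data, kept)
        X = np.column_stack([np.ones(len(data)), X])
        try:
            res = fit_logit(y, X)
        except FitError:
            # cannot attribute failure to a single variable: drop the last
            # (least-core) term and retry
            t = kept.pop()
            dropped.append(t.name)
            continue
        flags = (np.abs(res.std_params[1:]) > SEPARATION_COEF) | (
            res.std_bse[1:] > SEPARATION_SE
        )
        if not flags.any():
            break
        offending = int(np.flatnonzero(flags)[0])
        for t, sl in zip(kept, term_slices(freeze_terms(data, kept))):
            if sl.start <= offending < sl.stop:
                kept.remove(t)
                dropped.append(t.name)
                break
    return kept, dropped


# ---------------------------------------------------------------------------
# stepwise selection


def stepwise_select(
    data: pd.DataFrame,
    outcome: str,
    config: StepwiseConfig,
    sweep: int = 0,
) -> FittedPropensityModel:
    """Forward/backward stepwise refinement around the forced terms.

    Complete-case: rows with missing values on any forced or candidate
    variable are excluded (``n_used`` records the rows fitted).  Forward
    steps add the candidate with the smallest joint Wald p-value when it is
    below ``p_enter``; backward steps remove the included candidate with
    the largest p-value when it is at or above ``p_remove``.  Forced terms
    are never removed.  A visited-state set guards against cycling (possible
    since ``p_enter < p_remove``).
    """
    ycol = outcome_column(outcome, sweep) if outcome in OUTCOMES else outcome
    if ycol not in data.columns:
        ycol = outcome  # caller passed a raw column name
    needed = required_columns(config.forced_terms + config.candidate_terms) | {ycol}
    missing_cols = needed - set(data.columns)
    if missing_cols:
        raise KeyError(f"cohort table lacks columns {sorted(missing_cols)}")
    rows = data[sorted(needed)].notna().all(axis=1)
    df = data.loc[rows]
    if df.empty:
        raise ValueError("empty risk set after complete-case restriction")
    y = df[ycol].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(f"outcome {ycol!r} is constant; no model possible")

    forced, dropped = drop_perfect_predictors(df, ycol, config.forced_terms)
    forced = freeze_terms(df, forced)
    candidates = freeze_terms(df, config.candidate_terms)
    # candidates with their own separation problem are removed up front
    clean_cands = []
    for t in candidates:
        if _categorical_separation(df, y, t):
            dropped.append(t.name)
        else:
            clean_cands.append(t)
    candidates = clean_cands

    blocks: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for t in forced + candidates:
        cols, nm = t.columns(df)
        blocks[t.name] = cols
        names[t.name] = nm

    def stack(included: list[Term]):
        terms = forced + included
        X = np.column_stack([np.ones(len(df))] + [blocks[t.name] for t in terms])
        return X, terms

    def block_idx(terms: list[Term], target: Term) -> np.ndarray:
        start = 1  # intercept
        for t in terms:
            w = t.width()
            if t.name == target.name:
                return np.arange(start, start + w)
            start += w
        raise KeyError(target.name)

    included: list[Term] = []
    X, terms_now = stack(included)
    current = fit_logit(y, X)
    visited = {frozenset()}
    search_log: list[dict] = []

    for _ in range(config.max_iterations):
        changed = False
        # forward step
        best = None
        for t in candidates:
            if any(t.name == u.name for u in included):
                continue
            X_try, terms_try = stack(included + [t])
            try:
                res = fit_logit(y, X_try)
            except FitError as exc:
                log.warning("candidate %s skipped this step: %s", t.name, exc)
                continue
            idx = block_idx(terms_try, t)
            if (np.abs(res.std_params[idx]) > SEPARATION_COEF).any() or (
                res.std_bse[idx] > SEPARATION_SE
            ).any():
                continue
            p = wald_block_p(res, idx)
            search_log.append({"step": "forward", "term": t.name, "p": p})
            if p < config.p_enter and (best is None or p < best[0]):
                best = (p, t, res)
        if best is not None:
            _, t, res = best
            state = frozenset(u.name for u in included) | {t.name}
            if state not in visited:
                included.append(t)
                visited.add(state)
                current = res
                changed = True
        # backward step
        if included:
            X_now, terms_now = stack(included)
            worst = None
            for t in included:
                p = wald_block_p(current, block_idx(terms_now, t))
                search_log.append({"step": "backward", "term": t.name, "p": p})
                if p >= config.p_remove and (worst is None or p > worst[0]):
                    worst = (p, t)
            if worst is not None:
                t = worst[1]
                state = frozenset(u.name for u in included) - {t.name}
                if state in visited:
                    break  # revisiting a previous model: stop
                included = [u for u in included if u.name != t.name]
                visited.add(state)
                current = fit_logit(y, stack(included)[0])
                changed = True
        if not changed:
            break

    X, final_terms = stack(included)
    current = fit_logit(y, X)
    col_names = [n for t in final_terms for n in names[t.name]]
    probs = 1.0 / (1.0 + np.exp(-(X @ current.params)))
    return FittedPropensityModel(
        outcome=outcome,
        sweep=sweep,
        terms=final_terms,
        coefficients=np.asarray(current.params),
        standard_errors=np.asarray(current.bse),
        column_names=col_names,
        c_statistic=c_statistic(probs, y),
        dropped_for_separation=dropped,
        n_used=len(df),
        selected_candidates=[t.name for t in included],
        search_log=search_log,
    )
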