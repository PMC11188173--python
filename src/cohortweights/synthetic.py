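"""Synthetic envisioned-population generator.

Emulates a national matched test-positive/test-negative cohort of young
people (ages 11–17) invited after an index SARS-CoV-2 PCR test between
September 2020 and March 2021, with follow-up questionnaire sweeps 3, 6
and 12 months post-test.  The generator reproduces the selection structure
the weighting pipeline assumes:

* month of test determines which sweeps exist (see :mod:`.sweeps`);
* per available sweep a person responds (Bernoulli, covariate-driven
  log-odds — the MAR mechanism), responds *timely* (conditional on
  responding), and may be (re)infected (conditional on timely response;
  structurally impossible for index-positives at the 3-month sweep);
* questionnaire measures exist only for responders;
* latent "true" symptom states at 0/6/12 months are carried as
  generator-only oracle columns (``true_*``) so the bias of any estimator
  is measurable.

All draws come from a single :func:`numpy.random.default_rng` stream
seeded from the config, so a config determines its cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .sweeps import MONTHS, SWEEPS, SWEEP_ORDER, sweep_availability

REGIONS: tuple[str, ...] = (
    "East Midlands",
    "East of England",
    "London",
    "North East",
    "North West",
    "South East",
    "South West",
    "West Midlands",
    "Yorkshire and the Humber",
)

ETHNICITIES: tuple[str, ...] = ("Asian", "Black", "Mixed", "Other", "White")

SYMPTOMS: tuple[str, ...] = ("tired", "breathless")

TIMEPOINTS: tuple[int, ...] = (0, 6, 12)

#: which latent timepoint a sweep's questionnaire reports as "current"
#: (3-month questionnaires are treated as reflecting the baseline state;
#: finer symptom dynamics are not modelled)
SWEEP_TIMEPOINT: dict[int, int] = {3: 0, 6: 6, 12: 12}


class ConfigError(ValueError):
    """An invalid generator configuration, naming the offending field."""


def _check_distribution(name: str, dist: Mapping, support=None) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} probabilities sum to {total!r}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ConfigError(f"{name} contains a negative probability")
    if support is not None and set(dist) != set(support):
        raise ConfigError(f"{name} support {sorted(map(str, dist))} "
                          f"differs from expected {sorted(map(str, support))}")


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults give a desk-scale cohort
    (n = 20,000) with plausible national covariate margins, response rates
    around 9–14%, high timeliness, and (re)infection risk growing with
    follow-up length."""

    n_population: int = 20_000
    seed: int = 0
    month_distribution: dict[str, float] = field(default_factory=lambda: {
        "2020-09": 0.10, "2020-10": 0.11, "2020-11": 0.12, "2020-12": 0.13,
        "2021-01": 0.18, "2021-02": 0.18, "2021-03": 0.18,
    })
    sex_distribution: dict[str, float] = field(
        default_factory=lambda: {"Female": 0.53, "Male": 0.47})
    age_distribution: dict[int, float] = field(default_factory=lambda: {
        11: 0.13, 12: 0.14, 13: 0.14, 14: 0.15, 15: 0.15, 16: 0.15, 17: 0.14})
    region_distribution: dict[str, float] = field(default_factory=lambda: {
        "East Midlands": 0.065, "East of England": 0.175, "London": 0.21,
        "North East": 0.04, "North West": 0.145, "South East": 0.145,
        "South West": 0.04, "West Midlands": 0.105,
        "Yorkshire and the Humber": 0.075,
    })
    imd_distribution: dict[int, float] = field(
        default_factory=lambda: {d: 0.1 for d in range(1, 11)})
    ethnicity_distribution: dict[str, float] = field(default_factory=lambda: {
        "White": 0.78, "Asian": 0.10, "Black": 0.05, "Mixed": 0.04,
        "Other": 0.03,
    })
    index_distribution: dict[str, float] = field(
        default_factory=lambda: {"Positive": 0.415, "Negative": 0.585})
    #: fraction of December-2020 testers contacted at the 6-month sweep
    dec2020_contact_prob: float = 1.0
    #: standard deviation of a person-level "engagement" random effect
    #: added to the response log-odds at every sweep; it induces the
    #: within-person response correlation longitudinal studies show.
    #: Independent of symptoms given covariates, so MAR is preserved.
    response_random_effect_sd: float = 2.5
    #: probability a person's IMD decile is missing (tests the
    #: missing-covariate exclusion path; default none)
    missing_imd_prob: float = 0.0
    #: symptom → timepoint → logistic coefficients on the term vocabulary
    #: (intercept, female, positive, age_c, imd_c, ...)
    symptom_model: dict[str, dict[int, dict[str, float]]] = field(
        default_factory=lambda: _default_symptom_model())
    #: sweep → stage → logistic coefficients; stages "respond", "timely",
    #: "reinfected".  May reference current symptom terms ("tired",
    #: "breathless") for MNAR stress tests.
    selection_models: dict[int, dict[str, dict[str, float]]] = field(
        default_factory=lambda: _default_selection_models())
    #: sweep → (shape, scale) of the gamma from which weeks-to-response is
    #: drawn, truncated to agree with the drawn timeliness indicator
    weeks_gamma: dict[int, tuple[float, float]] = field(default_factory=lambda: {
        3: (14.0, 1.1), 6: (25.0, 1.1), 12: (48.0, 1.1)})

    def validate(self) -> None:
        if self.n_population <= 0:
            raise ConfigError("n_population must be positive")
        _check_distribution("month_distribution", self.month_distribution,
                            MONTHS)
        _check_distribution("sex_distribution", self.sex_distribution,
                            ("Female", "Male"))
        _check_distribution("age_distribution", self.age_distribution,
                            range(11, 18))
        _check_distribution("region_distribution", self.region_distribution,
                            REGIONS)
        _check_distribution("imd_distribution", self.imd_distribution,
                            range(1, 11))
        _check_distribution("ethnicity_distribution",
                            self.ethnicity_distribution)
        _check_distribution("index_distribution", self.index_distribution,
                            ("Positive", "Negative"))
        if not 0 <= self.dec2020_contact_prob <= 1:
            raise ConfigError("dec2020_contact_prob must lie in [0, 1]")
        if not 0 <= self.missing_imd_prob < 1:
            raise ConfigError("missing_imd_prob must lie in [0, 1)")
        if self.response_random_effect_sd < 0:
            raise ConfigError("response_random_effect_sd must be >= 0")
        for sweep, stages in self.selection_models.items():
            if sweep not in SWEEPS:
                raise ConfigError(f"selection_models has unknown sweep {sweep}")
            for stage, coeffs in stages.items():
                if stage not in ("respond", "timely", "reinfected"):
                    raise ConfigError(
                        f"selection_models[{sweep}] has unknown stage {stage!r}")
                for term, value in coeffs.items():
                    if not np.isfinite(value):
                        raise ConfigError(
                            f"selection_models[{sweep}][{stage}][{term}] "
                            "is not finite")


def _default_symptom_model() -> dict[str, dict[int, dict[str, float]]]:
    # marginal prevalences rise over follow-up and are higher for
    # index-positives, echoing published tiredness / shortness-of-breath
    # trajectories in this age group
    return {
        "tired": {
            0: {"intercept": -3.45, "positive": 2.30, "female": 0.20,
                "imd_c": -0.05},
            6: {"intercept": -1.25, "positive": 0.64, "female": 0.20,
                "imd_c": -0.05},
            12: {"intercept": -0.86, "positive": 0.55, "female": 0.20,
                 "imd_c": -0.05},
        },
        "breathless": {
            0: {"intercept": -4.25, "positive": 2.17, "female": 0.10},
            6: {"intercept": -2.30, "positive": 0.98, "female": 0.10},
            12: {"intercept": -1.90, "positive": 0.67, "female": 0.10},
        },
    }


def _default_selection_models() -> dict[int, dict[str, dict[str, float]]]:
    def stages(b_resp: float, b_timely: float, b_reinf: float):
        return {
            "respond": {"intercept": b_resp, "female": 0.62, "age_c": 0.14,
                        "imd_c": 0.18, "positive": 0.09},
            "timely": {"intercept": b_timely, "female": 0.10, "age_c": 0.05,
                       "imd_c": 0.05},
            "reinfected": {"intercept": b_reinf, "positive": -0.50,
                           "age_c": 0.05, "imd_c": -0.05},
        }

    # conditional intercepts are wider than the marginal rates they imply
    # because the engagement random effect attenuates marginal effects;
    # timeliness around 90-93% and (re)infection risk of a few percent
    # (rising to ~20% by 12 months) keep every risk set large enough to
    # fit at desk scale while preserving the real ordering of the stages
    return {3: stages(-3.60, 2.60, -3.20),
            6: stages(-4.10, 2.30, -3.00),
            12: stages(-4.40, 2.60, -1.40)}


# ---------------------------------------------------------------------------
# linear predictors on the generator's term vocabulary


def _term_vocabulary(df: pd.DataFrame, timepoint: int | None = None
                     ) -> dict[str, np.ndarray]:
    n = len(df)
    vocab = {
        "intercept": np.ones(n),
        "female": (df["sex"] == "Female").to_numpy(float),
        "positive": (df["index_status"] == "Positive").to_numpy(float),
        "age_c": df["age_years"].to_numpy(float) - 14.0,
        "imd_c": df["imd_decile"].to_numpy(float) - 5.5,
        "month_idx": np.array(
            [MONTHS.index(m) for m in df["month_of_test"]], dtype=float),
    }
    for r in REGIONS:
        vocab[f"region[{r}]"] = (df["region"] == r).to_numpy(float)
    for e in ETHNICITIES:
        vocab[f"ethnicity[{e}]"] = (df["ethnicity"] == e).to_numpy(float)
    if timepoint is not None:
        for s in SYMPTOMS:
            vocab[s] = df[f"true_{s}_{timepoint}"].to_numpy(float)
    return vocab


def _linpred(coeffs: Mapping[str, float], vocab: Mapping[str, np.ndarray],
             where: str) -> np.ndarray:
    eta = np.zeros_like(vocab["intercept"])
    for term, value in coeffs.items():
        if term not in vocab:
            raise ConfigError(f"{where} references unknown term {term!r}")
        eta = eta + value * vocab[term]
    return eta


# ---------------------------------------------------------------------------
# generation


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_categorical(rng, dist: Mapping, n: int) -> np.ndarray:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()  # guard 1e-9 slack
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=probs)]


def generate_population(config: CohortConfig) -> pd.DataFrame:
    """Draw the envisioned population: design covariates, month of test,
    sweep availability, and latent symptom states.  Questionnaire and
    selection columns are created empty; :func:`apply_selection` fills
    them."""
    config.validate()
    rng = _rng(config, 1)
    n = config.n_population

    df = pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "sex": _draw_categorical(rng, config.sex_distribution, n),
        "age_years": _draw_categorical(rng, config.age_distribution, n
                                       ).astype(int),
        "region": _draw_categorical(rng, config.region_distribution, n),
        "imd_decile": _draw_categorical(rng, config.imd_distribution, n
                                        ).astype(float),
        "ethnicity": _draw_categorical(rng, config.ethnicity_distribution, n),
        "index_status": _draw_categorical(rng, config.index_distribution, n),
        "month_of_test": _draw_categorical(rng, config.month_distribution, n),
    })
    contacted = np.ones(n, dtype=bool)
    dec = (df["month_of_test"] == "2020-12").to_numpy()
    if config.dec2020_contact_prob < 1:
        contacted[dec] = rng.random(dec.sum()) < config.dec2020_contact_prob
    df["contacted_6m"] = contacted

    if config.missing_imd_prob > 0:
        miss = rng.random(n) < config.missing_imd_prob
        df.loc[miss, "imd_decile"] = np.nan

    for s in SWEEP_ORDER:
        avail = np.array([
            s in sweep_availability(m, c)
            for m, c in zip(df["month_of_test"], df["contacted_6m"])
        ])
        df[f"available_{s}m"] = avail

    # latent symptom trajectories (oracle columns)
    vocab = _term_vocabulary(df.fillna({"imd_decile": 5.5}))
    for symptom in SYMPTOMS:
        for t in TIMEPOINTS:
            coeffs = config.symptom_model[symptom][t]
            p = special.expit(_linpred(
                coeffs, vocab, f"symptom_model[{symptom}][{t}]"))
            df[f"true_{symptom}_{t}"] = (rng.random(n) < p).astype(int)

    # selection and questionnaire columns, filled by apply_selection
    for s in SWEEP_ORDER:
        df[f"responded_{s}m"] = np.nan
        df[f"weeks_{s}m"] = np.nan
        df[f"timely_{s}m"] = np.nan
        df[f"reinfected_{s}m"] = np.nan
        for col in ("vacc", "phealth", "lonely", "nsympt", "tired",
                    "breathless", "swemws", "eqvas", "eq5dy", "sdq", "ucla",
                    "cfs"):
            df[f"{col}_{s}m"] = np.nan
    for symptom in SYMPTOMS:
        for t in TIMEPOINTS:
            df[f"obs_{symptom}_{t}"] = np.nan
    return df


def _truncated_gamma(rng, shape: float, scale: float, lower: np.ndarray,
                     upper: np.ndarray) -> np.ndarray:
    """Inverse-CDF draws from Gamma(shape, scale) restricted to
    (lower, upper]; vectorised over the bounds."""
    dist = stats.gamma(shape, scale=scale)
    lo = dist.cdf(lower)
    hi = dist.cdf(upper)
    u = lo + (hi - lo) * rng.random(len(lower))
    return dist.ppf(np.clip(u, 1e-12, 1 - 1e-12))


def apply_selection(cohort: pd.DataFrame, config: CohortConfig
                    ) -> pd.DataFrame:
    """Realise the three nested selection stages at every available sweep
    and fill in questionnaire measures for responders.

    Timeliness is drawn first from its configured conditional probability
    and weeks-to-response is then drawn from the sweep's gamma
    distribution truncated to the agreeing side of the cutoff, so the
    binary indicator honours the model by construction.
    """
    config.validate()
    df = cohort.copy()
    rng = _rng(config, 2)
    engagement = (rng.normal(0.0, config.response_random_effect_sd, len(df))
                  if config.response_random_effect_sd > 0
                  else np.zeros(len(df)))

    for s in SWEEP_ORDER:
        sweep = SWEEPS[s]
        avail = df[f"available_{s}m"].to_numpy(bool)
        vocab = _term_vocabulary(df.fillna({"imd_decile": 5.5}),
                                 timepoint=SWEEP_TIMEPOINT[s])
        stages = config.selection_models[s]

        p_resp = special.expit(_linpred(
            stages["respond"], vocab, f"selection_models[{s}][respond]")
            + engagement)
        responded = avail & (rng.random(len(df)) < p_resp)
        df.loc[avail, f"responded_{s}m"] = responded[avail].astype(float)

        p_timely = special.expit(_linpred(
            stages["timely"], vocab, f"selection_models[{s}][timely]"))
        timely = responded & (rng.random(len(df)) < p_timely)
        df.loc[responded, f"timely_{s}m"] = timely[responded].astype(float)

        shape, scale = config.weeks_gamma[s]
        idx = np.flatnonzero(responded)
        if len(idx):
            is_t = timely[idx]
            eps = 1e-9 if sweep.strict else 0.0
            lower = np.where(is_t, 0.0, sweep.cutoff_weeks + (0 if sweep.strict
                                                              else 1e-9))
            upper = np.where(is_t, sweep.cutoff_weeks - eps, np.inf)
            df.loc[df.index[idx], f"weeks_{s}m"] = _truncated_gamma(
                rng, shape, scale, lower, upper)

        p_reinf = special.expit(_linpred(
            stages["reinfected"], vocab, f"selection_models[{s}][reinfected]"))
        if s == 3:  # a test-positive person cannot be reinfected by 3 months
            p_reinf = np.where(df["index_status"] == "Positive", 0.0, p_reinf)
        reinfected = timely & (rng.random(len(df)) < p_reinf)
        df.loc[timely, f"reinfected_{s}m"] = reinfected[timely].astype(float)

        _fill_questionnaire(df, s, responded, rng)

    # observed symptom states: 6/12-month reports come from the matching
    # sweep; the baseline (0-month) report comes from the first
    # questionnaire the person completed
    for symptom in SYMPTOMS:
        for s, t in ((6, 6), (12, 12)):
            resp = df[f"responded_{s}m"] == 1
            df.loc[resp, f"obs_{symptom}_{t}"] = df.loc[resp,
                                                        f"true_{symptom}_{t}"]
        reported = pd.Series(False, index=df.index)
        for s in SWEEP_ORDER:
            first = (df[f"available_{s}m"] & (df[f"responded_{s}m"] == 1)
                     & ~reported)
            df.loc[first, f"obs_{symptom}_0"] = df.loc[first,
                                                       f"true_{symptom}_0"]
            reported |= df[f"available_{s}m"]
    return df


def _fill_questionnaire(df: pd.DataFrame, s: int, responded: np.ndarray,
                        rng) -> None:
    """Plausible instrument scores for responders; exact psychometrics are
    irrelevant to the weight mechanics."""
    idx = np.flatnonzero(responded)
    if not len(idx):
        return
    m = len(idx)
    t = SWEEP_TIMEPOINT[s]
    tired = df[f"true_tired_{t}"].to_numpy(float)[idx]
    breathless = df[f"true_breathless_{t}"].to_numpy(float)[idx]
    positive = (df["index_status"] == "Positive").to_numpy(float)[idx]
    rows = df.index[idx]

    vacc_probs = {3: (0.70, 0.25, 0.05), 6: (0.45, 0.35, 0.20),
                  12: (0.15, 0.30, 0.55)}[s]
    df.loc[rows, f"vacc_{s}m"] = rng.choice(3, size=m, p=vacc_probs).astype(float)

    lonely = np.clip(np.round(2.2 + 0.8 * tired + rng.normal(0, 1.0, m)), 1, 5)
    df.loc[rows, f"lonely_{s}m"] = lonely
    df.loc[rows, f"phealth_{s}m"] = np.clip(
        np.round(2.0 + 0.9 * tired + 0.6 * breathless + rng.normal(0, 0.9, m)),
        1, 5)
    p_other = special.expit(-2.5 + 0.5 * positive + 1.2 * tired)
    df.loc[rows, f"nsympt_{s}m"] = (tired + breathless
                                    + rng.binomial(19, p_other))
    df.loc[rows, f"tired_{s}m"] = tired
    df.loc[rows, f"breathless_{s}m"] = breathless
    df.loc[rows, f"swemws_{s}m"] = np.clip(np.round(
        25 - 2.5 * tired - 0.5 * (lonely - 2.2) + rng.normal(0, 4, m)), 7, 35)
    df.loc[rows, f"eqvas_{s}m"] = np.clip(np.round(
        85 - 10 * tired - 6 * breathless + rng.normal(0, 12, m)), 0, 100)
    df.loc[rows, f"eq5dy_{s}m"] = np.clip(
        0.95 - 0.08 * tired - 0.05 * breathless + rng.normal(0, 0.08, m), 0, 1)
    df.loc[rows, f"sdq_{s}m"] = np.clip(np.round(
        10 + 3.5 * tired + rng.normal(0, 5, m)), 0, 40)
    df.loc[rows, f"ucla_{s}m"] = np.clip(np.round(
        3.5 + 0.8 * (lonely - 2.2) + rng.normal(0, 1.2, m)), 3, 9)
    df.loc[rows, f"cfs_{s}m"] = np.clip(np.round(
        11 + 6 * tired + rng.normal(0, 5, m)), 0, 33)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Convenience: :func:`generate_population` then
    :func:`apply_selection`."""
    return apply_selection(generate_population(config), config)


# ---------------------------------------------------------------------------
# census margins

AGE_BANDS: tuple[tuple[int, int], ...] = ((11, 14), (15, 17))


def age_band_label(age) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age!r} outside the cohort support 11-17")


def derive_census_margins(config: CohortConfig, inflation: float = 10.0
                          ) -> pd.DataFrame:
    """Expected sex × age-band × region counts of a superpopulation of
    size ``inflation × n_population`` under the config's (independent)
    covariate distributions.  Stands in for an external census extract."""
    config.validate()
    if inflation <= 0:
        raise ValueError("inflation must be positive")
    total = inflation * config.n_population
    band_prob = {
        f"{lo}-{hi}": sum(config.age_distribution[a] for a in range(lo, hi + 1))
        for lo, hi in AGE_BANDS
    }
    rows = []
    for sex, ps in config.sex_distribution.items():
        for band, pb in band_prob.items():
            for region, pr in config.region_distribution.items():
                rows.append({"sex": sex, "age_band": band, "region": region,
                             "count": total * ps * pb * pr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study configurations


def solve_symptom_intercept(target_prevalence: float,
                            coeffs: dict[str, float],
                            config: CohortConfig) -> float:
    """Intercept making the population-expected symptom prevalence equal
    ``target_prevalence`` under the config's covariate distributions
    (exact cell enumeration over sex × IMD × index status)."""
    cells = []
    for sex, ps in config.sex_distribution.items():
        for imd, pi in config.imd_distribution.items():
            for ix, px in config.index_distribution.items():
                eta = (coeffs.get("female", 0.0) * (sex == "Female")
                       + coeffs.get("imd_c", 0.0) * (imd - 5.5)
                       + coeffs.get("positive", 0.0) * (ix == "Positive"))
                cells.append((ps * pi * px, eta))
    w = np.array([c[0] for c in cells])
    eta = np.array([c[1] for c in cells])

    def gap(b0):
        return float(w @ special.expit(b0 + eta)) - target_prevalence

    return float(optimize.brentq(gap, -20, 20))


def mar_recovery_config(n_population: int = 50_000, seed: int = 0,
                        target_prevalence: float = 0.30) -> CohortConfig:
    """Parameter-recovery study: covariate-driven response with rates
    ranging roughly 5–30% across sex × IMD strata, and a symptom whose
    population prevalence is exactly ``target_prevalence`` and which is
    correlated with response through the same observed covariates (MAR)."""
    config = CohortConfig(n_population=n_population, seed=seed,
                          response_random_effect_sd=0.0)
    respond = {"intercept": -2.2, "female": 0.60, "imd_c": 0.15}
    timely = {"intercept": 2.5, "female": 0.20}
    reinfected = {"intercept": -3.0, "imd_c": 0.10}
    config.selection_models = {
        s: {"respond": dict(respond), "timely": dict(timely),
            "reinfected": dict(reinfected)}
        for s in SWEEP_ORDER
    }
    sym = {"female": 0.50, "imd_c": 0.12}
    b0 = solve_symptom_intercept(target_prevalence, sym, config)
    config.symptom_model = {
        "tired": {t: {"intercept": b0, **sym} for t in TIMEPOINTS},
        "breathless": {t: {"intercept": b0 - 1.0, **sym} for t in TIMEPOINTS},
    }
    return config


def one_stage_config(n_population: int = 5_000, seed: int = 0,
                     target_prevalence: float = 0.30) -> CohortConfig:
    """Reduced design for variance studies: response is the only selection
    stage (everyone timely, nobody (re)infected) and all months of test
    fall in early 2021 so every person is envisioned at every sweep."""
    config = mar_recovery_config(n_population, seed, target_prevalence)
    config.month_distribution = {m: 0.0 for m in MONTHS}
    config.month_distribution.update(
        {"2021-01": 0.34, "2021-02": 0.33, "2021-03": 0.33})
    for s in SWEEP_ORDER:
        config.selection_models[s]["timely"] = {"intercept": 30.0}
        config.selection_models[s]["reinfected"] = {"intercept": -30.0}
    return config
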