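"""Synthetic-cohort generator: determinism, selection structure, margins."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from cohortweights.synthetic import (
    CohortConfig,
    ConfigError,
    apply_selection,
    derive_census_margins,
    generate_cohort,
    generate_population,
    mar_recovery_config,
)
from cohortweights.sweeps import MONTHS, sweep_availability


def month_point_mass(month):
    return {m: (1.0 if m == month else 0.0) for m in MONTHS}


class TestAvailabilityLogic:
    @pytest.mark.parametrize(
        "month, expected",
        [
            ("2020-09", {12}),
            ("2020-10", {6, 12}),
            ("2020-12", {6, 12}),
            ("2021-01", {3, 6, 12}),
            ("2021-03", {3, 6, 12}),
        ],
    )
    def test_month_rule(self, month, expected):
        assert sweep_availability(month) == frozenset(expected)

    def test_december_partial_contact_drops_six_months(self):
        assert sweep_availability("2020-12", contacted_6m=False) == {12}

    def test_september_only_cohort_has_only_twelve_month_sweep(self):
        config = CohortConfig(n_population=500, seed=1,
                              month_distribution=month_point_mass("2020-09"))
        pop = generate_population(config)
        assert not pop["available_3m"].any()
        assert not pop["available_6m"].any()
        assert pop["available_12m"].all()


class TestGeneratePopulation:
    def test_deterministic_given_seed(self):
        config = CohortConfig(n_population=2000, seed=42)
        a = generate_cohort(config)
        b = generate_cohort(config)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_output(self):
        a = generate_cohort(CohortConfig(n_population=2000, seed=1))
        b = generate_cohort(CohortConfig(n_population=2000, seed=2))
        assert not a.equals(b)

    def test_female_fraction_within_sampling_error(self):
        config = CohortConfig(n_population=10_000, seed=3)
        pop = generate_population(config)
        frac = (pop["sex"] == "Female").mean()
        se = np.sqrt(0.53 * 0.47 / 10_000)
        assert abs(frac - 0.53) < 3 * se

    def test_age_support(self, small_cohort):
        assert set(small_cohort["age_years"].unique()) <= set(range(11, 18))

    def test_invalid_distribution_names_offender(self):
        config = CohortConfig(n_population=100)
        config.sex_distribution = {"Female": 0.6, "Male": 0.6}
        with pytest.raises(ConfigError, match="sex_distribution"):
            generate_population(config)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ConfigError, match="n_population"):
            generate_population(CohortConfig(n_population=0))

    def test_unknown_selection_term_named(self):
        config = CohortConfig(n_population=200, seed=0)
        config.selection_models[3]["respond"]["not_a_term"] = 1.0
        pop = generate_population(config)
        with pytest.raises(ConfigError, match="not_a_term"):
            apply_selection(pop, config)


class TestApplySelection:
    def test_no_selection_keeps_everyone(self):
        config = CohortConfig(n_population=1000, seed=5,
                              response_random_effect_sd=0.0)
        for s in (3, 6, 12):
            config.selection_models[s] = {
                "respond": {"intercept": 40.0},
                "timely": {"intercept": 40.0},
                "reinfected": {"intercept": -40.0},
            }
        cohort = generate_cohort(config)
        for s in (3, 6, 12):
            avail = cohort[f"available_{s}m"]
            assert (cohort.loc[avail, f"responded_{s}m"] == 1).all()
            assert (cohort.loc[avail, f"timely_{s}m"] == 1).all()
            assert (cohort.loc[avail, f"reinfected_{s}m"] == 0).all()

    def test_positive_cannot_be_reinfected_by_three_months(self):
        config = CohortConfig(n_population=4000, seed=6)
        config.selection_models[3]["reinfected"] = {"intercept": 3.0}
        cohort = generate_cohort(config)
        timely_pos = ((cohort["timely_3m"] == 1)
                      & (cohort["index_status"] == "Positive"))
        assert timely_pos.any()
        assert (cohort.loc[timely_pos, "reinfected_3m"] == 0).all()
        timely_neg = ((cohort["timely_3m"] == 1)
                      & (cohort["index_status"] == "Negative"))
        assert (cohort.loc[timely_neg, "reinfected_3m"] == 1).mean() > 0.5

    def test_nesting_monotone(self, small_cohort):
        for s in (3, 6, 12):
            n_env = small_cohort[f"available_{s}m"].sum()
            n_resp = (small_cohort[f"responded_{s}m"] == 1).sum()
            n_timely = (small_cohort[f"timely_{s}m"] == 1).sum()
            n_analytic = ((small_cohort[f"timely_{s}m"] == 1)
                          & (small_cohort[f"reinfected_{s}m"] == 0)).sum()
            assert n_env >= n_resp >= n_timely >= n_analytic > 0

    def test_nesting_of_missingness(self, small_cohort):
        for s in (3, 6, 12):
            responded = small_cohort[f"responded_{s}m"] == 1
            assert small_cohort.loc[responded, f"weeks_{s}m"].notna().all()
            assert small_cohort.loc[~responded, f"weeks_{s}m"].isna().all()
            timely = small_cohort[f"timely_{s}m"] == 1
            assert small_cohort.loc[timely, f"reinfected_{s}m"].notna().all()
            assert small_cohort.loc[
                small_cohort[f"responded_{s}m"] != 1, f"reinfected_{s}m"
            ].isna().all()

    def test_weeks_respect_timeliness_cutoffs(self, small_cohort):
        cutoffs = {3: (24.0, True), 6: (34.0, False), 12: (60.0, False)}
        for s, (cut, strict) in cutoffs.items():
            timely = small_cohort[f"timely_{s}m"] == 1
            late = (small_cohort[f"responded_{s}m"] == 1) & ~timely
            w_timely = small_cohort.loc[timely, f"weeks_{s}m"]
            w_late = small_cohort.loc[late, f"weeks_{s}m"]
            if strict:
                assert (w_timely < cut).all() and (w_late >= cut).all()
            else:
                assert (w_timely <= cut).all() and (w_late > cut).all()

    def test_symptom_count_range(self, small_cohort):
        for s in (3, 6, 12):
            n = small_cohort[f"nsympt_{s}m"].dropna()
            assert ((n >= 0) & (n <= 21)).all()
            assert n.max() > 2  # not degenerate

    def test_questionnaire_only_for_responders(self, small_cohort):
        for s in (3, 6, 12):
            responded = small_cohort[f"responded_{s}m"] == 1
            for col in ("swemws", "eqvas", "cfs", "vacc"):
                assert small_cohort.loc[responded, f"{col}_{s}m"].notna().all()
                assert small_cohort.loc[~responded, f"{col}_{s}m"].isna().all()

    def test_mar_response_rates_match_model_by_cell(self):
        config = mar_recovery_config(n_population=50_000, seed=7)
        cohort = generate_cohort(config)
        # Pr(respond) = expit(-2.2 + 0.6 female + 0.15 (IMD - 5.5))
        for sex in ("Female", "Male"):
            for imd_lo, imd_hi in ((1, 3), (4, 7), (8, 10)):
                cell = ((cohort["sex"] == sex)
                        & cohort["imd_decile"].between(imd_lo, imd_hi)
                        & cohort["available_12m"])
                sub = cohort[cell]
                expected = special.expit(
                    -2.2 + 0.6 * (sex == "Female")
                    + 0.15 * (sub["imd_decile"] - 5.5)).mean()
                observed = (sub["responded_12m"] == 1).mean()
                se = np.sqrt(expected * (1 - expected) / len(sub))
                assert abs(observed - expected) < 3 * se

    def test_mcar_selection_leaves_covariates_unbiased(self):
        # under covariate-free (MCAR) response, responders are a simple
        # random subsample: chi-square p-values across seeds should not
        # concentrate near zero
        pvals = []
        for seed in range(5):
            config = CohortConfig(n_population=6000, seed=seed,
                                  response_random_effect_sd=0.0)
            for s in (3, 6, 12):
                config.selection_models[s]["respond"] = {"intercept": -1.5}
            cohort = generate_cohort(config)
            resp = cohort["responded_12m"] == 1
            table = pd.crosstab(cohort["region"], resp)
            pvals.append(stats.chi2_contingency(table).pvalue)
        assert min(pvals) > 1e-4
        assert not all(p < 0.05 for p in pvals)


class TestCensusMargins:
    def test_counts_conserve_inflated_total(self, small_config):
        margins = derive_census_margins(small_config, inflation=7.0)
        assert margins["count"].sum() == pytest.approx(
            7.0 * small_config.n_population, rel=1e-9)

    def test_uniform_region_closed_form(self):
        config = CohortConfig(n_population=9000, seed=0)
        config.region_distribution = {r: 1.0 / 9 for r in
                                      config.region_distribution}
        margins = derive_census_margins(config, inflation=10.0)
        band_prob = {"11-14": sum(config.age_distribution[a]
                                  for a in range(11, 15)),
                     "15-17": sum(config.age_distribution[a]
                                  for a in range(15, 18))}
        for _, row in margins.iterrows():
            expected = (90_000 * config.sex_distribution[row["sex"]]
                        * band_prob[row["age_band"]] / 9)
            assert row["count"] == pytest.approx(expected, rel=1e-12)

    def test_all_cells_present_exactly_once(self, small_margins):
        assert len(small_margins) == 2 * 2 * 9
        assert not small_margins[["sex", "age_band", "region"]] \
            .duplicated().any()

    def test_nonpositive_inflation_rejected(self, small_config):
        with pytest.raises(ValueError, match="inflation"):
            derive_census_margins(small_config, inflation=0.0)
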