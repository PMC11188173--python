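"""Weight engine: mini weights, the saturated-model oracle, trimming,
longitudinal combination and census calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortweights.design import CategoricalTerm, InteractionTerm
from cohortweights.selection import StepwiseConfig, stepwise_select
from cohortweights.weights import (
    TrimConfig,
    calibrate_to_census,
    combine_longitudinal,
    compute_sweep_weights,
    mini_weight,
    trim_weights,
)

from conftest import saturated_cells


class TestMiniWeight:
    @pytest.mark.parametrize("p, expected", [(1.0, 1.0), (0.5, 2.0),
                                             (0.2, 5.0)])
    def test_reciprocal(self, p, expected):
        assert mini_weight(p) == expected

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.2])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            mini_weight(p)


def _saturated_models(cohort):
    """Fit the three sweep-12 models saturated on sex × index status."""
    term_sets = lambda: [
        CategoricalTerm("sex"), CategoricalTerm("index_status"),
        InteractionTerm(CategoricalTerm("sex"),
                        CategoricalTerm("index_status")),
    ]
    models = {}
    risk = {
        "respond": cohort[cohort["available_12m"]],
        "timely": cohort[cohort["responded_12m"] == 1],
        "reinfected": cohort[cohort["timely_12m"] == 1],
    }
    ycol = {"respond": "responded_12m", "timely": "timely_12m",
            "reinfected": "reinfected_12m"}
    for stage, data in risk.items():
        config = StepwiseConfig(forced_terms=term_sets(), candidate_terms=[])
        models[stage] = stepwise_select(data, ycol[stage], config, sweep=12)
    return models


class TestSaturatedOracle:
    """With a fully saturated model on discrete covariates, every fitted
    probability is the empirical cell fraction, so every mini weight must
    equal the inverse empirical retention fraction and weights must add
    back to the envisioned cell counts exactly."""

    def test_mini_weights_equal_inverse_cell_fractions(self, saturated_cohort):
        models = _saturated_models(saturated_cohort)
        ws = compute_sweep_weights(saturated_cohort, models, 12)
        frame = ws.frame.join(
            saturated_cohort.set_index("id")[["sex", "index_status"]])
        for sex, index, n_env, n_resp, n_timely, n_reinf in saturated_cells():
            cell = (frame["sex"] == sex) & (frame["index_status"] == index)
            w_resp = frame.loc[cell, "w_response"].dropna()
            assert len(w_resp) == n_resp
            np.testing.assert_allclose(w_resp, n_env / n_resp, rtol=1e-9)
            w_timely = frame.loc[cell, "w_timely"].dropna()
            np.testing.assert_allclose(w_timely, n_resp / n_timely, rtol=1e-9)
            w_reinf = frame.loc[cell, "w_reinfection"].dropna()
            np.testing.assert_allclose(
                w_reinf, n_timely / (n_timely - n_reinf), rtol=1e-9)

    def test_weight_sums_reproduce_stratum_counts(self, saturated_cohort):
        models = _saturated_models(saturated_cohort)
        ws = compute_sweep_weights(saturated_cohort, models, 12)
        frame = ws.frame.join(
            saturated_cohort.set_index("id")[["sex", "index_status"]])
        for sex, index, n_env, n_resp, n_timely, n_reinf in saturated_cells():
            cell = (frame["sex"] == sex) & (frame["index_status"] == index)
            assert frame.loc[cell, "w_response"].sum() == pytest.approx(
                n_env, rel=1e-9)
            assert frame.loc[cell, "w_envisioned"].sum() == pytest.approx(
                n_env, rel=1e-9)

    def test_product_identity(self, saturated_cohort):
        models = _saturated_models(saturated_cohort)
        frame = compute_sweep_weights(saturated_cohort, models, 12).frame
        defined = frame["w_envisioned"].notna()
        np.testing.assert_allclose(
            frame.loc[defined, "w_envisioned"],
            frame.loc[defined, "w_response"] * frame.loc[defined, "w_timely"]
            * frame.loc[defined, "w_reinfection"], rtol=1e-12)

    def test_no_selection_degenerate_weights_are_one(self, saturated_cohort):
        cohort = saturated_cohort.copy()
        cohort["responded_12m"] = 1.0
        cohort["timely_12m"] = 1.0
        cohort["reinfected_12m"] = 0.0
        ws = compute_sweep_weights(
            cohort, {"respond": None, "timely": None, "reinfected": None}, 12)
        np.testing.assert_allclose(ws.frame["w_envisioned"], 1.0)

    def test_nonresponder_has_no_weight_and_no_flag(self, saturated_cohort):
        models = _saturated_models(saturated_cohort)
        frame = compute_sweep_weights(saturated_cohort, models, 12).frame
        joined = frame.join(saturated_cohort.set_index("id")["responded_12m"])
        nonresp = joined["responded_12m"] == 0
        assert joined.loc[nonresp, "w_response"].isna().all()
        assert not joined.loc[nonresp, "excluded_missing_covariates"].any()

    def test_missing_covariate_rows_flagged_and_unweighted(self,
                                                           saturated_cohort):
        cohort = saturated_cohort.copy()
        models = _saturated_models(cohort)
        # blank the sex of two responders after fitting
        responders = cohort.index[cohort["responded_12m"] == 1][:2]
        cohort.loc[responders, "sex"] = np.nan
        frame = compute_sweep_weights(cohort, models, 12).frame
        flagged = frame.loc[cohort.loc[responders, "id"]]
        assert flagged["w_response"].isna().all()
        assert flagged["excluded_missing_covariates"].all()


class TestTrimming:
    def test_constant_weights_untouched(self):
        out, md = trim_weights([2.0, 2.0, 2.0, 2.0])
        np.testing.assert_allclose(out, [2, 2, 2, 2])
        assert md.cutoff == 2.0
        assert md.rescale_factor == 1.0
        assert md.n_capped == 0

    def test_worked_example(self):
        # weights (1,2,3,4,50): interpolated Q1=2, median=3, Q3=4,
        # cutoff 3 + 3*2 = 9; capped sum 19, factor 60/19
        out, md = trim_weights([1.0, 2.0, 3.0, 4.0, 50.0], TrimConfig(k=3.0))
        assert md.cutoff == pytest.approx(9.0)
        assert md.rescale_factor == pytest.approx(60.0 / 19.0)
        np.testing.assert_allclose(
            out, np.array([1, 2, 3, 4, 9]) * 60.0 / 19.0, rtol=1e-12)
        assert out.sum() == pytest.approx(60.0, rel=1e-12)
        assert md.n_capped == 1

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=1,
                    max_size=60),
           st.floats(min_value=0.5, max_value=6.0))
    def test_sum_preserved_and_capped(self, values, k):
        w = np.asarray(values)
        out, md = trim_weights(w, TrimConfig(k=k))
        assert out.sum() == pytest.approx(w.sum(), rel=1e-9)
        # before rescaling nothing exceeds the cutoff
        np.testing.assert_array_less(
            out / md.rescale_factor, md.cutoff * (1 + 1e-12))

    def test_idempotent_on_capped_input(self):
        rng = np.random.default_rng(4)
        w = rng.lognormal(1.0, 1.0, 500)
        once, md1 = trim_weights(w)
        # an already-capped-and-rescaled vector with the same spread is
        # changed only through its (slightly different) new cutoff; a
        # vector already below its own cutoff is a strict fixed point
        flat = np.clip(w, None, np.quantile(w, 0.75))
        again, md2 = trim_weights(flat)
        np.testing.assert_allclose(again, flat, rtol=1e-12)
        assert md2.n_capped == 0

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            trim_weights([])
        with pytest.raises(ValueError):
            trim_weights([1.0, -2.0])
        with pytest.raises(ValueError):
            TrimConfig(k=0.0)


class TestCombineLongitudinal:
    @staticmethod
    def _mini_cohort():
        return pd.DataFrame({
            "id": [0, 1, 2, 3],
            "month_of_test": ["2020-10", "2021-01", "2021-02", "2020-09"],
            "responded_3m": [np.nan, 1.0, 0.0, np.nan],
        })

    @staticmethod
    def _weightset(sweep, values):
        from cohortweights.weights import WeightSet
        frame = pd.DataFrame({
            "w_response": values, "w_timely": 1.0, "w_reinfection": 1.0,
            "w_envisioned": values,
        }, index=[0, 1, 2, 3])
        frame.index.name = "id"
        return WeightSet(sweep=sweep, frame=frame)

    def test_component_product_rules(self):
        cohort = self._mini_cohort()
        wsets = {
            3: self._weightset(3, [np.nan, 2.0, np.nan, np.nan]),
            6: self._weightset(6, [4.0, 5.0, 6.0, np.nan]),
            12: self._weightset(12, [3.0, 7.0, 8.0, 2.0]),
        }
        combined, exclusions = combine_longitudinal(wsets, cohort)
        # October tester: 4 * 3 = 12; January tester: 2 * 5 * 7 = 70
        assert combined.loc[0, "w_combined"] == pytest.approx(12.0)
        assert combined.loc[1, "w_combined"] == pytest.approx(70.0)
        # February tester never completed the 3-month questionnaire
        assert np.isnan(combined.loc[2, "w_combined"])
        assert ("no 3-month questionnaire"
                in exclusions.set_index("id").loc[2, "reason"])
        # September tester has no 6-month sweep
        assert np.isnan(combined.loc[3, "w_combined"])

    def test_envisioned_component_switch(self):
        cohort = self._mini_cohort()
        ws3 = self._weightset(3, [np.nan, 2.0, np.nan, np.nan])
        ws3.frame.loc[1, "w_envisioned"] = 2.5
        wsets = {3: ws3,
                 6: self._weightset(6, [4.0, 5.0, 6.0, np.nan]),
                 12: self._weightset(12, [3.0, 7.0, 8.0, 2.0])}
        combined, _ = combine_longitudinal(wsets, cohort,
                                           jan_mar_component="envisioned")
        assert combined.loc[1, "w_combined"] == pytest.approx(2.5 * 5 * 7)

    def test_no_selection_combined_weights_all_one(self):
        cohort = self._mini_cohort().iloc[:3]
        wsets = {s: self._weightset(s, [1.0, 1.0, 1.0, 1.0]) for s in
                 (3, 6, 12)}
        combined, _ = combine_longitudinal(wsets, cohort)
        defined = combined["w_combined"].dropna()
        np.testing.assert_allclose(defined, 1.0)
        np.testing.assert_allclose(combined["w_combined_trimmed"].dropna(),
                                   1.0)


class TestCalibration:
    @staticmethod
    def _cohort(n_per_cell):
        rows = []
        pid = 0
        for (sex, region), n in n_per_cell.items():
            for _ in range(n):
                rows.append({"id": pid, "sex": sex, "age_years": 12,
                             "region": region})
                pid += 1
        return pd.DataFrame(rows)

    def test_self_calibration_is_identity(self):
        cohort = self._cohort({("Female", "London"): 3,
                               ("Male", "London"): 2})
        w = pd.Series([2.0, 1.0, 1.0, 4.0, 4.0],
                      index=cohort["id"].to_numpy())
        margins = pd.DataFrame({
            "sex": ["Female", "Male"], "age_band": ["11-14", "11-14"],
            "region": ["London", "London"], "count": [4.0, 8.0],
        })
        calibrated, ratios = calibrate_to_census(w, cohort, margins)
        pd.testing.assert_series_equal(calibrated, w)
        np.testing.assert_allclose(ratios["ratio"], 1.0)

    def test_two_cell_worked_example(self):
        cohort = self._cohort({("Female", "London"): 2,
                               ("Male", "London"): 2})
        w = pd.Series([100.0, 200.0, 250.0, 250.0],
                      index=cohort["id"].to_numpy())
        margins = pd.DataFrame({
            "sex": ["Female", "Male"], "age_band": ["11-14", "11-14"],
            "region": ["London", "London"], "count": [600.0, 400.0],
        })
        calibrated, ratios = calibrate_to_census(w, cohort, margins)
        r = ratios.set_index("sex")["ratio"]
        assert r["Female"] == pytest.approx(2.0)
        assert r["Male"] == pytest.approx(0.8)
        assert calibrated.sum() == pytest.approx(1000.0)

    def test_exactness_on_random_margins(self, small_cohort):
        rng = np.random.default_rng(8)
        analytic = small_cohort[(small_cohort["timely_12m"] == 1)
                                & (small_cohort["reinfected_12m"] == 0)]
        w = pd.Series(rng.lognormal(2, 0.8, len(analytic)),
                      index=analytic["id"].to_numpy())
        from cohortweights.weights import census_cells
        cells = census_cells(small_cohort).to_numpy()
        occupied = sorted(set(pd.Series(cells, index=small_cohort["id"])
                              .reindex(w.index)))
        margins = pd.DataFrame(
            [dict(zip(("sex", "age_band", "region"), c.split("|")),
                  count=rng.uniform(100, 5000)) for c in occupied])
        calibrated, ratios = calibrate_to_census(w, small_cohort, margins)
        cell_by_id = pd.Series(cells, index=small_cohort["id"].to_numpy())
        totals = calibrated.groupby(cell_by_id.reindex(calibrated.index)).sum()
        key = (margins["sex"] + "|" + margins["age_band"] + "|"
               + margins["region"])
        expected = pd.Series(margins["count"].to_numpy(), index=key)
        np.testing.assert_allclose(totals.sort_index(),
                                   expected.sort_index(), rtol=1e-9)

    def test_occupied_cell_missing_from_margins_is_error(self):
        cohort = self._cohort({("Female", "London"): 1,
                               ("Male", "London"): 1})
        w = pd.Series([1.0, 1.0], index=cohort["id"].to_numpy())
        margins = pd.DataFrame({"sex": ["Female"], "age_band": ["11-14"],
                                "region": ["London"], "count": [10.0]})
        with pytest.raises(ValueError, match="Male"):
            calibrate_to_census(w, cohort, margins)

    def test_unrepresentable_census_cell_warns(self):
        cohort = self._cohort({("Female", "London"): 2})
        w = pd.Series([1.0, 1.0], index=cohort["id"].to_numpy())
        margins = pd.DataFrame({
            "sex": ["Female", "Male"], "age_band": ["11-14", "11-14"],
            "region": ["London", "London"], "count": [10.0, 5.0],
        })
        with pytest.warns(UserWarning, match="no weighted sample"):
            calibrate_to_census(w, cohort, margins)
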