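"""Counterfactual construction, toll prediction and the excess bootstrap."""

import numpy as np
import pandas as pd
import pytest

import crisismort as cm
from crisismort._util import month_range, round_to
from crisismort.excess import ExcessReplicates, ScenarioSpec, _mode, aggregate_tables
from crisismort.models import fitted_from_coefficients


def _pop_series(districts, months, pop=1_000_000.0, u5_frac=0.25):
    idx = pd.MultiIndex.from_product([districts, months], names=["district", "month"])
    return cm.PopulationSeries(
        pd.DataFrame({"pop": pop, "pop_u5": u5_frac * pop, "prop_idp": 0.0}, index=idx)
    )


class TestBuildCounterfactual:
    def test_month_specific_median(self, tiny_panel):
        """January values 10/20/40 in the three reference years give a January
        2017 counterfactual of 20 (their median)."""
        panel = tiny_panel.copy()
        for y, v in zip((2014, 2015, 2016), (10.0, 20.0, 40.0)):
            panel.loc[("A", pd.Period(f"{y}-01", "M")), "sam_rate"] = v
        spec = ScenarioSpec("s", {"sam_rate": "month_specific_median_2014_16"})
        out = cm.build_counterfactual(panel, spec)
        assert out.loc[("A", pd.Period("2017-01", "M")), "sam_rate"] == pytest.approx(20.0)
        # pre-2017 cells stay actual
        jan14 = ("A", pd.Period("2014-01", "M"))
        assert out.loc[jan14, "sam_rate"] == panel.loc[jan14, "sam_rate"]

    def test_zero_rule(self, tiny_panel):
        spec = ScenarioSpec("s", {"measles_rate": "zero"})
        out = cm.build_counterfactual(tiny_panel, spec)
        cf = out.loc[out.index.get_level_values("month") >= pd.Period("2017-01", "M")]
        assert (cf["measles_rate"] == 0.0).all()

    def test_fraction_rule(self, tiny_panel):
        spec = ScenarioSpec("s", {"malaria_rate": ("fraction_of_actual", 0.25)})
        out = cm.build_counterfactual(tiny_panel, spec)
        m = pd.Period("2017-02", "M")
        assert out.loc[("B", m), "malaria_rate"] == pytest.approx(
            0.25 * tiny_panel.loc[("B", m), "malaria_rate"]
        )

    def test_as_actual_identity(self, tiny_panel):
        spec = ScenarioSpec("s", {c: "as_actual" for c in tiny_panel.columns})
        out = cm.build_counterfactual(tiny_panel, spec)
        pd.testing.assert_frame_equal(out, tiny_panel)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown rule"):
            ScenarioSpec("s", {"sam_rate": "p99"})

    def test_displacement_rules_filter_flows(self):
        flows = pd.DataFrame(
            {
                "month": pd.PeriodIndex(["2016-05", "2017-03", "2017-04"], freq="M"),
                "origin": ["A", "A", "B"],
                "destination": ["B", "B", "A"],
                "persons": [100, 200, 300],
                "reason": ["drought", "drought", "insecurity"],
                "kind": ["IDP", "IDP", "IDP"],
            }
        )
        no_drought = cm.counterfactual_flows(flows, "no_drought_displacement")
        assert len(no_drought) == 2  # pre-2017 drought flow kept, 2017 one dropped
        none_new = cm.counterfactual_flows(flows, "no_new_displacement")
        assert len(none_new) == 1
        same = cm.counterfactual_flows(flows, "as_actual")
        assert len(same) == 3


class TestPredictTolls:
    def _model(self):
        return fitted_from_coefficients("cdr", {}, 0.43)

    def test_rate_times_person_time_arithmetic(self):
        """0.43/10,000 person-days on 1,000,000 people for a 30-day month is
        1,290 expected deaths."""
        months = month_range("2017-04", "2017-04")  # April: 30 days
        districts = ["A"]
        idx = pd.MultiIndex.from_product([districts, months], names=["district", "month"])
        panel = pd.DataFrame(index=idx)
        tolls = cm.predict_tolls(self._model(), panel, _pop_series(districts, months), months)
        assert tolls.iloc[0] == pytest.approx(0.43e-4 * 1_000_000 * 30)

    def test_zero_population_zero_deaths(self):
        months = month_range("2017-04", "2017-04")
        idx = pd.MultiIndex.from_product([["A"], months], names=["district", "month"])
        pop = cm.PopulationSeries(
            pd.DataFrame({"pop": 0.0, "pop_u5": 0.0, "prop_idp": 0.0}, index=idx)
        )
        tolls = cm.predict_tolls(self._model(), pd.DataFrame(index=idx), pop, months)
        assert tolls.iloc[0] == 0.0

    def test_tolls_linear_in_population(self):
        months = month_range("2017-01", "2017-06")
        idx = pd.MultiIndex.from_product([["A"], months], names=["district", "month"])
        panel = pd.DataFrame(index=idx)
        t1 = cm.predict_tolls(self._model(), panel, _pop_series(["A"], months, 500_000), months)
        t2 = cm.predict_tolls(self._model(), panel, _pop_series(["A"], months, 1_000_000), months)
        assert np.allclose(2 * t1, t2)


class TestBootstrap:
    def _inputs(self, world):
        model = fitted_from_coefficients("cdr", world.config.true_coefficients, 0.43)
        months = world.months[world.months >= pd.Period("2017-01", "M")]
        pop = _pop_series(world.districts["district"], world.months, 200_000)
        return model, months, pop

    def test_identity_counterfactual_zero_excess_every_replicate(self, world):
        model, months, pop = self._inputs(world)
        cov = model.covariance + np.eye(len(model.coefficients)) * 1e-4
        model.covariance = cov
        reps = cm.bootstrap_excess(
            model, world.panel_true, pop, world.panel_true, pop, months, B=200, seed=1
        )
        assert np.all(reps.excess == 0.0)

    def test_zero_covariance_degenerate_at_plugin(self, world):
        model, months, pop = self._inputs(world)
        cf = cm.build_counterfactual(world.panel_true, cm.canonical_scenarios()["most_likely"])
        reps = cm.bootstrap_excess(model, world.panel_true, pop, cf, pop, months, B=150, seed=2)
        assert np.allclose(reps.actual, reps.actual[:, [0]])
        plug = cm.predict_tolls(model, world.panel_true, pop, months)
        total_plug = plug.sum()
        assert reps.actual[:, 0].sum() == pytest.approx(total_plug, rel=1e-9)

    def test_replicate_mean_matches_lognormal_moment(self):
        """1 district, intercept-only model with variance s2 on the intercept:
        E[toll] = plug-in x exp(s2/2) (lognormal mean), checked to 3 MC SEs."""
        months = month_range("2017-04", "2017-04")
        idx = pd.MultiIndex.from_product([["A"], months], names=["district", "month"])
        panel = pd.DataFrame(index=idx)
        pop = _pop_series(["A"], months)
        s2 = 0.04
        model = fitted_from_coefficients("cdr", {}, 0.43)
        model.covariance = pd.DataFrame([[s2]], index=["intercept"], columns=["intercept"])
        B = 4000
        reps = cm.bootstrap_excess(model, panel, pop, panel, pop, months, B=B, seed=3)
        plug = 0.43e-4 * 1_000_000 * 30
        expected = plug * np.exp(s2 / 2)
        mc_se = plug * np.sqrt((np.exp(2 * s2) - np.exp(s2)) / B)
        assert abs(reps.actual.mean() - expected) < 3 * mc_se

    def test_same_seed_reproducible(self, world):
        model, months, pop = self._inputs(world)
        model.covariance = model.covariance + np.eye(len(model.coefficients)) * 1e-4
        cf = cm.build_counterfactual(world.panel_true, cm.canonical_scenarios()["most_likely"])
        a = cm.bootstrap_excess(model, world.panel_true, pop, cf, pop, months, B=120, seed=9)
        b = cm.bootstrap_excess(model, world.panel_true, pop, cf, pop, months, B=120, seed=9)
        assert np.array_equal(a.excess, b.excess)

    def test_too_few_replicates_rejected(self, world):
        model, months, pop = self._inputs(world)
        with pytest.raises(ValueError, match="at least 100"):
            cm.bootstrap_excess(model, world.panel_true, pop, world.panel_true, pop, months, B=10)


class TestSummarize:
    def _reps(self, actual, cf, index=None):
        if index is None:
            index = pd.MultiIndex.from_tuples(
                [("A", 2017), ("A", 2018), ("B", 2017), ("B", 2018)],
                names=["district", "period"],
            )
        return ExcessReplicates(
            index=index, actual=actual, counterfactual=cf,
            region_of={"A": "R1", "B": "R2"}, scenario="most_likely", age_group="all",
        )

    def test_degenerate_distribution(self):
        actual = np.full((4, 200), 50.0)
        cf = np.full((4, 200), 20.0)
        out = cm.summarize(self._reps(actual, cf))
        row = out.iloc[0]
        assert row["excess_mode"] == pytest.approx(120.0)  # 4 rows x 30
        assert row["excess_lo"] == row["excess_hi"] == pytest.approx(120.0)

    def test_percentile_definition(self):
        """Replicates 1..100 give a 95% interval of [3.475, 97.525] under
        linear interpolation."""
        vals = np.arange(1.0, 101.0)
        actual = np.tile(vals, (1, 1))
        index = pd.MultiIndex.from_tuples([("A", 2017)], names=["district", "period"])
        out = cm.summarize(self._reps(actual, np.zeros_like(actual), index))
        assert out.iloc[0]["excess_lo"] == pytest.approx(3.475)
        assert out.iloc[0]["excess_hi"] == pytest.approx(97.525)

    def test_per_replicate_additivity(self):
        rng = np.random.default_rng(0)
        actual = rng.uniform(10, 100, (4, 300))
        cf = rng.uniform(5, 50, (4, 300))
        reps = self._reps(actual, cf)
        national = reps.excess.sum(axis=0)
        by_district = (
            reps.excess[[0, 1]].sum(axis=0),
            reps.excess[[2, 3]].sum(axis=0),
        )
        assert np.allclose(national, by_district[0] + by_district[1])
        out = cm.summarize(reps, by="region", period="overall")
        assert set(out["stratum"]) == {"R1", "R2"}

    def test_mode_of_constant_sample(self):
        assert _mode(np.full(500, 3.3)) == 3.3


class TestAggregateTables:
    def test_overall_is_sum_of_years_when_degenerate(self):
        """With all replicates identical, yearly excesses 29,600 and 15,100 sum
        to an overall row of 44,700."""
        index = pd.MultiIndex.from_tuples([("A", 2017), ("A", 2018)], names=["district", "period"])
        actual = np.tile(np.array([[229_600.0], [215_100.0]]), (1, 150))
        cf = np.tile(np.array([[200_000.0], [200_000.0]]), (1, 150))
        reps = ExcessReplicates(index, actual, cf, {"A": "R1"}, "most_likely", "all")
        years = cm.summarize(reps, period="period")
        overall = cm.summarize(reps, period="overall")
        tables = aggregate_tables([pd.concat([years, overall], ignore_index=True)])
        t = tables["by_year_scenario"]["excess_mode"]["most_likely"]
        assert t.loc[(2017, "all")] == 29_600.0
        assert t.loc[(2018, "all")] == 15_100.0
        assert t.loc[("overall", "all")] == 44_700.0

    @pytest.mark.parametrize("x,expected", [(44_650, 44_700), (44_649, 44_600), (-150, -100)])
    def test_rounding_half_up(self, x, expected):
        assert round_to(x, 100) == expected
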