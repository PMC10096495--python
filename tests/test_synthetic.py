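"""The generator must be deterministic, honour its null model, and produce
death counts whose pooled rate converges to the configured truth."""

import numpy as np
import pandas as pd
import pytest

import crisismort as cm
from crisismort.config import DEFAULT_CDR_COEFFICIENTS


def _pool(surveys):
    d = pt = d5 = pt5 = 0.0
    for s in surveys:
        hh = s.households
        d += hh["deaths"].sum()
        pt += hh["person_days"].sum()
        d5 += hh["deaths_u5"].sum()
        pt5 += hh["person_days_u5"].sum()
    return d, pt, d5, pt5


class TestGenerateWorld:
    def test_same_seed_identical_worlds(self):
        a = cm.generate_world(cm.WorldConfig(seed=5))
        b = cm.generate_world(cm.WorldConfig(seed=5))
        pd.testing.assert_frame_equal(a.districts, b.districts)
        pd.testing.assert_frame_equal(a.panel_true, b.panel_true)
        pd.testing.assert_frame_equal(a.panel_observed, b.panel_observed)
        pd.testing.assert_series_equal(a.true_log_cdr, b.true_log_cdr)
        pd.testing.assert_frame_equal(a.flows, b.flows)
        for x, y in zip(a.anchors, b.anchors):
            assert x.populations == y.populations

    def test_null_model_rates_equal_baseline(self, null_world):
        w = null_world
        cdr = np.exp(w.true_log_cdr) * 1e4
        assert np.allclose(cdr, w.config.baseline_cdr)
        u5 = np.exp(w.true_log_u5dr) * 1e4
        assert np.allclose(u5, w.config.baseline_u5dr)

    def test_null_model_rates_constant_in_time(self, null_world):
        per_district = np.exp(null_world.true_log_cdr).groupby(level="district").nunique()
        assert (per_district == 1).all()

    def test_conflict_category_rate_ratio_is_exact(self):
        """A lone conflict coefficient log(1.60) multiplies the baseline by
        exactly 1.60 in high-conflict district-months."""
        cfg = cm.WorldConfig(
            seed=9,
            true_coefficients={"conflict_rate[≥ 0.50]": np.log(1.60)},
            true_coefficients_u5={},
        )
        w = cm.generate_world(cfg)
        rate = np.exp(w.true_log_cdr) * 1e4
        conflict = w.panel_true["conflict_rate"].loc[rate.index]
        high = conflict >= 0.50
        assert np.allclose(rate[high] / cfg.baseline_cdr, 1.60)
        assert np.allclose(rate[~high], cfg.baseline_cdr)

    def test_unknown_coefficient_predictor_rejected(self):
        with pytest.raises(ValueError, match="unknown predictor"):
            cm.generate_world(cm.WorldConfig(true_coefficients={"rainfall_rank": 0.1}))

    def test_invalid_month_range_rejected(self):
        with pytest.raises(ValueError, match="24 months"):
            cm.WorldConfig(month_start="2017-01", month_end="2017-12")

    def test_flows_nonnegative_and_rates_positive(self, world):
        assert (world.flows["persons"] >= 0).all()
        assert np.isfinite(world.true_log_cdr).all()
        assert (world.pop_true["pop"] > 0).all()

    def test_monthly_outflows_bounded_by_population(self, world):
        """Generated departures never exceed the district's population: the
        generator caps outflows at 40% of the pre-flow stock, which implies
        total monthly departures stay below 2/3 of the end-of-month count."""
        out = world.flows.groupby(["origin", "month"])["persons"].sum()
        for (d, m), persons in out.items():
            assert persons <= (2 / 3) * world.pop_true.loc[(d, m), "pop"] + 1


class TestGenerateSurveys:
    def test_same_seed_identical_surveys(self, world):
        a = cm.generate_surveys(world, 3, seed=77)
        b = cm.generate_surveys(world, 3, seed=77)
        for x, y in zip(a, b):
            assert x.meta == y.meta
            pd.testing.assert_frame_equal(x.households, y.households)

    def test_pooled_rate_converges_to_truth(self, null_world):
        """Over >1e6 simulated person-days the pooled CDR estimate lies within
        3 Monte-Carlo standard errors of the configured rate."""
        surveys = cm.generate_surveys(null_world, 60, seed=11)
        d, pt, d5, pt5 = _pool(surveys)
        assert pt > 1e6
        truth = null_world.config.baseline_cdr
        se = np.sqrt(d) / pt * 1e4
        assert abs(d / pt * 1e4 - truth) < 3 * se
        truth5 = null_world.config.baseline_u5dr
        se5 = np.sqrt(d5) / pt5 * 1e4
        assert abs(d5 / pt5 * 1e4 - truth5) < 3 * se5

    def test_aggregate_questionnaire_has_no_member_rows(self, world):
        svs = cm.generate_surveys(world, 2, questionnaire="aggregate", seed=8)
        for s in svs:
            assert s.members is None
            assert {"n_end", "births", "joins", "leaves"} <= set(s.households.columns)
            assert "person_days" not in s.households.columns

    def test_recall_range_validation(self, world):
        with pytest.raises(ValueError, match="60..150"):
            cm.generate_surveys(world, 1, recall_days_range=(30, 90))
        with pytest.raises(ValueError, match="n_surveys"):
            cm.generate_surveys(world, 0)

    @staticmethod
    def _deff_ratio(sv):
        """Cluster-sum squared residuals over independent squared residuals —
        the ratio of the CR0 variance to the HC0 variance of the log rate."""
        hh = sv.households
        d = hh["deaths"].to_numpy(float)
        pt = hh["person_days"].to_numpy(float)
        if d.sum() < 2:
            return None
        r = d.sum() / pt.sum()
        resid = d - r * pt
        v_clu = pd.Series(resid).groupby(hh["cluster"].to_numpy()).sum().pow(2).sum()
        return v_clu / (resid**2).sum()

    def test_design_effect_near_one_without_frailty(self, null_world):
        """With zero between-cluster variance the cluster-robust variance
        matches the independence variance on average (design effect ~ 1)."""
        deffs = []
        for seed in range(25):
            (sv,) = cm.generate_surveys(null_world, 1, seed=seed, n_clusters=25,
                                        households_per_cluster=20)
            x = self._deff_ratio(sv)
            if x is not None:
                deffs.append(x)
        assert abs(np.mean(deffs) - 1.0) < 0.25

    def test_frailty_inflates_between_cluster_variance(self, null_world):
        """Lognormal cluster frailty inflates the cluster-level variance ratio
        relative to the same surveys drawn without frailty (paired seeds)."""
        with_f, without_f = [], []
        for seed in range(25):
            (a,) = cm.generate_surveys(null_world, 1, seed=seed, frailty_sd=0.8,
                                       n_clusters=25, households_per_cluster=20)
            (b,) = cm.generate_surveys(null_world, 1, seed=seed,
                                       n_clusters=25, households_per_cluster=20)
            xa, xb = self._deff_ratio(a), self._deff_ratio(b)
            if xa is not None and xb is not None:
                with_f.append(xa)
                without_f.append(xb)
        assert np.mean(with_f) > np.mean(without_f)


class TestUnderreporting:
    def test_p_zero_is_identity(self, surveys):
        sv = surveys[0]
        out = cm.apply_underreporting(sv, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.households, sv.households)

    def test_near_one_removes_almost_all(self, null_world):
        svs = cm.generate_surveys(null_world, 20, seed=3)
        total = sum(s.households["deaths_u5"].sum() for s in svs)
        kept = sum(
            cm.apply_underreporting(s, 0.999, seed=i).households["deaths_u5"].sum()
            for i, s in enumerate(svs)
        )
        assert total > 20 and kept <= 0.05 * total

    def test_half_removed_in_expectation(self, null_world):
        (sv,) = cm.generate_surveys(null_world, 1, seed=4, n_clusters=40,
                                    households_per_cluster=25)
        orig = sv.households["deaths_u5"].sum()
        assert orig >= 5
        kept = np.array(
            [cm.apply_underreporting(sv, 0.5, seed=s).households["deaths_u5"].sum()
             for s in range(200)]
        )
        se = np.sqrt(orig * 0.25 / 200)
        assert abs(kept.mean() - orig / 2) < 4 * se

    def test_person_time_and_allage_consistency(self, surveys):
        sv = surveys[1]
        out = cm.apply_underreporting(sv, 0.7, seed=2)
        pd.testing.assert_series_equal(out.households["person_days"], sv.households["person_days"])
        removed = sv.households["deaths_u5"] - out.households["deaths_u5"]
        assert ((sv.households["deaths"] - out.households["deaths"]) == removed).all()
        assert (out.households["deaths_u5"] <= out.households["deaths"]).all()

    def test_p_one_rejected(self, surveys):
        with pytest.raises(ValueError):
            cm.apply_underreporting(surveys[0], 1.0, seed=0)
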