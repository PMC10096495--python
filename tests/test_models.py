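"""Quasi-Poisson fitting, the Dawid-Sebastiani score, cross-validation and the
brute-force model search."""

import numpy as np
import pandas as pd
import pytest

import crisismort as cm
from crisismort.models import ModelScore, ModelSpec, Term, encode_design
from crisismort.predictors import CONFLICT_SCHEME


def _two_group_frame(n=400, rate0=0.5e-4, rr=2.0, pt=600.0, seed=0):
    """Closed-form oracle data: two groups with known rates, one binary term."""
    rng = np.random.default_rng(seed)
    group = np.repeat([0.0, 1.0], n // 2)
    deaths = rng.poisson(rate0 * np.where(group > 0, rr, 1.0) * pt, n)
    return pd.DataFrame(
        {
            "survey_id": np.repeat([f"S{i}" for i in range(10)], n // 10),
            "cluster": np.arange(n),
            "person_days": pt,
            "person_days_u5": pt / 4,
            "deaths": deaths,
            "deaths_u5": 0,
            "g": group,
        }
    )


class TestFitQuasipoisson:
    def test_intercept_only_closed_form(self):
        """2 deaths / 40,000 person-days: exp(intercept) = 5e-5 per person-day."""
        df = pd.DataFrame(
            {"survey_id": ["S1", "S1"], "cluster": [0, 1],
             "person_days": [20_000.0, 20_000.0], "person_days_u5": [5000.0, 5000.0],
             "deaths": [1, 1], "deaths_u5": [0, 0]}
        )
        fit = cm.fit_quasipoisson(df, ModelSpec("cdr"))
        assert np.exp(fit.coefficients["intercept"]) == pytest.approx(5e-5, rel=1e-8)

    def test_binary_covariate_equals_group_log_rate_ratio(self):
        """With one binary covariate the coefficient is exactly the log of the
        ratio of empirical group rates (analytic Poisson-GLM identity)."""
        df = _two_group_frame()
        fit = cm.fit_quasipoisson(df, ModelSpec("cdr", (Term("g"),)))
        r0 = df.loc[df.g == 0, "deaths"].sum() / df.loc[df.g == 0, "person_days"].sum()
        r1 = df.loc[df.g == 1, "deaths"].sum() / df.loc[df.g == 1, "person_days"].sum()
        assert fit.coefficients["g"] == pytest.approx(np.log(r1 / r0), rel=1e-6)

    def test_point_estimates_equal_poisson_mle(self, model_frame):
        """Dispersion never moves the point estimates: refitting with a plain
        Poisson likelihood (statsmodels, no phi) gives the same coefficients."""
        import statsmodels.api as sm

        spec = ModelSpec("cdr", (Term("conflict_rate", scheme=CONFLICT_SCHEME),))
        fit = cm.fit_quasipoisson(model_frame, spec)
        X, names = encode_design(model_frame, spec.terms)
        res = sm.GLM(
            model_frame["deaths"].to_numpy(float), X, family=sm.families.Poisson(),
            offset=np.log(model_frame["person_days"].to_numpy(float)),
        ).fit()
        assert np.allclose(fit.coefficients.to_numpy(), res.params, rtol=1e-6)

    def test_rank_deficiency_reported(self):
        df = _two_group_frame()
        df["g2"] = df["g"]
        with pytest.raises(ValueError, match="rank-deficient"):
            cm.fit_quasipoisson(df, ModelSpec("cdr", (Term("g"), Term("g2"))))

    def test_covariance_symmetric_psd(self, model_frame):
        fit = cm.fit_quasipoisson(
            model_frame, ModelSpec("cdr", (Term("conflict_rate", scheme=CONFLICT_SCHEME),))
        )
        cov = fit.covariance.to_numpy()
        assert np.allclose(cov, cov.T)
        assert (np.linalg.eigvalsh(cov) > -1e-12).all()
        assert fit.dispersion > 0


class TestDSS:
    @pytest.mark.parametrize(
        "y,mu,sigma2,expected",
        [(1.0, 1.0, 1.0, 0.0), (3.0, 1.0, 1.0, 4.0), (0.0, 2.0, 4.0, 1.0 + np.log(4.0))],
    )
    def test_closed_form(self, y, mu, sigma2, expected):
        assert cm.dss(y, mu, sigma2) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_mu_floored_finite(self):
        assert np.isfinite(cm.dss(0.0, 0.0, 0.0))

    def test_vectorized(self):
        out = cm.dss(np.array([1.0, 3.0]), np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert np.allclose(out, [0.0, 4.0])


class TestCrossValidate:
    def test_same_seed_same_score(self, model_frame):
        spec = ModelSpec("cdr")
        a = cm.cross_validate(spec, model_frame, k=5, seed=4)
        b = cm.cross_validate(spec, model_frame, k=5, seed=4)
        assert a == b

    def test_too_few_surveys_rejected(self, model_frame):
        with pytest.raises(ValueError, match="at least k"):
            cm.cross_validate(ModelSpec("cdr"), model_frame, k=500, seed=0)

    def test_leave_one_survey_out_limit(self, model_frame):
        k = model_frame["survey_id"].nunique()
        score = cm.cross_validate(ModelSpec("cdr"), model_frame, k=k, seed=0)
        assert np.isfinite(score)

    def test_duplicated_halves_give_equal_fold_scores(self):
        """A dataset made of two identical survey blocks, one per fold: by
        symmetry each fold's training data and held-out data coincide, so the
        fold scores are identical (deterministic fitting)."""
        from crisismort.models import _score_rows

        base = _two_group_frame(n=200, seed=3)
        dup = base.copy()
        dup["survey_id"] = dup["survey_id"] + "_dup"
        df = pd.concat([base, dup], ignore_index=True)
        spec = ModelSpec("cdr", (Term("g"),))
        scores = []
        for fold_ids in (set(base["survey_id"]), set(dup["survey_id"])):
            test = df["survey_id"].isin(fold_ids)
            fit = cm.fit_quasipoisson(df[~test], spec)
            scores.append(float(np.mean(_score_rows(fit, df[test]))))
        assert scores[0] == pytest.approx(scores[1], rel=1e-10)


class TestSearch:
    def test_enumeration_count_and_shortlist_arithmetic(self, model_frame):
        cands = [
            Term("conflict_rate", scheme=CONFLICT_SCHEME),
            Term("measles_rate", scheme=cm.CategoryScheme("measles_rate", (1e-9,), ("0", "> 0"))),
            Term("admin_level", levels=("somaliland_puntland", "south_central")),
        ]
        ranked = cm.brute_force_search(cands, model_frame, max_terms=3, k=5, seed=0)
        assert len(ranked) == 8  # all subsets of 3 candidates
        assert [s.cv_dss for s in ranked] == sorted(s.cv_dss for s in ranked)
        assert len(cm.shortlist(ranked, 0.2)) == 2  # ceil(0.2 * 8)

    def test_ranking_stable_under_rescore(self, model_frame):
        cands = [
            Term("conflict_rate", scheme=CONFLICT_SCHEME),
            Term("admin_level", levels=("somaliland_puntland", "south_central")),
        ]
        a = cm.brute_force_search(cands, model_frame, max_terms=2, k=5, seed=1)
        b = cm.brute_force_search(cands, model_frame, max_terms=2, k=5, seed=1)
        assert [s.spec.key for s in a] == [s.spec.key for s in b]

    def test_cap_refusal(self, model_frame):
        cands = [Term(f"x{i}") for i in range(20)]
        with pytest.raises(ValueError, match="cap"):
            cm.brute_force_search(cands, model_frame, max_terms=20, cap=100)

    def test_screen_empty_candidates(self, model_frame):
        assert cm.screen_predictors([], model_frame, k=5, seed=0) == []


class TestHoldout:
    def test_full_training_fraction_rejected(self, model_frame):
        with pytest.raises(ValueError, match="train_frac"):
            cm.holdout_validate(ModelSpec("cdr"), model_frame, train_frac=1.0)

    def test_same_seed_same_split(self, model_frame):
        a = cm.holdout_validate(ModelSpec("cdr"), model_frame, seed=9)
        b = cm.holdout_validate(ModelSpec("cdr"), model_frame, seed=9)
        assert a == b

    def test_select_final_is_deterministic(self, model_frame):
        short = [
            ModelScore(ModelSpec("cdr"), 1.0, None, 1),
            ModelScore(
                ModelSpec("cdr", (Term("conflict_rate", scheme=CONFLICT_SCHEME),)), 1.0, None, 3
            ),
        ]
        best1, rule = cm.select_final(short, model_frame, seed=2)
        best2, _ = cm.select_final(short, model_frame, seed=2)
        assert best1.spec.key == best2.spec.key
        assert rule == "lowest_holdout_then_fewest_params"
        assert best1.holdout_dss is not None


def test_null_cv_score_ignores_predictor_columns(model_frame):
    """The intercept-only model's CV score cannot depend on what predictor
    columns the frame carries."""
    a = cm.cross_validate(ModelSpec("cdr"), model_frame, k=5, seed=7)
    mutated = model_frame.copy()
    for c in mutated.columns:
        if c not in ("survey_id", "cluster", "person_days", "person_days_u5", "deaths", "deaths_u5"):
            mutated[c] = 0.0
    b = cm.cross_validate(ModelSpec("cdr"), mutated, k=5, seed=7)
    assert a == b
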