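"""Predictive quasi-Poisson mortality models and their selection.

Household death counts are modelled as quasi-Poisson with a log person-time
offset, so coefficients are log rate ratios on the death rate per person-day.
Dispersion phi is the Pearson chi-square over residual degrees of freedom;
coefficient covariance is the CR0 cluster sandwich, clustered on survey
cluster (each household is its own cluster under systematic sampling).

Candidate models are screened one predictor at a time, then enumerated by
brute force and ranked by mean 10-fold cross-validated Dawid-Sebastiani
score (folds partition *surveys*, never households, so a survey's clusters
cannot leak across folds); an 80/20 survey-level holdout supplies secondary
validation, and the final model is taken from the top-20% shortlist by a
deterministic rule (lowest holdout score, then fewest parameters).
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .predictors import CategoryScheme, DEFAULT_SCHEMES, categorize

__all__ = [
    "Term",
    "ModelSpec",
    "FittedModel",
    "ModelScore",
    "fit_quasipoisson",
    "dss",
    "cross_validate",
    "screen_predictors",
    "brute_force_search",
    "shortlist",
    "holdout_validate",
    "select_final",
    "fitted_from_coefficients",
    "parse_coefficient_key",
    "terms_from_coefficients",
    "encode_design",
    "linear_predictor_from_coefficients",
]

_DSS_MU_FLOOR = 1e-12

# static predictors whose levels are native categories, not cut continuous values
NATIVE_LEVELS: dict[str, tuple[str, ...]] = {
    "admin_level": ("somaliland_puntland", "south_central"),
    "livelihood": ("pastoral", "agropastoral", "riverine", "urban"),
}


@dataclass(frozen=True)
class Term:
    """One model term: a predictor at a lag, continuous or categorical."""

    predictor: str
    lag: int = 0
    scheme: CategoryScheme | None = None
    levels: tuple[str, ...] | None = None  # native categorical levels

    def __post_init__(self):
        if not 0 <= self.lag <= 6:
            raise ValueError(f"lag {self.lag} outside 0..6")
        if self.scheme is not None and self.levels is not None:
            raise ValueError("a term is either cut continuous or native categorical")

    @property
    def key(self) -> str:
        return self.predictor if self.lag == 0 else f"{self.predictor}@{self.lag}"

    def column_names(self) -> list[str]:
        if self.scheme is not None:
            return [f"{self.key}[{lab}]" for lab in self.scheme.labels[1:]]
        if self.levels is not None:
            return [f"{self.key}[{lab}]" for lab in self.levels[1:]]
        return [self.key]


@dataclass(frozen=True)
class ModelSpec:
    """Outcome plus an ordered, duplicate-free set of terms."""

    outcome: str  # "cdr" | "u5dr"
    terms: tuple[Term, ...] = ()
    max_terms: int = 6

    def __post_init__(self):
        if self.outcome not in ("cdr", "u5dr"):
            raise ValueError("outcome must be 'cdr' or 'u5dr'")
        keys = [t.key for t in self.terms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate terms in model spec")
        if len(self.terms) > self.max_terms:
            raise ValueError(f"more than {self.max_terms} terms")

    @property
    def key(self) -> str:
        return self.outcome + "~" + ("1" if not self.terms else "+".join(t.key for t in self.terms))

    def outcome_columns(self) -> tuple[str, str]:
        return ("deaths", "person_days") if self.outcome == "cdr" else ("deaths_u5", "person_days_u5")


def encode_design(df: pd.DataFrame, terms: tuple[Term, ...]) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) from continuous term-value columns.

    ``df`` must hold one column per term key with the continuous (or native
    categorical) value; cut schemes are applied here so categorization always
    happens after any recall-window averaging.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for t in terms:
        v = df[t.key]
        if t.scheme is not None:
            labels = categorize(v.to_numpy(dtype=float), t.scheme)
            for lab in t.scheme.labels[1:]:
                cols.append((labels == lab).astype(float))
        elif t.levels is not None:
            for lab in t.levels[1:]:
                cols.append((v.to_numpy(dtype=object) == lab).astype(float))
        else:
            cols.append(v.to_numpy(dtype=float))
        names.extend(t.column_names())
    return np.column_stack(cols), names


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: pd.Series  # log rate ratios, indexed by design column
    dispersion: float
    covariance: pd.DataFrame  # CR0 cluster-robust
    n_households: int
    n_clusters: int
    n_surveys: int

    @property
    def rate_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance.to_numpy())), index=self.coefficients.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.robust_se()
        return pd.DataFrame(
            {"lower": self.coefficients - z * se, "upper": self.coefficients + z * se}
        )

    def predict_rate(self, df: pd.DataFrame) -> np.ndarray:
        """Death rate per person-day for rows of continuous term values."""
        X, names = encode_design(df, self.spec.terms)
        beta = self.coefficients.reindex(names).to_numpy()
        return np.exp(X @ beta)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.key,
            "coefficients": self.coefficients.to_dict(),
            "dispersion": self.dispersion,
            "covariance": {c: self.covariance[c].to_dict() for c in self.covariance.columns},
            "n_households": self.n_households,
            "n_clusters": self.n_clusters,
            "n_surveys": self.n_surveys,
        }


@dataclass(frozen=True)
class ModelScore:
    spec: ModelSpec
    cv_dss: float
    holdout_dss: float | None
    n_params: int


def _cluster_key(df: pd.DataFrame) -> pd.Series:
    if "cluster" in df.columns:
        return df["survey_id"].astype(str) + ":" + df["cluster"].astype(str)
    return df["survey_id"].astype(str) + ":" + df.index.astype(str)


def fit_quasipoisson(df: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit the quasi-Poisson household model for one spec.

    Point estimates are the Poisson MLE (dispersion does not move them);
    phi = Pearson chi2 / df_resid; covariance is the CR0 sandwich
    B^{-1} (sum_g s_g s_g^T) B^{-1} with B the Fisher information and s_g the
    summed score of cluster g. Raises on rank deficiency or non-positive
    person-time.
    """
    ycol, ptcol = spec.outcome_columns()
    work = df[df[ptcol] > 0]
    if work.empty:
        raise ValueError("no rows with positive person-time")
    X, names = encode_design(work, spec.terms)
    # degenerate category levels in sparse survey draws are handled, with a
    # warning, before the rank check: (i) a level with no observations gives
    # an all-zero dummy, treated as reference (coefficient 0, zero variance);
    # (ii) if a term's *reference* level never occurs, its dummies sum to one
    # and are collinear with the intercept — the lowest observed level is
    # merged into the reference (its dummy dropped, coefficient 0)
    observed = (X != 0).any(axis=0)
    if not observed.all():
        dropped = [n for n, keep in zip(names, observed) if not keep]
        warnings.warn(
            f"levels never observed in training data treated as reference: {dropped}",
            stacklevel=2,
        )
    col_of = {n: j for j, n in enumerate(names)}
    for t in spec.terms:
        t_cols = [col_of[c] for c in t.column_names() if observed[col_of[c]]]
        if t.scheme is None and t.levels is None:
            continue  # continuous terms cannot have an unobserved reference
        if t_cols and not (X[:, t_cols] == 0).all(axis=1).any():
            merged = names[t_cols[0]]
            warnings.warn(
                f"reference level of {t.key} unobserved; merging {merged} into it",
                stacklevel=2,
            )
            observed[t_cols[0]] = False
    Xf = X[:, observed]
    kept_names = [n for n, keep in zip(names, observed) if keep]
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError(f"design matrix rank-deficient for {spec.key}")
    y = work[ycol].to_numpy(dtype=float)
    offset = np.log(work[ptcol].to_numpy(dtype=float))
    model = sm.GLM(y, Xf, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError(f"GLM did not converge for {spec.key}")
    mu = res.fittedvalues
    dof = max(len(y) - Xf.shape[1], 1)
    phi = float(np.sum((y - mu) ** 2 / mu) / dof)
    # CR0 sandwich, clustered on survey cluster
    bread = np.linalg.inv(Xf.T @ (Xf * mu[:, None]))
    score_rows = Xf * (y - mu)[:, None]
    groups = _cluster_key(work).to_numpy()
    scores = pd.DataFrame(score_rows).groupby(groups).sum().to_numpy()
    meat = scores.T @ scores
    cov_f = bread @ meat @ bread
    beta = pd.Series(0.0, index=names)
    beta[kept_names] = res.params
    cov = pd.DataFrame(0.0, index=names, columns=names)
    cov.loc[kept_names, kept_names] = cov_f
    return FittedModel(
        spec=spec,
        coefficients=beta,
        dispersion=phi,
        covariance=cov,
        n_households=len(work),
        n_clusters=len(np.unique(groups)),
        n_surveys=work["survey_id"].nunique(),
    )


def dss(y, mu, sigma2):
    """Dawid-Sebastiani score (y - mu)^2 / sigma2 + log sigma2; lower is better.

    For quasi-Poisson predictions sigma2 = phi * mu. mu (hence sigma2) is
    floored at 1e-12 so degenerate zero predictions stay finite without
    affecting comparisons at realistic scales.
    """
    mu = np.maximum(np.asarray(mu, dtype=float), _DSS_MU_FLOOR)
    sigma2 = np.maximum(np.asarray(sigma2, dtype=float), _DSS_MU_FLOOR)
    y = np.asarray(y, dtype=float)
    return (y - mu) ** 2 / sigma2 + np.log(sigma2)


def _score_rows(fit: FittedModel, df: pd.DataFrame) -> np.ndarray:
    ycol, ptcol = fit.spec.outcome_columns()
    work = df[df[ptcol] > 0]
    rate = fit.predict_rate(work)
    mu = rate * work[ptcol].to_numpy(dtype=float)
    return dss(work[ycol].to_numpy(dtype=float), mu, fit.dispersion * mu)


def _survey_folds(survey_ids: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    ids = np.sort(np.unique(survey_ids))
    rng.shuffle(ids)
    return [f for f in np.array_split(ids, k) if len(f)]


def cross_validate(spec: ModelSpec, df: pd.DataFrame, k: int = 10, seed: int = 0) -> float:
    """Mean Dawid-Sebastiani score over k survey-level folds.

    Each fold's held-out households are scored with the dispersion from that
    fold's training fit; the unweighted mean of fold means is returned.
    """
    ids = df["survey_id"].to_numpy()
    n_surveys = len(np.unique(ids))
    if n_surveys < k:
        raise ValueError(f"need at least k={k} surveys, have {n_surveys}")
    fold_means = []
    for fold in _survey_folds(ids, k, seed):
        test = np.isin(ids, fold)
        fit = fit_quasipoisson(df[~test], spec)
        fold_means.append(float(np.mean(_score_rows(fit, df[test]))))
    return float(np.mean(fold_means))


def screen_predictors(
    candidates: list[Term], df: pd.DataFrame, k: int = 10, seed: int = 0,
    margin: float = 0.0, outcome: str = "cdr",
) -> list[Term]:
    """Keep candidates whose single-term model beats the intercept-only CV score.

    A candidate survives iff cv(term) < cv(null) - margin (margin default 0).
    Candidates whose single-term fit fails (rank deficiency in some fold, e.g.
    an empty category level) are dropped.
    """
    null = cross_validate(ModelSpec(outcome), df, k=k, seed=seed)
    kept = []
    for t in candidates:
        try:
            score = cross_validate(ModelSpec(outcome, (t,)), df, k=k, seed=seed)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            continue
        if score < null - margin:
            kept.append(t)
    return kept


def brute_force_search(
    candidates: list[Term], df: pd.DataFrame, max_terms: int = 6, k: int = 10,
    seed: int = 0, outcome: str = "cdr", cap: int = 4096,
) -> list[ModelScore]:
    """CV-score every subset of candidates (within max_terms), ranked ascending.

    Ties are broken by fewer parameters, then by the spec key string. Refuses
    to enumerate more than ``cap`` subsets.
    """
    n_subsets = sum(
        math.comb(len(candidates), r) for r in range(0, min(max_terms, len(candidates)) + 1)
    )
    if n_subsets > cap:
        raise ValueError(f"{n_subsets} candidate subsets exceed the cap of {cap}")
    subsets = [
        combo
        for r in range(0, min(max_terms, len(candidates)) + 1)
        for combo in itertools.combinations(candidates, r)
    ]
    scored = []
    for combo in subsets:
        spec = ModelSpec(outcome, combo, max_terms=max_terms)
        try:
            score = cross_validate(spec, df, k=k, seed=seed)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            continue
        n_params = 1 + sum(len(t.column_names()) for t in combo)
        scored.append(ModelScore(spec, score, None, n_params))
    scored.sort(key=lambda s: (s.cv_dss, s.n_params, s.spec.key))
    return scored


def shortlist(ranked: list[ModelScore], frac: float = 0.2) -> list[ModelScore]:
    """Top fraction of a ranked leaderboard, at least one model (ceil rule)."""
    if not ranked:
        return []
    return ranked[: math.ceil(frac * len(ranked))]


def holdout_validate(
    spec: ModelSpec, df: pd.DataFrame, train_frac: float = 0.8, seed: int = 0
) -> float:
    """Mean DSS on a random survey-level holdout after fitting on the rest."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be strictly between 0 and 1")
    ids = np.sort(df["survey_id"].unique())
    if len(ids) < 5:
        raise ValueError("need at least 5 surveys for a holdout split")
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = int(round(train_frac * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids = set(ids[:n_train])
    train = df[df["survey_id"].isin(train_ids)]
    test = df[~df["survey_id"].isin(train_ids)]
    fit = fit_quasipoisson(train, spec)
    return float(np.mean(_score_rows(fit, test)))


def select_final(
    short: list[ModelScore], df: pd.DataFrame, train_frac: float = 0.8, seed: int = 0
) -> tuple[ModelScore, str]:
    """Deterministic default choice from the shortlist.

    Real analyses of this kind select the final model manually among the
    shortlisted ones; here the default rule is lowest holdout score, ties
    broken by fewest parameters then spec key. Returns the chosen score
    (holdout filled in) and the name of the rule that fired.
    """
    if not short:
        raise ValueError("empty shortlist")
    rescored = []
    for s in short:
        hd = holdout_validate(s.spec, df, train_frac=train_frac, seed=seed)
        rescored.append(ModelScore(s.spec, s.cv_dss, hd, s.n_params))
    rescored.sort(key=lambda s: (s.holdout_dss, s.n_params, s.spec.key))
    return rescored[0], "lowest_holdout_then_fewest_params"


def fitted_from_coefficients(
    outcome: str,
    coefficients: dict[str, float],
    baseline_rate_per_10k: float,
    covariance: pd.DataFrame | None = None,
    dispersion: float = 1.0,
    schemes: dict[str, CategoryScheme] | None = None,
) -> FittedModel:
    """A FittedModel with known coefficients (oracle/plug-in use).

    The intercept is log(baseline per 10,000 person-days / 10,000); the
    covariance defaults to all zeros, making bootstrap draws degenerate at
    the plug-in prediction.
    """
    terms = terms_from_coefficients(coefficients, schemes)
    names = ["intercept"] + [c for t in terms for c in t.column_names()]
    beta = pd.Series(
        [np.log(baseline_rate_per_10k / 1e4)] + [coefficients.get(n, 0.0) for n in names[1:]],
        index=names,
    )
    cov = covariance if covariance is not None else pd.DataFrame(
        np.zeros((len(names), len(names))), index=names, columns=names
    )
    return FittedModel(
        spec=ModelSpec(outcome, terms),
        coefficients=beta,
        dispersion=dispersion,
        covariance=cov,
        n_households=0,
        n_clusters=0,
        n_surveys=0,
    )


_KEY_RE = re.compile(r"^(?P<pred>[^@\[\]]+)(?:@(?P<lag>\d+))?(?:\[(?P<level>[^\]]+)\])?$")


def parse_coefficient_key(key: str) -> tuple[str, int, str | None]:
    """Parse 'pred@lag[level]' into (predictor, lag, level)."""
    m = _KEY_RE.match(key)
    if not m:
        raise ValueError(f"malformed coefficient key {key!r}")
    return m["pred"], int(m["lag"] or 0), m["level"]


def terms_from_coefficients(
    coefficients: dict[str, float], schemes: dict[str, CategoryScheme] | None = None
) -> tuple[Term, ...]:
    """Model terms implied by a coefficient map (one term per predictor+lag)."""
    schemes = {**DEFAULT_SCHEMES, **(schemes or {})}
    seen: dict[tuple[str, int], Term] = {}
    for key in coefficients:
        pred, lag, level = parse_coefficient_key(key)
        if (pred, lag) in seen:
            continue
        if pred in NATIVE_LEVELS:
            seen[(pred, lag)] = Term(pred, lag, levels=NATIVE_LEVELS[pred])
        elif level is not None:
            if pred not in schemes:
                raise ValueError(f"no category scheme known for predictor {pred!r}")
            seen[(pred, lag)] = Term(pred, lag, scheme=schemes[pred])
        else:
            seen[(pred, lag)] = Term(pred, lag)
    return tuple(seen.values())


def linear_predictor_from_coefficients(
    df: pd.DataFrame, coefficients: dict[str, float],
    schemes: dict[str, CategoryScheme] | None = None,
) -> np.ndarray:
    """Sum of coefficient x encoded-term-value for rows of continuous values.

    Used by the synthetic-data generator so the truth uses exactly the same
    term encodings (cut-points, lags, dummies) as fitted models.
    """
    terms = terms_from_coefficients(coefficients, schemes)
    X, names = encode_design(df, terms)
    beta = np.array([coefficients.get(n, 0.0) for n in names])
    return X @ beta
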