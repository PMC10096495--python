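"""Counterfactual scenarios and bootstrap estimation of excess death tolls.

The fitted mortality model predicts a death rate per person-day for every
district-month; multiplying by population person-time gives expected tolls.
A counterfactual no-crisis panel replaces crisis-sensitive predictors from
the start of the excess window (default Jan 2017) with reference statistics
of 2014-2016 (month-specific medians or percentiles within each district,
fractions of actuality, or zero) and rebuilds denominators under an
alternative displacement rule. Uncertainty comes from a parametric bootstrap
on the coefficients: each replicate draws one beta from N(beta_hat, Sigma)
with the cluster-robust covariance and uses the *same* draw for the actual
and counterfactual arm, so an identity counterfactual yields exactly zero
excess in every replicate. Point estimates are distribution modes
(Freedman-Diaconis histogram, midpoint of the modal bin); intervals are
2.5th/97.5th empirical percentiles with linear interpolation.

Coefficient uncertainty is the only error source propagated: the target is
the expected excess toll, so Poisson realization noise is deliberately
excluded. This is the single most consequential interpretation in the
package and is documented in the methods note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_month, round_to
from .denominators import PopulationSeries
from .models import FittedModel
from .predictors import lagged_values

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "ExcessReplicates",
    "canonical_scenarios",
    "build_counterfactual",
    "counterfactual_flows",
    "predict_tolls",
    "bootstrap_excess",
    "summarize",
    "aggregate_tables",
]

PREDICTOR_RULES = {
    "month_specific_median_2014_16",
    "month_specific_p75_2014_16",
    "month_specific_p25_2014_16",
    "median_2014_16",
    "as_actual",
    "zero",
}
DISPLACEMENT_RULES = {"no_drought_displacement", "as_actual", "no_new_displacement"}


@dataclass(frozen=True)
class ScenarioSpec:
    """Per-predictor counterfactual rules plus a displacement rule.

    Predictor rules are the rule-set names above or ("fraction_of_actual", q)
    with q in (0, 1]. Every model predictor must have exactly one rule;
    predictors without an entry default to "as_actual".
    """

    name: str
    predictor_rules: dict
    displacement_rule: str = "as_actual"

    def __post_init__(self):
        for pred, rule in self.predictor_rules.items():
            if isinstance(rule, tuple):
                kind, q = rule
                if kind != "fraction_of_actual" or not 0 < q <= 1:
                    raise ValueError(f"bad rule {rule!r} for {pred}")
            elif rule not in PREDICTOR_RULES:
                raise ValueError(f"unknown rule {rule!r} for {pred}")
        if self.displacement_rule not in DISPLACEMENT_RULES:
            raise ValueError(f"unknown displacement rule {self.displacement_rule!r}")


def canonical_scenarios() -> dict[str, ScenarioSpec]:
    """The three study scenarios: most likely, worst case, best case.

    Worst case lowers malaria (which predicts *lower* mortality) and keeps
    measles and conflict at actual levels; best case removes measles and cuts
    conflict to a quarter of actuality.
    """
    return {
        "most_likely": ScenarioSpec(
            "most_likely",
            {
                "sam_rate": "month_specific_median_2014_16",
                "measles_rate": "month_specific_median_2014_16",
                "malaria_rate": "month_specific_median_2014_16",
                "conflict_rate": "median_2014_16",
            },
            displacement_rule="no_drought_displacement",
        ),
        "worst_case": ScenarioSpec(
            "worst_case",
            {
                "sam_rate": "month_specific_p75_2014_16",
                "measles_rate": "as_actual",
                "malaria_rate": ("fraction_of_actual", 0.25),
                "conflict_rate": "as_actual",
            },
            displacement_rule="as_actual",
        ),
        "best_case": ScenarioSpec(
            "best_case",
            {
                "sam_rate": "month_specific_p25_2014_16",
                "measles_rate": "zero",
                "malaria_rate": "as_actual",
                "conflict_rate": ("fraction_of_actual", 0.25),
            },
            displacement_rule="no_new_displacement",
        ),
    }


def _reference_stat(rule: str):
    return {
        "month_specific_median_2014_16": 0.50,
        "month_specific_p75_2014_16": 0.75,
        "month_specific_p25_2014_16": 0.25,
    }[rule]


def build_counterfactual(
    panel: pd.DataFrame,
    scenario: ScenarioSpec,
    reference_years: tuple[int, ...] = (2014, 2015, 2016),
    start: str = "2017-01",
    region_of: dict | None = None,
) -> pd.DataFrame:
    """Counterfactual predictor panel; months before ``start`` stay actual.

    Month-specific rules replace the value at (district d, calendar month m,
    year >= start) with the stated percentile of {(d, m, y) : y in reference
    years}; the plain median rule pools all reference months. Districts with
    no reference-year data fall back to the region-level statistic (logged).
    """
    out = panel.copy()
    start_m = as_month(start)
    months = panel.index.get_level_values("month")
    cf_mask = months >= start_m
    ref_mask = np.isin(months.year, list(reference_years))
    if not ref_mask.any():
        raise ValueError("panel does not cover the reference years")
    for pred, rule in scenario.predictor_rules.items():
        if pred not in panel.columns or rule == "as_actual":
            continue
        if rule == "zero":
            out.loc[cf_mask, pred] = 0.0
            continue
        if isinstance(rule, tuple):
            out.loc[cf_mask, pred] = panel.loc[cf_mask, pred] * rule[1]
            continue
        ref = panel[ref_mask]
        if rule == "median_2014_16":
            stat = ref.groupby(level="district")[pred].median()
            districts_cf = panel.index.get_level_values("district")[cf_mask]
            out.loc[cf_mask, pred] = stat.reindex(districts_cf).to_numpy()
        else:
            q = _reference_stat(rule)
            by_dm = ref.groupby(
                [ref.index.get_level_values("district"), ref.index.get_level_values("month").month]
            )[pred].quantile(q)
            districts_cf = panel.index.get_level_values("district")[cf_mask]
            calmonth_cf = months[cf_mask].month
            key = list(zip(districts_cf, calmonth_cf))
            vals = by_dm.reindex(key).to_numpy()
            if np.isnan(vals).any() and region_of is not None:
                # region-level fallback for strata without reference data
                ref_r = ref.copy()
                ref_r["_region"] = [region_of[d] for d in ref.index.get_level_values("district")]
                by_rm = ref_r.groupby(["_region", ref.index.get_level_values("month").month])[
                    pred
                ].quantile(q)
                fb = by_rm.reindex(
                    [(region_of[d], m) for d, m in key]
                ).to_numpy()
                n_fb = int(np.isnan(vals).sum())
                log.info("%s: %d cells fell back to region-level reference", pred, n_fb)
                vals = np.where(np.isnan(vals), fb, vals)
            out.loc[cf_mask, pred] = vals
    return out


def counterfactual_flows(flows: pd.DataFrame, rule: str, start: str = "2017-01") -> pd.DataFrame:
    """Displacement flow table under a scenario's displacement rule."""
    if rule not in DISPLACEMENT_RULES:
        raise ValueError(f"unknown displacement rule {rule!r}")
    if flows is None or len(flows) == 0 or rule == "as_actual":
        return flows
    start_m = as_month(start)
    f = flows.copy()
    f["month"] = pd.PeriodIndex(f["month"], freq="M")
    after = f["month"] >= start_m
    if rule == "no_new_displacement":
        drop = after & f["kind"].isin(["IDP", "returnee"])
    else:  # no_drought_displacement
        drop = after & f["kind"].isin(["IDP", "returnee"]) & (f["reason"] == "drought")
    return f[~drop].reset_index(drop=True)


def _design_for_panel(
    model: FittedModel, panel: pd.DataFrame, months: pd.PeriodIndex
) -> tuple[np.ndarray, pd.MultiIndex]:
    rows = pd.DataFrame(index=panel.index)
    for t in model.spec.terms:
        rows[t.key] = lagged_values(panel, t.predictor, t.lag)
    mask = rows.index.get_level_values("month").isin(months)
    rows = rows[mask]
    if rows.isna().any().any():
        bad = rows.columns[rows.isna().any()].tolist()
        raise ValueError(f"missing predictor values for model terms {bad}")
    from .models import encode_design

    X, names = encode_design(rows, model.spec.terms)
    order = [names.index(c) for c in model.coefficients.index]
    return X[:, order], rows.index


def _person_time(pop: PopulationSeries, index: pd.MultiIndex, age_group: str) -> np.ndarray:
    col = "pop_u5" if age_group == "under5" else "pop"
    tab = pop.table[col].reindex(index)
    if tab.isna().any():
        raise ValueError("population series does not cover all prediction cells")
    days = np.array([m.days_in_month for m in index.get_level_values("month")], dtype=float)
    return tab.to_numpy() * days


def predict_tolls(
    model: FittedModel,
    panel: pd.DataFrame,
    pop: PopulationSeries,
    months: pd.PeriodIndex,
    age_group: str = "all",
) -> pd.Series:
    """Expected deaths per district-month: exp(x'beta) x population x days."""
    X, index = _design_for_panel(model, panel, months)
    pt = _person_time(pop, index, age_group)
    beta = model.coefficients.to_numpy()
    return pd.Series(np.exp(X @ beta) * pt, index=index, name="expected_deaths")


@dataclass
class ExcessReplicates:
    """Bootstrap death tolls by (district, period) for both arms.

    ``actual`` and ``counterfactual`` are (n_rows x B) arrays aligned to
    ``index``; excess is their difference, computed replicate by replicate so
    sums over districts/periods commute with the subtraction.
    """

    index: pd.MultiIndex  # (district, period)
    actual: np.ndarray
    counterfactual: np.ndarray
    region_of: dict
    scenario: str
    age_group: str

    @property
    def excess(self) -> np.ndarray:
        return self.actual - self.counterfactual

    @property
    def n_replicates(self) -> int:
        return self.actual.shape[1]


def _draw_betas(model: FittedModel, B: int, rng) -> np.ndarray:
    beta = model.coefficients.to_numpy()
    cov = model.covariance.to_numpy()
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if (vals < -1e-10 * max(vals.max(), 1.0)).any():
        log.warning("covariance not PSD; clipping negative eigenvalues")
    vals = np.clip(vals, 0.0, None)
    L = vecs * np.sqrt(vals)
    z = rng.standard_normal((B, len(beta)))
    return beta + z @ L.T


def bootstrap_excess(
    model: FittedModel,
    panel_actual: pd.DataFrame,
    pop_actual: PopulationSeries,
    panel_cf: pd.DataFrame,
    pop_cf: PopulationSeries,
    months: pd.PeriodIndex,
    B: int = 10_000,
    seed: int = 0,
    region_of: dict | None = None,
    scenario: str = "",
    age_group: str = "all",
    by: str = "year",
    chunk: int = 2_000,
) -> ExcessReplicates:
    """Parametric bootstrap of actual and counterfactual tolls.

    Each replicate draws one coefficient vector from N(beta_hat, Sigma) and
    applies it to both arms. Tolls are aggregated to (district, year) rows by
    default ("month" keeps full resolution); computation is chunked over
    replicates to bound memory.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    X_a, idx = _design_for_panel(model, panel_actual, months)
    X_c, idx_c = _design_for_panel(model, panel_cf, months)
    if not idx.equals(idx_c):
        raise ValueError("actual and counterfactual panels misaligned")
    pt_a = _person_time(pop_actual, idx, age_group)
    pt_c = _person_time(pop_cf, idx, age_group)
    betas = _draw_betas(model, B, rng)

    if by == "year":
        keys = list(zip(idx.get_level_values("district"), idx.get_level_values("month").year))
    else:
        keys = list(idx)
    out_index = pd.MultiIndex.from_tuples(sorted(set(keys)), names=["district", "period"])
    pos = {k: i for i, k in enumerate(out_index)}
    G = np.zeros((len(out_index), len(keys)))
    for j, k in enumerate(keys):
        G[pos[k], j] = 1.0

    act = np.empty((len(out_index), B))
    cf = np.empty((len(out_index), B))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        bl = betas[lo:hi].T  # p x b
        act[:, lo:hi] = G @ (np.exp(X_a @ bl) * pt_a[:, None])
        cf[:, lo:hi] = G @ (np.exp(X_c @ bl) * pt_c[:, None])
    return ExcessReplicates(
        index=out_index,
        actual=act,
        counterfactual=cf,
        region_of=region_of or {},
        scenario=scenario,
        age_group=age_group,
    )


def _mode(values: np.ndarray) -> float:
    """Midpoint of the modal Freedman-Diaconis histogram bin."""
    if np.ptp(values) == 0:
        return float(values[0])
    counts, edges = np.histogram(values, bins="fd")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _interval(values: np.ndarray, alpha: float) -> tuple[float, float]:
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)], method="linear")
    return float(lo), float(hi)


def summarize(
    reps: ExcessReplicates, alpha: float = 0.05, by: str = "national", period: str = "overall"
) -> pd.DataFrame:
    """Modes and 95% percentile intervals of tolls per stratum and period.

    ``by`` is district, region or national; ``period`` is "overall" (sum over
    all periods) or "period" (keep the replicate matrix's period resolution).
    Replicates are summed within each stratum *before* summarising, so the
    national mode need not equal the sum of district modes.
    """
    if reps.n_replicates < 100:
        raise ValueError("need at least 100 replicates to summarise")
    districts = reps.index.get_level_values("district")
    periods = reps.index.get_level_values("period")
    if by == "national":
        strata = pd.Series("national", index=reps.index)
    elif by == "region":
        strata = pd.Series([reps.region_of.get(d, d) for d in districts], index=reps.index)
    elif by == "district":
        strata = pd.Series(districts, index=reps.index)
    else:
        raise ValueError(f"unknown stratum level {by!r}")
    pkey = pd.Series("overall", index=reps.index) if period == "overall" else pd.Series(periods, index=reps.index)

    rows = []
    frame = pd.DataFrame({"stratum": strata.to_numpy(), "period": pkey.to_numpy()})
    for (s, p), grp in frame.groupby(["stratum", "period"], sort=True):
        sel = frame.index.isin(grp.index)
        a = reps.actual[sel].sum(axis=0)
        c = reps.counterfactual[sel].sum(axis=0)
        e = a - c
        a_lo, a_hi = _interval(a, alpha)
        e_lo, e_hi = _interval(e, alpha)
        rows.append(
            {
                "stratum": s,
                "period": p,
                "age_group": reps.age_group,
                "scenario": reps.scenario,
                "actual_mode": _mode(a),
                "actual_lo": a_lo,
                "actual_hi": a_hi,
                "counterfactual_mode": _mode(c),
                "excess_mode": _mode(e),
                "excess_lo": e_lo,
                "excess_hi": e_hi,
                "n_replicates": reps.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def aggregate_tables(
    summaries: list[pd.DataFrame], rounding: float = 100.0
) -> dict[str, pd.DataFrame]:
    """Report tables: tolls by year x scenario and by region, rounded to 100s.

    Rounding is half-up to the nearest ``rounding`` (44,650 -> 44,700),
    applied to every toll column.
    """
    allrows = pd.concat(summaries, ignore_index=True)
    toll_cols = [c for c in allrows.columns if c.endswith(("_mode", "_lo", "_hi"))]
    rounded = allrows.copy()
    rounded[toll_cols] = round_to(allrows[toll_cols].to_numpy(), rounding)
    by_year = rounded[rounded["stratum"] == "national"].pivot_table(
        index=["period", "age_group"],
        columns="scenario",
        values=["actual_mode", "excess_mode", "excess_lo", "excess_hi"],
        aggfunc="first",
    )
    regions = rounded[~rounded["stratum"].isin(["national"])]
    by_region = regions[regions["period"] == "overall"] if (regions["period"] == "overall").any() else regions
    return {"by_year_scenario": by_year, "by_region": by_region}
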