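"""Synthetic district-month world with SMART-style surveys drawn from it.

The generator builds everything the downstream stages need, with known
ground truth: a district table, monthly predictor series (armed-conflict
event rates, SAM treatment admissions, facility malaria and reported measles
incidence, a water-price series with realistic missingness), true log death
rates driven by a configurable coefficient map *using exactly the model's
term encodings* (cut-points, lags, dummy levels), population trajectories
with natural growth and reason-tagged displacement flows, discrepant
census-source anchors, and household surveys whose death counts are Poisson
with expectation true rate x person-time.

Death generation splits a household's expectation into under-5 and 5+
components so that E[all-age deaths] = CDR x person-days and
E[under-5 deaths] = U5DR x child-days hold simultaneously; between-cluster
heterogeneity is an optional lognormal frailty on the cluster's rate
(mean 1, default variance 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import as_month, month_range
from .config import WorldConfig
from .models import linear_predictor_from_coefficients, parse_coefficient_key, terms_from_coefficients
from .predictors import PredictorPanel, lagged_values
from .surveys import SurveyDataset, SurveyMeta

__all__ = ["SyntheticWorld", "generate_world", "generate_surveys", "apply_underreporting"]

REASONS = ("drought", "insecurity", "flooding", "other")
_KNOWN_PREDICTORS = {
    "conflict_rate",
    "sam_rate",
    "malaria_rate",
    "measles_rate",
    "water_price",
    "admin_level",
    "livelihood",
}


@dataclass
class SyntheticWorld:
    config: WorldConfig
    districts: pd.DataFrame  # district, region, admin_level, livelihood
    months: pd.PeriodIndex  # public analysis months
    panel_true: pd.DataFrame  # (district, month incl. 6-month lead-in) x predictors
    panel_observed: pd.DataFrame  # same, with price missingness + noise
    true_log_cdr: pd.Series  # (district, month) log deaths per person-day
    true_log_u5dr: pd.Series
    pop_true: pd.DataFrame  # (district, month) true all-age population
    anchors: list  # CensusAnchor
    flows: pd.DataFrame  # month, origin, destination, persons, reason, kind

    @property
    def region_of(self) -> dict:
        return dict(zip(self.districts["district"], self.districts["region"]))

    def term_panel(self, coefficients: dict[str, float] | None = None) -> pd.DataFrame:
        """Continuous term-value columns (lag applied) plus static columns.

        Columns are keyed by the model-term grammar ("sam_rate@2" is the SAM
        admission rate two months earlier), evaluated from the *true* panel so
        the generative rates and any oracle computation share one encoding.
        """
        coefficients = coefficients or self.config.true_coefficients
        keys = sorted({(parse_coefficient_key(k)[0], parse_coefficient_key(k)[1]) for k in coefficients})
        out = pd.DataFrame(index=self.panel_true.index)
        for pred, lag in keys:
            col = pred if lag == 0 else f"{pred}@{lag}"
            out[col] = lagged_values(self.panel_true, pred, lag)
        return out

    def true_rate_over_window(
        self, district: str, recall_start, recall_end
    ) -> tuple[float, float]:
        """(CDR, U5DR) per person-day over a recall window in one district.

        Predictor terms are day-weight averaged over the window on the
        continuous scale and then encoded — the same order of operations the
        fitted models use — so surveys are generated from the covariate value
        a correctly specified model would see.
        """
        from .predictors import average_over_recall

        cfg = self.config
        tp = self.term_panel({**cfg.true_coefficients, **cfg.true_coefficients_u5})
        row = average_over_recall(tp, district, recall_start, recall_end).to_frame().T
        lp_cdr = linear_predictor_from_coefficients(row, cfg.true_coefficients)[0]
        lp_u5 = linear_predictor_from_coefficients(row, cfg.true_coefficients_u5)[0]
        return (
            cfg.baseline_cdr / 1e4 * float(np.exp(lp_cdr)),
            cfg.baseline_u5dr / 1e4 * float(np.exp(lp_u5)),
        )


def _validate_coefficients(config: WorldConfig) -> None:
    for cmap in (config.true_coefficients, config.true_coefficients_u5):
        for key in cmap:
            pred, lag, _ = parse_coefficient_key(key)
            if pred not in _KNOWN_PREDICTORS:
                raise ValueError(f"coefficient references unknown predictor term {key!r}")
            if not 0 <= lag <= 6:
                raise ValueError(f"coefficient lag outside 0..6 in {key!r}")
        terms_from_coefficients(cmap)  # raises on missing category scheme


def _ar1(rng, n, rho, sigma):
    eps = rng.normal(0.0, sigma, n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(max(1 - rho**2, 1e-9))
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t]
    return out


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build the synthetic world deterministically from ``config.seed``."""
    _validate_coefficients(config)
    rng = np.random.default_rng(config.seed)
    months = month_range(config.month_start, config.month_end)
    lead_in = 6  # so every lag-k term is defined from the first analysis month
    months_ext = month_range((months[0] - lead_in).strftime("%Y-%m"), config.month_end)
    D, T = config.n_districts, len(months_ext)

    districts = [f"D{i + 1:02d}" for i in range(D)]
    regions = [f"R{i % config.n_regions + 1}" for i in range(D)]
    n_north = max(1, round(config.n_regions / 3))
    north = {f"R{i + 1}" for i in range(n_north)}
    admin = ["somaliland_puntland" if r in north else "south_central" for r in regions]
    livelihood = rng.choice(["pastoral", "agropastoral", "riverine", "urban"], size=D)
    district_table = pd.DataFrame(
        {"district": districts, "region": regions, "admin_level": admin, "livelihood": livelihood}
    )

    crisis = config.crisis
    c_start, c_end = as_month(crisis.start), as_month(crisis.end)
    in_crisis = np.array([(c_start <= m <= c_end) for m in months_ext])
    month_no = np.array([m.month for m in months_ext])
    season = 1.0 + 0.25 * np.sin(2 * np.pi * (month_no - 4) / 12)

    idx = pd.MultiIndex.from_product([districts, months_ext], names=["district", "month"])
    panel = pd.DataFrame(index=idx)

    conflict_base = np.exp(rng.normal(np.log(0.30), 0.8, D))
    sam_base = np.exp(rng.normal(np.log(130.0), 0.5, D))
    malaria_base = np.exp(rng.normal(np.log(40.0), 0.8, D))
    # a third of districts are low-transmission (mostly zero reporting)
    malaria_zero_p = np.where(rng.random(D) < 0.33, rng.uniform(0.7, 0.95, D), rng.uniform(0.1, 0.4, D))
    price_base = np.exp(rng.normal(np.log(10_000.0), 0.3, D))

    conflict = np.empty((D, T))
    sam = np.empty((D, T))
    malaria = np.empty((D, T))
    measles = np.zeros((D, T))
    price = np.empty((D, T))
    for i in range(D):
        conflict[i] = conflict_base[i] * np.exp(_ar1(rng, T, 0.6, 0.35))
        conflict[i, in_crisis] *= crisis.conflict_multiplier
        sam[i] = sam_base[i] * season * np.exp(_ar1(rng, T, 0.5, 0.25))
        sam[i, in_crisis] *= crisis.sam_multiplier
        mal = malaria_base[i] * season * np.exp(_ar1(rng, T, 0.5, 0.4))
        mal[in_crisis] *= crisis.malaria_multiplier
        # persistent zero runs: low-transmission districts report no cases for
        # stretches of months, not isolated single months
        zero = np.empty(T, dtype=bool)
        zero[0] = rng.random() < malaria_zero_p[i]
        for t in range(1, T):
            zero[t] = zero[t - 1] if rng.random() < 0.85 else rng.random() < malaria_zero_p[i]
        malaria[i] = np.where(zero, 0.0, mal)
        p_out = np.where(in_crisis, crisis.measles_outbreak_prob, 0.08)
        outbreak = rng.random(T) < p_out
        measles[i] = np.where(outbreak, np.exp(rng.normal(np.log(8.0), 0.9, T)), 0.0)
        trend = np.linspace(0, 0.15, T)
        price[i] = price_base[i] * np.exp(trend + _ar1(rng, T, 0.8, 0.06))
        price[i, in_crisis] *= 1.3

    panel["conflict_rate"] = conflict.ravel()
    panel["sam_rate"] = sam.ravel()
    panel["malaria_rate"] = malaria.ravel()
    panel["measles_rate"] = measles.ravel()
    panel["water_price"] = price.ravel()
    panel["admin_level"] = np.repeat(admin, T)
    panel["livelihood"] = np.repeat(livelihood, T)

    # observed panel: model predictors are administrative reporting series taken
    # as-is; the market price series carries missingness and reporting noise
    observed = panel.copy()
    miss = rng.random(len(observed)) < 0.25
    noise = np.exp(rng.normal(0.0, 0.05, len(observed)))
    observed["water_price"] = np.where(miss, np.nan, observed["water_price"] * noise)

    # true log rates on the analysis months, via the model's own encodings
    all_coefs = {**config.true_coefficients, **config.true_coefficients_u5}
    keys = sorted({(parse_coefficient_key(k)[0], parse_coefficient_key(k)[1]) for k in all_coefs})
    tp = pd.DataFrame(index=panel.index)
    for pred, lag in keys:
        col = pred if lag == 0 else f"{pred}@{lag}"
        tp[col] = lagged_values(panel, pred, lag)
    pub = tp[tp.index.get_level_values("month").isin(months)]
    lp_cdr = linear_predictor_from_coefficients(pub, config.true_coefficients)
    lp_u5 = linear_predictor_from_coefficients(pub, config.true_coefficients_u5)
    true_log_cdr = pd.Series(np.log(config.baseline_cdr / 1e4) + lp_cdr, index=pub.index)
    true_log_u5dr = pd.Series(np.log(config.baseline_u5dr / 1e4) + lp_u5, index=pub.index)

    # population and displacement flows, generated jointly month by month so
    # outflows never exceed the current population
    g = (1 + config.growth_rate_yr) ** (1 / 12)
    base_pop = np.exp(rng.normal(np.log(180_000.0), 0.45, D))
    pop = np.empty((D, len(months)))
    pop[:, 0] = base_pop
    flow_rows = []
    flows_from = as_month("2016-01")
    crisis_sev = conflict[:, -T + lead_in :]  # severity weight per district-month
    for t, m in enumerate(months):
        if t > 0:
            pop[:, t] = g * pop[:, t - 1]
        if m >= flows_from:
            mi = lead_in + t
            lam = 1.2 * D if in_crisis[mi] else 0.35 * D
            n_events = rng.poisson(lam)
            out_totals = np.zeros(D)
            for _ in range(n_events):
                if in_crisis[mi]:
                    p_reason = np.array([0.62, 0.22, 0.11, 0.05])
                else:
                    p_reason = np.array([0.18, 0.52, 0.20, 0.10])
                reason = REASONS[rng.choice(4, p=p_reason)]
                w = crisis_sev[:, t] + 0.1
                origin = int(rng.choice(D, p=w / w.sum()))
                kind = ("IDP", "returnee", "refugee")[rng.choice(3, p=[0.85, 0.10, 0.05])]
                persons = float(
                    np.exp(rng.normal(np.log(2000.0), 0.9))
                    * (crisis.displacement_scale if reason == "drought" else 1.0)
                )
                cap = 0.4 * pop[origin, t] - out_totals[origin]
                persons = min(persons, max(cap, 0.0))
                if persons < 1:
                    continue
                out_totals[origin] += persons
                if kind == "refugee":
                    dest = "EXTERNAL"
                else:
                    dest = districts[int(rng.choice([j for j in range(D) if j != origin]))]
                flow_rows.append(
                    {
                        "month": m,
                        "origin": districts[origin],
                        "destination": dest,
                        "persons": round(persons),
                        "reason": reason,
                        "kind": kind,
                    }
                )
            for row in flow_rows:
                if row["month"] != m:
                    continue
                o = districts.index(row["origin"]) if row["origin"] in districts else None
                d_ = districts.index(row["destination"]) if row["destination"] in districts else None
                if o is not None:
                    pop[o, t] -= row["persons"]
                if d_ is not None:
                    pop[d_, t] += row["persons"]
        pop[:, t] = np.maximum(pop[:, t], 1.0)
    flows = pd.DataFrame(
        flow_rows, columns=["month", "origin", "destination", "persons", "reason", "kind"]
    )
    pop_true = pd.DataFrame(
        {"pop": pop.ravel()},
        index=pd.MultiIndex.from_product([districts, months], names=["district", "month"]),
    )

    # discrepant census-source anchors: one multiplicative bias per source
    from .denominators import CensusAnchor

    anchor_specs = [
        ("demographic_survey", months[2] if len(months) > 2 else months[0], 0.70),
        ("remote_sensing_model", months[min(12, len(months) - 1)], 0.50),
        ("vaccination_enumeration", months[-1], 0.90),
        ("immunization_program", months[-1], 0.80),
    ]
    anchors = []
    for name, am, quality in anchor_specs:
        bias = rng.uniform(1 - config.census_bias_spread, 1 + config.census_bias_spread)
        t = list(months).index(am)
        pops = {d: float(pop[i, t] * bias) for i, d in enumerate(districts)}
        anchors.append(CensusAnchor(source=name, month=am, populations=pops, quality=quality))

    return SyntheticWorld(
        config=config,
        districts=district_table,
        months=months,
        panel_true=panel,
        panel_observed=observed,
        true_log_cdr=true_log_cdr,
        true_log_u5dr=true_log_u5dr,
        pop_true=pop_true,
        anchors=anchors,
        flows=flows,
    )


def generate_surveys(
    world: SyntheticWorld,
    n_surveys: int,
    design: str = "cluster",
    questionnaire: str = "individual",
    recall_days_range: tuple[int, int] = (80, 120),
    seed: int = 0,
    frailty_sd: float = 0.0,
    n_clusters: int = 30,
    households_per_cluster: int = 15,
) -> list[SurveyDataset]:
    """Draw SMART-style surveys from the world's true rates.

    Household sizes are 1 + Poisson(mean - 1); under-5 membership is binomial
    with the world's under-5 fraction. Every member is present for the whole
    recall window (the default household-level simulation has no event
    streams), so person-days = members x recall days; deaths are Poisson with
    expectation rate x person-time x cluster frailty.
    """
    if n_surveys < 1:
        raise ValueError("n_surveys must be >= 1")
    lo, hi = recall_days_range
    if lo < 60 or hi > 150 or lo > hi:
        raise ValueError("recall range must lie within 60..150 days")
    if design not in ("cluster", "systematic"):
        raise ValueError(f"unknown design {design!r}")
    if questionnaire not in ("individual", "aggregate"):
        raise ValueError(f"unknown questionnaire {questionnaire!r}")
    rng = np.random.default_rng(seed)
    cfg = world.config
    months = world.months
    first_ok = int(np.ceil(hi / 28)) + 1  # recall must fit inside the world
    if first_ok >= len(months):
        raise ValueError("month range too short for the requested recall window")

    # precompute term-value panel once; per-survey windows average over it
    all_coefs = {**cfg.true_coefficients, **cfg.true_coefficients_u5}
    tp = world.term_panel(all_coefs)
    from .predictors import average_over_recall

    district_ids = world.districts["district"].tolist()
    surveys = []
    for s in range(n_surveys):
        district = district_ids[s % len(district_ids)]
        m = months[int(rng.integers(first_ok, len(months)))]
        recall_days = int(rng.integers(lo, hi + 1))
        recall_end = m.start_time + pd.Timedelta(days=int(rng.integers(0, 10)))
        recall_start = recall_end - pd.Timedelta(days=recall_days)
        if as_month(recall_start) < months[0]:
            recall_start = months[0].start_time
            recall_days = int((recall_end - recall_start) / pd.Timedelta(days=1))

        row = average_over_recall(tp, district, recall_start, recall_end).to_frame().T
        lp_c = linear_predictor_from_coefficients(row, cfg.true_coefficients)[0]
        lp_5 = linear_predictor_from_coefficients(row, cfg.true_coefficients_u5)[0]
        cdr = cfg.baseline_cdr / 1e4 * np.exp(lp_c)
        u5dr = cfg.baseline_u5dr / 1e4 * np.exp(lp_5)

        n_hh = n_clusters * households_per_cluster
        sizes = 1 + rng.poisson(cfg.mean_household_size - 1, n_hh)
        n_u5 = rng.binomial(sizes, cfg.under5_fraction)
        pt = sizes.astype(float) * recall_days
        pt_u5 = n_u5.astype(float) * recall_days
        pt_o5 = pt - pt_u5
        if design == "cluster":
            cluster = np.repeat(np.arange(n_clusters), households_per_cluster)
            frailty = np.exp(rng.normal(-0.5 * frailty_sd**2, frailty_sd, n_clusters))[cluster]
        else:
            cluster = np.arange(n_hh)
            frailty = np.ones(n_hh)
        # over-5 rate from the population composition identity
        # CDR = u5_frac * U5DR + (1 - u5_frac) * rate_5plus, so that pooled
        # all-age deaths / person-days targets the CDR exactly
        f5 = cfg.under5_fraction
        rate_o5 = max(cdr - u5dr * f5, 0.0) / (1.0 - f5)
        mu_u5 = u5dr * pt_u5 * frailty
        mu_o5 = rate_o5 * pt_o5 * frailty
        deaths_u5 = np.minimum(rng.poisson(mu_u5), n_u5)
        deaths_o5 = np.minimum(rng.poisson(mu_o5), sizes - n_u5)
        deaths = deaths_u5 + deaths_o5

        hh = pd.DataFrame(
            {
                "household_id": np.arange(n_hh),
                "cluster": cluster,
                "n_members": sizes,
                "n_under5": n_u5,
                "person_days": pt,
                "person_days_u5": pt_u5,
                "deaths": deaths,
                "deaths_u5": deaths_u5,
            }
        )
        members = None
        if questionnaire == "aggregate":
            hh = hh.assign(
                n_end=sizes - deaths,
                n_end_u5=n_u5 - deaths_u5,
                births=0,
                joins=0,
                leaves=0,
                joins_u5=0,
                leaves_u5=0,
            ).drop(columns=["person_days", "person_days_u5"])
        else:
            members = pd.DataFrame(
                {
                    "household_id": np.repeat(hh["household_id"].to_numpy(), sizes),
                    "cluster": np.repeat(cluster, sizes),
                    "under5": np.concatenate(
                        [np.arange(sz) < k for sz, k in zip(sizes, n_u5)]
                    ),
                    "entry": pd.NaT,
                    "exit": pd.NaT,
                }
            )
        meta = SurveyMeta(
            survey_id=f"SYN{s + 1:03d}",
            district=district,
            universe="district",
            design=design,
            recall_start=recall_start,
            recall_end=recall_end,
            questionnaire=questionnaire,
            quality=float(np.round(rng.uniform(0.6, 0.95), 3)),
        )
        surveys.append(SurveyDataset(meta=meta, households=hh, members=members))
    return surveys


def apply_underreporting(survey: SurveyDataset, p: float, seed: int = 0) -> SurveyDataset:
    """Delete each recorded under-5 death independently with probability p.

    All-age deaths drop by the same amount; person-time is left unchanged (a
    documented simplification: the unseen decedents' exposure stays in the
    denominator). p must lie in [0, 1).
    """
    if not 0 <= p < 1:
        raise ValueError("p must be in [0, 1)")
    if p == 0:
        return survey
    rng = np.random.default_rng(seed)
    hh = survey.households.copy()
    kept = rng.binomial(hh["deaths_u5"].to_numpy(int), 1 - p)
    removed = hh["deaths_u5"].to_numpy(int) - kept
    hh["deaths_u5"] = kept
    hh["deaths"] = hh["deaths"] - removed
    if "n_end" in hh.columns:
        hh["n_end"] = hh["n_end"] + removed  # unseen deaths were never reported as deaths
        hh["n_end_u5"] = hh["n_end_u5"] + removed
    return SurveyDataset(meta=survey.meta, households=hh, members=survey.members)
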