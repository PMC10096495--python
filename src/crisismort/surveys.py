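"""Re-analysis of retrospective household mortality surveys.

Each SMART-style survey reports, per household, person-time at risk during a
3-4 month recall window and counts of deaths (all-age and under-5). The crude
death rate (CDR) and under-5 death rate (U5DR) are estimated with an
intercept-only Poisson model offset by log person-time — whose point
estimate is exactly total deaths / total person-time — with CR0 standard
errors clustered on survey cluster (each household its own cluster under
systematic sampling) and the confidence interval built on the log scale.

Two questionnaire generations are supported: the *individual* questionnaire
lists every member with entry/exit dates; the older *aggregate* questionnaire
records only end-of-recall household size and event counts, from which
person-time is reconstructed under a mid-period convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SurveyMeta",
    "SurveyDataset",
    "RateEstimate",
    "EligibilityCriteria",
    "compute_person_time",
    "household_person_time",
    "estimate_rates",
    "filter_eligible",
    "quality_score",
]

P_SCALE = 10_000.0  # death rates are reported per 10,000 person-days


@dataclass(frozen=True)
class SurveyMeta:
    survey_id: str
    district: str
    universe: str | None = "district"  # district | urban | idp_settlement | livelihood_zone
    design: str = "cluster"  # cluster | systematic
    recall_start: pd.Timestamp | None = None
    recall_end: pd.Timestamp | None = None
    questionnaire: str = "individual"  # individual | aggregate | nonstandard
    quality: float | None = None

    def __post_init__(self):
        if self.recall_start is not None and self.recall_end is not None:
            if pd.Timestamp(self.recall_end) <= pd.Timestamp(self.recall_start):
                raise ValueError("recall end must follow recall start")
        if self.quality is not None and not 0 <= self.quality <= 1:
            raise ValueError("quality score must lie in [0, 1]")

    @property
    def recall_days(self) -> float | None:
        if self.recall_start is None or self.recall_end is None:
            return None
        return (pd.Timestamp(self.recall_end) - pd.Timestamp(self.recall_start)) / pd.Timedelta(days=1)

    @property
    def year(self) -> int | None:
        return None if self.recall_end is None else pd.Timestamp(self.recall_end).year


@dataclass
class SurveyDataset:
    """One survey: metadata, a household table and (individual mode) members.

    ``households`` columns: household_id, cluster, n_members, n_under5,
    person_days, person_days_u5, deaths, deaths_u5 and, for aggregate
    questionnaires, n_end / births / joins / leaves (+ the under-5 mirrors).
    """

    meta: SurveyMeta
    households: pd.DataFrame
    members: pd.DataFrame | None = None

    def __post_init__(self):
        if self.meta.questionnaire == "aggregate" and self.members is not None:
            raise ValueError("aggregate questionnaires carry no per-individual rows")


@dataclass(frozen=True)
class RateEstimate:
    """A death rate per 10,000 person-days with its cluster-robust 95% CI."""

    rate: float
    ci_low: float
    ci_high: float
    n_households: int
    n_clusters: int
    person_days: float
    deaths: int

    def __post_init__(self):
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def compute_person_time(record: pd.Series, meta: SurveyMeta) -> tuple[float, float]:
    """Person-days at risk (all-age, under-5) for one household record.

    Individual mode expects the record to carry precomputed member day sums
    (person_days / person_days_u5) or is computed from the members table via
    :func:`household_person_time`. Aggregate mode reconstructs

        person_days = recall_days * [N_end + 0.5*(deaths + leaves - births - joins)]

    i.e. every member with an unknown entry/exit date is assumed present for
    half the recall window. Negative derived person-time signals inconsistent
    counts and raises.
    """
    if meta.questionnaire == "aggregate":
        rd = meta.recall_days
        if rd is None:
            raise ValueError("aggregate person-time needs a known recall window")
        pt = rd * (
            record["n_end"]
            + 0.5 * (record["deaths"] + record.get("leaves", 0) - record.get("births", 0) - record.get("joins", 0))
        )
        pt_u5 = rd * (
            record["n_end_u5"]
            + 0.5
            * (
                record["deaths_u5"]
                + record.get("leaves_u5", 0)
                - record.get("births", 0)
                - record.get("joins_u5", 0)
            )
        )
        if pt < 0 or pt_u5 < 0:
            raise ValueError(
                f"household {record.get('household_id')}: negative derived person-time "
                "(inconsistent demographic counts)"
            )
        return float(pt), float(pt_u5)
    return float(record["person_days"]), float(record["person_days_u5"])


def _person_time_from_members(members: pd.DataFrame, meta: SurveyMeta) -> pd.DataFrame:
    start, end = pd.Timestamp(meta.recall_start), pd.Timestamp(meta.recall_end)
    entry = members["entry"].fillna(start).clip(lower=start)
    exit_ = members["exit"].fillna(end).clip(upper=end)
    days = ((exit_ - entry) / pd.Timedelta(days=1)).clip(lower=0.0)
    out = members.assign(days=days)
    g = out.groupby("household_id", sort=False)
    return pd.DataFrame(
        {
            "person_days": g["days"].sum(),
            "person_days_u5": out.assign(d5=days.where(out["under5"], 0.0))
            .groupby("household_id", sort=False)["d5"]
            .sum(),
        }
    )


def household_person_time(survey: SurveyDataset) -> pd.DataFrame:
    """Household table with person-time filled per the questionnaire's rules.

    Rows whose reconstructed person-time is negative are dropped and listed in
    the ``_rejected`` attribute (attrs) of the returned frame.
    """
    hh = survey.households.copy()
    meta = survey.meta
    if meta.questionnaire == "aggregate":
        rd = meta.recall_days
        if rd is None:
            raise ValueError("aggregate person-time needs a known recall window")
        for c in ("births", "joins", "leaves", "joins_u5", "leaves_u5"):
            if c not in hh.columns:
                hh[c] = 0
        pt = rd * (hh["n_end"] + 0.5 * (hh["deaths"] + hh["leaves"] - hh["births"] - hh["joins"]))
        pt_u5 = rd * (
            hh["n_end_u5"] + 0.5 * (hh["deaths_u5"] + hh["leaves_u5"] - hh["births"] - hh["joins_u5"])
        )
        bad = (pt < 0) | (pt_u5 < 0)
        hh["person_days"] = pt
        hh["person_days_u5"] = pt_u5
        rejected = hh.loc[bad, "household_id"].tolist()
        hh = hh[~bad]
        hh.attrs["_rejected"] = rejected
        return hh
    if "person_days" not in hh.columns:
        if survey.members is None:
            raise ValueError("individual survey without member rows or person-days")
        pt = _person_time_from_members(survey.members, meta)
        hh = hh.drop(columns=[c for c in ("person_days", "person_days_u5") if c in hh], errors="ignore")
        hh = hh.merge(pt, left_on="household_id", right_index=True, how="left").fillna(
            {"person_days": 0.0, "person_days_u5": 0.0}
        )
    hh.attrs["_rejected"] = []
    return hh


def _poisson_rate(deaths: np.ndarray, pt: np.ndarray, clusters: np.ndarray, alpha: float = 0.05) -> RateEstimate:
    """Intercept-only Poisson with log-PT offset and CR0 cluster sandwich.

    The MLE is total deaths / total person-time; the CR0 variance of the log
    rate is sum_g (d_g - r*pt_g)^2 / (r*PT)^2 over clusters g. Zero-death
    surveys report rate 0 with a one-sided exact Poisson 95% upper bound.
    """
    keep = pt > 0
    deaths, pt, clusters = deaths[keep], pt[keep], clusters[keep]
    total_pt = float(pt.sum())
    if total_pt <= 0:
        raise ValueError("zero total person-time")
    n_cl = len(np.unique(clusters))
    if n_cl == 0:
        raise ValueError("zero clusters")
    d_total = int(deaths.sum())
    if d_total == 0:
        upper = -np.log(alpha) / total_pt * P_SCALE  # exact one-sided Poisson bound
        return RateEstimate(0.0, 0.0, upper, len(deaths), n_cl, total_pt, 0)
    r = d_total / total_pt
    resid = deaths - r * pt
    df = pd.DataFrame({"resid": resid, "cl": clusters})
    s = df.groupby("cl", sort=False)["resid"].sum().to_numpy()
    var_log = float((s**2).sum()) / (r * total_pt) ** 2
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var_log)
    rate = r * P_SCALE
    return RateEstimate(
        rate, rate * np.exp(-half), rate * np.exp(half), len(deaths), n_cl, total_pt, d_total
    )


def estimate_rates(survey: SurveyDataset, alpha: float = 0.05) -> tuple[RateEstimate, RateEstimate]:
    """(CDR, U5DR) estimates for one survey, per 10,000 person-days."""
    hh = household_person_time(survey)
    if survey.meta.design == "systematic" or "cluster" not in hh.columns:
        clusters = np.arange(len(hh))
    else:
        clusters = hh["cluster"].to_numpy()
    cdr = _poisson_rate(
        hh["deaths"].to_numpy(float), hh["person_days"].to_numpy(float), clusters, alpha
    )
    u5 = _poisson_rate(
        hh["deaths_u5"].to_numpy(float), hh["person_days_u5"].to_numpy(float), clusters, alpha
    )
    return cdr, u5


@dataclass(frozen=True)
class EligibilityCriteria:
    """Which surveys enter the models, mirroring the study's exclusion rules."""

    allowed_universes: tuple[str, ...] = ("district", "urban", "idp_settlement")
    allowed_questionnaires: tuple[str, ...] = ("individual", "aggregate")
    min_year: int = 2014


def filter_eligible(
    metas: list[SurveyMeta], criteria: EligibilityCriteria = EligibilityCriteria()
) -> tuple[list[SurveyMeta], pd.DataFrame]:
    """Split surveys into those usable for modelling and an exclusion log.

    Reasons (first matching, in order): a livelihood-zone sampling universe,
    an unclear sampling frame, a non-standard questionnaire or unknown recall
    window, and a recall year before the modelling period. Missing metadata
    excludes with reason "unclear".
    """
    eligible, log_rows = [], []
    for m in metas:
        reason = None
        if m.universe == "livelihood_zone":
            reason = "livelihood_zone_universe"
        elif m.universe is None or m.universe not in criteria.allowed_universes:
            reason = "unclear_sampling_frame"
        elif m.questionnaire not in criteria.allowed_questionnaires or m.recall_days is None:
            reason = "nonstandard_questionnaire_or_recall"
        elif m.year is not None and m.year < criteria.min_year:
            reason = "before_model_period"
        elif m.district is None or m.year is None:
            reason = "unclear"
        if reason is None:
            eligible.append(m)
        else:
            log_rows.append({"survey_id": m.survey_id, "reason": reason})
    log = pd.DataFrame(log_rows, columns=["survey_id", "reason"])
    return eligible, log


def quality_score(survey: SurveyDataset) -> float:
    """Simplified 0-1 quality checklist (reporting only, never a weight).

    Components: metadata completeness (0.4), plausible mean household size
    (0.2), plausible crude death rate (0.2), plausible under-5 membership
    share (0.2). This is a package-defined stand-in for the full SMART
    plausibility score, which needs anthropometric data out of scope here.
    """
    m = survey.meta
    score = 0.0
    meta_ok = sum(
        [
            m.universe in ("district", "urban", "idp_settlement"),
            m.design in ("cluster", "systematic"),
            m.recall_days is not None,
        ]
    )
    score += 0.4 * meta_ok / 3
    hh = household_person_time(survey)
    mean_size = hh["n_members"].mean() if "n_members" in hh else np.nan
    if np.isfinite(mean_size) and 3 <= mean_size <= 10:
        score += 0.2
    pt = hh["person_days"].sum()
    if pt > 0 and hh["deaths"].sum() / pt * P_SCALE < 5:
        score += 0.2
    pt5 = hh["person_days_u5"].sum()
    if pt > 0 and 0.05 <= pt5 / pt <= 0.5:
        score += 0.2
    return round(score, 3)
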