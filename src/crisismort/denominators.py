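"""Reconstruction of district-month population denominators.

No recent census exists for the setting this method targets, so each of
several discrepant "census-source" anchor estimates is projected forward and
backward from its anchor month with a constant natural growth rate
(default 2.1%/yr, compounded monthly) plus monthly net displacement flows,
and the per-source series are then combined by a quality-score weighted
mean. Under-5 populations apply a single global fraction (default 25.0%).

Projection arithmetic: with monthly growth factor g = (1+r)^(1/12),
forward P[t+1] = g*P[t] + netflow[t+1] and backward
P[t-1] = (P[t] - netflow[t]) / g — exact algebraic inverses, so a forward
projection followed by a backward one recovers the anchor to round-off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_month, month_range

log = logging.getLogger(__name__)

__all__ = [
    "CensusAnchor",
    "PopulationSeries",
    "project_source",
    "combine_sources",
    "displacement_summary",
    "net_flow_matrix",
    "build_denominators",
]

REASONS = ("drought", "insecurity", "flooding", "other")


@dataclass(frozen=True)
class CensusAnchor:
    """One census-source estimate: district populations at a single month."""

    source: str
    month: pd.Period
    populations: dict[str, float]
    quality: float

    def __post_init__(self):
        if not 0 <= self.quality <= 1:
            raise ValueError("quality score must lie in [0, 1]")
        if any(p <= 0 for p in self.populations.values()):
            raise ValueError("anchor populations must be positive")


@dataclass
class PopulationSeries:
    """District-month populations (all-age, under-5) and IDP/returnee share."""

    table: pd.DataFrame  # (district, month) -> pop, pop_u5, prop_idp

    @property
    def districts(self) -> list:
        return list(self.table.index.get_level_values(0).unique())

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.PeriodIndex(sorted(self.table.index.get_level_values(1).unique()), freq="M")

    def pop(self, district, month) -> float:
        return float(self.table.loc[(district, as_month(month)), "pop"])


def net_flow_matrix(
    flows: pd.DataFrame, districts: list[str], months: pd.PeriodIndex
) -> pd.DataFrame:
    """Net persons moving into each district per month (arrivals - departures).

    Flows to or from places outside the district list (e.g. refugee movements
    tagged EXTERNAL) count one-sidedly. Empty flow tables yield zeros.
    """
    net = pd.DataFrame(0.0, index=districts, columns=months)
    if flows is None or len(flows) == 0:
        return net
    f = flows.copy()
    f["month"] = pd.PeriodIndex(f["month"], freq="M")
    f = f[f["month"].isin(months)]
    arr = f[f["destination"].isin(districts)].groupby(["destination", "month"])["persons"].sum()
    dep = f[f["origin"].isin(districts)].groupby(["origin", "month"])["persons"].sum()
    for (d, m), v in arr.items():
        net.loc[d, m] += v
    for (d, m), v in dep.items():
        net.loc[d, m] -= v
    return net


def project_source(
    anchor: CensusAnchor,
    growth_rate_yr: float,
    flows: pd.DataFrame,
    months: pd.PeriodIndex,
    under5_fraction: float = 0.250,
    floor: float = 1.0,
    initial_idp_prop: float = 0.08,
    districts: list[str] | None = None,
) -> PopulationSeries:
    """Project one census anchor across the month range.

    The anchor month may sit inside the range or adjacent to it (it is
    back-projected in). Net flow is applied after growth within a month; the
    final series is floored (default 1 person) with a warning when the floor
    binds, which signals flows exceeding the projected stock.
    """
    if districts is None:
        districts = sorted(anchor.populations)
    missing = [d for d in districts if d not in anchor.populations]
    if missing:
        raise KeyError(f"anchor {anchor.source} missing districts {missing}")
    g = (1.0 + growth_rate_yr) ** (1.0 / 12.0)
    net = net_flow_matrix(flows, districts, months)
    a_month = as_month(anchor.month)
    # position of the anchor relative to the range (may be just outside)
    ext_months = months
    if a_month < months[0] or a_month > months[-1]:
        lo = min(a_month, months[0]).strftime("%Y-%m")
        hi = max(a_month, months[-1]).strftime("%Y-%m")
        ext_months = month_range(lo, hi)
        net = net_flow_matrix(flows, districts, ext_months)
    t0 = list(ext_months).index(a_month)
    P = np.empty((len(districts), len(ext_months)))
    P[:, t0] = [anchor.populations[d] for d in districts]
    for t in range(t0 + 1, len(ext_months)):
        P[:, t] = g * P[:, t - 1] + net[ext_months[t]].to_numpy()
    for t in range(t0 - 1, -1, -1):
        P[:, t] = (P[:, t + 1] - net[ext_months[t + 1]].to_numpy()) / g
    keep = [i for i, m in enumerate(ext_months) if m in set(months)]
    P = P[:, keep]
    if (P < floor).any():
        n_low = int((P < floor).sum())
        warnings.warn(
            f"{anchor.source}: {n_low} district-months floored at {floor} "
            "(flows exceed projected stock)",
            stacklevel=2,
        )
        P = np.maximum(P, floor)

    prop = _idp_proportion(flows, districts, months, P, initial_idp_prop)
    idx = pd.MultiIndex.from_product([districts, months], names=["district", "month"])
    table = pd.DataFrame(
        {
            "pop": P.ravel(),
            "pop_u5": under5_fraction * P.ravel(),
            "prop_idp": prop.ravel(),
        },
        index=idx,
    )
    return PopulationSeries(table)


def _idp_proportion(flows, districts, months, P, initial_prop) -> np.ndarray:
    """Displaced/returnee stock as a share of population.

    IDP arrivals add to the destination's displaced stock; returnee departures
    draw it down at the origin. The share is clipped to [0, 1].
    """
    stock = np.full(len(districts), initial_prop) * P[:, 0]
    out = np.empty_like(P)
    d_index = {d: i for i, d in enumerate(districts)}
    f = flows.copy() if flows is not None and len(flows) else pd.DataFrame(
        columns=["month", "origin", "destination", "persons", "kind"]
    )
    if len(f):
        f["month"] = pd.PeriodIndex(f["month"], freq="M")
    for t, m in enumerate(months):
        if len(f):
            fm = f[f["month"] == m]
            for _, r in fm.iterrows():
                if r["kind"] == "IDP" and r["destination"] in d_index:
                    stock[d_index[r["destination"]]] += r["persons"]
                elif r["kind"] == "returnee" and r["origin"] in d_index:
                    stock[d_index[r["origin"]]] = max(
                        stock[d_index[r["origin"]]] - r["persons"], 0.0
                    )
        out[:, t] = np.clip(stock / np.maximum(P[:, t], 1.0), 0.0, 1.0)
    return out


def combine_sources(series_by_source: list[tuple[PopulationSeries, float]]) -> PopulationSeries:
    """Quality-weighted arithmetic mean of per-source population series."""
    if not series_by_source:
        raise ValueError("need at least one source")
    weights = np.array([w for _, w in series_by_source], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must not all be zero")
    weights = weights / weights.sum()
    tables = [s.table for s, _ in series_by_source]
    out = sum(w * t for w, t in zip(weights, tables))
    return PopulationSeries(out)


def displacement_summary(flows: pd.DataFrame) -> pd.DataFrame:
    """Newly displaced or returned persons by reported reason, with shares.

    Internal (IDP + returnee) movements only; refugee flows are excluded.
    Shares are percentages rounded to 0.1. An all-zero table returns an empty
    frame with a warning.
    """
    cols = ["reason", "persons", "share_pct"]
    if flows is None or len(flows) == 0:
        warnings.warn("no displacement flows; summary undefined", stacklevel=2)
        return pd.DataFrame(columns=cols)
    internal = flows[flows["kind"].isin(["IDP", "returnee"])] if "kind" in flows else flows
    totals = internal.groupby("reason")["persons"].sum().reindex(REASONS, fill_value=0.0)
    grand = totals.sum()
    if grand <= 0:
        warnings.warn("zero displaced persons; shares undefined", stacklevel=2)
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        {
            "reason": totals.index,
            "persons": totals.to_numpy(),
            "share_pct": np.round(totals.to_numpy() / grand * 100, 1),
        }
    ).reset_index(drop=True)


def build_denominators(
    anchors: list[CensusAnchor],
    flows: pd.DataFrame,
    months: pd.PeriodIndex,
    growth_rate_yr: float = 0.021,
    under5_fraction: float = 0.250,
    initial_idp_prop: float = 0.08,
) -> PopulationSeries:
    """Project every anchor and combine them by quality weight."""
    series = [
        (
            project_source(
                a, growth_rate_yr, flows, months,
                under5_fraction=under5_fraction, initial_idp_prop=initial_idp_prop,
            ),
            a.quality,
        )
        for a in anchors
    ]
    return combine_sources(series)
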