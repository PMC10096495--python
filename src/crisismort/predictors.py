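"""District-month predictor panel preparation.

Raw predictor inputs (conflict events, SAM treatment admissions, epidemic
case counts, market prices, rainfall proxies) arrive as long-format
district-month series with missingness. This module turns them into the
analysis panel the mortality models consume:

* completeness screening (a predictor must be observed for at least 70% of
  district-months, inclusive, to be retained — both thresholds configurable),
* spatial weighted-mean imputation (same-region weight 1.0, out-of-region
  weight 0.3),
* penalized cubic-spline smoothing of price series (smoothness knob, default
  0.3),
* per-100,000 population rates, lagged copies (up to 6 months), categorical
  encodings with lower-inclusive cut-points, and
* day-weighted averaging over a survey's recall window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from ._util import month_overlap_days

__all__ = [
    "CategoryScheme",
    "PredictorPanel",
    "categorize",
    "screen_completeness",
    "impute_spatial",
    "smooth_series",
    "to_rate",
    "build_lags",
    "average_over_recall",
    "derived_ratio",
    "CONFLICT_SCHEME",
    "SAM_SCHEME",
    "MALARIA_SCHEME",
    "MEASLES_SCHEME",
    "DEFAULT_SCHEMES",
]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered cut-points mapping a continuous predictor to labelled levels.

    Intervals are half-open and lower-inclusive: a value equal to a cut-point
    belongs to the level above it (0.25 maps to "0.25 to 0.49"; 0.50 maps to
    "≥ 0.50"). The lowest level is the reference in model design matrices.
    """

    predictor: str
    cuts: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly one more label than cut-points")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut-points must be strictly increasing")

    @property
    def reference(self) -> str:
        return self.labels[0]


# Armed-conflict event rate per 100,000 person-months.
CONFLICT_SCHEME = CategoryScheme("conflict_rate", (0.25, 0.50), ("< 0.25", "0.25 to 0.49", "≥ 0.50"))
# SAM therapeutic admissions per 100,000 person-months. Cut-points 100/200 are
# a package default (the source table's labels for this predictor are
# internally inconsistent), not an established threshold.
SAM_SCHEME = CategoryScheme("sam_rate", (100.0, 200.0), ("< 100", "100 to 199", "≥ 200"))
# Facility-reported malaria cases per 100,000 person-months; "0" means < 1.
MALARIA_SCHEME = CategoryScheme("malaria_rate", (1.0, 50.0), ("0", "1 to 49", "≥ 50"))
# Any reported measles vs none.
MEASLES_SCHEME = CategoryScheme("measles_rate", (1e-9,), ("0", "> 0"))

DEFAULT_SCHEMES: dict[str, CategoryScheme] = {
    s.predictor: s for s in (CONFLICT_SCHEME, SAM_SCHEME, MALARIA_SCHEME, MEASLES_SCHEME)
}


def categorize(values, scheme: CategoryScheme):
    """Assign level labels; lower-inclusive half-open intervals.

    Scalar in, scalar out; array-like in, object ndarray out. Non-finite
    values raise.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value passed to categorize({scheme.predictor})")
    idx = np.searchsorted(np.asarray(scheme.cuts), arr, side="right")
    out = np.asarray(scheme.labels, dtype=object)[idx]
    if np.isscalar(values) or arr.ndim == 0:
        return out.item() if isinstance(out, np.ndarray) else out
    return out


@dataclass
class PredictorPanel:
    """Wide district-month panel of predictor values plus provenance flags.

    ``values`` is indexed by (district, month Period) with one column per
    predictor; ``provenance`` mirrors it with entries in
    {"observed", "imputed", "smoothed"} (NaN where the value itself is
    missing). Static district attributes (administrative zone, livelihood)
    are ordinary columns repeated over months.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame = None

    def __post_init__(self):
        if self.provenance is None:
            prov = pd.DataFrame("observed", index=self.values.index, columns=self.values.columns)
            prov = prov.where(self.values.notna())
            self.provenance = prov

    @property
    def districts(self) -> list:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.PeriodIndex(sorted(self.values.index.get_level_values(1).unique()), freq="M")

    def series(self, predictor: str, district) -> pd.Series:
        return self.values.loc[district][predictor]

    def copy(self) -> "PredictorPanel":
        return PredictorPanel(self.values.copy(), self.provenance.copy())


def screen_completeness(
    panel: pd.DataFrame, cell_threshold: float = 0.70, coverage_threshold: float = 0.70
) -> list[str]:
    """Return the predictors complete enough to keep.

    A predictor is retained iff its share of non-missing district-months is at
    least ``coverage_threshold`` (inclusive at the boundary). For composite
    predictors stored as multiple sub-columns ("name/part"), each sub-series
    must itself clear ``cell_threshold`` before the composite counts as
    observed.
    """
    retained = []
    cols = list(panel.columns)
    composites: dict[str, list[str]] = {}
    for c in cols:
        if "/" in c:
            composites.setdefault(c.split("/", 1)[0], []).append(c)
    for c in cols:
        if "/" in c:
            continue
        share = panel[c].notna().mean()
        if share >= coverage_threshold:
            retained.append(c)
    for name, parts in composites.items():
        ok = all(panel[p].notna().mean() >= cell_threshold for p in parts)
        share = panel[parts].notna().all(axis=1).mean()
        if ok and share >= coverage_threshold:
            retained.append(name)
    return retained


def impute_spatial(
    values: pd.Series,
    region_of: dict,
    w_in: float = 1.0,
    w_out: float = 0.3,
) -> pd.Series:
    """Fill missing district values for one month by spatially weighted mean.

    Observed districts in the same region carry weight ``w_in`` (default 1.0),
    districts in other regions ``w_out`` (default 0.3). Observed cells are
    never altered. If no district is observed at all the input is returned
    unchanged (callers flag the month).
    """
    obs = values.dropna()
    if obs.empty or values.notna().all():
        return values.copy()
    out = values.copy()
    obs_regions = np.asarray([region_of[d] for d in obs.index])
    obs_vals = obs.to_numpy(dtype=float)
    for d in values.index[values.isna()]:
        w = np.where(obs_regions == region_of[d], w_in, w_out)
        out.loc[d] = float(np.dot(w, obs_vals) / w.sum())
    return out


def smooth_series(series: pd.Series, smoothness: float = 0.3) -> pd.Series:
    """Penalized cubic smoothing spline over a monthly series.

    The 0-1 ``smoothness`` knob maps monotonically to the roughness penalty
    lambda = 10 ** (6 * smoothness - 2) on the month-index scale, so 0 is
    near-interpolation and 1 is near-linear; the default 0.3 gives mild
    smoothing. Constants and straight lines are reproduced exactly (the
    penalty acts on the second derivative only). Series shorter than 4 points
    are returned unchanged with a warning.
    """
    if not 0.0 <= smoothness <= 1.0:
        raise ValueError("smoothness must be in [0, 1]")
    y = series.to_numpy(dtype=float)
    if len(y) < 4:
        warnings.warn("fewer than 4 time points; smoothing skipped", stacklevel=2)
        return series.copy()
    x = np.arange(len(y), dtype=float)
    lam = 10.0 ** (6.0 * smoothness - 2.0)
    spl = make_smoothing_spline(x, y, lam=lam)
    return pd.Series(spl(x), index=series.index, name=series.name)


def to_rate(count, population, scale: float = 100_000.0):
    """Events per `scale` population (default per 100,000 person-months)."""
    pop = np.asarray(population, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be positive")
    return np.asarray(count, dtype=float) / pop * scale


def build_lags(panel: pd.DataFrame, predictor: str, lags) -> pd.DataFrame:
    """Add lag-k copies of a predictor column, shifting within each district.

    Lag-k value at (district, t) is the raw value at (district, t-k); the k
    leading months of each district are left missing. Lags must be in 0..6.
    """
    if isinstance(lags, int):
        lags = [lags]
    out = panel.copy()
    for k in lags:
        if not 0 <= k <= 6:
            raise ValueError(f"lag {k} outside 0..6")
        col = predictor if k == 0 else f"{predictor}_lag{k}"
        out[col] = panel.groupby(level=0, sort=False)[predictor].shift(k)
    return out


def lagged_values(panel: pd.DataFrame, predictor: str, lag: int) -> pd.Series:
    """Lag-k series for one predictor (no column bookkeeping)."""
    if not 0 <= lag <= 6:
        raise ValueError(f"lag {lag} outside 0..6")
    if lag == 0:
        return panel[predictor]
    return panel.groupby(level=0, sort=False)[predictor].shift(lag)


def average_over_recall(
    panel: pd.DataFrame,
    district,
    recall_start: pd.Timestamp,
    recall_end: pd.Timestamp,
    predictors: list[str] | None = None,
) -> pd.Series:
    """Day-weighted mean of each predictor over a recall window in a district.

    The weight of each calendar month is the number of recall days falling in
    it; a recall window covering 30 days of one month and 60 of the next
    weights them 1/3 and 2/3. Categorical model terms are averaged on the
    underlying continuous scale and re-categorized downstream.
    """
    recall_start, recall_end = pd.Timestamp(recall_start), pd.Timestamp(recall_end)
    if recall_end <= recall_start:
        raise ValueError("recall end must follow recall start")
    sub = panel.loc[district]
    span = pd.period_range(recall_start, recall_end, freq="M")
    months = [m for m in span if m in sub.index and month_overlap_days(recall_start, recall_end, m) > 0]
    if not months:
        raise ValueError(f"recall window {recall_start.date()}..{recall_end.date()} does not overlap panel")
    w = np.array([month_overlap_days(recall_start, recall_end, m) for m in months])
    block = sub.loc[months]
    if predictors is not None:
        block = block[predictors]
    num = block.select_dtypes(include=[np.number])
    avg = num.mul(w, axis=0).sum() / w.sum()
    # static non-numeric columns (admin zone etc.) pass through unchanged
    for c in block.columns.difference(num.columns):
        avg[c] = block[c].iloc[0]
    return avg[block.columns]


def derived_ratio(panel: pd.DataFrame, name: str, numerator: str, denominator: str, constant: float = 1.0) -> pd.DataFrame:
    """Generic derived-predictor hook: constant × numerator / denominator.

    Covers terms-of-trade style indicators (kcal-equivalent purchasing power
    as a ratio of two price series times a conversion constant).
    """
    out = panel.copy()
    out[name] = constant * panel[numerator] / panel[denominator]
    return out
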