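"""Plain-CSV schemas for every pipeline input and output.

All stage inputs/outputs are flat text so any stage can be run standalone:

* ``survey_meta.csv`` — one row per survey (survey_id, district, universe,
  design, recall_start, recall_end, questionnaire, quality)
* ``survey_households.csv`` — household rows keyed by survey_id
* ``census_anchors.csv`` — source, month, district, population, quality
* ``flows.csv`` — month, origin, destination, persons, reason, kind
* ``predictors_long.csv`` — district, month, predictor, value
* ``panel.csv`` / ``panel_provenance.csv`` — wide prepared panel
* ``population.csv`` — district, month, pop, pop_u5, prop_idp
* fitted-model JSON (coefficients, dispersion, covariance)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .denominators import CensusAnchor, PopulationSeries
from .surveys import SurveyDataset, SurveyMeta

__all__ = [
    "write_surveys",
    "read_surveys",
    "write_anchors",
    "read_anchors",
    "write_flows",
    "read_flows",
    "write_predictors_long",
    "read_predictors_long",
    "write_panel",
    "read_panel",
    "write_population",
    "read_population",
    "write_model_json",
    "read_model_json",
]


def write_surveys(surveys: list[SurveyDataset], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    hh_frames = []
    for sv in surveys:
        m = sv.meta
        meta_rows.append(
            {
                "survey_id": m.survey_id,
                "district": m.district,
                "universe": m.universe,
                "design": m.design,
                "recall_start": m.recall_start,
                "recall_end": m.recall_end,
                "questionnaire": m.questionnaire,
                "quality": m.quality,
            }
        )
        hh_frames.append(sv.households.assign(survey_id=m.survey_id))
    pd.DataFrame(meta_rows).to_csv(directory / "survey_meta.csv", index=False)
    pd.concat(hh_frames, ignore_index=True).to_csv(directory / "survey_households.csv", index=False)


def read_surveys(directory) -> list[SurveyDataset]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "survey_meta.csv", parse_dates=["recall_start", "recall_end"])
    hh_all = pd.read_csv(directory / "survey_households.csv")
    out = []
    for _, r in meta.iterrows():
        sm = SurveyMeta(
            survey_id=r["survey_id"],
            district=r["district"],
            universe=None if pd.isna(r["universe"]) else r["universe"],
            design=r["design"],
            recall_start=None if pd.isna(r["recall_start"]) else r["recall_start"],
            recall_end=None if pd.isna(r["recall_end"]) else r["recall_end"],
            questionnaire=r["questionnaire"],
            quality=None if pd.isna(r["quality"]) else float(r["quality"]),
        )
        hh = hh_all[hh_all["survey_id"] == r["survey_id"]].drop(columns=["survey_id"]).reset_index(drop=True)
        out.append(SurveyDataset(meta=sm, households=hh))
    return out


def write_anchors(anchors: list[CensusAnchor], path) -> None:
    rows = [
        {"source": a.source, "month": str(a.month), "district": d, "population": p, "quality": a.quality}
        for a in anchors
        for d, p in sorted(a.populations.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_anchors(path) -> list[CensusAnchor]:
    df = pd.read_csv(path)
    out = []
    for (source, month, quality), grp in df.groupby(["source", "month", "quality"], sort=False):
        out.append(
            CensusAnchor(
                source=source,
                month=pd.Period(month, freq="M"),
                populations=dict(zip(grp["district"], grp["population"])),
                quality=float(quality),
            )
        )
    return out


def write_flows(flows: pd.DataFrame, path) -> None:
    f = flows.copy()
    f["month"] = f["month"].astype(str)
    f.to_csv(path, index=False)


def read_flows(path) -> pd.DataFrame:
    f = pd.read_csv(path)
    f["month"] = pd.PeriodIndex(f["month"], freq="M")
    return f


def write_predictors_long(panel: pd.DataFrame, path) -> None:
    """Wide (district, month) panel -> long CSV (numeric predictors only)."""
    num = panel.select_dtypes(include=[np.number])
    long = num.stack(future_stack=True).rename("value").reset_index()
    long.columns = ["district", "month", "predictor", "value"]
    long["month"] = long["month"].astype(str)
    long.to_csv(path, index=False)


def read_predictors_long(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    long["month"] = pd.PeriodIndex(long["month"], freq="M")
    wide = long.pivot_table(index=["district", "month"], columns="predictor", values="value", aggfunc="first")
    wide.columns.name = None
    wide.index.names = ["district", "month"]
    return wide


def _panel_to_csv(df: pd.DataFrame, path) -> None:
    out = df.reset_index()
    out["month"] = out["month"].astype(str)
    out.to_csv(path, index=False)


def write_panel(panel, path, provenance_path=None) -> None:
    if hasattr(panel, "provenance"):  # PredictorPanel wrapper
        _panel_to_csv(panel.values, path)
        if provenance_path is not None:
            _panel_to_csv(panel.provenance, provenance_path)
    else:
        _panel_to_csv(panel, path)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    return df.set_index(["district", "month"])


def write_population(pop: PopulationSeries, path) -> None:
    _panel_to_csv(pop.table, path)


def read_population(path) -> PopulationSeries:
    return PopulationSeries(read_panel(path))


def write_model_json(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, ensure_ascii=False)


def read_model_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
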