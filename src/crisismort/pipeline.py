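"""End-to-end orchestration: simulate/load -> re-analyse -> denominators ->
predictors -> model selection -> excess -> (optional) sensitivity.

One master seed fans out to per-stage seeds by hashing (master, stage name);
stage outputs are plain CSV/JSON under the run directory, and a manifest
records the config hash, every derived seed and the design flags in force,
so a rerun with the same config and seed is file-for-file identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import month_range, stage_seed
from .config import AnalysisConfig, WorldConfig
from .denominators import build_denominators, displacement_summary
from .excess import (
    bootstrap_excess,
    build_counterfactual,
    canonical_scenarios,
    counterfactual_flows,
    predict_tolls,
    summarize,
)
from .models import (
    ModelSpec,
    Term,
    brute_force_search,
    fit_quasipoisson,
    holdout_validate,
    select_final,
    screen_predictors,
    shortlist,
)
from .predictors import (
    CONFLICT_SCHEME,
    MALARIA_SCHEME,
    MEASLES_SCHEME,
    SAM_SCHEME,
    average_over_recall,
    impute_spatial,
    lagged_values,
    screen_completeness,
    smooth_series,
)
from .surveys import EligibilityCriteria, estimate_rates, filter_eligible
from . import io as cio

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CANDIDATES", "build_model_frame", "prepare_panel", "run_all"]

# the candidate terms the default search explores (the study's final model
# uses all five: admin zone, conflict, SAM at lag 2, malaria, measles)
DEFAULT_CANDIDATES: tuple[Term, ...] = (
    Term("admin_level", levels=("somaliland_puntland", "south_central")),
    Term("conflict_rate", scheme=CONFLICT_SCHEME),
    Term("sam_rate", lag=2, scheme=SAM_SCHEME),
    Term("malaria_rate", scheme=MALARIA_SCHEME),
    Term("measles_rate", scheme=MEASLES_SCHEME),
)


def build_model_frame(surveys, panel: pd.DataFrame, terms) -> pd.DataFrame:
    """Household rows joined to recall-window-averaged predictor term values.

    For each survey, every term's continuous value is the day-weighted mean
    of its (lagged) series over the recall window in the surveyed district;
    categorization happens later, inside the design-matrix encoding.
    """
    term_cols = {}
    for t in terms:
        term_cols[t.key] = lagged_values(panel, t.predictor, t.lag)
    tp = pd.DataFrame(term_cols, index=panel.index)
    frames = []
    for sv in surveys:
        m = sv.meta
        vals = average_over_recall(tp, m.district, m.recall_start, m.recall_end)
        hh = sv.households.copy()
        if "person_days" not in hh.columns:
            from .surveys import household_person_time

            hh = household_person_time(sv)
        hh["survey_id"] = m.survey_id
        for k, v in vals.items():
            hh[k] = v
        frames.append(hh)
    return pd.concat(frames, ignore_index=True)


def prepare_panel(
    raw: pd.DataFrame,
    districts: pd.DataFrame,
    config: AnalysisConfig,
    price_predictors: tuple[str, ...] = ("water_price",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen, impute, smooth and decorate the raw predictor panel.

    Returns (panel, provenance). Price-type predictors get spatial
    weighted-mean imputation per month followed by spline smoothing per
    district; static district attributes are joined as repeated columns.
    """
    retained = screen_completeness(raw, config.completeness_cell, config.completeness_coverage)
    panel = raw[retained].copy()
    prov = pd.DataFrame("observed", index=panel.index, columns=panel.columns).where(panel.notna())
    region_of = dict(zip(districts["district"], districts["region"]))
    for pred in price_predictors:
        if pred not in panel.columns:
            continue
        months = panel.index.get_level_values("month").unique()
        for m in months:
            block = panel.xs(m, level="month")[pred]
            if block.isna().any() and block.notna().any():
                filled = impute_spatial(block, region_of, config.impute_w_in, config.impute_w_out)
                for d in block.index[block.isna()]:
                    panel.loc[(d, m), pred] = filled.loc[d]
                    prov.loc[(d, m), pred] = "imputed"
        for d in panel.index.get_level_values("district").unique():
            series = panel.loc[d, pred]
            if series.isna().any():
                log.warning("%s still missing for %s after imputation", pred, d)
                continue
            sm = smooth_series(series, config.smoothness)
            panel.loc[d, pred] = sm.to_numpy()
        prov.loc[panel[pred].notna(), pred] = prov.loc[panel[pred].notna(), pred].replace(
            {"observed": "smoothed"}
        )
    static = districts.set_index("district")[["admin_level", "livelihood"]]
    for c in static.columns:
        panel[c] = static[c].reindex(panel.index.get_level_values("district")).to_numpy()
    return panel, prov


def _config_hash(*cfgs) -> str:
    blob = repr([getattr(c, "__dict__", c) for c in cfgs])
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    cdr_model: object
    u5dr_model: object
    summaries: pd.DataFrame
    panel: pd.DataFrame


def run_all(
    outdir,
    config: AnalysisConfig = AnalysisConfig(),
    world_config: WorldConfig | None = None,
    input_dir=None,
    n_surveys: int = 36,
    search: bool = True,
    do_sensitivity: bool = False,
) -> RunResult:
    """Run the six analysis stages and write all outputs plus a manifest.

    Either ``world_config`` (simulate inputs) or ``input_dir`` (read the four
    CSV input families) must be given. ``search`` toggles the brute-force
    model search; when off, the default five-term specification is fitted
    directly (useful for smoke runs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = config.seed
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config, world_config or {}),
        "master_seed": master,
        "stage_seeds": {},
        "design_flags": {
            "sandwich": "CR0 clustered on survey cluster",
            "dss_variance": "phi * mu",
            "cv_unit": "survey",
            "bootstrap_error": "coefficient MVN only (no Poisson realization noise)",
            "mode_estimator": "Freedman-Diaconis histogram, modal-bin midpoint",
            "percentile": "linear interpolation",
            "counterfactual_start": config.excess_start,
        },
    }

    # ---- stage 0: inputs -------------------------------------------------
    if world_config is not None:
        from .synthetic import generate_surveys, generate_world

        sseed = stage_seed(master, "simulate")
        manifest["stage_seeds"]["simulate"] = sseed
        world = generate_world(world_config)
        surveys = generate_surveys(world, n_surveys=n_surveys, seed=sseed)
        inputs = outdir / "inputs"
        inputs.mkdir(exist_ok=True)
        cio.write_surveys(surveys, inputs)
        cio.write_anchors(world.anchors, inputs / "census_anchors.csv")
        cio.write_flows(world.flows, inputs / "flows.csv")
        cio.write_predictors_long(
            world.panel_observed.select_dtypes(include=[np.number]), inputs / "predictors_long.csv"
        )
        world.districts.to_csv(inputs / "districts.csv", index=False)
        anchors, flows = world.anchors, world.flows
        raw_panel = world.panel_observed.select_dtypes(include=[np.number]).copy()
        districts = world.districts
        months = world.months
    elif input_dir is not None:
        input_dir = Path(input_dir)
        for fname in ("survey_meta.csv", "census_anchors.csv", "flows.csv", "predictors_long.csv", "districts.csv"):
            if not (input_dir / fname).exists():
                raise FileNotFoundError(f"missing required input {fname} in {input_dir}")
        surveys = cio.read_surveys(input_dir)
        anchors = cio.read_anchors(input_dir / "census_anchors.csv")
        flows = cio.read_flows(input_dir / "flows.csv")
        raw_panel = cio.read_predictors_long(input_dir / "predictors_long.csv")
        districts = pd.read_csv(input_dir / "districts.csv")
        months = month_range(
            str(raw_panel.index.get_level_values("month").min()),
            str(raw_panel.index.get_level_values("month").max()),
        )
    else:
        raise ValueError("provide either world_config or input_dir")
    region_of = dict(zip(districts["district"], districts["region"]))

    # ---- stage 1: survey re-analysis ------------------------------------
    eligible, exclusion_log = filter_eligible([s.meta for s in surveys], EligibilityCriteria())
    eligible_ids = {m.survey_id for m in eligible}
    used = [s for s in surveys if s.meta.survey_id in eligible_ids]
    est_rows = []
    for sv in used:
        cdr, u5 = estimate_rates(sv)
        hh = sv.households
        py = cdr.person_days / 365.25  # person-years, for demographic rates
        births = float(hh["births"].sum()) if "births" in hh else np.nan
        net_mig = (
            float((hh["joins"] - hh["leaves"]).sum())
            if {"joins", "leaves"} <= set(hh.columns)
            else np.nan
        )
        est_rows.append(
            {
                "survey_id": sv.meta.survey_id,
                "district": sv.meta.district,
                "cdr": cdr.rate,
                "cdr_lo": cdr.ci_low,
                "cdr_hi": cdr.ci_high,
                "u5dr": u5.rate,
                "u5dr_lo": u5.ci_low,
                "u5dr_hi": u5.ci_high,
                "households": cdr.n_households,
                "clusters": cdr.n_clusters,
                "person_days": cdr.person_days,
                "deaths": cdr.deaths,
                "deaths_u5": u5.deaths,
                "mean_household_size": hh["n_members"].mean() if "n_members" in hh else np.nan,
                "prop_under5": u5.person_days / cdr.person_days if cdr.person_days else np.nan,
                "birth_rate_per_1000py": births / py * 1000 if py else np.nan,
                "net_migration_per_1000py": net_mig / py * 1000 if py else np.nan,
                "quality": sv.meta.quality,
            }
        )
    pd.DataFrame(est_rows).to_csv(outdir / "survey_estimates.csv", index=False)
    exclusion_log.to_csv(outdir / "survey_exclusions.csv", index=False)

    # ---- stage 2: denominators ------------------------------------------
    pop = build_denominators(anchors, flows, months, config.growth_rate_yr, config.under5_fraction)
    cio.write_population(pop, outdir / "population.csv")
    displacement_summary(flows).to_csv(outdir / "displacement_summary.csv", index=False)

    # ---- stage 3: predictor panel ----------------------------------------
    panel, prov = prepare_panel(raw_panel, districts, config)
    cio.write_panel(panel, outdir / "panel.csv")
    cio.write_panel(prov, outdir / "panel_provenance.csv")

    # ---- stage 4: model selection ----------------------------------------
    mseed = stage_seed(master, "model_selection")
    manifest["stage_seeds"]["model_selection"] = mseed
    candidates = [t for t in DEFAULT_CANDIDATES if t.predictor in panel.columns]
    frame = build_model_frame(used, panel, candidates)
    k = min(config.cv_folds, frame["survey_id"].nunique())
    if search:
        screened = screen_predictors(list(candidates), frame, k=k, seed=mseed)
        if not screened:
            screened = list(candidates)
        ranked = brute_force_search(screened, frame, max_terms=6, k=k, seed=mseed)
        short = shortlist(ranked, config.shortlist_frac)
        best, rule = select_final(short, frame, train_frac=config.train_frac, seed=mseed)
        final_spec = best.spec
        manifest["model_selection_rule"] = rule
        pd.DataFrame(
            [
                {"spec": s.spec.key, "cv_dss": s.cv_dss, "n_params": s.n_params}
                for s in ranked
            ]
        ).to_csv(outdir / "model_leaderboard.csv", index=False)
    else:
        final_spec = ModelSpec("cdr", tuple(candidates))
    cdr_model = fit_quasipoisson(frame, ModelSpec("cdr", final_spec.terms))
    u5dr_model = fit_quasipoisson(frame, ModelSpec("u5dr", final_spec.terms))
    cio.write_model_json(cdr_model, outdir / "model_cdr.json")
    cio.write_model_json(u5dr_model, outdir / "model_u5dr.json")

    # ---- stage 5: excess --------------------------------------------------
    from ._util import as_month

    excess_months = months[months >= as_month(config.excess_start)]
    summaries = []
    for name in config.scenarios:
        scenario = canonical_scenarios()[name]
        panel_cf = build_counterfactual(
            panel, scenario, reference_years=config.reference_years,
            start=config.excess_start, region_of=region_of,
        )
        flows_cf = counterfactual_flows(flows, scenario.displacement_rule, start=config.excess_start)
        pop_cf = build_denominators(
            anchors, flows_cf, months, config.growth_rate_yr, config.under5_fraction
        )
        for age, model in (("all", cdr_model), ("under5", u5dr_model)):
            bseed = stage_seed(master, f"excess:{name}:{age}")
            manifest["stage_seeds"][f"excess:{name}:{age}"] = bseed
            reps = bootstrap_excess(
                model, panel, pop, panel_cf, pop_cf, excess_months,
                B=config.n_bootstrap, seed=bseed, region_of=region_of,
                scenario=name, age_group=age,
            )
            summaries.append(summarize(reps, alpha=config.alpha, by="national", period="overall"))
            summaries.append(summarize(reps, alpha=config.alpha, by="national", period="period"))
            summaries.append(summarize(reps, alpha=config.alpha, by="region", period="overall"))
    summary_df = pd.concat(summaries, ignore_index=True)
    summary_df.to_csv(outdir / "excess_summaries.csv", index=False)
    from .excess import aggregate_tables

    tables = aggregate_tables([summary_df])
    tables["by_year_scenario"].to_csv(outdir / "table_year_scenario.csv")
    tables["by_region"].to_csv(outdir / "table_region.csv", index=False)

    # ---- stage 6: sensitivity (optional) ---------------------------------
    if do_sensitivity:
        from .sensitivity import BiasGridSpec, run_bias_grid

        gseed = stage_seed(master, "sensitivity:bias")
        manifest["stage_seeds"]["sensitivity:bias"] = gseed
        grid = run_bias_grid(
            cdr_model, panel, anchors, flows, months, excess_months,
            canonical_scenarios()["most_likely"],
            BiasGridSpec(population_multipliers=(0.9, 1.0, 1.1), displacement_multipliers=(0.5, 1.0, 2.0)),
            growth_rate_yr=config.growth_rate_yr, under5_fraction=config.under5_fraction,
            region_of=region_of, seed=gseed, excess_start=config.excess_start,
            reference_years=config.reference_years,
        )
        grid.to_csv(outdir / "sensitivity_bias_grid.csv", index=False)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(outdir, manifest, cdr_model, u5dr_model, summary_df, panel)
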