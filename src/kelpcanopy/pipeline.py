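"""End-to-end orchestration: simulate -> classify -> filter -> consensus ->
validate -> timeseries -> environment.

Every product is written into a run directory with a provenance file
(config, seed, package version); rerunning with the same config is
byte-identical for the deterministic stages.  Stage seeds are derived from
the global seed so stages stay independent of each other's draw counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .dtm_classifier import (
    classify_scene,
    extract_water_endmembers,
    train_decision_tree,
    EndmemberLibrary,
    KELP_ENDMEMBER,
)
from .ff_consensus import (
    clean_consensus,
    composite_consensus,
    optimize_threshold,
    rasterize_votes,
    threshold_consensus,
)
from .geo_core import (
    BinaryCanopyMap,
    Grid,
    coast_distance,
    resample_mean,
    write_coastline_geojson,
)
from .postprocess_filters import PixelTimeseriesStack, apply_cascade
from .synthetic_data import (
    AnnotatorModel,
    BedSpec,
    make_coastline,
    make_environment,
    make_scene_series,
    simulate_annotations,
)
from .timeseries_env import (
    annual_composite,
    annual_nitrate_from_sst,
    fit_nitrate_model,
    lag_correlation,
    trend_test,
)
from .validation import aggregate_canopy, compare_sources

log = logging.getLogger("kelpcanopy")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _default_beds(grid: Grid, coastline, rng: np.random.Generator,
                  n_beds: int) -> list[BedSpec]:
    """Scatter elliptical beds in the 300 m – 3 km offshore band."""
    from .synthetic_data import _coast_x_at

    beds = []
    height = grid.n_rows * grid.pixel_size
    east_edge = grid.origin_x + grid.n_cols * grid.pixel_size
    for i in range(n_beds):
        y = grid.origin_y - rng.uniform(0.12, 0.88) * height
        cx = float(_coast_x_at(coastline, np.array([y]))[0])
        offshore_max = min(2500.0, east_edge - cx - 600.0)
        x = cx + rng.uniform(400.0, max(500.0, offshore_max))
        beds.append(BedSpec(x=x, y=y,
                            rx=rng.uniform(200.0, 500.0),
                            ry=rng.uniform(200.0, 500.0),
                            peak=rng.uniform(0.6, 1.0),
                            angle=rng.uniform(0, np.pi),
                            bed_id=i))
    return beds


def run(config: PipelineConfig) -> Path:
    """Execute the configured stages and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    provenance = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "version": __version__,
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance["config"], sort_keys=True).encode()).hexdigest()[:16]
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    grid = Grid(config.grid_rows, config.grid_cols, 0.0, 0.0, config.pixel_size)
    coast_seed = _stage_seed(config.seed, "coastline")
    coastline = make_coastline(grid, seed=coast_seed)
    write_coastline_geojson(coastline, out / "coastline_segments.geojson")
    distance = coast_distance(grid, coastline)

    scenes = truth_table = None
    if "simulate" in config.stages:
        rng = np.random.default_rng(_stage_seed(config.seed, "beds"))
        beds = _default_beds(grid, coastline, rng, config.n_beds)
        scenes, truth_table = make_scene_series(
            grid, coastline, beds,
            n_dates=config.n_dates, span_days=config.span_days,
            tide_amplitude=config.tide_amplitude,
            noise_sd=config.noise_sd,
            seed=_stage_seed(config.seed, "scenes"),
        )
        truth_table.to_csv(out / "truth_table.csv", index=False)
        log.info("simulated %d scenes (%d beds)", len(scenes), len(beds))

    dtm_maps: list[BinaryCanopyMap] = []
    stack = None
    if "classify" in config.stages:
        if scenes is None:
            raise RuntimeError("classify stage needs the simulate stage's scenes")
        first = scenes[0]
        feats, labels = [], []
        from .dtm_classifier import _scene_features

        f0 = _scene_features(first.scene)
        ocean = first.scene.ocean_mask.ravel()
        truth = (first.kelp_fraction_truth.ravel()
                 >= config.candidate_label_fraction)
        feats, labels = f0[ocean], truth[ocean]
        model = train_decision_tree(feats, labels,
                                    max_depth=config.tree_max_depth,
                                    seed=_stage_seed(config.seed, "tree"))
        from .dtm_classifier import apply_decision_tree

        water = extract_water_endmembers(
            first.scene, distance, n=config.n_water_endmembers,
            seed=_stage_seed(config.seed, "water"),
            exclude_mask=apply_decision_tree(model, first.scene, distance))
        library = EndmemberLibrary(kelp=KELP_ENDMEMBER, water=water)
        library.to_csv(out / "endmembers.csv")
        fractions, presences, tides = [], [], []
        for ts in scenes:
            fcm, bcm = classify_scene(ts.scene, model, library,
                                      config.threshold_fraction, distance)
            frac = np.where(fcm.candidate_mask, fcm.fraction, 0.0)
            frac[~ts.scene.ocean_mask] = np.nan
            fractions.append(frac)
            presences.append(bcm.presence)
            tides.append(ts.scene.tide_height or 0.0)
            dtm_maps.append(bcm)
        stack = PixelTimeseriesStack(
            grid=grid, dates=[s.scene.acquired_at for s in scenes],
            presence=np.stack(presences), fraction=np.stack(fractions),
            tide_at_date=np.array(tides),
        )
        log.info("classified %d scenes", len(scenes))

    if "filter" in config.stages and stack is not None:
        params = {"d_min": config.d_min, "d_max": config.d_max,
                  "p_min": config.p_min, "f_max": config.f_max,
                  "tide_r_min": config.tide_r_min,
                  "coherence_r_min": config.coherence_r_min,
                  "coherence_radius": config.coherence_radius}
        stack, report = apply_cascade(stack, distance, params)
        report.to_json(out / "filter_report.json")
        for line in report.log_lines():
            log.info(line)
        dtm_maps = [
            BinaryCanopyMap(grid=grid, presence=stack.presence[i],
                            provenance="dtm", acquired_at=stack.dates[i],
                            sensor=dtm_maps[i].sensor if dtm_maps else None)
            for i in range(len(stack.dates))
        ]

    if "consensus" in config.stages and scenes is not None:
        grid10 = Grid(grid.n_rows * 3, grid.n_cols * 3, grid.origin_x,
                      grid.origin_y, grid.pixel_size / 3, grid.crs_id)
        distance10 = coast_distance(grid10, coastline)
        annotator = AnnotatorModel(n_users=config.n_users,
                                   boundary_jitter_sd=15.0,
                                   false_pos_rate=0.2)
        votes_list, expert_list, consensus_maps = [], [], []
        for ts in scenes[:: max(1, len(scenes) // 4)]:  # a subset of dates
            ann = simulate_annotations(
                ts, annotator,
                seed=_stage_seed(config.seed,
                                 f"ann-{ts.scene.acquired_at.isoformat()}"))
            ann.excluded_tiles = set(config.excluded_tiles)
            votes = rasterize_votes(ann, grid10,
                                    acquired_at=ts.scene.acquired_at)
            binary = threshold_consensus(votes, config.consensus_tau)
            from .synthetic_data import land_mask_for

            cleaned = clean_consensus(binary, distance10,
                                      land_mask_for(grid10, coastline),
                                      d_max=config.d_max)
            consensus_maps.append(cleaned)
            votes_list.append(votes)
            # the expert matchup labels all visible kelp (fraction > 0), the
            # same feature annotators outline
            expert_list.append(BinaryCanopyMap(
                grid=grid, provenance="expert",
                presence=(ts.kelp_fraction_truth > 0).astype(float),
                acquired_at=ts.scene.acquired_at))
        applicable = (~land_mask_for(grid, coastline)) & (distance.distance <= config.d_max)
        composites = composite_consensus(consensus_maps, grid, config.interval,
                                         applicable_mask=applicable,
                                         min_completeness=config.min_completeness)
        tau_star, mcc_table = optimize_threshold(votes_list, expert_list, grid)
        mcc_table.to_csv(out / "mcc_by_tau.csv", index=False)
        (out / "consensus_summary.json").write_text(json.dumps({
            "tau_star": tau_star, "n_composites": len(composites),
        }))
        log.info("consensus: tau*=%d, %d composites", tau_star, len(composites))

    if "validate" in config.stages and scenes is not None and dtm_maps:
        expert_rows, dtm_rows = [], []
        for ts, bcm in zip(scenes, dtm_maps):
            sid = ts.scene.acquired_at.isoformat()
            truth_map = BinaryCanopyMap(
                grid=grid, provenance="expert",
                presence=(ts.kelp_fraction_truth
                          >= config.threshold_fraction).astype(float),
                acquired_at=ts.scene.acquired_at)
            expert_rows.append(aggregate_canopy(truth_map, coastline, distance,
                                                config.d_min, config.d_max, sid))
            dtm_rows.append(aggregate_canopy(bcm, coastline, distance,
                                             config.d_min, config.d_max, sid))
        expert_agg = pd.concat(expert_rows, ignore_index=True)
        dtm_agg = pd.concat(dtm_rows, ignore_index=True)
        expert_agg.to_csv(out / "aggregates_expert.csv", index=False)
        dtm_agg.to_csv(out / "aggregates_dtm.csv", index=False)
        result = compare_sources(expert_agg, dtm_agg)
        (out / "validation.json").write_text(json.dumps({
            "r_squared": result.r_squared,
            "rmse_pct_range": result.rmse_pct_range,
            "bias": result.bias, "n_segments": result.n_segments,
        }, indent=2))
        log.info("validation: R^2=%.3f RMSE%%=%.1f", result.r_squared,
                 result.rmse_pct_range)

    canopy_ts = None
    if "timeseries" in config.stages and dtm_maps:
        canopy_ts = annual_composite(dtm_maps, config.interval)
        table = canopy_ts.merged.copy()
        table.to_csv(out / "canopy_timeseries.csv", index=False)
        if len(table) >= 3:
            tr = trend_test(canopy_ts)
            (out / "trend.json").write_text(json.dumps({
                "slope_m2_per_interval": tr.slope, "p_value": tr.p_value,
                "n": tr.n}))
            log.info("trend: slope=%.1f m^2/interval, p=%.3g", tr.slope,
                     tr.p_value)

    if "env" in config.stages:
        env = make_environment(config.n_env_years,
                               driver_noise_var=config.driver_noise_var,
                               seed=_stage_seed(config.seed, "env"))
        env.sst_monthly.to_csv(out / "sst_monthly.csv", index=False)
        env.nitrate_pairs.to_csv(out / "nitrate_pairs.csv", index=False)
        env.climate_index.to_csv(out / "climate_index.csv", index=False)
        model = fit_nitrate_model(env.nitrate_pairs)
        annual_n = annual_nitrate_from_sst(env.sst_monthly, model)
        driver = env.canopy_driver.set_index("year")["value"]
        nitrate = env.nitrate_annual.set_index("year")["nitrate_std"]
        r, p, n = lag_correlation(driver, nitrate, lag=config.env_lag)
        (out / "environment.json").write_text(json.dumps({
            "nitrate_model": {"intercept": model.intercept,
                              "slope": model.slope, "rmse": model.rmse,
                              "rmse_pct_range": model.rmse_pct_range,
                              "n_pairs": model.n_pairs},
            "annual_nitrate_mean": float(annual_n.mean()),
            "lag": config.env_lag,
            "canopy_nitrate_r": r, "p_value": p, "n": n,
        }, indent=2))
        log.info("env: nitrate fit rmse=%.2f, lag-%d r=%.3f (p=%.3g)",
                 model.rmse, config.env_lag, r, p)

    log.removeHandler(fh)
    fh.close()
    return out
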