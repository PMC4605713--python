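"""End-to-end orchestration of the synthetic velocity pipeline.

Chains the stages — simulate a world, fit the ordination, compute
climatic and biotic velocity, summarize — on a single `RunConfig`.
The CLI wraps these functions; they are equally usable from Python.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analog, biotic, summaries, synthetic
from .climate_space import ClimateGrid, fit_ordination, project
from .io import (
    RunConfig,
    field_to_raster,
    grid_header,
    read_ascii_grid,
    read_climate_grid,
    read_toml,
    write_ascii_grid,
    write_climate_grid,
    write_toml,
)

log = logging.getLogger("climvelocity")

__all__ = ["World", "simulate_world", "write_world", "load_world", "run_analysis"]


@dataclass
class World:
    """Everything a run consumes: climate, species, zones, protected areas."""

    cfg: RunConfig
    terrain: synthetic.TerrainGrid
    current: ClimateGrid
    futures: list[ClimateGrid]
    stack_current: biotic.SuitabilityStack
    stacks_future: list[biotic.SuitabilityStack]
    zones: summaries.ZoneMap
    pas: list[synthetic.ProtectedArea]


def simulate_world(cfg: RunConfig) -> World:
    """Generate the full synthetic world for a configuration (seeded)."""
    t0 = time.perf_counter()
    terrain = synthetic.make_terrain(
        cfg.nx, cfg.ny, cfg.n_mountains, cfg.max_elev, seed=cfg.seed,
        cell_size_km=cfg.cell_size_km,
    )
    scenario = synthetic.ScenarioConfig(
        n_pseudo_gcms=cfg.n_pseudo_gcms,
        warming_mean=list(cfg.warming_mean),
        spatial_noise_sd=cfg.spatial_noise_sd,
        precip_change_frac=list(cfg.precip_change_frac),
        years_between=cfg.years_between,
        cell_size_km=cfg.cell_size_km,
        seed=cfg.seed + 1,
    )
    current, futures = make_bioclim_from_cfg(terrain, scenario, cfg)
    niches = synthetic.sample_niches(
        current, cfg.n_species, seed=cfg.seed + 2,
        halfwidth_range=tuple(cfg.halfwidth_range),
    )
    stack_current, stacks_future = synthetic.make_species(current, futures, niches)
    lat_lo, lat_hi = float(terrain.lat.min()), float(terrain.lat.max())
    edges = np.linspace(lat_lo - 1e-9, lat_hi + 1e-9, cfg.n_zones + 1)
    zones = summaries.ZoneMap(
        cell_id=terrain.cell_id, zone=synthetic.make_zones(terrain, edges)
    )
    pas = synthetic.make_protected_areas(
        terrain, cfg.n_pa, radius_range=tuple(cfg.pa_radius_range), seed=cfg.seed + 3
    )
    log.info(
        "simulate: %d cells, %d vars, %d pseudo-GCMs, %d species, %d PAs (%.2fs)",
        terrain.n_cells, cfg.n_vars, cfg.n_pseudo_gcms, cfg.n_species, len(pas),
        time.perf_counter() - t0,
    )
    return World(cfg, terrain, current, futures, stack_current, stacks_future, zones, pas)


def make_bioclim_from_cfg(terrain, scenario, cfg: RunConfig):
    return synthetic.make_bioclim(
        terrain, scenario, n_vars=cfg.n_vars, lapse_rate=cfg.lapse_rate,
        var_noise_sd=cfg.var_noise_sd,
    )


def write_world(world: World, out_dir) -> None:
    """Write the world as ASCII rasters, CSV tables and a TOML manifest."""
    out = Path(out_dir)
    (out / "climate").mkdir(parents=True, exist_ok=True)
    (out / "species").mkdir(exist_ok=True)
    header = grid_header(world.current)
    write_toml({"run": world.cfg.to_manifest()}, out / "manifest.toml")
    write_climate_grid(world.current, out / "climate")
    for f in world.futures:
        write_climate_grid(f, out / "climate")
    t = world.terrain
    write_ascii_grid(
        out / "elevation.asc",
        field_to_raster(t.elevation, t.x_index, t.y_index, t.nx, t.ny),
        header,
    )
    write_ascii_grid(
        out / "zones.asc",
        field_to_raster(world.zones.zone.astype(float), t.x_index, t.y_index, t.nx, t.ny),
        header, integer=True,
    )
    pa_field = np.zeros(t.n_cells)
    for pa in world.pas:
        pa_field[pa.mask] = pa.pa_id + 1
    write_ascii_grid(
        out / "protected_areas.asc",
        field_to_raster(pa_field, t.x_index, t.y_index, t.nx, t.ny),
        header, integer=True,
    )
    pd.DataFrame(
        {
            "species_id": world.stack_current.species_ids,
            "taxon": world.stack_current.taxa,
        }
    ).to_csv(out / "species" / "species.csv", index=False)
    for stack in [world.stack_current] + world.stacks_future:
        for s, sp in enumerate(stack.species_ids):
            arr = field_to_raster(
                stack.mask[s].astype(float), t.x_index, t.y_index, t.nx, t.ny
            )
            write_ascii_grid(
                out / "species" / f"suit_{stack.period}_{stack.gcm_id}_{sp}.asc",
                arr, header, integer=True,
            )


def load_world(out_dir) -> World:
    """Reconstruct a world from the tree written by `write_world`."""
    out = Path(out_dir)
    cfg = RunConfig(**read_toml(out / "manifest.toml")["run"])
    # regenerate terrain (deterministic) to recover indices/elevation
    terrain = synthetic.make_terrain(
        cfg.nx, cfg.ny, cfg.n_mountains, cfg.max_elev, seed=cfg.seed,
        cell_size_km=cfg.cell_size_km,
    )
    var_names = ["tmean", "precip"] + [f"bio{k + 1}" for k in range(2, cfg.n_vars)]
    cdir = out / "climate"
    current = read_climate_grid(
        [cdir / f"current_obs_{v}.asc" for v in var_names], var_names,
        "current", "obs", cfg.cell_size_km,
    )
    futures = []
    for g in range(cfg.n_pseudo_gcms):
        gid = f"pgcm{g:02d}"
        futures.append(
            read_climate_grid(
                [cdir / f"future_{gid}_{v}.asc" for v in var_names], var_names,
                "future", gid, cfg.cell_size_km,
            )
        )
    sp = pd.read_csv(out / "species" / "species.csv")
    meta = dict(
        species_ids=sp["species_id"].tolist(),
        taxa=sp["taxon"].tolist(),
        cell_id=current.cell_id,
        lon=np.asarray(current.lon, dtype=float),
        lat=np.asarray(current.lat, dtype=float),
        cell_size_km=cfg.cell_size_km,
        xy_km=current.xy_km(),
    )

    def _read_stack(period: str, gcm_id: str) -> biotic.SuitabilityStack:
        rows = []
        for spid in meta["species_ids"]:
            arr, _ = read_ascii_grid(
                out / "species" / f"suit_{period}_{gcm_id}_{spid}.asc"
            )
            rows.append(arr[current.y_index, current.x_index] > 0.5)
        return biotic.SuitabilityStack(
            period=period, gcm_id=gcm_id, mask=np.vstack(rows), **meta
        )

    stack_current = _read_stack("current", "obs")
    stacks_future = [_read_stack("future", f.gcm_id) for f in futures]
    zone_arr, _ = read_ascii_grid(out / "zones.asc")
    zones = summaries.ZoneMap(
        cell_id=current.cell_id,
        zone=zone_arr[current.y_index, current.x_index].astype(np.int64),
    )
    pa_arr, _ = read_ascii_grid(out / "protected_areas.asc")
    pa_field = pa_arr[current.y_index, current.x_index]
    pas = []
    for pid in np.unique(pa_field[pa_field > 0]):
        mask = pa_field == pid
        pas.append(
            synthetic.ProtectedArea(
                pa_id=int(pid) - 1, mask=mask,
                area_km2=float(mask.sum()) * cfg.cell_size_km**2,
            )
        )
    return World(cfg, terrain, current, futures, stack_current, stacks_future, zones, pas)


def run_analysis(world: World, out_dir=None) -> dict:
    """Ordination, climatic and biotic velocity, and the summary layer.

    Returns a dict of the principal results; if ``out_dir`` is given the
    standard CSV/raster outputs are also written.
    """
    cfg = world.cfg
    t0 = time.perf_counter()
    model = fit_ordination(
        [world.current] + world.futures,
        min_fraction=cfg.min_variance_fraction,
        fit_basis=cfg.fit_basis,
    )
    sc_cur = project(world.current, model)
    sc_futs = [project(f, model) for f in world.futures]
    log.info(
        "ordinate: retained %d axes, variance fractions %s (%.2fs)",
        model.n_retained,
        np.round(model.variance_fraction[: model.n_retained], 3).tolist(),
        time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    fwd_fields, bwd_fields = [], []
    for f, sf in zip(world.futures, sc_futs):
        vf = analog.climatic_velocity(
            sc_cur, sf, bin_width=cfg.bin_width, n_offsets=cfg.n_offsets,
            years_between=cfg.years_between, mode=cfg.distance_mode, gcm_id=f.gcm_id,
        )
        fwd_fields.append(vf["forward"])
        bwd_fields.append(vf["backward"])
    ens_fwd = analog.ensemble_average(fwd_fields)
    ens_bwd = analog.ensemble_average(bwd_fields)
    log.info(
        "climatic velocity: %d cells x %d offsets x %d GCMs; "
        "no-analog fwd/bwd %.3f/%.3f (%.2fs)",
        sc_cur.n_cells, cfg.n_offsets, cfg.n_pseudo_gcms,
        float(np.mean(ens_fwd.no_analog_prob)), float(np.mean(ens_bwd.no_analog_prob)),
        time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    fwd_by_gcm = [
        biotic.species_velocity(
            world.stack_current, sf, years_between=cfg.years_between,
            direction="forward", mode=cfg.distance_mode,
        )
        for sf in world.stacks_future
    ]
    bwd_by_gcm = [
        biotic.species_velocity(
            world.stack_current, sf, years_between=cfg.years_between,
            direction="backward", mode=cfg.distance_mode,
        )
        for sf in world.stacks_future
    ]
    n_cells = world.stack_current.n_cells
    tax_fwd = biotic.aggregate_taxa(fwd_by_gcm, n_cells, world.stack_current.cell_id)
    tax_bwd = biotic.aggregate_taxa(bwd_by_gcm, n_cells, world.stack_current.cell_id)
    disap = biotic.disappearance_probability(world.stack_current, world.stacks_future)
    log.info(
        "biotic velocity: %d species x %d GCMs (%.2fs)",
        world.stack_current.n_species, cfg.n_pseudo_gcms, time.perf_counter() - t0,
    )

    bio_fwd = tax_fwd["all"].mean_velocity
    bio_bwd = tax_bwd["all"].mean_velocity
    rho_fwd = summaries.rank_correlation(ens_fwd.velocity, bio_fwd)
    rho_bwd = summaries.rank_correlation(ens_bwd.velocity, bio_bwd)
    prof_clim = summaries.latitudinal_profile(ens_fwd.velocity, ens_fwd.lat)
    prof_bio = summaries.latitudinal_profile(bio_fwd, world.stack_current.lat)
    zone_clim = summaries.zonal_distribution(ens_fwd.velocity, world.zones)
    classes = summaries.bivariate_quantile_classes(ens_fwd.velocity, ens_bwd.velocity)
    V = np.empty((world.stack_current.n_species, cfg.n_pseudo_gcms, n_cells))
    for g, fields in enumerate(fwd_by_gcm):
        for s, f in enumerate(fields):
            V[s, g] = np.nan
            if not f.range_disappears:
                V[s, g, f.cell_index] = f.velocity
    vardec = summaries.variance_decomposition(V)
    pa_records = summaries.protected_area_assessment(
        {
            "forward_climatic": ens_fwd.velocity,
            "backward_climatic": ens_bwd.velocity,
            "forward_biotic": bio_fwd,
            "backward_biotic": bio_bwd,
        },
        [pa.mask for pa in world.pas],
        [pa.area_km2 for pa in world.pas],
        min_area_km2=cfg.min_area_km2,
    )

    results = {
        "model": model,
        "scores_current": sc_cur,
        "ensemble_forward": ens_fwd,
        "ensemble_backward": ens_bwd,
        "climatic_forward_by_gcm": fwd_fields,
        "climatic_backward_by_gcm": bwd_fields,
        "taxa_forward": tax_fwd,
        "taxa_backward": tax_bwd,
        "disappearance_probability": disap,
        "spearman_forward": rho_fwd,
        "spearman_backward": rho_bwd,
        "profile_climatic": prof_clim,
        "profile_biotic": prof_bio,
        "zone_summary": zone_clim,
        "bivariate_classes": classes,
        "variance_decomposition": vardec,
        "pa_records": pa_records,
    }
    if out_dir is not None:
        _write_outputs(world, results, Path(out_dir))
    return results


def _write_outputs(world: World, results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    t = world.terrain
    header = grid_header(world.current)
    results["model"].to_json(out / "ordination.json")

    def _rast(name: str, values: np.ndarray) -> None:
        arr = field_to_raster(values, t.x_index, t.y_index, t.nx, t.ny)
        write_ascii_grid(out / name, arr, header)

    for direction, ens in (
        ("forward", results["ensemble_forward"]),
        ("backward", results["ensemble_backward"]),
    ):
        _rast(f"climatic_velocity_{direction}.asc", ens.velocity)
        _rast(f"climatic_no_analog_{direction}.asc", ens.no_analog_prob)
    for direction, key in (("forward", "taxa_forward"), ("backward", "taxa_backward")):
        _rast(f"biotic_velocity_{direction}.asc", results[key]["all"].mean_velocity)
    _rast("disappearance_probability.asc", results["disappearance_probability"])
    _rast("bivariate_classes.asc", results["bivariate_classes"].astype(float))

    rows = []
    for direction, fields in (
        ("forward", results["climatic_forward_by_gcm"]),
        ("backward", results["climatic_backward_by_gcm"]),
    ):
        for f in fields:
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": f.cell_id,
                        "gcm": f.gcm_id,
                        "direction": direction,
                        "mean_distance_km": f.mean_distance,
                        "velocity_km_yr": f.velocity,
                        "no_analog_prob": f.no_analog_prob,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(out / "climatic_velocity.csv", index=False)
    pd.DataFrame(
        {
            "metric": ["spearman_forward", "spearman_backward"],
            "value": [results["spearman_forward"], results["spearman_backward"]],
        }
    ).to_csv(out / "correlations.csv", index=False)
    for name in ("climatic", "biotic"):
        p = results[f"profile_{name}"]
        pd.DataFrame({"lat": p.lat_grid, "fitted_velocity": p.fitted}).to_csv(
            out / f"latitude_profile_{name}.csv", index=False
        )
    results["zone_summary"].drop(columns=["kde_x", "kde_y"]).to_csv(
        out / "zone_summary.csv", index=False
    )
    pd.DataFrame([results["variance_decomposition"]]).to_csv(
        out / "variance_decomposition.csv", index=False
    )
    results["pa_records"].to_csv(out / "pa_records.csv", index=False)
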