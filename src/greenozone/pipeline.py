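"""End-to-end orchestration: generate → fuse → emit → analyse → burden.

A run is driven by a single YAML-style mapping (:class:`RunConfig`): either
a ``synthetic`` block (the generator produces every input) or an ``inputs``
block of file paths from a previous ``generate`` — exactly one of the two.
Every stage validates its outputs through the module containers before the
next stage consumes them, writes its artifacts under the output directory,
and is recorded (with SHA-256 checksums) in a run manifest, so a rerun with
the same config and seed is bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .emissions import (ActivityParams, emission_flux, load_emission_factors,
                        seasonal_budget)
from .grid import hourly_dataset, read_raster, write_netcdf, write_raster
from .health import RRModel, attribute_to_urban_greening
from .landcover import PHENOLOGY_LAT_CUTOFF, fuse_landcover, lai_from_pft, load_lai_table
from .ozone_analysis import (ScenarioPair, delta_mda8, population_weighted_mean,
                             stratify, temperature_relationship)
from .synthetic_data import (Meteorology, SyntheticConfig, generate_landcover,
                             generate_meteorology,
                             generate_population_and_incidence,
                             generate_scenario_pair)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration (one synthetic block or input paths)."""

    seed: int = 0
    outdir: str = "greenozone_run"
    synthetic: dict | None = None
    inputs: dict | None = None
    landcover: dict = dataclasses.field(default_factory=dict)
    emissions: dict = dataclasses.field(default_factory=dict)
    ozone: dict = dataclasses.field(default_factory=dict)
    health: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of 'synthetic' or 'inputs'")
        if self.inputs is not None:
            required = {"fine_landcover", "coarse_pft", "urban_mask",
                        "meteorology", "base", "ug", "population", "incidence"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing paths: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input '{key}' not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        block = dict(self.synthetic or {})
        block.setdefault("seed", self.seed)
        # YAML 1.1 reads unsigned exponents ("2.0e7") as strings; coerce
        # scalars to the dataclass field types
        types = {f.name: f.type for f in dataclasses.fields(SyntheticConfig)}
        for key, val in block.items():
            if types.get(key) == "float" and val is not None:
                block[key] = float(val)
            elif types.get(key) == "int" and val is not None:
                block[key] = int(val)
        if "urban_center_km" in block and block["urban_center_km"] is not None:
            block["urban_center_km"] = tuple(block["urban_center_km"])
        if "wind_kmh" in block:
            block["wind_kmh"] = tuple(block["wind_kmh"])
        return SyntheticConfig(**block)

    def canonical_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all five stages and write the result bundle + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    results: dict = {"outdir": str(outdir)}

    # ---- stage 1: generate (or load) inputs ------------------------------
    stage = "generate"
    try:
        if config.synthetic is not None:
            cfg = config.synthetic_config()
            lc = generate_landcover(cfg)
            met = generate_meteorology(cfg)
            pair = generate_scenario_pair(cfg, met)
            pop, incidence = generate_population_and_incidence(cfg)
            grid = cfg.coarse_grid
            spinup_days = cfg.spinup_days
            season_days = cfg.n_days
            artifacts += [
                write_raster(outdir / "landcover_fine.tif", lc.fine_classes,
                             lc.fine_grid, class_codes="0=non-vegetated,1=tree,"
                             "2=shrub,3=grass,4=crop"),
                write_raster(outdir / "coarse_pft.tif", lc.coarse_chi.astype(np.float32),
                             grid, band_names=[f"pft_{j}" for j in range(1, 17)]),
                write_raster(outdir / "urban_mask.tif",
                             lc.urban_mask.astype(np.uint8), grid),
                write_raster(outdir / "population.tif", pop.astype(np.float32), grid),
                write_netcdf(hourly_dataset({"t2m_c": met.t2m_c, "par": met.par},
                                            grid), outdir / "meteorology.nc"),
                write_netcdf(hourly_dataset({"o3": pair.base}, grid,
                                            scenario="Base",
                                            spinup_days=spinup_days),
                             outdir / "o3_base.nc"),
                write_netcdf(hourly_dataset({"o3": pair.ug}, grid,
                                            scenario="UG",
                                            spinup_days=spinup_days),
                             outdir / "o3_ug.nc"),
            ]
            inc_path = outdir / "incidence.csv"
            incidence.to_csv(inc_path, index=False)
            artifacts.append(inc_path)
        else:
            paths = config.inputs
            fine, fine_grid, _ = read_raster(paths["fine_landcover"])
            chi, grid, _ = read_raster(paths["coarse_pft"])
            mask_arr, _, _ = read_raster(paths["urban_mask"])
            pop, _, _ = read_raster(paths["population"])
            met_ds = xr.open_dataset(paths["meteorology"])
            base_ds = xr.open_dataset(paths["base"])
            ug_ds = xr.open_dataset(paths["ug"])
            spinup_days = int(base_ds.attrs.get("spinup_days", 4))
            met = Meteorology(grid, met_ds["t2m_c"].values.astype(float),
                              met_ds["par"].values.astype(float),
                              day_anomaly_c=np.zeros(
                                  met_ds.sizes["time"] // 24))
            pair = ScenarioPair(grid, base_ds["o3"].values.astype(float),
                                ug_ds["o3"].values.astype(float),
                                spinup_days=spinup_days)
            from .landcover import LandCoverFusion
            lc = LandCoverFusion(grid, fine_grid, fine, chi.astype(float),
                                 mask_arr.astype(bool))
            incidence = pd.read_csv(paths["incidence"])
            season_days = pair.n_days - spinup_days
    except Exception as exc:                                   # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 2: land-cover fusion + LAI --------------------------------
    stage = "landcover"
    try:
        cutoff = config.landcover.get("phenology_lat_cutoff",
                                      PHENOLOGY_LAT_CUTOFF)
        pft_map = fuse_landcover(lc.fine_classes, lc.coarse_chi,
                                 lc.urban_mask, grid, cutoff)
        lai_path = config.landcover.get("lai_table")
        lai_map = lai_from_pft(pft_map, load_lai_table(lai_path))
        artifacts += [
            write_raster(outdir / "pft_fused.tif",
                         pft_map.chi.astype(np.float32), grid,
                         band_names=[f"pft_{j}" for j in range(1, 17)]),
            write_raster(outdir / "lai.tif", lai_map.lai.astype(np.float32),
                         grid),
        ]
    except Exception as exc:                                   # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 3: biogenic emissions -------------------------------------
    stage = "emissions"
    try:
        params = ActivityParams(**config.emissions.get("activity", {}))
        species = config.emissions.get("species", "isoprene")
        eps = load_emission_factors(config.emissions.get("epsilon_table"),
                                    species)
        em = emission_flux(pft_map, lai_map, met.t2m_k(), met.par, params, eps,
                           species)
        budget = seasonal_budget(em, lc.urban_mask)
        results["emissions"] = budget
        flux_path = write_netcdf(
            hourly_dataset({"flux": em.flux}, grid, species=species,
                           units="ug m-2 h-1"), outdir / "emission_flux.nc")
        budget_path = outdir / "emission_budget.csv"
        pd.DataFrame([budget]).to_csv(budget_path, index=False)
        artifacts += [flux_path, budget_path]
    except Exception as exc:                                   # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 4: ozone scenario analysis --------------------------------
    stage = "ozone"
    try:
        surf = delta_mda8(pair)
        strata = stratify(surf.delta_seasonal, lc.urban_mask)
        t_daily = met.daily_mean_t()[spinup_days:]
        rel = temperature_relationship(
            surf.delta_daily, t_daily, lc.urban_mask,
            bins=config.ozone.get("bins", 6),
            per_cell=config.ozone.get("per_cell", False))
        pw = population_weighted_mean(surf.delta_seasonal, pop)
        simple = float(np.nanmean(surf.delta_seasonal))
        urban_delta = float(np.nanmean(surf.delta_seasonal[lc.urban_mask]))
        results["ozone"] = {
            "urban_mean_delta_mda8_ppb": urban_delta,
            "suburban_mean_delta_mda8_ppb": float(strata.loc["suburban", "mean"]),
            "relative_change_pct": float(np.nanmean(
                surf.relative_pct[lc.urban_mask])),
            "pearson_r": rel["r"], "p_value": rel["p_value"],
            "pop_weighted_delta_ppb": pw, "simple_mean_delta_ppb": simple,
        }
        exp_ds = xr.Dataset(
            {"mda8_base": (("day", "y", "x"), surf.mda8_base.astype(np.float32)),
             "mda8_ug": (("day", "y", "x"), surf.mda8_ug.astype(np.float32)),
             "delta_daily": (("day", "y", "x"),
                             surf.delta_daily.astype(np.float32)),
             "delta_seasonal": (("y", "x"),
                                surf.delta_seasonal.astype(np.float32)),
             "seasonal_base": (("y", "x"),
                               surf.seasonal_base.astype(np.float32))},
            coords={"day": np.arange(surf.mda8_base.shape[0]),
                    "y": grid.y_centers(), "x": grid.x_centers()},
            attrs={"res_km": grid.res_km, "center_lat": grid.center_lat})
        exposure_path = write_netcdf(exp_ds, outdir / "exposure.nc")
        summary_path = outdir / "ozone_summary.csv"
        strata.assign(statistic="delta_seasonal_ppb").to_csv(summary_path)
        artifacts += [exposure_path, summary_path]
    except Exception as exc:                                   # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 5: health burden ------------------------------------------
    stage = "health"
    try:
        hcfg = dict(config.health)
        model = RRModel(rr_per_10ppb=hcfg.get("rr_per_10ppb", 1.06),
                        c0=hcfg.get("c0", 32.4),
                        cause=hcfg.get("cause", "copd"))
        season = hcfg.get("season_days", season_days)
        attribution = attribute_to_urban_greening(
            surf.seasonal_base, surf.seasonal_ug, pop, incidence, model,
            season_days=season)
        results["health"] = {
            "m_base": attribution["m_base"], "m_ug": attribution["m_ug"],
            "attributed": attribution["attributed"],
            "fraction": attribution["fraction"],
            "rr_bar_ug": attribution["burden_ug"].rr_bar,
            "season_days": season,
        }
        burden_path = write_raster(
            outdir / "burden.tif",
            attribution["burden_ug"].m_grid.astype(np.float32), grid)
        csv_path = outdir / "health_burden.csv"
        pd.DataFrame([{"region": "domain", "cause": model.cause,
                       "M_base": attribution["m_base"],
                       "M_ug": attribution["m_ug"],
                       "attributed": attribution["attributed"],
                       "fraction": attribution["fraction"],
                       "season_days": season}]).to_csv(csv_path, index=False)
        artifacts += [burden_path, csv_path]
    except Exception as exc:                                   # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": ["generate", "landcover", "emissions", "ozone", "health"],
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
        "results": _jsonable(results),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = str(manifest_path)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
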