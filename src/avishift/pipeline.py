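"""End-to-end orchestration: simulate -> prep -> model -> analyze -> prioritize.

A run is a pure function of its :class:`RunConfig` (including the master
seed): per-stage seeds are derived by hashing the stage name into the master
seed, so any stage can be re-run reproducibly from the manifest alone.  The
manifest records the config, derived seeds, per-stage species counts, the
exclusion log, and a SHA-256 checksum of every output file; it contains no
timestamps, so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, SpeciesError
from .niche import run_two_rounds
from .occurrences import thin_presences, uniformity_stats, validate_and_filter
from .ranges import (
    binarize,
    elevation_profile,
    range_change_record,
    richness_change,
    stack_richness,
    summarize_groups,
)
from .raster import RasterGrid, write_raster
from .synthetic import (
    WorldConfig,
    cohort_metadata,
    make_effort_bias,
    make_species_cohort,
    make_world,
    sample_occurrences,
)
from .zonation import caz_rank, compute_weights, coverage_stats, top_fraction

_CSV_KW = dict(index=False, float_format="%.10g")  # fixed dialect: utf-8, '.', comma


def derive_seed(master: int, *parts) -> int:
    """Stage seed: master seed with the stage path hashed in (< 2**31)."""
    h = zlib.crc32("/".join(str(p) for p in parts).encode())
    return int((int(master) * 2654435761 + h) % (2**31))


@dataclass
class RunConfig:
    """Validated parameter blocks of one pipeline run."""

    world: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)
    prep: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    prioritization: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=lambda: [
        {"name": "rcp_low", "climate_shift": [1.0, 0.0, 0.0, 0.0]},
        {"name": "rcp_high", "climate_shift": [2.5, 0.0, 0.0, 0.0]},
    ])
    seed: int = 0

    _SCHEMA = {
        "species": {"n_species": int, "n_points": int, "breadth_factor": float,
                    "effort_bias_strength": float},
        "prep": {"min_localities": int, "min_sep_arcmin": float},
        "model": {"n_background": int, "k_folds": int, "regularization": float,
                  "corr_threshold": float, "prune_tolerance": float,
                  "density_block_deg": float},
        "prioritization": {"warp_factor": int, "fractions": list},
    }

    def __post_init__(self) -> None:
        self.species = {"n_species": 20, "n_points": 250, "breadth_factor": 0.15,
                        "effort_bias_strength": 1.0, **self.species}
        self.prep = {"min_localities": 5, "min_sep_arcmin": 1.0, **self.prep}
        self.model = {"n_background": 2000, "k_folds": 5, "regularization": 1.0,
                      "corr_threshold": 0.9, "prune_tolerance": 1e-8,
                      "density_block_deg": 3.0, **self.model}
        self.prioritization = {"warp_factor": 1000, "fractions": [0.3, 0.5],
                               **self.prioritization}
        self._validate()

    def _validate(self) -> None:
        for block, fields in self._SCHEMA.items():
            values = getattr(self, block)
            for key, typ in fields.items():
                if key not in values:
                    raise ConfigurationError(f"{block}.{key} missing")
                v = values[key]
                if typ in (int, float) and not isinstance(v, (int, float)):
                    raise ConfigurationError(f"{block}.{key} must be numeric")
                if typ is list and not isinstance(v, (list, tuple)):
                    raise ConfigurationError(f"{block}.{key} must be a list")
        names = [s["name"] for s in self.scenarios]
        if len(names) != len(set(names)):
            raise ConfigurationError("scenario names must be unique")
        for s in self.scenarios:
            if "climate_shift" not in s:
                raise ConfigurationError(f"scenario {s['name']} lacks climate_shift")

    def world_config(self) -> WorldConfig:
        return WorldConfig(seed=derive_seed(self.seed, "world"), **self.world)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    With zero future scenarios the analysis and prioritization stages are
    skipped with an explicit notice in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "world": config.world, "species": config.species,
            "prep": config.prep, "model": config.model,
            "analysis": config.analysis,
            "prioritization": config.prioritization,
            "scenarios": config.scenarios,
        },
        "stage_seeds": {}, "counts": {}, "notices": [],
    }

    # ---- simulate ---------------------------------------------------------
    wc = config.world_config()
    manifest["stage_seeds"]["world"] = wc.seed
    world = make_world(wc)
    current = world["climate_current"]
    futures = {
        s["name"]: current.with_values(
            current.values.reshape(-1, current.n_rows, current.n_cols)
            + np.asarray(s["climate_shift"], dtype=float)[:, None, None],
            band_names=current.band_names,
        )
        for s in config.scenarios
    }
    world_dir = out / "world"
    world_dir.mkdir(exist_ok=True)
    write_raster(current, world_dir / "climate_current.tif")
    for name, grid in futures.items():
        write_raster(grid, world_dir / f"climate_{name}.tif")
    for key in ("elevation", "regions", "reserve_mask"):
        write_raster(world[key], world_dir / f"{key}.tif")

    sp_cfg = config.species
    cohort = make_species_cohort(
        wc, current, n_species=int(sp_cfg["n_species"]),
        breadth_factor=float(sp_cfg["breadth_factor"]),
        seed=derive_seed(config.seed, "cohort"),
    )
    effort = None
    if sp_cfg["effort_bias_strength"] > 0:
        effort = make_effort_bias(wc, strength=float(sp_cfg["effort_bias_strength"]),
                                  seed=derive_seed(config.seed, "effort"))
    occ = pd.concat(
        [sample_occurrences(t, current, int(sp_cfg["n_points"]), effort_bias=effort,
                            seed=derive_seed(config.seed, "occ", t.species_id))
         for t in cohort],
        ignore_index=True,
    )
    meta = cohort_metadata(cohort)
    occ.to_csv(world_dir / "occurrences.csv", **_CSV_KW)
    meta.to_csv(world_dir / "species_meta.csv", **_CSV_KW)
    manifest["counts"]["species_simulated"] = len(cohort)
    manifest["counts"]["occurrences_simulated"] = len(occ)

    # ---- prep -------------------------------------------------------------
    prep_dir = out / "prep"
    prep_dir.mkdir(exist_ok=True)
    bbox = (current.lon_west, current.lat_south, current.lon_east, current.lat_north)
    prep_seed = derive_seed(config.seed, "prep")
    manifest["stage_seeds"]["prep"] = prep_seed
    cleaned, excl = validate_and_filter(
        occ, bbox, min_localities=int(config.prep["min_localities"]))
    cleaned = thin_presences(
        cleaned, min_sep_arcmin=float(config.prep["min_sep_arcmin"]), seed=prep_seed)
    cleaned.to_csv(prep_dir / "cleaned.csv", **_CSV_KW)
    excl.to_csv(prep_dir / "prep_exclusions.csv", **_CSV_KW)
    report = uniformity_stats(cleaned)
    _write_json(report.to_dict(), prep_dir / "uniformity.json")
    manifest["counts"]["species_after_prep"] = int(cleaned["species_id"].nunique())
    manifest["counts"]["occurrences_after_prep"] = len(cleaned)

    # ---- two-round modelling ---------------------------------------------
    model_seed = derive_seed(config.seed, "model")
    manifest["stage_seeds"]["model"] = model_seed
    mc = config.model
    result = run_two_rounds(
        cleaned, current, world["elevation"], world["regions"], futures,
        n_background=int(mc["n_background"]), k_folds=int(mc["k_folds"]),
        regularization=float(mc["regularization"]),
        corr_threshold=float(mc["corr_threshold"]),
        prune_tolerance=float(mc["prune_tolerance"]),
        density_block_deg=float(mc["density_block_deg"]),
        seed=model_seed,
    )
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for sp, m in sorted(result.models.items()):
        _write_json({**m.to_dict(), "mtss_threshold": result.thresholds[sp]},
                    models_dir / f"{sp}.json")
    result.exclusion_log.to_csv(models_dir / "model_log.csv", **_CSV_KW)
    _write_json(
        {"retained": result.screening.retained_variables,
         "removal_order": result.screening.removal_order,
         "round1_variables": result.round1_variables},
        models_dir / "screening.json",
    )
    suit_dir = out / "suitability"
    for scen, grids in result.suitability.items():
        d = suit_dir / scen
        d.mkdir(parents=True, exist_ok=True)
        for sp, g in sorted(grids.items()):
            write_raster(g, d / f"{sp}.tif")
    manifest["counts"]["species_round2"] = len(result.models)

    if not futures:
        manifest["notices"].append(
            "no future scenarios configured: analysis and prioritization skipped")
        _finalize(manifest, out)
        return manifest

    # ---- analyze ----------------------------------------------------------
    ana_dir = out / "analysis"
    ana_dir.mkdir(exist_ok=True)
    drms: dict[str, dict[str, object]] = {scen: {} for scen in result.suitability}
    for scen, grids in result.suitability.items():
        drm_dir = ana_dir / "drm" / scen
        drm_dir.mkdir(parents=True, exist_ok=True)
        for sp, g in sorted(grids.items()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = binarize(g, result.thresholds[sp], species_id=sp, scenario=scen)
            drms[scen][sp] = d
            write_raster(
                d.grid.with_values(
                    np.nan_to_num(d.grid.values, nan=0.0).astype(np.uint8)),
                drm_dir / f"{sp}.tif",
            )

    records = []
    analysis_log = []
    for scen in futures:
        for sp in sorted(result.models):
            try:
                records.append(range_change_record(drms["current"][sp],
                                                   drms[scen][sp]))
            except SpeciesError as e:
                analysis_log.append({"species_id": sp, "stage": f"analyze/{scen}",
                                     "action": "excluded", "reason": str(e)})
    records_df = pd.DataFrame(records)
    records_df.to_csv(ana_dir / "range_changes.csv", **_CSV_KW)
    pd.DataFrame(analysis_log, columns=["species_id", "stage", "action", "reason"]
                 ).to_csv(ana_dir / "analysis_log.csv", **_CSV_KW)

    rich_current = stack_richness(list(drms["current"].values()), "current")
    write_raster(rich_current, ana_dir / "richness_current.tif")
    for scen in futures:
        rich = stack_richness(list(drms[scen].values()), scen)
        write_raster(rich, ana_dir / f"richness_{scen}.tif")
        write_raster(richness_change(rich_current, rich),
                     ana_dir / f"richness_change_{scen}.tif")

    profiles = []
    for scen in futures:
        prof = elevation_profile(
            list(drms["current"].values()), list(drms[scen].values()),
            world["elevation"],
        )
        df = prof.diversity.reset_index()
        df.insert(0, "scenario", scen)
        df["turning_point_m"] = (np.nan if prof.turning_point is None
                                 else prof.turning_point)
        profiles.append(df)
    pd.concat(profiles, ignore_index=True).to_csv(
        ana_dir / "elevation_profile.csv", **_CSV_KW)

    if len(records_df):
        summaries = summarize_groups(records_df, meta)
        for key in ("area_change", "shift", "quadrant"):
            summaries[key].to_csv(ana_dir / f"summary_{key}.csv", **_CSV_KW)
    manifest["counts"]["range_change_records"] = len(records_df)

    # ---- prioritize -------------------------------------------------------
    pri_dir = out / "priority"
    pri_dir.mkdir(exist_ok=True)
    coverage: dict[str, dict] = {}
    warp = int(config.prioritization["warp_factor"])
    fractions = [float(f) for f in config.prioritization["fractions"]]
    for scen in futures:
        scen_records = records_df[records_df["scenario"] == scen] if len(records_df) \
            else records_df
        if not len(scen_records):
            manifest["notices"].append(f"no records for scenario {scen}: skipped")
            continue
        weights = compute_weights(scen_records, meta)
        weights.to_csv(pri_dir / f"weights_{scen}.csv", **_CSV_KW)
        layers = {sp: result.suitability[scen][sp]
                  for sp in weights["species_id"]}
        coverage[scen] = {}
        for masked, mask in (("", None), ("_masked", world["reserve_mask"])):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ranking = caz_rank(layers, weights, warp_factor=warp, mask=mask)
            write_raster(ranking.rank_grid, pri_dir / f"rank_{scen}{masked}.tif")
            for frac in fractions:
                top = top_fraction(ranking, frac)
                write_raster(
                    top.with_values(np.nan_to_num(top.values, nan=0.0
                                                  ).astype(np.uint8)),
                    pri_dir / f"top{int(round(frac * 100))}_{scen}{masked}.tif",
                )
                key = f"top{int(round(frac * 100))}{masked}"
                coverage[scen][key] = coverage_stats(top, world["reserve_mask"])
    _write_json(coverage, pri_dir / "coverage.json")

    _finalize(manifest, out)
    return manifest


def _finalize(manifest: dict, out: Path) -> None:
    checksums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = _sha256(p)
    manifest["checksums"] = checksums
    _write_json(manifest, out / "manifest.json")
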