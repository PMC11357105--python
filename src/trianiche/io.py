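"""File readers/writers, pipeline configuration, and the orchestrator.

All tabular formats are comma-separated UTF-8 text with a mandatory
header row; trees are newick (a topology set is one newick per line);
rasters are ESRI ASCII grids; hull polygons export to GeoJSON. Every
table the pipeline writes is re-readable by the readers here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import niche, rangesize
from .errors import SchemaError, TrianicheError
from .inference import run_hypothesis_test
from .niche import (
    DBR_COLUMNS,
    HABITAT_COLUMNS,
    RANKS,
    HostTaxonomy,
    RasterGrid,
    validate_trait_table,
)
from .phylo import RootedTree, TopologySet, parse_newick
from .signal import signal_table

logger = logging.getLogger("trianiche.io")


# ---------------------------------------------------------------------------
# readers / writers

def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("species", "lon", "lat"):
        if col not in df.columns:
            raise SchemaError(f"occurrence file missing column {col!r}")
    return df


def read_tree(path) -> RootedTree:
    return parse_newick(Path(path).read_text())


def read_topologies(path) -> TopologySet:
    return TopologySet.from_newick_lines(Path(path).read_text())


def read_bloodmeals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return niche.validate_bloodmeals(df)


def read_taxonomy(path) -> HostTaxonomy:
    return HostTaxonomy(pd.read_csv(path))


def read_habitats(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"species", *HABITAT_COLUMNS}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"habitat file missing columns: {sorted(missing)}")
    for c in HABITAT_COLUMNS:
        df[c] = df[c].astype(bool)
    return df


def load_species_table(path) -> pd.DataFrame:
    """Read and validate a precomputed species trait table.

    This is the direct entry point for running the signal and inference
    stages on an already-assembled table (area, TNB, PNB, DBR at five
    ranks, habitat flags), bypassing the geometry/climate stages.
    """
    df = pd.read_csv(path)
    return validate_trait_table(df)


def write_species_table(df: pd.DataFrame, path) -> None:
    validate_trait_table(df).to_csv(path, index=False)


def read_ascii_grid(path) -> RasterGrid:
    """ESRI ASCII grid: 6 header lines then rows north-to-south."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][:1].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        values = np.loadtxt(fh, dtype=float)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise SchemaError(f"ASCII grid header missing {key}")
    if "xllcorner" not in header or "yllcorner" not in header:
        raise SchemaError("ASCII grid must use xllcorner/yllcorner referencing")
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise SchemaError(
            f"ASCII grid data shape {values.shape} does not match header"
        )
    return RasterGrid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, grid.values, fmt="%.6f")


def hulls_to_geojson(hulls: dict[str, rangesize.HullResult]) -> str:
    """GeoJSON FeatureCollection of per-species hull polygons."""
    import shapely.geometry

    features = []
    for sp, res in sorted(hulls.items()):
        if res.polygons.is_empty:
            continue
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "species": sp,
                    "alpha": res.alpha,
                    "area_km2": res.area_km2,
                    "n_parts": res.n_parts,
                    "fraction_contained": res.fraction_contained,
                },
                "geometry": shapely.geometry.mapping(res.polygons),
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": features}, indent=1)


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration

@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    trees: str  # newick file; one tree per line (first may be the MCC tree)
    occurrences: str
    raster_bio5: str
    raster_bio6: str
    raster_bio16: str
    raster_bio17: str
    bloodmeals: str
    taxonomy: str
    habitats: str
    outdir: str
    seed: int
    region: tuple[float, float, float, float] = niche.AMERICAS_BBOX
    initial_alpha: float = rangesize.DEFAULT_INITIAL_ALPHA
    increment: float = rangesize.DEFAULT_INCREMENT
    fraction: float = rangesize.DEFAULT_FRACTION
    max_parts: int = rangesize.DEFAULT_MAX_PARTS
    diet_ranks: tuple[str, ...] = RANKS
    n_sims: int = 1000
    export_geojson: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        if isinstance(cfg.region, list):
            cfg.region = tuple(cfg.region)
        if isinstance(cfg.diet_ranks, list):
            cfg.diet_ranks = tuple(cfg.diet_ranks)
        return cfg

    def validate(self) -> None:
        for name in (
            "trees", "occurrences", "raster_bio5", "raster_bio6",
            "raster_bio16", "raster_bio17", "bloodmeals", "taxonomy", "habitats",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise SchemaError(f"config path {name} does not exist: {p}")
        if self.n_sims < 1:
            raise SchemaError("n_sims must be >= 1")
        for r in self.diet_ranks:
            if r not in RANKS:
                raise SchemaError(f"unknown diet rank {r!r}")


class StageError(TrianicheError):
    """A pipeline stage failed; ``stage`` and ``code`` identify it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.code = getattr(cause, "code", "error")
        super().__init__(f"stage {stage!r} failed [{self.code}]: {cause}")


def run_pipeline(config: PipelineConfig) -> dict:
    """clean → range size → climate → diet → traits → signal → regression.

    Writes every intermediate table under ``config.outdir`` plus a
    ``manifest.json`` with parameters, seed, and per-stage record
    counts. Any stage failure raises :class:`StageError` naming the
    stage; partial outputs written so far are retained.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "trianiche",
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, (list, dict))
        },
        "stages": {},
    }
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                _write_manifest(out, manifest)
                raise StageError(name, exc) from exc
        return deco

    @stage("load")
    def _load():
        results["topologies"] = read_topologies(config.trees)
        results["raw_occurrences"] = read_occurrences(config.occurrences)
        results["rasters"] = {
            v: read_ascii_grid(getattr(config, f"raster_{v}"))
            for v in niche.CLIMATE_VARS
        }
        results["bloodmeals"] = read_bloodmeals(config.bloodmeals)
        results["taxonomy"] = read_taxonomy(config.taxonomy)
        results["habitats"] = read_habitats(config.habitats)
        manifest["stages"]["load"] = {
            "n_occurrence_records": len(results["raw_occurrences"]),
            "n_topologies": len(results["topologies"]),
        }

    @stage("clean")
    def _clean():
        points, report = niche.clean_occurrences(
            results["raw_occurrences"], region=config.region
        )
        results["points"] = points
        report.to_csv(out / "cleaning_report.csv", index=False)
        manifest["stages"]["clean"] = {
            "n_species": len(points),
            "n_retained": int(report["retained"].sum()),
            "n_dropped": int(
                (report["missing"] + report["duplicate"] + report["out_of_region"]).sum()
            ),
        }

    @stage("rangesize")
    def _range():
        table, hulls = rangesize.range_size_table(
            results["points"],
            initial_alpha=config.initial_alpha,
            increment=config.increment,
            fraction=config.fraction,
            max_parts=config.max_parts,
        )
        results["range_table"] = table
        table.to_csv(out / "range_sizes.csv", index=False)
        if config.export_geojson:
            (out / "hulls.geojson").write_text(hulls_to_geojson(hulls))
        manifest["stages"]["rangesize"] = {"n_species": len(table)}

    @stage("climate")
    def _climate():
        rows = []
        for sp, pts in sorted(results["points"].items()):
            sample, rep = niche.extract_climate(pts, results["rasters"])
            if len(sample) == 0:
                logger.warning("species %s: no climate values; excluded", sp)
                continue
            tnb, pnb = niche.climatic_niche_breadth(sample)
            rows.append({"species": sp, "tnb": tnb, "pnb": pnb,
                         "n_cells_used": rep["n_retained"]})
        results["climate_table"] = pd.DataFrame(rows)
        results["climate_table"].to_csv(out / "climate_breadths.csv", index=False)
        manifest["stages"]["climate"] = {"n_species": len(rows)}

    @stage("diet")
    def _diet():
        diet = niche.diet_breadth_table(results["bloodmeals"], results["taxonomy"])
        profile = niche.feeding_profile(
            results["bloodmeals"], results["taxonomy"], rank="family"
        )
        results["diet_table"] = diet
        diet.to_csv(out / "diet_breadths.csv", index=False)
        profile.to_csv(out / "feeding_profiles.csv", index=False)
        manifest["stages"]["diet"] = {"n_species": len(diet)}

    @stage("traits")
    def _traits():
        traits = niche.assemble_trait_table(
            results["range_table"],
            results["climate_table"],
            results["diet_table"],
            results["habitats"],
        )
        tips = set(results["topologies"].tip_labels)
        off_tree = sorted(set(traits["species"]) - tips)
        if off_tree:
            logger.warning("species not on the tree excluded: %s", off_tree)
            traits = traits[traits["species"].isin(tips)].reset_index(drop=True)
        results["traits"] = traits
        write_species_table(traits, out / "species_traits.csv")
        manifest["stages"]["traits"] = {"n_species": len(traits)}

    @stage("signal")
    def _signal():
        traits = results["traits"].set_index("species")
        sig_traits = pd.DataFrame(
            {
                "ln_area": np.log(traits["area_km2"]),
                "sqrt_tnb": np.sqrt(traits["tnb"]),
                "sqrt_pnb": np.sqrt(traits["pnb"]),
                **{f"ln_{c}": np.log(traits[c]) for c in DBR_COLUMNS},
            }
        )
        table = signal_table(
            results["topologies"], sig_traits, n_sims=config.n_sims, seed=config.seed
        )
        results["signal"] = table
        table.to_csv(out / "signal_table.csv", index=False)
        manifest["stages"]["signal"] = {"n_rows": len(table)}

    @stage("inference")
    def _infer():
        res = run_hypothesis_test(
            results["traits"], results["topologies"], diet_ranks=config.diet_ranks
        )
        results["hypothesis"] = res
        res.ols.to_csv(out / "ols_fits.csv", index=False)
        res.pgls_ensemble.to_csv(out / "pgls_ensemble.csv", index=False)
        res.collinearity.to_csv(out / "collinearity.csv", index=False)
        manifest["stages"]["inference"] = {
            "n_ols_rows": len(res.ols),
            "n_pgls_rows": len(res.pgls_ensemble),
            "skipped_strata": res.skipped_strata,
        }

    _write_manifest(out, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def write_simulation_bundle(outdir, seed: int, n_species: int = 30,
                            n_topologies: int = 10, **landscape_kwargs) -> dict:
    """Write a complete synthetic input bundle consumable by the pipeline.

    Produces newick topologies, an occurrence table, the four bioclim
    ASCII grids, blood-meal + taxonomy tables, a habitat table, and a
    ground-truth JSON. Returns the path map.
    """
    from . import simulate as sim

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    species = [f"sp{i:03d}" for i in range(1, n_species + 1)]

    topo = sim.simulate_topology_set(n_topologies, n_species, seed=seed)
    (out / "topologies.nwk").write_text(topo.to_newick_lines())

    cfg = sim.SimulationConfig(seed=seed, n_species=n_species, species=species,
                               **landscape_kwargs)
    raw, rasters, truth = sim.simulate_occurrence_landscape(cfg)
    raw.to_csv(out / "occurrences.csv", index=False)
    for v, grid in rasters.items():
        write_ascii_grid(grid, out / f"{v}.asc")

    tax = sim.default_host_taxonomy()
    tax.table.reset_index().to_csv(out / "taxonomy.csv", index=False)
    meals, dbr_truth = sim.simulate_bloodmeal_dataset(species, seed=seed, tax=tax)
    meals.to_csv(out / "bloodmeals.csv", index=False)

    hab_rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    patterns = list(sim.HABITAT_COMPOSITION)
    probs = np.array(list(sim.HABITAT_COMPOSITION.values()))
    picks = hab_rng.choice(len(patterns), size=n_species, p=probs / probs.sum())
    habitats = pd.DataFrame({"species": species})
    for j, col in enumerate(HABITAT_COLUMNS):
        habitats[col] = [patterns[k][j] for k in picks]
    habitats.to_csv(out / "habitats.csv", index=False)

    (out / "ground_truth.json").write_text(
        json.dumps({"landscape": truth, "dbr": dbr_truth.to_dict("records")}, indent=1)
    )
    return {
        "trees": str(out / "topologies.nwk"),
        "occurrences": str(out / "occurrences.csv"),
        **{f"raster_{v}": str(out / f"{v}.asc") for v in niche.CLIMATE_VARS},
        "bloodmeals": str(out / "bloodmeals.csv"),
        "taxonomy": str(out / "taxonomy.csv"),
        "habitats": str(out / "habitats.csv"),
    }
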