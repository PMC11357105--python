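"""Occurrence cleaning, climate extraction, and niche-breadth measures.

Climatic niche breadth follows the extreme-conditions definition used in
macroecology: over all of a species' occurrence cells,

* TNB (°C) = max(bio5) − min(bio6) — warmest-month maximum minus
  coldest-month minimum temperature, the annual thermal envelope;
* PNB (mm) = max(bio16) − min(bio17) — wettest-quarter maximum minus
  driest-quarter minimum precipitation.

Diet breadth (DBR) is the number of distinct host taxa a species feeds
on, evaluated at five nested ranks (class, order, family, genus,
species). Blood-meal tables record per-individual host detections;
individuals with mixed meals are allocated across their component host
categories proportionally to the pure-meal counts of those categories
when feeding profiles are summarized.

Raster lookup is containing-cell (no interpolation), with half-open cell
membership [west, east) × (south, north] so a point on a shared edge
belongs to exactly one cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import EmptySampleError, SchemaError

logger = logging.getLogger("trianiche.niche")

#: Host taxonomy ranks, coarse to fine.
RANKS = ("class", "order", "family", "genus", "species")

#: Americas bounding box (lon_min, lon_max, lat_min, lat_max), degrees.
AMERICAS_BBOX = (-170.0, -25.0, -60.0, 75.0)

#: Bioclim layers used for climatic niche breadth.
CLIMATE_VARS = ("bio5", "bio6", "bio16", "bio17")

#: DBR column names in the species trait table.
DBR_COLUMNS = tuple(f"dbr_{r}" for r in RANKS)
HABITAT_COLUMNS = ("domiciliary", "peridomiciliary", "sylvatic")


# ---------------------------------------------------------------------------
# rasters

@dataclass
class RasterGrid:
    """A regular lon/lat grid (ESRI ASCII layout: row 0 is the north edge)."""

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray  # (nrows, ncols), row 0 = northernmost
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
            and self.values.shape == other.values.shape
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lons = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.yll + (np.arange(self.nrows) + 0.5) * self.cellsize
        return lons, lats[::-1]  # matching row order (north first)

    def lookup(self, lons, lats) -> np.ndarray:
        """Containing-cell values; NaN for points outside the extent or nodata.

        Cell membership is [west, east) × (south, north]: a point exactly
        on a shared vertical edge belongs to the cell to its east, one on
        a shared horizontal edge to the cell below (south) it.
        """
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        col = np.floor((lons - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.ceil((lats - self.yll) / self.cellsize).astype(int) - 1
        row = self.nrows - 1 - row_from_bottom
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out = np.full(lons.shape, np.nan)
        vals = self.values[row[ok], col[ok]]
        vals = np.where(np.isclose(vals, self.nodata), np.nan, vals)
        out[ok] = vals
        return out


# ---------------------------------------------------------------------------
# occurrence cleaning

def _region_mask(lon: np.ndarray, lat: np.ndarray, region) -> np.ndarray:
    if region is None:
        region = AMERICAS_BBOX
    if isinstance(region, (tuple, list)) and len(region) == 4:
        lo, hi, s, n = region
        return (lon >= lo) & (lon <= hi) & (lat >= s) & (lat <= n)
    if isinstance(region, Polygon):
        return shapely.covers(region, shapely.points(np.column_stack([lon, lat])))
    raise ValueError("region must be a (lon_min, lon_max, lat_min, lat_max) box or Polygon")


def clean_occurrences(
    raw: pd.DataFrame, region=None
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Drop unusable occurrence records and report why, per species.

    Dropped, in order: records with missing/unparseable coordinates,
    exact duplicates of (species, lon, lat), records outside ``region``
    (default: an Americas bounding box). Returns the per-species point
    arrays and a report with columns species, n_input, missing,
    duplicate, out_of_region, retained. A species losing all its records
    is flagged in the report, not fatal. Idempotent.
    """
    for col in ("species", "lon", "lat"):
        if col not in raw.columns:
            raise SchemaError(f"occurrence table missing required column {col!r}")
    df = raw.loc[:, ["species", "lon", "lat"]].copy()
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")

    missing = df["lon"].isna() | df["lat"].isna() | df["species"].isna()
    df1 = df[~missing]
    dup = df1.duplicated(subset=["species", "lon", "lat"], keep="first")
    df2 = df1[~dup]
    inside = _region_mask(df2["lon"].to_numpy(), df2["lat"].to_numpy(), region)
    df3 = df2[inside]

    def per_species(frame, mask=None):
        s = frame.loc[mask if mask is not None else slice(None), "species"]
        return s.value_counts()

    species_all = sorted(df["species"].dropna().unique())
    report = pd.DataFrame(
        {
            "species": species_all,
            "n_input": per_species(df).reindex(species_all).fillna(0).astype(int).values,
            "missing": per_species(df, missing).reindex(species_all).fillna(0).astype(int).values,
            "duplicate": per_species(df1, dup).reindex(species_all).fillna(0).astype(int).values,
            "out_of_region": per_species(df2, ~inside).reindex(species_all).fillna(0).astype(int).values,
            "retained": per_species(df3).reindex(species_all).fillna(0).astype(int).values,
        }
    )
    for _, row in report[report["retained"] == 0].iterrows():
        logger.warning("species %s has no usable occurrences after cleaning", row["species"])
    points = {
        sp: grp[["lon", "lat"]].to_numpy()
        for sp, grp in df3.groupby("species", sort=True)
    }
    return points, report


# ---------------------------------------------------------------------------
# climate extraction and breadth

def extract_climate(
    points, rasters: Mapping[str, RasterGrid]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cell values of the four bioclim layers at each occurrence.

    Points outside the raster extent or hitting nodata in any layer are
    dropped and counted in the report. Layers must share one grid.
    Violations of the cellwise invariants bio5 >= bio6 and bio16 >= bio17
    are data errors (corrupt rasters) and raise :class:`SchemaError`.
    """
    missing = [v for v in CLIMATE_VARS if v not in rasters]
    if missing:
        raise SchemaError(f"missing climate layers: {missing}")
    ref = rasters[CLIMATE_VARS[0]]
    for v in CLIMATE_VARS[1:]:
        if not ref.same_grid(rasters[v]):
            raise SchemaError(f"raster {v} is not aligned with {CLIMATE_VARS[0]}")
    pts = np.asarray(points, dtype=float)
    sample = pd.DataFrame(
        {v: rasters[v].lookup(pts[:, 0], pts[:, 1]) for v in CLIMATE_VARS}
    )
    bad = sample.isna().any(axis=1)
    kept = sample[~bad].reset_index(drop=True)
    if len(kept):
        if (kept["bio5"] < kept["bio6"]).any() or (kept["bio16"] < kept["bio17"]).any():
            raise SchemaError(
                "raster data violate bio5 >= bio6 / bio16 >= bio17 cellwise"
            )
    report = {
        "n_input": int(len(pts)),
        "n_dropped_nodata_or_outside": int(bad.sum()),
        "n_retained": int(len(kept)),
    }
    return kept, report


def climatic_niche_breadth(sample: pd.DataFrame) -> tuple[float, float]:
    """(TNB °C, PNB mm) = (max bio5 − min bio6, max bio16 − min bio17)."""
    if sample is None or len(sample) == 0:
        raise EmptySampleError("no climate values to compute niche breadth from")
    tnb = float(sample["bio5"].max() - sample["bio6"].min())
    pnb = float(sample["bio16"].max() - sample["bio17"].min())
    return tnb, pnb


# ---------------------------------------------------------------------------
# host taxonomy and blood meals

class HostTaxonomy:
    """Host taxon → (class, order, family, genus, species) lookup.

    Rows are keyed by the host identifier used in blood-meal tables;
    finer ranks may be unresolved (empty/NaN). Nesting is validated:
    two hosts sharing a value at a fine rank must agree at every coarser
    rank.
    """

    def __init__(self, table: pd.DataFrame):
        need = {"host", *RANKS}
        missing = need - set(table.columns)
        if missing:
            raise SchemaError(f"taxonomy table missing columns: {sorted(missing)}")
        t = table.set_index("host")[list(RANKS)].copy()
        for c in RANKS:
            t[c] = t[c].replace("", np.nan)
        if t.index.has_duplicates:
            raise SchemaError("duplicate host entries in taxonomy")
        # nesting: same value at a fine rank implies same value at coarser ranks
        for fine_i in range(len(RANKS) - 1, 0, -1):
            fine = RANKS[fine_i]
            sub = t.dropna(subset=[fine])
            for coarse in RANKS[:fine_i]:
                bad = sub.groupby(fine)[coarse].nunique(dropna=True)
                if (bad > 1).any():
                    raise SchemaError(
                        f"inconsistent nesting: {fine} values map to multiple {coarse} values"
                    )
        self.table = t

    def rank_of(self, host: str, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        if host not in self.table.index:
            raise KeyError(f"host {host!r} not in taxonomy")
        val = self.table.at[host, rank]
        return None if pd.isna(val) else str(val)

    def hosts(self) -> list[str]:
        return list(self.table.index)


def validate_bloodmeals(meals: pd.DataFrame, tax: HostTaxonomy | None = None) -> pd.DataFrame:
    """Normalize a blood-meal table to columns (species, hosts: tuple, count)."""
    need = {"species", "hosts", "count"}
    missing = need - set(meals.columns)
    if missing:
        raise SchemaError(f"blood-meal table missing columns: {sorted(missing)}")
    df = meals.copy()

    def to_tuple(h):
        if isinstance(h, (tuple, list, set, frozenset)):
            parts = [str(p) for p in h]
        else:
            parts = [p.strip() for p in str(h).split(";")]
        parts = [p for p in parts if p]
        return tuple(sorted(set(parts)))

    df["hosts"] = df["hosts"].map(to_tuple)
    df["count"] = pd.to_numeric(df["count"], errors="raise").astype(int)
    if (df["count"] < 1).any():
        raise SchemaError("blood-meal counts must be >= 1")
    if df["hosts"].map(len).eq(0).any():
        raise SchemaError("blood-meal host sets must be non-empty")
    if tax is not None:
        known = set(tax.hosts())
        unknown = sorted({h for hs in df["hosts"] for h in hs} - known)
        if unknown:
            raise SchemaError(f"hosts absent from taxonomy: {unknown}")
    return df


def diet_breadth(
    meals: pd.DataFrame,
    tax: HostTaxonomy,
    level: str,
    species: str,
    include_unresolved: bool = False,
) -> int:
    """Distinct host taxa at ``level`` for one triatomine species.

    Hosts resolved below the rank collapse to their ancestor at the
    rank; hosts unresolved at the rank are excluded from the count (and
    logged) unless ``include_unresolved`` is set, in which case each
    distinct unresolved host identifier counts as one unit.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    df = validate_bloodmeals(meals, tax)
    sub = df[df["species"] == species]
    if len(sub) == 0:
        raise EmptySampleError(f"no blood-meal records for species {species!r}")
    hosts = {h for hs in sub["hosts"] for h in hs}
    taxa, unresolved = set(), set()
    for h in hosts:
        val = tax.rank_of(h, level)
        if val is None:
            unresolved.add(h)
        else:
            taxa.add(val)
    if unresolved:
        logger.info(
            "%s: %d host(s) unresolved at rank %s excluded from DBR: %s",
            species, len(unresolved), level, sorted(unresolved),
        )
        if include_unresolved:
            taxa |= unresolved
    return len(taxa)


def diet_breadth_table(
    meals: pd.DataFrame, tax: HostTaxonomy, include_unresolved: bool = False
) -> pd.DataFrame:
    """DBR at all five ranks for every species in the blood-meal table."""
    df = validate_bloodmeals(meals, tax)
    rows = []
    for sp in sorted(df["species"].unique()):
        row = {"species": sp}
        for rank in RANKS:
            row[f"dbr_{rank}"] = diet_breadth(
                df, tax, rank, sp, include_unresolved=include_unresolved
            )
        rows.append(row)
    return pd.DataFrame(rows)


def feeding_profile(
    meals: pd.DataFrame,
    tax: HostTaxonomy | None = None,
    rank: str | None = None,
) -> pd.DataFrame:
    """Host-category proportions per species with mixed-meal allocation.

    Pure-meal individuals count fully toward their category. Each
    mixed-meal individual's count is split across its component
    categories proportionally to those categories' pure-meal counts; if
    none of the components has pure meals the split is equal. With
    ``rank`` given, hosts are first collapsed to that taxonomic rank
    (hosts unresolved there keep their own identifier). Proportions sum
    to 1 per species and allocated totals conserve the individual count.
    """
    df = validate_bloodmeals(meals, tax)
    if rank is not None:
        if tax is None:
            raise ValueError("rank mapping requires a taxonomy")
        df = df.copy()
        df["hosts"] = df["hosts"].map(
            lambda hs: tuple(sorted({tax.rank_of(h, rank) or h for h in hs}))
        )
    out = []
    for sp, grp in df.groupby("species", sort=True):
        pure: dict[str, float] = {}
        for _, r in grp.iterrows():
            if len(r["hosts"]) == 1:
                pure[r["hosts"][0]] = pure.get(r["hosts"][0], 0.0) + r["count"]
        totals = dict(pure)
        for _, r in grp.iterrows():
            hs = r["hosts"]
            if len(hs) == 1:
                continue
            weights = np.array([pure.get(h, 0.0) for h in hs])
            if weights.sum() == 0:
                weights = np.ones(len(hs))
            weights = weights / weights.sum()
            for h, w in zip(hs, weights):
                totals[h] = totals.get(h, 0.0) + r["count"] * w
        grand = float(sum(totals.values()))
        for h, v in sorted(totals.items()):
            out.append(
                {"species": sp, "category": h, "count": v, "proportion": v / grand}
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# species trait table

def assemble_trait_table(
    range_table: pd.DataFrame,
    climate_breadths: pd.DataFrame,
    diet_table: pd.DataFrame,
    habitats: pd.DataFrame,
) -> pd.DataFrame:
    """Merge the per-stage outputs into the central species trait table.

    Inputs are keyed by ``species``: range sizes (area_km2), climatic
    breadths (tnb, pnb), DBR at five ranks, and habitat flags. The merge
    is inner — only species present in all four inputs are analyzed —
    with exclusions logged.
    """
    for name, df, cols in (
        ("range", range_table, {"species", "area_km2"}),
        ("climate", climate_breadths, {"species", "tnb", "pnb"}),
        ("diet", diet_table, {"species", *DBR_COLUMNS}),
        ("habitat", habitats, {"species", *HABITAT_COLUMNS}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise SchemaError(f"{name} table missing columns: {sorted(missing)}")
    merged = (
        range_table[["species", "area_km2"]]
        .merge(climate_breadths[["species", "tnb", "pnb"]], on="species")
        .merge(diet_table[["species", *DBR_COLUMNS]], on="species")
        .merge(habitats[["species", *HABITAT_COLUMNS]], on="species")
    )
    all_sp = (
        set(range_table["species"]) | set(climate_breadths["species"])
        | set(diet_table["species"]) | set(habitats["species"])
    )
    lost = sorted(all_sp - set(merged["species"]))
    if lost:
        logger.warning("species excluded from trait table (incomplete data): %s", lost)
    return validate_trait_table(merged)


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce species-trait-table invariants; returns the validated frame."""
    need = {"species", "area_km2", "tnb", "pnb", *DBR_COLUMNS, *HABITAT_COLUMNS}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"species table missing columns: {sorted(missing)}")
    if df["species"].duplicated().any():
        raise SchemaError("duplicate species rows")
    if (df["area_km2"] <= 0).any():
        raise SchemaError("area_km2 must be > 0 for analyzed species")
    if (df["tnb"] < 0).any() or (df["pnb"] < 0).any():
        raise SchemaError("TNB and PNB must be >= 0")
    for c in DBR_COLUMNS:
        if (df[c] < 1).any():
            raise SchemaError(f"{c} must be >= 1 for species with blood-meal data")
    flags = df[list(HABITAT_COLUMNS)].astype(bool)
    if (~flags.any(axis=1)).any():
        raise SchemaError("every species needs at least one habitat flag set")
    out = df.copy()
    out[list(HABITAT_COLUMNS)] = flags
    return out.reset_index(drop=True)
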