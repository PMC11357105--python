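"""Occurrence cleaning, raster lookup, niche breadths, diet, feeding profiles."""

import numpy as np
import pandas as pd
import pytest

from trianiche.errors import EmptySampleError, SchemaError
from trianiche.niche import (
    RANKS,
    HostTaxonomy,
    RasterGrid,
    clean_occurrences,
    climatic_niche_breadth,
    diet_breadth,
    diet_breadth_table,
    extract_climate,
    feeding_profile,
    validate_bloodmeals,
    validate_trait_table,
)
from trianiche.simulate import default_host_taxonomy


# ---------------------------------------------------------------------------
# cleaning

def _occ(rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


def test_clean_drops_missing_coordinates():
    raw = _occ(
        [("a", -60, -10), ("a", -61, -11), ("a", None, -12), ("a", -63, -13), ("a", -64, -14)]
    )
    points, report = clean_occurrences(raw)
    assert len(points["a"]) == 4
    assert report.loc[0, "missing"] == 1


def test_clean_drops_exact_duplicates():
    raw = _occ([("a", -60.0, -10.0), ("a", -60.0, -10.0)])
    points, report = clean_occurrences(raw)
    assert len(points["a"]) == 1
    assert report.loc[0, "duplicate"] == 1


def test_clean_drops_out_of_region():
    raw = _occ([("a", 120.0, 10.0), ("a", -60.0, -10.0)])
    points, report = clean_occurrences(raw)
    assert len(points["a"]) == 1
    assert report.loc[0, "out_of_region"] == 1


def test_clean_is_idempotent():
    raw = _occ(
        [("a", -60, -10), ("a", -60, -10), ("b", 130, 5), ("b", -70, 3), ("b", np.nan, 1)]
    )
    points, _ = clean_occurrences(raw)
    again = pd.concat(
        [pd.DataFrame({"species": sp, "lon": p[:, 0], "lat": p[:, 1]})
         for sp, p in points.items()]
    )
    points2, report2 = clean_occurrences(again)
    assert {sp: pts.tolist() for sp, pts in points2.items()} == {
        sp: pts.tolist() for sp, pts in points.items()
    }
    assert (report2[["missing", "duplicate", "out_of_region"]] == 0).all().all()


def test_clean_missing_column_raises():
    with pytest.raises(SchemaError, match="lon"):
        clean_occurrences(pd.DataFrame({"species": ["a"], "lat": [1.0]}))


# ---------------------------------------------------------------------------
# rasters

@pytest.fixture
def grid():
    # 4x4 one-degree grid over lon [0,4), lat (0,4]; value = 10*row_from_north + col
    vals = np.arange(16, dtype=float).reshape(4, 4)
    return RasterGrid(xll=0.0, yll=0.0, cellsize=1.0, values=vals)


def test_lookup_cell_center(grid):
    # center of the NW cell (row 0, col 0)
    assert grid.lookup([0.5], [3.5])[0] == 0.0
    # center of the SE cell (row 3, col 3)
    assert grid.lookup([3.5], [0.5])[0] == 15.0


def test_lookup_edge_belongs_to_exactly_one_cell(grid):
    # vertical shared edge lon=1: belongs to the cell to the east (col 1)
    assert grid.lookup([1.0], [3.5])[0] == 1.0
    # horizontal shared edge lat=3: (south, north] puts it in the lower cell
    assert grid.lookup([0.5], [3.0])[0] == 4.0


def test_lookup_outside_is_nan(grid):
    out = grid.lookup([-0.5, 4.5, 0.5], [0.5, 0.5, 0.0])
    assert np.isnan(out[0]) and np.isnan(out[1]) and np.isnan(out[2])


def _aligned_rasters(bio5_vals):
    mk = lambda v: RasterGrid(xll=0.0, yll=0.0, cellsize=1.0, values=v)
    bio5 = np.asarray(bio5_vals, dtype=float)
    return {
        "bio5": mk(bio5),
        "bio6": mk(bio5 - 10.0),
        "bio16": mk(np.full_like(bio5, 900.0)),
        "bio17": mk(np.full_like(bio5, 100.0)),
    }


def test_extract_gradient_matches_generator_formula():
    # bio5(lat) = 40 - 0.3*lat evaluated at cell centers
    lat_centers = np.array([3.5, 2.5, 1.5, 0.5])
    vals = np.tile((40.0 - 0.3 * lat_centers)[:, None], (1, 4))
    rasters = _aligned_rasters(vals)
    pts = np.array([[0.5, 0.5], [1.5, 2.5], [3.5, 3.5]])
    sample, rep = extract_climate(pts, rasters)
    np.testing.assert_allclose(
        sample["bio5"], 40.0 - 0.3 * np.array([0.5, 2.5, 3.5])
    )
    assert rep["n_dropped_nodata_or_outside"] == 0


def test_extract_drops_nodata_and_outside():
    vals = np.full((4, 4), 20.0)
    vals[0, 0] = -9999.0
    rasters = _aligned_rasters(vals)
    rasters["bio5"].values[0, 0] = -9999.0
    pts = np.array([[0.5, 3.5], [10.0, 10.0], [2.5, 2.5]])
    sample, rep = extract_climate(pts, rasters)
    assert rep["n_dropped_nodata_or_outside"] == 2
    assert len(sample) == 1


def test_extract_misaligned_rasters_rejected():
    rasters = _aligned_rasters(np.full((4, 4), 20.0))
    rasters["bio17"] = RasterGrid(xll=0.5, yll=0.0, cellsize=1.0,
                                  values=np.full((4, 4), 1.0))
    with pytest.raises(SchemaError, match="aligned"):
        extract_climate(np.array([[0.5, 0.5]]), rasters)


def test_extract_flags_cellwise_invariant_violation():
    rasters = _aligned_rasters(np.full((4, 4), 20.0))
    rasters["bio6"].values[:] = 30.0  # bio6 > bio5: corrupt
    with pytest.raises(SchemaError, match="bio5"):
        extract_climate(np.array([[0.5, 0.5]]), rasters)


# ---------------------------------------------------------------------------
# climatic niche breadth

def test_tnb_pnb_arithmetic():
    sample = pd.DataFrame(
        {"bio5": [30.2, 28.1], "bio6": [4.5, -2.0], "bio16": [900.0, 500.0],
         "bio17": [100.0, 250.0]}
    )
    tnb, pnb = climatic_niche_breadth(sample)
    assert tnb == pytest.approx(32.2)
    assert pnb == pytest.approx(800.0)


def test_single_occurrence_breadth():
    sample = pd.DataFrame({"bio5": [30.0], "bio6": [5.0], "bio16": [900.0],
                           "bio17": [100.0]})
    tnb, pnb = climatic_niche_breadth(sample)
    assert tnb == 25.0 and pnb == 800.0


def test_breadth_invariant_to_order_and_duplication(rng):
    base = pd.DataFrame(
        {"bio5": rng.uniform(25, 40, 10), "bio6": rng.uniform(-5, 10, 10),
         "bio16": rng.uniform(500, 1500, 10), "bio17": rng.uniform(10, 400, 10)}
    )
    shuffled = base.sample(frac=1, random_state=1)
    doubled = pd.concat([base, base])
    assert climatic_niche_breadth(base) == climatic_niche_breadth(shuffled)
    assert climatic_niche_breadth(base) == climatic_niche_breadth(doubled)


def test_breadth_dominates_single_cell_span(rng):
    base = pd.DataFrame(
        {"bio5": rng.uniform(25, 40, 10), "bio6": rng.uniform(-5, 10, 10),
         "bio16": rng.uniform(500, 1500, 10), "bio17": rng.uniform(10, 400, 10)}
    )
    tnb, _ = climatic_niche_breadth(base)
    assert tnb >= (base["bio5"] - base["bio6"]).max()


def test_empty_sample_raises():
    with pytest.raises(EmptySampleError):
        climatic_niche_breadth(pd.DataFrame(columns=["bio5", "bio6", "bio16", "bio17"]))


# ---------------------------------------------------------------------------
# diet breadth

@pytest.fixture
def tax():
    return default_host_taxonomy()


def _meals(rows):
    return pd.DataFrame(rows, columns=["species", "hosts", "count"])


def test_diet_breadth_rank_collapse(tax):
    meals = _meals(
        [("v", "Homo sapiens", 2), ("v", "Gallus gallus", 1), ("v", "Canis familiaris", 1)]
    )
    assert diet_breadth(meals, tax, "species", "v") == 3
    assert diet_breadth(meals, tax, "family", "v") == 3
    assert diet_breadth(meals, tax, "class", "v") == 2  # Mammalia, Aves


def test_diet_breadth_repeated_host_counts_once(tax):
    meals = _meals([("v", "Homo sapiens", 3), ("v", "Homo sapiens", 2)])
    for rank in RANKS:
        assert diet_breadth(meals, tax, rank, "v") == 1


def test_unresolved_host_excluded_at_fine_ranks(tax):
    meals = _meals([("v", "Cricetidae sp.", 2), ("v", "Homo sapiens", 1)])
    assert diet_breadth(meals, tax, "genus", "v") == 1  # only Homo
    assert diet_breadth(meals, tax, "family", "v") == 2  # Cricetidae + Hominidae
    assert diet_breadth(meals, tax, "genus", "v", include_unresolved=True) == 2


def test_diet_breadth_no_records_is_error(tax):
    meals = _meals([("v", "Homo sapiens", 1)])
    with pytest.raises(EmptySampleError):
        diet_breadth(meals, tax, "species", "absent")


def test_diet_breadth_monotone_across_ranks(tax, rng):
    hosts = [h for h in tax.hosts() if tax.rank_of(h, "species")]
    rows = [("v", ";".join(rng.choice(hosts, size=2, replace=False)), 1)
            for _ in range(10)]
    meals = _meals(rows)
    counts = [diet_breadth(meals, tax, rank, "v") for rank in RANKS]
    # RANKS is coarse→fine: counts must be non-decreasing
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_diet_breadth_table_shape(tax):
    meals = _meals([("v", "Homo sapiens", 1), ("w", "Gallus gallus;Canis familiaris", 2)])
    tbl = diet_breadth_table(meals, tax)
    assert set(tbl["species"]) == {"v", "w"}
    assert set(tbl.columns) == {"species", *(f"dbr_{r}" for r in RANKS)}


def test_bloodmeal_validation(tax):
    with pytest.raises(SchemaError):
        validate_bloodmeals(_meals([("v", "Homo sapiens", 0)]), tax)
    with pytest.raises(SchemaError):
        validate_bloodmeals(_meals([("v", "Martian", 1)]), tax)


# ---------------------------------------------------------------------------
# feeding profiles

def test_mixed_meal_allocation_hand_example(tax):
    meals = _meals(
        [("v", "Homo sapiens", 4), ("v", "Gallus gallus", 2),
         ("v", "Homo sapiens;Gallus gallus", 3)]
    )
    prof = feeding_profile(meals).set_index("category")
    # pure A=4, B=2; mixed 3 split 2:1 → totals A=6, B=3
    assert prof.loc["Homo sapiens", "count"] == pytest.approx(6.0)
    assert prof.loc["Gallus gallus", "count"] == pytest.approx(3.0)
    assert prof.loc["Homo sapiens", "proportion"] == pytest.approx(2 / 3)


def test_profile_without_mixed_is_normalized_counts(tax):
    meals = _meals([("v", "Homo sapiens", 6), ("v", "Gallus gallus", 2)])
    prof = feeding_profile(meals).set_index("category")
    assert prof.loc["Homo sapiens", "proportion"] == pytest.approx(0.75)


def test_mixed_with_no_pure_splits_equally(tax):
    meals = _meals([("v", "Homo sapiens;Gallus gallus", 2)])
    prof = feeding_profile(meals).set_index("category")
    assert prof.loc["Homo sapiens", "count"] == pytest.approx(1.0)
    assert prof.loc["Gallus gallus", "count"] == pytest.approx(1.0)


def test_profile_conserves_individuals_and_sums_to_one(tax, rng):
    hosts = tax.hosts()
    rows = []
    for _ in range(25):
        k = int(rng.integers(1, 3))
        hs = ";".join(rng.choice(hosts, size=k, replace=False))
        rows.append(("v", hs, int(rng.integers(1, 6))))
    meals = _meals(rows)
    prof = feeding_profile(meals, tax)
    total_in = validate_bloodmeals(meals)["count"].sum()
    assert prof["count"].sum() == pytest.approx(total_in, abs=1e-9)
    assert prof["proportion"].sum() == pytest.approx(1.0, abs=1e-9)


def test_profile_rank_collapse_makes_family_categories(tax):
    meals = _meals([("v", "Rattus rattus", 1), ("v", "Mus musculus", 1)])
    prof = feeding_profile(meals, tax, rank="family").set_index("category")
    assert prof.loc["Muridae", "proportion"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# taxonomy and trait-table validation

def test_taxonomy_nesting_violation_rejected():
    df = pd.DataFrame(
        [
            ("h1", "Mammalia", "Rodentia", "Muridae", "Rattus", "Rattus rattus"),
            ("h2", "Aves", "Rodentia", "Muridae", "Mus", "Mus musculus"),
        ],
        columns=["host", "class", "order", "family", "genus", "species"],
    )
    with pytest.raises(SchemaError, match="nesting"):
        HostTaxonomy(df)


def _trait_row(**kw):
    base = dict(species="a", area_km2=1e5, tnb=20.0, pnb=800.0,
                dbr_class=1, dbr_order=1, dbr_family=2, dbr_genus=2, dbr_species=3,
                domiciliary=True, peridomiciliary=False, sylvatic=False)
    base.update(kw)
    return base


def test_trait_table_validation():
    good = pd.DataFrame([_trait_row(), _trait_row(species="b")])
    validate_trait_table(good)
    with pytest.raises(SchemaError):
        validate_trait_table(pd.DataFrame([_trait_row(tnb=-1.0)]))
    with pytest.raises(SchemaError):
        validate_trait_table(pd.DataFrame([_trait_row(dbr_species=0)]))
    with pytest.raises(SchemaError):
        validate_trait_table(
            pd.DataFrame([_trait_row(domiciliary=False, peridomiciliary=False,
                                     sylvatic=False)])
        )
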