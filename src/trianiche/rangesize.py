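"""Range-size estimation: alpha shapes, dynamic alpha hulls, geodesic area.

A species' geographic range is estimated from its occurrence points as
an alpha shape — the union of Delaunay triangles whose circumradius does
not exceed α (in degrees). The "dynamic" variant starts from a small α
and grows it until the hull is contiguous enough (at most ``max_parts``
components) and covers enough of the occurrences
(``fraction_contained``), mimicking how range polygons are fitted in
macroecological practice. Areas are reported in km² on a sphere of
authalic radius 6371.0088 km via the spherical-excess (Gauss–Bonnet
turn-angle) formula, so a hull spanning many degrees of latitude is not
distorted the way a planar degree² → km² conversion would be.

Triangulation happens in raw lon/lat degrees; point sets spanning more
than 90° of longitude (or crossing the antimeridian) trigger a warning
because degree-space circumradii are then hard to interpret.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .errors import InsufficientGeometryError, InvalidGeometryError

logger = logging.getLogger("trianiche.rangesize")

#: Authalic (equal-area) Earth radius, km.
EARTH_RADIUS_KM = 6371.0088
#: Exact-duplicate tolerance when deduplicating points, degrees.
DUPLICATE_TOL = 1e-9

#: Defaults of the dynamic-alpha search (all in degrees except fraction/parts).
DEFAULT_INITIAL_ALPHA = 3.0
DEFAULT_INCREMENT = 1.0
DEFAULT_FRACTION = 0.95
DEFAULT_MAX_PARTS = 1


@dataclass(frozen=True)
class HullResult:
    """An alpha hull with the α that produced it and its geodesic area."""

    polygons: Polygon | MultiPolygon
    alpha: float
    area_km2: float
    fraction_contained: float
    n_parts: int


def _prepare_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (lon, lat)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    lon, lat = pts[:, 0], pts[:, 1]
    if lon.min() < -180 or lon.max() > 180 or lat.min() < -90 or lat.max() > 90:
        raise ValueError("coordinates outside lon [-180,180] / lat [-90,90]")
    # rounding defines the duplicate key only; original coordinates are kept
    key = np.round(pts / DUPLICATE_TOL).astype(np.int64)
    _, first = np.unique(key, axis=0, return_index=True)
    uniq = pts[np.sort(first)]
    if lon.max() - lon.min() > 90:
        logger.warning(
            "point set spans %.1f deg of longitude; degree-space alpha hulls "
            "are unreliable near/across the antimeridian",
            lon.max() - lon.min(),
        )
    return uniq


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay triangle; inf for degenerate ones."""
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def _triangulate(points) -> tuple[np.ndarray, Delaunay]:
    pts = _prepare_points(points)
    if len(pts) < 3:
        raise InsufficientGeometryError(
            f"need >= 3 unique points for a hull, got {len(pts)}"
        )
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise InsufficientGeometryError(
            "points are collinear or otherwise degenerate; no triangulation"
        ) from exc
    return pts, tri


def _assemble(pts: np.ndarray, tri: Delaunay, keep: np.ndarray, alpha: float,
              all_points: np.ndarray) -> HullResult:
    if keep.any():
        triangles = [Polygon(pts[s]) for s in tri.simplices[keep]]
        hull = unary_union(triangles)
    else:
        hull = Polygon()
    if hull.is_empty:
        n_parts, fraction = 0, 0.0
    else:
        n_parts = len(hull.geoms) if isinstance(hull, MultiPolygon) else 1
        inside = shapely.covers(hull, shapely.points(all_points))
        fraction = float(np.mean(inside))
    return HullResult(
        polygons=hull,
        alpha=float(alpha),
        area_km2=geodesic_area_km2(hull),
        fraction_contained=fraction,
        n_parts=n_parts,
    )


def alpha_shape(points, alpha: float) -> HullResult:
    """Alpha shape at a fixed α: union of triangles with circumradius <= α.

    ``fraction_contained`` counts all *input* points (before
    deduplication) inside or on the hull. An α too small for any
    triangle yields an empty hull with zero area.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    all_pts = np.asarray(points, dtype=float)
    pts, tri = _triangulate(points)
    keep = _circumradii(pts, tri.simplices) <= alpha
    return _assemble(pts, tri, keep, alpha, all_pts)


def dynamic_alpha_hull(
    points,
    initial_alpha: float = DEFAULT_INITIAL_ALPHA,
    increment: float = DEFAULT_INCREMENT,
    fraction: float = DEFAULT_FRACTION,
    max_parts: int = DEFAULT_MAX_PARTS,
) -> HullResult:
    """Grow α from ``initial_alpha`` until the hull is acceptable.

    Accepts the first hull with at most ``max_parts`` connected
    components and at least ``fraction`` of the occurrences contained.
    Termination is guaranteed: once α exceeds the largest finite
    circumradius the hull is the convex hull, which has one part and
    contains every point.
    """
    if initial_alpha <= 0 or increment <= 0:
        raise ValueError("initial_alpha and increment must be > 0")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if max_parts < 1:
        raise ValueError("max_parts must be >= 1")
    all_pts = np.asarray(points, dtype=float)
    pts, tri = _triangulate(points)
    radii = _circumradii(pts, tri.simplices)
    finite = radii[np.isfinite(radii)]
    alpha_ceiling = float(finite.max()) if finite.size else initial_alpha

    alpha = float(initial_alpha)
    while True:
        keep = radii <= alpha
        result = _assemble(pts, tri, keep, alpha, all_pts)
        ok = (
            result.n_parts >= 1
            and result.n_parts <= max_parts
            and result.fraction_contained >= fraction
        )
        if ok or alpha > alpha_ceiling:
            return result
        alpha += increment


def _ring_area_steradians(coords: np.ndarray) -> float:
    """Unsigned spherical area of a geodesic-edged ring, in steradians.

    Gauss–Bonnet with geodesic edges: the area left of a traversal is
    2π minus the sum of signed turn angles. The smaller of the two
    complementary areas is returned, making the result independent of
    vertex order; rings enclosing more than a hemisphere are therefore
    out of scope (species ranges are far smaller).
    """
    c = np.asarray(coords, dtype=float)
    if len(c) and np.allclose(c[0], c[-1]):
        c = c[:-1]
    # drop consecutive duplicates
    if len(c) > 1:
        keep = np.r_[True, np.any(np.abs(np.diff(c, axis=0)) > 1e-15, axis=1)]
        c = c[keep]
    if len(c) < 3:
        return 0.0
    lon = np.radians(c[:, 0])
    lat = np.radians(c[:, 1])
    v = np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )
    n = len(v)
    turn_sum = 0.0
    for i in range(n):
        h, j = v[(i - 1) % n], v[(i + 1) % n]
        vi = v[i]
        # tangent directions at vi toward previous and next vertex
        t_prev = h - np.dot(h, vi) * vi
        t_next = j - np.dot(j, vi) * vi
        np_prev, np_next = np.linalg.norm(t_prev), np.linalg.norm(t_next)
        if np_prev == 0 or np_next == 0:
            raise InvalidGeometryError("ring contains antipodal/duplicate vertices")
        t_prev /= np_prev
        t_next /= np_next
        d_in = -t_prev  # direction of travel arriving at vi
        sin_t = float(np.dot(np.cross(d_in, t_next), vi))
        cos_t = float(np.dot(d_in, t_next))
        turn_sum += np.arctan2(sin_t, cos_t)
    area_left = 2.0 * np.pi - turn_sum
    return float(min(abs(area_left), abs(4.0 * np.pi - area_left)))


def geodesic_area_km2(polygons, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Spherical surface area of lon/lat polygons, km².

    Holes are subtracted, multipart geometries summed; vertex order does
    not matter. Self-intersecting rings raise
    :class:`InvalidGeometryError`.
    """
    if polygons is None:
        return 0.0
    if isinstance(polygons, np.ndarray):
        # a bare (n, 2) lon/lat ring: planar validity does not apply
        return float(_ring_area_steradians(polygons) * radius_km**2)
    if isinstance(polygons, (list, tuple)):
        arr = np.asarray(polygons, dtype=object)
        if arr.ndim >= 2 or (len(polygons) and isinstance(polygons[0], (list, tuple))):
            return float(
                _ring_area_steradians(np.asarray(polygons, float)) * radius_km**2
            )
        return float(sum(geodesic_area_km2(p, radius_km) for p in polygons))
    geom = polygons
    if geom.is_empty:
        return 0.0
    if isinstance(geom, MultiPolygon):
        return float(sum(geodesic_area_km2(p, radius_km) for p in geom.geoms))
    if not isinstance(geom, Polygon):
        raise InvalidGeometryError(f"expected polygonal geometry, got {geom.geom_type}")
    if not geom.is_valid:
        raise InvalidGeometryError("polygon ring is self-intersecting or invalid")
    sr = _ring_area_steradians(np.asarray(geom.exterior.coords))
    for hole in geom.interiors:
        sr -= _ring_area_steradians(np.asarray(hole.coords))
    return float(max(sr, 0.0) * radius_km**2)


def range_size_table(points_by_species: dict[str, np.ndarray], **hull_kwargs):
    """Dynamic alpha hulls for many species.

    Returns ``(table, hulls)``: a DataFrame with columns species, alpha,
    n_parts, fraction_contained, area_km2 (species lacking enough
    geometry are excluded with a logged reason) and the per-species
    :class:`HullResult` objects.
    """
    import pandas as pd

    rows, hulls = [], {}
    for species in sorted(points_by_species):
        pts = points_by_species[species]
        try:
            res = dynamic_alpha_hull(pts, **hull_kwargs)
        except InsufficientGeometryError as exc:
            logger.warning("species %s excluded from range size: %s", species, exc)
            continue
        hulls[species] = res
        rows.append(
            {
                "species": species,
                "alpha": res.alpha,
                "n_parts": res.n_parts,
                "fraction_contained": res.fraction_contained,
                "area_km2": res.area_km2,
            }
        )
    return pd.DataFrame(rows), hulls
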