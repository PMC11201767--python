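"""Radial-zone geometry of a cortical column.

Builds the six depth zones between the pia and white-matter boundaries:
evenly spaced (equal arclength fraction) lines connect the two boundaries to
delimit vertical columns; each column line is split by its endpoints plus
five equidistant interior points, and matching points on adjacent lines are
connected by straight segments to bound six polygons, Zone 1 abutting the
pia and Zone 6 the white matter. Cells are assigned to zones by centroid
point-in-polygon with a pia-ward tie-break on shared boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, mapping, shape
from shapely.geometry.polygon import orient
from shapely.ops import substring

__all__ = [
    "GeometryError",
    "ColumnAnnotation",
    "ZoneSet",
    "build_columns",
    "zone_points",
    "build_zones",
    "assign_zone",
    "zones_from_boundaries",
    "assign_zones_multi",
    "total_zone_areas",
    "zones_to_geojson",
    "zones_from_geojson",
]


class GeometryError(ValueError):
    pass


def _as_polyline(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or len(a) < 2:
        raise GeometryError("polyline must be an (N, 2) array with N >= 2")
    return a


def _point_at_fraction(poly: np.ndarray, frac: float) -> np.ndarray:
    """Point at the given cumulative chord-length fraction along a polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        raise GeometryError("zero-length polyline")
    target = frac * total
    i = int(np.searchsorted(cum, target, side="right")) - 1
    i = min(max(i, 0), len(seg) - 1)
    t = (target - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return poly[i] + t * (poly[i + 1] - poly[i])


@dataclass
class ColumnAnnotation:
    """One vertical column: pia and wm sub-polylines plus two lateral lines."""

    pia_segment: np.ndarray
    wm_segment: np.ndarray
    left_line: np.ndarray  # (2, 2): pia end first
    right_line: np.ndarray


@dataclass
class ZoneSet:
    """Six ordered, interior-disjoint zone polygons; index 1 abuts the pia."""

    zones: list  # shapely Polygons, index 0 -> Zone 1
    areas_mm2: np.ndarray

    @property
    def column_polygon(self) -> Polygon:
        u = shapely.union_all(self.zones)
        return u


def build_columns(pia, wm, n_columns: int) -> list[ColumnAnnotation]:
    """Split the ribbon into columns by lines at equal arclength fractions.

    The i-th line joins the point at arclength fraction i/n along the pia to
    the point at the same fraction along the white matter; the wm polyline is
    flipped if its orientation opposes the pia's.
    """
    if n_columns < 1:
        raise GeometryError("n_columns must be >= 1")
    pia = _as_polyline(pia)
    wm = _as_polyline(wm)
    # orientation consistency: matched endpoints should be the near ones
    if np.linalg.norm(pia[0] - wm[0]) > np.linalg.norm(pia[0] - wm[-1]):
        wm = wm[::-1]
    fracs = np.linspace(0.0, 1.0, n_columns + 1)
    p_pts = [_point_at_fraction(pia, f) for f in fracs]
    w_pts = [_point_at_fraction(wm, f) for f in fracs]
    lines = [np.array([p, q]) for p, q in zip(p_pts, w_pts)]
    ls = [LineString(l) for l in lines]
    for i in range(len(ls)):
        for j in range(i + 1, len(ls)):
            if ls[i].intersects(ls[j]):
                raise GeometryError(f"column lines {i} and {j} intersect inside the ribbon")
    pia_ls = LineString(pia)
    wm_ls = LineString(wm)
    cols = []
    for i in range(n_columns):
        pseg = substring(pia_ls, fracs[i], fracs[i + 1], normalized=True)
        wseg = substring(wm_ls, fracs[i], fracs[i + 1], normalized=True)
        cols.append(
            ColumnAnnotation(
                pia_segment=np.asarray(pseg.coords),
                wm_segment=np.asarray(wseg.coords),
                left_line=lines[i],
                right_line=lines[i + 1],
            )
        )
    return cols


def zone_points(line, pia_point=None) -> np.ndarray:
    """Endpoints plus five equidistant interior points of a column line.

    Returns 7 points ordered pia-first, splitting the segment into six equal
    parts. If ``pia_point`` is given, the segment is flipped when its second
    endpoint is the one nearer the pia.
    """
    seg = np.asarray(line, dtype=float)
    if seg.shape != (2, 2):
        raise GeometryError("line must be a (2, 2) array of endpoints")
    if np.allclose(seg[0], seg[1]):
        raise GeometryError("zero-length segment")
    if pia_point is not None:
        p = np.asarray(pia_point, dtype=float)
        if np.linalg.norm(seg[1] - p) < np.linalg.norm(seg[0] - p):
            seg = seg[::-1]
    t = np.linspace(0.0, 1.0, 7)[:, None]
    return seg[0] + t * (seg[1] - seg[0])


def build_zones(left_points, right_points) -> ZoneSet:
    """Six zone polygons from the 7-point splits of two adjacent column lines."""
    lp = np.asarray(left_points, dtype=float)
    rp = np.asarray(right_points, dtype=float)
    if lp.shape != (7, 2) or rp.shape != (7, 2):
        raise GeometryError("expected two (7, 2) point lists")
    zones = []
    for k in range(6):
        poly = Polygon([lp[k], lp[k + 1], rp[k + 1], rp[k]])
        if not poly.is_valid:
            raise GeometryError(f"zone {k + 1} polygon is self-intersecting")
        zones.append(orient(poly, sign=1.0))
    areas = np.array([z.area for z in zones]) / 1e6
    return ZoneSet(zones=zones, areas_mm2=areas)


def assign_zone(centroids, zone_set: ZoneSet) -> np.ndarray:
    """Zone index (1-6) per centroid, 0 for unassigned.

    Point-in-polygon including boundaries; a centroid on a shared boundary
    goes to the lower (pia-ward) zone because zones are scanned in order.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    out = np.zeros(len(pts), dtype=int)
    for k, poly in enumerate(zone_set.zones, start=1):
        todo = out == 0
        if not todo.any():
            break
        hit = shapely.intersects(poly, geoms[todo])
        idx = np.flatnonzero(todo)[hit]
        out[idx] = k
    return out


def zones_from_boundaries(pia, wm, n_columns: int = 4) -> list[ZoneSet]:
    """Columns + zones in one call; one ZoneSet per column."""
    cols = build_columns(pia, wm, n_columns)
    sets = []
    for c in cols:
        lp = zone_points(c.left_line)
        rp = zone_points(c.right_line)
        sets.append(build_zones(lp, rp))
    return sets


def assign_zones_multi(centroids, zone_sets: list[ZoneSet]) -> np.ndarray:
    """Zone index per centroid over several columns (first matching column wins)."""
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    out = np.zeros(len(pts), dtype=int)
    for zs in zone_sets:
        todo = out == 0
        if not todo.any():
            break
        out[todo] = assign_zone(pts[todo], zs)
    return out


def total_zone_areas(zone_sets: list[ZoneSet]) -> np.ndarray:
    """Per-zone areas (mm²) summed over columns; index 0 -> Zone 1."""
    return np.sum([zs.areas_mm2 for zs in zone_sets], axis=0)


def zones_to_geojson(zone_sets: list[ZoneSet]) -> dict:
    features = []
    for ci, zs in enumerate(zone_sets):
        for k, poly in enumerate(zs.zones, start=1):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {"zone": k, "column": ci, "area_mm2": float(zs.areas_mm2[k - 1])},
                }
            )
    return {"type": "FeatureCollection", "features": features}


def zones_from_geojson(obj) -> list[ZoneSet]:
    if isinstance(obj, str):
        obj = json.loads(obj)
    by_col: dict[int, dict[int, Polygon]] = {}
    for f in obj["features"]:
        props = f["properties"]
        by_col.setdefault(int(props.get("column", 0)), {})[int(props["zone"])] = shape(
            f["geometry"]
        )
    sets = []
    for ci in sorted(by_col):
        polys = [by_col[ci][k] for k in range(1, 7)]
        areas = np.array([p.area for p in polys]) / 1e6
        sets.append(ZoneSet(zones=polys, areas_mm2=areas))
    return sets
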