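"""Threshold-area curves: polygonize the density surface at successively
decreasing biomass thresholds and account for every point and polygon.

For aggregating taxa the total area enclosed at or above a threshold grows
slowly while the thresholds are still mapping out the dense aggregations,
then jumps sharply once the threshold drops low enough to start capturing
dispersed individuals.  The machinery here produces, per threshold, the
superlevel-set polygons (with holes), the total area in km^2, and the
bookkeeping needed by the selection criteria: how many input points are
newly enclosed, how many of those fall in genuinely new areas, and which
polygons arose by merging polygons of the previous (higher) threshold.

Contours come from marching squares with linear interpolation on the
cell-center values; areas are computed both from the vector polygons and
from raster cell counts as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping
from shapely.ops import unary_union
from shapely.prepared import prep
from skimage import measure

from .kde import DensitySurface

__all__ = [
    "ThresholdStep",
    "ThresholdCurve",
    "polygonize",
    "cell_count_area",
    "build_curve",
    "polygons_to_geojson",
]

M2_PER_KM2 = 1e6


@dataclass
class ThresholdStep:
    """One threshold's polygons and accounting deltas.

    Areas are km^2.  "New" points are enclosed at this threshold but not at
    the previous (higher) one; "in new areas" additionally fall outside the
    previous step's polygon union.  A merge event records the indices of
    previous-step polygons united into one polygon here.
    """

    threshold: float
    polygons: list[Polygon]
    total_area: float
    n_points_enclosed: int = 0
    n_new_points: int = 0
    n_new_points_in_new_areas: int = 0
    merges: list[list[int]] = field(default_factory=list)
    new_polygon_count: int = 0
    edge_contact: list[bool] = field(default_factory=list)


@dataclass
class ThresholdCurve:
    """Steps in decreasing-threshold order plus successive area ratios."""

    steps: list[ThresholdStep]

    @property
    def area_ratios(self) -> list[float]:
        """A(t_{k+1}) / A(t_k) for successive (higher, lower) pairs.

        nan where the higher-threshold area is zero.
        """
        out = []
        for hi, lo in zip(self.steps, self.steps[1:]):
            out.append(lo.total_area / hi.total_area
                       if hi.total_area > 0 else float("nan"))
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per step: the threshold-area histogram quantities."""
        rows = []
        ratios = [float("nan")] + self.area_ratios
        for step, ratio in zip(self.steps, ratios):
            rows.append({
                "threshold": step.threshold,
                "total_area_km2": step.total_area,
                "area_ratio": ratio,
                "n_polygons": len(step.polygons),
                "n_points_enclosed": step.n_points_enclosed,
                "n_new_points": step.n_new_points,
                "n_new_points_in_new_areas": step.n_new_points_in_new_areas,
                "n_merge_events": len(step.merges),
                "new_polygon_count": step.new_polygon_count,
            })
        return pd.DataFrame(rows)


def _assemble_polygons(rings: list[np.ndarray]) -> list[Polygon]:
    """Nest closed contour rings into polygons with holes.

    The region outside all rings is below the level (the raster is padded
    with a sub-level border before contouring), so top-level rings are
    exteriors, their immediate children are holes, children of holes are
    exterior rings of islands, and so on (even depth = exterior).
    """
    shells = [Polygon(r) for r in rings if len(r) >= 4]
    shells = [(i, s) for i, s in enumerate(shells) if s.is_valid and s.area > 0]
    # sort big to small so parents precede children
    order = sorted(shells, key=lambda t: -t[1].area)
    depth = {}
    parent = {}
    preps = []
    for i, s in order:
        d = 0
        par = None
        for j, ps, sj in reversed(preps):  # innermost enclosing ring wins
            if ps.contains(Point(s.exterior.coords[0])) or sj.contains(s):
                d = depth[j] + 1
                par = j
                break
        depth[i] = d
        parent[i] = par
        preps.append((i, prep(s), s))

    polys: list[Polygon] = []
    for i, s in order:
        if depth[i] % 2 == 0:
            holes = [t.exterior.coords for j, t in order
                     if parent.get(j) == i and depth[j] == depth[i] + 1]
            polys.append(Polygon(s.exterior.coords, holes))
    return polys


def polygonize(
    surface: DensitySurface, level: float
) -> tuple[list[Polygon], float]:
    """Contour the superlevel set {value >= level} into closed polygons.

    Marching squares with linear interpolation on cell-center values.  The
    raster is padded with one ring of sub-level cells so every contour
    closes, even where the level set touches the raster edge.

    Returns
    -------
    (polygons, total_area_km2)
        Holes are subtracted from the area.  A level above the surface
        maximum yields ``([], 0.0)`` (an empty superlevel set, not an
        error).
    """
    if not level > 0:
        raise ValueError("contour level must be > 0")
    v = surface.values
    if level > v.max():
        return [], 0.0
    pad = np.pad(v, 1, constant_values=min(-1.0, level - 1.0))
    rings = measure.find_contours(pad, level)
    cell = surface.cell_size
    xy_rings = []
    for r in rings:
        # r[:, 0] = row, r[:, 1] = col in padded index space
        x = surface.x_origin + (r[:, 1] - 1 + 0.5) * cell
        y = surface.y_origin - (r[:, 0] - 1 + 0.5) * cell
        xy_rings.append(np.column_stack([x, y]))
    polys = _assemble_polygons(xy_rings)
    area = sum(p.area for p in polys) / M2_PER_KM2
    return polys, area


def cell_count_area(surface: DensitySurface, level: float) -> float:
    """Raster oracle for the superlevel-set area: cells >= level x cell area."""
    n = int((surface.values >= level).sum())
    return n * surface.cell_size**2 / M2_PER_KM2


def _edge_contact_flags(surface: DensitySurface, polys: list[Polygon]) -> list[bool]:
    """Flag polygons whose extent reaches within one cell of the raster edge."""
    c = surface.cell_size
    xmin = surface.x_origin + c
    xmax = surface.x_origin + surface.ncols * c - c
    ymax = surface.y_origin - c
    ymin = surface.y_origin - surface.nrows * c + c
    out = []
    for p in polys:
        bx0, by0, bx1, by1 = p.bounds
        out.append(bx0 <= xmin or by0 <= ymin or bx1 >= xmax or by1 >= ymax)
    return out


def build_curve(
    surface: DensitySurface,
    records,
    levels,
) -> ThresholdCurve:
    """Build the threshold-area curve over a strictly decreasing level list.

    Parameters
    ----------
    surface : DensitySurface
    records : DataFrame with x, y columns (the points to account for;
        normally the positive-catch records that built the surface)
    levels : sequence of float, strictly decreasing, all > 0

    Notes
    -----
    Point-in-polygon tests are boundary-inclusive (thresholds are "at or
    above", so a point exactly on a contour counts as enclosed).  A polygon
    whose interior intersects two or more previous-step polygons records a
    merge event; a polygon intersecting none is new.
    """
    levels = [float(t) for t in levels]
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly decreasing")
    if any(t <= 0 for t in levels):
        raise ValueError("levels must be > 0")

    if isinstance(records, pd.DataFrame):
        pts = [Point(x, y) for x, y in zip(records["x"], records["y"])]
    else:
        pts = [Point(x, y) for x, y in records]

    steps: list[ThresholdStep] = []
    prev_polys: list[Polygon] = []
    prev_union = None
    prev_enclosed: set[int] = set()

    for level in levels:
        polys, area = polygonize(surface, level)
        enclosed = set()
        for k, pt in enumerate(pts):
            if k in prev_enclosed:
                enclosed.add(k)  # nesting: once enclosed, stays enclosed
                continue
            for p in polys:
                if p.covers(pt):
                    enclosed.add(k)
                    break
        new_pts = enclosed - prev_enclosed
        if prev_union is None:
            n_new_in_new = len(new_pts)
        elif new_pts:
            pu = prep(prev_union)
            n_new_in_new = sum(1 for k in new_pts if not pu.intersects(pts[k]))
        else:
            n_new_in_new = 0

        merges: list[list[int]] = []
        new_polygon_count = 0
        for p in polys:
            pp = prep(p)
            preds = [j for j, q in enumerate(prev_polys)
                     if pp.intersects(q) and p.intersection(q).area > 0]
            if len(preds) >= 2:
                merges.append(preds)
            elif len(preds) == 0:
                new_polygon_count += 1

        steps.append(ThresholdStep(
            threshold=level,
            polygons=polys,
            total_area=area,
            n_points_enclosed=len(enclosed),
            n_new_points=len(new_pts),
            n_new_points_in_new_areas=n_new_in_new,
            merges=merges,
            new_polygon_count=new_polygon_count,
            edge_contact=_edge_contact_flags(surface, polys),
        ))
        prev_polys = polys
        prev_union = unary_union(polys) if polys else None
        prev_enclosed = enclosed

    return ThresholdCurve(steps)


def polygons_to_geojson(
    step: ThresholdStep,
    records=None,
    extra_properties: dict | None = None,
) -> dict:
    """One threshold's polygons as a GeoJSON FeatureCollection (dict).

    Each feature carries the threshold, its area in km^2, merge/new flags,
    the enclosed-point count and the raster-edge-contact flag.
    """
    if records is not None and isinstance(records, pd.DataFrame):
        pts = [Point(x, y) for x, y in zip(records["x"], records["y"])]
    else:
        pts = []
    features = []
    for i, p in enumerate(step.polygons):
        props = {
            "threshold": step.threshold,
            "area_km2": p.area / M2_PER_KM2,
            "edge_contact": bool(step.edge_contact[i]) if step.edge_contact else False,
            "n_points": sum(1 for pt in pts if p.covers(pt)),
        }
        if extra_properties:
            props.update(extra_properties)
        features.append(
            {"type": "Feature", "geometry": mapping(p), "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}
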