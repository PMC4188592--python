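"""Selection of the aggregation-defining biomass threshold.

A "significant concentration" threshold is the catch weight at which the
threshold-area curve jumps: above it, the polygons delineate dense
aggregations; below it, they begin to absorb dispersed individuals.  Expert
assessment of such curves weighs several things at once — the size of the
area jump after the aggregations are first established, how many new points
support the jump, whether the area grew by genuinely new ground or merely by
polygons merging, and whether the new ground holds any real density.  This
module makes that judgment algorithmic and auditable: every constant is a
field of :class:`SelectionCriteria`, candidate jumps are ranked by area
ratio, and rejection rules veto candidates with explicit flags rather than a
silent pick.

Rejection flags
---------------
``single-point-jump``
    The jump is carried by fewer than ``min_new_points`` newly enclosed
    records (e.g. one isolated datum inflating the area).
``merge-without-support``
    Most (>50%) of the area growth comes from polygons merging across
    bridges that contain almost no data — no evidence of a continuous
    distribution between them.
``low-density-new-area``
    The newly added area has mean surface density below
    ``low_density_fraction`` of the candidate level: area added by near-empty
    ground.
``gradual-increase``
    Every successive change is modest — the curve grows steadily with no
    single defining jump, i.e. there is no aggregation signal.
``no-large-jump``
    No successive pair reaches ``jump_min`` at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union
from shapely.prepared import prep

from .contours import M2_PER_KM2, ThresholdCurve
from .kde import DensitySurface

__all__ = [
    "SelectionCriteria",
    "CandidateJump",
    "SelectionResult",
    "find_candidates",
    "apply_rejection_rules",
    "select_threshold",
    "summarize_enclosure",
    "flag_isolated_polygons",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Tunable constants of the selection rules.

    jump_min : minimum area ratio for a successive pair to qualify as the
        defining jump (>1).
    min_new_points : minimum newly enclosed points supporting a jump.
    min_spread : minimum widely-spaced new points required inside merge
        bridges before merge-driven growth counts as supported.
    low_density_fraction : fraction of the candidate level below which the
        mean density of newly added area counts as "very low".
    plateau_tol : maximum relative area change during the initial
        establishment plateau of the aggregations.
    """

    jump_min: float = 1.2
    min_new_points: int = 3
    min_spread: int = 2
    low_density_fraction: float = 0.5
    plateau_tol: float = 0.10

    def __post_init__(self):
        if not self.jump_min > 1:
            raise ValueError("jump_min must be > 1")
        if min(self.min_new_points, self.min_spread) <= 0:
            raise ValueError("point counts must be strictly positive")
        if self.low_density_fraction <= 0 or self.plateau_tol <= 0:
            raise ValueError("fractions must be strictly positive")


@dataclass
class CandidateJump:
    """A successive threshold pair whose area ratio reaches jump_min."""

    upper_level: float
    lower_level: float
    area_ratio: float
    n_new_points: int
    n_new_points_in_new_areas: int
    n_merge_events: int
    upper_index: int  # index of the upper step in the curve


@dataclass
class SelectionResult:
    selected_threshold: float | None
    candidate_jumps: list[CandidateJump] = field(default_factory=list)
    rejection_flags: dict[int, set[str]] = field(default_factory=dict)
    curve_flags: set[str] = field(default_factory=set)
    narrative: str = ""

    def to_json_dict(self) -> dict:
        return {
            "selected_threshold": self.selected_threshold,
            "candidates": [
                {
                    "upper_level": c.upper_level,
                    "lower_level": c.lower_level,
                    "area_ratio": c.area_ratio,
                    "n_new_points": c.n_new_points,
                    "n_new_points_in_new_areas": c.n_new_points_in_new_areas,
                    "n_merge_events": c.n_merge_events,
                    "flags": sorted(self.rejection_flags.get(i, set())),
                }
                for i, c in enumerate(self.candidate_jumps)
            ],
            "curve_flags": sorted(self.curve_flags),
            "narrative": self.narrative,
        }


def find_candidates(
    curve: ThresholdCurve, criteria: SelectionCriteria | None = None
) -> list[CandidateJump]:
    """Candidate jumps: ratio >= jump_min after the establishment plateau.

    The establishment phase is the maximal leading run of successive pairs
    (starting at the first non-empty step) whose ratios stay within
    ``1 + plateau_tol`` — the thresholds are still mapping out the dense
    aggregations.  Pairs after that run qualify when their ratio reaches
    ``jump_min``; candidates are returned ordered by ratio, largest first.
    """
    criteria = criteria or SelectionCriteria()
    steps = curve.steps
    if len(steps) < 3:
        raise ValueError("curve must have at least 3 steps")
    ratios = curve.area_ratios  # ratios[i] pairs steps[i] (upper), steps[i+1]

    s0 = next((i for i, s in enumerate(steps) if s.total_area > 0), None)
    if s0 is None:
        return []
    i = s0
    while i < len(ratios) and ratios[i] <= 1 + criteria.plateau_tol:
        i += 1
    establishment_end = i

    cands = []
    for k in range(establishment_end, len(ratios)):
        r = ratios[k]
        if np.isfinite(r) and r >= criteria.jump_min:
            lo = steps[k + 1]
            cands.append(CandidateJump(
                upper_level=steps[k].threshold,
                lower_level=lo.threshold,
                area_ratio=r,
                n_new_points=lo.n_new_points,
                n_new_points_in_new_areas=lo.n_new_points_in_new_areas,
                n_merge_events=len(lo.merges),
                upper_index=k,
            ))
    cands.sort(key=lambda c: -c.area_ratio)
    return cands


def _merge_growth_support(
    candidate: CandidateJump,
    curve: ThresholdCurve,
    points: list[Point],
    criteria: SelectionCriteria,
) -> tuple[float, float, int]:
    """(total growth, unsupported merge growth, bridge point count) in km^2."""
    upper = curve.steps[candidate.upper_index]
    lower = curve.steps[candidate.upper_index + 1]
    total_growth = lower.total_area - upper.total_area
    upper_union = unary_union(upper.polygons) if upper.polygons else None
    unsupported = 0.0
    bridge_points_total = 0
    for poly in lower.polygons:
        pp = prep(poly)
        preds = [q for q in upper.polygons
                 if pp.intersects(q) and poly.intersection(q).area > 0]
        if len(preds) < 2:
            continue
        growth = (poly.area - sum(q.area for q in preds)) / M2_PER_KM2
        bridge = poly.difference(upper_union) if upper_union is not None else poly
        bp = prep(bridge)
        n_bridge = sum(1 for pt in points if bp.covers(pt))
        bridge_points_total += n_bridge
        if n_bridge < criteria.min_spread:
            unsupported += growth
    return total_growth, unsupported, bridge_points_total


def apply_rejection_rules(
    candidate: CandidateJump,
    curve: ThresholdCurve,
    records,
    criteria: SelectionCriteria | None = None,
    surface: DensitySurface | None = None,
) -> set[str]:
    """Evaluate the rejection rules against one candidate jump.

    ``records`` are the points used to build the curve; ``surface`` enables
    the low-density-new-area check (skipped when not given).
    """
    criteria = criteria or SelectionCriteria()
    flags: set[str] = set()

    if candidate.n_new_points < criteria.min_new_points:
        flags.add("single-point-jump")

    if isinstance(records, pd.DataFrame):
        points = [Point(x, y) for x, y in zip(records["x"], records["y"])]
    else:
        points = [Point(x, y) for x, y in records]

    if candidate.n_merge_events > 0:
        total_growth, unsupported, _ = _merge_growth_support(
            candidate, curve, points, criteria
        )
        if total_growth > 0 and unsupported > 0.5 * total_growth:
            flags.add("merge-without-support")

    if surface is not None:
        v = surface.values
        in_new = (v >= candidate.lower_level) & (v < candidate.upper_level)
        if in_new.any():
            mean_new = float(v[in_new].mean())
            if mean_new < criteria.low_density_fraction * candidate.upper_level:
                flags.add("low-density-new-area")

    return flags


def select_threshold(
    curve: ThresholdCurve,
    records,
    criteria: SelectionCriteria | None = None,
    surface: DensitySurface | None = None,
) -> SelectionResult:
    """Nominate the aggregation-defining threshold, or none.

    The threshold demarcates the onset of the rapid-increase phase: among
    the candidates surviving all rejection rules, the one with the highest
    threshold wins, and the selected value is the UPPER level of that jump
    (a jump from 75 to 50 kg selects 75 kg).  Once the curve has entered
    its rapid phase every further step keeps inflating the area with
    dispersed individuals, so a deeper jump with a larger ratio must not
    displace the first supported one — a rejected high candidate (e.g. a
    single-datum jump) simply passes the nomination down to the next.
    Flags veto: a rejected candidate is never selected however large its
    ratio.  When every candidate is rejected, or none exists, no threshold
    is selected and the narrative explains why.
    """
    criteria = criteria or SelectionCriteria()
    candidates = find_candidates(curve, criteria)
    # evaluate in curve order (descending threshold): first supported jump
    candidates = sorted(candidates, key=lambda c: c.upper_index)
    lines: list[str] = []
    flags_by_idx: dict[int, set[str]] = {}
    selected = None

    if not candidates:
        ratios = [r for r in curve.area_ratios if np.isfinite(r)]
        growing = any(r > 1 + criteria.plateau_tol for r in ratios)
        flag = "gradual-increase" if growing else "no-large-jump"
        lines.append(
            f"no successive area change reaches jump_min={criteria.jump_min:g}"
            + (" although the curve grows steadily (no single defining jump)"
               if growing else "")
        )
        return SelectionResult(None, [], {}, curve_flags={flag},
                               narrative="; ".join(lines) + f"; flag: {flag}")

    for i, cand in enumerate(candidates):
        fl = apply_rejection_rules(cand, curve, records, criteria, surface)
        flags_by_idx[i] = fl
        desc = (f"{cand.upper_level:g}->{cand.lower_level:g}: area x"
                f"{cand.area_ratio:.2f}, {cand.n_new_points} new points "
                f"({cand.n_new_points_in_new_areas} in new areas), "
                f"{cand.n_merge_events} merge event(s)")
        if fl:
            lines.append(f"rejected {desc} [{', '.join(sorted(fl))}]")
        elif selected is None:
            selected = cand.upper_level
            lines.append(f"selected {desc}")
        else:
            lines.append(f"passed but deeper than the selected jump: {desc}")

    if selected is None:
        lines.append("all candidates rejected; no significant-concentration "
                     "threshold nominated")
    return SelectionResult(selected, candidates, flags_by_idx,
                           curve_flags=set(), narrative="; ".join(lines))


def summarize_enclosure(
    surface: DensitySurface | None,
    polygons: list[Polygon],
    records,
    all_records=None,
    sampled_area_mask: Polygon | None = None,
) -> tuple[float, float]:
    """Fractions summarizing how concentrated the enclosed biomass is.

    Returns
    -------
    (biomass_fraction_enclosed, area_fraction_of_sampled)
        Biomass fraction: share of total catch weight (of ``records``, i.e.
        the harmonized records) inside the polygons.  Area fraction: polygon
        area over the sampled area — by default the convex hull of all
        trawl-set locations in ``all_records`` (including null sets), or an
        explicit mask polygon.
    """
    if isinstance(records, pd.DataFrame):
        xs, ys = records["x"].to_numpy(), records["y"].to_numpy()
        ws = records["biomass"].to_numpy(dtype=float)
    else:
        xs, ys, ws = (np.asarray(v, dtype=float) for v in records)
    total = float(ws.sum())
    if total <= 0:
        raise ValueError("total biomass is zero")

    if not polygons:
        return 0.0, 0.0
    union = unary_union(polygons)
    pu = prep(union)
    inside = np.fromiter(
        (pu.covers(Point(x, y)) for x, y in zip(xs, ys)), dtype=bool,
        count=len(xs),
    )
    biomass_fraction = float(ws[inside].sum()) / total

    if sampled_area_mask is not None:
        sampled_area = sampled_area_mask.area
    else:
        base = all_records if all_records is not None else records
        if isinstance(base, pd.DataFrame):
            pts = MultiPoint(list(zip(base["x"], base["y"])))
        else:
            bx, by, _ = (np.asarray(v, dtype=float) for v in base)
            pts = MultiPoint(list(zip(bx, by)))
        sampled_area = pts.convex_hull.area
    area_fraction = union.area / sampled_area if sampled_area > 0 else float("nan")
    return biomass_fraction, float(area_fraction)


def flag_isolated_polygons(polygons: list[Polygon], records) -> list[bool]:
    """True where a polygon encloses a single positive record.

    Such areas rest on one datum (often with null sets around it) and carry
    an insufficient-data caveat rather than being dropped: they may be real
    concentrations whose extent needs targeted sampling to resolve.
    """
    if isinstance(records, pd.DataFrame):
        pos = records[records["biomass"] > 0]
        pts = [Point(x, y) for x, y in zip(pos["x"], pos["y"])]
    else:
        pts = [Point(x, y) for x, y in records]
    out = []
    for p in polygons:
        pp = prep(p)
        out.append(sum(1 for pt in pts if pp.covers(pt)) == 1)
    return out
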