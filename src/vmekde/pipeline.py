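"""End-to-end wiring: records -> density surface -> curve -> threshold.

Also provides the ground-truth diagnostics used to score the pipeline on
synthetic scenes: the background ceiling (the highest surface value found
away from any true aggregation) is the surface-level boundary between the
aggregation regime and the dispersed-background regime, and recovery is
judged by whether the selected threshold lands within one level-grid step
of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import ThresholdCurve, build_curve
from .kde import DensitySurface, default_config, kde
from .records import data_extent, positive_records
from .select import SelectionCriteria, SelectionResult, select_threshold
from .simulate import SyntheticScene

__all__ = [
    "default_level_grid",
    "analyze_records",
    "AnalysisResult",
    "background_ceiling",
    "boundary_weight",
    "recovery_error_steps",
]


def default_level_grid(
    surface: DensitySurface,
    records: pd.DataFrame,
    n_levels: int = 16,
    high_quantile: float = 0.90,
    low_quantile: float = 0.05,
) -> list[float]:
    """Descending log-spaced contour levels spanning the catch weights.

    Thresholds are catch-weight classes, so the grid spans the positive
    catch-weight distribution: from its ``high_quantile`` (the largest
    catches — by which level the aggregation cores are already established
    and the curve is in its slow initial phase) down to ``low_quantile``
    (the weight scale of single dispersed individuals).  Log spacing
    matches the right-skew of catch weights, which cover decades rather
    than a linear band.  Levels above the surface maximum, possible on
    surfaces with little kernel overlap, are dropped.
    """
    pos = positive_records(records)
    w = pos["biomass"].to_numpy(dtype=float)
    lo = float(np.quantile(w, low_quantile))
    hi = float(np.quantile(w, high_quantile))
    if not 0 < lo < hi:
        raise ValueError("cannot build a level grid: degenerate weight range")
    levels = np.geomspace(hi, lo, n_levels)
    return list(levels[levels <= surface.values.max()])


@dataclass
class AnalysisResult:
    surface: DensitySurface
    curve: ThresholdCurve
    selection: SelectionResult
    levels: list[float]


def analyze_records(
    records: pd.DataFrame,
    levels=None,
    criteria: SelectionCriteria | None = None,
    config=None,
    n_levels: int = 16,
) -> AnalysisResult:
    """Run the full delineation pipeline on harmonized records.

    KDE geometry defaults to the data extent with the /30 search radius and
    /250 cell size rules; the level grid defaults to
    :func:`default_level_grid`.
    """
    pos = positive_records(records)
    if config is None:
        config = default_config(data_extent(pos))
    surface = kde(pos, config)
    if levels is None:
        levels = default_level_grid(surface, records, n_levels=n_levels)
    curve = build_curve(surface, pos, levels)
    selection = select_threshold(curve, pos, criteria, surface)
    return AnalysisResult(surface, curve, selection, list(levels))


def background_ceiling(scene: SyntheticScene, surface: DensitySurface) -> float:
    """Highest surface value attained away from every true aggregation.

    "Away" means farther than 4 x cluster_sd + search_radius from every
    parent: offspring displacements are truncated at 4 x cluster_sd, so no
    cluster kernel reaches such a cell and the value there is pure
    background.  Thresholds above the ceiling enclose only aggregation
    structure; thresholds below it begin to admit dispersed individuals.
    Returns 0.0 if no cell lies beyond that distance.
    """
    guard = 4 * scene.spec.cluster_sd + surface.config.search_radius
    xs, ys = surface.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    far = np.ones(gx.shape, dtype=bool)
    for px, py in scene.parents:
        far &= (gx - px) ** 2 + (gy - py) ** 2 > guard * guard
    if not far.any():
        return 0.0
    return float(surface.values[far].max())


def boundary_weight(scene: SyntheticScene, quantile: float = 0.95) -> float:
    """The generator's cluster/background boundary in catch-weight terms.

    The upper edge of the background catch-weight distribution (its
    ``quantile``, default the 95th percentile): a density threshold at this
    level excludes the polygons of essentially all dispersed individuals
    while the aggregations — whose catches lie far above — remain.  This is
    the catch level that separates aggregations from dispersed individuals
    in the scene's own terms.
    """
    mu, sd = scene.spec.biomass_background
    from scipy.stats import norm

    return float(np.exp(mu + norm.ppf(quantile) * sd))


def recovery_error_steps(
    scene: SyntheticScene, result: AnalysisResult
) -> float:
    """Selected-threshold error in units of level-grid steps.

    Distance, in (log-spaced) grid steps, between the selected threshold
    and the grid level closest to the scene's cluster/background boundary
    (:func:`boundary_weight`).  ``inf`` when nothing was selected.
    """
    sel = result.selection.selected_threshold
    if sel is None:
        return float("inf")
    target = boundary_weight(scene)
    levels = np.asarray(result.levels, dtype=float)
    log_levels = np.log(levels)
    target_idx = int(np.argmin(np.abs(log_levels - np.log(target))))
    sel_idx = int(np.argmin(np.abs(log_levels - np.log(sel))))
    return float(abs(sel_idx - target_idx))
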