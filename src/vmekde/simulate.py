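"""Seeded synthetic trawl-survey scenes with known aggregation structure.

Aggregating benthos (sponge grounds, sea-pen fields, coral forests) is
emulated with a Thomas cluster process: Poisson-distributed parents
(aggregation centers) each spawn a Poisson number of offspring displaced by
an isotropic Gaussian, over a diffuse Poisson background of dispersed
individuals.  Cluster catches draw from a high-biomass lognormal, background
catches from a low-biomass lognormal, so the pooled catch-weight
distribution is strongly right-skewed — many small catches, few very large
ones — as survey catch data for these taxa are.  A zero-inflation
probability turns records into null sets (nothing caught) while keeping
their locations, mimicking trawls that missed the taxon.

The default parameters describe a study region of roughly 600 x 600 km
holding a handful of aggregations a few tens of km across (catches of tens
of kg) over a sparse background of dispersed individuals (catches of a few
hundred grams), with a roughly 150-fold biomass contrast between the two
regimes.  Everything is reproducible from the scene seed.

Offspring displacements are truncated at 4 standard deviations (the draw is
repeated past that), so every cluster-labelled record is guaranteed to lie
within 4 x cluster_sd of its parent; the nominal truth region around each
parent uses radius 2 x cluster_sd (~86% of offspring mass).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from .records import Extent

__all__ = ["SceneSpec", "SyntheticScene", "generate_scene", "make_multisurvey"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic survey landscape.

    Intensities are per m^2; distances in m; biomasses in kg.  The lognormal
    parameters are (mu, sigma) of the underlying normal, i.e.
    ``exp(mu)`` is the median catch.
    """

    window: Extent = Extent(0.0, 0.0, 600_000.0, 600_000.0)
    parent_intensity: float = 8 / 600_000.0**2       # ~8 aggregations
    offspring_mean: float = 40.0                     # sets crossing each one
    cluster_sd: float = 8_000.0                      # aggregation scale (m)
    background_intensity: float = 300 / 600_000.0**2  # ~300 dispersed sets
    biomass_cluster: tuple[float, float] = (np.log(30.0), 0.8)
    biomass_background: tuple[float, float] = (np.log(0.2), 0.25)
    zero_inflation: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.parent_intensity < 0 or self.background_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if not self.cluster_sd > 0:
            raise ValueError("cluster_sd must be > 0")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must be in [0, 1]")

    @property
    def expected_points(self) -> float:
        area = self.window.width * self.window.height
        return area * (self.parent_intensity * self.offspring_mean
                       + self.background_intensity)

    def to_json(self) -> str:
        d = asdict(self)
        d["window"] = {"xmin": self.window.xmin, "ymin": self.window.ymin,
                       "xmax": self.window.xmax, "ymax": self.window.ymax}
        return json.dumps(d, indent=2)


@dataclass
class SyntheticScene:
    """A generated scene: records plus the generator's ground truth."""

    records: pd.DataFrame
    parents: np.ndarray              # (n_parents, 2)
    truth_labels: np.ndarray         # bool per record: cluster member
    spec: SceneSpec

    @property
    def truth_regions(self):
        """Union of disks of radius 2 x cluster_sd around the parents."""
        r = 2 * self.spec.cluster_sd
        disks = [Point(x, y).buffer(r) for x, y in self.parents]
        return unary_union(disks) if disks else Point(0, 0).buffer(0)


def _truncated_normal_displacements(rng, n, sd, max_sd=4.0):
    """Isotropic Gaussian displacements resampled beyond max_sd radii."""
    out = np.empty((n, 2))
    need = np.arange(n)
    while need.size:
        d = rng.normal(0.0, sd, size=(need.size, 2))
        r = np.hypot(d[:, 0], d[:, 1])
        ok = r <= max_sd * sd
        out[need[ok]] = d[ok]
        need = need[~ok]
    return out


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Draw one scene from the spec; fully reproducible from ``spec.seed``.

    Offspring falling outside the window are dropped (border thinning), as
    a survey only samples inside its footprint.

    Raises
    ------
    ValueError
        If the expected total point count is below 3.
    """
    if spec.expected_points < 3:
        raise ValueError(
            f"expected point count {spec.expected_points:.2f} < 3; "
            "increase intensities or the window"
        )
    rng = np.random.default_rng(spec.seed)
    w = spec.window
    area = w.width * w.height

    n_parents = rng.poisson(spec.parent_intensity * area)
    parents = np.column_stack([
        rng.uniform(w.xmin, w.xmax, n_parents),
        rng.uniform(w.ymin, w.ymax, n_parents),
    ])

    xs, ys, labels = [], [], []
    for px, py in parents:
        n_off = rng.poisson(spec.offspring_mean)
        disp = _truncated_normal_displacements(rng, n_off, spec.cluster_sd)
        ox, oy = px + disp[:, 0], py + disp[:, 1]
        inside = (w.xmin <= ox) & (ox <= w.xmax) & (w.ymin <= oy) & (oy <= w.ymax)
        xs.append(ox[inside]); ys.append(oy[inside])
        labels.append(np.ones(int(inside.sum()), dtype=bool))

    n_bg = rng.poisson(spec.background_intensity * area)
    xs.append(rng.uniform(w.xmin, w.xmax, n_bg))
    ys.append(rng.uniform(w.ymin, w.ymax, n_bg))
    labels.append(np.zeros(n_bg, dtype=bool))

    x = np.concatenate(xs); y = np.concatenate(ys)
    lab = np.concatenate(labels)

    mu_c, sd_c = spec.biomass_cluster
    mu_b, sd_b = spec.biomass_background
    biomass = np.where(
        lab,
        rng.lognormal(mu_c, sd_c, lab.size),
        rng.lognormal(mu_b, sd_b, lab.size),
    )
    nulls = rng.uniform(size=lab.size) < spec.zero_inflation
    biomass = np.where(nulls, 0.0, biomass)

    records = pd.DataFrame({
        "x": x, "y": y, "biomass": biomass,
        "survey_id": "sim", "gear": "Campelen", "duration": 30.0,
        "speed": 3.0, "taxon": "synthetic",
    })
    records.attrs["n_zero_biomass"] = int((biomass == 0).sum())
    return SyntheticScene(records, parents, lab, spec)


def make_multisurvey(
    scene: SyntheticScene,
    gear_effects: dict[str, float],
    cutoff: float = 0.2,
    durations: dict[str, float] | None = None,
    n_strata: int | None = None,
) -> pd.DataFrame:
    """Split a scene into spatial survey strata with gear-dependent catches.

    The window is cut into ``n_strata`` equal-width vertical strata assigned
    to the gears round-robin, giving each survey interleaved coverage of the
    same landscape (as depth-stratified designs do); strata much wider than
    a cluster would instead hand whole aggregations to single surveys and
    confound gear effects with spatial biomass differences.  The default
    stratum width is one cluster_sd, well under an aggregation's footprint,
    so every aggregation is sampled by all gears.

    Catches strictly below ``cutoff`` kg are multiplied by the gear's
    factor, emulating gear-dependent catchability of small individuals
    while leaving large catches untouched.  Optional per-gear tow durations
    let duration-ladder comparisons be exercised too.

    Deterministic given the scene (no new randomness).
    """
    gears = list(gear_effects)
    if len(gears) < 2:
        raise ValueError("need at least 2 gear labels")
    df = scene.records.copy()
    w = scene.spec.window
    if n_strata is None:
        n_strata = max(2 * len(gears),
                       int(np.ceil(w.width / scene.spec.cluster_sd)))
    band = w.width / n_strata
    idx = np.minimum(((df["x"] - w.xmin) // band).astype(int), n_strata - 1)
    df["gear"] = [gears[i % len(gears)] for i in idx]
    df["survey_id"] = df["gear"]
    if durations:
        df["duration"] = df["gear"].map(durations).fillna(30.0)
    small = df["biomass"] < cutoff
    factor = df["gear"].map(gear_effects)
    df.loc[small, "biomass"] = df.loc[small, "biomass"] * factor[small]
    return df
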