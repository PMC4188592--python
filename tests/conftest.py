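import numpy as np
import pandas as pd
import pytest

from vmekde import (
    Extent,
    KDEConfig,
    SceneSpec,
    analyze_records,
    generate_scene,
    kde,
)


def records_frame(xs, ys, ws, **extra):
    """Minimal canonical record table from coordinate/weight arrays."""
    n = len(xs)
    df = pd.DataFrame({
        "x": np.asarray(xs, dtype=float),
        "y": np.asarray(ys, dtype=float),
        "biomass": np.asarray(ws, dtype=float),
        "survey_id": extra.get("survey_id", "s"),
        "gear": extra.get("gear", "Campelen"),
        "duration": extra.get("duration", 30.0),
        "speed": extra.get("speed", 3.0),
        "taxon": extra.get("taxon", "t"),
    })
    return df


def single_point_surface(w=1.0, h=100.0, cell=2.0, scaling="peak"):
    """Surface of one point of weight w placed exactly on a cell center."""
    extent = Extent(0.0, 0.0, 1000.0, 1000.0)
    cfg = KDEConfig(search_radius=h, cell_size=cell, extent=extent,
                    scaling=scaling)
    # cell centers sit at (xmin - h) + (j + 0.5) * cell; pick one mid-grid
    x = (extent.xmin - h) + (int((500 + h) / cell) + 0.5) * cell
    y_top = extent.ymin - h + np.ceil((extent.height + 2 * h) / cell) * cell
    y = y_top - (int((y_top - 500) / cell) + 0.5) * cell
    df = records_frame([x], [y], [w])
    return kde(df, cfg), (x, y), cfg


@pytest.fixture(scope="session")
def demo_scene():
    return generate_scene(SceneSpec(seed=11))


@pytest.fixture(scope="session")
def demo_analysis(demo_scene):
    return analyze_records(demo_scene.records)
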