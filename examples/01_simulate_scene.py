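"""Generate a synthetic trawl survey over a clustered benthic landscape.

A Thomas cluster process plants a handful of dense aggregations (sponge
grounds, say) on a diffuse background of dispersed individuals; catch
weights are lognormal with a ~150-fold contrast between the two regimes,
and some sets catch nothing at all.
"""

import numpy as np

from vmekde import SceneSpec, generate_scene

spec = SceneSpec(seed=11)
scene = generate_scene(spec)

records = scene.records
positive = records[records["biomass"] > 0]
print(f"trawl sets:           {len(records)}")
print(f"  null sets (no catch): {records.attrs['n_zero_biomass']}")
print(f"  cluster members:      {int(scene.truth_labels.sum())}")
print(f"aggregations (parents): {len(scene.parents)}")
print(f"catch weights (kg):   median {positive['biomass'].median():.2f}, "
      f"max {positive['biomass'].max():.1f}, "
      f"skewness {float(((positive['biomass'] - positive['biomass'].mean())**3).mean() / positive['biomass'].std()**3):.1f}")

# The skewness is strongly positive: many small catches, few very large
# ones, which is the signature of an aggregating taxon. The truth regions
# (disks of 2 cluster-sd around each aggregation centre) are what the
# downstream threshold selection should rediscover from the catches alone.
area_km2 = scene.truth_regions.area / 1e6
window_km2 = spec.window.width * spec.window.height / 1e6
print(f"true aggregation area: {area_km2:,.0f} km^2 "
      f"({100 * area_km2 / window_km2:.1f}% of the window)")
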