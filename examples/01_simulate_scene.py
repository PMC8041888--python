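"""Generate a synthetic landscape and look at its ground truth.

Builds a 256 x 256 scene (10 m pixels) of a flat agricultural plain with
trees placed as homestead clusters, field-boundary lines and riparian
corridors, then prints the realized tree fraction, the height range and
the terrain relief.
"""

import numpy as np

from tofscape import SceneParams, generate_landscape

params = SceneParams(shape=(256, 256), tree_fraction=0.15, seed=42)
truth = generate_landscape(params)

tree = truth.tree_mask.data == 1
print(f"requested tree fraction : {params.tree_fraction:.3f}")
print(f"realized tree fraction  : {tree.mean():.3f}")
print(f"tree height range (m)   : {truth.tree_height.data[tree].min():.1f}"
      f" - {truth.tree_height.data[tree].max():.1f}")
print(f"terrain relief (m)      : {truth.terrain.data.min():.1f}"
      f" - {truth.terrain.data.max():.1f}")
print(f"divisions               : {', '.join(truth.division_polygons)}")

# The realized fraction tracks the request because patches are placed until
# the pixel budget is met; heights are positive exactly on tree pixels.
assert (truth.tree_height.data > 0).sum() == tree.sum()
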