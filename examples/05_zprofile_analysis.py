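"""Analyze the z-heights of focus probes: layers, statistics, arithmetic.

Autofocus probes on a dusty slide form two z-layers: the cell layer and
a dust layer on the coverslip.  After separating them, the cell layer's
descriptive statistics say how much focal variation a single-layer scan
must cover — and how many z-stack planes the alternative would need.
"""

import numpy as np

from cytofocus.zprofile import (LAYER_CELL, LAYER_DUST, ZDataset,
                                layers_needed, separate_layers, z_stats)

rng = np.random.default_rng(3)
z_cell = rng.normal(118.0, 5.0, 570)        # cells on a folded surface
z_dust = rng.normal(55.0, 2.0, 90)          # dust on the coverslip
pts = np.column_stack([rng.uniform(0, 2000, 660), rng.uniform(0, 2000, 660),
                       np.concatenate([z_cell, z_dust])])
data = ZDataset(pts)

labeled = separate_layers(data)
cell = labeled.subset(LAYER_CELL)
dust = labeled.subset(LAYER_DUST)
print(f"{len(labeled.points)} focus points -> "
      f"{len(cell.points)} cell-layer, {len(dust.points)} dust-layer")

stats = z_stats(cell)
print(f"cell layer: mean {stats.mean:.1f} um, median {stats.median:.1f} um, "
      f"sd {stats.sd:.1f} um")
print(f"            min {stats.min:.1f}, max {stats.max:.1f}, "
      f"range {stats.range:.1f} um")

n_layers = layers_needed(stats.range, 2.0)
print(f"a 2-um z-stack would need {n_layers} layers to cover this range;")
print("a single master-focus layer that follows the surface needs one.")
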