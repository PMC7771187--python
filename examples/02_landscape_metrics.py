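"""Percent grassland and edge density inside a buffered route footprint.

Builds a random 30-m classified grid, buffers a short two-vertex route
at 300 m, and prints the two landscape metrics.  Edge density divides
total grassland/non-grassland boundary length by the grassland area
(m/ha): higher values mean more fragmented grassland.
"""

import numpy as np

import thresholdnmix as t

raster = t.make_raster_fixture(60, 60, "random", seed=7, density=0.55)
route = np.array([[500.0, 700.0], [1300.0, 900.0]])

mask = t.buffer_mask(route, radius=300.0, raster=raster)
grass = t.percent_grassland(raster, mask)
ed = t.edge_density(raster, mask)

print(f"buffer includes {mask.include.sum()} cells of {mask.include.size}")
print(f"percent grassland: {grass:.1f}%")
print(f"edge density:      {ed:.1f} m/ha (grassland-area denominator)")
print("A single isolated 30-m grassland cell would score "
      f"{4 * 30 / 0.09:.0f} m/ha, the fragmentation maximum for this grid.")
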