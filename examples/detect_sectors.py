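"""Detect sector-like patterns in a synthetic bacterial colony.

Grows a two-type colony on a 101x101 grid, builds the mutant-fraction grid
of the final state, runs the region-detection pipeline and prints the
spatial measures of each detected sector.
"""

import numpy as np

from stmc import (
    ColonyGeneratorConfig,
    RegionDetectionConfig,
    SpaceGeometry,
    detect_regions,
    generate_colony_trace,
    grid_to_grayscale,
    region_measures,
)

cfg = ColonyGeneratorConfig(seed=2, n_timepoints=40, switch_probability=0.05)
wildtype, mutant = generate_colony_trace(cfg)[-1]
total = wildtype + mutant
fraction = np.where(total > 0, mutant / np.maximum(total, 1e-300), 0.0)

detection = RegionDetectionConfig(threshold_value=127, epsilon_size=5,
                                  morph_close_iterations=1, blur_kernel_size=3)
regions = detect_regions(grid_to_grayscale(fraction, 1.0), detection)
geom = SpaceGeometry(rows=101, cols=101)

print(f"{len(regions)} sector-like regions in the final colony state")
for i, region in enumerate(regions):
    m = region_measures(region, fraction, geom)
    print(f"  region {i}: area={m.area:7.1f}  perimeter={m.perimeter:6.1f}  "
          f"density={m.density:.2f}  angle={m.angle:5.1f}  "
          f"triangular={m.triangularMeasure:.2f}  shape={m.shape}")
print("High density means the sector is dominated by switched cells; a high")
print("triangular measure is the signature of a radially growing sector wedge.")
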