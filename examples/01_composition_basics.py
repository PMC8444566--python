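"""Closure, ilr coordinates and the variation matrix on a small sample.

Builds a handful of 24-h time-use days, closes them to 1440 min, computes
the compositional (geometric) mean, the pairwise log-ratio variation
matrix, and the ilr pivot coordinates of the mean day.
"""

import numpy as np

from timecoda import (
    close,
    compositional_mean,
    ilr_transform,
    ternary_density,
    variation_matrix,
)

# five days: minutes in Sleep, SB, LPA, MVPA (raw totals differ slightly,
# as accelerometer-registered time does)
days = np.array([
    [455, 790, 150, 40],
    [480, 760, 130, 55],
    [470, 800, 140, 45],
    [440, 770, 160, 50],
    [465, 785, 135, 48],
], dtype=float)

mean = compositional_mean(days, total=1440.0)
print("compositional mean (min/day):",
      dict(zip(mean.labels, mean.parts.round(1))))
print("as percent of the day:      ",
      dict(zip(mean.labels, mean.reclose(100.0).parts.round(2))))
# The geometric-mean day: the center of the sample in Aitchison geometry.

z = ilr_transform(mean)
print("ilr coordinates of the mean day:", z.round(4))
# z1: sleep vs everything else; z2: SB vs the activity behaviors;
# z3: light vs moderate-to-vigorous activity.  These three numbers carry
# all the relative information of the 4-part day.

T = variation_matrix(days)
print("\nvariation matrix (pairwise log-ratio variances):")
print(T.round(4))
# Small entries = the two behaviors move together; the largest entries
# typically involve MVPA, the least co-dependent behavior.

grid = ternary_density(days, ("Sleep", "SB", "MVPA"), resolution=12)
occupied = grid[grid["count"] > 0]
print(f"\nternary density: {len(occupied)} occupied of {len(grid)} cells;"
      f" frequencies sum to {grid['frequency'].sum():.1f}")
# Long-format (b1, b2, b3, frequency) rows are plot-ready for a ternary
# heat map of the time-use distribution.
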