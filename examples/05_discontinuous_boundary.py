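"""Crossing an invisible stretch of boundary.

A straight two-region edge is erased over a 12-row band (no contrast, no
spurious edges).  The first crack front stalls at the band; the driver
spawns a second front past it and joins the two traces with a straight
bridge, recovering the full edge.
"""

import numpy as np

from crackseg import run_lcpm
from crackseg.synthetic import gen_edge_with_blank_band

img, true_col = gen_edge_with_blank_band(size=96, edge_col=48, band=(40, 52))
seed = np.array([[6.0, true_col], [9.0, true_col]])

result = run_lcpm(img, first_center=(8, 48), seed_points=seed)

pts = result.contour.points
outside = pts[(pts[:, 0] < 36) | (pts[:, 0] > 56)]
print(f"stalled fronts: {result.contour.stalls}")
print(f"second fronts spawned: {sum(f.bridge_before for f in result.fragments)}")
print(f"contour rows {pts[:, 0].min():.0f}..{pts[:, 0].max():.0f} "
      f"(blank band was rows 40..52)")
print(f"edge position error outside the band: max {np.abs(outside[:, 1] - true_col).max():.2f} px")
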