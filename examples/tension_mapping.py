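"""Locating high-tension points on the cell periphery.

A synthetic tension map plants red spots (lifetime-colormap rendering of
high tension) at known angles on the rim of a cell silhouette.  The
analysis fits a circle to the cell, detects the spots, expresses them in
normalized polar coordinates, and measures how concentrated they are
over eight 45-degree sectors — against the 12.5% uniform baseline.
"""

import numpy as np

from mechanoquant import (
    angular_concentration,
    detect_high_tension_points,
    polarize_points,
    segment_cell_circle,
)
from mechanoquant.synthetic import gen_tension_image

planted = (100.0, 110.0, 120.0, 128.0)  # one 45-degree sector
img, truth = gen_tension_image(cell_radius=100, point_angles=planted,
                               image_size=512, seed=0)

centroid, radius = segment_cell_circle(np.asarray(img[:, :, 0], dtype=float))
points = detect_high_tension_points(img)
pmap = polarize_points(points, centroid, radius)
conc = angular_concentration(pmap)

print(f"fitted cell circle: centre {centroid[0]:.1f}, {centroid[1]:.1f}, radius {radius:.1f} px")
for p in sorted(pmap.points, key=lambda q: q.theta):
    print(f"  point at theta = {p.theta:6.1f} deg, norm_r = {p.norm_r:.2f}")
print(f"max bin fraction: {conc.max_bin_fraction:.1f}% (uniform baseline {conc.baseline}%)")
print(
    "All spots sit at norm_r ~ 1 (the membrane) and in a single 45-degree "
    "sector: the signature of one localized pore site."
)
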