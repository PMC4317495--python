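"""Cortical microtubule residence under stimulatory vs inhibitory signalling.

Simulates tip trajectories in a circular cell at a 10 s frame interval for
the two activation regimes, measures per-microtubule distance to the cell
edge and the residence lifetime within 2 um of the periphery, and tiles the
cell edge with 5 x 2 um counting boxes.
"""

import numpy as np
from scipy.stats import mannwhitneyu
from shapely.geometry import Point

from adhesiomics.cortical import (
    membrane_residence,
    mt_box_counts,
    peripheral_boxes,
    tip_edge_distance,
)
from adhesiomics.synthetic import SimTrackConfig, gen_tracks

cell = Point(0, 0).buffer(20, quad_segs=32)  # 20 um radius cell

lifetimes = {}
for regime, dwell in (("stimulatory", 6.0), ("inhibitory", 2.0)):
    cfg = SimTrackConfig(
        boundary=cell, n_microtubules=100, n_frames=60,
        cortical_dwell_frames=dwell, regime=regime, seed=2,
    )
    tracks = gen_tracks(cfg)
    lifetimes[regime] = np.array([
        membrane_residence(tip_edge_distance(g, cell), band_um=2.0, dt_s=10.0)[0]
        for _, g in tracks.groupby("mt_id")
    ])
    print(f"{regime}: median residence {np.median(lifetimes[regime]):.0f} s, "
          f"mean {lifetimes[regime].mean():.0f} s")
_, p = mannwhitneyu(lifetimes["stimulatory"], lifetimes["inhibitory"], alternative="greater")
print(f"one-sided rank test stimulatory > inhibitory: P = {p:.2e}")
# Longer dwell at the cortex under stimulatory signalling translates into
# longer uninterrupted episodes within 2 um of the cell edge.

square = [(0, 0), (40, 0), (40, 40), (0, 40)]
boxes = peripheral_boxes(square, length_um=5, depth_um=2)
segments = [[(x, 0.5), (x, 6.0)] for x in np.linspace(2, 38, 10)]
counts, mean, sd = mt_box_counts(segments, boxes)
print(f"\n{len(boxes)} peripheral boxes on a 40 um square cell; "
      f"microtubule density {mean:.2f} +/- {sd:.2f} per box")
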