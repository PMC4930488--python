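"""Kinematics quantification on synthetic imaging data.

Exercises the measurement operators against their paired generators:
cell-outline deformation (tension mapping), tracked-point speeds from a
simulated explosion movie, and the landing-field distance census.
"""

import numpy as np

from podburst.params import ReferenceParameterSet
from podburst.quantify import cell_deformation, tension_map, track_speeds
from podburst.synth import (gen_landing_field, gen_outline_pairs,
                            gen_tracked_explosion)

ref = ReferenceParameterSet()

# --- excised-cell outlines -> principal contraction map ---------------
bundle = gen_outline_pairs(12, magnitude_pct=20.0, direction_deg=0.0,
                           vertex_noise_um=0.5, seed=5)
table, axis_label = tension_map(bundle.payload)
print("tension map over 12 cells (uniaxial 20% field):")
print(f"  mean shrinkage {table['shrinkage_percent'].mean():.1f} % "
      f"along {axis_label}")
one = cell_deformation(bundle.payload[0])
print(f"  first cell: lambda1 = {one.lambda1:.3f}, "
      f"lambda2 = {one.lambda2:.3f}, "
      f"max shrinkage {one.max_shrinkage_percent:.1f} % at "
      f"{one.max_shrinkage_direction_deg:.1f} deg")

# --- tracked explosion movie -> point speeds --------------------------
movie = gen_tracked_explosion(ref, n_points=6, noise_sd_um=5.0, seed=8,
                              n_segments=40, T_ms=3.0)
speeds = track_speeds(movie.payload, fps=movie.ground_truth["fps"])
print("\ntracked-point launch speeds (m/s):")
for pid, v in sorted(speeds["launch_speed"].items()):
    print(f"  point {pid}: {v:.2f}")
print(f"  mean {speeds['mean']:.2f} +/- {speeds['sd']:.2f}, "
      f"max {speeds['max']:.2f}")

# --- landing-field census ---------------------------------------------
field = gen_landing_field(2000, seed=13)
d = field.payload["distance_m"].to_numpy()
print(f"\nlanding field: n = {len(d)}, "
      f"median {np.median(d):.2f} m, p99 {np.percentile(d, 99):.2f} m")
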