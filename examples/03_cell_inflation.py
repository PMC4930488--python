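"""Pressurized-cell wall mechanics: inflation, calibration, file force.

Inflates the mature 50 x 50 x 20 um exocarp cell with anisotropic
walls, calibrates the longitudinal wall modulus against a +53% osmotic
volume change, and evaluates the pulling force transmitted by a file of
turgid cells — the cross-scale quantity that links cell turgor to the
organ-level exocarp tension.
"""

from podburst.cells import (CellGeom, WallMaterial, calibrate,
                            file_tension_force, osmotic_response)
from podburst.params import ReferenceParameterSet

ref = ReferenceParameterSet()
geom = CellGeom(*ref.cell_dims_mature, ref.wall_thickness)
material = WallMaterial(ref.E_wall_length, ref.E_wall_transverse,
                        ref.E_wall_depth)

# osmotic response of the reference-calibrated walls, 0 -> 0.7 MPa
resp = osmotic_response(geom, material, 0.0, ref.turgor_pressure,
                        refinement=1)
print("reference walls, 0 -> 0.7 MPa:")
print(f"  length {resp.percent_change[0]:+6.2f} %   "
      f"width {resp.percent_change[1]:+6.2f} %   "
      f"depth {resp.percent_change[2]:+6.2f} %   "
      f"volume {resp.volume_percent_change:+6.2f} %")

# volume-only calibration: free the longitudinal modulus until the
# simulated volume change hits +53%
fit = calibrate({"volume": 53.0}, geom, free=("E_length",),
                P=ref.turgor_pressure, material0=material, refinement=1)
mat53 = fit["material"]
print(f"\nvolume-calibrated E_length = {mat53.E_length:.1f} MPa")
resp53 = osmotic_response(geom, mat53, 0.0, ref.turgor_pressure,
                          refinement=1)
print(f"  length {resp53.percent_change[0]:+6.2f} %   "
      f"depth {resp53.percent_change[2]:+6.2f} %   "
      f"volume {resp53.volume_percent_change:+6.2f} %")

# pulling force of the exocarp cell files across the valve width
n_files = ref.valve_width * 1e3 / ref.cell_dims_mature[1]
force = file_tension_force(geom, mat53, ref.turgor_pressure,
                           n_cells=3, n_files=n_files, refinement=1)
print(f"\ncell-file pulling force: "
      f"{force['force_per_file'] * 1e3:.3f} mN per file, "
      f"{force['total_force'] * 1e3:.1f} mN over {n_files:.0f} files")
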