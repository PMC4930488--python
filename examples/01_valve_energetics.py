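"""Trilayer valve energetics: stored energy, equilibrium curvature, coils.

Builds the two reference valve cross-sections (hinged endocarp-b cells
and rigid boxed cells), evaluates the elastic energy landscape over
curvature, and prints the released energy, the equilibrium curvature
and the implied number of coils for a fully curled valve.
"""

import numpy as np

from podburst import energetics
from podburst.params import ReferenceParameterSet

ref = ReferenceParameterSet()

for geometry in ("hinged", "boxed"):
    valve = energetics.reference_valve(ref, geometry)
    ls = energetics.landscape(valve)
    print(f"--- {geometry} cross-section ---")
    print(f"  equilibrium curvature : {ls.kappa_star:8.1f} 1/m")
    print(f"  released energy       : {ls.delta_E * 1e3:8.4f} mJ")
    print(f"  coils at equilibrium  : {ls.coils:8.2f} "
          f"(rounds to {ls.coils_rounded:.0f})")

# the landscape itself: energy vs curvature for the hinged valve
valve = energetics.reference_valve(ref, "hinged")
ls = energetics.landscape(valve)
kappas = np.linspace(0.0, 1.2 * ls.kappa_star, 7)
print("\nhinged energy landscape U(kappa) [mJ]:")
for k in kappas:
    U = energetics.energy_at_curvature(valve, k)
    print(f"  kappa = {k:7.1f} 1/m   U = {U * 1e3:8.4f}")

# closed-form resultants of the laminate
r = energetics.stack_resultants(valve)
print(f"\nstack resultants: EA = {r.EA:.3g} N, EI = {r.EI:.3g} N m^2, "
      f"B_hat = {(r.EI - r.ES ** 2 / r.EA):.3g} N m^2")
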