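"""Organ-scale elastica fit: extensometer curve -> bending stiffness.

Generates a synthetic valve-straightening force-displacement curve
(with setup compliance and noise), corrects for the setup spring, fits
the elastica bending stiffness, and converts it into a tissue-level
exocarp modulus and pulling force for the reference valve.
"""

from podburst import energetics
from podburst.organ import (correct_setup_compliance, exocarp_from_valve,
                            fit_bending_stiffness)
from podburst.params import ReferenceParameterSet
from podburst.synth import gen_extensometer, measured_scale_extensometer

ref = ReferenceParameterSet()
p = measured_scale_extensometer(ref)
print(f"ground truth: B = {p['B_true']:.3e} N m^2, "
      f"kappa_hat = {p['kappa_hat']:.0f} 1/m, L = {p['L'] * 1e3:.1f} mm")

bundle = gen_extensometer(p["B_true"], p["kappa_hat"], p["L"],
                          k_setup=0.05, noise_frac=0.01, n_nodes=60,
                          seed=3)
curve = correct_setup_compliance(bundle.payload)
fit = fit_bending_stiffness(curve, p["kappa_hat"], p["L"], n_boot=20,
                            n_nodes=60, seed=3)
print(f"fitted B = {fit.B:.3e} N m^2 "
      f"(boot 95% CI {fit.B_ci[0]:.3e} .. {fit.B_ci[1]:.3e}), "
      f"residual {fit.residual_norm:.3f} mN")

valve = energetics.reference_valve(ref, "hinged")
E_exo, force = exocarp_from_valve(fit.B, valve)
print(f"implied exocarp modulus : {E_exo / 1e6:.2f} MPa")
print(f"implied exocarp tension : {force * 1e3:.1f} mN")
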