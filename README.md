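# podburst

Multi-scale mechanics of explosive seed dispersal in *Cardamine
hirsuta* (popping cress). The package models how a fruit valve stores
elastic energy in a turgid, contractile exocarp layer held flat by a
lignified endocarp geometry, and how that energy is released in
milliseconds as the valve coils and flings its seeds:

- **`podburst.energetics`** — trilayer (exocarp / middle / endocarp-b)
  laminate energetics with closed-form stack resultants, cross-section
  flattening cost, equilibrium curvature and the released-energy
  landscape for "hinged" vs "boxed" endocarp-b cell geometries.
- **`podburst.dynamics`** — planar discrete elastic rod driven by the
  energy landscape, with viscoelastic seed tethers that rupture at a
  critical extension; records per-seed launch time, speed and angle.
- **`podburst.ballistics`** — drag-resolved point-mass flight and a
  Monte Carlo over launch records, with plateau/Rayleigh
  distance-distribution statistics.
- **`podburst.cells`** — pressurized single-cell and cell-file finite
  element membrane model (orthotropic Saint Venant–Kirchhoff walls,
  tension-field wrinkling), osmotic response, indentation stiffness,
  parameter calibration and the cross-scale cell-file pulling force.
- **`podburst.organ`** — clamped elastica model of the excised coiled
  valve, extensometer-curve correction and bending-stiffness fitting,
  and conversion to a tissue-level exocarp modulus and tension.
- **`podburst.quantify`** — measurement operators for imaging data:
  cell-outline deformation / tension maps, orientation statistics,
  tracked-point speeds.
- **`podburst.synth`** — paired synthetic-data generators (with ground
  truth) for every measurement operator.
- **`podburst.params`** — the single reference parameter record with
  per-field units and provenance tags, YAML-overridable.

## Worked example

```python
from podburst import energetics
from podburst.params import ReferenceParameterSet

ref = ReferenceParameterSet()
valve = energetics.reference_valve(ref, "hinged")
ls = energetics.landscape(valve)
print(f"equilibrium curvature {ls.kappa_star:.0f} 1/m, "
      f"released energy {ls.delta_E * 1e3:.3f} mJ, "
      f"coils {ls.coils:.2f}")
```

prints

```
equilibrium curvature 1315 1/m, released energy 0.084 mJ, coils 3.35
```

i.e. the 16 mm valve coils ~3–4 times at equilibrium. Swapping the
cross-section for the "boxed" geometry (deep, stiff endocarp-b cells)
raises the flattening cost so much that coiling barely pays: ~1 coil
and no net energy release — the geometric switch that arms the fruit.

The `examples/` directory has one narrative script per capability:

1. `01_valve_energetics.py` — energy landscapes for both geometries
2. `02_coiling_and_launch.py` — rod dynamics, seed launches, dispersal
3. `03_cell_inflation.py` — cell FEM, calibration, cell-file force
4. `04_organ_elastica.py` — extensometer fit → exocarp modulus
5. `05_quantify_synthetic_data.py` — measurement operators on
   generated data

## Acceptance quantities

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities (released energy, calibrated-cell
osmotic changes, cell-file force, coiling duration, dispersal
percentile, grand-mean launch speed) from the reference parameter set
and writes them as JSON. `tests/test_acceptance.py` asserts the
published target bands directly; several fail honestly (see below).

## Known limitations

- The reconstructed laminate energy functional, anchored to the
  measured exocarp pulling force (~61 mN) and 20% contraction, stores
  ~0.08 mJ — about 5× less than the ~0.5 mJ reported from the original
  (unavailable) energy functional. The released energy of any
  single-active-layer laminate is bounded by ½·F·γ·L, so force and
  energy targets cannot both be met; this package anchors to force.
  Consequences: slower simulated launches (~2.8 m/s grand mean vs
  5.0 ± 2.1), energy conversion and full seed release take ~8 ms
  rather than ≤3 ms, and the simulated landing-distance distribution
  is clumpier than the field plateau.
- The orthotropic membrane cell model cannot reproduce the printed
  −12% cell-length change together with the +53% volume change; the
  volume-calibrated cell shortens by ~4% and its cell-file force is
  ~24 mN vs the measured 61 ± 9 mN.
- The rod dynamics are planar; out-of-plane valve twist is not
  modelled.

See `docs/methods.md` for the model derivations and design choices.
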