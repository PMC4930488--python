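# Methods

Model accounts for each module, with the design choices that are not
visible from the code alone. Units: the parameter record stores each
field in its natural unit (μm / mm / MPa / mN / mg / ms, see
`podburst.params.FIELD_UNITS`); all computation is in SI via
`podburst.units`.

## Valve energetics (`energetics`)

The valve is a laminate of three layers through the thickness:
exocarp (thickness ~20 μm, rest contraction γ = 0.20), a soft middle
parenchyma block, and the lignified endocarp-b band. Each layer `i`
occupies `[z0_i, z1_i]` with modulus `E_i` and rest strain `ε0_i`; the
energy density per unit length of a layer under midplane strain `ε`
and curvature `κ` is the plane-strain quadratic
`½ E_i w ∫ (ε + κ z − ε0_i)² dz`. Integrating gives the closed-form
stack resultants

```
EA = Σ E w (z1 − z0)            ES = ½ Σ E w (z1² − z0²)
EI = ⅓ Σ E w (z1³ − z0³)        N0 = Σ E w ε0 (z1 − z0)
M0 = ½ Σ E w ε0 (z1² − z0²)
```

For fixed κ the optimal midplane strain is `ε*(κ) = (N0 − ES κ)/EA`,
which eliminates ε and leaves an effective bending problem with
stiffness `B̂ = EI − ES²/EA` and equilibrium curvature
`κ* = −(M0 − ES·N0/EA)/B̂`. With two layers this reduces exactly to
Timoshenko's bimetal formula `κ* = 24ε/(h(12 + (1+n)²/n))`, which the
test suite uses as an oracle.

Coiling a transversely curved cross-section requires flattening it
first. `flatten_cost` charges the cross-section's transverse bending
energy plus, for the *hinged* geometry, only the thin hinge webs
between endocarp-b cells (cheap), while the *boxed* geometry must
bend the full-depth lignified cell boxes (expensive). The landscape
`U(κ) = U_stack(κ) + flatten_cost` then yields the released energy
`ΔE = U(0) − U(κ*)`; for the boxed geometry ΔE is negative (coiling
does not pay), reproducing the hinged-vs-boxed arming switch.

## Coiling dynamics (`dynamics`)

The valve is a planar discrete rod of N segments (80 in the
acceptance configuration) with per-node mass from the laminate areal
density. Internal forces are the gradients of the discretized
landscape: axial springs with the κ-dependent rest strain `ε*(κ)` and
discrete bending with stiffness `B̂` and rest curvature `κ*`, so the
rod relaxes toward the energy-landscape equilibrium. Integration is
velocity Verlet at `dt = 1e-7 s` (stability-checked by `stable_dt`).

Seeds are point masses attached by a Kelvin–Voigt tether (spring k,
dashpot c) that ruptures when its extension exceeds the critical
δ_c = 40 μm; at rupture the seed's position/velocity are frozen into a
`LaunchRecord` (time, speed, angle). The tether constants are not
printed in the source study and were frozen once from a design scan
against the qualitative launch behaviour (see the decisions ledger).

## Ballistics (`ballistics`)

A launched seed is a point mass with quadratic drag,
`m v̇ = −½ ρ C_d A |v| v + m g`, integrated with `scipy`'s event-based
`solve_ivp` until ground contact from the 0.2 m release height. C_d is
either constant (0.5) or a sphere Reynolds-number correlation.
`monte_carlo_dispersal` resamples the recorded launches with
measurement-scale jitter, assigns uniform azimuths, and returns
landing samples; `distance_summary` reports a plateau statistic (CV of
the radial probability density over the central 50% probability mass)
and `rayleigh_plateau_comparator` the same statistic for a
moment-matched Rayleigh sample.

## Cell and cell-file model (`cells`)

A single exocarp cell is a closed box of triangulated membrane walls.
Wall mechanics is orthotropic Saint Venant–Kirchhoff plane stress per
element: with Green strain E in the element's material frame
(longitudinal × transverse axes assigned per face), energy
`½ t A (Q11 E11² + Q22 E22² + 2 Q12 E11 E22 + 4 G E12²)`. Turgor
enters as the exact pressure potential `−P V(x)` with V the enclosed
mesh volume, so the solved state minimizes total potential energy
(L-BFGS-B) under a pressure ramp.

Design choices:

- **Shared walls.** Neighbouring cells in the tissue share walls, so
  the single-cell model doubles side/end/bottom wall thickness (2t)
  and uses a thicker outer (top) wall (4t). The cell-file mesh uses
  the identical wall model with true 1t internal transverse walls.
- **Initial bulge.** Flat membrane walls have zero transverse
  stiffness at rest (a pressure singularity); walls start with a small
  outward bulge (default 20% of the shortest half-dimension) which the
  literature cell images also show. The file model starts flat since
  inflation itself supplies the bulge.
- **Junction-frame measurement.** Reported cell length/width are
  measured junction-to-junction (where walls meet), not over the
  bulging wall bellies, matching how cell dimensions are segmented
  from microscopy; depth is the bounding extent.
- **Tension-field wrinkling.** Thin walls cannot carry compression; a
  frozen active-set iteration replaces compressive principal membrane
  states by their uniaxial (wrinkled) branch. The wrinkling iteration
  runs only at the final step of the pressure ramp — intermediate ramp
  states only provide a continuation path — which was verified to give
  node-level identical solutions ~5× faster.
- **Indentation.** The inflated cell is pinned at the bottom face
  (vertical) plus two corner pins (rigid modes); a spherical indenter
  applies a quadratic contact penalty sampled at nodes plus four
  barycentric points per triangle so the sphere cannot pass between
  nodes. Stiffness is the slope of the force–depth record.

`osmotic_response` reports percent dimension and volume changes
between two pressures (plasmolyzed → turgid). `calibrate` runs a
weighted least-squares fit of log-moduli and/or pressure against
percent-change targets, with an identifiability check (no more free
parameters than independent targets). `file_tension_force` inflates an
n-cell file whose end wall is held at the rest length and reports the
longitudinal reaction force — the tension one cell file exerts on its
neighbours — scaled by the number of files across the valve width.

## Organ scale (`organ`)

The excised coiled valve straightened in an extensometer is a
clamped–clamped inextensible elastica with intrinsic curvature κ̂ and
bending stiffness B: in angle representation θ(s), the equilibrium
satisfies `B θ'' + F sin θ = B κ̂'` with clamp separation d as the
constraint. Since the force at separation d scales linearly in B,
`F = B f(d; κ̂, L)`, fitting B to a measured curve is linear least
squares after computing the shape factor f by solving the elastica
boundary-value problem on a displacement grid (`_ElasticaSolver`,
collocation + continuation). `correct_setup_compliance` removes the
series compliance of the testing frame (machine displacement = valve
displacement + F/k_setup) before fitting; samples where the valve is
nearly taut (d > 0.86 L) are excluded because there the recorded force
is dominated by the setup spring. `exocarp_from_valve` inverts the
laminate relation B̂(E_exocarp) to report a tissue-level exocarp
modulus and the corresponding pulling force `E γ w t`.

## Quantification operators (`quantify`)

- `cell_deformation`: best-fit affine map between pre/post outlines
  (least squares on vertices), principal stretches from the polar
  decomposition, shrinkage percentages and directions.
- `tension_map`: table of per-cell principal contractions plus the
  dominant tissue axis.
- `orientation_stats`: circular statistics of wall/microtubule
  segment orientations relative to the fruit axis.
- `track_speeds`: central-difference speeds of tracked points from a
  frame table, with per-point launch speeds.

## Synthetic data (`synth`)

Every operator has a paired generator returning a `SyntheticBundle`
(payload + ground truth + seed + noise description): tracked explosion
movies (camera-rate sampling and digitisation noise of the rod
simulation), extensometer curves (elastica forward model + setup
spring + rupture), osmotic/CFM cell tables, outline pairs under a
uniaxial contraction field, and landing-distance censuses. Generators
are deterministic given a seed.

## Known limitations

- **Energy scale.** Anchoring the laminate to the measured exocarp
  force (~61 mN, E_exocarp ≈ 7.6 MPa) bounds the released energy at
  `ΔE ≤ ½ F γ L ≈ 0.1 mJ`, ~5× below the ~0.5 mJ obtained from the
  original study's (unavailable) energy functional. All downstream
  speed/time acceptance gaps trace to this single discrepancy; the
  alternative — tuning the modulus to the printed energy — would break
  the force, coil-count and contraction observables.
- **Cell length change.** No orthotropic membrane box of the printed
  dimensions reaches −12% length with +53% volume; the geometric
  (Poisson-type) shortening saturates near −7%.
- The rod model is planar (no valve twist); the cell model is a
  membrane (no wall bending stiffness); drag on seeds ignores spin.
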