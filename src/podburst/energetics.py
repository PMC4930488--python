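"""Trilayer elastic energetics of the fruit-valve cross-section.

The valve is modelled as a stack of elastic layers (active exocarp,
passive middle tissue, stiff lignified endocarp-*b* band) glued along
their length.  With ``z`` the through-thickness coordinate measured from
the endocarp-*b* inner face toward the exocarp, the axial strain of a
fibre at height ``z`` when the valve mid-line carries axial strain
``eps0`` and longitudinal curvature ``kappa`` (positive = curling toward
the exocarp, i.e. the fibre at height ``z`` shortens) is
``eps(z) = eps0 - kappa * z``.  Each layer *i* has a rest axial strain
``g_i`` (the exocarp wants to be shorter: ``g = -gamma``), so the stored
energy per unit valve length is the quadratic functional

    U(eps0, kappa) = 1/2 * sum_i E_i w a_i  ∫ (eps0 - kappa z - g_i)^2 dz

integrated over each layer's z-band; ``a_i`` is the load-bearing area
fraction (lignified rods cover only part of the width).  Minimising over
``eps0`` in closed form (zero net axial force) leaves an upward parabola
``Uhat(kappa)`` whose vertex is the equilibrium coiling curvature.

The cross-section of the attached valve is bowed transversally; before
the valve can coil it must flatten.  With a *hinged* lignified wall
(three rods joined by thin hinges) flattening is nearly free; with a
*boxed* wall it costs transverse plate-bending energy, which is charged
against the released energy.

Internal units here: SI (m, N, Pa, J).  The public constructors accept
the natural units of :class:`podburst.params.ReferenceParameterSet` and
convert once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ReferenceParameterSet, load_reference
from .units import from_si, to_si

__all__ = [
    "LayerSpec", "CrossSectionSpec", "ValveModel", "EnergyLandscape",
    "StackResultants", "stack_resultants", "energy_at_curvature",
    "flatten_cost", "landscape", "reference_valve",
]


@dataclass(frozen=True)
class LayerSpec:
    """One elastic layer of the valve stack (SI units).

    ``z_lo``/``z_hi`` bound the layer through the thickness (m), ``E`` is
    its Young's modulus (Pa), ``g`` its rest axial strain (the exocarp
    carries ``g = -gamma``), and ``area_fraction`` the fraction of the
    valve width that is load-bearing.
    """

    name: str
    z_lo: float
    z_hi: float
    E: float
    g: float = 0.0
    area_fraction: float = 1.0

    def __post_init__(self):
        if not self.z_hi > self.z_lo:
            raise ValueError(f"layer {self.name}: z_hi must exceed z_lo")
        if not self.E > 0:
            raise ValueError(f"layer {self.name}: modulus must be positive")
        if not 0.0 <= self.area_fraction <= 1.0:
            raise ValueError(f"layer {self.name}: area_fraction in [0, 1]")
        if not abs(self.g) < 1.0:
            raise ValueError(f"layer {self.name}: |rest strain| must be < 1")

    @property
    def thickness(self) -> float:
        return self.z_hi - self.z_lo


@dataclass(frozen=True)
class CrossSectionSpec:
    """Transverse geometry of the endocarp-b secondary wall.

    ``kind`` is ``"hinged"`` (three lignified rods joined by thin hinges,
    the explosive geometry) or ``"boxed"`` (a stiff lignified box around
    each cell, the non-explosive geometry).  ``kappa_t`` is the initial
    transverse curvature of the attached valve (1/m), ``hinge_stiffness``
    the rotational stiffness per unit length of the thin hinges
    (N·m/rad² per m), and ``lignified_subregions`` lists
    ``(z_lo, z_hi, area_fraction)`` bands (m) occupied by lignin.
    """

    kind: str
    kappa_t: float
    hinge_stiffness: float
    lignified_subregions: tuple = ()

    def __post_init__(self):
        if self.kind not in ("hinged", "boxed"):
            raise ValueError("cross-section kind must be 'hinged' or 'boxed'")
        if self.kappa_t < 0 or self.hinge_stiffness < 0:
            raise ValueError("kappa_t and hinge_stiffness must be >= 0")
        zs = sorted(self.lignified_subregions)
        for (a_lo, a_hi, _), (b_lo, b_hi, _) in zip(zs, zs[1:]):
            if b_lo < a_hi:
                raise ValueError("lignified subregions overlap in z")


@dataclass(frozen=True)
class ValveModel:
    """Full valve: length, width, layer stack and cross-section (SI)."""

    L: float                      # m
    w: float                      # m
    layers: tuple                 # ordered LayerSpec, inner -> outer
    cross_section: CrossSectionSpec
    mass_per_area: float          # kg/m², summed over layers

    def __post_init__(self):
        if len(self.layers) < 3:
            raise ValueError("valve needs at least exocarp, middle and "
                             "endocarp-b layers")
        for lo, hi in zip(self.layers, self.layers[1:]):
            if abs(hi.z_lo - lo.z_hi) > 1e-12:
                raise ValueError("layers must be contiguous in z")

    @property
    def mass(self) -> float:
        """Total valve mass (kg)."""
        return self.mass_per_area * self.w * self.L


@dataclass(frozen=True)
class StackResultants:
    """Closed-form section resultants of the layer stack (SI).

    ``EA`` (N), ``ES`` (N·m), ``EI`` (N·m²) are the 0th/1st/2nd moduli-
    weighted moments; ``N0`` (N) and ``M0`` (N·m) the rest-strain force
    and moment resultants; ``R0`` (N) the rest-strain energy constant.
    """

    EA: float
    ES: float
    EI: float
    N0: float
    M0: float
    R0: float


def stack_resultants(valve: ValveModel) -> StackResultants:
    """Exact integrals of the quadratic strain energy over each layer."""
    if not valve.layers:
        raise ValueError("empty layer list")
    EA = ES = EI = N0 = M0 = R0 = 0.0
    for lay in valve.layers:
        c = lay.E * valve.w * lay.area_fraction
        d1 = lay.z_hi - lay.z_lo
        d2 = (lay.z_hi ** 2 - lay.z_lo ** 2) / 2.0
        d3 = (lay.z_hi ** 3 - lay.z_lo ** 3) / 3.0
        EA += c * d1
        ES += c * d2
        EI += c * d3
        N0 += c * lay.g * d1
        M0 += c * lay.g * d2
        R0 += c * lay.g ** 2 * d1
    return StackResultants(EA=EA, ES=ES, EI=EI, N0=N0, M0=M0, R0=R0)


def energy_density(valve: ValveModel, eps0: float, kappa: float) -> float:
    """Energy per unit length U(eps0, kappa) (J/m), before eps0 relaxation."""
    r = stack_resultants(valve)
    return 0.5 * (r.EA * eps0 ** 2 + r.EI * kappa ** 2 + r.R0
                  - 2.0 * r.ES * eps0 * kappa
                  - 2.0 * r.N0 * eps0 + 2.0 * r.M0 * kappa)


def energy_at_curvature(valve: ValveModel, kappa: float,
                        resultants: StackResultants | None = None) -> float:
    """Uhat(kappa): energy per unit length with eps0 minimised out (J/m).

    The optimum axial strain satisfies zero net axial force,
    ``EA eps0 = N0 + ES kappa``; substituting gives a convex parabola in
    ``kappa``.
    """
    r = resultants if resultants is not None else stack_resultants(valve)
    return 0.5 * (r.EI * kappa ** 2 + 2.0 * r.M0 * kappa + r.R0
                  - (r.N0 + r.ES * kappa) ** 2 / r.EA)


def optimal_axial_strain(valve: ValveModel, kappa: float) -> float:
    """eps0 minimising the energy at fixed curvature (force balance)."""
    r = stack_resultants(valve)
    return (r.N0 + r.ES * kappa) / r.EA


def _quadratic_coefficients(r: StackResultants) -> tuple[float, float, float]:
    """Uhat(kappa) = 1/2 Bhat kappa^2 + bhat kappa + chat."""
    Bhat = r.EI - r.ES ** 2 / r.EA
    bhat = r.M0 - r.ES * r.N0 / r.EA
    chat = 0.5 * (r.R0 - r.N0 ** 2 / r.EA)
    return Bhat, bhat, chat


def effective_bending_stiffness(valve: ValveModel) -> float:
    """Bhat = EI - ES²/EA (N·m²): bending stiffness about the neutral axis."""
    return _quadratic_coefficients(stack_resultants(valve))[0]


def flatten_cost(cross_section: CrossSectionSpec, valve: ValveModel) -> float:
    """Energy (J) to flatten the transverse bowing of the cross-section.

    Hinged walls widen by opening their thin hinges: a rotational-spring
    cost ``1/2 k_h theta^2`` per unit length with ``theta = kappa_t * w``
    the total hinge opening, essentially zero for the default hinges.
    Boxed walls must bend the lignified plates flat transversally:
    ``1/2 D_t kappa_t^2 w L`` with ``D_t`` the plate bending stiffness of
    the lignified bands.
    """
    kt = cross_section.kappa_t
    if kt == 0.0:
        return 0.0
    if cross_section.kind == "hinged":
        theta = kt * valve.w
        return 0.5 * cross_section.hinge_stiffness * theta ** 2 * valve.L
    # boxed: transverse plate bending of the lignified subregions about
    # their common mid-surface
    if not cross_section.lignified_subregions:
        return 0.0
    regions = cross_section.lignified_subregions
    E_lig = next(l.E for l in valve.layers if "endocarp" in l.name)
    z_mid = sum(0.5 * (lo + hi) * af for lo, hi, af in regions) / \
        sum(af for _, _, af in regions)
    D_t = 0.0
    for lo, hi, af in regions:
        D_t += E_lig * af * ((hi - z_mid) ** 3 - (lo - z_mid) ** 3) / 3.0
    return 0.5 * D_t * kt ** 2 * valve.w * valve.L


@dataclass(frozen=True)
class EnergyLandscape:
    """Energy of the flat-cross-section valve vs longitudinal curvature.

    Natural-unit views (mJ, 1/mm) are provided for reporting; internal
    fields are SI.
    """

    kappa_grid: np.ndarray        # 1/m
    U_flat: np.ndarray            # J, whole-valve energy at each curvature
    U_initial: float              # J, attached flat state (kappa = 0)
    kappa_star: float             # 1/m, vertex of the parabola
    delta_E: float                # J, released energy
    coils: float                  # L * kappa_star / (2 pi)
    flatten_cost: float           # J
    valve: ValveModel = field(repr=False, default=None)

    @property
    def coils_rounded(self) -> float:
        """Coil count rounded to the nearest half coil."""
        return round(2.0 * self.coils) / 2.0

    def summary(self) -> dict:
        """Key quantities in reporting units (mJ, 1/mm)."""
        return {
            "kappa_star_per_mm": self.kappa_star / 1e3,
            "coils": self.coils,
            "coils_rounded": self.coils_rounded,
            "delta_E_mJ": from_si(self.delta_E, "mJ"),
            "U_initial_mJ": from_si(self.U_initial, "mJ"),
            "flatten_cost_mJ": from_si(self.flatten_cost, "mJ"),
        }


def landscape(valve: ValveModel, kappa_max: float | None = None,
              n_grid: int = 201) -> EnergyLandscape:
    """Compute the energy landscape over longitudinal curvature.

    ``kappa_max`` (1/m) bounds the grid (default: twice the vertex
    curvature); the minimiser is located from the closed-form vertex of
    the parabola, not by grid search.  The initial (attached) state is
    flat with the cross-section still bowed; flattening the cross-section
    costs :func:`flatten_cost`, which is charged against the released
    energy.
    """
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")
    r = stack_resultants(valve)
    Bhat, bhat, _ = _quadratic_coefficients(r)
    kappa_star = max(0.0, -bhat / Bhat)
    if kappa_max is None:
        kappa_max = 2.0 * kappa_star if kappa_star > 0 else 100.0
    if kappa_max <= 0:
        raise ValueError("kappa_max must be positive")
    grid = np.linspace(0.0, kappa_max, n_grid)
    U_flat = np.array([valve.L * energy_at_curvature(valve, k, r)
                       for k in grid])
    U0 = valve.L * energy_at_curvature(valve, 0.0, r)
    fcost = flatten_cost(valve.cross_section, valve)
    dE = U0 - valve.L * energy_at_curvature(valve, kappa_star, r) - fcost
    return EnergyLandscape(
        kappa_grid=grid, U_flat=U_flat, U_initial=U0,
        kappa_star=kappa_star, delta_E=dE,
        coils=valve.L * kappa_star / (2.0 * np.pi),
        flatten_cost=fcost, valve=valve,
    )


# ---------------------------------------------------------------------------
# reference valve construction


def reference_valve(ref: ReferenceParameterSet | None = None,
                    geometry: str = "hinged") -> ValveModel:
    """Build the reference trilayer valve in hinged or boxed geometry.

    Hinged: the lignified band is a single inner-face band of rods
    covering ``lignified_area_fraction`` of the width.  Boxed: two
    lignified plates (inner and outer face of the endocarp-b cells,
    separated by the cell depth) plus side walls folded into an extra
    area fraction, which both stiffens longitudinal bending and makes
    transverse flattening costly.
    """
    if ref is None:
        ref = load_reference()
    if geometry not in ("hinged", "boxed"):
        raise ValueError("geometry must be 'hinged' or 'boxed'")

    t_rod = to_si(ref.endocarpb_rod_thickness, "um")
    t_mid = to_si(ref.middle_thickness, "um")
    t_exo = to_si(ref.exocarp_thickness, "um")
    E_lig = to_si(ref.E_lignin, "MPa")
    E_mid = to_si(ref.E_middle, "MPa")
    E_exo = to_si(ref.E_exocarp, "MPa")
    gamma = ref.exocarp_rest_contraction
    phi = ref.lignified_area_fraction
    kappa_t = ref.transverse_curvature * 1e3          # 1/mm -> 1/m
    # hinge stiffness: N·mm/rad² per mm length -> N·m/rad² per m (= N)
    k_hinge = ref.hinge_stiffness * 1e-3

    if geometry == "hinged":
        z0 = t_rod
        layers = (
            LayerSpec("endocarp_b", 0.0, t_rod, E_lig, 0.0, phi),
            LayerSpec("middle", z0, z0 + t_mid, E_mid),
            LayerSpec("exocarp", z0 + t_mid, z0 + t_mid + t_exo, E_exo,
                      -gamma),
        )
        cs = CrossSectionSpec("hinged", kappa_t, k_hinge,
                              ((0.0, t_rod, phi),))
    else:
        depth = to_si(ref.boxed_cell_depth, "um")
        # inner plate, lumen (side walls as area fraction), outer plate;
        # the outer plate and side walls replace the innermost part of the
        # middle tissue so the overall valve thickness matches the hinged
        # stack (the endocarp-b cells are present in both, only their
        # lignification pattern differs)
        side_af = 2.0 * t_rod / to_si(ref.cell_dims_mature[1], "um")
        z_top = depth + 2.0 * t_rod
        z_exo = t_rod + t_mid
        if z_top >= z_exo:
            raise ValueError("boxed cell depth exceeds middle thickness")
        layers = (
            LayerSpec("endocarp_b_inner", 0.0, t_rod, E_lig, 0.0, 1.0),
            LayerSpec("endocarp_b_sides", t_rod, t_rod + depth, E_lig,
                      0.0, min(1.0, side_af)),
            LayerSpec("endocarp_b_outer", t_rod + depth, z_top, E_lig,
                      0.0, 1.0),
            LayerSpec("middle", z_top, z_exo, E_mid),
            LayerSpec("exocarp", z_exo, z_exo + t_exo, E_exo, -gamma),
        )
        cs = CrossSectionSpec(
            "boxed", kappa_t, 0.0,
            ((0.0, t_rod, 1.0), (t_rod + depth, z_top, 1.0)))

    rho = ref.tissue_density * 1e3                    # mg/mm³ -> kg/m³
    thickness = sum(l.thickness for l in layers)
    return ValveModel(
        L=to_si(ref.valve_length, "mm"),
        w=to_si(ref.valve_width, "mm"),
        layers=layers, cross_section=cs,
        mass_per_area=rho * thickness,
    )
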