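import numpy as np
import pytest

from podburst.energetics import (CrossSectionSpec, LayerSpec, ValveModel,
                                 effective_bending_stiffness, energy_density,
                                 energy_at_curvature, flatten_cost, landscape,
                                 optimal_axial_strain, reference_valve,
                                 stack_resultants)
from podburst.params import load_reference


def simple_valve(layers, L=0.016, w=0.001, kind="hinged", kappa_t=0.0,
                 k_hinge=0.0, subregions=()):
    cs = CrossSectionSpec(kind, kappa_t, k_hinge, subregions)
    return ValveModel(L=L, w=w, layers=tuple(layers), cross_section=cs,
                      mass_per_area=0.1)


def quadrature_resultants(valve, n=10000):
    """Brute-force numerical quadrature oracle for the stack integrals."""
    EA = ES = EI = N0 = M0 = R0 = 0.0
    for lay in valve.layers:
        z = np.linspace(lay.z_lo, lay.z_hi, n)
        c = lay.E * valve.w * lay.area_fraction
        EA += c * np.trapezoid(np.ones_like(z), z)
        ES += c * np.trapezoid(z, z)
        EI += c * np.trapezoid(z ** 2, z)
        N0 += c * lay.g * np.trapezoid(np.ones_like(z), z)
        M0 += c * lay.g * np.trapezoid(z, z)
        R0 += c * lay.g ** 2 * np.trapezoid(np.ones_like(z), z)
    return EA, ES, EI, N0, M0, R0


class TestStackResultants:
    def test_single_centered_layer_closed_form(self):
        # E = 1 MPa, w = 1 mm, z in [-0.5, 0.5] mm: EA = 1 N, EI = 1/12
        # N mm^2, ES = 0
        v = simple_valve([
            LayerSpec("a", -0.5e-3, 0.0, 1e6, 0.0),
            LayerSpec("b", 0.0, 0.25e-3, 1e6, 0.0),
            LayerSpec("c", 0.25e-3, 0.5e-3, 1e6, 0.0)])
        r = stack_resultants(v)
        assert r.EA == pytest.approx(1.0, rel=1e-12)
        assert r.EI == pytest.approx(1.0 / 12.0 * 1e-6, rel=1e-12)
        assert r.ES == pytest.approx(0.0, abs=1e-15)

    def test_zero_area_fraction_contributes_nothing(self):
        layers = [LayerSpec("a", 0.0, 1e-4, 1e6, 0.0),
                  LayerSpec("mid", 1e-4, 2e-4, 2e6, 0.0),
                  LayerSpec("c", 2e-4, 3e-4, 3e6, -0.1)]
        full = stack_resultants(simple_valve(layers))
        zeroed = stack_resultants(simple_valve(
            layers[:2] + [LayerSpec("c", 2e-4, 3e-4, 3e6, -0.1,
                                    area_fraction=0.0)]))
        two_only = quadrature_resultants(simple_valve(
            layers[:2] + [LayerSpec("c", 2e-4, 3e-4, 1e-6, 0.0)]))
        assert zeroed.N0 == pytest.approx(0.0, abs=1e-18)
        assert zeroed.R0 == pytest.approx(0.0, abs=1e-18)
        assert zeroed.EA == pytest.approx(two_only[0], rel=1e-6)
        assert zeroed.EA < full.EA

    def test_reference_stack_matches_quadrature(self, hinged_valve):
        r = stack_resultants(hinged_valve)
        EA, ES, EI, N0, M0, R0 = quadrature_resultants(hinged_valve)
        assert r.EA == pytest.approx(EA, rel=1e-8)
        assert r.ES == pytest.approx(ES, rel=1e-8)
        assert r.EI == pytest.approx(EI, rel=1e-8)
        assert r.N0 == pytest.approx(N0, rel=1e-8)
        assert r.M0 == pytest.approx(M0, rel=1e-8)
        assert r.R0 == pytest.approx(R0, rel=1e-8)

    def test_empty_layers_rejected(self):
        with pytest.raises(ValueError):
            simple_valve([])


class TestEnergyAtCurvature:
    def test_stress_free_stack_minimises_at_zero(self):
        v = simple_valve([LayerSpec("a", 0.0, 1e-4, 1e6),
                          LayerSpec("b", 1e-4, 2e-4, 2e6),
                          LayerSpec("c", 2e-4, 3e-4, 5e6)])
        assert energy_at_curvature(v, 0.0) == pytest.approx(0.0, abs=1e-18)
        for k in (100.0, -100.0, 500.0):
            assert energy_at_curvature(v, k) > 0.0

    @pytest.mark.parametrize("E_ratio", [1.0, 0.25, 4.0])
    def test_timoshenko_bilayer_curvature(self, E_ratio):
        """Bimetal-strip closed form for equal-thickness layers:
        kappa* = 24 eps / (h (12 + (1 + n)^2 / n)), n = E_bottom/E_top,
        h the total thickness (reduces to 3 eps / (2 h) for n = 1)."""
        t2 = 50e-6                       # each layer
        E2, eps = 8e6, 0.05
        E1 = E_ratio * E2
        v = simple_valve([
            LayerSpec("bottom", 0.0, t2, E1, 0.0),
            LayerSpec("top", t2, 2 * t2, E2, -eps),
            LayerSpec("ghost", 2 * t2, 2 * t2 + 1e-9, 1.0, 0.0)])
        r = stack_resultants(v)
        Bhat = r.EI - r.ES ** 2 / r.EA
        bhat = r.M0 - r.ES * r.N0 / r.EA
        kappa_star = -bhat / Bhat
        n = E1 / E2
        h = 2 * t2
        kappa_timo = 24.0 * eps / (h * (12.0 + (1.0 + n) ** 2 / n))
        assert kappa_star == pytest.approx(kappa_timo, rel=1e-6)

    def test_axial_force_balance_at_optimum(self, hinged_valve):
        r = stack_resultants(hinged_valve)
        for k in (0.0, 500.0, 1315.0):
            e0 = optimal_axial_strain(hinged_valve, k)
            # net axial resultant N = EA e0 - ES k - N0 must vanish
            N = r.EA * e0 - r.ES * k - r.N0
            assert abs(N) < 1e-10

    def test_parabola_convexity(self, hinged_valve):
        ks = np.linspace(0.0, 4000.0, 41)
        u = np.array([energy_at_curvature(hinged_valve, k) for k in ks])
        assert np.all(np.diff(u, 2) > 0)

    def test_eps0_relaxation_never_increases_energy(self, hinged_valve):
        for k in (0.0, 800.0, 2000.0):
            relaxed = energy_at_curvature(hinged_valve, k)
            assert relaxed <= energy_density(hinged_valve, 0.0, k) + 1e-18


class TestFlattenCost:
    def test_zero_transverse_curvature_costs_nothing(self, ref):
        for geom in ("hinged", "boxed"):
            v = reference_valve(ref, geom)
            cs = CrossSectionSpec(v.cross_section.kind, 0.0,
                                  v.cross_section.hinge_stiffness,
                                  v.cross_section.lignified_subregions)
            assert flatten_cost(cs, v) == 0.0

    def test_free_hinges_cost_exactly_zero(self, hinged_valve):
        cs = CrossSectionSpec("hinged", 2000.0, 0.0,
                              hinged_valve.cross_section.lignified_subregions)
        assert flatten_cost(cs, hinged_valve) == 0.0

    def test_hinged_cost_negligible_vs_release(self, ref, hinged_valve):
        ls = landscape(hinged_valve)
        assert ls.flatten_cost <= 0.01 * ls.delta_E

    def test_boxed_cost_matches_quadrature(self, boxed_valve):
        cs = boxed_valve.cross_section
        E_lig = next(l.E for l in boxed_valve.layers if "endocarp" in l.name)
        z_mid = sum(0.5 * (lo + hi) * af for lo, hi, af in
                    cs.lignified_subregions) / sum(
                        af for _, _, af in cs.lignified_subregions)
        D = 0.0
        for lo, hi, af in cs.lignified_subregions:
            z = np.linspace(lo, hi, 20001)
            D += E_lig * af * np.trapezoid((z - z_mid) ** 2, z)
        expect = 0.5 * D * cs.kappa_t ** 2 * boxed_valve.w * boxed_valve.L
        assert flatten_cost(cs, boxed_valve) == pytest.approx(expect,
                                                              rel=1e-8)


class TestLandscape:
    def test_hinged_reference_coils_and_release(self, hinged_landscape):
        assert 3.0 <= hinged_landscape.coils <= 4.0
        assert hinged_landscape.delta_E > 0.0
        # minimiser beats every grid point
        i = np.argmin(hinged_landscape.U_flat)
        umin = hinged_landscape.valve.L * energy_at_curvature(
            hinged_landscape.valve, hinged_landscape.kappa_star)
        assert umin <= hinged_landscape.U_flat[i] + 1e-18

    def test_boxed_reference_fewer_coils_less_energy(self, boxed_valve,
                                                     hinged_landscape):
        ls = landscape(boxed_valve)
        assert round(ls.coils) == 1
        assert ls.delta_E < hinged_landscape.delta_E
        assert ls.coils < hinged_landscape.coils

    def test_no_rest_strain_means_no_coiling(self, ref):
        import copy
        r2 = copy.deepcopy(ref)
        r2.exocarp_rest_contraction = 1e-12
        v = reference_valve(r2)
        ls = landscape(v, kappa_max=100.0)
        assert ls.kappa_star == pytest.approx(0.0, abs=1e-6)
        assert ls.coils == pytest.approx(0.0, abs=1e-9)
        # only the (tiny) hinge-opening cost remains
        assert abs(ls.delta_E) < 1e-9

    def test_monotonicity_in_contraction_and_stiffness(self, ref):
        import copy
        kappas, energies = [], []
        for gamma in np.linspace(0.05, 0.45, 5):
            r2 = copy.deepcopy(ref)
            r2.exocarp_rest_contraction = float(gamma)
            ls = landscape(reference_valve(r2))
            kappas.append(ls.kappa_star)
            energies.append(ls.delta_E)
        assert np.all(np.diff(kappas) > 0)
        assert np.all(np.diff(energies) > 0)
        # stiffer endocarp-b rods (higher EI) uncoil the equilibrium
        kappas = []
        for t_rod in np.linspace(1.0, 12.0, 5):
            r2 = copy.deepcopy(ref)
            r2.endocarpb_rod_thickness = float(t_rod)
            kappas.append(landscape(reference_valve(r2)).kappa_star)
        assert np.all(np.diff(kappas) < 0)

    def test_bad_grid_rejected(self, hinged_valve):
        with pytest.raises(ValueError):
            landscape(hinged_valve, n_grid=2)
        with pytest.raises(ValueError):
            landscape(hinged_valve, kappa_max=-1.0)
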