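import numpy as np
import pytest

from podburst.cells import (CellGeom, CellMesh, WallMaterial,
                            _element_stiffness, _membrane_energy_grad,
                            build_cell, build_file, calibrate,
                            file_tension_force, indentation_stiffness,
                            inflate, osmotic_response, total_energy_grad,
                            wrinkle_state)

MATURE = CellGeom(50.0, 50.0, 20.0, 1.0)
IMMATURE = CellGeom(30.0, 20.0, 14.0, 1.0)
ATHALIANA = CellGeom(100.0, 20.0, 20.0, 1.0)
ISO = WallMaterial.isotropic(100.0)


class TestGeometryAndMaterial:
    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            CellGeom(0.0, 20.0, 14.0)
        with pytest.raises(ValueError):
            CellGeom(30.0, 20.0, 14.0, wall_thickness=-1.0)

    def test_material_validation(self):
        with pytest.raises(ValueError, match="positive"):
            WallMaterial(-5.0, 10.0)
        with pytest.raises(ValueError, match="nu"):
            WallMaterial(10.0, 10.0, nu=0.6)
        with pytest.raises(ValueError, match="isotropic"):
            WallMaterial(10.0, 20.0, model="isotropic")

    def test_depth_modulus_defaults_to_width(self):
        m = WallMaterial(100.0, 30.0)
        assert m.E_depth == 30.0


class TestMeshing:
    def test_flat_box_has_exact_volume_and_area(self):
        mesh = build_cell(IMMATURE, refinement=1, bulge=0.0)
        L, W, D = (d * 1e-6 for d in IMMATURE.dims)
        assert mesh.enclosed_volume() == pytest.approx(L * W * D, rel=1e-12)
        assert mesh.surface_area() == pytest.approx(
            2 * (L * W + L * D + W * D), rel=1e-12)
        assert np.allclose(mesh.bounding_dims(), [L, W, D], rtol=1e-12)

    def test_junction_dims_ignore_the_wall_bulge(self):
        # with an initial outward bulge the bounding box is larger but
        # the junction-to-junction frame still spans the box edges
        mesh = build_cell(MATURE, refinement=1, bulge=0.4)
        L, W, D = (d * 1e-6 for d in MATURE.dims)
        md = mesh.measured_dims()
        assert md[0] == pytest.approx(L, rel=1e-9)
        assert md[1] == pytest.approx(W, rel=1e-9)
        assert md[2] > D                     # depth includes the bulge
        assert mesh.bounding_dims()[0] > L

    def test_element_count_scales_with_refinement_squared(self):
        m1 = build_cell(IMMATURE, refinement=1)
        m2 = build_cell(IMMATURE, refinement=2)
        assert len(m2.tris) == 4 * len(m1.tris)

    def test_shared_wall_thickness_doubling(self):
        single = build_cell(IMMATURE, refinement=1, shared_walls=False,
                            outer_wall_factor=1.0, bulge=0.0)
        shared = build_cell(IMMATURE, refinement=1, shared_walls=True,
                            outer_wall_factor=4.0, bulge=0.0)
        t = IMMATURE.wall_thickness * 1e-6
        assert np.allclose(single.thickness, t)
        assert np.allclose(shared.thickness[shared.face == 1], 4 * t)
        for f in (0, 2, 3, 4, 5):
            assert np.allclose(shared.thickness[shared.face == f], 2 * t)

    def test_file_volume_and_internal_walls(self):
        n = 3
        mesh = build_file(IMMATURE, n, refinement=1)
        L, W, D = (d * 1e-6 for d in IMMATURE.dims)
        assert mesh.enclosed_volume() == pytest.approx(n * L * W * D,
                                                       rel=1e-12)
        internal = mesh.face == 6
        assert internal.sum() > 0
        assert not mesh.envelope[internal].any()
        assert mesh.envelope[~internal].all()

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError, match="refinement"):
            build_cell(IMMATURE, refinement=0)
        with pytest.raises(ValueError, match="n_cells"):
            build_file(IMMATURE, 0)


class TestElementOracle:
    @staticmethod
    def single_element(axes=(0, 1)):
        nodes = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                          [0.0, 1.0, 0.0]]) * 1e-5
        tris = np.array([[0, 1, 2]])
        return CellMesh(nodes, tris, np.array([axes]),
                        np.array([1e-6]), np.array([False]),
                        np.array([0]))

    def test_uniaxial_stretch_matches_plane_stress_closed_form(self):
        mesh = self.single_element()
        mat = WallMaterial(120.0, 40.0, nu=0.25)
        Q11, Q22, Q12, G = (q[0] for q in _element_stiffness(mesh, mat))
        lam = 1.07
        x = mesh.nodes.copy()
        x[:, 0] *= lam
        e11 = 0.5 * (lam ** 2 - 1.0)
        t, A = 1e-6, 0.5 * 1e-10
        E, grad = _membrane_energy_grad(x, mesh, _element_stiffness(mesh,
                                                                    mat))
        assert E == pytest.approx(0.5 * Q11 * e11 ** 2 * t * A, rel=1e-12)

    def test_rest_state_is_stress_free(self):
        mesh = self.single_element()
        E, G = _membrane_energy_grad(mesh.nodes, mesh,
                                     _element_stiffness(mesh, ISO))
        # a characteristic elastic force for this element is Q t l ~ 1e-3 N;
        # the rest state must be force-free at machine precision vs that
        assert E < 1e-25
        assert np.abs(G).max() < 1e-15

    def test_energy_gradient_is_consistent(self, rng):
        mesh = build_cell(IMMATURE, refinement=1)
        Q = _element_stiffness(mesh, WallMaterial(80.0, 30.0))
        x = mesh.nodes * (1.0 + 0.01 * rng.standard_normal(
            mesh.nodes.shape))
        _, G = total_energy_grad(x, mesh, Q, 0.5e6)
        h = 1e-10
        for idx in [(3, 0), (17, 2), (40, 1)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            Ep, _ = total_energy_grad(xp, mesh, Q, 0.5e6)
            Em, _ = total_energy_grad(xm, mesh, Q, 0.5e6)
            assert (Ep - Em) / (2 * h) == pytest.approx(G[idx], rel=5e-4)


class TestInflation:
    def test_zero_pressure_is_identity(self):
        mesh = build_cell(IMMATURE, refinement=1)
        out = inflate(mesh, ISO, 0.0)
        assert np.abs(out.nodes - mesh.nodes).max() < 1e-15

    def test_negative_pressure_rejected(self):
        mesh = build_cell(IMMATURE, refinement=1)
        with pytest.raises(ValueError):
            inflate(mesh, ISO, -0.1)

    def test_cube_with_isotropic_walls_deforms_symmetrically(self):
        cube = CellGeom(20.0, 20.0, 20.0, 1.0)
        mesh = build_cell(cube, refinement=1, shared_walls=False,
                          outer_wall_factor=1.0)
        out = inflate(mesh, ISO, 0.5)
        change = out.bounding_dims() / mesh.bounding_dims() - 1.0
        assert change.max() - change.min() < 0.005 * (1 + change.max())

    def test_equilibrium_gradient_residual_is_small(self):
        mesh = build_cell(IMMATURE, refinement=1)
        mat = WallMaterial(200.0, 60.0)
        out = inflate(mesh, mat, 0.7)
        Q = _element_stiffness(out, mat)
        branch = wrinkle_state(out.nodes, out, Q)
        _, G = total_energy_grad(out.nodes, out, Q, 0.7e6, branch)
        F_char = 0.7e6 * out.area0.sum() / out.n_nodes
        assert np.abs(G).max() < 5e-2 * F_char

    def test_isotropic_slender_cell_lengthens(self):
        r = osmotic_response(ATHALIANA, ISO, 0.0, 0.7, refinement=1)
        hi = np.asarray(r.dims_high)
        lo = np.asarray(r.dims_low)
        assert hi[0] > lo[0]
        assert r.volume_percent_change > 0.0

    def test_isotropic_square_cell_shortens_slightly(self):
        r = osmotic_response(MATURE, ISO, 0.0, 0.7, refinement=1)
        assert -10.0 < r.length_change < 0.0
        assert r.depth_change > 0.0
        assert r.volume_percent_change > 0.0

    def test_anisotropy_deepens_the_shortening(self):
        iso = osmotic_response(MATURE, ISO, 0.0, 0.7, refinement=1)
        aniso = osmotic_response(MATURE, WallMaterial(500.0, 20.0), 0.0,
                                 0.7, refinement=1)
        assert aniso.length_change < iso.length_change

    def test_pressure_ordering_rejected(self):
        with pytest.raises(ValueError):
            osmotic_response(MATURE, ISO, 0.7, 0.7, refinement=1)

    def test_refinement_convergence(self):
        mat = WallMaterial(200.0, 60.0)
        r1 = osmotic_response(IMMATURE, mat, 0.0, 0.7, refinement=1)
        r2 = osmotic_response(IMMATURE, mat, 0.0, 0.7, refinement=2)
        for a, b in zip(r1.percent_change, r2.percent_change):
            assert abs(a - b) < 2.0


class TestIndentation:
    def test_stiffness_increases_with_pressure(self):
        ks = [indentation_stiffness(IMMATURE, WallMaterial(200.0, 60.0), P,
                                    refinement=1).stiffness
              for P in (0.35, 0.7, 1.05)]
        assert ks[0] < ks[1] < ks[2]

    def test_mature_cell_stiffer_than_immature(self):
        mat = WallMaterial(200.0, 60.0)
        k_i = indentation_stiffness(IMMATURE, mat, 0.7,
                                    refinement=1).stiffness
        k_m = indentation_stiffness(MATURE, mat, 0.7,
                                    refinement=1).stiffness
        assert k_m > k_i


class TestCalibration:
    def test_volume_only_target_is_non_identifiable(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            calibrate({"volume": 50.0}, MATURE,
                      free=("E_width", "E_length"))

    def test_more_params_than_targets_rejected(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            calibrate({"length": -12.0}, MATURE,
                      free=("E_width", "E_length"))

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            calibrate({"girth": 3.0}, MATURE)

    def test_noise_free_recovery_within_2_percent(self):
        truth = WallMaterial(250.0, 50.0)
        r = osmotic_response(IMMATURE, truth, 0.0, 0.7, refinement=1)
        targets = {"length": r.percent_change[0],
                   "width": r.percent_change[1],
                   "depth": r.percent_change[2]}
        out = calibrate(targets, IMMATURE, free=("E_width", "E_length"),
                        refinement=1, material0=WallMaterial(150.0, 80.0))
        assert out["material"].E_length == pytest.approx(250.0, rel=0.02)
        assert out["material"].E_width == pytest.approx(50.0, rel=0.02)


class TestFileForce:
    def test_zero_pressure_transmits_no_force(self):
        out = file_tension_force(IMMATURE, WallMaterial(200.0, 60.0), 0.0,
                                 n_cells=2, refinement=1)
        assert abs(out["force_per_file"]) < 1e-9

    def test_force_monotone_in_constrained_length(self):
        mat = WallMaterial(200.0, 60.0)
        L = IMMATURE.length * 2
        forces = [file_tension_force(IMMATURE, mat, 0.7, n_cells=2,
                                     refinement=1,
                                     constrained_length_um=f * L)
                  ["force_per_file"] for f in (1.0, 1.02, 1.04)]
        assert forces[0] < forces[1] < forces[2]

    def test_n_files_scaling(self):
        mat = WallMaterial(200.0, 60.0)
        out = file_tension_force(IMMATURE, mat, 0.7, n_cells=2,
                                 n_files=40.0, refinement=1)
        assert out["total_force"] == pytest.approx(
            40.0 * out["force_per_file"], rel=1e-12)
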