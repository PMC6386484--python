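"""Finite-volume conduction solver: construction, conservation, oracles."""

import numpy as np
import pytest

from tenssim.fibers import FiberGeometry, FiberTrajectory, parallel_fiber
from tenssim.geometry import ElectrodeArray, FingerGeometry, TissueConductivities
from tenssim.volume_conductor import (BasisFieldSet, ExtracellularProfile,
                                      Field3D, NailPatch, build_finger_model,
                                      sample_along_fiber, solve_basis_potentials,
                                      superpose)


@pytest.fixture(scope="module")
def small_basis(small_model):
    return solve_basis_potentials(small_model)


class TestBuildFingerModel:
    def test_study_geometry_has_three_tissues_and_patches(self):
        model = build_finger_model(resolution=0.3e-3)
        labels = set(np.unique(model.labels)) - {0}
        assert labels == {1, 2, 3}  # skin, fat, bone
        assert len(model.electrode_faces) == 8
        assert len(model.ground_faces) > 0

    def test_bone_volume_close_to_analytic_cylinder(self):
        model = build_finger_model(resolution=0.3e-3)
        geo = model.geometry
        # bone occupies the cylindrical section beyond the tip cap
        analytic = np.pi * geo.bone_radius**2 * (geo.finger_length - geo.radius)
        assert model.tissue_volume(3) == pytest.approx(analytic, rel=0.10)

    def test_degenerate_skin_rejected(self):
        with pytest.raises(ValueError):
            FingerGeometry(skin_thickness=0.0)

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolve"):
            build_finger_model(resolution=1.0e-3)  # skin is 0.9 mm

    def test_array_outside_pad_rejected(self):
        array = ElectrodeArray(longitudinal_offset=0.075)
        with pytest.raises(ValueError, match="footprint"):
            build_finger_model(array=array, resolution=0.5e-3)

    def test_patches_disjoint(self, small_model):
        all_faces = np.concatenate(small_model.electrode_faces)
        assert len(np.unique(all_faces)) == len(all_faces)
        assert not set(all_faces) & set(small_model.ground_faces)


class TestSolver:
    def test_current_conservation_through_ground(self, small_basis):
        # unit current in must leave through the grounded nail
        for flux in small_basis.meta["ground_flux_A"]:
            assert flux == pytest.approx(1.0, abs=1e-8)

    def test_ground_patch_is_the_potential_sink(self, small_basis):
        # the Dirichlet zero sits on the grounded faces; the adjacent cell
        # centres carry only the half-cell ohmic drop of the return current,
        # far below the potentials near the injecting electrode
        model = small_basis.model
        gidx = np.unravel_index(model.ground_faces, model.shape)
        for k in range(small_basis.n_electrodes):
            ground_vals = small_basis.fields[k][gidx]
            assert np.all(ground_vals > 0)  # current flows out, not in
            assert np.abs(ground_vals).max() < 0.15 * np.nanmax(
                np.abs(small_basis.fields[k])
            )

    def test_zero_currents_give_zero_field(self, small_basis):
        f = superpose(small_basis, np.zeros(small_basis.n_electrodes))
        assert np.nanmax(np.abs(f.values)) == 0.0

    def test_superposition_additive_to_machine_precision(self, small_basis, rng):
        n = small_basis.n_electrodes
        a = rng.uniform(-2e-3, 2e-3, n)
        b = rng.uniform(-2e-3, 2e-3, n)
        f_ab = superpose(small_basis, a + b).values
        f_sum = superpose(small_basis, a).values + superpose(small_basis, b).values
        np.testing.assert_allclose(f_ab, f_sum, rtol=1e-12, atol=1e-12)

    def test_out_of_range_current_names_electrode(self, small_basis):
        currents = np.zeros(small_basis.n_electrodes)
        currents[2] = 6e-3
        with pytest.raises(ValueError, match="electrode 3"):
            superpose(small_basis, currents)

    def test_iterative_route_matches_direct(self, small_model, small_basis):
        # BiCGStab at the 1e-12 residual must agree with the factorization
        iterative = solve_basis_potentials(small_model, method="bicgstab")
        act = small_model.active
        for k in range(small_basis.n_electrodes):
            a = small_basis.fields[k][act]
            b = iterative.fields[k][act]
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-8 * np.abs(a).max())
        assert all(i > 0 for i in iterative.meta["iterations"])
        assert max(iterative.meta["residuals"]) < 1e-11

    def test_invalid_tolerance_rejected(self, small_model):
        with pytest.raises(ValueError):
            solve_basis_potentials(small_model, tolerance=0.0)


class TestHalfSpaceOracle:
    def test_small_electrode_matches_point_source_form(self):
        # uniform-conductivity wide-cylinder variant approximating a half
        # space; a ~1.3 mm electrode injects 1 A.  The finite domain adds a
        # constant return-path offset, so the closed form I/(2 pi sigma r)
        # is compared through potential differences to a 9 mm reference
        # depth, at depths well beyond the electrode size.
        sigma = 0.05
        geo = FingerGeometry(finger_diameter=0.044, bone_diameter=0.004,
                             skin_thickness=0.004, finger_length=0.048,
                             spherical_tip=False)
        cond = TissueConductivities(sigma, sigma, sigma)
        array = ElectrodeArray(n_electrodes=1, electrode_width=0.0013,
                               electrode_length=0.0013, pitch=0.003,
                               longitudinal_offset=0.024)
        nail = NailPatch(x_start=0.002, length=0.010, width=0.010)
        model = build_finger_model(geo, cond, array, resolution=0.00125, nail=nail)
        basis = solve_basis_potentials(model)
        interp = Field3D(basis.fields[0], model).interpolator()
        r_axis = geo.radius
        ref = 0.009
        phi_ref = float(interp([[0.024, 0.0, -r_axis + ref]])[0])
        for depth in (0.003, 0.004, 0.005):
            phi = float(interp([[0.024, 0.0, -r_axis + depth]])[0])
            analytic = (1.0 / (2 * np.pi * sigma)) * (1 / depth - 1 / ref)
            assert (phi - phi_ref) == pytest.approx(analytic, rel=0.15)


class TestFieldStructure:
    def test_depth_monotonic_below_single_electrode(self, coarse_env):
        basis = coarse_env.basis
        k = 3
        interp = Field3D(basis.fields[k], basis.model).interpolator()
        x = basis.model.array.centres[k]
        r = basis.model.geometry.radius
        depths = np.arange(1.0e-3, 3.01e-3, 0.25e-3)
        vals = interp([[x, 0.0, -r + d] for d in depths])
        assert np.all(np.diff(np.abs(vals)) < 0)

    def test_mirror_symmetry_of_sampled_profile(self):
        # symmetric configuration: flat-tipped cylinder with the array and
        # the nail both centred at mid-length; mirroring the currents about
        # the array centre must mirror the profile on a centred fibre
        geo = FingerGeometry(finger_diameter=0.012, bone_diameter=0.003,
                             skin_thickness=0.0015, finger_length=0.040,
                             spherical_tip=False)
        array = ElectrodeArray(n_electrodes=4, electrode_width=0.0015,
                               electrode_length=0.006, pitch=0.003,
                               longitudinal_offset=0.0155)
        nail = NailPatch(x_start=0.015, length=0.010, width=0.006)
        model = build_finger_model(geo, TissueConductivities(), array,
                                   resolution=0.001, nail=nail)
        basis = solve_basis_potentials(model)
        x_nodes = np.linspace(0.008, 0.032, 49)
        traj = FiberTrajectory(
            points=np.column_stack(
                [x_nodes, np.zeros_like(x_nodes),
                 np.full_like(x_nodes, -geo.radius + 0.002)]
            ),
            arc_length=x_nodes - x_nodes[0],
            tag="symmetric-test",
        )
        currents = np.array([2.0, -1.0, 0.5, -1.5]) * 1e-3
        fwd = sample_along_fiber(superpose(basis, currents), traj).v_e
        mirrored = sample_along_fiber(superpose(basis, currents[::-1]), traj).v_e
        scale = np.abs(fwd).max()
        np.testing.assert_allclose(mirrored, fwd[::-1], atol=0.02 * scale)

    def test_grid_convergence_is_cauchy(self):
        # successive refinements must produce shrinking RMS differences of
        # the potential sampled along a fibre
        geo = FingerGeometry(finger_diameter=0.012, bone_diameter=0.003,
                             skin_thickness=0.0015, finger_length=0.030,
                             spherical_tip=False)
        array = ElectrodeArray(n_electrodes=2, electrode_width=0.0016,
                               electrode_length=0.006, pitch=0.003,
                               longitudinal_offset=0.012)
        nail = NailPatch(x_start=0.002, length=0.008, width=0.006)
        x_nodes = np.linspace(0.006, 0.024, 37)
        traj = FiberTrajectory(
            points=np.column_stack(
                [x_nodes, np.zeros_like(x_nodes),
                 np.full_like(x_nodes, -geo.radius + 0.002)]
            ),
            arc_length=x_nodes - x_nodes[0],
            tag="convergence-test",
        )
        currents = np.array([1.0, -1.0]) * 1e-3
        profiles = []
        for res in (1.5e-3, 1.0e-3, 0.6e-3):
            model = build_finger_model(geo, TissueConductivities(), array,
                                       resolution=res, nail=nail)
            basis = solve_basis_potentials(model)
            profiles.append(
                sample_along_fiber(superpose(basis, currents), traj).v_e
            )
        d_coarse = np.sqrt(np.mean((profiles[1] - profiles[0]) ** 2))
        d_fine = np.sqrt(np.mean((profiles[2] - profiles[1]) ** 2))
        assert d_fine < d_coarse
        # and the finest pair agrees within 5 % RMS of the profile scale
        assert d_fine < 0.05 * np.sqrt(np.mean(profiles[2] ** 2))


class TestSampling:
    def test_zero_field_gives_zero_profile(self, small_basis):
        model = small_basis.model
        f = superpose(small_basis, np.zeros(small_basis.n_electrodes))
        fiber = FiberGeometry(span=0.012)
        traj = parallel_fiber(0.002, model.geometry, fiber)
        profile = sample_along_fiber(f, traj)
        assert np.all(profile.v_e == 0.0)
        assert len(profile) == traj.n_nodes

    def test_constant_field_sampled_exactly(self, small_model):
        f = Field3D(np.full(small_model.shape, 3.7), small_model)
        fiber = FiberGeometry(span=0.012)
        traj = parallel_fiber(0.002, small_model.geometry, fiber)
        np.testing.assert_allclose(sample_along_fiber(f, traj).v_e, 3.7)

    def test_node_outside_volume_reports_index(self, small_model):
        f = Field3D(np.zeros(small_model.shape), small_model)
        pts = np.array([[0.01, 0.0, -0.004], [0.01, 0.0, 0.5]])
        traj = FiberTrajectory(points=pts, arc_length=np.array([0.0, 1.0]),
                               tag="bad")
        with pytest.raises(ValueError, match="node 1"):
            sample_along_fiber(f, traj)

    def test_profile_shape_validation(self):
        with pytest.raises(ValueError):
            ExtracellularProfile(np.zeros(5), np.zeros(4))
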