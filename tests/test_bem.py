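"""Boundary-element solver: operator identities and sphere-oracle physics.

The independent references are (a) the spectral series solution for the
surface potential of a dipole in a homogeneous sphere and (b) the Sarvas
closed form for its external magnetic field.
"""

import numpy as np
import pytest

from spinefield.analytic import DipoleSource, SphereModelSpec, b_sphere
from spinefield.bem import (BemSolution, Compartment, ConductorModel,
                            build_bem_system, b_primary, b_volume, b_total,
                            conductor_model, field_decomposition,
                            solve_boundary_potentials)
from spinefield.geometry import SensorArray
from spinefield.integrals import double_layer_matrix
from spinefield.metrics import relative_error, squared_correlation
from spinefield.sphere_series import sphere_surface_potential

from conftest import SPHERE_RADIUS, SPHERE_SIGMA, make_sphere_mesh


def sphere_conductor(mesh, sigma=SPHERE_SIGMA):
    return ConductorModel([Compartment(mesh, sigma, 0.0, "sphere")], tag="1c")


class TestDoubleLayerOperator:
    def test_solid_angle_row_sums(self, sphere_mesh):
        """Row sums realise the solid-angle identity: 1 from inside, 0 from
        outside (to quadrature exactness), the interior vertex angle on the
        surface."""
        W = double_layer_matrix(np.array([[0.0, 0, 0], [15.0, -22.0, 40.0],
                                          [300.0, 0, 0]]),
                                sphere_mesh.vertices, sphere_mesh.faces)
        assert W.sum(axis=1) == pytest.approx([1.0, 1.0, 0.0], abs=1e-6)

    def test_vertex_row_sums_are_interior_angles(self, sphere_mesh):
        Wv = double_layer_matrix(sphere_mesh.vertices, sphere_mesh.vertices,
                                 sphere_mesh.faces)
        rows = Wv.sum(axis=1)
        # convex polyhedron: interior vertex solid angle below the smooth 2pi
        assert np.all(rows > 0.25) and np.all(rows < 0.5)
        # nearly smooth discretisation: close to 1/2
        assert np.abs(rows - 0.5).max() < 0.05

    def test_smoke_system_size(self, sphere_mesh, sphere_system):
        assert sphere_system.size == sphere_mesh.n_vertices == 642


class TestBoundaryPotentials:
    def test_matches_analytic_series(self, sphere_mesh, sphere_system):
        """Tangential dipole at 70% radius: collocation potential agrees
        with the spectral solution (additive constant removed)."""
        dip = DipoleSource([0, 0, 0.7 * SPHERE_RADIUS], [1.0, 0, 0])
        phi = solve_boundary_potentials(sphere_system, dip).phi[:, 0]
        ref = sphere_surface_potential(sphere_mesh.vertices, dip.position,
                                       dip.moment, SPHERE_RADIUS, SPHERE_SIGMA)
        a, b = phi - phi.mean(), ref - ref.mean()
        assert relative_error(a, b) < 0.02

    def test_solution_constant_invariance(self, sphere_system,
                                          external_sensors):
        """The deflated constant is non-physical: re-deflating a shifted
        potential recovers the solution exactly, and a constant of the
        solution's own scale perturbs the volume field only at the
        quadrature level (a closed surface integrates a constant to ~0)."""
        dip = DipoleSource([0, 0, 50.0], [1.0, 0, 0])
        sol = solve_boundary_potentials(sphere_system, dip)
        c = float(np.abs(sol.phi).max())
        redeflated = (sol.phi + c) - np.mean(sol.phi + c)
        assert np.allclose(redeflated, sol.phi - sol.phi.mean(),
                           rtol=0.0, atol=1e-8 * c)
        shifted = BemSolution(sol.phi + c, sol.positions, sol.moments)
        bv = b_volume(sol, sphere_system, external_sensors)
        bv2 = b_volume(shifted, sphere_system, external_sensors)
        assert np.abs(bv2 - bv).max() <= 1e-2 * np.abs(bv).max()

    def test_linearity_in_moment(self, sphere_system):
        d1 = DipoleSource([0, 0, 50.0], [1.0, 2.0, 0.5])
        d2 = DipoleSource([0, 0, 50.0], [2.0, 4.0, 1.0])
        p1 = solve_boundary_potentials(sphere_system, d1).phi
        p2 = solve_boundary_potentials(sphere_system, d2).phi
        assert np.allclose(p2, 2.0 * p1, rtol=1e-12, atol=0.0)

    def test_dipole_outside_rejected(self, sphere_system):
        with pytest.raises(ValueError):
            solve_boundary_potentials(
                sphere_system, DipoleSource([0, 0, 200.0], [1.0, 0, 0]))

    def test_near_boundary_warning(self, sphere_system):
        with pytest.warns(UserWarning, match="vertex spacing"):
            solve_boundary_potentials(
                sphere_system, DipoleSource([0, 0, 97.0], [1.0, 0, 0]))


class TestMagneticField:
    def test_sphere_oracle_and_refinement(self, external_sensors):
        """Total BEM field matches the closed form for tangential dipoles up
        to eccentricity 0.8, improving under mesh refinement."""
        spec = SphereModelSpec([0.0, 0, 0])
        errs = {}
        for sub in (2, 3):
            system = build_bem_system(
                sphere_conductor(make_sphere_mesh(sub)))
            worst = 0.0
            for ecc in (0.4, 0.7, 0.8):
                dip = DipoleSource([0, 0, ecc * SPHERE_RADIUS], [1.0, 0, 0])
                _, _, bt = field_decomposition(system, dip, external_sensors)
                worst = max(worst, relative_error(
                    bt, b_sphere(spec, dip, external_sensors)))
            errs[sub] = worst
        assert errs[3] < 0.02
        assert errs[3] < errs[2]

    def test_radial_dipole_cancellation(self, sphere_system,
                                        external_sensors):
        dip = DipoleSource([0, 0, 70.0], [0, 0, 1.0])
        bp, bv, bt = field_decomposition(sphere_system, dip, external_sensors)
        assert np.linalg.norm(bt) / (np.linalg.norm(bp) + np.linalg.norm(bt)) < 0.03

    def test_decomposition_sum_identity(self, sphere_system,
                                        external_sensors):
        dip = DipoleSource([20.0, 10.0, 40.0], [1.0, -1.0, 2.0])
        bp, bv, bt = field_decomposition(sphere_system, dip, external_sensors)
        assert np.array_equal(bt, bp + bv)

    def test_zero_jump_surface_contributes_exactly_nothing(
            self, sphere_mesh, external_sensors):
        """A surface with equal conductivity on both sides drops out of the
        Geselowitz sum exactly."""
        inner = make_sphere_mesh(2, radius=50.0)
        model = ConductorModel([
            Compartment(sphere_mesh, SPHERE_SIGMA, 0.0, "outer"),
            Compartment(inner, SPHERE_SIGMA, SPHERE_SIGMA, "inner")],
            tag="2c")
        system = build_bem_system(model)
        phi = np.zeros((system.size, 1))
        phi[system.slices[1]] = 3.3e-7     # potential only on the zero-jump shell
        fake = BemSolution(phi, np.array([[0.0, 0, 30.0]]),
                           np.array([[1.0, 0, 0]]))
        assert np.all(b_volume(fake, system, external_sensors) == 0.0)

    def test_concentric_shell_invariance(self, sphere_mesh, sphere_system,
                                         external_sensors):
        """External field of a spherical conductor is blind to any internal
        spherically symmetric conductivity structure."""
        inner = make_sphere_mesh(2, radius=50.0)
        model = ConductorModel([
            Compartment(sphere_mesh, SPHERE_SIGMA, 0.0, "outer"),
            Compartment(inner, 5.0 * SPHERE_SIGMA, SPHERE_SIGMA, "inner")],
            tag="2c")
        system2 = build_bem_system(model)
        dip = DipoleSource([0, 0, 75.0], [1.0, 0, 0])
        _, _, b1 = field_decomposition(sphere_system, dip, external_sensors)
        _, _, b2 = field_decomposition(system2, dip, external_sensors)
        assert relative_error(b1, b2) < 0.03

    def test_conductivity_rescaling_leaves_field_unchanged(
            self, sphere_mesh, external_sensors):
        dip = DipoleSource([0, 0, 60.0], [0.5, 1.0, 0])
        fields = []
        for k in (1.0, 10.0):
            system = build_bem_system(
                sphere_conductor(sphere_mesh, sigma=k * SPHERE_SIGMA))
            sol = solve_boundary_potentials(system, dip)
            fields.append(b_total(sol, system, external_sensors))
            # potentials scale as 1/k ...
            if k != 1.0:
                assert np.allclose(sol.phi * k, phi_ref, rtol=1e-9)
            else:
                phi_ref = sol.phi
        # ... and the magnetic field not at all
        assert np.allclose(fields[0], fields[1], rtol=1e-9)

    def test_sensor_on_boundary_rejected(self, sphere_system):
        on_surface = SensorArray(np.array([[0.0, 0.0, SPHERE_RADIUS]]),
                                 np.tile(np.eye(3), (1, 1, 1)))
        dip = DipoleSource([0, 0, 30.0], [1.0, 0, 0])
        sol = solve_boundary_potentials(sphere_system, dip)
        with pytest.raises(ValueError, match="on the integration surface"):
            b_volume(sol, sphere_system, on_surface)


class TestIsolatedSourceApproach:
    def test_isolated_matches_direct_on_separated_geometry(
            self, sphere_mesh, external_sensors):
        inner = make_sphere_mesh(2, radius=50.0)
        model = ConductorModel([
            Compartment(sphere_mesh, 0.23, 0.0, "outer"),
            Compartment(inner, 0.33, 0.23, "cord")],
            tag="2c", isolation_index=1)
        system = build_bem_system(model)
        dip = DipoleSource([0, 0, 30.0], [1.0, 0, 0])
        direct = solve_boundary_potentials(system, dip, isolated=False)
        isolated = solve_boundary_potentials(system, dip, isolated=True)
        assert isolated.isolated
        b1 = b_total(direct, system, external_sensors)
        b2 = b_total(isolated, system, external_sensors)
        assert relative_error(b1, b2) < 0.05

    def test_isolation_requires_configuration(self, sphere_system):
        with pytest.raises(ValueError, match="isolation"):
            solve_boundary_potentials(
                sphere_system, DipoleSource([0, 0, 30.0], [1.0, 0, 0]),
                isolated=True)


class TestModelConstruction:
    def test_unknown_tag_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            conductor_model(small_bundle, "2c")

    def test_default_conductivities(self, small_bundle):
        model = conductor_model(small_bundle, "5c", isolated=True)
        sigma = {c.name: c.sigma_in for c in model.compartments}
        assert sigma == {"torso": 0.23, "heart": 0.62, "lungs": 0.05,
                         "bone": 0.007, "cord": 0.33}
        cord = model.compartments[-1]
        assert cord.name == "cord" and cord.sigma_out == 0.007
        assert model.isolation_index == len(model.compartments) - 1

    def test_five_compartment_system_size(self, small_bundle):
        model = conductor_model(small_bundle, "5c")
        expected = sum(c.mesh.n_vertices for c in model.compartments)
        system = build_bem_system(model)
        assert system.size == expected

    def test_nonpositive_sigma_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            conductor_model(small_bundle, "1c", {"torso": -0.2})

    def test_outer_surface_needs_vacuum_outside(self, sphere_mesh):
        model = ConductorModel(
            [Compartment(sphere_mesh, 0.23, 0.1, "outer")], tag="bad")
        with pytest.raises(ValueError, match="sigma_out"):
            model.validate()
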