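import warnings

import numpy as np
import pytest

from aotsim.beam import FocusedBeam
from aotsim.constants import C_M_PER_S
from aotsim.geometry import EllipticalCylinder, voxelize
from aotsim.materials import MetamaterialSpec, material_preset
from aotsim.scattering import CoupledDipoleSolver
from aotsim.trap_mechanics import (axial_landscape, dipole_force, tilt_torque,
                                   torque_curve, wrench)

from _oracles import mie_cross_sections


def make_solver(cyl, spacing, n_medium=1.33):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lat = voxelize(cyl, spacing)
    return CoupledDipoleSolver(lat, n_medium=n_medium)


class TestWrench:
    def test_plane_wave_force_matches_mie_radiation_pressure(
            self, mie_sphere_solution):
        pw, sol = mie_sphere_solution
        _, _, _, c_pr = mie_cross_sections(1.45, 1.33, 150.0, 1064.0)
        w = wrench(sol)
        f_pred = 1.33 * pw.intensity_w_per_m2 * c_pr / C_M_PER_S * 1e12
        assert w.F[2] == pytest.approx(f_pred, rel=0.10)
        # transverse force and torque vanish by symmetry
        assert np.all(np.abs(w.F[:2]) < 1e-6 * abs(w.F[2]))

    def test_stress_tensor_agrees_with_dipole_summation(self, flagship_solver,
                                                        trap_beam):
        sol = flagship_solver.solve(trap_beam, offset_nm=(0, 0, 300.0))
        f_mst = wrench(sol).F
        f_dip = dipole_force(sol)
        assert np.linalg.norm(f_mst - f_dip) / np.linalg.norm(f_mst) < 0.05

    def test_wrench_linear_in_power(self, flagship_solver):
        b1 = FocusedBeam(power_specimen_mw=6.3)
        b2 = FocusedBeam(power_specimen_mw=12.6)
        w1 = wrench(flagship_solver.solve(b1.rotate_polarization(-0.5),
                                          offset_nm=(0, 0, 200.0)))
        w2 = wrench(flagship_solver.solve(b2.rotate_polarization(-0.5),
                                          offset_nm=(0, 0, 200.0)))
        atol_f = 1e-9 * np.linalg.norm(w2.F)
        atol_t = 1e-9 * np.linalg.norm(w2.tau)
        np.testing.assert_allclose(w2.F, 2.0 * w1.F, rtol=1e-9, atol=atol_f)
        np.testing.assert_allclose(w2.tau, 2.0 * w1.tau, rtol=1e-9, atol=atol_t)

    def test_quadrature_refinement_stable(self, flagship_solver, trap_beam):
        sol = flagship_solver.solve(trap_beam, offset_nm=(0, 0, 200.0))
        w1 = wrench(sol, n_theta=26, n_phi=52)
        w2 = wrench(sol, n_theta=37, n_phi=74)   # ~2x nodes
        assert np.linalg.norm(w2.F - w1.F) / np.linalg.norm(w2.F) < 0.01

    def test_integration_sphere_must_enclose_particle(self, flagship_solver,
                                                      trap_beam):
        sol = flagship_solver.solve(trap_beam)
        with pytest.raises(ValueError):
            wrench(sol, radius_nm=100.0)


class TestTorqueSymmetries:
    @pytest.fixture(scope="class")
    def circular_solver(self):
        cyl = EllipticalCylinder(a=160.0, b=160.0, h=400.0,
                                 material=material_preset("sio2"))
        return make_solver(cyl, 40.0)

    @pytest.fixture(scope="class")
    def elliptical_tau_scale(self, flagship_solver, trap_beam):
        sol = flagship_solver.solve(trap_beam.rotate_polarization(-np.pi / 4),
                                    offset_nm=(0, 0, 200.0))
        return abs(wrench(sol).tau[2])

    def test_circular_cylinder_generates_no_torque(self, circular_solver,
                                                   trap_beam,
                                                   elliptical_tau_scale):
        """A circular cross-section produces no alignment torque at any
        polarization angle (compared against the elliptical torque scale)."""
        for psi in (0.0, np.pi / 8, np.pi / 4):
            sol = circular_solver.solve(trap_beam.rotate_polarization(psi),
                                        offset_nm=(0, 0, 200.0))
            tau_z = wrench(sol).tau[2]
            assert abs(tau_z) < 1e-3 * elliptical_tau_scale

    def test_torque_odd_in_misalignment(self, flagship_solver, trap_beam):
        sols = [flagship_solver.solve(trap_beam.rotate_polarization(s * 0.5),
                                      offset_nm=(0, 0, 200.0))
                for s in (+1, -1)]
        t1, t2 = (wrench(s).tau[2] for s in sols)
        assert t1 == pytest.approx(-t2, rel=1e-6)

    def test_weak_anisotropy_torque_is_sinusoidal(self):
        """Weakly elliptical cross-section: tau_z(alpha) ~ A sin 2alpha.

        The eccentricity is kept mild but large enough that the cubic dipole
        lattice resolves the a-b asymmetry at the test spacing."""
        cyl = EllipticalCylinder(a=100.0, b=89.0, h=200.0,
                                 material=material_preset("sio2"))
        solver = make_solver(cyl, 20.0)
        beam = FocusedBeam(power_specimen_mw=12.6)
        alphas = np.array([0.2, 0.5, 0.8, 1.1, 1.35, 1.5])
        taus = []
        for a in alphas:
            sol = solver.solve(beam.rotate_polarization(-a),
                               offset_nm=(0, 0, 0.0))
            taus.append(wrench(sol).tau[2])
        taus = np.array(taus)
        A = np.sum(taus * np.sin(2 * alphas)) / np.sum(np.sin(2 * alphas) ** 2)
        ss_res = np.sum((taus - A * np.sin(2 * alphas)) ** 2)
        ss_tot = np.sum((taus - taus.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        assert A < 0  # restoring


class TestTorqueCurve:
    @pytest.fixture(scope="class")
    def curve(self, flagship_cylinder, trap_beam, flagship_solver):
        return torque_curve(flagship_cylinder, trap_beam, z_eq_nm=100.0,
                            solver=flagship_solver, n_alpha=8)

    def test_zero_at_symmetry_axes(self, curve, flagship_cylinder, trap_beam,
                                   flagship_solver):
        tau0 = curve.tau_z[0]
        sol = flagship_solver.solve(trap_beam.rotate_polarization(-np.pi / 2),
                                    offset_nm=(0, 0, 100.0))
        tau90 = wrench(sol).tau[2]
        assert abs(tau0) < 1e-3 * curve.tau_max
        assert abs(tau90) < 1e-3 * curve.tau_max

    def test_restoring_sign_convention(self, curve):
        small = (curve.alpha_grid > 0) & (curve.alpha_grid < np.pi / 2)
        assert np.all(curve.tau_z[small] < 0)

    def test_peak_location_bracketed(self, curve):
        # fold onto [0, pi/2]: tau_z is odd about alpha = pi/2
        folded = np.minimum(curve.alpha_grid, np.pi - curve.alpha_grid)
        i = np.argmax(np.abs(curve.tau_z))
        assert np.pi / 8 <= folded[i] <= 3 * np.pi / 8


class TestAxialLandscape:
    @pytest.fixture(scope="class")
    def landscape(self, flagship_cylinder, trap_beam, flagship_solver):
        return axial_landscape(flagship_cylinder, trap_beam,
                               z_range_nm=(-900.0, 1500.0), n_points=17,
                               solver=flagship_solver)

    def test_flagship_is_trappable(self, landscape):
        assert landscape.trappable
        assert landscape.Uesc > 21.0
        assert landscape.Fmax > 0.0

    def test_potential_is_integral_of_force(self, landscape):
        """dU/dz = -Fz on the grid (trapezoid/central-difference pair)."""
        z = landscape.z_grid
        dU = np.gradient(landscape.U * 4.089, z)
        # central differences of a trapezoid integral reproduce the midpoint
        # average of Fz; compare away from the ends
        avg = -np.gradient(np.concatenate([[0], np.cumsum(
            0.5 * (landscape.Fz[1:] + landscape.Fz[:-1]) * np.diff(z))]), z)
        np.testing.assert_allclose(dU[1:-1], avg[1:-1], rtol=1e-9)
        # and the coarse consistency with Fz itself
        scale = np.max(np.abs(landscape.Fz))
        assert np.max(np.abs(dU + landscape.Fz)[2:-2]) / scale < 0.35

    def test_equilibrium_is_potential_minimum(self, landscape):
        i = np.argmin(np.abs(landscape.z_grid - landscape.z_eq))
        assert landscape.U[i] == 0.0
        assert np.all(landscape.U >= 0.0)

    def test_uesc_linear_in_power(self, flagship_cylinder, flagship_solver):
        b = FocusedBeam(power_specimen_mw=6.3)
        ls1 = axial_landscape(flagship_cylinder, b,
                              z_range_nm=(-600.0, 1200.0), n_points=10,
                              solver=flagship_solver)
        b2 = FocusedBeam(power_specimen_mw=12.6)
        ls2 = axial_landscape(flagship_cylinder, b2,
                              z_range_nm=(-600.0, 1200.0), n_points=10,
                              solver=flagship_solver)
        np.testing.assert_allclose(ls2.Fz, 2.0 * ls1.Fz, rtol=1e-9)
        assert ls2.Uesc == pytest.approx(2.0 * ls1.Uesc, rel=1e-9)


class TestDopingTrend:
    def test_force_and_torque_capacities_grow_with_doping(self, trap_beam):
        """Mirrors the design sweep: higher Si3N4 doping increases Fmax and
        tau_max while the trap stays stable."""
        fmax, tmax = [], []
        for rho in (0.0, 0.25, 0.5):
            cyl = EllipticalCylinder(a=187.5, b=150.0, h=600.0,
                                     material=MetamaterialSpec(rho).material())
            solver = make_solver(cyl, 40.0)
            ls = axial_landscape(cyl, trap_beam, z_range_nm=(-900.0, 1500.0),
                                 n_points=13, solver=solver)
            taus = []
            for a in (np.pi / 8, np.pi / 4, 3 * np.pi / 8):
                sol = solver.solve(trap_beam.rotate_polarization(-a),
                                   offset_nm=(0, 0, max(ls.z_eq, 0.0)))
                taus.append(abs(wrench(sol).tau[2]))
            fmax.append(ls.Fmax)
            tmax.append(max(taus))
        assert fmax[0] < fmax[1] < fmax[2]
        assert tmax[0] < tmax[1] < tmax[2]


class TestTiltTorque:
    def test_restoring_and_odd_about_minor_axis(self, flagship_cylinder,
                                                trap_beam):
        tau_p = tilt_torque(flagship_cylinder, trap_beam, (0, 1, 0), 0.15,
                            spacing_nm=40.0, z_eq_nm=100.0)
        tau_m = tilt_torque(flagship_cylinder, trap_beam, (0, 1, 0), -0.15,
                            spacing_nm=40.0, z_eq_nm=100.0)
        assert tau_p < 0.0          # opposes the tilt
        assert tau_m == pytest.approx(-tau_p, rel=0.05)

    def test_zero_tilt_zero_transverse_torque(self, flagship_solver,
                                              trap_beam, flagship_cylinder):
        sol = flagship_solver.solve(trap_beam, offset_nm=(0, 0, 100.0))
        w = wrench(sol)
        scale = 1e-3 * max(abs(w.tau[2]), 1.0)
        assert abs(w.tau[0]) < max(scale, 1e-2)
        assert abs(w.tau[1]) < max(scale, 1e-2)

    def test_large_tilt_rejected(self, flagship_cylinder, trap_beam):
        with pytest.raises(ValueError):
            tilt_torque(flagship_cylinder, trap_beam, (0, 1, 0), 0.5)
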