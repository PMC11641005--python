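"""Optical force/torque (Maxwell stress tensor) and trap-landscape metrics.

The time-averaged force and torque on the particle are surface integrals of
the Maxwell stress tensor of the total (incident + scattered) field over a
sphere enclosing the particle:

    F   = oint <T> . n dS
    tau = oint r x (<T> . n) dS

with <T> = 1/2 Re[ eps E (x) E* + mu0 H (x) H* - 1/2 (eps |E|^2 + mu0 |H|^2) I ].

The landscape metrics mirror how an angular-trap design is scored: the axial
equilibrium z_eq, the escape barrier Uesc from z_eq to the downstream
potential maximum (the scattering force pushes a particle that escapes
downstream), the maximum restoring axial force Fmax, and the maximum
alignment torque tau_max over the misalignment angle alpha between the
cylinder's major axis and the beam polarization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .beam import FocusedBeam
from .constants import (C_M_PER_S, EPS0_F_PER_M, KBT_ROOM_PNNM, NM_TO_M,
                        NM_TO_PNNM, N_TO_PN, Z0_OHM)
from .geometry import DipoleLattice, EllipticalCylinder, voxelize
from .scattering import CoupledDipoleSolver, ScatteringSolution

__all__ = ["Wrench", "TrapLandscape", "wrench", "dipole_force",
           "axial_landscape", "torque_curve", "tilt_torque"]

MU0 = Z0_OHM / C_M_PER_S


@dataclass(frozen=True)
class Wrench:
    """Optical force (pN) and torque about the particle centroid (pN·nm)."""

    F: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        object.__setattr__(self, "tau", np.asarray(self.tau, dtype=float))
        if not (np.all(np.isfinite(self.F)) and np.all(np.isfinite(self.tau))):
            raise ValueError("non-finite wrench")


@dataclass
class TrapLandscape:
    """Axial force/potential profile and angular torque curve of one design."""

    z_grid: np.ndarray            # nm
    Fz: np.ndarray                # pN
    U: np.ndarray                 # kBT, zeroed at z_eq
    z_eq: float                   # nm (nan when not trappable)
    Uesc: float                   # kBT
    Fmax: float                   # pN
    trappable: bool
    alpha_grid: Optional[np.ndarray] = None   # rad
    tau_z: Optional[np.ndarray] = None        # pN·nm
    tau_max: Optional[float] = None           # pN·nm

    def summary(self) -> dict:
        out = {"z_eq_nm": self.z_eq, "Uesc_kBT": self.Uesc,
               "Fmax_pN": self.Fmax, "trappable": self.trappable}
        if self.tau_max is not None:
            out["tau_max_pN_nm"] = self.tau_max
        return out


# ---------------------------------------------------------------------------
# stress-tensor integration
# ---------------------------------------------------------------------------

def _sphere_quadrature(radius_nm: float, n_theta: int, n_phi: int):
    """Product quadrature on a sphere: Gauss–Legendre in cos(theta) x uniform
    azimuth.  Returns points (nm), outward normals, weights (m^2)."""
    x, w = np.polynomial.legendre.leggauss(n_theta)
    phi = np.arange(n_phi) * 2.0 * np.pi / n_phi
    ct = x
    st = np.sqrt(1.0 - ct**2)
    n = np.empty((n_theta * n_phi, 3))
    n[:, 0] = np.outer(st, np.cos(phi)).ravel()
    n[:, 1] = np.outer(st, np.sin(phi)).ravel()
    n[:, 2] = np.outer(ct, np.ones(n_phi)).ravel()
    wq = np.outer(w, np.full(n_phi, 2.0 * np.pi / n_phi)).ravel()
    wq = wq * (radius_nm * NM_TO_M) ** 2
    return radius_nm * n, n, wq


def _surface_radius(lattice: DipoleLattice) -> float:
    rmax = float(np.linalg.norm(lattice.positions, axis=1).max())
    return rmax + 3.0 * lattice.spacing


def wrench(sol: ScatteringSolution, *, radius_nm: Optional[float] = None,
           n_theta: int = 26, n_phi: int = 52) -> Wrench:
    """Force (pN) and torque (pN·nm) about the particle centroid by surface
    integration of the time-averaged Maxwell stress tensor of the total field
    over an enclosing sphere."""
    if radius_nm is None:
        radius_nm = _surface_radius(sol.lattice)
    rmax = float(np.linalg.norm(sol.lattice.positions, axis=1).max())
    if radius_nm <= rmax:
        raise ValueError(f"integration sphere (r={radius_nm:.0f} nm) intersects "
                         f"the particle (extent {rmax:.0f} nm)")
    pts, nrm, wq = _sphere_quadrature(radius_nm, n_theta, n_phi)
    E, H = sol.total_field(pts)
    eps = EPS0_F_PER_M * sol.n_medium**2

    En = np.einsum("ia,ia->i", E, nrm)
    Hn = np.einsum("ia,ia->i", H, nrm)
    e2 = np.einsum("ia,ia->i", E, np.conj(E)).real
    h2 = np.einsum("ia,ia->i", H, np.conj(H)).real
    tn = 0.5 * np.real(eps * np.conj(E) * En[:, None]
                       + MU0 * np.conj(H) * Hn[:, None]) \
        - 0.25 * (eps * e2 + MU0 * h2)[:, None] * nrm

    F_N = (wq[:, None] * tn).sum(axis=0)
    tau_Nm = (wq[:, None] * np.cross(pts * NM_TO_M, tn)).sum(axis=0)
    return Wrench(F=F_N * N_TO_PN, tau=tau_Nm * NM_TO_PNNM)


def dipole_force(sol: ScatteringSolution, *, step_nm: float = 0.5) -> np.ndarray:
    """Independent force route (pN): gradient-force summation over dipoles,
    F_a = 1/2 Re sum_i p_i . d_a E_ext*(r_i), with the external field (incident
    plus other dipoles') gradient taken by central differences.  Used to
    cross-check the stress-tensor integral."""
    pos = sol.lattice.positions
    eps = EPS0_F_PER_M * sol.n_medium**2
    F = np.zeros(3)
    for a in range(3):
        dd = np.zeros(3)
        dd[a] = step_nm
        # displaced copies keep self-interaction excluded via pair distances
        Ep = _e_ext_excluding_self(sol, pos + dd)
        Em = _e_ext_excluding_self(sol, pos - dd)
        dE = (Ep - Em) / (2.0 * step_nm * NM_TO_M)
        F[a] = 0.5 * eps * np.real(np.sum(sol.moments * np.conj(dE)))
    return F * N_TO_PN


def _e_ext_excluding_self(sol: ScatteringSolution, points: np.ndarray) -> np.ndarray:
    """Incident-plus-other-dipoles field at slightly displaced site copies."""
    from .scattering import _green_blocks
    Ei, _ = sol.incident.fields(points, offset_nm=sol.offset_nm)
    G = _green_blocks(sol.lattice.positions, points, sol.k_per_m)
    # zero the near-diagonal (self) blocks: site i displaced vs site i
    idx = np.arange(points.shape[0])
    G[idx, idx] = 0.0
    return Ei + np.einsum("ijab,jb->ia", G, sol.moments)


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

def _aligned_beam(cyl: EllipticalCylinder, beam: FocusedBeam) -> FocusedBeam:
    """Zero-net-torque convention: polarization along the cylinder major axis."""
    return beam.rotate_polarization(cyl.angle_alpha)


def axial_landscape(cyl: EllipticalCylinder, beam: FocusedBeam,
                    z_range_nm: tuple = (-1500.0, 3000.0), n_points: int = 31,
                    *, spacing_nm: float = 30.0,
                    solver: Optional[CoupledDipoleSolver] = None,
                    kbt_pnnm: float = KBT_ROOM_PNNM,
                    n_theta: int = 26, n_phi: int = 52) -> TrapLandscape:
    """Axial force profile Fz(z), potential U(z) = -int Fz dz and the trap
    metrics z_eq, Uesc, Fmax.

    The beam polarization is aligned with the cylinder major axis (the
    zero-net-torque orientation a trapped cylinder adopts), and the particle
    centroid is stepped along the beam axis.  A design with no interior
    potential minimum is reported untrappable (Uesc = 0), not an error.
    """
    beam = _aligned_beam(cyl, beam)
    if solver is None:
        lattice = voxelize(cyl, spacing_nm, wavelength_nm=beam.wavelength_nm)
        solver = CoupledDipoleSolver(lattice, n_medium=beam.n_medium,
                                     wavelength_nm=beam.wavelength_nm)
    z_grid = np.linspace(z_range_nm[0], z_range_nm[1], n_points)
    Fz = np.empty(n_points)
    for i, z in enumerate(z_grid):
        sol = solver.solve(beam, offset_nm=(0.0, 0.0, z))
        Fz[i] = wrench(sol, n_theta=n_theta, n_phi=n_phi).F[2]

    # U(z) = -int Fz dz, in kBT
    U = -np.concatenate([[0.0], np.cumsum(0.5 * (Fz[1:] + Fz[:-1]) * np.diff(z_grid))])
    U = U / kbt_pnnm

    # equilibrium = deepest interior *local* minimum of U: the global minimum
    # is grid-dependent (the scattering-force tail keeps lowering U far
    # downstream), the trapping well is not
    interior = np.arange(1, n_points - 1)
    is_min = (U[interior] <= U[interior - 1]) & (U[interior] <= U[interior + 1])
    candidates = interior[is_min]
    trappable = candidates.size > 0
    if not trappable:
        return TrapLandscape(z_grid=z_grid, Fz=Fz, U=U - U.min(), z_eq=np.nan,
                             Uesc=0.0, Fmax=float(np.max(np.abs(Fz))),
                             trappable=False)
    i_eq = int(candidates[np.argmin(U[candidates])])
    U = U - U[i_eq]
    z_eq = float(z_grid[i_eq])
    uesc = float(np.max(U[i_eq:]))          # barrier to the downstream maximum
    restoring = np.maximum(np.where(z_grid < z_eq, Fz, -Fz), 0.0)
    fmax = float(np.max(restoring))
    return TrapLandscape(z_grid=z_grid, Fz=Fz, U=U, z_eq=z_eq, Uesc=uesc,
                         Fmax=fmax, trappable=True)


def torque_curve(cyl: EllipticalCylinder, beam: FocusedBeam,
                 z_eq_nm: float = 0.0, *, n_alpha: int = 19,
                 spacing_nm: float = 30.0,
                 solver: Optional[CoupledDipoleSolver] = None,
                 n_theta: int = 26, n_phi: int = 52,
                 landscape: Optional[TrapLandscape] = None) -> TrapLandscape:
    """Alignment torque tau_z(alpha) at the axial equilibrium.

    alpha is the angle of the cylinder major axis past the beam polarization;
    by symmetry this equals rotating the polarization to -alpha with the
    lattice fixed, which lets one matrix factorization serve every angle.
    Restoring convention: tau_z < 0 for small alpha > 0.
    """
    if solver is None:
        lattice = voxelize(cyl, spacing_nm, wavelength_nm=beam.wavelength_nm)
        solver = CoupledDipoleSolver(lattice, n_medium=beam.n_medium,
                                     wavelength_nm=beam.wavelength_nm)
    alphas = np.linspace(0.0, np.pi, n_alpha, endpoint=False)
    tau = np.empty(n_alpha)
    for i, alpha in enumerate(alphas):
        rotated = beam.rotate_polarization(cyl.angle_alpha - alpha)
        sol = solver.solve(rotated, offset_nm=(0.0, 0.0, z_eq_nm))
        tau[i] = wrench(sol, n_theta=n_theta, n_phi=n_phi).tau[2]
    out = landscape if landscape is not None else TrapLandscape(
        z_grid=np.array([z_eq_nm]), Fz=np.zeros(1), U=np.zeros(1),
        z_eq=z_eq_nm, Uesc=0.0, Fmax=0.0, trappable=True)
    out.alpha_grid = alphas
    out.tau_z = tau
    out.tau_max = float(np.max(np.abs(tau)))
    return out


def tilt_torque(cyl: EllipticalCylinder, beam: FocusedBeam,
                tilt_axis, tilt_angle: float, *, z_eq_nm: float = 0.0,
                spacing_nm: float = 30.0, n_theta: int = 26,
                n_phi: int = 52) -> float:
    """Torque component (pN·nm) about ``tilt_axis`` with the cylinder tilted
    off the beam axis by ``tilt_angle`` (rad); negative = restoring.

    Probes the anti-tilt stability of the uniaxial metamaterial cylinder
    (extraordinary axis along the cylinder axis)."""
    if abs(tilt_angle) > 0.35:
        raise ValueError("tilt_torque is a small-tilt probe (|angle| <= 0.35 rad)")
    axis = np.asarray(tilt_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    beam = _aligned_beam(cyl, beam)
    lattice = voxelize(cyl, spacing_nm, wavelength_nm=beam.wavelength_nm)
    R = _rotation_about(axis, tilt_angle)
    tensors = lattice.tensors()
    rotated = DipoleLattice(
        spacing=lattice.spacing,
        positions=lattice.positions @ R.T,
        site_permittivity=np.einsum("ab,nbc,dc->nad", R, tensors, R))
    solver = CoupledDipoleSolver(rotated, n_medium=beam.n_medium,
                                 wavelength_nm=beam.wavelength_nm)
    sol = solver.solve(beam, offset_nm=(0.0, 0.0, z_eq_nm))
    w = wrench(sol, n_theta=n_theta, n_phi=n_phi)
    return float(w.tau @ axis)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    ax = np.array([[0, -axis[2], axis[1]],
                   [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return np.eye(3) * c + s * ax + (1 - c) * np.outer(axis, axis)
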