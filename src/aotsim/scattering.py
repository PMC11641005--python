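"""Coupled-dipole (discrete-dipole) scattering with anisotropic sites.

Each lattice site carries a Clausius–Mossotti tensor polarizability with the
radiative-reaction correction; the self-consistent moments solve

    d_i - alpha_i . sum_{j != i} G(r_i - r_j) d_j = alpha_i . E_inc(r_i)

where ``d = p / (eps0 eps_m)`` is the reduced dipole moment (units V·m^2) and
G is the free-space dyadic Green function of the surrounding medium.  The
system is solved either by a dense LU factorization — cached, so landscape
scans that only move or re-polarize the beam reuse it across every
right-hand side — or by matrix-free BiCGStab over the same operator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.sparse.linalg import LinearOperator, bicgstab

from .constants import C_M_PER_S, EPS0_F_PER_M, NM_TO_M, TWO_PI
from .geometry import DipoleLattice

__all__ = ["polarizability", "CoupledDipoleSolver", "ScatteringSolution",
           "SolverError"]


class SolverError(RuntimeError):
    pass


def polarizability(eps_site: np.ndarray, d_nm: float, k_per_m: float,
                   eps_medium: float) -> np.ndarray:
    """Tensor polarizability (m^3) of one cubic lattice cell.

    Clausius–Mossotti per principal axis of the (relative-to-medium)
    permittivity, with the radiative-reaction correction
    ``alpha = alpha0 / (1 - i k^3 alpha0 / 6 pi)``, assembled in the tensor's
    principal frame and rotated back.  A site matching the medium returns the
    zero tensor.
    """
    eps_site = np.asarray(eps_site, dtype=float)
    if eps_site.shape != (3, 3) or not np.allclose(eps_site, eps_site.T, atol=1e-9):
        raise ValueError("site permittivity must be a symmetric 3x3 tensor")
    evals, evecs = np.linalg.eigh(eps_site)
    if np.any(evals <= 0):
        raise ValueError("site permittivity must be positive-definite")
    eps_rel = evals / eps_medium
    d3 = (d_nm * NM_TO_M) ** 3
    a0 = 3.0 * d3 * (eps_rel - 1.0) / (eps_rel + 2.0)
    alpha = a0 / (1.0 - 1j * k_per_m**3 * a0 / (6.0 * np.pi))
    alpha = np.where(np.abs(eps_rel - 1.0) < 1e-14, 0.0, alpha)
    return (evecs * alpha) @ evecs.T.conj().astype(complex)


def _green_blocks(r_src_nm: np.ndarray, r_obs_nm: np.ndarray, k: float,
                  *, self_zero: bool = False) -> np.ndarray:
    """Dense dyadic Green blocks G[i, j] (3x3) such that E(obs_i) = G[i,j] d_j.

    G(r) = e^{ikr}/(4 pi) [ k^2 (I - rr)/r + (3 rr - I)(1/r^3 - ik/r^2) ].
    """
    dr = (r_obs_nm[:, None, :] - r_src_nm[None, :, :]) * NM_TO_M
    r = np.linalg.norm(dr, axis=-1)
    if self_zero:
        np.fill_diagonal(r, 1.0)  # placeholder; diagonal blocks zeroed below
    elif np.any(r < 1e-15):
        raise ValueError("observation point coincides with a source dipole")
    rhat = dr / r[..., None]
    rr = rhat[..., :, None] * rhat[..., None, :]
    eye = np.eye(3)
    phase = np.exp(1j * k * r) / (4.0 * np.pi)
    near = 1.0 / r**3 - 1j * k / r**2
    G = (phase * k**2 / r)[..., None, None] * (eye - rr) \
        + (phase * near)[..., None, None] * (3.0 * rr - eye)
    if self_zero:
        idx = np.arange(G.shape[0])
        G[idx, idx] = 0.0
    return G


@dataclass
class ScatteringSolution:
    """Self-consistent reduced dipole moments for one incident configuration."""

    lattice: DipoleLattice
    moments: np.ndarray          # (N, 3) complex, d = p/(eps0 eps_m), V·m^2
    residual: float
    k_per_m: float
    n_medium: float
    incident: object             # field source with .fields(points, offset_nm=...)
    offset_nm: np.ndarray        # particle-centroid position in the lab frame
    e_inc_sites: np.ndarray      # (N, 3) incident E at the sites

    def scattered_field(self, points_nm: np.ndarray, *, chunk: int = 2048,
                        check_exclusion: bool = True):
        """Scattered (E, H) at particle-frame points (nm, relative to the
        particle centroid).  Points must stay a lattice spacing away from
        every dipole."""
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        pos = self.lattice.positions
        k = self.k_per_m
        if check_exclusion:
            for lo in range(0, pts.shape[0], chunk):
                dr = pts[lo:lo + chunk, None, :] - pos[None, :, :]
                dmin = np.sqrt((dr**2).sum(-1)).min()
                if dmin <= self.lattice.spacing:
                    raise ValueError(
                        f"evaluation point within the dipole exclusion zone "
                        f"(min distance {dmin:.1f} nm <= d={self.lattice.spacing} nm)")
        E = np.zeros((pts.shape[0], 3), dtype=complex)
        H = np.zeros_like(E)
        omega = k * C_M_PER_S / self.n_medium
        hfac = EPS0_F_PER_M * self.n_medium**2 * omega * k / (4.0 * np.pi)
        for lo in range(0, pts.shape[0], chunk):
            sl = slice(lo, lo + chunk)
            G = _green_blocks(pos, pts[sl], k)
            E[sl] = np.einsum("ijab,jb->ia", G, self.moments)
            dr = (pts[sl][:, None, :] - pos[None, :, :]) * NM_TO_M
            r = np.linalg.norm(dr, axis=-1)
            rhat = dr / r[..., None]
            amp = hfac * np.exp(1j * k * r) / r * (1.0 - 1.0 / (1j * k * r))
            H[sl] = np.einsum("ij,ija->ia", amp,
                              np.cross(rhat, np.broadcast_to(
                                  self.moments[None, :, :], rhat.shape)))
        return E, H

    def total_field(self, points_nm: np.ndarray, **kw):
        """Incident + scattered (E, H) at particle-frame points."""
        Es, Hs = self.scattered_field(points_nm, **kw)
        Ei, Hi = self.incident.fields(points_nm, offset_nm=self.offset_nm)
        return Es + Ei, Hs + Hi

    def extinction_cross_section_m2(self) -> float:
        """Extinction cross-section for a plane-wave incident field (m^2)."""
        omega = self.k_per_m * C_M_PER_S / self.n_medium
        p_ext = 0.5 * omega * EPS0_F_PER_M * self.n_medium**2 * float(
            np.imag(np.sum(self.moments * np.conj(self.e_inc_sites))))
        return p_ext / self.incident.intensity_w_per_m2


class CoupledDipoleSolver:
    """Coupled-dipole solver bound to one lattice.

    The interaction matrix depends only on the lattice, so one factorization
    serves every beam offset and polarization angle.
    """

    MAX_DENSE_SITES = 2500

    def __init__(self, lattice: DipoleLattice, *, n_medium: float = 1.33,
                 wavelength_nm: float = 1064.0, tol: float = 1e-5,
                 method: str = "auto", max_iter: int = 2000):
        if lattice.n_sites == 0:
            raise ValueError("empty lattice")
        if lattice.n_sites > self.MAX_DENSE_SITES:
            raise SolverError(
                f"{lattice.n_sites} sites exceeds the dense-solver budget "
                f"({self.MAX_DENSE_SITES}); use a coarser dipole spacing")
        self.lattice = lattice
        self.n_medium = float(n_medium)
        self.wavelength_nm = float(wavelength_nm)
        self.k_per_m = TWO_PI * n_medium / (wavelength_nm * NM_TO_M)
        self.tol = float(tol)
        self.method = method
        self.max_iter = int(max_iter)
        self._alphas = np.stack([
            polarizability(t, lattice.spacing, self.k_per_m, n_medium**2)
            for t in lattice.tensors()])
        self._matrix = None
        self._lu = None

    # -- system matrix --------------------------------------------------------

    def _build_matrix(self) -> np.ndarray:
        if self._matrix is None:
            n = self.lattice.n_sites
            G = _green_blocks(self.lattice.positions, self.lattice.positions,
                              self.k_per_m, self_zero=True)
            A = np.einsum("iab,ijbc->iajc", self._alphas, G).reshape(3 * n, 3 * n)
            A *= -1.0
            A[np.arange(3 * n), np.arange(3 * n)] += 1.0
            self._matrix = A
        return self._matrix

    def _factorize(self):
        if self._lu is None:
            self._lu = lu_factor(self._build_matrix())
        return self._lu

    # -- solve ----------------------------------------------------------------

    def solve(self, incident, *, offset_nm=(0.0, 0.0, 0.0),
              x0: Optional[np.ndarray] = None,
              method: Optional[str] = None) -> ScatteringSolution:
        """Solve for the self-consistent moments under ``incident`` fields with
        the particle centroid at ``offset_nm`` in the lab frame."""
        offset = np.asarray(offset_nm, dtype=float)
        e_inc, _ = incident.fields(self.lattice.positions, offset_nm=offset)
        rhs = np.einsum("iab,ib->ia", self._alphas, e_inc).ravel()
        meth = method or self.method
        if meth == "auto":
            meth = "direct"
        if meth == "direct":
            x = lu_solve(self._factorize(), rhs)
            info = 0
        elif meth == "bicgstab":
            A = self._build_matrix()
            op = LinearOperator(A.shape, matvec=lambda v: A @ v, dtype=complex)
            rnorm = np.linalg.norm(rhs)
            if rnorm == 0.0:
                x, info = np.zeros_like(rhs), 0
            else:
                # unit-scale the system: physical moments are ~1e-24 of the
                # incident field and underflow BiCGStab's inner products
                x, info = bicgstab(
                    op, rhs / rnorm, rtol=self.tol * 1e-2, atol=0.0,
                    x0=None if x0 is None else np.asarray(x0).ravel() / rnorm,
                    maxiter=self.max_iter)
                x = x * rnorm
            if info != 0:
                raise SolverError(f"BiCGStab failed (info={info}); "
                                  f"residual {self._residual(x, rhs):.2e}")
        else:
            raise ValueError(f"unknown method {meth!r}")
        res = self._residual(x, rhs)
        if res > self.tol:
            raise SolverError(f"solution residual {res:.2e} exceeds tol {self.tol}")
        return ScatteringSolution(
            lattice=self.lattice, moments=x.reshape(-1, 3), residual=res,
            k_per_m=self.k_per_m, n_medium=self.n_medium, incident=incident,
            offset_nm=offset, e_inc_sites=e_inc)

    def _residual(self, x: np.ndarray, rhs: np.ndarray) -> float:
        scale = np.linalg.norm(rhs)
        if scale == 0.0:
            return 0.0
        return float(np.linalg.norm(self._build_matrix() @ x - rhs) / scale)
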