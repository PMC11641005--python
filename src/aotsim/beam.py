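"""Vectorial focused Gaussian trap beam (Richards–Wolf angular spectrum).

A linearly polarized Gaussian beam overfilling a high-NA objective is focused
into the aqueous medium.  The focal field is the Debye–Wolf diffraction
integral over the converging spherical wavefront; for a linearly polarized
input with an azimuthally symmetric pupil (Gaussian apodization set by the
filling factor, plus the spherical-aberration phase of the oil–aqueous
interface) the azimuthal integral is analytic and the field reduces to three
one-dimensional polar integrals I0, I1, I2 (the classic Richards–Wolf form):

    E_x = A (I0 + I2 cos 2phi),  E_y = A I2 sin 2phi,  E_z = -2i A I1 cos phi

with the magnetic field given by the matching y-polarized set.  The overall
amplitude A is fixed analytically so the time-averaged Poynting flux through
any transverse plane equals the specimen-plane power.

Lengths are nm at the interface; fields are SI (V/m, A/m) internally so the
Maxwell stress tensor yields newtons without bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import j0, j1, jn

from .constants import MW_TO_W, NM_TO_M, TWO_PI, Z0_OHM

__all__ = ["FocusedBeam", "PlaneWave", "VectorFieldGrid", "transverse_flux"]


@dataclass(frozen=True)
class VectorFieldGrid:
    """Complex E/H field samples on a set of points (nm)."""

    points: np.ndarray   # (N, 3) nm
    E: np.ndarray        # (N, 3) complex, V/m
    H: np.ndarray        # (N, 3) complex, A/m

    def __post_init__(self):
        for name in ("points", "E", "H"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (self.points.shape == self.E.shape == self.H.shape):
            raise ValueError("points, E and H must share shape (N, 3)")

    def poynting(self) -> np.ndarray:
        """Time-averaged Poynting vector (W/m^2) at each point."""
        return 0.5 * np.real(np.cross(self.E, np.conj(self.H)))


def _rot_z(psi: float) -> np.ndarray:
    c, s = np.cos(psi), np.sin(psi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class FocusedBeam:
    """Linearly polarized Gaussian beam focused by a high-NA objective.

    Parameters
    ----------
    wavelength_nm : vacuum wavelength (default 1064 nm).
    na : numerical aperture (default 1.3).
    fill_factor : beam-waist-to-aperture-radius ratio w/R (default 0.98).
    power_specimen_mw : time-averaged power delivered to the specimen plane.
    polarization_angle : linear-polarization direction, radians from +x.
    n_immersion / n_medium : immersion-oil and aqueous indices.
    interface_depth_nm : focus depth past the oil/glass–water interface used
        by the spherical-aberration phase (0 disables aberration).
    n_theta : polar Gauss–Legendre quadrature order.
    """

    wavelength_nm: float = 1064.0
    na: float = 1.3
    fill_factor: float = 0.98
    power_specimen_mw: float = 12.6
    polarization_angle: float = 0.0
    n_immersion: float = 1.518
    n_medium: float = 1.33
    interface_depth_nm: float = 1000.0
    n_theta: int = 160

    def __post_init__(self):
        if self.na <= 0 or self.na > self.n_immersion:
            raise ValueError(f"NA must satisfy 0 < NA <= n_immersion "
                             f"(NA={self.na}, n_immersion={self.n_immersion})")
        if self.na > self.n_medium:
            raise ValueError("NA exceeding the sample-medium index would need "
                             "evanescent components; not supported")
        if self.power_specimen_mw <= 0:
            raise ValueError("power_specimen_mw must be positive")
        if self.fill_factor <= 0:
            raise ValueError("fill_factor must be positive")

    # ---- derived quantities -------------------------------------------------

    @property
    def k_medium(self) -> float:
        """Wavenumber in the medium, 1/m."""
        return TWO_PI * self.n_medium / (self.wavelength_nm * NM_TO_M)

    @property
    def theta_max(self) -> float:
        return float(np.arcsin(self.na / self.n_medium))

    def rotate_polarization(self, psi: float) -> "FocusedBeam":
        """Beam with polarization along angle ``psi``; its focal fields are the
        psi=0 fields rigidly rotated about the propagation axis."""
        return replace(self, polarization_angle=psi)

    # ---- pupil / quadrature -------------------------------------------------

    def _quadrature(self):
        """Polar nodes, weights and pupil amplitude a(theta) (complex)."""
        x, w = np.polynomial.legendre.leggauss(self.n_theta)
        theta = 0.5 * self.theta_max * (x + 1.0)
        w = 0.5 * self.theta_max * w
        s = np.sin(theta) / np.sin(self.theta_max)
        apod = np.exp(-(s / self.fill_factor) ** 2) * np.sqrt(np.cos(theta))
        phase = np.exp(1j * self._aberration_phase(theta))
        return theta, w, apod * phase

    def _aberration_phase(self, theta: np.ndarray) -> np.ndarray:
        """Index-mismatch aberration: optical-path difference between the ray
        path in the aqueous medium and the path the objective is corrected for
        (immersion oil), over the focus depth past the interface."""
        if self.interface_depth_nm == 0.0:
            return np.zeros_like(theta)
        k0 = TWO_PI / (self.wavelength_nm * NM_TO_M)
        d = self.interface_depth_nm * NM_TO_M
        sin1 = np.clip(self.n_medium * np.sin(theta) / self.n_immersion, 0.0, 1.0)
        cos1 = np.sqrt(1.0 - sin1**2)
        return k0 * d * (self.n_medium * np.cos(theta) - self.n_immersion * cos1)

    def _amplitude(self) -> float:
        """Prefactor A (V/m) normalizing total flux to power_specimen."""
        theta, w, a = self._quadrature()
        q = float(np.sum(w * np.abs(a) ** 2 * np.sin(theta)))
        z_med = Z0_OHM / self.n_medium
        p = self.power_specimen_mw * MW_TO_W
        # P = (2 pi)^3 |C|^2 Q / (2 Z k^2),  A = pi C
        c = np.sqrt(2.0 * z_med * self.k_medium**2 * p / ((TWO_PI) ** 3 * q))
        return float(np.pi * c)

    # ---- field evaluation ---------------------------------------------------

    def fields(self, points_nm: np.ndarray, *, offset_nm=None,
               chunk: int = 8192) -> tuple[np.ndarray, np.ndarray]:
        """Complex (E, H) at lab-frame positions (nm, focus at the origin).

        ``offset_nm`` shifts the evaluation points rigidly (used to translate
        the particle through the trap without rebuilding anything).
        """
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        if offset_nm is not None:
            pts = pts + np.asarray(offset_nm, dtype=float)
        # linear polarization is a director: period pi
        psi = self.polarization_angle % np.pi
        body = pts @ _rot_z(psi)  # == (Rz(-psi) @ pts.T).T
        E = np.empty((body.shape[0], 3), dtype=complex)
        H = np.empty_like(E)
        for lo in range(0, body.shape[0], chunk):
            sl = slice(lo, lo + chunk)
            e, h = self._fields_body(body[sl])
            E[sl], H[sl] = e, h
        R = _rot_z(psi)
        return E @ R.T, H @ R.T

    def field_grid(self, points_nm: np.ndarray, **kw) -> VectorFieldGrid:
        E, H = self.fields(points_nm, **kw)
        return VectorFieldGrid(points=np.atleast_2d(points_nm), E=E, H=H)

    def _fields_body(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fields for x-polarization in the beam body frame."""
        theta, w, a = self._quadrature()
        k = self.k_medium
        x, y, z = (pts * NM_TO_M).T
        rho = np.hypot(x, y)
        phi = np.arctan2(y, x)

        st, ct = np.sin(theta), np.cos(theta)
        u = np.outer(rho, k * st)                      # (N, n_theta)
        prop = np.exp(1j * np.outer(z, k * ct))
        base = (w * a * st) * prop                     # common integrand factor

        i00 = (base * (1.0 + ct) * j0(u)).sum(axis=1)
        i01 = (base * st * j1(u)).sum(axis=1)
        i02 = (base * (1.0 - ct) * jn(2, u)).sum(axis=1)

        A = self._amplitude()
        c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
        cp, sp = np.cos(phi), np.sin(phi)
        E = A * np.column_stack([i00 + i02 * c2, i02 * s2, -2j * i01 * cp])
        Hfac = A * self.n_medium / Z0_OHM
        H = Hfac * np.column_stack([i02 * s2, i00 - i02 * c2, -2j * i01 * sp])
        return E, H


@dataclass(frozen=True)
class PlaneWave:
    """Linearly polarized plane wave in the medium (test/oracle input).

    amplitude is the E-field amplitude in V/m; direction and polarization are
    lab-frame vectors (polarization is orthogonalized against direction).
    """

    amplitude: float = 1.0
    wavelength_nm: float = 1064.0
    n_medium: float = 1.33
    direction: tuple = (0.0, 0.0, 1.0)
    polarization: tuple = (1.0, 0.0, 0.0)

    @property
    def k_medium(self) -> float:
        return TWO_PI * self.n_medium / (self.wavelength_nm * NM_TO_M)

    @property
    def intensity_w_per_m2(self) -> float:
        return 0.5 * self.n_medium * self.amplitude**2 / Z0_OHM

    def fields(self, points_nm, *, offset_nm=None, **_):
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        if offset_nm is not None:
            pts = pts + np.asarray(offset_nm, dtype=float)
        khat = np.asarray(self.direction, dtype=float)
        khat = khat / np.linalg.norm(khat)
        pol = np.asarray(self.polarization, dtype=float)
        pol = pol - khat * (pol @ khat)
        pol = pol / np.linalg.norm(pol)
        phase = np.exp(1j * self.k_medium * (pts * NM_TO_M) @ khat)
        E = self.amplitude * phase[:, None] * pol
        H = (self.n_medium / Z0_OHM) * np.cross(np.broadcast_to(khat, E.shape), E)
        return E, H

    def field_grid(self, points_nm, **kw) -> VectorFieldGrid:
        E, H = self.fields(points_nm, **kw)
        return VectorFieldGrid(points=np.atleast_2d(points_nm), E=E, H=H)


def transverse_flux(beam, *, z_nm: float = 0.0, half_width_nm: float = 3000.0,
                    n: int = 201) -> float:
    """Numerically integrate the axial Poynting flux through the transverse
    plane at ``z_nm`` over a square of half-width ``half_width_nm``; returns W.
    """
    xs = np.linspace(-half_width_nm, half_width_nm, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z_nm)])
    E, H = beam.fields(pts)
    sz = 0.5 * np.real(E[:, 0] * np.conj(H[:, 1]) - E[:, 1] * np.conj(H[:, 0]))
    dx = (xs[1] - xs[0]) * NM_TO_M
    return float(sz.sum() * dx * dx)
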