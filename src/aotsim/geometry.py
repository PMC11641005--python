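"""Elliptical-cylinder geometry and dipole-lattice discretization.

The trapping particle is a right cylinder of elliptical cross-section with
semi-major axis ``a``, semi-minor axis ``b`` and height ``h`` (all nm).  Its
cylindrical axis is along z (the beam propagation direction — the orientation
a trapped cylinder adopts); ``angle_alpha`` rotates the major axis in-plane
away from the lab x-axis.

`voxelize` clips a cubic lattice to the cylinder to produce the point-dipole
discretization consumed by the coupled-dipole scattering solver.  Site centers
sit at half-integer offsets from the centroid so the lattice inherits the
cylinder's 180-degree rotational symmetry (and, for a = b, its 90-degree
symmetry) — the torque symmetry tests rely on this registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import OpticalMaterial, permittivity_tensor

__all__ = [
    "EllipticalCylinder",
    "DipoleLattice",
    "eccentricity",
    "volume_um3",
    "voxelize",
    "cylinder_from_design",
    "LatticeResolutionWarning",
]


class LatticeResolutionWarning(UserWarning):
    """Dipole spacing too coarse for the target wavelength/index."""


def eccentricity(a: float, b: float) -> float:
    """Cross-section eccentricity sqrt(1 - b^2/a^2); 0 for a circle.

    ``a`` is the semi-major, ``b`` the semi-minor axis; passing b > a is an
    argument-order error, not a geometry.
    """
    if not (a >= b > 0.0):
        raise ValueError(f"require a >= b > 0 (got a={a}, b={b})")
    return float(np.sqrt(1.0 - (b / a) ** 2))


@dataclass(frozen=True)
class EllipticalCylinder:
    """Right elliptical cylinder (dimensions in nm)."""

    a: float
    b: float
    h: float
    material: OpticalMaterial
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    angle_alpha: float = 0.0

    def __post_init__(self):
        if not (self.a >= self.b > 0.0):
            raise ValueError(f"require a >= b > 0 (got a={self.a}, b={self.b})")
        if self.h <= 0.0:
            raise ValueError("height h must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def eccentricity(self) -> float:
        return eccentricity(self.a, self.b)

    @property
    def aspect_ratio(self) -> float:
        """Height over major-axis length, h / (2a)."""
        return self.h / (2.0 * self.a)

    @property
    def volume_nm3(self) -> float:
        return float(np.pi * self.a * self.b * self.h)

    @property
    def volume_um3(self) -> float:
        return self.volume_nm3 * 1e-9

    @property
    def circumscribing_radius(self) -> float:
        """Radius of the smallest origin-centered sphere containing the shape."""
        return float(np.hypot(self.a, self.h / 2.0))

    def rotated(self, alpha: float) -> "EllipticalCylinder":
        return replace(self, angle_alpha=alpha)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (N, 3; nm, relative to the centroid) inside."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = np.cos(self.angle_alpha), np.sin(self.angle_alpha)
        # rotate into the body frame (major axis along x)
        x = c * p[:, 0] + s * p[:, 1]
        y = -s * p[:, 0] + c * p[:, 1]
        inside = (x / self.a) ** 2 + (y / self.b) ** 2 <= 1.0
        return inside & (np.abs(p[:, 2]) <= self.h / 2.0)


def volume_um3(cyl: EllipticalCylinder) -> float:
    """Cylinder volume pi*a*b*h in cubic microns."""
    return cyl.volume_um3


def cylinder_from_design(eccentricity_: float, aspect_ratio: float,
                         volume_um3_: float, material: OpticalMaterial,
                         **kwargs) -> EllipticalCylinder:
    """Build a cylinder from the design-space coordinates used in the trapping
    sweeps: cross-section eccentricity, aspect ratio h/(2a), and volume (μm³).
    """
    if not 0.0 <= eccentricity_ < 1.0:
        raise ValueError("eccentricity must lie in [0, 1)")
    ratio_b = np.sqrt(1.0 - eccentricity_**2)       # b = ratio_b * a
    v_nm3 = volume_um3_ * 1e9
    # V = pi * a * (ratio_b a) * (2 aspect a) = 2 pi aspect ratio_b a^3
    a = (v_nm3 / (2.0 * np.pi * aspect_ratio * ratio_b)) ** (1.0 / 3.0)
    return EllipticalCylinder(a=a, b=ratio_b * a, h=2.0 * aspect_ratio * a,
                              material=material, **kwargs)


@dataclass(frozen=True)
class DipoleLattice:
    """Cubic dipole lattice clipped to a particle shape.

    positions are nm, relative to the particle centroid; ``site_permittivity``
    is either a single shared 3x3 relative-permittivity tensor (homogeneous
    particle) broadcast over sites, or an (N, 3, 3) array.
    """

    spacing: float
    positions: np.ndarray
    site_permittivity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions",
                           np.ascontiguousarray(self.positions, dtype=float))
        object.__setattr__(self, "site_permittivity",
                           np.asarray(self.site_permittivity, dtype=float))

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def volume_nm3(self) -> float:
        """Discretized volume N d^3."""
        return self.n_sites * self.spacing**3

    def tensors(self) -> np.ndarray:
        """Per-site permittivity tensors as an (N, 3, 3) array."""
        t = self.site_permittivity
        if t.ndim == 2:
            return np.broadcast_to(t, (self.n_sites, 3, 3))
        return t


def _rot_z(alpha: float) -> np.ndarray:
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def voxelize(cyl: EllipticalCylinder, d: float, *, wavelength_nm: float = 1064.0,
             min_sites: int = 8) -> DipoleLattice:
    """Discretize the cylinder into a cubic dipole lattice of spacing ``d`` nm.

    Sites are cube centers at half-integer multiples of ``d`` from the
    centroid; a site belongs to the lattice when its center lies inside the
    cylinder.  Each site carries the material permittivity tensor rotated by
    ``angle_alpha``.  Deterministic for fixed inputs.

    A warning (not an error) is issued when ``d`` exceeds the usual
    wavelength-resolution guideline d <= lambda0 / (10 n_max).
    """
    if d <= 0.0:
        raise ValueError("spacing d must be positive")
    if d >= min(cyl.a, cyl.b, cyl.h / 2.0):
        raise ValueError(f"spacing d={d} nm too coarse for shape "
                         f"(a={cyl.a}, b={cyl.b}, h={cyl.h})")
    n_max = max(cyl.material.n_o, cyl.material.n_e)
    if d > wavelength_nm / (10.0 * n_max):
        warnings.warn(
            f"dipole spacing {d:g} nm exceeds lambda0/(10 n_max) = "
            f"{wavelength_nm / (10 * n_max):.1f} nm; results may be coarse",
            LatticeResolutionWarning, stacklevel=2)

    def centers(extent: float) -> np.ndarray:
        m = int(np.ceil(extent / d - 0.5))
        return (np.arange(-m, m + 1) + 0.5) * d if m > 0 else np.array([-0.5, 0.5]) * d

    # generous in-plane extent: the rotated ellipse fits inside radius a
    xs = centers(cyl.a)
    ys = centers(cyl.a)
    zs = centers(cyl.h / 2.0)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[cyl.contains(pts)]
    if pts.shape[0] < min_sites:
        raise ValueError(f"spacing d={d} nm places only {pts.shape[0]} sites "
                         f"(need >= {min_sites})")
    R = _rot_z(cyl.angle_alpha)
    eps = permittivity_tensor(cyl.material)
    eps_lab = R @ eps @ R.T
    return DipoleLattice(spacing=d, positions=pts, site_permittivity=eps_lab)
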