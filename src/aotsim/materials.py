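"""Optical materials: constituents, uniaxial crystals and the SiO2/Si3N4 metamaterial.

A sub-wavelength stack of alternating SiO2 and Si3N4 layers behaves as a
homogeneous *negative uniaxial* dielectric.  With doping fraction ``rho`` (the
volume fraction of Si3N4) the in-plane (ordinary) permittivity is the
arithmetic mean of the constituent permittivities and the stack-normal
(extraordinary) permittivity is their harmonic mean:

    n_o(rho) = sqrt((1 - rho) n1^2 + rho n2^2)
    n_e(rho) = 1 / sqrt((1 - rho) / n1^2 + rho / n2^2)

so both effective indices are tunable between n_SiO2 and n_Si3N4.  In the
cylinders modelled here the layer normal — the extraordinary axis — lies along
the cylinder axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OpticalMaterial",
    "MetamaterialSpec",
    "effective_indices",
    "permittivity_tensor",
    "material_preset",
    "N_SIO2_1064",
    "N_SI3N4_1064",
    "N_WATER",
]

# Constituent refractive indices at the 1064-nm trapping wavelength.
N_SIO2_1064 = 1.45
N_SI3N4_1064 = 2.01

# Aqueous surrounding medium (configurable at the beam/solver level).
N_WATER = 1.33

# Crystalline quartz at 1064 nm (positive uniaxial, literature default).
N_QUARTZ_O = 1.534
N_QUARTZ_E = 1.543

_UNIT_TOL = 1e-12


def _as_unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("axis must be a 3-vector")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"axis must be a unit vector (|axis| = {n:.3g})")
    return v / n


@dataclass(frozen=True)
class OpticalMaterial:
    """Lossless (possibly uniaxial) dielectric.

    Parameters
    ----------
    name : str
        Label used in configs and output manifests.
    n_o, n_e : float
        Ordinary and extraordinary refractive indices (>= 1).  Equal indices
        describe an isotropic material.
    axis : (3,) array
        Unit vector of the extraordinary axis in the particle frame.
    """

    name: str
    n_o: float
    n_e: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        object.__setattr__(self, "axis", _as_unit(self.axis))
        if self.n_o < 1.0 or self.n_e < 1.0:
            raise ValueError("refractive indices must be >= 1 (lossless dielectric)")

    @property
    def isotropic(self) -> bool:
        return abs(self.n_o - self.n_e) < _UNIT_TOL

    def with_axis(self, axis) -> "OpticalMaterial":
        return replace(self, axis=np.asarray(axis, dtype=float))


@dataclass(frozen=True)
class MetamaterialSpec:
    """SiO2/Si3N4 multilayer metamaterial, parametrized by the Si3N4 doping
    fraction ``rho`` (relative Si3N4 layer thickness)."""

    rho: float
    n_SiO2: float = N_SIO2_1064
    n_Si3N4: float = N_SI3N4_1064

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"doping fraction rho must lie in [0, 1], got {self.rho}")
        if self.n_SiO2 < 1.0 or self.n_Si3N4 < 1.0:
            raise ValueError("constituent indices must be >= 1")

    def material(self, axis=(0.0, 0.0, 1.0)) -> OpticalMaterial:
        """Homogenized uniaxial material with the extraordinary axis along
        ``axis`` (the stack normal; the cylinder axis in this design)."""
        n_o, n_e = effective_indices(self)
        return OpticalMaterial(f"meta(rho={self.rho:g})", n_o=n_o, n_e=n_e,
                               axis=np.asarray(axis, dtype=float))


def effective_indices(spec: MetamaterialSpec) -> tuple[float, float]:
    """Effective (ordinary, extraordinary) indices of the multilayer.

    The ordinary permittivity is the thickness-weighted arithmetic mean of the
    constituent permittivities; the extraordinary one is the harmonic mean.
    By the arithmetic–harmonic-mean inequality n_e <= n_o with equality only
    for a pure film (rho in {0, 1}).
    """
    e1, e2 = spec.n_SiO2**2, spec.n_Si3N4**2
    rho = spec.rho
    n_o = float(np.sqrt((1.0 - rho) * e1 + rho * e2))
    n_e = float(1.0 / np.sqrt((1.0 - rho) / e1 + rho / e2))
    return n_o, n_e


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ z_hat = axis (minimal rotation)."""
    z = np.array([0.0, 0.0, 1.0])
    a = _as_unit(axis)
    c = float(np.dot(z, a))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, a)
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def permittivity_tensor(material: OpticalMaterial) -> np.ndarray:
    """Relative permittivity tensor in the particle frame.

    In the material principal frame (z along the extraordinary axis) the
    tensor is diag(n_o^2, n_o^2, n_e^2); it is returned rotated so that the
    principal z-direction coincides with ``material.axis``.  The result is
    symmetric positive-definite with eigenvalues {n_o^2, n_o^2, n_e^2}.
    """
    diag = np.diag([material.n_o**2, material.n_o**2, material.n_e**2])
    R = _rotation_from_z(material.axis)
    eps = R @ diag @ R.T
    return 0.5 * (eps + eps.T)


def material_preset(name: str, axis=(0.0, 0.0, 1.0)) -> OpticalMaterial:
    """Materials addressable by name: "sio2", "si3n4", "quartz", "meta(rho)"
    (e.g. "meta(0.5)"), or "n=<value>" for a custom isotropic index."""
    key = name.strip().lower()
    axis = np.asarray(axis, dtype=float)
    if key == "sio2":
        return OpticalMaterial("sio2", N_SIO2_1064, N_SIO2_1064, axis)
    if key == "si3n4":
        return OpticalMaterial("si3n4", N_SI3N4_1064, N_SI3N4_1064, axis)
    if key == "quartz":
        return OpticalMaterial("quartz", N_QUARTZ_O, N_QUARTZ_E, axis)
    if key.startswith("meta(") and key.endswith(")"):
        rho = float(key[5:-1].replace("rho=", ""))
        return MetamaterialSpec(rho).material(axis)
    if key.startswith("n="):
        n = float(key[2:])
        return OpticalMaterial(name, n, n, axis)
    raise KeyError(f"unknown material preset {name!r}")
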