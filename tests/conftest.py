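import warnings

import numpy as np
import pytest

from aotsim.beam import FocusedBeam, PlaneWave
from aotsim.geometry import DipoleLattice, EllipticalCylinder, voxelize
from aotsim.materials import MetamaterialSpec
from aotsim.scattering import CoupledDipoleSolver


@pytest.fixture(scope="session")
def flagship_cylinder() -> EllipticalCylinder:
    """The fabricated design: rho=0.5 metamaterial, 2a=375/2b=300/h=600 nm."""
    return EllipticalCylinder(a=187.5, b=150.0, h=600.0,
                              material=MetamaterialSpec(0.5).material())


@pytest.fixture(scope="session")
def trap_beam() -> FocusedBeam:
    """NA 1.3, fill 0.98 beam at the 12.6-mW specimen power."""
    return FocusedBeam(power_specimen_mw=12.6)


@pytest.fixture(scope="session")
def flagship_solver(flagship_cylinder, trap_beam) -> CoupledDipoleSolver:
    """Coarse (40 nm) coupled-dipole solver for the flagship design, shared
    across tests (one factorization serves every beam offset/angle)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lat = voxelize(flagship_cylinder, 40.0)
    return CoupledDipoleSolver(lat, n_medium=trap_beam.n_medium)


def sphere_lattice(radius_nm: float, spacing_nm: float, n_index: float
                   ) -> DipoleLattice:
    """Cubic-lattice voxelization of an isotropic sphere (test scaffolding)."""
    m = int(np.ceil(radius_nm / spacing_nm - 0.5))
    c = (np.arange(-m, m + 1) + 0.5) * spacing_nm
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[(pts**2).sum(1) <= radius_nm**2]
    return DipoleLattice(spacing=spacing_nm, positions=pts,
                         site_permittivity=np.eye(3) * n_index**2)


@pytest.fixture(scope="session")
def mie_sphere_solution():
    """Converged plane-wave solve for the n=1.45, r=150 nm test sphere."""
    lat = sphere_lattice(150.0, 25.0, 1.45)
    pw = PlaneWave(n_medium=1.33)
    sol = CoupledDipoleSolver(lat, n_medium=1.33).solve(pw)
    return pw, sol
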