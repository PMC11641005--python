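"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own code paths: the Mie series is the
textbook Lorenz–Mie solution for a homogeneous sphere; the boxcar-averaged
Ornstein–Uhlenbeck variance is the closed-form second-moment integral; the
brute-force focal field sums the Debye–Wolf angular spectrum directly in 2-D
(theta, phi) without the Bessel reduction used by the implementation.
"""

import numpy as np
from scipy.special import spherical_jn, spherical_yn

Z0 = 376.730313668


def mie_cross_sections(n_particle: float, n_medium: float, radius_nm: float,
                       wavelength_nm: float):
    """(C_ext, C_sca, g, C_pr) in m^2 for a lossless homogeneous sphere."""
    k = 2 * np.pi * n_medium / (wavelength_nm * 1e-9)
    x = k * radius_nm * 1e-9
    m = n_particle / n_medium
    nmax = int(x + 4 * x ** (1 / 3) + 10)
    n = np.arange(1, nmax + 1)
    jx = spherical_jn(n, x)
    jpx = spherical_jn(n, x, derivative=True)
    hx = jx + 1j * spherical_yn(n, x)
    hpx = jpx + 1j * spherical_yn(n, x, derivative=True)
    mx = m * x
    jm = spherical_jn(n, mx)
    jpm = spherical_jn(n, mx, derivative=True)
    psix, psipx = x * jx, jx + x * jpx
    psim, psipm = mx * jm, jm + mx * jpm
    xix, xipx = x * hx, hx + x * hpx
    a = (m * psim * psipx - psix * psipm) / (m * psim * xipx - xix * psipm)
    b = (psim * psipx - m * psix * psipm) / (psim * xipx - m * xix * psipm)
    c_ext = (2 * np.pi / k**2) * np.sum((2 * n + 1) * np.real(a + b))
    c_sca = (2 * np.pi / k**2) * np.sum((2 * n + 1)
                                        * (np.abs(a)**2 + np.abs(b)**2))
    t1 = np.sum(n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
                * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])))
    t2 = np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b)))
    g = (4 * np.pi / k**2) * (t1 + t2) / c_sca
    return c_ext, c_sca, g, c_ext - g * c_sca


def ou_boxcar_variance(sigma2: float, tau_c: float, t_window: float) -> float:
    """Variance of the time average of a stationary OU process (variance
    ``sigma2``, correlation time ``tau_c``) over a window ``t_window``."""
    r = tau_c / t_window
    return sigma2 * 2 * r * (1 - r * (1 - np.exp(-1.0 / r)))


def brute_force_focal_fields(beam, points_nm, n_theta=400, n_phi=512):
    """Direct 2-D angular-spectrum evaluation of the focused beam's (E, H).

    Sums plane-wave components over a (theta, phi) product grid using the
    s/p decomposition explicitly; shares only the pupil definition and the
    power normalization constant with the implementation.
    """
    theta_max = beam.theta_max
    k = beam.k_medium
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = 0.5 * theta_max * (x + 1.0)
    wt = 0.5 * theta_max * w
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    wp = 2 * np.pi / n_phi

    # pupil (same definition as the implementation, including aberration)
    s = np.sin(theta) / np.sin(theta_max)
    apod = np.exp(-(s / beam.fill_factor) ** 2) * np.sqrt(np.cos(theta))
    apod = apod * np.exp(1j * beam._aberration_phase(theta))
    amp = beam._amplitude() / np.pi   # the raw C prefactor

    T, P = np.meshgrid(theta, phi, indexing="ij")
    st, ct = np.sin(T), np.cos(T)
    cp, sp = np.cos(P), np.sin(P)
    khat = np.stack([st * cp, st * sp, ct], axis=-1)
    s_hat = np.stack([-sp, cp, np.zeros_like(cp)], axis=-1)
    p_hat = np.stack([ct * cp, ct * sp, -st], axis=-1)
    # x-polarized input: e = -sin(phi) s_hat + cos(phi) p_hat
    e = -sp[..., None] * s_hat + cp[..., None] * p_hat
    h = np.cross(khat, e) * beam.n_medium / Z0
    weight = (wt[:, None] * wp * st) * apod[:, None]

    pts = np.atleast_2d(np.asarray(points_nm, float)) * 1e-9
    E = np.zeros((pts.shape[0], 3), complex)
    H = np.zeros_like(E)
    for i, r in enumerate(pts):
        phase = np.exp(1j * k * (khat @ r))
        E[i] = amp * np.einsum("tp,tp,tpa->a", weight, phase, e)
        H[i] = amp * np.einsum("tp,tp,tpa->a", weight, phase, h)
    return E, H
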