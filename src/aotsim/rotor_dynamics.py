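"""Rotation of a trapped cylinder under rotating polarization: phase locking,
slippage, and the torque-vs-rate fit.

The orientation theta of the trapped cylinder relative to the rotating
polarization psi(t) = 2 pi omega t obeys an overdamped Adler equation,

    gamma_theta dtheta/dt = -tau_max sin(2 (theta - psi(t))) [+ thermal torque]

(the alignment potential has period pi: rotating the major axis by half a
turn is a symmetry).  Below the critical rate omega_max = tau_max /
gamma_theta the cylinder phase-locks and the mean viscous drag torque grows
linearly, tau = gamma_theta omega; above it the cylinder slips and the mean
drag torque falls as

    tau = gamma_theta [ omega - sqrt(omega^2 - omega_max^2) ],

the Adler mean-drift law.  Fitting measured (omega, mean tau) pairs to this
piecewise curve yields gamma_theta and tau_max, and omega_max via their
ratio.

Units: user-facing rates are turn/s and drag coefficients pN·nm·s/turn (the
experiment's units); all internal integration is per-radian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .constants import ROOM_TEMPERATURE_K, TWO_PI, kbt

__all__ = ["SpinProtocol", "SpinTrajectory", "SlippageFit",
           "mean_torque_model", "simulate_rotation", "fit_slippage"]


def mean_torque_model(omega, gamma_theta: float, tau_max: float):
    """Mean viscous drag torque (pN·nm) vs polarization rate (turn/s).

    ``gamma_theta`` in pN·nm·s/turn, ``tau_max`` in pN·nm.  Continuous at
    omega_max = tau_max/gamma_theta, where the torque peaks at tau_max.
    """
    if gamma_theta <= 0 or tau_max <= 0:
        raise ValueError("gamma_theta and tau_max must be positive")
    omega = np.asarray(omega, dtype=float)
    omega_max = tau_max / gamma_theta
    locked = gamma_theta * omega
    over = np.maximum(omega**2 - omega_max**2, 0.0)
    slipping = gamma_theta * (omega - np.sqrt(over))
    out = np.where(omega <= omega_max, locked, slipping)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SpinProtocol:
    """One spin test: rotate the polarization at ``omega`` for ``duration``.

    ``gamma_theta`` is pN·nm·s/turn, ``tau_max`` pN·nm.  ``seed=None`` runs
    the deterministic (zero-temperature) dynamics; an integer seed adds
    thermal torque with rotational diffusion D = kBT/gamma_theta.
    """

    omega: float                  # turn/s
    duration: float               # s
    gamma_theta: float            # pN·nm·s/turn
    tau_max: float                # pN·nm
    dt: float = 1e-5              # s
    temperature: float = ROOM_TEMPERATURE_K
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("omega", "duration", "gamma_theta", "tau_max", "dt",
                     "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # explicit-Euler stability of the sin(2x) drive
        if self.dt * 2.0 * self.tau_max / self.gamma_theta_per_rad >= 0.1:
            raise ValueError(
                f"dt={self.dt} too large for tau_max/gamma_theta="
                f"{self.tau_max / self.gamma_theta:.3g} turn/s; "
                "reduce dt (angular update must stay below 0.1 rad)")

    @property
    def gamma_theta_per_rad(self) -> float:
        return self.gamma_theta / TWO_PI

    @property
    def omega_max(self) -> float:
        """Critical (slippage) rate tau_max/gamma_theta, turn/s."""
        return self.tau_max / self.gamma_theta


@dataclass
class SpinTrajectory:
    """Integrated orientation trace and derived drag torque."""

    t: np.ndarray                  # s
    theta: np.ndarray              # rad
    psi: np.ndarray                # rad (polarization angle)
    drag_torque: np.ndarray        # pN·nm, gamma_theta_rad * dtheta/dt
    protocol: SpinProtocol

    def mean_drag_torque(self, burn_in: float = 0.2) -> float:
        """Mean viscous drag torque (pN·nm) over the steady portion.

        Discards ``burn_in`` (fraction of the duration) as transient.  In the
        slipping regime the average is taken over an integer number of slip
        cycles (the lag angle advances by pi per cycle), which removes the
        partial-cycle bias from the estimate.
        """
        p = self.protocol
        i0 = int(burn_in * len(self.t))
        chi = self.theta - self.psi
        tail = chi[i0:]
        tt = self.t[i0:]
        drop = float(chi[i0] - tail.min())
        if drop < 1.5 * np.pi:
            # phase-locked (or barely slipping): plain tail average
            mean_rate = (self.theta[-1] - self.theta[i0]) / (self.t[-1] - self.t[i0])
        else:
            # integer slip cycles: first and last crossing of chi0 - k*pi
            k = np.floor((tail[0] - tail) / np.pi).astype(int)
            n_cyc = k.max()
            ia = int(np.argmax(k >= 1))
            ib = int(np.argmax(k >= n_cyc))
            slip_rate = (n_cyc - 1) * np.pi / (tt[ib] - tt[ia]) if n_cyc > 1 else \
                np.pi / (tt[ib] - tt[0])
            mean_rate = TWO_PI * p.omega - slip_rate
        return p.gamma_theta_per_rad * mean_rate


def simulate_rotation(protocol: SpinProtocol) -> SpinTrajectory:
    """Integrate the driven Adler dynamics (Euler–Maruyama when thermal noise
    is on; plain Euler otherwise).  Deterministic given the seed."""
    p = protocol
    n = int(round(p.duration / p.dt))
    t = np.arange(n + 1) * p.dt
    psi = TWO_PI * p.omega * t
    gamma_rad = p.gamma_theta_per_rad
    rate = p.tau_max / gamma_rad           # rad/s scale of the drive
    theta = np.empty(n + 1)
    theta[0] = 0.0
    if p.seed is None:
        noise = None
    else:
        d_rot = kbt(p.temperature) / gamma_rad      # rad^2/s
        rng = np.random.default_rng(p.seed)
        noise = rng.standard_normal(n) * np.sqrt(2.0 * d_rot * p.dt)
    th = 0.0
    for i in range(n):
        th += -rate * np.sin(2.0 * (th - psi[i])) * p.dt
        if noise is not None:
            th += noise[i]
        theta[i + 1] = th
    drag = gamma_rad * np.gradient(theta, p.dt)
    return SpinTrajectory(t=t, theta=theta, psi=psi, drag_torque=drag,
                          protocol=p)


# ---------------------------------------------------------------------------
# slippage fit
# ---------------------------------------------------------------------------

@dataclass
class SlippageFit:
    """Result of fitting (omega, mean tau) data to the phase-slip torque curve.

    ``omega_max = tau_max / gamma_theta`` holds exactly by construction.
    """

    gamma_theta: float             # pN·nm·s/turn
    tau_max: float                 # pN·nm
    gamma_theta_se: float
    tau_max_se: float
    omegas: np.ndarray
    torques: np.ndarray
    residuals: np.ndarray
    omega_max_is_lower_bound: bool = False

    @property
    def omega_max(self) -> float:
        return self.tau_max / self.gamma_theta

    def predict(self, omega):
        return mean_torque_model(omega, self.gamma_theta, self.tau_max)

    def summary(self) -> str:
        bound = " (lower bound)" if self.omega_max_is_lower_bound else ""
        lines = [
            "Phase-slip torque-curve fit",
            "---------------------------",
            f"gamma_theta : {self.gamma_theta:8.4g} +/- {self.gamma_theta_se:.2g} pN·nm·s/turn",
            f"tau_max     : {self.tau_max:8.4g} +/- {self.tau_max_se:.2g} pN·nm",
            f"omega_max   : {self.omega_max:8.4g} turn/s{bound}",
            f"n points    : {len(self.omegas)}   rms residual: "
            f"{np.sqrt(np.mean(self.residuals**2)):.3g} pN·nm",
        ]
        return "\n".join(lines)


def fit_slippage(omegas, torques, weights=None) -> SlippageFit:
    """Least-squares fit of the piecewise locked/slipping torque curve.

    Parameters are (gamma_theta, tau_max); omega_max is reported as their
    ratio.  ``weights`` (optional) multiply the residuals.  If no data point
    lies beyond the fitted omega_max the peak is unconstrained: the fit
    warns and flags ``omega_max_is_lower_bound``.
    """
    om = np.asarray(omegas, dtype=float)
    tq = np.asarray(torques, dtype=float)
    if om.size != tq.size or om.size < 5:
        raise ValueError("need >= 5 (omega, torque) pairs")
    w = np.ones_like(om) if weights is None else np.asarray(weights, float)

    # initial guess: slope of the low-rate half; peak torque
    order = np.argsort(om)
    half = order[: max(om.size // 2, 2)]
    g0 = max(np.sum(tq[half] * om[half]) / np.sum(om[half] ** 2), 1e-12)
    t0 = max(tq.max(), 1e-12)

    def resid(logp):
        g, tm = np.exp(logp)
        return w * (mean_torque_model(om, g, tm) - tq)

    fit = least_squares(resid, np.log([g0, t0]), method="lm", xtol=1e-14,
                        ftol=1e-14)
    g, tm = np.exp(fit.x)
    # parameter covariance from the Jacobian (delta method for the log-params)
    dof = max(om.size - 2, 1)
    s2 = float(np.sum(fit.fun**2) / dof)
    try:
        cov_log = s2 * np.linalg.inv(fit.jac.T @ fit.jac)
        se = np.sqrt(np.diag(cov_log)) * np.array([g, tm])
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    flag = not np.any(om > tm / g)
    if flag:
        warnings.warn("no sampled rate exceeds the fitted omega_max; "
                      "tau_max and omega_max are lower bounds", stacklevel=2)
    return SlippageFit(gamma_theta=float(g), tau_max=float(tm),
                       gamma_theta_se=float(se[0]), tau_max_se=float(se[1]),
                       omegas=om, torques=tq,
                       residuals=mean_torque_model(om, g, tm) - tq,
                       omega_max_is_lower_bound=bool(flag))
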