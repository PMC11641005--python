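"""Synthetic DNA twisting traces and the extension/torque-vs-turns analysis.

A torsionally constrained DNA held at constant force (~1 pN) and twisted at a
constant rate shows a characteristic phenomenology: torque builds linearly
with added turns while extension stays flat; past the buckling transition a
plectoneme grows, extension falls linearly, and torque plateaus at the
buckling torque; unwinding instead drives the duplex into local melting with
a constant negative torque plateau.  The generator reproduces exactly this
piecewise backbone — the quantity torque spectroscopy measures — plus the
measurement noise of an angular trap: the cylinder's angular coordinate is an
Ornstein–Uhlenbeck process with stiffness kappa_theta and drag gamma_theta
(variance kBT/kappa_theta, corner frequency kappa_theta / (2 pi
gamma_theta_rad)), read out as torque through kappa_theta * alpha.

The torque signal-to-noise ratio of such a measurement is

    SNR = tau_DNA / sqrt(4 kBT gamma_theta_rad B)

for measurement bandwidth B well below the corner frequency — so reducing
the rotational drag of the trapped particle directly buys torque resolution.

The analysis mirrors standard practice: boxcar smoothing in turns, a
two-segment continuous piecewise-linear fit of extension to locate buckling,
a linear pre-buckling torque fit, and Gaussian fits to the plateau torque
histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .constants import ROOM_TEMPERATURE_K, TWO_PI, kbt

__all__ = ["TwistConfig", "TwistTrace", "TwistAnalysis", "PlateauStats",
           "torque_snr", "generate_twist_trace", "analyze_twist_trace"]


def torque_snr(tau_dna: float, gamma_theta: float, bandwidth_hz: float,
               temperature_k: float = ROOM_TEMPERATURE_K) -> float:
    """Torque-measurement signal-to-noise ratio.

    ``tau_dna`` pN·nm, ``gamma_theta`` pN·nm·s/turn (converted to per-rad
    internally), ``bandwidth_hz`` Hz.  Valid when the bandwidth is well below
    the particle's corner frequency.
    """
    if min(tau_dna, gamma_theta, bandwidth_hz, temperature_k) <= 0:
        raise ValueError("all SNR arguments must be positive")
    gamma_rad = gamma_theta / TWO_PI
    return tau_dna / np.sqrt(4.0 * kbt(temperature_k) * gamma_rad * bandwidth_hz)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwistConfig:
    """Conditions of one synthetic twisting run (defaults: 1-pN experiment,
    2 turn/s winding, 400 Hz sampling, metamaterial-cylinder drag).

    The torque backbone is linear in turns with slope ``torsional_slope``
    between ``melting_turn`` and ``buckling_turn`` and clamped at the plateau
    values beyond; extension is flat before buckling and decreases at
    ``extension_slope_post_buckling`` past it (floored at zero).  Defaults
    put the plateaus at the 1-pN buckling/melting torques (+12.8 / −10.5
    pN·nm) of a ~6.5-kb molecule.
    """

    force: float = 1.0                      # pN (ideal clamp; bookkeeping only)
    twist_rate: float = 2.0                 # turn/s
    sampling_rate: float = 400.0            # Hz
    turns_end: float = 30.0                 # final turn count (sign = direction)
    torsional_slope: float = 0.85           # pN·nm per turn, pre-buckling
    buckling_plateau: float = 12.8          # pN·nm
    melting_plateau: float = -10.5          # pN·nm
    buckling_turn: Optional[float] = None   # default: plateau / slope
    melting_turn: Optional[float] = None
    extension0: float = 1860.0              # nm at 1 pN, ~6.5 kb
    extension_slope_post_buckling: float = -45.0   # nm/turn
    extension_noise_nm: float = 10.0        # white, per 400-Hz sample
    gamma_theta: float = 3.2                # pN·nm·s/turn
    kappa_theta: float = 3000.0             # pN·nm/rad angular trap stiffness
    acquisition_rate: float = 10000.0       # Hz; hardware rate averaged down
    temperature: float = ROOM_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self):
        if self.buckling_plateau <= 0 or self.melting_plateau >= 0:
            raise ValueError("need buckling_plateau > 0 > melting_plateau")
        if self.torsional_slope <= 0:
            raise ValueError("torsional_slope must be positive")
        if self.sampling_rate < 4.0 * self.twist_rate:
            raise ValueError("sampling_rate must comfortably resolve the "
                             "twist rate (>= 4x)")
        if self.acquisition_rate < self.sampling_rate:
            raise ValueError("acquisition_rate must be >= sampling_rate")
        if self.buckling_turn is None:
            object.__setattr__(self, "buckling_turn",
                               self.buckling_plateau / self.torsional_slope)
        if self.melting_turn is None:
            object.__setattr__(self, "melting_turn",
                               self.melting_plateau / self.torsional_slope)
        if not (self.melting_turn < 0 < self.buckling_turn):
            raise ValueError("invalid regime ordering: need "
                             "melting_turn < 0 < buckling_turn")
        if self.gamma_theta <= 0 or self.kappa_theta <= 0:
            raise ValueError("gamma_theta and kappa_theta must be positive")
        if self.corner_frequency_hz < 10.0 / TWO_PI:
            warnings.warn("corner frequency is very low; the white-noise "
                          "bandwidth assumption of the SNR formula fails",
                          stacklevel=2)

    @property
    def gamma_theta_per_rad(self) -> float:
        return self.gamma_theta / TWO_PI

    @property
    def corner_frequency_hz(self) -> float:
        return self.kappa_theta / (TWO_PI * self.gamma_theta_per_rad)

    def backbone(self, turns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Noise-free (torque, extension) at the given turn counts."""
        turns = np.asarray(turns, dtype=float)
        torque = np.clip(self.torsional_slope * turns,
                         self.melting_plateau, self.buckling_plateau)
        ext = self.extension0 + self.extension_slope_post_buckling * np.maximum(
            turns - self.buckling_turn, 0.0)
        return torque, np.maximum(ext, 0.0)


@dataclass(frozen=True)
class TwistTrace:
    """Sampled twisting run: time (s), turns, extension (nm), torque (pN·nm)."""

    t: np.ndarray
    turns: np.ndarray
    extension: np.ndarray
    torque: np.ndarray
    config: Optional[TwistConfig] = None

    def __post_init__(self):
        for name in ("t", "turns", "extension", "torque"):
            object.__setattr__(self, name, np.asarray(getattr(self, name),
                                                      dtype=float))
        n = self.t.size
        if not all(getattr(self, k).size == n
                   for k in ("turns", "extension", "torque")):
            raise ValueError("all trace arrays must have equal length")

    @property
    def samples_per_turn(self) -> float:
        dn = np.abs(np.median(np.diff(self.turns)))
        if dn == 0:
            raise ValueError("turns do not advance")
        return 1.0 / dn


def generate_twist_trace(config: TwistConfig, *, noise: bool = True) -> TwistTrace:
    """Synthesize one twisting run (reproducible per seed).

    The torque channel emulates the instrument's acquisition chain: the
    cylinder's angular fluctuation alpha is an exactly discretized OU process
    at ``acquisition_rate`` (e.g. 10 kHz), converted to torque through
    kappa_theta and boxcar-averaged down to ``sampling_rate`` — the averaging
    is what makes the recorded noise follow the sqrt(4 kBT gamma B) bandwidth
    law rather than the full aliased sqrt(kBT kappa) spread.  Extension noise
    is white Gaussian per recorded sample.  ``noise=False`` returns the
    piecewise backbone exactly.
    """
    cfg = config
    n = int(round(abs(cfg.turns_end) / cfg.twist_rate * cfg.sampling_rate))
    t = np.arange(n + 1) / cfg.sampling_rate
    turns = np.sign(cfg.turns_end) * cfg.twist_rate * t
    torque_bb, ext_bb = cfg.backbone(turns)
    if not noise:
        return TwistTrace(t=t, turns=turns, extension=ext_bb,
                          torque=torque_bb, config=cfg)

    from scipy.signal import lfilter

    rng = np.random.default_rng(cfg.seed)
    over = max(int(round(cfg.acquisition_rate / cfg.sampling_rate)), 1)
    n_acq = (n + 1) * over
    # exact OU update at the acquisition rate
    sigma_alpha = np.sqrt(kbt(cfg.temperature) / cfg.kappa_theta)
    tau_c = cfg.gamma_theta_per_rad / cfg.kappa_theta        # s
    rho = np.exp(-1.0 / (cfg.sampling_rate * over * tau_c))
    innov = rng.standard_normal(n_acq) * (sigma_alpha * np.sqrt(1.0 - rho**2))
    innov[0] = sigma_alpha * rng.standard_normal()           # stationary start
    alpha = lfilter([1.0], [1.0, -rho], innov)
    alpha_rec = alpha.reshape(n + 1, over).mean(axis=1)      # averaged to 400 Hz
    torque = torque_bb + cfg.kappa_theta * alpha_rec
    ext = ext_bb + cfg.extension_noise_nm * rng.standard_normal(n + 1)
    return TwistTrace(t=t, turns=turns, extension=ext, torque=torque,
                      config=cfg)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateauStats:
    """Gaussian fit to a torque-plateau histogram of window-averaged samples."""

    mean: float                  # pN·nm
    sd: float                    # pN·nm
    n_windows: int
    fit_params: tuple            # (amplitude, mean, sd) of the Gaussian fit


@dataclass
class TwistAnalysis:
    """Extension/torque-vs-turns analysis of one (or half of one) trace."""

    buckling_turn_hat: Optional[float] = None
    pre_buckling_slope_hat: Optional[float] = None
    plateau_pos: Optional[PlateauStats] = None
    melting_turn_hat: Optional[float] = None
    plateau_neg: Optional[PlateauStats] = None
    extension_slope_hat: Optional[float] = None
    flags: list = field(default_factory=list)

    def summary(self) -> str:
        def fmt(x, unit=""):
            return "   --" if x is None else f"{x:8.3f}{unit}"
        lines = ["DNA twist-trace analysis", "------------------------",
                 f"buckling turn        : {fmt(self.buckling_turn_hat, ' turns')}",
                 f"pre-buckling slope   : {fmt(self.pre_buckling_slope_hat, ' pN·nm/turn')}",
                 f"extension slope      : {fmt(self.extension_slope_hat, ' nm/turn')}"]
        for label, p in (("(+) plateau", self.plateau_pos),
                         ("(−) plateau", self.plateau_neg)):
            if p is not None:
                lines.append(f"{label}          : {p.mean:8.3f} ± {p.sd:.3f} pN·nm "
                             f"(Gaussian fit, {p.n_windows} windows)")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _boxcar_turns(y: np.ndarray, window_turns: float, spt: float) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d
    w = max(int(round(window_turns * spt)), 1)
    return uniform_filter1d(y, size=w, mode="nearest")


def _plateau_samples(y: np.ndarray, window_turns: float, spt: float
                     ) -> tuple[np.ndarray, int]:
    """Boxcar-smoothed plateau torque (edge-trimmed) and the effective number
    of independent smoothing windows it contains."""
    w = max(int(round(window_turns * spt)), 1)
    from scipy.ndimage import uniform_filter1d
    sm = uniform_filter1d(y, size=w, mode="nearest")
    if y.size > 2 * w:
        sm = sm[w // 2: -(w // 2)]
    return sm, max(y.size // w, 1)


def _gaussian_fit(samples: np.ndarray, n_eff: int) -> PlateauStats:
    """Histogram (Freedman–Diaconis width on the effective independent count)
    + least-squares Gaussian fit, mirroring how plateau torque histograms are
    reported."""
    mu0, sd0 = float(np.mean(samples)), float(np.std(samples, ddof=1))
    q75, q25 = np.percentile(samples, [75, 25])
    bw = 2.0 * (q75 - q25) / max(n_eff, 2) ** (1.0 / 3.0)
    if bw <= 0:
        return PlateauStats(mean=mu0, sd=sd0, n_windows=n_eff,
                            fit_params=(np.nan, mu0, sd0))
    nbins = max(int(np.ceil((samples.max() - samples.min()) / bw)), 4)
    counts, edges = np.histogram(samples, bins=nbins)
    centers = 0.5 * (edges[1:] + edges[:-1])

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    try:
        popt, _ = curve_fit(gauss, centers, counts,
                            p0=(counts.max(), mu0, sd0), maxfev=5000)
        amp, mu, sd = popt
        sd = abs(float(sd))
        return PlateauStats(mean=float(mu), sd=sd, n_windows=n_eff,
                            fit_params=(float(amp), float(mu), sd))
    except RuntimeError:
        return PlateauStats(mean=mu0, sd=sd0, n_windows=n_eff,
                            fit_params=(np.nan, mu0, sd0))


def _two_segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Continuous two-line fit y ~ c0 + c1 x + c2 max(x - xb, 0).

    Returns (breakpoint, second-segment slope change c2).  The breakpoint is
    found by minimizing the profiled SSE over interior candidates.
    """
    lo, hi = np.quantile(x, [0.05, 0.95])

    def sse(xb):
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - xb, 0.0)])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    grid = np.linspace(lo, hi, 60)
    xb0 = grid[int(np.argmin([sse(g) for g in grid]))]
    span = (hi - lo) / 59.0
    res = minimize_scalar(sse, bounds=(max(lo, xb0 - 2 * span),
                                       min(hi, xb0 + 2 * span)),
                          method="bounded")
    xb = float(res.x)
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - xb, 0.0)])
    coef = np.linalg.lstsq(X, y, rcond=None)[0]
    return xb, float(coef[2])


def analyze_twist_trace(trace: TwistTrace, *, extension_window: float = 0.1,
                        torque_window: float = 1.0,
                        plateau_margin: float = 2.0) -> TwistAnalysis:
    """Analyze a twisting trace (either winding direction, or both in turn).

    Positive side: extension smoothed to ``extension_window`` turns is fit by
    a continuous two-segment line whose breakpoint estimates the buckling
    turn; torque smoothed to ``torque_window`` gives the pre-buckling slope;
    plateau statistics are Gaussian fits to window-averaged torque beyond the
    breakpoint plus ``plateau_margin`` turns.  Negative side: the melting
    onset is located on the smoothed torque (linear-then-flat two-segment
    fit) and the melting plateau treated the same way.  Missing regimes
    produce flags, not errors.
    """
    out = TwistAnalysis()
    spt = trace.samples_per_turn
    pos = trace.turns >= 0.0
    neg = trace.turns <= 0.0
    if np.count_nonzero(pos) > 10 * spt:
        _analyze_positive(trace, pos, spt, extension_window, torque_window,
                          plateau_margin, out)
    if np.count_nonzero(neg) > 10 * spt:
        _analyze_negative(trace, neg, spt, torque_window, plateau_margin, out)
    if out.plateau_pos is None and out.plateau_neg is None:
        out.flags.append("no plateau detected")
    return out


def _analyze_positive(trace, mask, spt, ext_win, tq_win, margin, out):
    turns = trace.turns[mask]
    order = np.argsort(turns)
    turns = turns[order]
    ext = _boxcar_turns(trace.extension[mask][order], ext_win, spt)
    tq_s = _boxcar_turns(trace.torque[mask][order], tq_win, spt)

    # restrict the breakpoint fit to where the tether is not fully compacted
    ext0 = np.median(ext[: max(int(spt), 2)])
    usable = ext > 0.1 * ext0
    if np.count_nonzero(usable) < 4 * spt:
        out.flags.append("extension fully compacted; no breakpoint fit")
        return
    xb, dslope = _two_segment_fit(turns[usable], ext[usable])
    if dslope > -1e-9 or xb >= turns[usable].max() - 1.0:
        out.flags.append("no buckling detected on (+) side")
        xb = None
    out.buckling_turn_hat = xb
    if xb is not None:
        out.extension_slope_hat = dslope
        pre = (turns > 0.5) & (turns < xb - 0.5)
        if np.count_nonzero(pre) > spt:
            out.pre_buckling_slope_hat = float(
                np.polyfit(turns[pre], tq_s[pre], 1)[0])
        plat = trace.turns[mask][order] > xb + margin
        samples, n_eff = _plateau_samples(trace.torque[mask][order][plat],
                                          tq_win, spt)
        if n_eff >= 8:
            out.plateau_pos = _gaussian_fit(samples, n_eff)
        else:
            out.flags.append("insufficient (+) plateau data")


def _analyze_negative(trace, mask, spt, tq_win, margin, out):
    turns = trace.turns[mask]
    order = np.argsort(-turns)          # 0 -> most negative
    tneg = -turns[order]                # positive coordinate
    tq = trace.torque[mask][order]
    tq_s = _boxcar_turns(tq, tq_win, spt)
    xb, dslope = _two_segment_fit(tneg, tq_s)
    if dslope < 1e-9 or xb >= tneg.max() - 1.0:
        out.flags.append("no melting onset detected on (−) side")
        return
    out.melting_turn_hat = -xb
    plat = tneg > xb + margin
    samples, n_eff = _plateau_samples(tq[plat], tq_win, spt)
    if n_eff >= 8:
        out.plateau_neg = _gaussian_fit(samples, n_eff)
    else:
        out.flags.append("insufficient (−) plateau data")
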