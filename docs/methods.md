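# Methods

This note documents the models implemented in aotsim, the numerical choices
behind them, what the synthetic-data generators do and do not emulate, and
the known limitations. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## Effective-medium optics

A stack of alternating SiO₂/Si₃N₄ layers, each far thinner than the 1064-nm
trapping wavelength, is homogenized as a uniaxial dielectric whose optic
(extraordinary) axis is the layer normal — in these cylinders, the cylinder
axis. With Si₃N₄ volume fraction ρ the in-plane permittivity is the
arithmetic mean of the constituent permittivities and the normal
permittivity their harmonic mean, so n_e ≤ n_o (negative uniaxial) with
equality only at ρ ∈ {0, 1}, and both indices increase monotonically with ρ
between n_SiO₂ = 1.45 and n_Si₃N₄ = 2.01 (1064-nm values; overridable).
Layer-resolved simulation of the physical ~60-nm stack is deliberately out
of scope — the homogenized tensor is the model. The surrounding medium is
water, n_m = 1.33 (configurable); quartz for comparison runs uses the
literature 1064-nm values n_o = 1.534, n_e = 1.543. All materials are
lossless.

## Beam synthesis

The focused trap beam is computed with the Richards–Wolf (Debye–Wolf)
angular spectrum for a linearly polarized Gaussian input. Because the pupil
is azimuthally symmetric, the two-dimensional diffraction integral reduces
to three one-dimensional polar integrals (I₀, I₁, I₂) with Bessel kernels;
a brute-force 2-D plane-wave summation over the same spectrum is kept in
the tests as an independent oracle and agrees to ~1e-6 relative.

Choices that matter:

- **Aperture filling.** `fill_factor` is the waist-to-aperture-radius ratio
  w/R (default 0.98): pupil amplitude ∝ exp(−(sinθ / (f₀ sinθ_max))²),
  with the aplanatic √cosθ factor. At f₀ ≈ 1 the pupil is strongly
  truncated and the focal spot is Airy-like rather than Gaussian — the
  Gaussian-waist closed form is only used as a test oracle at f₀ = 0.35.
- **Interface aberration.** Focusing from immersion oil (n = 1.518) into
  water adds the index-mismatch optical-path-difference phase
  k₀ d (n_m cosθ_m − n_imm cosθ_imm) with the focus a depth d past the
  interface (default d = 1000 nm, configurable; the appropriate value
  depends on the trap height above the coverslip in the experiment being
  modeled). Fresnel s/p transmission amplitudes are neglected — at these
  angles they redistribute at most tens of percent of the marginal-ray
  power and no reported quantity is sensitive at leading order — and the
  propagation runs entirely with the aqueous wavenumber (NA ≤ n_m is
  enforced; supercritical, evanescent components are unsupported).
- **Normalization.** The overall amplitude is fixed analytically from the
  plane-wave orthogonality relation so that the time-averaged Poynting flux
  through any transverse plane equals the specimen-plane power; the flux
  test recovers it numerically within 1%. Polarization angle is a director
  (period π) and rotating it rotates the focal field rigidly about the
  axis, which the solver exploits.
- **Quadrature.** Gauss–Legendre in θ (160 nodes by default); doubling the
  order changes fields by < 0.1%.

Internally fields are SI (V/m, A/m) so stress-tensor integrals emerge in
newtons; all user-facing lengths are nm and outputs pN / pN·nm.

## Scattering and optical wrench

The cylinder is voxelized on a cubic lattice (site centers at half-integer
spacings from the centroid, preserving the 180°—and for circular sections
90°—rotational symmetry that the torque symmetry tests rely on). Each site
carries the material permittivity tensor and a Clausius–Mossotti tensor
polarizability with radiative-reaction correction; the coupled-dipole
system with free-space dyadic Green interactions in the medium is solved by
a cached dense LU factorization (the matrix depends only on the lattice, so
one factorization serves a whole landscape scan; a matrix-free BiCGStab
path exists and matches the direct solve). The Clausius–Mossotti choice —
rather than a lattice-dispersion-relation prescription — is the simplest
correct-to-leading-order polarizability; its accuracy at the spacings used
here is checked directly against the Lorenz–Mie series: extinction and
radiation-pressure force agree within 1–7% for relative indices up to 1.4
at 25–40 nm spacing.

Force and torque are surface integrals of the time-averaged Maxwell stress
tensor of the total field over a sphere (circumscribing radius + 3 lattice
spacings; Gauss–Legendre × uniform-azimuth product quadrature with ≥ 1300
nodes; doubling nodes moves results < 1%). An independent gradient-force
dipole summation agrees with the stress-tensor force to better than 5%
(observed: ~1e-5 relative on the flagship design).

Landscape conventions:

- The axial scan holds the beam polarization along the cylinder's major
  axis (the zero-net-torque orientation a trapped cylinder adopts) and
  steps the particle along the axis. U(z) = −∫F_z dz by trapezoid.
- **z_eq is the deepest interior *local* minimum of U.** The global minimum
  is grid-dependent — the scattering-force tail keeps lowering U far
  downstream — while the trapping well is not. No interior local minimum ⇒
  "not trappable" (U_esc = 0), a result, not an error.
- **U_esc** is the barrier from z_eq to the downstream potential maximum
  (escape is downstream, where the scattering force pushes); **F_max** is
  the maximum restoring axial force magnitude; **τ_max** the maximum
  |τ_z(α)| over misalignment α, computed by rotating the beam polarization
  (equivalent to rotating the particle, but reusing the factorization),
  with the restoring convention τ_z < 0 for small α > 0.
- kBT = 4.089 pN·nm (23 °C) converts barriers to thermal units.
- Default dipole spacing 30 nm, coarse mode 40 nm; the landscape problem
  sizes used throughout (≈ 800–1000 dipoles, 15–30 axial points) keep a
  full design evaluation at the few-minute scale on one core.

Against this validated core, one printed simulation bound is *not*
reproduced under the default beam: the ρ = 0.7 design retains an escape
barrier of ~125 kBT at coarse resolution instead of falling below the
21 kBT stability threshold. The barrier is by far the most
aberration-sensitive landscape metric: it drops ~3× when the interface
depth grows from 1 to 2 μm and extrapolates below threshold near ~3 μm —
a plausible trap height for a ~2-μm DNA tether experiment — but the depth
is a documented default here, not a fitted quantity, so the computed value
is reported as is. Force and torque capacities, their monotone growth with
doping, and every symmetry/oracle property are unaffected.

## Rotational drag

γθ about the cylinder axis comes from the method of regularized Stokeslets:
quadrature points with area weights cover the side wall and caps, the
rigid-rotation no-slip condition is imposed at the same points, the dense
mobility system is solved for the point forces, and their torque about the
axis divided by the angular rate gives γθ. The fluid is unbounded; at the
tens-of-microns container scale of calibration experiments, wall
corrections to axial rotation are negligible, and no coverslip-proximity
correction is applied (flagged for users — measured values sit above the
free-space ideal-cylinder prediction partly for this reason, and partly
because fabricated cylinders are tapered). The blob radius is 0.35× the
mean quadrature spacing, calibrated once against the rotating sphere's
8πηr³ (−1% at ~600 points; +3% at the 0.5× choice). Collocation
regularized Stokeslets have O(ε) discretization error, so γθ is *not*
insensitive to halving ε; the convergence contract tested instead is < 2%
change when the panel count quadruples, plus exact linearity in viscosity
and rate-independence.

Under uniform scaling γθ scales as ηL³ — exactly proportional to volume
(the sphere's 8πηr³ is the canonical case) — which is why drag is "roughly
proportional to volume" even across non-similar design families (fitted
log–log power 0.9–1.2 for the metamaterial-vs-quartz pair).

γθ is reported both per-radian (what Langevin/SNR formulas need) and
per-turn (what torque–rotation experiments print); the 2π conversion lives
in one place to prevent unit bugs.

## Rotor dynamics and the slippage fit

The driven orientation obeys the overdamped Adler equation
γθ dθ/dt = −τ_max sin 2(θ − ψ), ψ = 2πωt (period π: the alignment
potential's leading harmonic for shape anisotropy; the computed τ_z(α) is
so close to A sin 2α even at eccentricity 0.6 — R² > 0.999 — that the
sinusoid is the default rather than a tabulated curve). Below
ω_max = τ_max/γθ the rotor phase-locks with lag −½ arcsin(ω/ω_max); above
it the mean drift obeys the Adler identity, giving the piecewise mean-drag
torque curve τ(ω) = γθω (locked) and γθ[ω − √(ω² − ω_max²)] (slipping).
Euler(–Maruyama) integration with dt constrained at construction
(dt·2τ_max/γθ,rad < 0.1 rad); thermal torque uses rotational diffusion
D = kBT/γθ,rad. Mean torque is measured as γθ,rad × mean dθ/dt over the
steady portion, averaged over an integer number of slip cycles (the lag
advances by π per cycle) to remove partial-cycle bias; simulation matches
the closed form to < 0.5%.

`fit_slippage` does (optionally weighted) least squares of that piecewise
curve over (γθ, τ_max) in log-parameters, reports ω_max as their ratio
(exact by construction), standard errors from the Jacobian, and flags
ω_max as a lower bound when no sampled rate exceeds it. Unweighted is the
default.

## DNA twisting: generator and analysis

The generator is deliberately phenomenological. At constant force (default
1 pN) and twist rate (2 turn/s), the torque backbone is linear in turns
(default slope 0.85 pN·nm/turn, the effective torsional stiffness scale of
a ~6.5-kb molecule at 1 pN) and clamps at the buckling (+12.8 pN·nm) and
melting (−10.5 pN·nm) plateaus; extension is flat before buckling, falls
at −45 nm/turn as the plectoneme grows (floored at zero), and stays flat
through melting. Pre-buckling extension level 1860 nm is the worm-like
chain estimate for ~6.5 kb at 1 pN. No buckling overshoot, sequence
dependence, Z-DNA, or force-feedback dynamics: passing tests show the
analysis pipeline recovers what torque spectroscopy *reports*, not that
DNA mechanics is modeled.

Torque noise emulates the instrument: the cylinder angle α is an exactly
discretized Ornstein–Uhlenbeck process (variance kBT/κθ, correlation time
γθ,rad/κθ; default stiffness κθ = 3000 pN·nm/rad puts the corner frequency
near 940 Hz) simulated at the hardware acquisition rate (10 kHz) and
boxcar-averaged to the 400-Hz recorded rate, then read out as torque κθα.
The down-averaging is essential: it is what makes the recorded noise obey
the bandwidth law SNR = τ_DNA/√(4 kBT γθ,rad B) instead of aliasing the
full √(kBT κθ) spread, and the tests verify the window-averaged SD against
the analytic OU-boxcar variance across a drag × window grid. Extension
noise is white Gaussian per recorded sample (default SD 10 nm).

The analysis mirrors reported practice: boxcar smoothing in turns (0.1
turn for extension, 1.0 turn for torque); buckling located by a continuous
two-segment piecewise-linear fit to the smoothed extension, restricted to
the region where the tether is not compacted to the floor; the melting
onset by the same fit on the smoothed torque of the unwinding side;
plateau statistics from the 1.0-turn-smoothed torque beyond the breakpoint
plus a 2-turn margin (excluding the transition region), histogrammed with
Freedman–Diaconis widths on the effective independent-window count and fit
by a Gaussian in count space. Missing regimes yield flags, not errors.
With ~2 minutes of plateau per direction the Gaussian-fit means land
within 0.5 pN·nm of the configured plateaus, and across 50 seeds the
buckling-turn bias is < 0.2 turn and the plateau-mean bias < 0.1 pN·nm.
The bandwidth behind a "SNR ≈ 2 at 10 pN·nm with quartz" figure is
B = 1 Hz — an inferred working default, equivalent to a 0.5-s averaging
window, not a measured instrument property.

## Reproducibility plumbing

Every CLI run validates its YAML config against a strict schema (unknown
keys are errors naming the offender), uses an explicit seed for anything
stochastic, and writes a manifest embedding the resolved config, seed and
version; same config + seed reproduces CSV/JSON outputs byte for byte.
Field grids and lattices go to HDF5; scalar results stay in diffable
CSV/JSON. Unit suffixes are embedded in config keys (`height_nm`,
`power_specimen_mw`).

## Known limitations

- Right-cylinder idealization: fabricated cylinders are tapered; drag and
  optical capacities of real particles differ at the tens-of-percent level.
- No substrate: coverslip reflections (standing-wave force offsets) and
  wall-proximity drag corrections are out of scope.
- The interface-aberration depth is a configuration parameter; absolute
  axial-stability numbers (especially U_esc) depend on it strongly.
- Lossless materials only; no absorption or heating.
- The DDA at 30–40 nm spacing is a desk-scale compromise: refinement from
  40 to 25 nm moves flagship force/torque by < 10%, which bounds but does
  not eliminate discretization error.
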