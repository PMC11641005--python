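"""Reproducible runs: strict config validation, dispatch, and manifests.

A run is described by a nested key-value config (YAML on disk).  Keys carry
unit suffixes (``height_nm``, ``power_specimen_mw``) to keep units explicit;
unknown keys are rejected.  Every run writes its outputs plus a
``manifest.json`` embedding the fully resolved config and seed, so identical
config+seed reproduces identical CSV/JSON outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beam import FocusedBeam
from .dna_twist import TwistConfig, analyze_twist_trace, generate_twist_trace
from .geometry import EllipticalCylinder, cylinder_from_design, voxelize
from .hydrodynamics import rotational_drag
from .materials import MetamaterialSpec, material_preset
from .rotor_dynamics import SpinProtocol, fit_slippage, simulate_rotation
from .scattering import CoupledDipoleSolver
from .trap_mechanics import axial_landscape, torque_curve
from .io import save_lattice_h5, write_csv, write_json

__all__ = ["RunConfig", "ConfigError", "run", "load_config"]

log = logging.getLogger("aotsim")


class ConfigError(ValueError):
    """Schema violation; message names the offending keys."""


# Allowed keys per config section (strict schema).
_SCHEMA = {
    "beam": {"wavelength_nm", "na", "fill_factor", "power_specimen_mw",
             "polarization_angle", "n_immersion", "n_medium",
             "interface_depth_nm", "n_theta"},
    "particle": {"material", "a_nm", "b_nm", "height_nm", "eccentricity",
                 "aspect_ratio", "volume_um3"},
    "landscape": {"z_min_nm", "z_max_nm", "n_points", "spacing_nm", "n_alpha",
                  "with_torque"},
    "sweep": {"rho_values", "spacing_nm", "z_min_nm", "z_max_nm", "n_points"},
    "drag": {"viscosity_pas", "n_panels", "rate_turn_per_s"},
    "spin": {"omega_turn_per_s", "duration_s", "gamma_theta_pnnms_per_turn",
             "tau_max_pnnm", "dt_s", "temperature_k"},
    "spin_fit": {"input_csv"},
    "twist_sim": {f.name for f in dataclasses.fields(TwistConfig)},
    "twist_analyze": {"input_csv", "extension_window_turn",
                      "torque_window_turn", "plateau_margin_turn"},
    "solve": {"spacing_nm", "offset_z_nm"},
}

_SUBCOMMANDS = ("beam", "solve", "landscape", "sweep", "drag", "spin",
                "spin-fit", "twist-sim", "twist-analyze")


@dataclass
class RunConfig:
    subcommand: str
    params: dict
    seed: int = 0
    out_dir: Path = Path("aotsim-out")
    coarse: bool = False
    version: str = __version__

    def __post_init__(self):
        if self.subcommand not in _SUBCOMMANDS:
            raise ConfigError(f"unknown subcommand {self.subcommand!r}; "
                              f"choose from {_SUBCOMMANDS}")
        self.out_dir = Path(self.out_dir)
        _validate(self.subcommand, self.params)


def _validate(subcommand: str, params: dict) -> None:
    bad = []
    allowed_sections = {"beam", "particle",
                        subcommand.replace("-", "_")}
    for section, content in params.items():
        if section not in allowed_sections or section not in _SCHEMA:
            if section not in _SCHEMA:
                bad.append(section)
                continue
        extra = set(content) - _SCHEMA[section]
        bad.extend(f"{section}.{k}" for k in sorted(extra))
    if bad:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _build_beam(params: dict) -> FocusedBeam:
    return FocusedBeam(**params.get("beam", {}))


def _build_particle(params: dict) -> EllipticalCylinder:
    p = dict(params.get("particle", {}))
    if "material" not in p:
        raise ConfigError("particle.material is required")
    mat = material_preset(p.pop("material"))
    if {"a_nm", "b_nm", "height_nm"} <= set(p):
        return EllipticalCylinder(a=p["a_nm"], b=p["b_nm"], h=p["height_nm"],
                                  material=mat)
    if {"eccentricity", "aspect_ratio", "volume_um3"} <= set(p):
        return cylinder_from_design(p["eccentricity"], p["aspect_ratio"],
                                    p["volume_um3"], mat)
    raise ConfigError(
        "particle needs either {a_nm, b_nm, height_nm} or "
        "{eccentricity, aspect_ratio, volume_um3}; got "
        + (", ".join(sorted(p)) or "nothing"))


# ---------------------------------------------------------------------------
# subcommand implementations
# ---------------------------------------------------------------------------

def _run_beam(cfg: RunConfig, out: Path) -> dict:
    beam = _build_beam(cfg.params)
    zs = np.linspace(-3000, 3000, 241)
    axial = beam.field_grid(np.column_stack([0 * zs, 0 * zs, zs]))
    xs = np.linspace(-1500, 1500, 241)
    trans_x = beam.field_grid(np.column_stack([xs, 0 * xs, 0 * xs]))
    trans_y = beam.field_grid(np.column_stack([0 * xs, xs, 0 * xs]))

    def inten(g):
        return np.einsum("ia,ia->i", g.E, np.conj(g.E)).real

    write_csv(out / "beam_axial.csv",
              pd.DataFrame({"z_nm": zs, "intensity": inten(axial)}))
    write_csv(out / "beam_transverse.csv",
              pd.DataFrame({"r_nm": xs, "intensity_x": inten(trans_x),
                            "intensity_y": inten(trans_y)}))
    return {"outputs": ["beam_axial.csv", "beam_transverse.csv"],
            "metrics": {"theta_max_rad": beam.theta_max}}


def _run_solve(cfg: RunConfig, out: Path) -> dict:
    beam = _build_beam(cfg.params)
    cyl = _build_particle(cfg.params)
    p = cfg.params.get("solve", {})
    spacing = p.get("spacing_nm", 40.0 if cfg.coarse else 30.0)
    lattice = voxelize(cyl, spacing, wavelength_nm=beam.wavelength_nm)
    solver = CoupledDipoleSolver(lattice, n_medium=beam.n_medium,
                                 wavelength_nm=beam.wavelength_nm)
    sol = solver.solve(beam, offset_nm=(0, 0, p.get("offset_z_nm", 0.0)))
    save_lattice_h5(out / "lattice.h5", lattice, residual=sol.residual)
    from .trap_mechanics import wrench as mst_wrench
    w = mst_wrench(sol)
    metrics = {"n_sites": lattice.n_sites, "residual": sol.residual,
               "F_pN": list(w.F), "tau_pN_nm": list(w.tau)}
    write_json(out / "wrench.json", metrics)
    return {"outputs": ["lattice.h5", "wrench.json"], "metrics": metrics}


def _run_landscape(cfg: RunConfig, out: Path) -> dict:
    beam = _build_beam(cfg.params)
    cyl = _build_particle(cfg.params)
    p = cfg.params.get("landscape", {})
    spacing = p.get("spacing_nm", 40.0 if cfg.coarse else 30.0)
    ls = axial_landscape(cyl, beam,
                         z_range_nm=(p.get("z_min_nm", -1500.0),
                                     p.get("z_max_nm", 3000.0)),
                         n_points=p.get("n_points", 16 if cfg.coarse else 31),
                         spacing_nm=spacing)
    if p.get("with_torque", True) and ls.trappable:
        ls = torque_curve(cyl, beam, ls.z_eq,
                          n_alpha=p.get("n_alpha", 9 if cfg.coarse else 19),
                          spacing_nm=spacing, landscape=ls)
    write_csv(out / "axial.csv", pd.DataFrame(
        {"z_nm": ls.z_grid, "Fz_pN": ls.Fz, "U_kBT": ls.U}))
    if ls.tau_z is not None:
        write_csv(out / "torque.csv", pd.DataFrame(
            {"alpha_rad": ls.alpha_grid, "tau_z_pN_nm": ls.tau_z}))
    write_json(out / "summary.json", ls.summary())
    outputs = ["axial.csv", "summary.json"]
    if ls.tau_z is not None:
        outputs.insert(1, "torque.csv")
    return {"outputs": outputs, "metrics": ls.summary()}


def _run_sweep(cfg: RunConfig, out: Path) -> dict:
    beam = _build_beam(cfg.params)
    p = cfg.params.get("sweep", {})
    base = dict(cfg.params.get("particle", {}))
    rhos = p.get("rho_values", [0.0, 0.25, 0.5])
    rows, summaries = [], []
    for rho in rhos:
        mat = MetamaterialSpec(float(rho)).material()
        part = dict(base)
        part.pop("material", None)
        cyl = (EllipticalCylinder(a=part["a_nm"], b=part["b_nm"],
                                  h=part["height_nm"], material=mat)
               if "a_nm" in part else
               cylinder_from_design(part["eccentricity"], part["aspect_ratio"],
                                    part["volume_um3"], mat))
        ls = axial_landscape(
            cyl, beam,
            z_range_nm=(p.get("z_min_nm", -1000.0), p.get("z_max_nm", 2000.0)),
            n_points=p.get("n_points", 16),
            spacing_nm=p.get("spacing_nm", 40.0))
        s = ls.summary()
        s["rho"] = rho
        summaries.append(s)
        rows.append({"rho": rho, "Uesc_kBT": ls.Uesc, "Fmax_pN": ls.Fmax,
                     "trappable": ls.trappable})
    write_csv(out / "sweep.csv", pd.DataFrame(rows))
    write_json(out / "sweep_summaries.json", summaries)
    return {"outputs": ["sweep.csv", "sweep_summaries.json"],
            "metrics": {"n_designs": len(rows)}}


def _run_drag(cfg: RunConfig, out: Path) -> dict:
    cyl = _build_particle(cfg.params)
    p = cfg.params.get("drag", {})
    res = rotational_drag(cyl, p.get("viscosity_pas", 0.001),
                          n_panels=p.get("n_panels", 1500),
                          rate_turn_per_s=p.get("rate_turn_per_s", 1.0))
    row = {"a_nm": cyl.a, "b_nm": cyl.b, "h_nm": cyl.h,
           "volume_um3": cyl.volume_um3,
           "gamma_theta_pnnms_per_rad": res.gamma_theta_per_rad,
           "gamma_theta_pnnms_per_turn": res.gamma_theta_per_turn,
           "mesh_size": res.mesh_size}
    write_csv(out / "drag.csv", pd.DataFrame([row]))
    return {"outputs": ["drag.csv"], "metrics": row}


def _run_spin(cfg: RunConfig, out: Path) -> dict:
    p = dict(cfg.params.get("spin", {}))
    proto = SpinProtocol(omega=p["omega_turn_per_s"], duration=p["duration_s"],
                         gamma_theta=p["gamma_theta_pnnms_per_turn"],
                         tau_max=p["tau_max_pnnm"], dt=p.get("dt_s", 1e-5),
                         temperature=p.get("temperature_k", 296.15),
                         seed=cfg.seed)
    traj = simulate_rotation(proto)
    stride = max(len(traj.t) // 20000, 1)
    write_csv(out / "spin_trajectory.csv", pd.DataFrame(
        {"t_s": traj.t[::stride], "theta_rad": traj.theta[::stride],
         "psi_rad": traj.psi[::stride]}))
    metrics = {"mean_drag_torque_pnnm": traj.mean_drag_torque(),
               "omega_max_turn_per_s": proto.omega_max}
    write_json(out / "spin_summary.json", metrics)
    return {"outputs": ["spin_trajectory.csv", "spin_summary.json"],
            "metrics": metrics}


def _run_spin_fit(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params.get("spin_fit", {})
    df = pd.read_csv(p["input_csv"])
    fit = fit_slippage(df["omega_turn_per_s"], df["tau_pN_nm"])
    metrics = {"gamma_theta_pnnms_per_turn": fit.gamma_theta,
               "tau_max_pnnm": fit.tau_max,
               "omega_max_turn_per_s": fit.omega_max,
               "omega_max_is_lower_bound": fit.omega_max_is_lower_bound}
    write_json(out / "spin_fit.json", metrics)
    (out / "spin_fit.txt").write_text(fit.summary() + "\n")
    return {"outputs": ["spin_fit.json", "spin_fit.txt"], "metrics": metrics}


def _run_twist_sim(cfg: RunConfig, out: Path) -> dict:
    p = dict(cfg.params.get("twist_sim", {}))
    p.setdefault("seed", cfg.seed)
    tc = TwistConfig(**p)
    trace = generate_twist_trace(tc)
    write_csv(out / "twist_trace.csv", pd.DataFrame(
        {"time_s": trace.t, "turns": trace.turns,
         "extension_nm": trace.extension, "torque_pN_nm": trace.torque}))
    write_json(out / "twist_trace.config.json", dataclasses.asdict(tc))
    return {"outputs": ["twist_trace.csv", "twist_trace.config.json"],
            "metrics": {"n_samples": trace.t.size,
                        "corner_frequency_hz": tc.corner_frequency_hz}}


def _run_twist_analyze(cfg: RunConfig, out: Path) -> dict:
    from .dna_twist import TwistTrace
    p = cfg.params.get("twist_analyze", {})
    df = pd.read_csv(p["input_csv"])
    trace = TwistTrace(t=df["time_s"], turns=df["turns"],
                       extension=df["extension_nm"], torque=df["torque_pN_nm"])
    ana = analyze_twist_trace(
        trace,
        extension_window=p.get("extension_window_turn", 0.1),
        torque_window=p.get("torque_window_turn", 1.0),
        plateau_margin=p.get("plateau_margin_turn", 2.0))
    metrics = {
        "buckling_turn": ana.buckling_turn_hat,
        "pre_buckling_slope_pnnm_per_turn": ana.pre_buckling_slope_hat,
        "extension_slope_nm_per_turn": ana.extension_slope_hat,
        "plateau_pos_mean_pnnm": ana.plateau_pos.mean if ana.plateau_pos else None,
        "plateau_pos_sd_pnnm": ana.plateau_pos.sd if ana.plateau_pos else None,
        "plateau_neg_mean_pnnm": ana.plateau_neg.mean if ana.plateau_neg else None,
        "plateau_neg_sd_pnnm": ana.plateau_neg.sd if ana.plateau_neg else None,
        "flags": ana.flags,
    }
    write_json(out / "twist_analysis.json", metrics)
    (out / "twist_analysis.txt").write_text(ana.summary() + "\n")
    return {"outputs": ["twist_analysis.json", "twist_analysis.txt"],
            "metrics": metrics}


_RUNNERS = {
    "beam": _run_beam, "solve": _run_solve, "landscape": _run_landscape,
    "sweep": _run_sweep, "drag": _run_drag, "spin": _run_spin,
    "spin-fit": _run_spin_fit, "twist-sim": _run_twist_sim,
    "twist-analyze": _run_twist_analyze,
}


def run(config: RunConfig) -> dict:
    """Execute one subcommand; returns (and writes) the output manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log.info("run %s -> %s (seed %d)", config.subcommand, out, config.seed)
    result = _RUNNERS[config.subcommand](config, out)
    manifest = {"subcommand": config.subcommand, "seed": config.seed,
                "version": config.version, "coarse": config.coarse,
                "config": config.params, **result}
    write_json(out / "manifest.json", manifest)
    log.info("run %s done: %s", config.subcommand, result.get("metrics"))
    return manifest
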