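"""Serialization helpers: HDF5 for field grids and lattices, CSV/JSON for
scalar results (kept diffable)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import DipoleLattice

__all__ = ["save_lattice_h5", "load_lattice_h5", "save_fields_h5",
           "write_csv", "write_json"]

CSV_FLOAT_FMT = "%.10g"


def save_lattice_h5(path, lattice: DipoleLattice, **metadata) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions_nm", data=lattice.positions)
        f.create_dataset("site_permittivity", data=lattice.site_permittivity)
        f.attrs["spacing_nm"] = lattice.spacing
        for k, v in metadata.items():
            f.attrs[k] = v


def load_lattice_h5(path) -> DipoleLattice:
    with h5py.File(path, "r") as f:
        return DipoleLattice(spacing=float(f.attrs["spacing_nm"]),
                             positions=f["positions_nm"][...],
                             site_permittivity=f["site_permittivity"][...])


def save_fields_h5(path, points_nm: np.ndarray, E: np.ndarray, H: np.ndarray,
                   **metadata) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("points_nm", data=np.asarray(points_nm))
        f.create_dataset("E", data=np.asarray(E))
        f.create_dataset("H", data=np.asarray(H))
        for k, v in metadata.items():
            f.attrs[k] = v


def write_csv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FMT)


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=default)
        f.write("\n")
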