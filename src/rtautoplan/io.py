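"""HDF5 persistence for phantoms, influence matrices and dose arrays."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
from scipy import sparse

from .dose import InfluenceMatrix
from .geometry import StructureSet, VoxelGrid

__all__ = [
    "save_structure_set",
    "load_structure_set",
    "save_dose",
    "load_dose",
    "save_influence_matrix",
    "load_influence_matrix",
]


def save_structure_set(ss: StructureSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["shape"] = ss.grid.shape
        f.attrs["spacing_mm"] = ss.grid.spacing_mm
        g = f.create_group("masks")
        for name, mask in ss.masks.items():
            d = g.create_dataset(name, data=mask.astype(np.uint8), compression="gzip")
            d.attrs["role"] = ss.roles[name]


def load_structure_set(path: str | Path) -> StructureSet:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(tuple(int(n) for n in f.attrs["shape"]),
                         tuple(float(s) for s in f.attrs["spacing_mm"]))
        ss = StructureSet(grid=grid)
        for name, d in f["masks"].items():
            ss.add(name, np.asarray(d[()], dtype=bool), str(d.attrs["role"]))
    return ss


def save_dose(d: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["shape"] = grid.shape
        f.attrs["spacing_mm"] = grid.spacing_mm
        f.create_dataset("dose_cGy", data=np.asarray(d, dtype=float), compression="gzip")


def load_dose(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(tuple(int(n) for n in f.attrs["shape"]),
                         tuple(float(s) for s in f.attrs["spacing_mm"]))
        return np.asarray(f["dose_cGy"][()], dtype=float), grid


def save_influence_matrix(im: InfluenceMatrix, path: str | Path) -> None:
    A = im.entries.tocsr()
    with h5py.File(path, "w") as f:
        f.attrs["shape"] = im.grid.shape
        f.attrs["spacing_mm"] = im.grid.spacing_mm
        f.attrs["beam_angles_deg"] = im.beam_angles_deg
        f.attrs["beamlet_width_mm"] = im.beamlet_width_mm
        f.attrs["mu_per_mm"] = im.mu_per_mm
        f.attrs["sigma_mm"] = im.sigma_mm
        f.attrs["matrix_shape"] = A.shape
        f.create_dataset("data", data=A.data, compression="gzip")
        f.create_dataset("indices", data=A.indices, compression="gzip")
        f.create_dataset("indptr", data=A.indptr, compression="gzip")
        f.create_dataset("beamlet_offsets", data=im.beamlet_offsets)


def load_influence_matrix(path: str | Path) -> InfluenceMatrix:
    with h5py.File(path, "r") as f:
        A = sparse.csr_matrix(
            (f["data"][()], f["indices"][()], f["indptr"][()]),
            shape=tuple(int(n) for n in f.attrs["matrix_shape"]),
        )
        return InfluenceMatrix(
            entries=A,
            beam_angles_deg=tuple(float(a) for a in f.attrs["beam_angles_deg"]),
            beamlet_width_mm=float(f.attrs["beamlet_width_mm"]),
            mu_per_mm=float(f.attrs["mu_per_mm"]),
            sigma_mm=float(f.attrs["sigma_mm"]),
            grid=VoxelGrid(tuple(int(n) for n in f.attrs["shape"]),
                           tuple(float(s) for s in f.attrs["spacing_mm"])),
            beamlet_offsets=np.asarray(f["beamlet_offsets"][()]),
        )
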