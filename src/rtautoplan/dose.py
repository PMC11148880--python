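"""Linear beamlet dose model d = A x and coverage normalization.

The influence matrix A maps nonnegative beamlet fluences to voxel doses.
Physics is reduced to the two effects the planning loop actually exercises:
exponential depth attenuation exp(-mu * depth) along each coplanar beam, and a
Gaussian lateral penumbra integrated over the beamlet width (an erf profile).
This is a stand-in for a clinical dose engine: the agent and optimizer only
require a deterministic, nonnegative, linear dose operator with realistic
trade-off structure, not dosimetric accuracy.

Dose vectors are stored over the full flattened grid (zero outside the body)
so every structure mask indexes them directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import erf

from .geometry import BODY, StructureSet, VoxelGrid

__all__ = [
    "InfluenceMatrix",
    "build_influence_matrix",
    "compute_dose",
    "normalize_to_coverage",
]


@dataclass
class InfluenceMatrix:
    """Sparse nonnegative voxels-by-beamlets dose operator."""

    entries: sparse.csr_matrix
    beam_angles_deg: tuple[float, ...]
    beamlet_width_mm: float
    mu_per_mm: float
    sigma_mm: float
    grid: VoxelGrid
    #: (beam index, lateral offset mm) per column
    beamlet_offsets: np.ndarray

    @property
    def n_beamlets(self) -> int:
        return self.entries.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.entries.shape[0]


def _beam_depths(
    centers: np.ndarray, body_flat: np.ndarray, grid: VoxelGrid, u: np.ndarray
) -> np.ndarray:
    """Radiological depth of every voxel along direction ``u`` (ray marching).

    March upstream from each voxel center in steps of half the finest spacing
    and accumulate the in-body path length.
    """
    step = min(grid.spacing_mm) / 2.0
    ext = grid.extent_mm
    t_max = float(np.linalg.norm(ext))
    ts = np.arange(step / 2.0, t_max, step)
    shape = grid.shape
    spacing = np.asarray(grid.spacing_mm)

    depth = np.zeros(centers.shape[0])
    # chunk over steps to bound memory
    for chunk in np.array_split(ts, max(1, len(ts) // 64)):
        pts = centers[:, None, :] - u[None, None, :] * chunk[None, :, None]
        idx = np.floor(pts / spacing).astype(np.int64)
        valid = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=2)
        flat = (
            idx[..., 0].clip(0, shape[0] - 1) * (shape[1] * shape[2])
            + idx[..., 1].clip(0, shape[1] - 1) * shape[2]
            + idx[..., 2].clip(0, shape[2] - 1)
        )
        inside = valid & body_flat[flat]
        depth += inside.sum(axis=1) * step
    return depth


def build_influence_matrix(
    ss: StructureSet,
    n_beams: int = 5,
    beamlet_width_mm: float = 8.0,
    mu_per_mm: float = 0.005,
    sigma_mm: float = 4.0,
    margin_mm: float = 5.0,
    kernel_floor: float = 1e-4,
) -> InfluenceMatrix:
    """Ray-traced influence matrix for equispaced coplanar beams.

    Beamlets tile the projection of the union of PTVs (or the body, if no
    targets exist) onto each beam's lateral axis, padded by ``margin_mm``.
    Deterministic given its inputs.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if beamlet_width_mm <= 0 or mu_per_mm <= 0 or sigma_mm <= 0:
        raise ValueError("physical parameters must be positive")
    grid = ss.grid
    body = ss[BODY]
    if not body.any():
        raise ValueError("empty body mask")
    body_flat = body.ravel()

    target_names = [n for n, r in ss.roles.items() if r == "target" and n.startswith("PTV")]
    if target_names:
        target = np.logical_or.reduce([ss[n] for n in target_names])
    else:
        target = body

    X, Y, Z = grid.voxel_centers()
    centers = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tgt_pts = centers[target.ravel()]

    angles = tuple(float(a) for a in np.arange(n_beams) * (360.0 / n_beams))
    cols: list[sparse.csc_matrix] = []
    offsets: list[tuple[int, float]] = []
    sq2s = np.sqrt(2.0) * sigma_mm
    half = beamlet_width_mm / 2.0

    for b, ang in enumerate(angles):
        th = np.deg2rad(ang)
        u = np.array([np.cos(th), np.sin(th), 0.0])   # beam direction
        w = np.array([-np.sin(th), np.cos(th), 0.0])  # lateral axis

        depth = _beam_depths(centers, body_flat, grid, u)
        atten = np.exp(-mu_per_mm * depth)
        atten[~body_flat] = 0.0

        proj = tgt_pts @ w
        lo, hi = proj.min() - margin_mm, proj.max() + margin_mm
        n_lets = max(1, int(np.ceil((hi - lo) / beamlet_width_mm)))
        lat = centers @ w
        for k in range(n_lets):
            c = lo + (k + 0.5) * beamlet_width_mm
            x = lat - c
            profile = 0.5 * (erf((x + half) / sq2s) - erf((x - half) / sq2s))
            col = atten * profile
            col[col < kernel_floor] = 0.0
            if col.any():
                cols.append(sparse.csc_matrix(col[:, None]))
                offsets.append((b, c))

    if not cols:
        raise ValueError("influence matrix has no nonzero beamlets")
    A = sparse.hstack(cols).tocsr()
    return InfluenceMatrix(
        entries=A,
        beam_angles_deg=angles,
        beamlet_width_mm=beamlet_width_mm,
        mu_per_mm=mu_per_mm,
        sigma_mm=sigma_mm,
        grid=grid,
        beamlet_offsets=np.array(offsets, dtype=float),
    )


def compute_dose(influence: InfluenceMatrix | sparse.spmatrix, x: np.ndarray) -> np.ndarray:
    """Dose d = A x (linear, homogeneous)."""
    A = influence.entries if isinstance(influence, InfluenceMatrix) else influence
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != A.shape[1]:
        raise ValueError(f"fluence length {x.shape[0]} != beamlet count {A.shape[1]}")
    return np.asarray(A @ x).ravel()


def normalize_to_coverage(
    d: np.ndarray,
    ptv_mask: np.ndarray,
    rx_cGy: float,
    coverage_fraction: float = 0.95,
) -> tuple[np.ndarray, float]:
    """Rescale dose so the PTV fraction receiving >= ``rx_cGy`` equals
    ``coverage_fraction`` (to within one voxel quantile).

    The scale is ``rx / q`` where q is the (1 - coverage) quantile of PTV
    dose, with ties resolved toward the higher quantile.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    d = np.asarray(d, dtype=float)
    vals = d.ravel()[ptv_mask.ravel()]
    if vals.size == 0:
        raise ValueError("PTV mask is empty")
    if not np.any(vals > 0):
        raise ValueError("all-zero dose in PTV: cannot normalize")
    q = float(np.quantile(vals, 1.0 - coverage_fraction, method="higher"))
    if q <= 0:
        # fall back to the smallest positive dose so the scale stays finite
        q = float(vals[vals > 0].min())
    scale = rx_cGy / q
    return d * scale, scale
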