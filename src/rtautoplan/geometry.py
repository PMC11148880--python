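"""Synthetic head-and-neck voxel phantoms and planning-structure algebra.

The phantom is a deliberately simplified, fully synthetic geometry: a single
axial slab (optionally a 3D stack) in which the body is an ellipse and the
targets/organs are jittered ellipsoids.  Four nested planning target volumes
(PTV63 .. PTV54, prescription 6300..5400 cGy) sit laterally in the "neck",
surrounded by the organs at risk a head-and-neck planner actually negotiates
with: parotid glands, spinal cord, brainstem, esophagus, oral cavity,
pharyngeal constrictor and brachial plexus.  The geometry reproduces the
clinically decisive topology — which targets intersect which organs — rather
than anatomical shape.

The structure algebra (`expand`, `crop_overlap`, `inner_ring`) operates in
physical millimetres on voxel-center coordinates, so results are independent
of grid spacing, and is used to derive the auxiliary planning structures
(organ-minus-PTV crops, cord expansion, target boundary rings, avoidance
shells) that the objective template references.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "StructureSet",
    "PhantomSpec",
    "InfeasibleGeometryError",
    "generate_phantom",
    "expand",
    "erode",
    "crop_overlap",
    "inner_ring",
    "derive_auxiliary_structures",
    "default_phantom_spec",
    "mini_phantom_spec",
    "PLANNING_STRUCTURES",
]

BODY = "BODY"

#: The 26 planning structures referenced by the default objective template.
PLANNING_STRUCTURES = (
    "PTV63", "PTV60", "PTV57", "PTV54",
    "CTV63", "CTV60", "CTV57", "CTV54",
    "PTV57_push", "PTV54_push",
    "PTV_all", "PTV-CTV63",
    "Brainstem", "Cord+5mm", "Esophagus",
    "Avoidance1", "Avoidance2", "Avoidance3",
    "L Parotid", "L Parotid_opti",
    "R Parotid", "R Parotid_opti",
    "Oral Cavity_opti",
    "Constrictor", "Constrictor_opti",
    "Brachial Plexus",
)


class InfeasibleGeometryError(RuntimeError):
    """Raised when a grid cannot realize the requested structure topology."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice; physical coordinates anchored at the grid corner."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three counts >= 1, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinate arrays, each of shape ``self.shape``."""
        axes = [
            (np.arange(n) + 0.5) * s
            for n, s in zip(self.shape, self.spacing_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))


@dataclass
class StructureSet:
    """A voxel grid plus named binary masks with target/organ/auxiliary roles."""

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray, role: str) -> None:
        if mask.shape != self.grid.shape:
            raise ValueError(f"mask {name!r} shape {mask.shape} != grid {self.grid.shape}")
        if role not in ("target", "organ", "auxiliary", "body"):
            raise ValueError(f"unknown role {role!r}")
        self.masks[name] = np.asarray(mask, dtype=bool)
        self.roles[name] = role

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"structure {name!r} not in structure set") from None

    def names(self) -> list[str]:
        return list(self.masks)

    def validate(self) -> None:
        """Check mask conformity and containment in the body mask."""
        if BODY not in self.masks:
            raise ValueError("structure set has no BODY mask")
        body = self.masks[BODY]
        for name, mask in self.masks.items():
            if mask.shape != self.grid.shape:
                raise ValueError(f"mask {name!r} does not conform to grid")
            if name != BODY and np.any(mask & ~body):
                raise ValueError(f"structure {name!r} is not contained in BODY")

    def copy(self) -> "StructureSet":
        return StructureSet(
            grid=self.grid,
            masks={k: v.copy() for k, v in self.masks.items()},
            roles=dict(self.roles),
        )


# ---------------------------------------------------------------------------
# Default layout.  Centers and semi-axes are fractions of the body semi-axes,
# chosen so every clinically required target/organ intersection has a few
# millimetres of overlap depth and survives placement jitter and a 5 mm grid.
# ---------------------------------------------------------------------------

_TARGET_LAYOUT = {
    # name: (center_frac, semi_frac); PTVs are unioned smallest-outward so the
    # four levels are strictly nested regardless of jitter.
    "PTV63": ((-0.28, 0.00), (0.20, 0.16)),
    "PTV60": ((-0.22, 0.00), (0.32, 0.26)),
    "PTV57": ((-0.12, 0.02), (0.46, 0.34)),
    "PTV54": ((0.00, 0.05), (0.60, 0.42)),
}

_ORGAN_LAYOUT = {
    "L Parotid": ((-0.60, -0.08), (0.18, 0.18)),
    "R Parotid": ((0.60, -0.08), (0.18, 0.18)),
    "Oral Cavity": ((-0.08, 0.40), (0.30, 0.26)),
    "Constrictor": ((-0.18, -0.14), (0.38, 0.12)),
    "Esophagus": ((0.02, -0.38), (0.10, 0.10)),
    "Cord": ((0.00, -0.68), (0.09, 0.09)),
    "Brainstem": ((0.28, -0.55), (0.12, 0.10)),
    "Brachial Plexus": ((-0.42, -0.10), (0.11, 0.11)),
}

#: Target/organ pairs that must intersect, mirroring the overlap topology of a
#: locally advanced H&N case with a left-lateralized primary.
_DEFAULT_REQUIRED_OVERLAPS = (
    ("PTV54", "Oral Cavity"),
    ("PTV54", "Constrictor"),
    ("PTV54", "L Parotid"),
    ("PTV54", "R Parotid"),
    ("PTV54", "Esophagus"),
    ("PTV57", "Constrictor"),
    ("PTV57", "L Parotid"),
    ("PTV57", "Brachial Plexus"),
    ("PTV60", "Oral Cavity"),
    ("PTV60", "L Parotid"),
    ("PTV60", "Constrictor"),
    ("PTV63", "Constrictor"),
    ("PTV63", "Brachial Plexus"),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to deterministically generate a phantom."""

    seed: int
    grid: VoxelGrid
    prescription_levels_cGy: tuple[float, ...] = (6300.0, 6000.0, 5700.0, 5400.0)
    target_layout: Mapping[str, tuple] = field(default_factory=lambda: dict(_TARGET_LAYOUT))
    organ_layout: Mapping[str, tuple] = field(default_factory=lambda: dict(_ORGAN_LAYOUT))
    required_overlaps: tuple[tuple[str, str], ...] = _DEFAULT_REQUIRED_OVERLAPS
    body_semi_frac: tuple[float, float] = (0.88, 0.92)
    center_jitter_frac: float = 0.02
    size_jitter: tuple[float, float] = (0.96, 1.05)
    ctv_margin_mm: float = 2.5
    max_attempts: int = 8

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.prescription_levels_cGy)
        if any(a <= b for a, b in zip(levels, levels[1:])):
            raise ValueError("prescription levels must be strictly decreasing")
        declared = set(self.target_layout) | set(self.organ_layout)
        for a, b in self.required_overlaps:
            if a not in declared or b not in declared:
                raise ValueError(f"required overlap ({a!r}, {b!r}) references undeclared structure")


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """The full-size single-slice phantom (64x64 voxels at 3.5 mm)."""
    return PhantomSpec(seed=seed, grid=VoxelGrid((64, 64, 1), (3.5, 3.5, 3.5)))


def mini_phantom_spec(seed: int = 7) -> PhantomSpec:
    """The desk-scale training phantom: 32x32 voxels at 5 mm spacing."""
    return PhantomSpec(seed=seed, grid=VoxelGrid((32, 32, 1), (5.0, 5.0, 5.0)))


def _ellipse_mask(grid: VoxelGrid, center_mm: Sequence[float], semi_mm: Sequence[float]) -> np.ndarray:
    """Axis-aligned ellipse/ellipsoid on voxel centers; z ignored on slabs."""
    X, Y, Z = grid.voxel_centers()
    r2 = ((X - center_mm[0]) / semi_mm[0]) ** 2 + ((Y - center_mm[1]) / semi_mm[1]) ** 2
    if grid.shape[2] > 1:
        r2 = r2 + ((Z - center_mm[2]) / semi_mm[2]) ** 2
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> StructureSet:
    """Generate the primary structures (body, nested PTVs/CTVs, organs).

    Deterministic given ``spec`` (including its seed).  Placement jitter is
    re-drawn up to ``spec.max_attempts`` times until every required
    target/organ overlap is realized on the grid; if the grid is too coarse or
    small to realize them, :class:`InfeasibleGeometryError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    last_missing: list[tuple[str, str]] = []
    for _ in range(spec.max_attempts):
        ss = _attempt_phantom(spec, rng)
        missing = [
            (a, b)
            for a, b in spec.required_overlaps
            if not np.any(ss[a] & ss[b])
        ]
        if not missing:
            ss.validate()
            return ss
        last_missing = missing
    raise InfeasibleGeometryError(
        f"could not realize required overlaps {last_missing} on grid "
        f"{spec.grid.shape} at {spec.grid.spacing_mm} mm"
    )


def _attempt_phantom(spec: PhantomSpec, rng: np.random.Generator) -> StructureSet:
    grid = spec.grid
    ext = grid.extent_mm
    center = (ext[0] / 2.0, ext[1] / 2.0, ext[2] / 2.0)
    body_semi = (
        spec.body_semi_frac[0] * ext[0] / 2.0,
        spec.body_semi_frac[1] * ext[1] / 2.0,
        max(ext[2], 1.0),  # slab: body spans the full z extent
    )
    ss = StructureSet(grid=grid)
    body = _ellipse_mask(grid, center, body_semi)
    if not body.any():
        raise InfeasibleGeometryError("grid too small: empty body mask")
    ss.add(BODY, body, "body")

    def place(frac_center, frac_semi):
        jc = rng.uniform(-spec.center_jitter_frac, spec.center_jitter_frac, size=2)
        js = rng.uniform(*spec.size_jitter, size=2)
        c = (
            center[0] + (frac_center[0] + jc[0]) * body_semi[0],
            center[1] + (frac_center[1] + jc[1]) * body_semi[1],
            center[2],
        )
        s = (
            max(frac_semi[0] * js[0] * body_semi[0], 1e-3),
            max(frac_semi[1] * js[1] * body_semi[1], 1e-3),
            body_semi[2],
        )
        return _ellipse_mask(grid, c, s) & body

    # Targets: build the boost level first and union outward so nesting holds.
    ptv_names = ["PTV63", "PTV60", "PTV57", "PTV54"]
    prev = np.zeros(grid.shape, dtype=bool)
    for name in ptv_names:
        fc, fs = spec.target_layout[name]
        mask = place(fc, fs) | prev
        ss.add(name, mask, "target")
        prev = mask
    if not ss["PTV63"].any():
        raise InfeasibleGeometryError("grid too coarse: empty PTV63")

    # CTVs: erode each PTV; fall back to the PTV itself on very coarse grids.
    for name in ptv_names:
        ctv = erode(ss[name], grid, spec.ctv_margin_mm)
        if not ctv.any():
            ctv = ss[name].copy()
        ss.add("CTV" + name[3:], ctv, "target")

    for name, (fc, fs) in spec.organ_layout.items():
        mask = place(fc, fs)
        if not mask.any():
            raise InfeasibleGeometryError(f"grid too coarse: empty organ {name!r}")
        ss.add(name, mask, "organ")
    return ss


# ---------------------------------------------------------------------------
# Structure algebra (physical units, voxel-center semantics)
# ---------------------------------------------------------------------------

def expand(mask: np.ndarray, grid: VoxelGrid, margin_mm: float) -> np.ndarray:
    """Isotropic dilation: voxels whose center is within ``margin_mm`` of a
    mask voxel center.  ``margin_mm = 0`` is the identity."""
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing_mm)
    return dist <= margin_mm + 1e-9


def erode(mask: np.ndarray, grid: VoxelGrid, margin_mm: float) -> np.ndarray:
    """Erosion by physical distance to the mask surface.

    The EDT of the mask gives each inside voxel its center-to-center distance
    to the nearest outside voxel; subtracting half a voxel spacing converts it
    to an approximate distance to the mask boundary surface, so a margin
    smaller than the voxel size still strips the peripheral voxel layer.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=grid.spacing_mm)
    half = min(grid.spacing_mm) / 2.0
    return dist - half > margin_mm + 1e-9


def crop_overlap(organ_mask: np.ndarray, target_masks: Iterable[np.ndarray]) -> np.ndarray:
    """Organ minus the union of targets (the ``_opti`` construction)."""
    organ_mask = np.asarray(organ_mask, dtype=bool)
    out = organ_mask.copy()
    for t in target_masks:
        t = np.asarray(t, dtype=bool)
        if t.shape != organ_mask.shape:
            raise ValueError(f"target mask shape {t.shape} != organ shape {organ_mask.shape}")
        out &= ~t
    return out


def inner_ring(mask: np.ndarray, grid: VoxelGrid, width_mm: float) -> np.ndarray:
    """The peripheral shell of ``mask``: mask minus its erosion by ``width_mm``."""
    if width_mm <= 0:
        raise ValueError(f"ring width must be > 0, got {width_mm}")
    mask = np.asarray(mask, dtype=bool)
    return mask & ~erode(mask, grid, width_mm)


# ---------------------------------------------------------------------------
# Auxiliary planning structures
# ---------------------------------------------------------------------------

_AUX_PREREQUISITES = (
    "PTV63", "PTV60", "PTV57", "PTV54", "CTV63",
    "L Parotid", "R Parotid", "Oral Cavity", "Constrictor", "Cord",
)


def derive_auxiliary_structures(ss: StructureSet) -> StructureSet:
    """Add the auxiliary planning structures used by the objective template.

    Adds organ-minus-PTV crops (``*_opti``), the 5 mm cord expansion, 3 mm
    target boundary rings, the PTV union and boost shell, and three avoidance
    regions (posterior-neck band, oral-cavity shell, antero-lateral tube).
    Idempotent: re-running overwrites the derived names with identical masks;
    primary masks are never modified.
    """
    for name in _AUX_PREREQUISITES:
        if name not in ss:
            raise KeyError(f"cannot derive auxiliary structures: missing {name!r}")
    out = ss.copy()
    grid = out.grid
    body = out[BODY]
    ptvs = [out[n] for n in ("PTV63", "PTV60", "PTV57", "PTV54")]
    ptv_all = np.logical_or.reduce(ptvs)

    out.add("PTV_all", ptv_all, "auxiliary")
    out.add("PTV-CTV63", ptv_all & ~out["CTV63"], "auxiliary")
    out.add("L Parotid_opti", crop_overlap(out["L Parotid"], ptvs), "auxiliary")
    out.add("R Parotid_opti", crop_overlap(out["R Parotid"], ptvs), "auxiliary")
    out.add("Oral Cavity_opti", crop_overlap(out["Oral Cavity"], ptvs), "auxiliary")
    out.add("Constrictor_opti", crop_overlap(out["Constrictor"], ptvs), "auxiliary")
    out.add("Cord+5mm", expand(out["Cord"], grid, 5.0) & body, "auxiliary")
    out.add("PTV54_push", inner_ring(out["PTV54"], grid, 3.0), "auxiliary")
    out.add("PTV57_push", inner_ring(out["PTV57"], grid, 3.0), "auxiliary")

    # Avoidance regions: stand-ins for the dosimetrist-designed control shells
    # (posterior neck, peri-oral, trachea); shapes are geometric, not anatomic.
    X, Y, _ = grid.voxel_centers()
    ext = grid.extent_mm
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    semi_x = 0.88 * ext[0] / 2.0
    semi_y = 0.92 * ext[1] / 2.0
    out.add("Avoidance1", body & (Y <= cy - 0.62 * semi_y) & ~ptv_all, "auxiliary")
    out.add("Avoidance2", expand(out["Oral Cavity"], grid, 6.0) & body & ~ptv_all, "auxiliary")
    tube = ((X - (cx + 0.55 * semi_x)) ** 2 + (Y - (cy + 0.35 * semi_y)) ** 2) <= (0.12 * semi_x) ** 2
    out.add("Avoidance3", tube & body & ~ptv_all, "auxiliary")

    out.validate()
    return out
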