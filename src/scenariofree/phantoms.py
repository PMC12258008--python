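"""Synthetic 3D and 4D box phantoms with named structures.

Conventions
-----------
* Axis order is (x, y, z); voxel indices are 0-based; flat indices use C order.
* Positions are voxel *centers* in mm; ``origin`` is the center of voxel
  (0, 0, 0).
* Structures are stored as sorted, duplicate-free flat voxel-index arrays.
* 4D motion is rigid, single-axis and whole-voxel, so masks move without
  interpolation and voxel correspondence between phases is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError, ValidationError

__all__ = [
    "VoxelGrid",
    "StructureSet",
    "Phantom4D",
    "OarSpec",
    "make_box_phantom",
    "make_4d_box",
    "expand_margin",
    "build_itv",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid carrying relative (water-equivalent) densities."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    density: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        if any(d < 1 for d in dims):
            raise ValidationError(f"grid dims must be positive, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ValidationError(f"grid spacing must be positive, got {spacing}")
        rho = np.asarray(self.density, dtype=float)
        if rho.shape != dims:
            raise ValidationError(
                f"density shape {rho.shape} does not match dims {dims}"
            )
        if not np.all(np.isfinite(rho)) or np.any(rho < 0):
            raise ValidationError("densities must be finite and >= 0")
        object.__setattr__(self, "density", rho)

    @property
    def nvox(self) -> int:
        return int(np.prod(self.dims))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def center_coords(self) -> np.ndarray:
        """(nvox, 3) voxel-center positions in mm, flat C order."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (lo, hi) of the voxelized volume in mm."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.dims) * np.asarray(self.spacing)
        return lo, hi


_ROLES = {"target", "oar", "body"}


@dataclass
class StructureSet:
    """Named voxel-index sets with clinical roles (target / oar / body)."""

    structures: dict[str, np.ndarray]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for name, idx in self.structures.items():
            arr = np.asarray(idx, dtype=np.int64).ravel()
            uniq = np.unique(arr)
            if uniq.size != arr.size or (arr.size and np.any(np.sort(arr) != arr)):
                arr = uniq  # enforce sorted, duplicate-free storage
            clean[name] = arr
        self.structures = clean
        for name, role in self.roles.items():
            if role not in _ROLES:
                raise ValidationError(f"unknown role {role!r} for structure {name!r}")
            if name not in self.structures:
                raise ValidationError(f"role given for unknown structure {name!r}")
        if "target" not in set(self.roles.values()) or "body" not in set(
            self.roles.values()
        ):
            raise ValidationError("a structure set needs at least one target and one body")

    def validate_against(self, grid: VoxelGrid) -> None:
        for name, idx in self.structures.items():
            if idx.size and (idx.min() < 0 or idx.max() >= grid.nvox):
                raise ValidationError(f"structure {name!r} has out-of-grid indices")

    def mask(self, name: str, dims: tuple[int, int, int]) -> np.ndarray:
        """Boolean volume for one structure."""
        m = np.zeros(int(np.prod(dims)), dtype=bool)
        m[self.structures[name]] = True
        return m.reshape(dims)

    def names_with_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]


@dataclass
class Phantom4D:
    """Ordered CT phases of one phantom under rigid single-axis motion.

    ``phase_shifts_mm[k]`` is the displacement of phase ``k`` relative to the
    base (reference) geometry.  The zero-shift phase is index ``(n - 1) // 2``.
    """

    phases: list[tuple[VoxelGrid, StructureSet]]
    phase_weights: np.ndarray
    phase_shifts_mm: np.ndarray
    motion_axis: int = 0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValidationError("Phantom4D needs at least one phase")
        dims0, sp0 = self.phases[0][0].dims, self.phases[0][0].spacing
        for g, _ in self.phases:
            if g.dims != dims0 or g.spacing != sp0:
                raise ValidationError("all phases must share dims and spacing")
        w = np.asarray(self.phase_weights, dtype=float)
        if w.shape != (len(self.phases),) or np.any(w < 0):
            raise ValidationError("phase weights must be nonnegative, one per phase")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError("phase weights must sum to 1 within 1e-12")
        self.phase_weights = w
        self.phase_shifts_mm = np.asarray(self.phase_shifts_mm, dtype=float).reshape(
            len(self.phases), 3
        )

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def reference_index(self) -> int:
        return (self.n_phases - 1) // 2

    @property
    def reference(self) -> tuple[VoxelGrid, StructureSet]:
        return self.phases[self.reference_index]


@dataclass(frozen=True)
class OarSpec:
    """Cubic organ-at-risk: center offset from the phantom center and half-width."""

    offset_mm: tuple[float, float, float] = (33.0, 0.0, 0.0)
    halfwidth_mm: float = 9.0


def _cube_indices(grid: VoxelGrid, center_mm: np.ndarray, halfwidth_mm: float) -> np.ndarray:
    """Flat indices of voxels whose center lies inside an axis-aligned cube."""
    per_axis = []
    for a in range(3):
        c = grid.axis_centers(a)
        per_axis.append(np.abs(c - center_mm[a]) <= halfwidth_mm + 1e-9)
    m = (
        per_axis[0][:, None, None]
        & per_axis[1][None, :, None]
        & per_axis[2][None, None, :]
    )
    return np.flatnonzero(m.ravel())


def make_box_phantom(
    dims_mm: tuple[float, float, float] = (120.0, 120.0, 120.0),
    spacing_mm: float | tuple[float, float, float] = 3.0,
    target_halfwidth_mm: float = 18.0,
    oar_spec: OarSpec | None = OarSpec(),
    target_density_delta: float = 0.1,
) -> tuple[VoxelGrid, StructureSet]:
    """Homogeneous water box with a centered cubic target and an offset OAR.

    The body covers the whole grid at relative density 1; target voxels get
    density ``1 + target_density_delta`` to mimic the raised HU of the target.
    """
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be positive, got {spacing}")
    dims = tuple(int(round(dm / s)) for dm, s in zip(dims_mm, spacing))
    if any(d < 1 for d in dims):
        raise ValidationError("phantom smaller than one voxel per axis")
    origin = tuple(0.5 * s for s in spacing)
    grid = VoxelGrid(dims, spacing, origin, np.ones(dims))

    center = np.array([d * s / 2.0 for d, s in zip(dims, spacing)])
    if target_halfwidth_mm <= 0:
        raise GeometryError("target half-width must be positive")
    if np.any(center - target_halfwidth_mm < 0) or np.any(
        center + target_halfwidth_mm > np.array(dims) * np.array(spacing)
    ):
        raise GeometryError("target does not fit inside the phantom")
    target = _cube_indices(grid, center, target_halfwidth_mm)
    if target.size == 0:
        raise GeometryError("target mask is empty at this resolution")

    structures = {"body": np.arange(grid.nvox, dtype=np.int64), "target": target}
    roles = {"body": "body", "target": "target"}
    if oar_spec is not None:
        oc = center + np.asarray(oar_spec.offset_mm, dtype=float)
        lo, hi = grid.bounds()
        if np.any(oc - oar_spec.halfwidth_mm < lo) or np.any(
            oc + oar_spec.halfwidth_mm > hi
        ):
            raise GeometryError("OAR does not fit inside the phantom")
        oar = _cube_indices(grid, oc, oar_spec.halfwidth_mm)
        if oar.size == 0:
            raise GeometryError("OAR mask is empty at this resolution")
        structures["oar"] = oar
        roles["oar"] = "oar"

    rho = grid.density.copy()
    rho.ravel()[target] += float(target_density_delta)
    grid = VoxelGrid(dims, spacing, origin, rho)
    sset = StructureSet(structures, roles)
    sset.validate_against(grid)
    return grid, sset


def _shift_volume(arr: np.ndarray, shift_vox: int, axis: int, fill: float) -> np.ndarray:
    out = np.full_like(arr, fill)
    if shift_vox == 0:
        return arr.copy()
    n = arr.shape[axis]
    if abs(shift_vox) >= n:
        return out
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift_vox > 0:
        dst[axis] = slice(shift_vox, n)
        src[axis] = slice(0, n - shift_vox)
    else:
        dst[axis] = slice(0, n + shift_vox)
        src[axis] = slice(-shift_vox, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shift_indices(
    idx: np.ndarray, shift_vox: int, axis: int, dims: tuple[int, int, int]
) -> tuple[np.ndarray, bool]:
    """Shift flat indices by whole voxels along one axis.

    Returns (shifted indices, clipped) where *clipped* flags voxels pushed
    outside the grid (those are dropped).  Single-axis whole-voxel shifts
    preserve the sorted flat-index order, which keeps per-phase structure rows
    aligned with the reference phase.
    """
    multi = np.array(np.unravel_index(idx, dims))
    multi[axis] += shift_vox
    inside = (multi[axis] >= 0) & (multi[axis] < dims[axis])
    clipped = not bool(inside.all())
    multi = multi[:, inside]
    return np.ravel_multi_index(tuple(multi), dims).astype(np.int64), clipped


def make_4d_box(
    base: tuple[VoxelGrid, StructureSet],
    n_phases: int = 10,
    step_mm: float = 3.0,
    axis: int = 0,
) -> Phantom4D:
    """Rigidly shifted CT phases of a base phantom (uniform phase weights).

    Phase k is the base displaced by ``(k - (n_phases - 1)//2) * step_mm``
    along ``axis``; for an odd phase count the shifts are symmetric about
    zero, for an even count they are off-center by one step.
    """
    grid, sset = base
    if n_phases < 1:
        raise ValidationError("n_phases must be >= 1")
    sp = grid.spacing[axis]
    ratio = step_mm / sp
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValidationError(
            f"step_mm={step_mm} is not a whole-voxel multiple of spacing {sp}"
        )
    step_vox = int(round(ratio))

    phases: list[tuple[VoxelGrid, StructureSet]] = []
    shifts = np.zeros((n_phases, 3))
    for k in range(n_phases):
        off = k - (n_phases - 1) // 2
        sv = off * step_vox
        shifts[k, axis] = off * step_mm
        rho = _shift_volume(grid.density, sv, axis, fill=1.0)
        structures = {}
        for name, idx in sset.structures.items():
            if sset.roles[name] == "body":
                structures[name] = idx.copy()
                continue
            sidx, clipped = _shift_indices(idx, sv, axis, grid.dims)
            if clipped and sset.roles[name] == "target":
                raise GeometryError(
                    f"phase {k}: shift pushes target outside the grid"
                )
            structures[name] = sidx
        g = VoxelGrid(grid.dims, grid.spacing, grid.origin, rho)
        phases.append((g, StructureSet(structures, dict(sset.roles))))

    w = np.full(n_phases, 1.0 / n_phases)
    return Phantom4D(phases, w, shifts, motion_axis=axis)


def expand_margin(
    mask: np.ndarray, margin_mm: float, grid: VoxelGrid
) -> np.ndarray:
    """Isotropic Euclidean margin expansion of a voxel-index set.

    The output contains exactly the voxels whose center lies within
    ``margin_mm`` (Euclidean, mm) of some input-voxel center.
    """
    if margin_mm < 0:
        raise ValidationError("margin must be >= 0")
    idx = np.asarray(mask, dtype=np.int64).ravel()
    if margin_mm == 0:
        return np.unique(idx)
    sp = np.asarray(grid.spacing)
    rad = np.floor(margin_mm / sp + 1e-9).astype(int)
    offs = np.meshgrid(
        *(np.arange(-r, r + 1) for r in rad), indexing="ij"
    )
    dist = np.sqrt(sum((o * s) ** 2 for o, s in zip(offs, sp)))
    ball = dist <= margin_mm + 1e-9
    vol = np.zeros(grid.nvox, dtype=bool)
    vol[idx] = True
    out = ndimage.binary_dilation(vol.reshape(grid.dims), structure=ball)
    return np.flatnonzero(out.ravel()).astype(np.int64)


def build_itv(phantom4d: Phantom4D, ctv_name: str = "target") -> np.ndarray:
    """Internal target volume on the reference phase.

    All phases share one room-frame grid related by known rigid whole-voxel
    shifts, so the ITV is the voxelwise union of the per-phase CTV masks; it
    is elongated along the motion axis and a superset of every phase CTV.
    """
    union: list[np.ndarray] = []
    for k, (_, sset) in enumerate(phantom4d.phases):
        if ctv_name not in sset.structures:
            raise ValidationError(f"structure {ctv_name!r} missing in phase {k}")
        union.append(sset.structures[ctv_name])
    return np.unique(np.concatenate(union))
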