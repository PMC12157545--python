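"""Volumetric data model: grids, scalar volumes, masks, atlases, NIfTI I/O.

Conventions used throughout the package:

* voxel indexing is 0-based;
* an integer continuous coordinate (i, j, k) lies at the voxel centre;
* mask membership of a continuous point is decided by nearest-voxel
  rounding, with ties (.5 fractions) rounding toward -inf.

Masks are written as uint8 NIfTI with a JSON sidecar carrying the label
and protocol role so that any standard viewer can inspect them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Raised when volumes defined on different grids are combined."""


class VolumeFormatError(ValueError):
    """Raised for corrupt or non-conforming volume files."""


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid of a volume: shape, voxel size and voxel->world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_mm: float, origin: Sequence[float] = (0.0, 0.0, 0.0)) -> "VolumeGrid":
        aff = np.eye(4)
        aff[:3, :3] *= voxel_mm
        aff[:3, 3] = origin
        return cls(tuple(shape), aff)

    def same_as(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)

    def require_same(self, other: "VolumeGrid"):
        if not self.same_as(other):
            raise GridMismatchError(
                f"grid mismatch: shape {self.shape} affine\n{self.affine}\nvs shape {other.shape} affine\n{other.affine}"
            )

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.asarray(vox, dtype=float)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def contains_voxel(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        ok = np.ones(len(idx), dtype=bool)
        for a in range(3):
            ok &= (idx[:, a] >= 0) & (idx[:, a] < self.shape[a])
        return ok


def nearest_voxel(coord: np.ndarray) -> np.ndarray:
    """Round continuous voxel coordinates to the nearest voxel index.

    Ties (.5) round toward -inf so that the convention is total.
    """
    return np.ceil(np.asarray(coord, dtype=float) - 0.5).astype(np.int64)


def world_to_voxel(point: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    return grid.world_to_voxel(point)


def voxel_to_world(coord: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    return grid.voxel_to_world(coord)


@dataclass
class ScalarVolume:
    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise VolumeFormatError("scalar volume contains non-finite values")


@dataclass
class MaskVolume:
    grid: VolumeGrid
    membership: np.ndarray
    label: str = ""
    role: str = ""

    def __post_init__(self):
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.membership.shape} != grid shape {self.grid.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def voxel_indices(self) -> np.ndarray:
        return np.argwhere(self.membership)

    def contains_points(self, coords: np.ndarray) -> np.ndarray:
        """Membership of continuous voxel coordinates (nearest-voxel rule)."""
        idx = nearest_voxel(np.atleast_2d(coords))
        ok = self.grid.contains_voxel(idx)
        out = np.zeros(len(idx), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.membership[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    # -- boolean algebra (exact set semantics) --------------------------------
    def _binary(self, other: "MaskVolume", op) -> "MaskVolume":
        self.grid.require_same(other.grid)
        return MaskVolume(self.grid, op(self.membership, other.membership),
                          label=f"({self.label}?{other.label})")

    def union(self, other: "MaskVolume") -> "MaskVolume":
        m = self._binary(other, np.logical_or)
        m.label = f"({self.label}|{other.label})"
        return m

    def intersect(self, other: "MaskVolume") -> "MaskVolume":
        m = self._binary(other, np.logical_and)
        m.label = f"({self.label}&{other.label})"
        return m

    def minus(self, other: "MaskVolume") -> "MaskVolume":
        m = self._binary(other, lambda a, b: a & ~b)
        m.label = f"({self.label}-{other.label})"
        return m

    def complement(self) -> "MaskVolume":
        return MaskVolume(self.grid, ~self.membership, label=f"~{self.label}")

    def dilate(self, iterations: int = 1) -> "MaskVolume":
        """6-connected binary dilation, ``iterations`` times."""
        struct = ndimage.generate_binary_structure(3, 1)
        out = ndimage.binary_dilation(self.membership, structure=struct, iterations=iterations) \
            if iterations > 0 else self.membership.copy()
        return MaskVolume(self.grid, out, label=f"dilate({self.label},{iterations})")

    @classmethod
    def empty(cls, grid: VolumeGrid, label: str = "") -> "MaskVolume":
        return cls(grid, np.zeros(grid.shape, dtype=bool), label=label)

    @classmethod
    def full(cls, grid: VolumeGrid, label: str = "") -> "MaskVolume":
        return cls(grid, np.ones(grid.shape, dtype=bool), label=label)

    @classmethod
    def union_all(cls, masks: Iterable["MaskVolume"], label: str = "") -> "MaskVolume":
        masks = list(masks)
        if not masks:
            raise ValueError("union_all of no masks")
        out = masks[0]
        for m in masks[1:]:
            out = out.union(m)
        out.label = label or out.label
        return out


@dataclass
class GreyMatterAtlas:
    """Grey-matter elements for blueprint rows.

    ``cortical_elements`` is an ordered list of (voxel index triple,
    hemisphere tag) for ribbon voxels adjacent to white matter — a
    voxel-based stand-in for a downsampled cortical surface.
    ``subcortical_nuclei`` maps names like ``"putamen_l"`` to masks.
    """

    grid: VolumeGrid
    cortical_elements: list[tuple[tuple[int, int, int], str]]
    subcortical_nuclei: dict[str, MaskVolume]
    wm_mask: MaskVolume
    zones: dict[str, MaskVolume] = field(default_factory=dict)

    def __post_init__(self):
        names = list(self.subcortical_nuclei)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if (self.subcortical_nuclei[names[a]].membership
                        & self.subcortical_nuclei[names[b]].membership).any():
                    raise ValueError(f"nuclei {names[a]} and {names[b]} overlap")
        nuc = np.zeros(self.grid.shape, dtype=bool)
        for m in self.subcortical_nuclei.values():
            nuc |= m.membership
        for (i, j, k), _ in self.cortical_elements:
            if nuc[i, j, k]:
                raise ValueError(f"cortical element {(i, j, k)} inside a nucleus")

    def nuclei_union(self) -> MaskVolume:
        return MaskVolume.union_all(list(self.subcortical_nuclei.values()), label="subcortex")

    def cortical_element_array(self) -> np.ndarray:
        return np.array([idx for idx, _ in self.cortical_elements], dtype=np.int64)


# -----------------------------------------------------------------------------
# NIfTI I/O with JSON sidecars
# -----------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: ScalarVolume | MaskVolume, path: str | Path, meta: Mapping | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, MaskVolume):
        data = vol.membership.astype(np.uint8)
        side = {"kind": "mask", "label": vol.label, "role": vol.role}
    else:
        data = vol.values.astype(np.float64)
        side = {"kind": "scalar"}
    side.update(meta or {})   # caller-provided sidecar entries win
    img = nib.Nifti1Image(data, vol.grid.affine)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(side, indent=1))


def read_volume(path: str | Path) -> ScalarVolume | MaskVolume:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as e:  # corrupt header, truncated file, wrong magic
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {e}") from e
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"{path}: volume contains non-finite values")
    grid = VolumeGrid(data.shape, affine)

    side = {}
    sc = _sidecar_path(path)
    if sc.exists():
        side = json.loads(sc.read_text())
    is_mask = side.get("kind") == "mask" or (
        side.get("kind") is None and np.isin(np.unique(data), (0.0, 1.0)).all()
    )
    if is_mask:
        return MaskVolume(grid, data > 0.5, label=side.get("label", path.stem),
                          role=side.get("role", ""))
    return ScalarVolume(grid, data)


def downsample_block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling by an integer factor (edge blocks padded with 0)."""
    if factor == 1:
        return values.copy()
    shape = values.shape
    padded = [int(np.ceil(s / factor)) * factor for s in shape]
    buf = np.zeros(padded, dtype=float)
    buf[: shape[0], : shape[1], : shape[2]] = values
    return buf.reshape(padded[0] // factor, factor,
                       padded[1] // factor, factor,
                       padded[2] // factor, factor).mean(axis=(1, 3, 5))


def downsample_grid(grid: VolumeGrid, factor: int) -> VolumeGrid:
    if factor == 1:
        return grid
    shape = tuple(int(np.ceil(s / factor)) for s in grid.shape)
    aff = grid.affine.copy()
    aff[:3, :3] *= factor
    # voxel centres of the coarse grid sit at the mean of fine-voxel centres
    aff[:3, 3] = grid.affine[:3, 3] + grid.affine[:3, :3] @ (np.full(3, (factor - 1) / 2.0))
    return VolumeGrid(shape, aff)
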