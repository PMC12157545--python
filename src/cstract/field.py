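"""Crossing-fibre orientation fields.

Each voxel hosts up to ``MAX_POPULATIONS`` fibre populations.  A population
has a mean direction (an axial, sign-free unit vector), a volume fraction,
and ``n_samples`` orientation samples emulating posterior draws from a
crossing-fibre model fit.  All directions are expressed in world (mm) space.

Serialised as a directory of three 4-D NIfTI volumes (mean directions,
fractions, samples) plus a JSON metadata file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import VolumeGrid, VolumeFormatError

MAX_POPULATIONS = 3


@dataclass
class OrientationField:
    """Per-voxel fibre populations on a grid.

    Arrays (nx, ny, nz prefix implied):

    * ``mean_directions`` — (..., P, 3) unit vectors; zero rows mean "no
      population".
    * ``fractions`` — (..., P) volume fractions, sum <= 1 per voxel.
    * ``samples`` — (..., P, S, 3) unit orientation samples.
    """

    grid: VolumeGrid
    mean_directions: np.ndarray
    fractions: np.ndarray
    samples: np.ndarray

    def __post_init__(self):
        nx, ny, nz = self.grid.shape
        P = MAX_POPULATIONS
        if self.mean_directions.shape != (nx, ny, nz, P, 3):
            raise ValueError(f"mean_directions shape {self.mean_directions.shape}")
        if self.fractions.shape != (nx, ny, nz, P):
            raise ValueError(f"fractions shape {self.fractions.shape}")
        if self.samples.ndim != 6 or self.samples.shape[:4] != (nx, ny, nz, P) or self.samples.shape[5] != 3:
            raise ValueError(f"samples shape {self.samples.shape}")
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.samples.shape[4]

    def validate(self):
        f = self.fractions
        if (f < -1e-12).any():
            raise ValueError("negative volume fraction")
        if (f.sum(axis=-1) > 1 + 1e-9).any():
            raise ValueError("volume fractions sum above 1")
        present = f > 0
        norms = np.linalg.norm(self.mean_directions, axis=-1)
        if not np.allclose(norms[present], 1.0, atol=1e-9):
            raise ValueError("mean directions of present populations must be unit norm")
        snorms = np.linalg.norm(self.samples, axis=-1)
        if not np.allclose(snorms[present], 1.0, atol=1e-9):
            raise ValueError("orientation samples must be unit norm")

    def save(self, out_dir: str | Path):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nx, ny, nz = self.grid.shape
        P = MAX_POPULATIONS
        S = self.n_samples
        nib.save(nib.Nifti1Image(self.mean_directions.reshape(nx, ny, nz, P * 3), self.grid.affine),
                 str(out / "mean_directions.nii.gz"))
        nib.save(nib.Nifti1Image(self.fractions, self.grid.affine),
                 str(out / "fractions.nii.gz"))
        nib.save(nib.Nifti1Image(self.samples.reshape(nx, ny, nz, P * S * 3), self.grid.affine),
                 str(out / "samples.nii.gz"))
        (out / "field.json").write_text(json.dumps({
            "format": "cstract-orientation-field",
            "max_populations": P,
            "n_samples": S,
            "shape": [nx, ny, nz],
        }, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "OrientationField":
        src = Path(in_dir)
        meta_path = src / "field.json"
        if not meta_path.exists():
            raise VolumeFormatError(f"{src}: not an orientation-field directory (field.json missing)")
        meta = json.loads(meta_path.read_text())
        P, S = meta["max_populations"], meta["n_samples"]
        img = nib.load(str(src / "mean_directions.nii.gz"))
        grid = VolumeGrid(img.shape[:3], np.asarray(img.affine))
        nx, ny, nz = grid.shape
        dirs = np.asarray(img.dataobj, dtype=float).reshape(nx, ny, nz, P, 3)
        fracs = np.asarray(nib.load(str(src / "fractions.nii.gz")).dataobj, dtype=float)
        samples = np.asarray(nib.load(str(src / "samples.nii.gz")).dataobj, dtype=float).reshape(nx, ny, nz, P, S, 3)
        return cls(grid, dirs, fracs, samples)

    @classmethod
    def empty(cls, grid: VolumeGrid, n_samples: int) -> "OrientationField":
        nx, ny, nz = grid.shape
        return cls.__new__(cls).__init_empty(grid, nx, ny, nz, n_samples)

    def __init_empty(self, grid, nx, ny, nz, S):
        self.grid = grid
        self.mean_directions = np.zeros((nx, ny, nz, MAX_POPULATIONS, 3))
        self.fractions = np.zeros((nx, ny, nz, MAX_POPULATIONS))
        self.samples = np.zeros((nx, ny, nz, MAX_POPULATIONS, S, 3))
        return self
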