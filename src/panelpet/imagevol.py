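"""Voxel grids and image volumes.

Axis order is fixed (X, Y, Z = axial); voxel centres sit at
``origin + (index + 0.5) * voxel_size``.  Volumes can be written/read as
NIfTI-1 (voxel size in the header) or as raw float32 with a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ImageGrid:
    """Regular voxel grid. ``shape`` = (nx, ny, nz), isotropic or
    per-axis ``voxel_mm``, ``origin_mm`` = world position of the corner of
    voxel (0,0,0)."""

    shape: tuple
    voxel_mm: tuple
    origin_mm: tuple

    @classmethod
    def centered(cls, shape, voxel_mm, center_mm=(0.0, 0.0, 0.0)) -> "ImageGrid":
        shape = tuple(int(s) for s in np.broadcast_to(shape, 3))
        voxel = tuple(float(v) for v in np.broadcast_to(voxel_mm, 3))
        origin = tuple(
            float(c) - s * v / 2.0 for c, s, v in zip(center_mm, shape, voxel)
        )
        return cls(shape=shape, voxel_mm=voxel, origin_mm=origin)

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel size must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_mm)

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.origin_mm) + self.extent_mm / 2.0

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_mm[axis]

    def voxel_center_mesh(self):
        xs = [self.voxel_centers_1d(a) for a in range(3)]
        return np.meshgrid(*xs, indexing="ij")


@dataclass
class ImageVolume:
    """3D image with physical spacing/origin."""

    data: np.ndarray
    grid: ImageGrid

    def __post_init__(self):
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def total(self) -> float:
        return float(self.data.sum())

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data=data, grid=self.grid)

    # -- I/O ----------------------------------------------------------------

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.grid.voxel_mm) + [1.0])
        affine[:3, 3] = np.asarray(self.grid.origin_mm) + np.asarray(self.grid.voxel_mm) / 2.0
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
        affine = img.affine
        origin = tuple(float(affine[i, 3] - voxel[i] / 2.0) for i in range(3))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        grid = ImageGrid(shape=tuple(data.shape), voxel_mm=voxel, origin_mm=origin)
        return cls(data=data, grid=grid)

    def to_raw(self, path) -> None:
        path = Path(path)
        self.data.astype(np.float32).tofile(path)
        sidecar = {
            "shape": list(self.grid.shape),
            "voxel_mm": list(self.grid.voxel_mm),
            "origin_mm": list(self.grid.origin_mm),
            "dtype": "float32",
            "order": "C",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_raw(cls, path) -> "ImageVolume":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.fromfile(path, dtype=np.float32).reshape(meta["shape"]).astype(np.float64)
        grid = ImageGrid(
            shape=tuple(meta["shape"]),
            voxel_mm=tuple(meta["voxel_mm"]),
            origin_mm=tuple(meta["origin_mm"]),
        )
        return cls(data=data, grid=grid)
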