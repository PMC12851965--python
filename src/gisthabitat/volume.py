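"""Minimal 3-D image containers with spacing metadata and NIfTI I/O.

Intensities are abstract (z-score-like) units rather than Hounsfield units:
the pipeline z-normalizes every volume before any downstream step, so the
absolute scale carries no information.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "TumorMask", "save_nifti", "load_nifti", "load_mask"]


@dataclass
class ImageVolume:
    """A 3-D scalar grid with voxel spacing in millimetres.

    ``voxels`` is indexed (x, y, z); ``spacing_mm`` gives the physical edge
    length of a voxel along each axis. Origin is kept for round-tripping but
    plays no role in the analysis (phantoms live on their own grid).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.voxels.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)


@dataclass
class TumorMask:
    """Binary region of interest on the same grid as its image."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(np.uint8)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.voxels.ndim}")
        if not np.isin(self.voxels, (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")
        if self.voxels.sum() < 1:
            raise ValueError("mask has no foreground voxels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_compatible(self, image: ImageVolume) -> None:
        if self.shape != image.shape:
            raise ValueError(f"mask grid {self.shape} != image grid {image.shape}")
        if not np.allclose(self.spacing_mm, image.spacing_mm):
            raise ValueError("mask and image spacing differ")


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(path: str | Path, voxels: np.ndarray, spacing_mm, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a volume as NIfTI. ``.nii.gz`` output is byte-deterministic
    (gzip mtime fixed to 0) so identical seeds give identical checksums."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(voxels), _affine(tuple(spacing_mm), tuple(origin)))
    if path.name.endswith(".nii.gz"):
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))


def load_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path: str | Path) -> TumorMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    vox = np.asarray(img.dataobj)
    return TumorMask((vox > 0.5).astype(np.uint8), spacing, origin)
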