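"""Image preprocessing: z-score normalization, 1 mm isotropic resampling,
and within-ROI [0, 1] rescaling for the clustering path.

Processing order is znormalize -> resample_isotropic -> rescale_unit.
Z-score statistics are computed over the whole volume with the population
SD; [0, 1] rescaling uses the ROI-only min/max because clustering operates
on ROI voxels.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .volume import ImageVolume, TumorMask

__all__ = [
    "ZeroVarianceError",
    "DegenerateROIError",
    "znormalize",
    "resample_isotropic",
    "rescale_unit",
]


class ZeroVarianceError(ValueError):
    """Constant image (or constant ROI): normalization undefined."""


class DegenerateROIError(ValueError):
    """Resampling left the mask without foreground voxels."""


def znormalize(image: ImageVolume) -> ImageVolume:
    """Whole-volume z-score normalization: (v - mean) / sd, population SD.

    Output mean is ~0 and SD ~1 to 1e-6. Idempotent to the same tolerance.
    """
    v = np.asarray(image.voxels, dtype=np.float64)
    sd = float(v.std())  # population SD (ddof=0)
    if sd == 0.0:
        raise ZeroVarianceError("constant image: z-score normalization undefined")
    return image.with_voxels((v - v.mean()) / sd)


def _to_sitk(voxels: np.ndarray, spacing_mm, origin) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our convention is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(voxels, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def resample_isotropic(
    image: ImageVolume, mask: TumorMask, target_mm: float = 1.0
) -> tuple[ImageVolume, TumorMask]:
    """Resample an image/mask pair onto an isotropic grid (default 1 mm).

    The image is interpolated with a cubic B-spline, the mask with nearest
    neighbour and re-binarized. A pair already on the target grid is
    returned unchanged.
    """
    mask.check_compatible(image)
    spacing = np.asarray(image.spacing_mm, dtype=float)
    if np.allclose(spacing, target_mm, atol=1e-9):
        return image, mask

    new_size = [
        max(1, int(round(n * s / target_mm)))
        for n, s in zip(image.shape, spacing)
    ]
    ref = sitk.Image(new_size, sitk.sitkFloat64)
    ref.SetSpacing((target_mm,) * 3)
    ref.SetOrigin(tuple(float(o) for o in image.origin))

    img = _to_sitk(image.voxels.astype(np.float64), image.spacing_mm, image.origin)
    msk = _to_sitk(mask.voxels.astype(np.uint8), mask.spacing_mm, image.origin)

    img_rs = sitk.Resample(img, ref, sitk.Transform(), sitk.sitkBSpline, 0.0)
    msk_rs = sitk.Resample(msk, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0)

    mask_vox = (_from_sitk(msk_rs) > 0.5).astype(np.uint8)
    if mask_vox.sum() == 0:
        raise DegenerateROIError("mask is empty after resampling")
    spacing_out = (target_mm,) * 3
    return (
        ImageVolume(_from_sitk(img_rs), spacing_out, image.origin),
        TumorMask(mask_vox, spacing_out, image.origin),
    )


def rescale_unit(image: ImageVolume, mask: TumorMask) -> ImageVolume:
    """Affinely map within-ROI intensities to [0, 1] (min -> 0, max -> 1).

    Voxels outside the mask are left unchanged (downstream steps ignore
    them). Strictly monotone on ROI voxels.
    """
    mask.check_compatible(image)
    fg = np.asarray(mask.voxels, bool)
    roi = image.voxels[fg]
    lo, hi = float(roi.min()), float(roi.max())
    if hi == lo:
        raise ZeroVarianceError("constant ROI: [0, 1] rescaling undefined")
    out = np.array(image.voxels, dtype=np.float64)
    out[fg] = (roi - lo) / (hi - lo)
    return image.with_voxels(out)
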