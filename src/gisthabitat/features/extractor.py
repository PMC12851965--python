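"""Radiomics feature extractor.

Names follow the ``<image>_<class>_<feature>`` convention
(e.g. ``wavelet-LHH_firstorder_Skewness``, ``original_shape_Flatness``).
The default configuration yields exactly 1,045 features per region:

* original image: 18 first-order + 14 shape + 68 texture
  (GLCM 24, GLDM 14, GLRLM 16, GLSZM 14) = 100;
* 8 wavelet sub-bands x 86 (first-order + texture) = 688;
* 2 LoG sigmas x 86 = 172;
* lbp-3D x 85 = 85 (TotalEnergy omitted: on the integer LBP code map at
  1 mm isotropic spacing it exactly duplicates Energy).

Shape features are extracted only from the original (unfiltered) image.
Texture families use a fixed 32-bin equal-width discretization within the
region. Regions below ``min_voxels`` produce a missing-feature record (all
NaN) rather than an error.
"""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, TumorMask
from ._filters import filter_bank
from ._firstorder import FIRSTORDER_NAMES, firstorder_features
from ._shape import SHAPE_NAMES, shape_features
from ._texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    label_volume,
)

__all__ = ["FeatureExtractor", "extract_features", "EXPECTED_TOTAL"]

EXPECTED_TOTAL = 1045

TEXTURE_FAMILIES = {
    "glcm": (GLCM_NAMES, glcm_features),
    "gldm": (GLDM_NAMES, gldm_features),
    "glrlm": (GLRLM_NAMES, glrlm_features),
    "glszm": (GLSZM_NAMES, glszm_features),
}
DEFAULT_FAMILIES = ("firstorder", "shape", "glcm", "gldm", "glrlm", "glszm")
DEFAULT_FILTERS = ("wavelet", "log", "lbp")
LBP_FIRSTORDER_EXCLUDE = ("TotalEnergy",)


class FeatureExtractor:
    """Configurable extractor; the default configuration is the full
    1,045-feature bank. Reduced banks (e.g. ``families=("firstorder",
    "shape"), filters=()``) keep the same naming scheme."""

    def __init__(
        self,
        families: tuple[str, ...] = DEFAULT_FAMILIES,
        filters: tuple[str, ...] = DEFAULT_FILTERS,
        n_bins: int = 32,
        min_voxels: int = 27,
    ):
        for fam in families:
            if fam not in ("firstorder", "shape") and fam not in TEXTURE_FAMILIES:
                raise ValueError(f"unknown feature family {fam!r}")
        self.families = tuple(families)
        self.filters = tuple(filters)
        self.n_bins = int(n_bins)
        self.min_voxels = int(min_voxels)
        self._filter_image_names = self._enumerate_filter_images()
        self._names = tuple(self._enumerate_names())
        if set(self.families) == set(DEFAULT_FAMILIES) and set(self.filters) == set(
            DEFAULT_FILTERS
        ):
            assert len(self._names) == EXPECTED_TOTAL, (
                f"default configuration must yield {EXPECTED_TOTAL} features, "
                f"got {len(self._names)}"
            )

    def _enumerate_filter_images(self) -> tuple[str, ...]:
        from itertools import product

        names = []
        if "wavelet" in self.filters:
            names += sorted("wavelet-" + "".join(c) for c in product("HL", repeat=3))
        if "log" in self.filters:
            from ._filters import LOG_SIGMAS_MM
            names += [
                f"log-sigma-{str(float(s)).replace('.', '-')}-mm-3D" for s in LOG_SIGMAS_MM
            ]
        if "lbp" in self.filters:
            names += ["lbp-3D"]
        return tuple(names)

    def _firstorder_names(self, image_name: str) -> tuple[str, ...]:
        if image_name == "lbp-3D":
            return tuple(n for n in FIRSTORDER_NAMES if n not in LBP_FIRSTORDER_EXCLUDE)
        return FIRSTORDER_NAMES

    def _enumerate_names(self):
        for img in ("original",) + self._filter_image_names:
            if "firstorder" in self.families:
                for n in self._firstorder_names(img):
                    yield f"{img}_firstorder_{n}"
            if img == "original" and "shape" in self.families:
                for n in SHAPE_NAMES:
                    yield f"original_shape_{n}"
            for fam in ("glcm", "gldm", "glrlm", "glszm"):
                if fam in self.families:
                    for n in TEXTURE_FAMILIES[fam][0]:
                        yield f"{img}_{fam}_{n}"

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self._names

    def settings(self) -> dict:
        return {
            "families": list(self.families),
            "filters": list(self.filters),
            "n_bins": self.n_bins,
            "min_voxels": self.min_voxels,
            "total_features": len(self._names),
            "wavelet": "coif1 (single-level stationary)",
            "lbp_firstorder_excluded": list(LBP_FIRSTORDER_EXCLUDE),
        }

    def missing_record(self) -> dict[str, float]:
        return {n: np.nan for n in self._names}

    def extract(self, image: ImageVolume, region) -> dict[str, float]:
        """Feature vector for one region of one image.

        ``region`` is a boolean array on the image grid (or a TumorMask).
        Returns the full name->value map; an undersized region yields NaNs.
        """
        reg = region.voxels if isinstance(region, TumorMask) else region
        reg = np.asarray(reg).astype(bool)
        if reg.shape != image.shape:
            raise ValueError("region grid does not match image grid")
        if reg.sum() < self.min_voxels:
            return self.missing_record()

        voxvol = image.voxel_volume_mm3
        out: dict[str, float] = {}
        images = {"original": np.asarray(image.voxels, dtype=np.float64)}
        if self.filters:
            images.update(filter_bank(images["original"], self.filters))

        for img_name in ("original",) + self._filter_image_names:
            vol = images[img_name]
            vals = vol[reg]
            if "firstorder" in self.families:
                fo = firstorder_features(
                    vals, voxvol, self.n_bins,
                    exclude=LBP_FIRSTORDER_EXCLUDE if img_name == "lbp-3D" else (),
                )
                out.update({f"{img_name}_firstorder_{k}": v for k, v in fo.items()})
            if img_name == "original" and "shape" in self.families:
                sh = shape_features(reg, image.spacing_mm)
                out.update({f"original_shape_{k}": v for k, v in sh.items()})
            needed = [f for f in TEXTURE_FAMILIES if f in self.families]
            if needed:
                lab = label_volume(vol, reg, self.n_bins)
                for fam in ("glcm", "gldm", "glrlm", "glszm"):
                    if fam in self.families:
                        vals_f = TEXTURE_FAMILIES[fam][1](lab, self.n_bins)
                        out.update({f"{img_name}_{fam}_{k}": v for k, v in vals_f.items()})
        # schema stability: same names, same order, every time
        return {n: float(out[n]) for n in self._names}


def extract_features(image: ImageVolume, region_mask, settings: dict | None = None):
    """One-call extraction with the default (or overridden) configuration."""
    extractor = FeatureExtractor(**(settings or {}))
    return extractor.extract(image, region_mask)
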