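#!/usr/bin/env python
"""Preprocess one phantom and partition it into intensity habitats.

Saves the subregion label map as NIfTI next to a CSV of per-subregion
summaries (centroid, voxel count, mean intensity), illustrating the
density-ordered labelling (subregion 1 = densest, 3 = hypodense core).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gisthabitat.habitat import cluster_subregions
from gisthabitat.preprocess import rescale_unit, resample_isotropic, znormalize
from gisthabitat.synthetic_cohort import PhantomSpec, generate_phantom
from gisthabitat.volume import save_nifti

RESULTS = Path(__file__).resolve().parents[1] / "results" / "habitats"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(
        diameter_mm=34, class_label="high", core_fraction=0.3,
        skewness_target=-2.0, flatness_target=0.65, seed=42,
    )
    unenh, _, mask, truth = generate_phantom(spec)
    img, mask = resample_isotropic(znormalize(unenh), mask)
    rescaled = rescale_unit(img, mask)
    label_map = cluster_subregions(rescaled, mask, 3)

    save_nifti(RESULTS / "subregions.nii.gz", label_map.labels.astype(np.int16),
               img.spacing_mm)
    rows = []
    for lab in (1, 2, 3):
        sel = label_map.labels == lab
        rows.append({
            "subregion": lab,
            "centroid": round(float(label_map.centroids[lab - 1]), 4),
            "n_voxels": int(sel.sum()),
            "mean_intensity": round(float(rescaled.voxels[sel].mean()), 4),
            "truth_core_overlap": round(float((truth.labels[sel] == 3).mean()), 4),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "subregion_summary.csv", index=False)
    print(table.to_string(index=False))
    agree = float((label_map.labels == truth.labels)[mask.voxels.astype(bool)].mean())
    print(f"voxel agreement with generator truth: {agree:.3f}")


if __name__ == "__main__":
    main()
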