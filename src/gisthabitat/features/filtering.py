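"""Feature stability and redundancy filters.

Stability: features are re-extracted on morphologically jittered masks (a
synthetic stand-in for a second reader's ROI outlines) and kept when the
two-way random-effects, absolute-agreement, single-measure ICC — ICC(2,1)
— exceeds the threshold (strict >, default 0.75).

Redundancy: pairwise Spearman correlation; while any pair has |rho| above
the threshold (default 0.9), the member of the worst pair with the larger
mean absolute correlation to the currently retained set is removed
(ties broken toward the lexicographically later name). Deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["icc_2_1", "stability_filter", "redundancy_filter", "jitter_mask"]


def icc_2_1(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) between two measurement sets.

    ``x1``, ``x2`` are (n_subjects,) or (n_subjects, n_features). Returns
    the per-feature ICC; NaN where the measurements have no variance.
    """
    a = np.atleast_2d(np.asarray(x1, float).T).T
    b = np.atleast_2d(np.asarray(x2, float).T).T
    if a.shape != b.shape:
        raise ValueError("both tables must have identical shape")
    n = a.shape[0]
    k = 2.0
    grand = (a + b).sum(axis=0) / (k * n)
    subj = (a + b) / k                       # per-subject means (n, F)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)  # per-rater means

    ssr = k * ((subj - grand) ** 2).sum(axis=0)
    ssc = n * ((m1 - grand) ** 2 + (m2 - grand) ** 2)
    sst = ((a - grand) ** 2 + (b - grand) ** 2).sum(axis=0)
    sse = np.maximum(sst - ssr - ssc, 0.0)

    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc = np.where(sst > 0, icc, np.nan)
    return icc if np.asarray(x1).ndim > 1 else float(icc[0])


def stability_filter(
    table_ref: pd.DataFrame, table_perturbed: pd.DataFrame, threshold: float = 0.75
) -> list[str]:
    """Feature names whose ICC(2,1) between the two extractions is > threshold."""
    if list(table_ref.columns) != list(table_perturbed.columns) or len(table_ref) != len(
        table_perturbed
    ):
        raise ValueError("tables must share cases and features")
    icc = icc_2_1(table_ref.to_numpy(float), table_perturbed.to_numpy(float))
    retained = []
    for name, value in zip(table_ref.columns, np.atleast_1d(icc)):
        if np.isnan(value):
            warnings.warn(f"feature {name!r}: zero variance, ICC undefined -> dropped")
        elif value > threshold:
            retained.append(name)
    return retained


def redundancy_filter(table: pd.DataFrame, rho_threshold: float = 0.9) -> list[str]:
    """Greedy removal of one member of every |Spearman rho| > threshold pair."""
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique(dropna=True) <= 1]
    for c in constant:
        warnings.warn(f"feature {c!r}: constant, correlation undefined -> dropped")
    retained = [c for c in cols if c not in constant]
    if len(retained) < 2:
        return retained
    corr = table[retained].corr(method="spearman").abs()
    np.fill_diagonal(corr.values, 0.0)

    while True:
        sub = corr.loc[retained, retained]
        mat = sub.to_numpy()
        worst = mat.max()
        if worst <= rho_threshold:
            break
        # worst pair; ties broken lexicographically by the (sorted) name pair
        pairs = [
            tuple(sorted((retained[i], retained[j])))
            for i, j in zip(*np.nonzero(mat >= worst - 1e-15))
            if i < j
        ]
        f1, f2 = min(pairs)
        mean_abs = sub.mean(axis=0)  # mean |rho| to the currently retained set
        if mean_abs[f1] > mean_abs[f2]:
            drop = f1
        elif mean_abs[f2] > mean_abs[f1]:
            drop = f2
        else:
            drop = max(f1, f2)  # tie -> lexicographically later name
        retained = [c for c in retained if c != drop]
        if len(retained) < 2:
            break
    return retained


def jitter_mask(mask: np.ndarray, seed: int, n_patches: int = 4, radius: int = 2) -> np.ndarray:
    """One-voxel-radius random morphological perturbation of a binary mask.

    Emulates a second reader's outline: around ``n_patches`` random surface
    voxels, the mask is locally dilated or eroded (one voxel). Returns a
    non-empty uint8 mask on the same grid.
    """
    rng = np.random.default_rng(seed)
    m = np.asarray(mask).astype(bool)
    dilated = ndimage.binary_dilation(m)
    eroded = ndimage.binary_erosion(m)
    surface = np.argwhere(m & ~eroded)
    if len(surface) == 0:
        return m.astype(np.uint8)
    out = m.copy()
    centers = surface[rng.integers(0, len(surface), size=n_patches)]
    grids = np.indices(m.shape)
    for c, grow in zip(centers, rng.random(n_patches) < 0.5):
        ball = ((grids - c[:, None, None, None]) ** 2).sum(axis=0) <= radius**2
        out[ball] = dilated[ball] if grow else eroded[ball]
    if not out.any():
        return m.astype(np.uint8)
    return out.astype(np.uint8)
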