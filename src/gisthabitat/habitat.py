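"""Intensity-habitat clustering: deterministic bin-initialized K-means.

Each tumor ROI is partitioned, per case and per phase, into N subregions by
running Lloyd's algorithm on the scalar voxel intensities (rescaled to
[0, 1] within the ROI). Initial centroids are the mean intensities of N
equal-width bins, which removes the usual K-means seeding randomness:
the same input always yields the same partition. Final labels are
renumbered in order of decreasing centroid, so subregion 1 is the densest
habitat and subregion N the least dense (e.g. a hypodense/necrotic core).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume, TumorMask

__all__ = [
    "SubregionLabelMap",
    "UnderPopulatedROIError",
    "init_centroids",
    "kmeans_1d",
    "cluster_subregions",
    "select_cluster_count",
]

MAX_ITER = 300


class UnderPopulatedROIError(ValueError):
    """ROI has fewer distinct intensities than requested clusters."""


@dataclass
class SubregionLabelMap:
    """K-way partition of a tumor mask, density-ordered.

    ``labels`` uses 0 for background and 1..N for subregions, where the
    mean (rescaled) intensity of subregion i is >= that of subregion i+1.
    """

    labels: np.ndarray
    centroids: np.ndarray  # descending, one per subregion, in [0, 1]
    n: int
    flagged_empty: tuple[int, ...] = field(default_factory=tuple)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def validate_partition(self, mask: TumorMask) -> None:
        fg = np.asarray(mask.voxels, bool)
        inside = self.labels[fg]
        if (inside < 1).any() or (inside > self.n).any():
            raise ValueError("foreground labels outside 1..N")
        if (self.labels[~fg] != 0).any():
            raise ValueError("nonzero labels outside the mask")


def init_centroids(roi_intensities: np.ndarray, n: int) -> np.ndarray:
    """Deterministic centroid seeds from N equal-width intensity bins.

    Intensities must already be rescaled to [0, 1]. Bin b covers
    [(b-1)/N, b/N), with the last bin closed at 1. An empty bin falls back
    to its midpoint so that exactly N centroids are always produced.
    """
    x = np.asarray(roi_intensities, dtype=np.float64).ravel()
    if n < 2:
        raise ValueError("need at least 2 clusters")
    if np.unique(x).size < n:
        raise UnderPopulatedROIError(
            f"ROI has {np.unique(x).size} distinct intensities < N={n}"
        )
    if x.min() < 0 or x.max() > 1:
        raise ValueError("intensities must lie in [0, 1] (run rescale_unit first)")
    # half-open bins: value v lands in bin floor(v*N), except v == 1 -> last bin
    idx = np.minimum((x * n).astype(np.int64), n - 1)
    centroids = np.empty(n)
    for b in range(n):
        sel = x[idx == b]
        centroids[b] = sel.mean() if sel.size else (b + 0.5) / n
    return centroids


def kmeans_1d(x: np.ndarray, centroids: np.ndarray, max_iter: int = MAX_ITER):
    """Lloyd's algorithm on scalars from fixed initial centroids.

    Returns (assignments, centroids, n_iter). A cluster that loses all its
    points keeps its previous centroid (it may re-acquire points later);
    clusters still empty at convergence are reported by the caller.
    Convergence is zero assignment changes.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    c = np.array(centroids, dtype=np.float64)
    assign = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
    for it in range(1, max_iter + 1):
        for k in range(c.size):
            sel = x[assign == k]
            if sel.size:
                c[k] = sel.mean()
        new_assign = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
        if np.array_equal(new_assign, assign):
            return assign, c, it
        assign = new_assign
    return assign, c, max_iter


def cluster_subregions(image: ImageVolume, mask: TumorMask, n: int = 3) -> SubregionLabelMap:
    """Partition the ROI into N density-ordered subregions.

    ``image`` must be preprocessed so that ROI intensities lie in [0, 1]
    (see :func:`gisthabitat.preprocess.rescale_unit`). Deterministic: no
    random restarts, bin-mean initialization.
    """
    mask.check_compatible(image)
    fg = np.asarray(mask.voxels, bool)
    x = image.voxels[fg]
    c0 = init_centroids(x, n)
    assign, c, _ = kmeans_1d(x, c0)
    # density-descending renumbering: label 1 <- highest centroid
    order = np.argsort(-c, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)
    labels = np.zeros(image.shape, dtype=np.int16)
    labels[fg] = rank[assign]
    sizes = np.bincount(rank[assign], minlength=n + 1)[1:]
    flagged = tuple(int(i + 1) for i in range(n) if sizes[i] == 0)
    return SubregionLabelMap(labels=labels, centroids=c[order], n=n, flagged_empty=flagged)


def wcss(x: np.ndarray, assign: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squares of a scalar clustering."""
    return float(np.sum((np.asarray(x, float) - np.asarray(centroids, float)[assign]) ** 2))


def select_cluster_count(score_by_candidate, candidates=(3, 4, 5)) -> tuple[int, dict]:
    """Choose the cluster count N maximizing downstream cross-validated AUC.

    ``score_by_candidate`` maps each candidate N to the mean 5-fold CV AUC
    of the selection+model pipeline, averaged over subregions and phases
    (a callable N -> score, or a precomputed mapping). Candidates whose
    pipeline fails are recorded and dropped; ties go to the smallest N.

    Returns (n_star, details) where details holds per-candidate scores and
    errors.
    """
    scores: dict[int, float] = {}
    errors: dict[int, str] = {}
    for n in candidates:
        try:
            s = score_by_candidate(n) if callable(score_by_candidate) else score_by_candidate[n]
        except Exception as exc:  # per-candidate failure is reported, not fatal
            errors[n] = f"{type(exc).__name__}: {exc}"
            continue
        scores[n] = float(s)
    if not scores:
        raise ValueError(f"all candidates failed: {errors}")
    best = max(scores.values())
    n_star = min(n for n, s in scores.items() if s >= best - 1e-12)
    return n_star, {"scores": scores, "errors": errors}


def pipeline_score_for_count(
    tables_by_region, labels, folds: int = 5, seed: int = 0,
    min_case_fraction: float = 0.7,
) -> float:
    """Mean CV-AUC of the full selection+model pipeline for one candidate N.

    ``tables_by_region`` maps (phase, region) -> feature DataFrame (cases in
    the same order as ``labels``). For each table the redundancy filter and
    greedy forward selection are run, and the selected subset's mean 5-fold
    CV AUC is recorded; the candidate's score is the mean over tables.

    A candidate whose subregions are too small to support feature
    extraction in more than ``1 - min_case_fraction`` of cases is not a
    usable partition of the cohort and fails the pipeline (the caller
    reports it and selects over the remaining candidates).
    """
    from .features.filtering import redundancy_filter
    from .rfa_select import cv_auc, rfa

    labels = np.asarray(labels)
    aucs = []
    for key in sorted(tables_by_region):
        table = tables_by_region[key]
        keep = ~table.isna().any(axis=1).to_numpy()  # undersized-region exclusions
        if keep.mean() < min_case_fraction:
            raise ValueError(
                f"subregion {key} usable in only {keep.mean():.0%} of cases"
            )
        table, y = table.loc[keep], labels[keep]
        kept = redundancy_filter(table)
        res = rfa(table[kept], y, folds=folds, seed=seed)
        if res.selected:
            aucs.append(res.trajectory[-1])
        else:  # empty selection: fall back to the best single feature's CV AUC
            best = max(cv_auc(table[[f]], y, folds=folds, seed=seed) for f in kept)
            aucs.append(best)
    return float(np.mean(aucs))
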