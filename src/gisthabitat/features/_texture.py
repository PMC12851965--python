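"""Gray-level texture-matrix families: GLCM, GLRLM, GLSZM, GLDM.

All families operate on a discretized label volume (0 outside the region,
1..Ng inside; fixed bin count within the region). Directional families
(GLCM, GLRLM) use the 13 unique 3-D directions, with features computed per
direction and averaged; GLSZM uses 26-connected zones and GLDM 26-neighbour
dependence counts (alpha = 0). Run/zone/dependence families are computed
from run, zone and voxel lists rather than dense matrices, which keeps
large homogeneous regions cheap.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

_EPS = np.finfo(float).eps


def offsets_13() -> list[tuple[int, int, int]]:
    """The 13 unique 3-D directions (half of the 26-neighbourhood)."""
    out = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        first = next(v for v in d if v != 0)
        if first > 0:
            out.append(d)
    return out


def discretize(values: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Equal-width discretization of region intensities to levels 1..n_bins."""
    x = np.asarray(values, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.shape, dtype=np.int64)
    lev = ((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.minimum(lev, n_bins - 1) + 1


def label_volume(intensities: np.ndarray, region: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Cropped discretized volume: 0 outside region, 1..Ng inside."""
    region = np.asarray(region, bool)
    idx = np.argwhere(region)
    lo = idx.min(0)
    hi = idx.max(0) + 1
    sub_reg = region[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_int = np.asarray(intensities, float)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    lab = np.zeros(sub_reg.shape, dtype=np.int64)
    lab[sub_reg] = discretize(sub_int[sub_reg], n_bins)
    return lab


def _shifted_pairs(lab: np.ndarray, off: tuple[int, int, int]):
    """Aligned (center, neighbour) views of ``lab`` for one offset."""
    sl_a, sl_b = [], []
    for o, n in zip(off, lab.shape):
        if o == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif o > 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return lab[tuple(sl_a)], lab[tuple(sl_b)]


# ---------------------------------------------------------------- GLCM ----

def glcm_features(lab: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    g = n_bins
    mats = []
    for off in offsets_13():
        a, b = _shifted_pairs(lab, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        codes = (a[valid] - 1) * g + (b[valid] - 1)
        c = np.bincount(codes.ravel(), minlength=g * g).reshape(g, g).astype(np.float64)
        c = c + c.T  # symmetric co-occurrence
        mats.append(c / c.sum())
    if not mats:
        return {k: np.nan for k in GLCM_NAMES}
    P = np.stack(mats)  # (D, G, G)
    D = P.shape[0]
    i = np.arange(1, g + 1, dtype=np.float64)
    ii = i[:, None] * np.ones((1, g))
    jj = ii.T

    px = P.sum(axis=2)  # (D, G)
    py = P.sum(axis=1)
    ux = (px * i).sum(axis=1)
    uy = (py * i).sum(axis=1)
    sx = np.sqrt(np.maximum((px * (i - ux[:, None]) ** 2).sum(axis=1), 0.0))
    sy = np.sqrt(np.maximum((py * (i - uy[:, None]) ** 2).sum(axis=1), 0.0))

    # p_{x+y}(k), k = 2..2G and p_{x-y}(k), k = 0..G-1
    ksum = (ii + jj - 2).astype(np.int64).ravel()
    kdiff = np.abs(ii - jj).astype(np.int64).ravel()
    p_sum = np.zeros((D, 2 * g - 1))
    p_diff = np.zeros((D, g))
    for d in range(D):
        p_sum[d] = np.bincount(ksum, weights=P[d].ravel(), minlength=2 * g - 1)
        p_diff[d] = np.bincount(kdiff, weights=P[d].ravel(), minlength=g)
    k_sum = np.arange(2, 2 * g + 1, dtype=np.float64)
    k_diff = np.arange(g, dtype=np.float64)

    def ent(p, axis=None):
        return -np.sum(np.where(p > 0, p * np.log2(p + _EPS), 0.0), axis=axis)

    autocorr = (P * (ii * jj)).sum(axis=(1, 2))
    cluster = ii + jj - ux[:, None, None] - uy[:, None, None]
    contrast = (P * (ii - jj) ** 2).sum(axis=(1, 2))
    da = (p_diff * k_diff).sum(axis=1)
    joint_ent = ent(P.reshape(D, -1), axis=1)
    hx = ent(px, axis=1)
    hy = ent(py, axis=1)
    pxpy = px[:, :, None] * py[:, None, :]
    hxy1 = -np.sum(P * np.log2(pxpy + _EPS), axis=(1, 2))
    hxy2 = -np.sum(pxpy * np.log2(pxpy + _EPS), axis=(1, 2))
    denom = np.maximum(np.maximum(hx, hy), _EPS)
    imc1 = (joint_ent - hxy1) / denom
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_ent)), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (autocorr - ux * uy) / (sx * sy)
    corr = np.where((sx > _EPS) & (sy > _EPS), corr, 1.0)

    mcc = np.empty(D)
    for d in range(D):
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(px[d][:, None] > 0, P[d] / px[d][:, None], 0.0)
            B = np.where(py[d][None, :] > 0, P[d] / py[d][None, :], 0.0)
        Q = A @ B.T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc[d] = np.sqrt(max(ev[1], 0.0)) if ev.size > 1 else 1.0

    off_diag = np.abs(ii - jj) > 0
    inv_var = np.array(
        [np.sum(P[d][off_diag] / (ii - jj)[off_diag] ** 2) for d in range(D)]
    )

    feats = {
        "Autocorrelation": autocorr,
        "ClusterProminence": (P * cluster**4).sum(axis=(1, 2)),
        "ClusterShade": (P * cluster**3).sum(axis=(1, 2)),
        "ClusterTendency": (P * cluster**2).sum(axis=(1, 2)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff, axis=1),
        "DifferenceVariance": (p_diff * (k_diff - da[:, None]) ** 2).sum(axis=1),
        "Id": (P / (1.0 + np.abs(ii - jj))).sum(axis=(1, 2)),
        "Idm": (P / (1.0 + (ii - jj) ** 2)).sum(axis=(1, 2)),
        "Idmn": (P / (1.0 + (ii - jj) ** 2 / g**2)).sum(axis=(1, 2)),
        "Idn": (P / (1.0 + np.abs(ii - jj) / g)).sum(axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": joint_ent,
        "MCC": mcc,
        "MaximumProbability": P.reshape(D, -1).max(axis=1),
        "SumAverage": (p_sum * k_sum).sum(axis=1),
        "SumEntropy": ent(p_sum, axis=1),
        "SumSquares": (P * (ii - ux[:, None, None]) ** 2).sum(axis=(1, 2)),
    }
    return {k: float(np.mean(v)) for k, v in feats.items()}


# --------------------------------------------------------------- GLRLM ----

def _runs(lab: np.ndarray, off: tuple[int, int, int]):
    """Run-length encode the region along one direction.

    Returns (run_level, run_length). Voxels on the same lattice line are
    grouped by the integer anchor point p - t*d; gaps (non-region voxels)
    break runs.
    """
    idx = np.nonzero(lab)
    coords = np.stack(idx, axis=1)
    vals = lab[idx]
    d = np.asarray(off)
    a = int(np.nonzero(d)[0][0])
    t = coords[:, a] * d[a]
    anchor = coords - t[:, None] * d[None, :]
    order = np.lexsort((t, anchor[:, 2], anchor[:, 1], anchor[:, 0]))
    t, anchor, vals = t[order], anchor[order], vals[order]
    breaks = (
        (anchor[1:] != anchor[:-1]).any(axis=1)
        | (t[1:] != t[:-1] + 1)
        | (vals[1:] != vals[:-1])
    )
    starts = np.concatenate([[True], breaks])
    run_id = np.cumsum(starts) - 1
    return vals[starts], np.bincount(run_id)


def _cell_entropy(i: np.ndarray, j: np.ndarray) -> float:
    codes = i.astype(np.int64) * (j.max() + 1) + j
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def glrlm_features(lab: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    n_p = int((lab > 0).sum())
    per_dir = {k: [] for k in GLRLM_NAMES}
    for off in offsets_13():
        lev, rl = _runs(lab, off)
        i = lev.astype(np.float64)
        j = rl.astype(np.float64)
        nr = i.size
        ni = np.bincount(lev)
        nj = np.bincount(rl)
        mu_i = i.mean()
        mu_j = j.mean()
        vals = {
            "GrayLevelNonUniformity": float((ni.astype(float) ** 2).sum() / nr),
            "GrayLevelNonUniformityNormalized": float((ni.astype(float) ** 2).sum() / nr**2),
            "GrayLevelVariance": float(((i - mu_i) ** 2).mean()),
            "HighGrayLevelRunEmphasis": float((i**2).mean()),
            "LongRunEmphasis": float((j**2).mean()),
            "LongRunHighGrayLevelEmphasis": float((i**2 * j**2).mean()),
            "LongRunLowGrayLevelEmphasis": float((j**2 / i**2).mean()),
            "LowGrayLevelRunEmphasis": float((1.0 / i**2).mean()),
            "RunEntropy": _cell_entropy(lev, rl),
            "RunLengthNonUniformity": float((nj.astype(float) ** 2).sum() / nr),
            "RunLengthNonUniformityNormalized": float((nj.astype(float) ** 2).sum() / nr**2),
            "RunPercentage": float(nr / n_p),
            "RunVariance": float(((j - mu_j) ** 2).mean()),
            "ShortRunEmphasis": float((1.0 / j**2).mean()),
            "ShortRunHighGrayLevelEmphasis": float((i**2 / j**2).mean()),
            "ShortRunLowGrayLevelEmphasis": float((1.0 / (i**2 * j**2)).mean()),
        }
        for k, v in vals.items():
            per_dir[k].append(v)
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


# --------------------------------------------------------------- GLSZM ----

def glszm_features(lab: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    n_p = int((lab > 0).sum())
    structure = np.ones((3, 3, 3), dtype=np.int8)  # 26-connectivity
    zone_level, zone_size = [], []
    for g in np.unique(lab[lab > 0]):
        comp, n_comp = ndimage.label(lab == g, structure=structure)
        if n_comp:
            sizes = np.bincount(comp.ravel())[1:]
            zone_size.append(sizes)
            zone_level.append(np.full(n_comp, g))
    i = np.concatenate(zone_level).astype(np.float64)
    s = np.concatenate(zone_size).astype(np.float64)
    nz = i.size
    ni = np.bincount(i.astype(np.int64))
    ns = np.bincount(s.astype(np.int64))
    mu_i, mu_s = i.mean(), s.mean()
    return {
        "GrayLevelNonUniformity": float((ni.astype(float) ** 2).sum() / nz),
        "GrayLevelVariance": float(((i - mu_i) ** 2).mean()),
        "HighGrayLevelZoneEmphasis": float((i**2).mean()),
        "LargeAreaEmphasis": float((s**2).mean()),
        "LargeAreaHighGrayLevelEmphasis": float((i**2 * s**2).mean()),
        "LargeAreaLowGrayLevelEmphasis": float((s**2 / i**2).mean()),
        "LowGrayLevelZoneEmphasis": float((1.0 / i**2).mean()),
        "SizeZoneNonUniformity": float((ns.astype(float) ** 2).sum() / nz),
        "SmallAreaEmphasis": float((1.0 / s**2).mean()),
        "SmallAreaHighGrayLevelEmphasis": float((i**2 / s**2).mean()),
        "SmallAreaLowGrayLevelEmphasis": float((1.0 / (i**2 * s**2)).mean()),
        "ZoneEntropy": _cell_entropy(i.astype(np.int64), s.astype(np.int64)),
        "ZonePercentage": float(nz / n_p),
        "ZoneVariance": float(((s - mu_s) ** 2).mean()),
    }


# ---------------------------------------------------------------- GLDM ----

def gldm_features(lab: np.ndarray, n_bins: int = 32, alpha: int = 0) -> dict[str, float]:
    region = lab > 0
    dep = np.zeros(lab.shape, dtype=np.int64)
    for off in offsets_13():
        a, b = _shifted_pairs(lab, off)
        both = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        # symmetric: count the neighbour for both voxels of the pair
        sl_a, sl_b = [], []
        for o, n in zip(off, lab.shape):
            if o == 0:
                sl_a.append(slice(None)); sl_b.append(slice(None))
            elif o > 0:
                sl_a.append(slice(0, n - o)); sl_b.append(slice(o, n))
            else:
                sl_a.append(slice(-o, n)); sl_b.append(slice(0, n + o))
        dep[tuple(sl_a)] += both
        dep[tuple(sl_b)] += both
    i = lab[region].astype(np.float64)
    j = (dep[region] + 1).astype(np.float64)  # dependence size = count + 1 (self)
    nz = i.size
    ni = np.bincount(i.astype(np.int64))
    nj = np.bincount(j.astype(np.int64))
    mu_i, mu_j = i.mean(), j.mean()
    return {
        "DependenceEntropy": _cell_entropy(i.astype(np.int64), j.astype(np.int64)),
        "DependenceNonUniformity": float((nj.astype(float) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((nj.astype(float) ** 2).sum() / nz**2),
        "DependenceVariance": float(((j - mu_j) ** 2).mean()),
        "GrayLevelNonUniformity": float((ni.astype(float) ** 2).sum() / nz),
        "GrayLevelVariance": float(((i - mu_i) ** 2).mean()),
        "HighGrayLevelEmphasis": float((i**2).mean()),
        "LargeDependenceEmphasis": float((j**2).mean()),
        "LargeDependenceHighGrayLevelEmphasis": float((i**2 * j**2).mean()),
        "LargeDependenceLowGrayLevelEmphasis": float((j**2 / i**2).mean()),
        "LowGrayLevelEmphasis": float((1.0 / i**2).mean()),
        "SmallDependenceEmphasis": float((1.0 / j**2).mean()),
        "SmallDependenceHighGrayLevelEmphasis": float((i**2 / j**2).mean()),
        "SmallDependenceLowGrayLevelEmphasis": float((1.0 / (i**2 * j**2)).mean()),
    }
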