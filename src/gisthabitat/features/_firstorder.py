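"""First-order (intensity histogram) features, IBSI-style definitions.

18 features; histogram-based entries (Entropy, Uniformity) use the same
fixed-bin-count discretization as the texture families. Skewness and
Kurtosis use population moments; Kurtosis is NOT excess (a normal
distribution scores ~3).
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray,
    voxel_volume_mm3: float = 1.0,
    n_bins: int = 32,
    exclude: tuple[str, ...] = (),
) -> dict[str, float]:
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    mean = x.mean()
    centered = x - mean
    m2 = float(np.mean(centered**2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # discretized probabilities for Entropy / Uniformity
    lo, hi = x.min(), x.max()
    if hi > lo:
        idx = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)
        p = np.bincount(idx, minlength=n_bins) / n
    else:
        p = np.array([1.0])
    p_nz = p[p > 0]

    robust = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))

    out = {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz))),
        "Minimum": float(lo),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(hi),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(hi - lo),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centered))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(np.mean(centered**3) / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(np.mean(centered**4) / m2**2) if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": float(np.sum(p_nz**2)),
    }
    for name in exclude:
        out.pop(name, None)
    return out
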