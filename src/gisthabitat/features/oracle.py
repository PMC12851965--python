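"""Independent first-order oracle for tests.

Plain-Python, direct-from-definition implementations of the 18 first-order
features, deliberately avoiding the vectorized production path in
``_firstorder``. Used only by the test suite as a cross-implementation
check.
"""

from __future__ import annotations

import math

__all__ = ["firstorder_oracle"]


def _percentile(sorted_x: list[float], q: float) -> float:
    """Linear-interpolation percentile (matches numpy's default)."""
    n = len(sorted_x)
    if n == 1:
        return sorted_x[0]
    pos = q / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac


def firstorder_oracle(
    roi_intensities, voxel_volume_mm3: float = 1.0, n_bins: int = 32
) -> dict[str, float]:
    x = [float(v) for v in roi_intensities]
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    n = len(x)
    s = sorted(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10 = _percentile(s, 10)
    p90 = _percentile(s, 90)

    lo, hi = s[0], s[-1]
    counts = [0] * n_bins
    if hi > lo:
        for v in x:
            b = int((v - lo) / (hi - lo) * n_bins)
            counts[min(b, n_bins - 1)] += 1
        probs = [c / n for c in counts if c > 0]
    else:
        probs = [1.0]

    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    energy = sum(v * v for v in x)

    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": lo,
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": hi,
        "Mean": mean,
        "Median": _percentile(s, 50),
        "InterquartileRange": _percentile(s, 75) - _percentile(s, 25),
        "Range": hi - lo,
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": (
            sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0
        ),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p * p for p in probs),
    }
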