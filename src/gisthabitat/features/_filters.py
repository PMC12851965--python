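"""Image filter bank for higher-order features.

* wavelet — single-level stationary (undecimated) 3-D wavelet transform
  (coif1), yielding the 8 low/high-pass sub-band combinations
  (LLL ... HHH, incl. LHH);
* LoG — Laplacian-of-Gaussian at sigma = 1 and 2 mm (images are on a 1 mm
  isotropic grid, so sigma is in voxels);
* lbp-3D — a simple rotation-invariant 3-D local binary pattern code map:
  for each voxel, the count of its 26 neighbours whose intensity is >= the
  centre voxel (codes 0..26).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

WAVELET = "coif1"
LOG_SIGMAS_MM = (1.0, 2.0)


def wavelet_bands(volume: np.ndarray) -> dict[str, np.ndarray]:
    """8 single-level stationary-wavelet sub-bands, named e.g. wavelet-LHH."""
    vol = np.asarray(volume, dtype=np.float64)
    pad = [(0, n % 2) for n in vol.shape]  # swt needs even extents
    padded = np.pad(vol, pad, mode="edge")
    coeffs = pywt.swtn(padded, WAVELET, level=1, trim_approx=False)[0]
    out = {}
    for key, band in coeffs.items():
        name = "wavelet-" + "".join("L" if ch == "a" else "H" for ch in key)
        out[name] = band[tuple(slice(0, n) for n in vol.shape)]
    return dict(sorted(out.items()))


def log_bands(volume: np.ndarray, sigmas_mm=LOG_SIGMAS_MM) -> dict[str, np.ndarray]:
    vol = np.asarray(volume, dtype=np.float64)
    out = {}
    for s in sigmas_mm:
        name = f"log-sigma-{str(float(s)).replace('.', '-')}-mm-3D"
        out[name] = ndimage.gaussian_laplace(vol, sigma=s)
    return out


def lbp3d_band(volume: np.ndarray) -> dict[str, np.ndarray]:
    vol = np.asarray(volume, dtype=np.float64)
    code = np.zeros(vol.shape, dtype=np.float64)
    padded = np.pad(vol, 1, mode="edge")
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                nb = padded[
                    1 + dx : 1 + dx + vol.shape[0],
                    1 + dy : 1 + dy + vol.shape[1],
                    1 + dz : 1 + dz + vol.shape[2],
                ]
                code += nb >= vol
    return {"lbp-3D": code}


def filter_bank(volume: np.ndarray, filters=("wavelet", "log", "lbp")) -> dict[str, np.ndarray]:
    """All requested filtered versions of a volume, keyed by filter name."""
    out: dict[str, np.ndarray] = {}
    if "wavelet" in filters:
        out.update(wavelet_bands(volume))
    if "log" in filters:
        out.update(log_bands(volume))
    if "lbp" in filters:
        out.update(lbp3d_band(volume))
    return out
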