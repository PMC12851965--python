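"""3-D shape/morphology features (14), extracted from the binary region only.

Mesh-based quantities (volume, surface area, sphericity) use a marching-
cubes surface; axis lengths derive from the eigenvalues of the physical-
coordinate covariance matrix (MajorAxisLength = 4*sqrt(lambda_1), etc.).
Maximum diameters are computed over convex-hull vertices of the surface
voxels.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    # divergence theorem: sum of signed tetrahedron volumes
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return abs(float(np.sum(np.einsum("ij,ij->i", a, np.cross(b, c)))) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance, via the convex hull when it helps."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 16:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:  # degenerate (flat/collinear) point sets
            pass
    return float(pdist(pts).max())


def _max_inplane_diameter(coords: np.ndarray, plane_axes: tuple[int, int], slice_axis: int) -> float:
    """Max in-plane diameter over slices perpendicular to ``slice_axis``."""
    best = 0.0
    for v in np.unique(coords[:, slice_axis]):
        sl = coords[coords[:, slice_axis] == v][:, plane_axes]
        if len(sl) >= 2:
            best = max(best, _max_pairwise(np.unique(sl, axis=0)))
    return best


def shape_features(region: np.ndarray, spacing_mm) -> dict[str, float]:
    region = np.asarray(region, bool)
    spacing = np.asarray(spacing_mm, dtype=float)
    n_vox = int(region.sum())
    voxel_volume = float(np.prod(spacing))

    padded = np.pad(region.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    mesh_volume = _mesh_volume(verts, faces)
    tri = verts[faces]
    surface_area = float(
        np.sum(0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1))
    )

    coords_idx = np.argwhere(region)
    phys = coords_idx * spacing
    center = phys.mean(axis=0)
    cov = np.cov((phys - center).T, bias=True) if n_vox > 1 else np.zeros((3, 3))
    eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    # surface voxels: region voxels with at least one non-region 6-neighbour
    from scipy.ndimage import binary_erosion

    surface_vox = region & ~binary_erosion(region)
    surf_phys = np.argwhere(surface_vox) * spacing

    max3d = _max_pairwise(surf_phys)
    surf_idx = np.argwhere(surface_vox).astype(np.float64) * spacing
    max_slice = _max_inplane_diameter(surf_idx, (0, 1), 2)   # in-plane (x, y)
    max_column = _max_inplane_diameter(surf_idx, (0, 2), 1)  # (x, z)
    max_row = _max_inplane_diameter(surf_idx, (1, 2), 0)     # (y, z)

    sphericity = (
        (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
        if surface_area > 0
        else 0.0
    )
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n_vox * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else np.nan,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max_slice,
        "Maximum2DDiameterColumn": max_column,
        "Maximum2DDiameterRow": max_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
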