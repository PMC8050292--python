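"""3D shape descriptors of the ROI mask — 14 values.

Mesh-based descriptors (volume, surface area, sphericity, diameters) are
computed on a triangulated isosurface of the binary mask obtained by marching
cubes at level 0.5 on a zero-padded volume, with physical (mm) vertex
coordinates.  Axis lengths derive from the principal components of the voxel
centre coordinates (population covariance), scaled by 4 so that for an
ellipsoidal ROI they approach the ellipsoid axis diameters.

Shape features are never grey-level quantised and are excluded from every
grey-level or voxel-count dependency correction downstream: they are the
features that legitimately carry volume information.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES = [
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
]


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    # undo the one-voxel pad so vertices sit in the mask's physical frame
    verts = verts - np.asarray(spacing)
    return verts, faces

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def _planar_diameter(verts: np.ndarray, fixed_axis: int) -> float:
    """Largest in-plane vertex distance within any single plane along an axis."""
    plane_axes = [a for a in range(3) if a != fixed_axis]
    coords = np.round(verts[:, fixed_axis], 6)
    best = 0.0
    for value in np.unique(coords):
        pts = verts[coords == value][:, plane_axes]
        if len(pts) < 2:
            continue
        if len(pts) > 10:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:
                pass
        best = max(best, float(pdist(pts).max()))
    return best


def shape_features(mask_values: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Compute the 14 shape descriptors of a binary mask.

    Single-voxel masks (no 2x2x2 neighbourhood) yield NaN for the mesh-based
    descriptors; voxel-count-based values are still defined.
    """
    mask = np.asarray(mask_values, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))

    idx = np.argwhere(mask)
    coords = idx * np.asarray(spacing)

    # principal axis lengths from the population covariance of voxel centres
    if n > 1:
        cov = np.cov(coords, rowvar=False, ddof=0)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()

    out = {
        "VoxelVolume": n * voxel_volume,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else np.nan,
        "Flatness": float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else np.nan,
    }

    try:
        verts, faces = _mesh(mask, spacing)
    except (ValueError, RuntimeError):
        for name in (
            "MeshVolume",
            "SurfaceArea",
            "SurfaceVolumeRatio",
            "Sphericity",
            "Maximum3DDiameter",
            "Maximum2DDiameterSlice",
            "Maximum2DDiameterColumn",
            "Maximum2DDiameterRow",
        ):
            out[name] = np.nan
        return out

    volume = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    out["MeshVolume"] = volume
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / volume if volume > 0 else np.nan
    out["Sphericity"] = float((36 * np.pi * volume**2) ** (1.0 / 3.0) / area) if area > 0 else np.nan
    out["Maximum3DDiameter"] = _max_pairwise(verts)
    # fixed axis: slice plane fixes z (axis 2), column plane fixes x (axis 0),
    # row plane fixes y (axis 1) for (x, y, z)-ordered arrays
    out["Maximum2DDiameterSlice"] = _planar_diameter(verts, 2)
    out["Maximum2DDiameterColumn"] = _planar_diameter(verts, 0)
    out["Maximum2DDiameterRow"] = _planar_diameter(verts, 1)
    return out
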