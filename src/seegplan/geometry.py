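"""Metric geometry on voxel head models.

Everything the planner and the metrics module need geometrically lives
here: Euclidean distance fields with trilinear off-grid queries,
trajectory discretization into sampling nodes, scalp surface normals,
closed-form segment-segment distances, and forbidden-zone crossing
tests. All world coordinates are millimetres; voxel indices are
0-based and refer to voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DistanceField",
    "distance_field",
    "signed_distance_field",
    "sample_nodes",
    "surface_normal",
    "angle_from_orthogonal",
    "min_segment_distance",
    "crosses_mask",
    "interpolate_volume",
    "world_to_voxel_coords",
]


def world_to_voxel_coords(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world-mm points (..., 3) to continuous voxel coordinates."""
    points = np.asanyarray(points, dtype=float)
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def interpolate_volume(volume: np.ndarray, affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a voxel volume at world-mm points.

    Points outside the grid are evaluated against the nearest edge
    value (mode="nearest"), which is the right behavior for distance
    fields and for masks whose foreground never touches the grid edge.
    """
    vox = world_to_voxel_coords(np.atleast_2d(points), affine)
    vals = ndimage.map_coordinates(
        np.asarray(volume, dtype=float), vox.T, order=1, mode="nearest"
    )
    return vals


@dataclass
class DistanceField:
    """Euclidean distance (mm) to the nearest foreground voxel of a source mask.

    ``values[i,j,k]`` is 0 exactly on source voxels; anisotropic voxel
    spacing is respected. ``sentinel`` is set when the source mask was
    empty, in which case the field is uniformly the grid diagonal.
    """

    values: np.ndarray
    affine: np.ndarray
    source: str = ""
    sentinel: bool = False
    cap_mm: float = field(default=np.inf)

    def at(self, points: np.ndarray) -> np.ndarray:
        """Distance at world points, trilinearly interpolated."""
        return interpolate_volume(self.values, self.affine, points)


def _voxel_spacing(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


def grid_diagonal_mm(shape, affine) -> float:
    """Length of the grid's main diagonal in mm; documented distance cap."""
    spacing = _voxel_spacing(affine)
    return float(np.linalg.norm((np.asarray(shape) - 1) * spacing))


def distance_field(mask: np.ndarray, affine: np.ndarray, source: str = "") -> DistanceField:
    """Exact Euclidean distance transform of a binary mask, in mm.

    An empty mask yields a sentinel field uniformly equal to the grid
    diagonal (the largest distance representable on the grid) and emits
    a warning: metrics stay total, and any risk computed against the
    sentinel is 0 because every distance exceeds the outer range.
    """
    mask = np.asarray(mask) > 0
    spacing = _voxel_spacing(affine)
    cap = grid_diagonal_mm(mask.shape, affine)
    if not mask.any():
        warnings.warn(
            f"distance_field: source mask {source!r} is empty; "
            f"returning sentinel field at grid diagonal {cap:.1f} mm",
            stacklevel=2,
        )
        values = np.full(mask.shape, cap, dtype=float)
        return DistanceField(values, np.array(affine, float), source, sentinel=True, cap_mm=cap)
    values = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return DistanceField(np.asarray(values, float), np.array(affine, float), source, cap_mm=cap)


def signed_distance_field(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Signed distance volume: positive outside the mask, negative inside."""
    mask = np.asarray(mask) > 0
    spacing = _voxel_spacing(affine)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return np.asarray(outside - inside, dtype=float)


def sample_nodes(entry, target, n: int = 128) -> np.ndarray:
    """Discretize the straight entry→target trajectory into ``n`` nodes.

    Node i sits at entry + i/(n-1)·(target-entry); nodes are equally
    spaced and include both endpoints. Returns an (n, 3) array.
    """
    entry = np.asarray(entry, dtype=float)
    target = np.asarray(target, dtype=float)
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    if np.allclose(entry, target):
        raise ValueError("entry and target coincide; trajectory is degenerate")
    t = np.linspace(0.0, 1.0, n)[:, None]
    return entry[None, :] * (1 - t) + target[None, :] * t


class SurfaceNormalError(ValueError):
    """Raised when a surface normal cannot be estimated at a point."""


def surface_normal(
    scalp_mask: np.ndarray,
    affine: np.ndarray,
    point,
    sigma_mm: float = 2.0,
    *,
    _smoothed_sdf: np.ndarray | None = None,
    max_surface_distance_mm: float | None = None,
) -> np.ndarray:
    """Outward unit normal of a mask surface at a world point.

    Estimated as the normalized gradient of a Gaussian-smoothed
    (default σ = 2 mm) signed distance field of the mask, which
    stabilizes the voxel staircase. The gradient of the signed distance
    (negative inside, positive outside) points away from the interior.

    The point must lie within one voxel of the surface (configurable via
    ``max_surface_distance_mm``); elsewhere the normal is meaningless.
    """
    point = np.asarray(point, dtype=float)
    spacing = _voxel_spacing(affine)
    sdf = signed_distance_field(scalp_mask, affine)
    tol = max_surface_distance_mm if max_surface_distance_mm is not None else float(spacing.max())
    d_here = float(interpolate_volume(sdf, affine, point)[0])
    if abs(d_here) > tol:
        raise SurfaceNormalError(
            f"point {point.tolist()} is {d_here:.2f} mm from the surface "
            f"(tolerance {tol:.2f} mm)"
        )
    if _smoothed_sdf is None:
        _smoothed_sdf = smooth_sdf(sdf, affine, sigma_mm)
    return _normal_from_smoothed(_smoothed_sdf, affine, point)


def smooth_sdf(sdf: np.ndarray, affine: np.ndarray, sigma_mm: float = 2.0) -> np.ndarray:
    """Gaussian-smooth a signed distance volume with σ given in mm."""
    spacing = _voxel_spacing(affine)
    return ndimage.gaussian_filter(sdf, sigma=sigma_mm / spacing)


def _normal_from_smoothed(smoothed: np.ndarray, affine: np.ndarray, point: np.ndarray) -> np.ndarray:
    # central differences in world space, 1 mm step
    h = 1.0
    offsets = np.array(
        [[h, 0, 0], [-h, 0, 0], [0, h, 0], [0, -h, 0], [0, 0, h], [0, 0, -h]], float
    )
    vals = interpolate_volume(smoothed, affine, point[None, :] + offsets)
    grad = np.array(
        [vals[0] - vals[1], vals[2] - vals[3], vals[4] - vals[5]]
    ) / (2 * h)
    norm = np.linalg.norm(grad)
    if norm < 1e-12:
        raise SurfaceNormalError(f"zero gradient at {point.tolist()}; cannot orient normal")
    return grad / norm


def angle_from_orthogonal(direction, normal) -> float:
    """Angle in degrees between a trajectory and the surface normal.

    0° means drilling exactly along the normal (orthogonal to the
    surface, the preferred drilling direction); 90° means drilling
    parallel to the surface. Sign of either vector is irrelevant.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    dn = np.linalg.norm(d)
    nn = np.linalg.norm(n)
    if dn < 1e-12 or nn < 1e-12:
        raise ValueError("zero-length vector has no drilling angle")
    c = abs(float(np.dot(d, n))) / (dn * nn)
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def min_segment_distance(a, b) -> float:
    """Exact minimum distance between two 3D line segments, in mm.

    Closed-form quadratic minimization with clamping to the unit square
    of segment parameters (the standard robust algorithm); symmetric in
    its arguments.
    """
    p0, p1 = (np.asarray(p, dtype=float) for p in a)
    q0, q1 = (np.asarray(p, dtype=float) for p in b)
    u = p1 - p0
    v = q1 - q0
    if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
        raise ValueError("degenerate (zero-length) segment")
    w0 = p0 - q0
    A = float(u @ u)
    B = float(u @ v)
    C = float(v @ v)
    D = float(u @ w0)
    E = float(v @ w0)
    denom = A * C - B * B

    if denom > 1e-12 * A * C:
        s = (B * E - C * D) / denom
        t = (A * E - B * D) / denom
    else:  # (near-)parallel: pick any s, optimize t below
        s = 0.0
        t = E / C
    s = float(np.clip(s, 0.0, 1.0))
    # re-optimize t for the clamped s, then s for the clamped t
    t = (B * s + E) / C
    t = float(np.clip(t, 0.0, 1.0))
    s = (B * t - D) / A
    s = float(np.clip(s, 0.0, 1.0))
    return float(np.linalg.norm((p0 + s * u) - (q0 + t * v)))


def crosses_mask(nodes: np.ndarray, mask: np.ndarray, affine: np.ndarray) -> bool:
    """True iff any trajectory node falls inside the mask.

    A node counts as inside when the trilinearly interpolated mask
    value exceeds 0.5, i.e. the node is closer to foreground than to
    background. Used for the sulcal no-entry test.
    """
    vals = interpolate_volume(np.asarray(mask) > 0, affine, nodes)
    return bool((vals > 0.5).any())
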