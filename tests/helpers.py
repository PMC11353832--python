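"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: volumes come from voxel
counting on the generator's exact signed-distance fields, and circle fits
from a multi-resolution brute-force grid search on the geometric
least-squares objective.
"""

from __future__ import annotations

import numpy as np


def voxel_volume(sdf, lo, hi, resolution: float) -> float:
    """Volume of {sdf < 0} by counting voxel centers on a regular grid."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    axes = [np.arange(lo[i] + resolution / 2, hi[i], resolution) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return float((sdf(grid) < 0).sum()) * resolution**3


def halfspace_sdf(sdf, plane_point, plane_normal, side: float):
    """Intersect an SDF with the halfspace on ``side`` (+1/-1) of a plane."""
    p0 = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)

    def clipped(p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return np.maximum(sdf(p), -side * ((p - p0) @ n))

    return clipped


def grid_circle_fit(points_2d: np.ndarray, span: float | None = None, levels: int = 45):
    """Brute-force geometric least-squares circle fit in 2-D.

    Multi-resolution grid search over the center; for a fixed center the
    optimal radius is the mean point distance in the geometric LS objective
    sum((|p-c|-r)^2).  Refines 10x10 grids around the best cell down to
    ~1e-9 of the initial span, independent of any Gauss-Newton machinery.
    """
    pts = np.asarray(points_2d, dtype=float)
    center = pts.mean(axis=0)
    # the center of a short arc sits well away from the point centroid, so
    # the first grid must span the whole data extent
    half = span if span is not None else 1.5 * float(np.ptp(pts, axis=0).max())

    def cost_and_radius(cs):
        d = np.linalg.norm(pts[None, :, :] - cs[:, None, :], axis=2)
        r = d.mean(axis=1)
        cost = ((d - r[:, None]) ** 2).sum(axis=1)
        return cost, r

    best_r = None
    for _ in range(levels):
        xs = np.linspace(center[0] - half, center[0] + half, 11)
        ys = np.linspace(center[1] - half, center[1] + half, 11)
        cs = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
        cost, r = cost_and_radius(cs)
        k = int(np.argmin(cost))
        center = cs[k]
        best_r = r[k]
        half *= 0.3  # next grid comfortably covers the best cell
    return center, float(best_r)


def fitted_axes_and_frame(mesh, landmarks):
    """Shorthand for the full per-bone fit used in many tests."""
    from handlink.axes import joint_axis_from_mesh

    return joint_axis_from_mesh(mesh, landmarks)


def angle_between(u, v) -> float:
    """Unsigned angle in degrees between two directions (sign ignored)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
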