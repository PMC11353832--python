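"""Core 3-D geometry for bone meshes.

All coordinates are millimetres in a right-handed frame; all angles are
degrees.  Triangle meshes are :class:`trimesh.Trimesh` objects throughout the
package.  This module provides the geometric substrate used everywhere else:

* STL input/output with exact-coordinate vertex welding,
* rigid transforms and rotations about arbitrary axes,
* the principal (long) inertial axis of a solid bone,
* cutting a watertight mesh with a plane into two capped, watertight
  fragments (the virtual osteotomy primitive),
* signed angles between vectors projected onto a plane (the transverse-plane
  rotation measurement primitive),
* exact mesh-mesh intersection testing (the scissoring check primitive).

Capping of cut faces and the exact triangle-pair intersection test are
implemented here directly (ear clipping and segment-triangle tests under an
AABB/KD-tree broad phase).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path as _FsPath

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _Rot

from .errors import (
    AmbiguousAxisError,
    EmptyFragmentError,
    MeshFormatError,
    UndefinedProjectionError,
    UnsupportedMeshError,
    ValidationError,
)

__all__ = [
    "RigidTransform",
    "Plane",
    "Axis",
    "IntersectionReport",
    "load_mesh",
    "save_mesh",
    "principal_inertia_axis",
    "rotation_about_axis",
    "plane_mesh_cut",
    "signed_projected_angle",
    "meshes_intersect",
    "transform_mesh",
]

_ORTHO_TOL = 1e-9


def _unit(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise ValidationError(f"{name} has zero or non-finite norm")
    return v / n


# ---------------------------------------------------------------------------
# primitive types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation in SO(3), mm translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValidationError("rotation matrix is not orthonormal to 1e-9")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation matrix has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies *other* first: (self∘other)(p)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        object.__setattr__(self, "normal", _unit(self.normal, "plane normal"))

    def signed_distance(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.point) @ self.normal

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass(frozen=True)
class Axis:
    """Infinite line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        object.__setattr__(self, "direction", _unit(self.direction, "axis direction"))

    def transformed(self, T: RigidTransform) -> "Axis":
        return Axis(T.apply(self.point), T.apply_vector(self.direction))

    def distance_to_point(self, p) -> float:
        d = np.asarray(p, dtype=float) - self.point
        return float(np.linalg.norm(d - (d @ self.direction) * self.direction))


@dataclass(frozen=True)
class IntersectionReport:
    """Result of an exact mesh-mesh intersection test."""

    intersects: bool
    pair_count: int
    witness: tuple[int, int] | None = None

    def __post_init__(self):
        if self.intersects != (self.pair_count > 0):
            raise ValidationError("intersects flag inconsistent with pair_count")


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------


def load_mesh(path, weld_tol: float = 0.0) -> trimesh.Trimesh:
    """Load a binary or ASCII STL file as a welded triangle mesh.

    Vertices are merged on exact coordinate match by default; ``weld_tol``
    (mm) rounds coordinates to that tolerance first, for noisy exports.
    """
    path = _FsPath(path)
    if not path.is_file():
        raise ValidationError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # truncated/garbled file
        size = path.stat().st_size
        offset = 0
        if size >= 84:
            # binary STL promises 84 + 50*n bytes; report where it fell short
            with open(path, "rb") as fh:
                fh.seek(80)
                n = struct.unpack("<I", fh.read(4))[0]
            offset = min(size, 84 + 50 * n)
        raise MeshFormatError(
            f"cannot parse STL {path} (file size {size} bytes, "
            f"error near byte offset {offset}): {exc}"
        ) from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise MeshFormatError(f"no geometry in {path} (byte offset 0)")
        mesh = trimesh.util.concatenate(geoms)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if weld_tol > 0:
        verts = np.round(verts / weld_tol) * weld_tol
    return _weld(verts, faces)


def _weld(verts: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Merge exactly-equal vertices and drop degenerate faces."""
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = inverse[faces]
    keep = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    mesh = trimesh.Trimesh(uniq, faces[keep], process=False)
    # drop zero-area slivers that survive index dedup
    areas = mesh.area_faces
    if (areas <= 0).any():
        mesh.update_faces(areas > 0)
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path, format: str = "binary") -> None:
    """Write an STL file (``binary`` or ``ascii``).

    Output is deterministic: identical meshes produce byte-identical files
    (fixed header, no timestamps).
    """
    if len(mesh.faces) == 0:
        raise ValidationError("refusing to save an empty mesh")
    if format not in ("binary", "ascii"):
        raise ValidationError(f"unknown STL format {format!r}")
    tri = np.asarray(mesh.triangles, dtype=np.float64)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    normals = normals / lens[:, None]
    path = _FsPath(path)
    try:
        if format == "binary":
            header = b"handlink binary STL".ljust(80, b"\0")
            n = len(tri)
            rec = np.zeros(
                n, dtype=[("n", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
            )
            rec["n"] = normals.astype("<f4")
            rec["v"] = tri.astype("<f4")
            with open(path, "wb") as fh:
                fh.write(header)
                fh.write(struct.pack("<I", n))
                fh.write(rec.tobytes())
        else:
            lines = ["solid handlink"]
            for nrm, t in zip(normals, tri):
                lines.append(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}")
                lines.append("    outer loop")
                for v in t:
                    lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
                lines.append("    endloop")
                lines.append("  endfacet")
            lines.append("endsolid handlink\n")
            path.write_text("\n".join(lines))
    except OSError as exc:
        raise ValidationError(f"cannot write mesh to {path}: {exc}") from exc


def transform_mesh(mesh: trimesh.Trimesh, T: RigidTransform) -> trimesh.Trimesh:
    """Return a rigidly transformed copy of *mesh*."""
    out = trimesh.Trimesh(T.apply(mesh.vertices), mesh.faces.copy(), process=False)
    return out


# ---------------------------------------------------------------------------
# inertial axis
# ---------------------------------------------------------------------------


def principal_inertia_axis(
    mesh: trimesh.Trimesh, distal_hint=None
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit direction of the long inertial axis of the bone.

    The inertia tensor of the uniform-density solid is integrated over the
    watertight surface (divergence theorem, via trimesh's mass properties);
    the long axis is the eigenvector with the smallest moment.  For a
    non-watertight mesh an area-weighted surface approximation is used and a
    warning emitted.

    The sign is chosen so the direction points from the centroid toward
    ``distal_hint`` (a point, e.g. the bone head) when given, otherwise
    toward the end with the larger extent along the axis.
    """
    if mesh.is_watertight and mesh.volume > 0:
        centroid = np.asarray(mesh.center_mass, dtype=float)
        inertia = np.asarray(mesh.moment_inertia, dtype=float)
    else:
        warnings.warn(
            "mesh is not watertight; using area-weighted surface moments "
            "for the inertial axis",
            stacklevel=2,
        )
        tri = mesh.triangles
        areas = mesh.area_faces
        cent = tri.mean(axis=1)
        w = areas / areas.sum()
        centroid = (w[:, None] * cent).sum(axis=0)
        d = cent - centroid
        cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
        inertia = np.trace(cov) * np.eye(3) - cov
    evals, evecs = np.linalg.eigh(inertia)
    scale = max(abs(evals[1]), 1e-30)
    if (evals[1] - evals[0]) / scale < 0.01:
        raise AmbiguousAxisError(
            "the two smallest inertia moments differ by <1%: no unique long axis "
            f"(moments {evals.tolist()})"
        )
    direction = evecs[:, 0]
    if distal_hint is not None:
        if (np.asarray(distal_hint, dtype=float) - centroid) @ direction < 0:
            direction = -direction
    else:
        s = np.asarray(mesh.vertices) @ direction
        c = centroid @ direction
        if (s.max() - c) < (c - s.min()):
            direction = -direction
        elif np.isclose(s.max() - c, c - s.min()):
            # symmetric: deterministic tie-break on the largest component
            k = int(np.argmax(np.abs(direction)))
            if direction[k] < 0:
                direction = -direction
    return centroid, direction / np.linalg.norm(direction)


def rotation_about_axis(axis: Axis, angle_deg: float) -> RigidTransform:
    """Right-handed rotation by ``angle_deg`` about the line *axis*.

    Points on the axis are fixed; all distances are preserved.
    """
    R = _Rot.from_rotvec(np.radians(angle_deg) * axis.direction).as_matrix()
    t = axis.point - R @ axis.point
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# plane cutting with capped fragments
# ---------------------------------------------------------------------------


def plane_mesh_cut(
    mesh: trimesh.Trimesh, plane: Plane
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Cut a watertight mesh with a plane into two capped watertight fragments.

    Returns ``(positive_fragment, negative_fragment)`` by the sign of the
    plane's normal.  Each cut loop is capped with an ear-clipped planar
    polygon; fragment volumes sum to the parent volume (exact linear
    interpolation at the plane).
    """
    if not mesh.is_watertight:
        raise UnsupportedMeshError("plane_mesh_cut requires a watertight mesh")
    d = plane.signed_distance(mesh.vertices)
    if (d >= 0).all() or (d <= 0).all():
        raise EmptyFragmentError("cut plane does not intersect the mesh")
    pos = _slice_and_cap(mesh, plane)
    neg = _slice_and_cap(mesh, plane.flipped())
    return pos, neg


def _slice_and_cap(mesh: trimesh.Trimesh, plane: Plane) -> trimesh.Trimesh:
    """Keep the side of *mesh* on the positive side of *plane*, capped."""
    open_part = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.point, cap=False
    )
    # the slicer emits per-face copies of the new cut vertices: weld them so
    # the cut boundary forms closed loops (trimesh merges within tol.merge)
    open_part = trimesh.Trimesh(
        np.asarray(open_part.vertices), np.asarray(open_part.faces), process=False
    )
    open_part.merge_vertices()
    open_part.update_faces(open_part.area_faces > 0)
    verts = np.asarray(open_part.vertices, dtype=float)
    faces = list(np.asarray(open_part.faces, dtype=np.int64))
    loops = _boundary_loops(open_part)
    if not loops:
        raise EmptyFragmentError("slicing produced no cut boundary")
    # in-plane 2D basis for ear clipping
    n = plane.normal
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    for loop in loops:
        # the cap must traverse each boundary edge opposite to the surface,
        # so triangulate the reversed loop
        ring = loop[::-1]
        pts2 = np.column_stack([verts[ring] @ u, verts[ring] @ v])
        for tri in _ear_clip(pts2):
            faces.append([ring[tri[0]], ring[tri[1]], ring[tri[2]]])
    out = trimesh.Trimesh(verts, np.asarray(faces, dtype=np.int64), process=False)
    out.remove_unreferenced_vertices()
    return out


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Closed loops of directed boundary edges (edges used by one face only),
    in the surface's winding order."""
    edges = mesh.edges  # directed, 3 per face
    srt = np.sort(edges, axis=1)
    _, inv, cnt = np.unique(srt, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[cnt[inv] == 1]
    nxt = {}
    for a, b in boundary:
        a, b = int(a), int(b)
        if a in nxt:
            raise EmptyFragmentError("non-manifold cut boundary")
        nxt[a] = b
    loops = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            if cur not in nxt:
                raise EmptyFragmentError("open boundary is not a closed loop")
            cur = nxt[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _ear_clip(pts: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple polygon given as an (n,2) array of 2D points.

    Returns index triples in the polygon's own orientation.  O(n^2); the cut
    cross-sections of bones are small simple polygons, so this is plenty.
    """
    n = len(pts)
    if n < 3:
        return []
    idx = list(range(n))
    # polygon orientation sign from the shoelace formula
    x, y = pts[:, 0], pts[:, 1]
    area2 = float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    sign = 1.0 if area2 >= 0 else -1.0
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3 and guard < 4 * n * n:
        guard += 1
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if sign * cross <= 1e-14 * max(1.0, abs(area2)):
                continue  # reflex or degenerate corner
            if _any_point_strictly_in_tri(
                pts, [j for j in idx if j not in (i0, i1, i2)], a, b, c, sign
            ):
                continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            # numerically stuck (collinear run): clip the least-reflex corner
            best, best_cross = 0, -np.inf
            for k in range(m):
                i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
                a, b, c = pts[i0], pts[i1], pts[i2]
                cross = sign * (
                    (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                )
                if cross > best_cross:
                    best, best_cross = k, cross
            m = len(idx)
            tris.append((idx[(best - 1) % m], idx[best], idx[(best + 1) % m]))
            idx.pop(best)
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    return tris


def _any_point_strictly_in_tri(pts, others, a, b, c, sign) -> bool:
    if not others:
        return False
    p = pts[others]
    tol = 1e-12
    d1 = (b[0] - a[0]) * (p[:, 1] - a[1]) - (b[1] - a[1]) * (p[:, 0] - a[0])
    d2 = (c[0] - b[0]) * (p[:, 1] - b[1]) - (c[1] - b[1]) * (p[:, 0] - b[0])
    d3 = (a[0] - c[0]) * (p[:, 1] - c[1]) - (a[1] - c[1]) * (p[:, 0] - c[0])
    return bool(((sign * d1 > tol) & (sign * d2 > tol) & (sign * d3 > tol)).any())


# ---------------------------------------------------------------------------
# projected angles
# ---------------------------------------------------------------------------


def signed_projected_angle(v1, v2, plane_normal) -> float:
    """Signed angle (degrees, right-handed about ``plane_normal``) carrying
    the projection of ``v1`` onto the projection of ``v2``.

    Range ``(-180, 180]``.  Raises if either vector is parallel to the
    normal (projection norm <= 1e-6).
    """
    n = _unit(plane_normal, "plane normal")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    p1 = v1 - (v1 @ n) * n
    p2 = v2 - (v2 @ n) * n
    if np.linalg.norm(p1) <= 1e-6 or np.linalg.norm(p2) <= 1e-6:
        raise UndefinedProjectionError(
            "vector (near-)parallel to the plane normal: projection undefined"
        )
    ang = np.degrees(np.arctan2(np.cross(p1, p2) @ n, p1 @ p2))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# ---------------------------------------------------------------------------
# exact mesh-mesh intersection
# ---------------------------------------------------------------------------


def meshes_intersect(
    mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh
) -> IntersectionReport:
    """Exact triangle-pair intersection test between two meshes.

    Broad phase: axis-aligned bounding boxes plus a KD-tree over triangle
    centroids in the overlap region.  Narrow phase: a triangle pair
    intersects iff an edge of one crosses the face of the other
    (Moller-Trumbore segment-triangle tests, run both ways), which makes the
    result symmetric in the two meshes.  ``pair_count`` is deterministic.
    """
    ta = np.asarray(mesh_a.triangles, dtype=float)
    tb = np.asarray(mesh_b.triangles, dtype=float)
    if len(ta) == 0 or len(tb) == 0:
        return IntersectionReport(False, 0)
    lo = np.maximum(ta.min(axis=(0, 1)), tb.min(axis=(0, 1))) - 1e-9
    hi = np.minimum(ta.max(axis=(0, 1)), tb.max(axis=(0, 1))) + 1e-9
    if (lo > hi).any():
        return IntersectionReport(False, 0)

    def _in_region(tris):
        mins = tris.min(axis=1)
        maxs = tris.max(axis=1)
        mask = ((maxs >= lo) & (mins <= hi)).all(axis=1)
        return np.nonzero(mask)[0], mins[mask], maxs[mask]

    ia, amin, amax = _in_region(ta)
    ib, bmin, bmax = _in_region(tb)
    if len(ia) == 0 or len(ib) == 0:
        return IntersectionReport(False, 0)
    ca = ta[ia].mean(axis=1)
    cb = tb[ib].mean(axis=1)
    ra = np.linalg.norm(ta[ia] - ca[:, None, :], axis=2).max()
    rb = np.linalg.norm(tb[ib] - cb[:, None, :], axis=2).max()
    tree = cKDTree(cb)
    neighbours = tree.query_ball_point(ca, r=ra + rb + 1e-9)
    pairs = [(i, j) for i, js in enumerate(neighbours) for j in js]
    if not pairs:
        return IntersectionReport(False, 0)
    pa = np.array([p[0] for p in pairs])
    pb = np.array([p[1] for p in pairs])
    # exact AABB rejection per pair
    keep = ((amax[pa] >= bmin[pb]) & (amin[pa] <= bmax[pb])).all(axis=1)
    pa, pb = pa[keep], pb[keep]
    if len(pa) == 0:
        return IntersectionReport(False, 0)
    A = ta[ia[pa]]
    B = tb[ib[pb]]
    hit = np.zeros(len(pa), dtype=bool)
    for e0, e1 in ((0, 1), (1, 2), (2, 0)):
        hit |= _segment_hits_triangle(A[:, e0], A[:, e1], B)
        hit |= _segment_hits_triangle(B[:, e0], B[:, e1], A)
    count = int(hit.sum())
    witness = None
    if count:
        order = np.lexsort((ib[pb[hit]], ia[pa[hit]]))
        k = np.nonzero(hit)[0][order[0]]
        witness = (int(ia[pa[k]]), int(ib[pb[k]]))
    return IntersectionReport(count > 0, count, witness)


def _segment_hits_triangle(p0, p1, tri, eps: float = 1e-12) -> np.ndarray:
    """Vectorized Moller-Trumbore: does segment p0->p1 cross triangle tri?"""
    d = p1 - p0
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > eps
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = p0 - tri[:, 0]
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * np.einsum("ij,ij->i", d, q)
    t = f * np.einsum("ij,ij->i", e2, q)
    return (
        ok
        & (u >= -eps)
        & (v >= -eps)
        & (u + v <= 1 + eps)
        & (t >= -eps)
        & (t <= 1 + eps)
    )
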