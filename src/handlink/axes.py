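"""Joint rotation-axis construction from condylar circle fits.

The flexion axis of an MP/PIP/DIP joint is approximated by the line through
the centers of two circles fitted to the radial and ulnar condyles of the
proximal bone's head, each drawn in a sagittal slab.  Together with the
bone's long inertial axis this defines the bone-specific anatomical frame:

* ``Z`` - long inertial axis, pointing proximal to distal,
* ``Y`` - the predicted rotation axis, orthogonalized against Z
  (radial to ulnar); the discarded out-of-transverse-plane tilt is kept as
  ``y_obliquity_deg`` rather than silently dropped,
* ``X = Y x Z`` - dorso-palmar, completing a right-handed frame.

The transverse, sagittal and coronal planes of the bone are the planes
perpendicular to Z, Y and X respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import (
    DegenerateFitError,
    InvalidAnatomyError,
    SelectionError,
    UnstableAxisError,
    ValidationError,
)
from .geometry import Axis, RigidTransform, principal_inertia_axis

__all__ = [
    "Circle3D",
    "CondyleSelection",
    "BoneFrame",
    "fit_circle_3d",
    "extract_condyle_points",
    "predicted_rotation_axis",
    "build_bone_frame",
    "provisional_frame",
    "joint_axis_from_mesh",
]


@dataclass(frozen=True)
class Circle3D:
    """Circle in 3-D: center (mm), radius (mm), unit plane normal."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        n = np.asarray(self.normal, dtype=float).reshape(3)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))
        if self.radius <= 0:
            raise ValidationError("circle radius must be positive")


@dataclass(frozen=True)
class CondyleSelection:
    """Surface points selected on the radial and ulnar condyles."""

    radial_points: np.ndarray
    ulnar_points: np.ndarray
    source: str  # "manual-landmarks" | "automatic-slab"


@dataclass(frozen=True)
class BoneFrame:
    """Right-handed orthonormal anatomical frame of one bone."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    y_obliquity_deg: float = 0.0

    def __post_init__(self):
        for name in ("origin", "X", "Y", "Z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        R = np.column_stack([self.X, self.Y, self.Z])
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValidationError("bone frame axes are not orthonormal to 1e-9")
        if np.linalg.det(R) < 0:
            raise ValidationError("bone frame is left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-bone rotation (columns are the X/Y/Z axes)."""
        return np.column_stack([self.X, self.Y, self.Z])

    def transformed(self, T: RigidTransform) -> "BoneFrame":
        return BoneFrame(
            T.apply(self.origin),
            T.apply_vector(self.X),
            T.apply_vector(self.Y),
            T.apply_vector(self.Z),
            self.y_obliquity_deg,
        )


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------


def fit_circle_3d(points, max_iter: int = 100, tol: float = 1e-10) -> Circle3D:
    """Total-least-squares plane + geometric least-squares circle fit.

    The plane is the smallest-singular-vector plane of the centered points;
    the in-plane circle is initialized algebraically (Kasa) and refined by
    Gauss-Newton on the radial residuals ``|p - c| - r``.  Geometric
    refinement matters because condylar arcs cover less than a half circle,
    where algebraic fits are biased toward small radii.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegenerateFitError("need at least 3 points to fit a circle")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise DegenerateFitError("points are collinear: circle fit is degenerate")
    normal = vt[2]
    u, v = vt[0], vt[1]
    x = q @ u
    y = q @ v
    # Kasa algebraic fit: x^2+y^2 = 2 a x + 2 b y + c
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x**2 + y**2
    (a, b, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    r = float(np.sqrt(max(c + a**2 + b**2, 1e-30)))
    p = np.array([a, b, r])
    for _ in range(max_iter):
        dx = x - p[0]
        dy = y - p[1]
        dist = np.hypot(dx, dy)
        dist = np.where(dist < 1e-15, 1e-15, dist)
        res = dist - p[2]
        J = np.column_stack([-dx / dist, -dy / dist, -np.ones_like(dist)])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        p = p + step
        if np.linalg.norm(step) < tol:
            break
    dx = x - p[0]
    dy = y - p[1]
    res = np.hypot(dx, dy) - p[2]
    rms = float(np.sqrt(np.mean(res**2)))
    if p[2] <= 0:
        raise DegenerateFitError("circle fit collapsed to non-positive radius")
    center = centroid + p[0] * u + p[1] * v
    return Circle3D(center, float(p[2]), normal, rms)


# ---------------------------------------------------------------------------
# condyle point selection
# ---------------------------------------------------------------------------


def provisional_frame(mesh: trimesh.Trimesh, distal_hint=None):
    """Provisional (centroid, long axis, lateral axis) from the inertia tensor.

    The lateral axis is the principal direction with the intermediate moment
    (the condylar spread makes the radio-ulnar direction stiffer than the
    dorso-palmar one), used only to seed automatic slab placement.
    """
    centroid, z = principal_inertia_axis(mesh, distal_hint=distal_hint)
    inertia = np.asarray(mesh.moment_inertia, dtype=float)
    evals, evecs = np.linalg.eigh(inertia)
    lateral = evecs[:, 1]
    lateral = lateral - (lateral @ z) * z
    lateral /= np.linalg.norm(lateral)
    return centroid, z, lateral


def extract_condyle_points(
    mesh: trimesh.Trimesh,
    frame_hint: Axis,
    landmarks: dict | None = None,
    *,
    slab_half_thickness: float = 0.75,
    head_fraction: float = 0.25,
    max_landmark_distance: float = 10.0,
    lateral_hint=None,
) -> CondyleSelection:
    """Select condylar surface points for the two circle fits.

    ``frame_hint`` is the provisional long axis (point at the centroid,
    direction pointing distal).  In *manual* mode ``landmarks`` holds
    ``radial_condyle`` and ``ulnar_condyle`` points (condyle centers); each
    slab of half-thickness ``slab_half_thickness`` (mm) lies about the
    sagittal plane through one landmark, normal to the landmark separation.
    Points are restricted to the distal ``head_fraction`` of the bone, to
    within ``max_landmark_distance`` of the landmark, and to the articular
    arc distal to the landmark plane.

    In *automatic* mode the two slabs sit at +-1/4 of the head width from
    the head midline along the lateral direction, and the arc is limited to
    within half the slab's dorso-palmar extent of the distal tip.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    z = frame_hint.direction
    s = verts @ z
    s_min, s_max = s.min(), s.max()
    head = s >= s_max - head_fraction * (s_max - s_min)

    if landmarks is not None:
        try:
            radial = np.asarray(landmarks["radial_condyle"], dtype=float).reshape(3)
            ulnar = np.asarray(landmarks["ulnar_condyle"], dtype=float).reshape(3)
        except (KeyError, TypeError) as exc:
            raise ValidationError(
                "landmarks must provide 'radial_condyle' and 'ulnar_condyle'"
            ) from exc
        ny = ulnar - radial
        nn = np.linalg.norm(ny)
        if nn < 1e-9:
            raise ValidationError("condyle landmarks coincide")
        ny = ny / nn
        sets = []
        for lm in (radial, ulnar):
            off = verts - lm
            slab = np.abs(off @ ny) <= slab_half_thickness
            near = np.linalg.norm(off, axis=1) <= max_landmark_distance
            distal = off @ z >= 0.0
            pts = verts[head & slab & near & distal]
            if len(pts) < 3:
                raise SelectionError(
                    "fewer than 3 condyle points in slab; landmark may be off "
                    "the bone or the slab too thin (increase slab_half_thickness)"
                )
            sets.append(pts)
        return CondyleSelection(sets[0], sets[1], "manual-landmarks")

    # automatic slab placement
    if lateral_hint is None:
        _, _, lateral_hint = provisional_frame(mesh, distal_hint=frame_hint.point)
    ny = np.asarray(lateral_hint, dtype=float)
    ny = ny / np.linalg.norm(ny)
    hv = verts[head]
    w = hv @ ny
    lo, hi = np.percentile(w, [2, 98])
    mid = 0.5 * (lo + hi)
    width = hi - lo
    sets = []
    for side in (-1.0, 1.0):
        target = mid + side * width / 4.0
        slab = np.abs(hv @ ny - target) <= slab_half_thickness
        pts = hv[slab]
        if len(pts) < 3:
            raise SelectionError(
                "automatic slab selected fewer than 3 points; "
                "increase slab_half_thickness"
            )
        # keep the distal articular arc: within half the slab's dorso-palmar
        # extent (~ the condyle radius) of the slab's distal tip
        dp = np.cross(z, ny)
        dp /= np.linalg.norm(dp)
        depth = 0.5 * float(np.ptp(pts @ dp))
        sz = pts @ z
        pts = pts[sz >= sz.max() - max(depth, 1.0)]
        if len(pts) < 3:
            raise SelectionError("automatic distal-arc filter left fewer than 3 points")
        sets.append(pts)
    return CondyleSelection(sets[0], sets[1], "automatic-slab")


def predicted_rotation_axis(radial: Circle3D, ulnar: Circle3D) -> Axis:
    """Line through the two fitted circle centers (radial -> ulnar)."""
    delta = ulnar.center - radial.center
    sep = np.linalg.norm(delta)
    if sep <= 1.0:
        raise UnstableAxisError(
            f"condylar circle centers only {sep:.3f} mm apart: axis unstable"
        )
    return Axis(0.5 * (radial.center + ulnar.center), delta / sep)


def build_bone_frame(
    mesh: trimesh.Trimesh, rotation_axis: Axis, distal_hint=None
) -> BoneFrame:
    """Assemble the anatomical frame from the mesh and its joint axis.

    Z is the long inertial axis (signed toward the joint axis, i.e. distal,
    unless ``distal_hint`` overrides); Y is the rotation-axis direction with
    its Z-component removed; X completes the right-handed frame.
    """
    hint = distal_hint if distal_hint is not None else rotation_axis.point
    centroid, z = principal_inertia_axis(mesh, distal_hint=hint)
    raw = rotation_axis.direction
    cos_to_z = abs(float(raw @ z))
    angle_to_z = np.degrees(np.arccos(np.clip(cos_to_z, -1.0, 1.0)))
    if angle_to_z <= 10.0:
        raise InvalidAnatomyError(
            f"rotation axis within {angle_to_z:.1f} deg of the long axis"
        )
    y = raw - (raw @ z) * z
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    obliquity = np.degrees(np.arcsin(np.clip(cos_to_z, 0.0, 1.0)))
    return BoneFrame(centroid, x, y, z, float(obliquity))


def joint_axis_from_mesh(
    mesh: trimesh.Trimesh,
    landmarks: dict | None = None,
    *,
    slab_half_thickness: float = 0.75,
    head_fraction: float = 0.25,
    distal_hint=None,
) -> tuple[Axis, BoneFrame, tuple[Circle3D, Circle3D]]:
    """Full per-bone pipeline: provisional axis, condylar circles, joint
    axis, anatomical frame.  Convenience wrapper used by the CLI and the
    re-derivation step after a wedge reduction."""
    if distal_hint is None and landmarks is not None:
        distal_hint = 0.5 * (
            np.asarray(landmarks["radial_condyle"], float)
            + np.asarray(landmarks["ulnar_condyle"], float)
        )
    centroid, z, lateral = provisional_frame(mesh, distal_hint=distal_hint)
    hint = Axis(distal_hint if distal_hint is not None else centroid + z, z)
    sel = extract_condyle_points(
        mesh,
        hint,
        landmarks,
        slab_half_thickness=slab_half_thickness,
        head_fraction=head_fraction,
        lateral_hint=lateral,
    )
    radial = fit_circle_3d(sel.radial_points)
    ulnar = fit_circle_3d(sel.ulnar_points)
    axis = predicted_rotation_axis(radial, ulnar)
    frame = build_bone_frame(mesh, axis, distal_hint=axis.point)
    return axis, frame, (radial, ulnar)
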