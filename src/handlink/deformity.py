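"""Transverse-plane deformity measurement, osteotomy planning and virtual
reduction.

The rotational deformity of a malunited bone is the signed angle between the
predicted rotation axes of its proximal and distal joints after projecting
both onto the bone's transverse plane (normal to its long inertial axis Z).
Positive angles are right-handed about +Z viewed from distal; supination vs
pronation then follows from the digit and side.

Osteotomies are planned as a transverse cut (default at the proximal 25% of
bone length, emulating the preference for proximal-metaphysis cuts which
give a larger union surface), optionally with an open- or closed-wedge
component in the coronal or sagittal plane.  The virtual reduction rotates
the distal fragment and every bone distal to it about the plan's rotation
axis; after a wedge correction the predicted rotation axis must be derived
again, because the reduction changes it.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .axes import BoneFrame, joint_axis_from_mesh
from .errors import PlanningError, ValidationError
from .geometry import (
    Axis,
    Plane,
    RigidTransform,
    plane_mesh_cut,
    rotation_about_axis,
    signed_projected_angle,
    transform_mesh,
)
from .linkage import Bone, HandModel, KinematicChain

__all__ = [
    "DeformityMeasurement",
    "OsteotomyPlan",
    "measure_transverse_rotation",
    "plan_transverse_osteotomy",
    "plan_wedge_osteotomy",
    "simulate_reduction",
    "rederive_after_reduction",
]


@dataclass(frozen=True)
class DeformityMeasurement:
    """Signed transverse-plane rotation between the projected joint axes."""

    angle_deg: float
    transverse_normal: np.ndarray
    proximal_axis_projected: np.ndarray
    distal_axis_projected: np.ndarray

    def __post_init__(self):
        for name in ("transverse_normal", "proximal_axis_projected", "distal_axis_projected"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v / np.linalg.norm(v))
        n = self.transverse_normal
        for v in (self.proximal_axis_projected, self.distal_axis_projected):
            if abs(v @ n) > 1e-9:
                raise ValidationError("projected axis does not lie in the transverse plane")
        if not -180.0 < self.angle_deg <= 180.0:
            raise ValidationError("angle outside (-180, 180]")

    @property
    def direction_label(self) -> str:
        """Pronation/supination label by the right-hand rule about +Z
        (distal); for a right hand a positive angle supinates the fragment."""
        if abs(self.angle_deg) < 0.5:
            return "neutral"
        return "supination" if self.angle_deg > 0 else "pronation"


@dataclass(frozen=True)
class OsteotomyPlan:
    """A planned cut plus the rotation axis used for the virtual reduction."""

    cut_plane: Plane
    kind: str  # "transverse-rotation" | "open-wedge" | "closed-wedge"
    rotation_axis: Axis
    wedge_plane: str = "none"  # "coronal" | "sagittal" | "none"
    wedge_angle_deg: float = 0.0
    bone: str | None = None

    def __post_init__(self):
        if self.kind not in ("transverse-rotation", "open-wedge", "closed-wedge"):
            raise ValidationError(f"unknown osteotomy kind {self.kind!r}")
        if self.kind == "transverse-rotation":
            if abs(self.cut_plane.normal @ self.rotation_axis.direction) < 1 - 1e-6:
                raise ValidationError(
                    "transverse-rotation plan needs cut normal parallel to bone Z"
                )
        elif self.wedge_angle_deg < 0:
            raise ValidationError(
                "wedge plans need wedge_angle_deg >= 0 (zero is degenerate "
                "and only produced with an explicit warning)"
            )
        if self.wedge_plane not in ("coronal", "sagittal", "none"):
            raise ValidationError(f"unknown wedge plane {self.wedge_plane!r}")


def measure_transverse_rotation(
    proximal_joint_axis: Axis, distal_joint_axis: Axis, bone_frame: BoneFrame
) -> DeformityMeasurement:
    """Project both joint axes onto the malunited bone's transverse plane and
    return the signed angle carrying the proximal projection onto the distal
    one (right-handed about +Z)."""
    z = bone_frame.Z
    angle = signed_projected_angle(
        proximal_joint_axis.direction, distal_joint_axis.direction, z
    )

    def proj(v):
        p = v - (v @ z) * z
        return p / np.linalg.norm(p)

    return DeformityMeasurement(
        angle, z, proj(proximal_joint_axis.direction), proj(distal_joint_axis.direction)
    )


def _cut_plane_at_fraction(
    bone_frame: BoneFrame, mesh: trimesh.Trimesh, level_fraction: float
) -> tuple[Plane, np.ndarray]:
    """Transverse plane at ``level_fraction`` of bone length from the
    proximal end, and the centroid of the cut cross-section."""
    if not 0.0 < level_fraction < 1.0:
        raise PlanningError("level_fraction must be in (0, 1)")
    z = bone_frame.Z
    s = np.asarray(mesh.vertices) @ z
    s_cut = s.min() + level_fraction * (s.max() - s.min())
    origin = bone_frame.origin + (s_cut - bone_frame.origin @ z) * z
    section = mesh.section(plane_origin=origin, plane_normal=z)
    if section is None or len(section.vertices) == 0:
        raise PlanningError("osteotomy plane does not intersect the bone")
    centroid = np.asarray(section.vertices, dtype=float).mean(axis=0)
    centroid = centroid + (s_cut - centroid @ z) * z  # exactly in-plane
    return Plane(centroid, z), centroid


def plan_transverse_osteotomy(
    bone_frame: BoneFrame,
    mesh: trimesh.Trimesh,
    level_fraction: float = 0.25,
    bone: str | None = None,
) -> OsteotomyPlan:
    """Transverse derotation osteotomy: cut perpendicular to Z at the given
    fraction of length from the proximal end; the derotation axis is the
    bone's Z through the cut-face centroid."""
    plane, centroid = _cut_plane_at_fraction(bone_frame, mesh, level_fraction)
    return OsteotomyPlan(
        cut_plane=plane,
        kind="transverse-rotation",
        rotation_axis=Axis(centroid, bone_frame.Z),
        bone=bone,
    )


def plan_wedge_osteotomy(
    bone_frame: BoneFrame,
    mesh: trimesh.Trimesh,
    plane: str,
    angle_deg: float,
    kind: str = "closed",
    level_fraction: float = 0.25,
    hinge_offset: float = 1.0,
    bone: str | None = None,
) -> OsteotomyPlan:
    """Open- or closed-wedge osteotomy correcting an angular deformity.

    ``plane`` is the anatomical plane of the correction: a *coronal*
    (radial/ulnar) correction hinges about the bone's X axis, a *sagittal*
    (flexion/extension) correction about Y.  A positive ``angle_deg``
    rotates the distal fragment by ``-angle_deg`` about the hinge when the
    plan is executed (so it removes a deformity of ``+angle_deg``); pass a
    negative angle for the opposite direction.  The hinge sits on the cortex
    entry side, ``hinge_offset`` (0 = cut center, 1 = cortex) along the
    in-plane direction perpendicular to the hinge.  Open wedge: one
    transverse cut, fragment rotated leaving a gap.  Closed wedge: the
    transverse cut plus a second cut inclined by the wedge angle; the wedge
    is removed and the fragments apposed.
    """
    if kind not in ("open", "closed"):
        raise PlanningError(f"wedge kind must be 'open' or 'closed', got {kind!r}")
    if plane not in ("coronal", "sagittal"):
        raise PlanningError(f"wedge plane must be 'coronal' or 'sagittal', got {plane!r}")
    if not abs(angle_deg) < 45.0:
        raise PlanningError("wedge angle must be below 45 degrees")
    if angle_deg == 0.0:
        warnings.warn("wedge angle 0: degenerate plan (identity correction)")
    cut_plane, centroid = _cut_plane_at_fraction(bone_frame, mesh, level_fraction)
    hinge_dir = bone_frame.X if plane == "coronal" else bone_frame.Y
    if angle_deg < 0:
        hinge_dir = -hinge_dir
        angle_deg = -angle_deg
    # in-plane offset direction perpendicular to the hinge
    u = np.cross(bone_frame.Z, hinge_dir)
    u /= np.linalg.norm(u)
    s = np.asarray(mesh.vertices) @ u
    half_extent = 0.5 * (s.max() - s.min())
    hinge_point = centroid + hinge_offset * half_extent * u
    hinge_point = hinge_point + (
        (centroid - hinge_point) @ cut_plane.normal
    ) * cut_plane.normal
    return OsteotomyPlan(
        cut_plane=cut_plane,
        kind=f"{kind}-wedge",
        rotation_axis=Axis(hinge_point, hinge_dir),
        wedge_plane=plane,
        wedge_angle_deg=float(angle_deg),
        bone=bone,
    )


def _execute_on_mesh(
    mesh: trimesh.Trimesh, plan: OsteotomyPlan, rotation_deg: float
) -> tuple[trimesh.Trimesh, trimesh.Trimesh, trimesh.Trimesh, RigidTransform]:
    """Cut one bone and move its distal fragment.

    Returns (combined mesh, proximal fragment, moved distal fragment, the
    applied transform).  The combined mesh keeps the two closed fragments as
    separate components, which is exact for all downstream solid integrals.
    """
    distal, proximal = plane_mesh_cut(mesh, plan.cut_plane)  # +normal side = distal
    if plan.kind == "closed-wedge":
        # second cut inclined by the wedge angle about the hinge; the sliver
        # between the planes is discarded
        tilt = rotation_about_axis(plan.rotation_axis, -plan.wedge_angle_deg)
        second = Plane(
            plan.rotation_axis.point, tilt.apply_vector(plan.cut_plane.normal)
        )
        if (second.signed_distance(distal.vertices) > 0).any():
            distal, _wedge = plane_mesh_cut(distal, second)
    T = rotation_about_axis(plan.rotation_axis, rotation_deg)
    distal_moved = transform_mesh(distal, T)
    combined = trimesh.util.concatenate([proximal, distal_moved])
    return combined, proximal, distal_moved, T


def simulate_reduction(
    hand: HandModel,
    plan: OsteotomyPlan,
    derotation_deg: float | None = None,
    measurement: DeformityMeasurement | None = None,
) -> tuple[HandModel, RigidTransform]:
    """Execute an osteotomy plan on the named bone of a hand.

    The distal fragment *and every bone distal to it in the chain* (with
    their joint axes) receive the same rigid rotation about the plan's
    rotation axis.  For a transverse-rotation plan the angle defaults to the
    negated measured angle (pass ``measurement`` or ``derotation_deg``); for
    wedge plans it defaults to ``-wedge_angle_deg`` (the closing rotation).
    Returns the reduced hand and the applied transform.
    """
    if plan.bone is None:
        raise ValidationError("plan does not name the bone to osteotomize")
    if derotation_deg is None:
        if plan.kind == "transverse-rotation":
            if measurement is None:
                raise ValidationError(
                    "transverse plan needs derotation_deg or a measurement"
                )
            derotation_deg = -measurement.angle_deg
        else:
            derotation_deg = -plan.wedge_angle_deg
    chain, idx = hand.find_bone(plan.bone)
    target = chain.bones[idx]
    combined, proximal, distal_moved, T = _execute_on_mesh(
        target.mesh, plan, derotation_deg
    )
    new_target = Bone(
        target.name,
        combined,
        target.frame,  # stale by design: rederive_after_reduction refreshes it
        target.world_from_generated,
        fragments=(proximal, distal_moved),
    )
    new_bones = list(chain.bones)
    new_bones[idx] = new_target
    new_joints = list(chain.joints)
    # bones distal to the osteotomized one follow the fragment rigidly, and
    # so do the joint axes at and beyond the malunited bone's head
    for k in range(idx, len(new_joints)):
        j = new_joints[k]
        new_joints[k] = Joint_copy = copy.copy(j)
        Joint_copy.axis = j.axis.transformed(T)
    for k in range(idx + 1, len(new_bones)):
        new_bones[k] = new_bones[k].transformed(T)
    new_chain = KinematicChain(chain.digit, new_bones, new_joints)
    chains = dict(hand.chains)
    chains[chain.digit] = new_chain
    return HandModel(chains, hand.scaphoid_tubercle, hand.laterality), T


def rederive_after_reduction(
    hand: HandModel, bone_name: str, landmarks: dict | None = None, **kwargs
) -> tuple[Axis, BoneFrame]:
    """Re-run the full axis pipeline on the post-reduction bone mesh.

    Required after any wedge correction, because a coronal or sagittal
    reduction changes the predicted rotation axis; after a pure transverse
    derotation the long axis is unchanged (it is the rotation axis).
    """
    chain, idx = hand.find_bone(bone_name)
    mesh = chain.bones[idx].mesh
    axis, frame, _ = joint_axis_from_mesh(mesh, landmarks, **kwargs)
    return axis, frame
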