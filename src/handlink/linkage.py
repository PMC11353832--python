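"""Rigid kinematic-chain simulation of finger flexion.

Each digit is an ordered chain metacarpal -> distal phalanx.  Every joint is
a fixed-axis revolute joint about the predicted rotation axis housed in the
proximal bone's head - deliberately ignoring the small translational and
axis-wandering components of real finger joints (a simplification of about
two degrees, accepted for osteotomy planning).  Posing composes rotations
proximal to distal; each joint's axis is itself carried along by the more
proximal joints before its own rotation is applied.

The two clinical checks are implemented on the posed model:

* scissoring - exact mesh intersection between adjacent digits,
* scaphoid alignment - distance from the line of the posed distal
  phalanx's long inertial axis to the scaphoid tubercle landmark (flexed
  fingertips of a normal hand converge toward it; DIP extended).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import StructuralError, ValidationError
from .geometry import (
    Axis,
    IntersectionReport,
    RigidTransform,
    meshes_intersect,
    principal_inertia_axis,
    rotation_about_axis,
    transform_mesh,
)

__all__ = [
    "Joint",
    "Bone",
    "KinematicChain",
    "HandModel",
    "DEFAULT_JOINT_LIMITS",
    "build_chain",
    "pose_chain",
    "pose_hand",
    "detect_scissoring",
    "scaphoid_alignment",
]

DEFAULT_JOINT_LIMITS = {"MP": (0.0, 110.0), "PIP": (0.0, 100.0), "DIP": (-10.0, 80.0)}
_JOINT_NAMES = ["MP", "PIP", "DIP"]


@dataclass
class Bone:
    """One bone in a chain: mesh plus bookkeeping transforms.

    ``world_from_generated`` accumulates every rigid motion applied to the
    mesh since generation (placement, posing, reduction), which lets
    voxel-level oracles evaluate the generator's implicit model at any pose.
    """

    name: str
    mesh: trimesh.Trimesh
    frame: object | None = None
    world_from_generated: RigidTransform = field(default_factory=RigidTransform.identity)
    fragments: tuple[trimesh.Trimesh, trimesh.Trimesh] | None = None

    def transformed(self, T: RigidTransform) -> "Bone":
        frags = None
        if self.fragments is not None:
            frags = tuple(transform_mesh(f, T) for f in self.fragments)
        return Bone(
            self.name,
            transform_mesh(self.mesh, T),
            self.frame.transformed(T) if self.frame is not None else None,
            T @ self.world_from_generated,
            frags,
        )


@dataclass
class Joint:
    """Revolute joint between two adjacent bones of one chain."""

    name: str
    proximal_bone: str
    distal_bone: str
    axis: Axis
    flexion_deg: float = 0.0
    limits: tuple[float, float] | None = None

    def __post_init__(self):
        if self.limits is None:
            self.limits = DEFAULT_JOINT_LIMITS.get(self.name, (-180.0, 180.0))


@dataclass
class KinematicChain:
    """Ordered bones of one digit with the joints between them."""

    digit: str
    bones: list[Bone]
    joints: list[Joint]

    def __post_init__(self):
        if len(self.joints) != len(self.bones) - 1:
            raise StructuralError("a chain of n bones needs n-1 joints")
        for j, (p, d) in zip(self.joints, zip(self.bones, self.bones[1:])):
            if j.proximal_bone != p.name or j.distal_bone != d.name:
                raise StructuralError(
                    f"joint {j.name} does not connect adjacent bones "
                    f"{p.name} -> {d.name}"
                )

    def bone(self, name: str) -> Bone:
        for b in self.bones:
            if b.name == name:
                return b
        raise StructuralError(f"no bone named {name} in digit {self.digit}")

    def concatenated_mesh(self) -> trimesh.Trimesh:
        return trimesh.util.concatenate([b.mesh for b in self.bones])


@dataclass
class HandModel:
    """Chains per digit plus the scaphoid tubercle landmark."""

    chains: dict[str, KinematicChain]
    scaphoid_tubercle: np.ndarray | None = None
    laterality: str = "right"

    def __post_init__(self):
        if self.scaphoid_tubercle is not None:
            p = np.asarray(self.scaphoid_tubercle, dtype=float).reshape(3)
            if not np.isfinite(p).all():
                raise ValidationError("scaphoid tubercle landmark is not finite")
            self.scaphoid_tubercle = p
        if self.laterality not in ("left", "right"):
            raise ValidationError("laterality must be 'left' or 'right'")

    def find_bone(self, name: str) -> tuple[KinematicChain, int]:
        for chain in self.chains.values():
            for i, b in enumerate(chain.bones):
                if b.name == name:
                    return chain, i
        raise StructuralError(f"no bone named {name} in the hand")


def build_chain(digit: str, bones: list[Bone], joint_axes: list[Axis]) -> KinematicChain:
    """Assemble a zero-pose chain; joint k rotates about ``joint_axes[k]``,
    the axis fitted on bone k's head, and is named MP/PIP/DIP in order."""
    if len(bones) < 2:
        raise StructuralError("a chain needs at least 2 bones")
    if len(joint_axes) != len(bones) - 1:
        raise StructuralError(
            f"{len(bones)} bones need {len(bones) - 1} joint axes, "
            f"got {len(joint_axes)}"
        )
    joints = []
    for k, axis in enumerate(joint_axes):
        if axis is None:
            raise StructuralError(f"missing joint axis {k} for digit {digit}")
        name = _JOINT_NAMES[k] if k < len(_JOINT_NAMES) else f"J{k}"
        joints.append(Joint(name, bones[k].name, bones[k + 1].name, axis))
    return KinematicChain(digit, list(bones), joints)


def pose_chain(
    chain: KinematicChain, flexion_angles: dict, *, strict_limits: bool = False
) -> KinematicChain:
    """Return a posed copy of the chain.

    ``flexion_angles`` maps joint name -> degrees; every joint must be
    given.  Rotations compose proximal to distal: each joint rotates about
    its *current* axis (already moved by the more proximal joints) and the
    rotation applies to every more distal bone.  Out-of-limit angles warn,
    or raise when ``strict_limits``.
    """
    missing = [j.name for j in chain.joints if j.name not in flexion_angles]
    if missing:
        raise ValidationError(f"posture missing angles for joints {missing}")
    T = RigidTransform.identity()
    new_bones = [copy.copy(chain.bones[0])]
    new_bones[0].mesh = chain.bones[0].mesh.copy()
    new_joints = []
    for k, joint in enumerate(chain.joints):
        ang = float(flexion_angles[joint.name])
        lo, hi = joint.limits
        if not lo <= ang <= hi:
            msg = (
                f"{chain.digit} {joint.name} flexion {ang:.1f} deg outside "
                f"limits [{lo}, {hi}]"
            )
            if strict_limits:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        current_axis = joint.axis.transformed(T)
        T = rotation_about_axis(current_axis, ang) @ T
        new_joints.append(
            Joint(joint.name, joint.proximal_bone, joint.distal_bone,
                  current_axis, ang, joint.limits)
        )
        new_bones.append(chain.bones[k + 1].transformed(T))
    return KinematicChain(chain.digit, new_bones, new_joints)


def pose_hand(hand: HandModel, posture: dict, *, strict_limits: bool = False) -> HandModel:
    """Pose every chain; ``posture`` maps digit -> {joint: degrees}."""
    missing = [d for d in hand.chains if d not in posture]
    if missing:
        raise ValidationError(f"posture missing digits {missing}")
    chains = {
        d: pose_chain(c, posture[d], strict_limits=strict_limits)
        for d, c in hand.chains.items()
    }
    return HandModel(chains, hand.scaphoid_tubercle, hand.laterality)


def detect_scissoring(
    hand: HandModel, posture: dict | None = None
) -> list[tuple[tuple[str, str], IntersectionReport]]:
    """Intersection reports for all adjacent digit pairs at the given posture
    (or the hand's current pose when ``posture`` is None)."""
    posed = pose_hand(hand, posture) if posture is not None else hand
    order = list(posed.chains)
    out = []
    for a, b in zip(order, order[1:]):
        rep = meshes_intersect(
            posed.chains[a].concatenated_mesh(), posed.chains[b].concatenated_mesh()
        )
        out.append(((a, b), rep))
    return out


def scaphoid_alignment(hand: HandModel, digit: str, posture: dict | None = None) -> float:
    """Distance (mm) from the posed distal phalanx's long inertial axis line
    to the scaphoid tubercle landmark."""
    if hand.scaphoid_tubercle is None:
        raise ValidationError("hand has no scaphoid tubercle landmark")
    if digit not in hand.chains:
        raise ValidationError(f"no digit named {digit}")
    posed = pose_hand(hand, posture) if posture is not None else hand
    dp = posed.chains[digit].bones[-1]
    centroid, direction = principal_inertia_axis(dp.mesh)
    return Axis(centroid, direction).distance_to_point(hand.scaphoid_tubercle)
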