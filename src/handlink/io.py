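"""JSON artifact serialization.

Every workflow stage writes a small versioned JSON file (``"schema": 1``)
so intermediates are diffable and each stage can validate its inputs.
Serialization is deterministic: sorted keys, no timestamps, plain ``repr``
floats - re-running a stage with unchanged inputs reproduces the artifact
byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .axes import BoneFrame, Circle3D
from .deformity import DeformityMeasurement, OsteotomyPlan
from .errors import DependencyError, ValidationError
from .geometry import Axis, Plane, RigidTransform

SCHEMA = 1


def _vec(v) -> list[float]:
    return [float(x) for x in np.asarray(v, dtype=float).reshape(-1)]


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def read_json(path, expected_kind: str | None = None) -> dict:
    path = Path(path)
    if not path.is_file():
        raise DependencyError(
            f"required artifact {path} does not exist; run the producing stage first"
        )
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise ValidationError(f"{path}: top-level JSON value must be an object")
    if obj.get("schema") != SCHEMA:
        raise ValidationError(f"{path}: missing or unsupported 'schema' field")
    if expected_kind is not None and obj.get("kind") != expected_kind:
        raise DependencyError(
            f"{path}: expected a {expected_kind!r} artifact, found "
            f"{obj.get('kind')!r}; stages may have been run out of order"
        )
    return obj


# -- axes / planes / transforms ---------------------------------------------


def axis_to_json(axis: Axis) -> dict:
    return {"point": _vec(axis.point), "direction": _vec(axis.direction)}


def axis_from_json(obj: dict) -> Axis:
    try:
        return Axis(obj["point"], obj["direction"])
    except KeyError as exc:
        raise ValidationError(f"axis object missing field {exc}") from exc


def plane_to_json(plane: Plane) -> dict:
    return {"point": _vec(plane.point), "normal": _vec(plane.normal)}


def plane_from_json(obj: dict) -> Plane:
    try:
        return Plane(obj["point"], obj["normal"])
    except KeyError as exc:
        raise ValidationError(f"plane object missing field {exc}") from exc


def transform_to_json(t: RigidTransform) -> dict:
    return {"rotation": [_vec(r) for r in t.rotation], "translation": _vec(t.translation)}


def transform_from_json(obj: dict) -> RigidTransform:
    try:
        return RigidTransform(np.asarray(obj["rotation"]), obj["translation"])
    except KeyError as exc:
        raise ValidationError(f"transform object missing field {exc}") from exc


# -- frames -------------------------------------------------------------------


def frame_artifact(
    frame: BoneFrame,
    joint_axis: Axis,
    circles: tuple[Circle3D, Circle3D] | None = None,
    bone: str | None = None,
) -> dict:
    obj = {
        "schema": SCHEMA,
        "kind": "bone_frame",
        "bone": bone,
        "origin": _vec(frame.origin),
        "X": _vec(frame.X),
        "Y": _vec(frame.Y),
        "Z": _vec(frame.Z),
        "y_obliquity_deg": float(frame.y_obliquity_deg),
        "joint_axis": axis_to_json(joint_axis),
    }
    if circles is not None:
        obj["circles"] = {
            name: {
                "center": _vec(c.center),
                "radius": float(c.radius),
                "normal": _vec(c.normal),
                "rms_residual": float(c.rms_residual),
            }
            for name, c in zip(("radial", "ulnar"), circles)
        }
    return obj


def frame_from_artifact(obj: dict) -> tuple[BoneFrame, Axis]:
    try:
        frame = BoneFrame(
            obj["origin"], obj["X"], obj["Y"], obj["Z"], obj["y_obliquity_deg"]
        )
        axis = axis_from_json(obj["joint_axis"])
    except KeyError as exc:
        raise ValidationError(f"bone_frame artifact missing field {exc}") from exc
    return frame, axis


# -- measurements and plans ---------------------------------------------------


def measurement_artifact(m: DeformityMeasurement, bone: str | None = None) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "measurement",
        "bone": bone,
        "angle_deg": float(m.angle_deg),
        "direction_label": m.direction_label,
        "transverse_normal": _vec(m.transverse_normal),
        "proximal_axis_projected": _vec(m.proximal_axis_projected),
        "distal_axis_projected": _vec(m.distal_axis_projected),
    }


def measurement_from_artifact(obj: dict) -> DeformityMeasurement:
    try:
        return DeformityMeasurement(
            obj["angle_deg"],
            obj["transverse_normal"],
            obj["proximal_axis_projected"],
            obj["distal_axis_projected"],
        )
    except KeyError as exc:
        raise ValidationError(f"measurement artifact missing field {exc}") from exc


def plan_artifact(plan: OsteotomyPlan) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "osteotomy_plan",
        "bone": plan.bone,
        "cut_kind": plan.kind,
        "cut_plane": plane_to_json(plan.cut_plane),
        "rotation_axis": axis_to_json(plan.rotation_axis),
        "wedge_plane": plan.wedge_plane,
        "wedge_angle_deg": float(plan.wedge_angle_deg),
    }


def plan_from_artifact(obj: dict) -> OsteotomyPlan:
    try:
        return OsteotomyPlan(
            cut_plane=plane_from_json(obj["cut_plane"]),
            kind=obj["cut_kind"],
            rotation_axis=axis_from_json(obj["rotation_axis"]),
            wedge_plane=obj["wedge_plane"],
            wedge_angle_deg=obj["wedge_angle_deg"],
            bone=obj.get("bone"),
        )
    except KeyError as exc:
        raise ValidationError(f"osteotomy_plan artifact missing field {exc}") from exc


# -- hands --------------------------------------------------------------------


def hand_manifest(
    digit_bones: dict[str, list[str]],
    scaphoid_tubercle,
    laterality: str = "right",
) -> dict:
    """Manifest listing per-digit bone names; mesh files are
    ``<bone>.stl``, landmarks ``<bone>_landmarks.json`` and fitted frames
    ``<bone>_frame.json`` alongside the manifest."""
    return {
        "schema": SCHEMA,
        "kind": "hand",
        "digits": {d: list(names) for d, names in digit_bones.items()},
        "scaphoid_tubercle": _vec(scaphoid_tubercle) if scaphoid_tubercle is not None else None,
        "laterality": laterality,
    }


def posture_artifact(posture: dict) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "posture",
        "angles": {
            d: {j: float(a) for j, a in angles.items()} for d, angles in posture.items()
        },
    }


def posture_from_artifact(obj: dict) -> dict:
    try:
        return {
            d: {j: float(a) for j, a in angles.items()}
            for d, angles in obj["angles"].items()
        }
    except (KeyError, AttributeError) as exc:
        raise ValidationError(f"posture artifact malformed: {exc}") from exc
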