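"""Deterministic parametric generator of finger/metacarpal bones and hands.

Bones are modelled as implicit solids - a tapered round-cone shaft capped by
two condylar spheres (offset symmetrically along the local Y axis at the
distal end) and a flattened base ellipsoid - polygonized by marching cubes
on a regular grid.  Building malunions on the implicit model (rigidly
transforming the distal part of the signed-distance field beyond a cut
plane and re-polygonizing the union) guarantees a welded, watertight result
with an exactly known imposed transform, which is what makes the generator
usable as ground truth.

The default grid pitch is 0.4 mm, the slice thickness of the clinical CT
protocol this emulates.  Default deformity magnitudes used in the standard
scenarios span 7-25 degrees, the range reported for operated malunions.

Local bone frame: the base is at z=0, the shaft runs along +z (proximal to
distal), condyles at z=length offset +-condyle_spacing/2 along y (radial at
-y, ulnar at +y), x dorso-palmar so that {x,y,z} is right-handed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure as _skmeasure

from .axes import BoneFrame
from .errors import (
    GenerationError,
    LayoutError,
    ParameterError,
    ValidationError,
)
from .geometry import (
    Axis,
    RigidTransform,
    meshes_intersect,
    rotation_about_axis,
)
from .linkage import Bone, HandModel, KinematicChain, build_chain

__all__ = [
    "BoneParams",
    "DeformitySpec",
    "BoneTruth",
    "HandTruth",
    "generate_bone",
    "impose_malunion",
    "generate_hand",
    "DEFAULT_BONE_PARAMS",
    "DIGIT_SCALES",
    "MAX_FLEXION_POSTURE",
    "SCAPHOID_POSTURE",
]


@dataclass(frozen=True)
class BoneParams:
    """Shape parameters of one synthetic bone (all mm, taper dimensionless)."""

    length: float
    shaft_radius: float
    condyle_radius: float
    condyle_spacing: float
    base_radius: float
    taper: float = 0.15

    def __post_init__(self):
        vals = (
            self.length,
            self.shaft_radius,
            self.condyle_radius,
            self.condyle_spacing,
            self.base_radius,
        )
        if any(v <= 0 for v in vals):
            raise ParameterError("all bone dimensions must be positive")
        if self.condyle_spacing >= 2 * (self.condyle_radius + self.shaft_radius):
            raise ParameterError("condyle_spacing too large for the head to be connected")
        if not 0 <= self.taper < 1:
            raise ParameterError("taper must be in [0, 1)")

    def scaled(self, s: float) -> "BoneParams":
        return BoneParams(
            self.length * s,
            self.shaft_radius * s,
            self.condyle_radius * s,
            self.condyle_spacing * s,
            self.base_radius * s,
            self.taper,
        )


@dataclass(frozen=True)
class DeformitySpec:
    """Malunion imposed on one bone at a transverse cut plane.

    Angles are degrees; rotations are applied to the distal fragment about
    the cut centroid in the order coronal (about local X), sagittal (about
    local Y), transverse (about local Z).  Positive transverse rotation is
    right-handed about +Z viewed from distal (supination of a right-hand
    digit).
    """

    bone: str
    cut_fraction: float = 0.5
    transverse_rotation_deg: float = 0.0
    coronal_angulation_deg: float = 0.0
    sagittal_angulation_deg: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.cut_fraction < 1.0:
            raise ParameterError("cut_fraction must be in (0, 1)")
        for a in (
            self.transverse_rotation_deg,
            self.coronal_angulation_deg,
            self.sagittal_angulation_deg,
        ):
            if abs(a) >= 45.0:
                raise ParameterError("deformity angles must be below 45 degrees")


@dataclass
class BoneTruth:
    """Exact construction record of one generated bone, in world coordinates."""

    name: str
    params: BoneParams
    frame: BoneFrame                      # construction frame (origin = centroid)
    joint_axis: Axis                      # condylar axis of this bone's head
    radial_condyle: np.ndarray            # condyle sphere centers
    ulnar_condyle: np.ndarray
    length: float                         # shaft length (base plane to head center)
    world_from_generated: RigidTransform  # placement of the generated mesh
    sdf: object = None                    # callable p(N,3)->signed distance, generation frame
    deformity: DeformitySpec | None = None
    malunion_transform: RigidTransform | None = None  # distal-fragment transform (local)
    cut_z: float | None = None            # cut plane height in the generation frame

    def landmarks(self) -> dict:
        return {
            "radial_condyle": self.radial_condyle.tolist(),
            "ulnar_condyle": self.ulnar_condyle.tolist(),
        }


@dataclass
class HandTruth:
    """Ground truth for a generated hand."""

    bones: dict[str, BoneTruth]
    digit_order: list[str]
    deformities: list[DeformitySpec]
    scaphoid_tubercle: np.ndarray
    max_flexion_posture: dict
    scaphoid_posture: dict
    resolution_mm: float
    seed: int


# Default morphologies.  Proximal-phalanx defaults are the reference shape;
# the others are plausible relative sizes for an adult hand.
DEFAULT_BONE_PARAMS: dict[str, BoneParams] = {
    "mc": BoneParams(60.0, 4.5, 5.5, 8.0, 6.5, 0.12),
    "pp": BoneParams(40.0, 4.0, 4.5, 7.0, 5.5, 0.15),
    "ip": BoneParams(25.0, 3.2, 3.6, 5.5, 4.5, 0.15),
    "dp": BoneParams(18.0, 2.5, 2.8, 4.0, 3.6, 0.20),
}

DIGIT_SCALES: dict[str, float] = {
    "index": 1.0,
    "middle": 1.08,
    "ring": 1.0,
    "small": 0.85,
}

DIGIT_ORDER = ["index", "middle", "ring", "small"]

# Postures calibrated once on the deformity-free synthetic hand.  The
# scaphoid (fingertip-convergence) posture flexes MP/PIP deeply with the DIP
# extended; each digit's MP is then fine-tuned so its distal axis passes
# through the tubercle.  The scissoring posture backs composite flexion off
# (MP -20 deg from the convergence value, PIP 70) to where the healthy hand
# keeps >1.5 mm inter-digit clearance while every clinically reported
# rotational malunion magnitude (7-25 deg) still produces contact.
MAX_FLEXION_POSTURE = {"MP": 60.0, "PIP": 70.0, "DIP": 20.0}
SCAPHOID_POSTURE = {"MP": 80.0, "PIP": 90.0, "DIP": 0.0}

_BASE_SPACING = 20.0   # mm between adjacent digit bases
_SPLAY_DEG = 5.0       # divergence between adjacent digit rays
_JOINT_CLEARANCE = 0.5 # mm gap between head surface and next base surface
_SCAPHOID_Z = -40.0    # scaphoid tubercle height: mid-carpus, proximal to the
                       # metacarpal bases at z=0
_BASE_HALF_DEPTH_FRACTION = 0.4  # base ellipsoid z semi-axis / base_radius


# ---------------------------------------------------------------------------
# signed-distance primitives
# ---------------------------------------------------------------------------


def _sd_round_cone(p: np.ndarray, r_base: float, r_top: float, h: float) -> np.ndarray:
    """Exact SDF of a round cone along z from (0,0,0) radius r_base to
    (0,0,h) radius r_top (a tapered capsule)."""
    b = (r_base - r_top) / h
    a = np.sqrt(max(1.0 - b * b, 1e-12))
    qx = np.hypot(p[:, 0], p[:, 1])
    qz = p[:, 2]
    k = -b * qx + a * qz
    out = a * qx + b * qz - r_base
    lower = np.hypot(qx, qz) - r_base
    upper = np.hypot(qx, qz - h) - r_top
    return np.where(k < 0.0, lower, np.where(k > a * h, upper, out))


def _sd_sphere(p: np.ndarray, center, r: float) -> np.ndarray:
    return np.linalg.norm(p - np.asarray(center, dtype=float), axis=1) - r


def _sd_ellipsoid(p: np.ndarray, center, radii) -> np.ndarray:
    """Near-exact ellipsoid SDF (first-order normalization)."""
    q = (p - np.asarray(center, dtype=float)) / np.asarray(radii, dtype=float)
    k0 = np.linalg.norm(q, axis=1)
    k1 = np.linalg.norm(q / np.asarray(radii, dtype=float), axis=1)
    k1 = np.where(k1 < 1e-12, 1e-12, k1)
    return k0 * (k0 - 1.0) / k1


def make_bone_sdf(params: BoneParams):
    """Signed-distance field of a bone in its generation frame."""
    L = params.length
    r0 = params.base_radius * 0.95
    rb = params.shaft_radius
    rt = params.shaft_radius * (1.0 - params.taper)
    half = params.condyle_spacing / 2.0
    rc = params.condyle_radius
    bz = params.base_radius * _BASE_HALF_DEPTH_FRACTION

    def sdf(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        d = _sd_round_cone(p, rb, rt, L)
        d = np.minimum(d, _sd_sphere(p, (0.0, -half, L), rc))
        d = np.minimum(d, _sd_sphere(p, (0.0, half, L), rc))
        d = np.minimum(d, _sd_ellipsoid(p, (0.0, 0.0, 0.0), (r0, r0, bz)))
        return d

    return sdf


def malunited_sdf(base_sdf, cut_z: float, local_transform: RigidTransform):
    """SDF of a bone whose part distal to ``z = cut_z`` has been rigidly
    moved by ``local_transform`` (generation-frame coordinates)."""
    inv = local_transform.inverse()

    def sdf(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        proximal = np.maximum(base_sdf(p), p[:, 2] - cut_z)
        q = inv.apply(p)
        distal = np.maximum(base_sdf(q), cut_z - q[:, 2])
        return np.minimum(proximal, distal)

    return sdf


# ---------------------------------------------------------------------------
# polygonization
# ---------------------------------------------------------------------------


def _polygonize(sdf, bounds_lo, bounds_hi, resolution: float) -> trimesh.Trimesh:
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / resolution).astype(int) + 1, 2)
    axes = [lo[i] + resolution * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    field = sdf(grid).reshape(shape)
    if field.min() > 0:
        raise GenerationError("implicit surface lies outside the sampling grid")
    verts, faces, _, _ = _skmeasure.marching_cubes(
        field, level=0.0, spacing=(resolution,) * 3
    )
    verts = verts + lo
    mesh = trimesh.Trimesh(verts, faces, process=False)
    mesh.merge_vertices()
    mesh.update_faces(mesh.area_faces > 0)
    if not mesh.is_watertight:
        raise GenerationError("marching-cubes output is not watertight")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def generate_bone(
    params: BoneParams, resolution_mm: float = 0.4, name: str = "bone"
) -> tuple[trimesh.Trimesh, BoneTruth]:
    """Polygonize one bone and return it with its ground-truth record.

    ``resolution_mm`` is the marching-cubes grid pitch (0.2-1.0 mm); it must
    resolve the condyles (<= condyle_radius / 3).
    """
    _check_resolution(params, resolution_mm)
    sdf = make_bone_sdf(params)
    mesh = _polygonize(sdf, *_bone_bounds(params), resolution_mm)
    half = params.condyle_spacing / 2.0
    truth = BoneTruth(
        name=name,
        params=params,
        frame=BoneFrame(
            mesh.center_mass, (1, 0, 0), (0, 1, 0), (0, 0, 1), 0.0
        ),
        joint_axis=Axis((0.0, 0.0, params.length), (0.0, 1.0, 0.0)),
        radial_condyle=np.array([0.0, -half, params.length]),
        ulnar_condyle=np.array([0.0, half, params.length]),
        length=params.length,
        world_from_generated=RigidTransform.identity(),
        sdf=sdf,
    )
    return mesh, truth


def _check_resolution(params: BoneParams, resolution_mm: float) -> None:
    if not 0.2 <= resolution_mm <= 1.0:
        raise ParameterError("resolution must be between 0.2 and 1.0 mm")
    if resolution_mm > params.condyle_radius / 3.0:
        raise ParameterError(
            f"resolution {resolution_mm} mm too coarse to resolve condyles "
            f"(need <= {params.condyle_radius / 3.0:.2f} mm)"
        )


def _bone_bounds(params: BoneParams, pad: float = 1.6):
    half = params.condyle_spacing / 2.0
    m_xy = max(params.base_radius, params.shaft_radius, params.condyle_radius)
    y_ext = half + params.condyle_radius
    # the shaft capsule's proximal hemisphere reaches -shaft_radius
    z_lo = -max(params.base_radius * _BASE_HALF_DEPTH_FRACTION, params.shaft_radius)
    lo = (-m_xy - pad, -max(m_xy, y_ext) - pad, z_lo - pad)
    hi = (m_xy + pad, max(m_xy, y_ext) + pad, params.length + params.condyle_radius + pad)
    return lo, hi


def malunion_transform(spec: DeformitySpec, cut_z: float) -> RigidTransform:
    """Composed rigid transform of the distal fragment, generation frame.

    Coronal angulation rotates about local X, sagittal about local Y,
    transverse about local Z, in that order, all about the cut-plane center
    ``(0, 0, cut_z)``.
    """
    pivot = np.array([0.0, 0.0, cut_z])
    t = RigidTransform.identity()
    for axis_dir, ang in (
        ((1.0, 0.0, 0.0), spec.coronal_angulation_deg),
        ((0.0, 1.0, 0.0), spec.sagittal_angulation_deg),
        ((0.0, 0.0, 1.0), spec.transverse_rotation_deg),
    ):
        if ang != 0.0:
            t = rotation_about_axis(Axis(pivot, axis_dir), ang) @ t
    return t


def impose_malunion(
    truth: BoneTruth, spec: DeformitySpec, resolution_mm: float = 0.4
) -> tuple[trimesh.Trimesh, BoneTruth]:
    """Re-polygonize a bone with the given malunion imposed.

    The distal part of the implicit model beyond the cut plane is rigidly
    transformed and the union re-polygonized; the truth record stores the
    exact composed transform and maps the head landmarks/axis through it.
    """
    _check_resolution(truth.params, resolution_mm)
    z_lo = -max(
        truth.params.base_radius * _BASE_HALF_DEPTH_FRACTION,
        truth.params.shaft_radius,
    )
    z_hi = truth.params.length + truth.params.condyle_radius
    cut_z = z_lo + spec.cut_fraction * (z_hi - z_lo)
    T = malunion_transform(spec, cut_z)
    sdf = malunited_sdf(truth.sdf, cut_z, T)
    lo, hi = _bone_bounds(truth.params)
    # widen bounds for the swung distal fragment
    pad = np.tan(np.radians(45.0)) * (z_hi - cut_z) * 0.5
    lo = (lo[0] - pad, lo[1] - pad, lo[2])
    hi = (hi[0] + pad, hi[1] + pad, hi[2] + pad * 0.5)
    mesh = _polygonize(sdf, lo, hi, resolution_mm)
    if len(mesh.split(only_watertight=False)) != 1:
        raise GenerationError("malunited fragments are detached")
    new = copy.copy(truth)
    new.sdf = sdf
    new.deformity = spec
    new.malunion_transform = T
    new.cut_z = cut_z
    new.joint_axis = truth.joint_axis.transformed(T)
    new.radial_condyle = T.apply(truth.radial_condyle)
    new.ulnar_condyle = T.apply(truth.ulnar_condyle)
    new.frame = BoneFrame(mesh.center_mass, (1, 0, 0), (0, 1, 0), (0, 0, 1), 0.0)
    return mesh, new


# ---------------------------------------------------------------------------
# whole hands
# ---------------------------------------------------------------------------


def _canonical_digit_index(digit: str, fallback: int) -> int:
    """Named digits always occupy their anatomical slot in the four-digit
    fan, so a two-digit hand is geometrically a subset of the full hand."""
    try:
        return DIGIT_ORDER.index(digit)
    except ValueError:
        return fallback


def _digit_layout(
    digits: list[str],
    splay_deg: float,
    base_spacing: float,
    obliquity: dict[str, float] | None = None,
):
    """Placement transform of each digit's generation frame in the world.

    Digit bases sit ``base_spacing`` apart along y; adjacent rays diverge by
    ``splay_deg`` (rotation about x at each base).  ``obliquity`` adds a
    per-digit axial rotation about the digit's own ray: the slight pronation
    or supination that aims each finger's flexion plane at the scaphoid
    tubercle, which is what makes flexed fingertips converge even though
    every joint is a fixed hinge.
    """
    obliquity = obliquity or {}
    out = {}
    for i, digit in enumerate(digits):
        k = _canonical_digit_index(digit, i)
        off = (k - (len(DIGIT_ORDER) - 1) / 2.0) * base_spacing
        ang = (k - (len(DIGIT_ORDER) - 1) / 2.0) * splay_deg
        base = np.array([0.0, off, 0.0])
        # rotation about +x by -ang sends +z toward +y: digits fan outward
        rot = rotation_about_axis(Axis(base, (1.0, 0.0, 0.0)), -ang)
        place = rot @ RigidTransform(np.eye(3), base)
        phi = obliquity.get(digit, 0.0)
        if phi:
            ray = Axis(base, place.apply_vector([0.0, 0.0, 1.0]))
            place = rotation_about_axis(ray, phi) @ place
        out[digit] = place
    return out


def _bone_stack_offsets(param_list: list[BoneParams]) -> list[float]:
    """z of each bone's generation origin along the digit ray."""
    z = 0.0
    offsets = []
    for k, p in enumerate(param_list):
        offsets.append(z)
        gap = (
            p.condyle_radius
            + (
                param_list[k + 1].base_radius * _BASE_HALF_DEPTH_FRACTION
                if k + 1 < len(param_list)
                else 0.0
            )
            + _JOINT_CLEARANCE
        )
        z += p.length + gap
    return offsets


_JOINT_NAMES = ["MP", "PIP", "DIP"]
_BONE_KINDS = ["mc", "pp", "ip", "dp"]


def _digit_params(digit: str) -> list[BoneParams]:
    scale = DIGIT_SCALES.get(digit, 1.0)
    return [DEFAULT_BONE_PARAMS[k].scaled(scale) for k in _BONE_KINDS]


def _truth_dp_axis(digit: str, place: RigidTransform, posture: dict) -> Axis:
    """Distal-phalanx long-axis line under analytic forward kinematics of
    the deformity-free truth model (no meshes involved)."""
    plist = _digit_params(digit)
    offsets = _bone_stack_offsets(plist)
    T = RigidTransform.identity()
    for k, jname in enumerate(_JOINT_NAMES):
        axis_local = Axis((0.0, 0.0, offsets[k] + plist[k].length), (0.0, 1.0, 0.0))
        axis_world = axis_local.transformed(place).transformed(T)
        T = rotation_about_axis(axis_world, posture[jname]) @ T
    dp_axis_local = Axis((0.0, 0.0, offsets[3]), (0.0, 0.0, 1.0))
    return dp_axis_local.transformed(place).transformed(T)


def _calibrate_convergence(
    digits: list[str], splay_deg: float, base_spacing: float
) -> tuple[np.ndarray, dict[str, float], dict[str, dict[str, float]]]:
    """Choose the scaphoid tubercle point and per-digit calibration.

    The tubercle is placed on the reference (most central) digit's flexed
    distal-phalanx axis just proximal to the carpal line.  Each other digit
    then gets (a) the axial obliquity that turns its flexion plane through
    that point - the pronation/supination real fingers have - solved in
    closed form, and (b) an MP flexion angle that zeroes the in-plane miss,
    found by a bounded 1-D search.  Everything is analytic truth kinematics,
    so the calibration is deterministic and costs no mesh work.
    """
    from scipy.optimize import minimize_scalar

    base = _digit_layout(digits, splay_deg, base_spacing)
    center = (len(DIGIT_ORDER) - 1) / 2.0
    offsets = {
        d: (_canonical_digit_index(d, i) - center) * base_spacing
        for i, d in enumerate(digits)
    }
    ref = min(digits, key=lambda d: abs(offsets[d]))
    ref_line = _truth_dp_axis(ref, base[ref], SCAPHOID_POSTURE)
    t = (_SCAPHOID_Z - ref_line.point[2]) / ref_line.direction[2]
    scaphoid = ref_line.point + t * ref_line.direction

    obliquity: dict[str, float] = {}
    for d in digits:
        place = base[d]
        B = place.apply([0.0, 0.0, 0.0])
        zhat = place.apply_vector([0.0, 0.0, 1.0])
        yhat = place.apply_vector([0.0, 1.0, 0.0])
        xhat = place.apply_vector([1.0, 0.0, 0.0])
        v = scaphoid - B
        # rotate y about z by phi so the flexion plane (normal y') contains v
        phi = np.degrees(np.arctan2(-(yhat @ v), -(xhat @ v)))
        if phi > 90.0:
            phi -= 180.0
        elif phi < -90.0:
            phi += 180.0
        obliquity[d] = float(phi)

    layout = _digit_layout(digits, splay_deg, base_spacing, obliquity)
    postures: dict[str, dict[str, float]] = {}
    for d in digits:
        def miss(mp, _d=d):
            posture = dict(SCAPHOID_POSTURE, MP=float(mp))
            return _truth_dp_axis(_d, layout[_d], posture).distance_to_point(scaphoid)

        res = minimize_scalar(miss, bounds=(60.0, 100.0), method="bounded",
                              options={"xatol": 1e-4})
        postures[d] = {"MP": float(res.x), "PIP": SCAPHOID_POSTURE["PIP"],
                       "DIP": SCAPHOID_POSTURE["DIP"]}
    return scaphoid, obliquity, postures


def generate_hand(
    digits: list[str] | None = None,
    deformities: list[DeformitySpec] | None = None,
    seed: int = 0,
    resolution_mm: float = 0.4,
    splay_deg: float = _SPLAY_DEG,
    base_spacing: float = _BASE_SPACING,
    check_layout: bool = True,
) -> tuple[HandModel, HandTruth]:
    """Generate a multi-digit hand with known ground truth.

    Each digit is a metacarpal plus three phalanges stacked along a ray from
    the carpal origin; adjacent rays diverge by ``splay_deg``, bases sit
    ``base_spacing`` mm apart, and each digit carries the calibrated axial
    obliquity that makes its flexed fingertip aim at the scaphoid tubercle.
    ``deformities`` name bones like ``"index_pp"``; every bone distal to a
    malunion inherits the malunion transform, exactly as the distal finger
    of a patient follows the rotated fragment.  Generation is fully
    deterministic for a given seed (the seed only drives optional shape
    jitter, none by default).
    """
    digits = list(digits) if digits is not None else list(DIGIT_ORDER)
    deformities = list(deformities) if deformities is not None else []
    if not 2 <= len(digits) <= 5:
        raise ValidationError("a hand needs between 2 and 5 digits")
    by_bone = {}
    for spec in deformities:
        if spec.bone in by_bone:
            raise ValidationError(f"duplicate deformity for bone {spec.bone}")
        by_bone[spec.bone] = spec

    scaphoid, obliquity, scaphoid_postures = _calibrate_convergence(
        digits, splay_deg, base_spacing
    )
    layout = _digit_layout(digits, splay_deg, base_spacing, obliquity)
    chains: dict[str, KinematicChain] = {}
    truth_bones: dict[str, BoneTruth] = {}

    for digit in digits:
        plist = _digit_params(digit)
        offsets = _bone_stack_offsets(plist)
        bones: list[Bone] = []
        joint_axes: list[Axis] = []
        carry = RigidTransform.identity()  # malunion transform carried distally
        for k, (kind, params, z0) in enumerate(zip(_BONE_KINDS, plist, offsets)):
            bname = f"{digit}_{kind}"
            mesh, btruth = generate_bone(params, resolution_mm, name=bname)
            if bname in by_bone:
                mesh, btruth = impose_malunion(btruth, by_bone[bname], resolution_mm)
            place = (
                carry
                @ layout[digit]
                @ RigidTransform(np.eye(3), np.array([0.0, 0.0, z0]))
            )
            mesh.vertices = place.apply(mesh.vertices)
            btruth.world_from_generated = place
            btruth.frame = btruth.frame.transformed(place)
            btruth.joint_axis = btruth.joint_axis.transformed(place)
            btruth.radial_condyle = place.apply(btruth.radial_condyle)
            btruth.ulnar_condyle = place.apply(btruth.ulnar_condyle)
            truth_bones[bname] = btruth
            bones.append(Bone(bname, mesh, frame=btruth.frame,
                              world_from_generated=place))
            if k < len(_BONE_KINDS) - 1:
                joint_axes.append(btruth.joint_axis)
            if btruth.malunion_transform is not None:
                # bones distal to the malunion follow the rotated fragment
                local = btruth.malunion_transform
                carry = (place @ local @ place.inverse()) @ carry
        chains[digit] = build_chain(digit, bones, joint_axes)

    hand = HandModel(chains=chains, scaphoid_tubercle=scaphoid, laterality="right")
    mp_offset = MAX_FLEXION_POSTURE["MP"] - SCAPHOID_POSTURE["MP"]
    max_flexion = {
        d: {
            "MP": scaphoid_postures[d]["MP"] + mp_offset,
            "PIP": MAX_FLEXION_POSTURE["PIP"],
            "DIP": MAX_FLEXION_POSTURE["DIP"],
        }
        for d in digits
    }
    truth = HandTruth(
        bones=truth_bones,
        digit_order=digits,
        deformities=deformities,
        scaphoid_tubercle=scaphoid,
        max_flexion_posture=max_flexion,
        scaphoid_posture=scaphoid_postures,
        resolution_mm=resolution_mm,
        seed=seed,
    )
    if check_layout:
        _check_zero_pose_disjoint(hand)
    return hand, truth


def voxel_intersection_volume(
    posed_hand: HandModel,
    truth: HandTruth,
    digit_a: str,
    digit_b: str,
    resolution_mm: float = 0.2,
) -> float:
    """Overlap volume (mm^3) between two posed digits, measured on the
    generator's implicit models.

    Every bone's ``world_from_generated`` transform maps grid points back to
    its generation frame where the exact signed-distance field is known, so
    this is an oracle independent of the mesh-based intersection test.
    """
    vols = []
    meshes = {}
    for d in (digit_a, digit_b):
        meshes[d] = posed_hand.chains[d].concatenated_mesh()
    lo = np.maximum(meshes[digit_a].bounds[0], meshes[digit_b].bounds[0]) - resolution_mm
    hi = np.minimum(meshes[digit_a].bounds[1], meshes[digit_b].bounds[1]) + resolution_mm
    if (lo >= hi).any():
        return 0.0
    axes_1d = [np.arange(lo[i], hi[i] + resolution_mm, resolution_mm) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes_1d, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = {}
    for d in (digit_a, digit_b):
        mask = np.zeros(len(grid), dtype=bool)
        for bone in posed_hand.chains[d].bones:
            bt = truth.bones[bone.name]
            local = bone.world_from_generated.inverse().apply(grid)
            mask |= bt.sdf(local) < 0.0
        inside[d] = mask
    return float((inside[digit_a] & inside[digit_b]).sum()) * resolution_mm**3


def _check_zero_pose_disjoint(hand: HandModel) -> None:
    order = list(hand.chains)
    for a, b in zip(order, order[1:]):
        ma = hand.chains[a].concatenated_mesh()
        mb = hand.chains[b].concatenated_mesh()
        if meshes_intersect(ma, mb).intersects:
            raise LayoutError(f"digits {a} and {b} intersect at zero pose")
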