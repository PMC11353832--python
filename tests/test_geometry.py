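"""Geometric substrate: STL I/O, inertia, transforms, cutting, projection,
mesh intersection."""

import numpy as np
import pytest
import trimesh

from handlink import geometry as g
from handlink.errors import (
    AmbiguousAxisError,
    EmptyFragmentError,
    MeshFormatError,
    UndefinedProjectionError,
    UnsupportedMeshError,
)
import helpers


@pytest.fixture(scope="module")
def cylinder():
    return trimesh.creation.cylinder(radius=4.0, height=40.0, sections=64)


# ---------------------------------------------------------------------- I/O


def test_ascii_single_triangle_loads(tmp_path):
    p = tmp_path / "tri.stl"
    p.write_text(
        "solid t\n facet normal 0 0 1\n  outer loop\n"
        "   vertex 0 0 0\n   vertex 1 0 0\n   vertex 0 1 0\n"
        "  endloop\n endfacet\nendsolid t\n"
    )
    m = g.load_mesh(p)
    assert len(m.vertices) == 3 and len(m.faces) == 1


def test_binary_cube_welds_to_eight_vertices(tmp_path):
    cube = trimesh.creation.box(extents=(1, 1, 1))
    p = tmp_path / "cube.stl"
    g.save_mesh(cube, p, "binary")
    # binary STL stores three loose vertices per facet; welding restores topology
    m = g.load_mesh(p)
    assert len(m.vertices) == 8 and len(m.faces) == 12
    assert m.is_watertight


def test_single_triangle_binary_is_134_bytes(tmp_path):
    one = trimesh.Trimesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]], process=False)
    p = tmp_path / "one.stl"
    g.save_mesh(one, p, "binary")
    assert p.stat().st_size == 80 + 4 + 50


# binary STL stores float32, so its round trip is only exact to ~4e-6 mm at
# coordinates of tens of mm; ASCII is written with 9 significant digits
@pytest.mark.parametrize("fmt, tol", [("binary", 5e-5), ("ascii", 1e-6)])
def test_phalanx_roundtrip(fmt, tol, pp_bone, tmp_path):
    from scipy.spatial import cKDTree

    mesh, _ = pp_bone
    p = tmp_path / f"pp.{fmt}.stl"
    g.save_mesh(mesh, p, fmt)
    back = g.load_mesh(p)
    assert len(back.vertices) == len(mesh.vertices)
    d, _ = cKDTree(mesh.vertices).query(back.vertices)
    assert d.max() < tol
    assert abs(back.volume - mesh.volume) / mesh.volume < 1e-5


def test_save_is_deterministic(pp_bone, tmp_path):
    mesh, _ = pp_bone
    g.save_mesh(mesh, tmp_path / "a.stl", "binary")
    g.save_mesh(mesh, tmp_path / "b.stl", "binary")
    assert (tmp_path / "a.stl").read_bytes() == (tmp_path / "b.stl").read_bytes()


def test_truncated_binary_reports_byte_offset(tmp_path):
    p = tmp_path / "trunc.stl"
    import struct

    data = b"\0" * 80 + struct.pack("<I", 100) + b"\0" * 60  # promises 100 facets
    p.write_bytes(data)
    with pytest.raises(MeshFormatError, match="byte offset"):
        g.load_mesh(p)


# ------------------------------------------------------------------ inertia


def test_cylinder_long_axis(cylinder):
    c, d = g.principal_inertia_axis(cylinder)
    assert np.abs(c).max() < 1e-6
    assert helpers.angle_between(d, [0, 0, 1]) < 1e-6


def test_inertia_axis_equivariance(cylinder, rng):
    from scipy.spatial.transform import Rotation

    for _ in range(5):
        R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        t = rng.normal(size=3) * 10
        T = g.RigidTransform(R, t)
        moved = g.transform_mesh(cylinder, T)
        c0, d0 = g.principal_inertia_axis(cylinder)
        c1, d1 = g.principal_inertia_axis(moved)
        assert np.abs(c1 - T.apply(c0)).max() < 1e-6
        assert helpers.angle_between(d1, T.apply_vector(d0)) < 1e-6


def test_sphere_axis_is_ambiguous():
    with pytest.raises(AmbiguousAxisError):
        g.principal_inertia_axis(trimesh.creation.icosphere(3, 1.0))


def test_non_watertight_falls_back_with_warning(cylinder):
    broken = trimesh.Trimesh(
        cylinder.vertices.copy(), cylinder.faces[:-1].copy(), process=False
    )
    with pytest.warns(UserWarning, match="not watertight"):
        _, d = g.principal_inertia_axis(broken)
    assert helpers.angle_between(d, [0, 0, 1]) < 1.0


def test_generated_phalanx_axis_matches_construction(pp_bone):
    mesh, truth = pp_bone
    _, d = g.principal_inertia_axis(mesh, distal_hint=(0, 0, truth.length))
    assert helpers.angle_between(d, [0, 0, 1]) < 2.0


# ------------------------------------------------------------------ rotation


def test_rotation_about_axis_basics():
    ax = g.Axis([0, 0, 0], [0, 0, 1])
    assert np.abs(g.rotation_about_axis(ax, 0).matrix - np.eye(4)).max() < 1e-12
    assert np.abs(g.rotation_about_axis(ax, 90).apply([1, 0, 0]) - [0, 1, 0]).max() < 1e-12
    assert np.abs(g.rotation_about_axis(ax, 360).matrix - np.eye(4)).max() < 1e-12


def test_rotation_fixes_axis_points_and_is_rigid(rng):
    ax = g.Axis([1.0, -2.0, 3.0], [1.0, 2.0, 2.0])
    T = g.rotation_about_axis(ax, 37.0)
    on_axis = ax.point + 2.5 * ax.direction
    assert np.abs(T.apply(on_axis) - on_axis).max() < 1e-9
    pts = rng.normal(size=(50, 3)) * 20
    d0 = np.linalg.norm(pts[:25] - pts[25:], axis=1)
    moved = T.apply(pts)
    d1 = np.linalg.norm(moved[:25] - moved[25:], axis=1)
    assert np.abs(d0 - d1).max() < 1e-9


def test_transform_composition_and_inverse(rng):
    from scipy.spatial.transform import Rotation

    a = g.RigidTransform(Rotation.random(random_state=1).as_matrix(), [1, 2, 3])
    b = g.RigidTransform(Rotation.random(random_state=2).as_matrix(), [-4, 0, 2])
    p = rng.normal(size=(10, 3))
    assert np.abs((a @ b).apply(p) - a.apply(b.apply(p))).max() < 1e-12
    assert np.abs((a @ a.inverse()).matrix - np.eye(4)).max() < 1e-12


# ------------------------------------------------------------------- cutting


def test_cylinder_cut_in_half(cylinder):
    pos, neg = g.plane_mesh_cut(cylinder, g.Plane([0, 0, 0], [0, 0, 1]))
    assert pos.is_watertight and neg.is_watertight
    assert abs(pos.volume - cylinder.volume / 2) / cylinder.volume < 1e-3
    assert abs(pos.volume + neg.volume - cylinder.volume) / cylinder.volume < 1e-3


def test_oblique_cut_conserves_volume(cylinder):
    plane = g.Plane([0.5, -0.3, 2.0], [0.2, 0.3, 0.93])
    pos, neg = g.plane_mesh_cut(cylinder, plane)
    assert pos.is_watertight and neg.is_watertight
    assert abs(pos.volume + neg.volume - cylinder.volume) / cylinder.volume < 1e-3


def test_phalanx_cut_matches_voxel_oracle(pp_bone):
    mesh, truth = pp_bone
    s = mesh.vertices[:, 2]
    z_cut = s.min() + 0.25 * (s.max() - s.min())
    plane = g.Plane([0, 0, z_cut], [0, 0, 1])
    distal, proximal = g.plane_mesh_cut(mesh, plane)
    assert abs(distal.volume + proximal.volume - mesh.volume) / mesh.volume < 1e-3
    lo, hi = mesh.bounds[0] - 0.5, mesh.bounds[1] + 0.5
    vox_prox = helpers.voxel_volume(
        helpers.halfspace_sdf(truth.sdf, plane.point, plane.normal, -1), lo, hi, 0.2
    )
    assert abs(proximal.volume - vox_prox) / vox_prox < 0.01


def test_cut_errors():
    cyl = trimesh.creation.cylinder(radius=1, height=2, sections=32)
    with pytest.raises(EmptyFragmentError):
        g.plane_mesh_cut(cyl, g.Plane([0, 0, 10], [0, 0, 1]))
    broken = trimesh.Trimesh(cyl.vertices.copy(), cyl.faces[:-1].copy(), process=False)
    with pytest.raises(UnsupportedMeshError):
        g.plane_mesh_cut(broken, g.Plane([0, 0, 0], [0, 0, 1]))


# --------------------------------------------------------- projected angles


@pytest.mark.parametrize(
    "v1, v2, n, expected",
    [
        ((1, 0, 0), (0, 1, 0), (0, 0, 1), 90.0),
        ((1, 0, 0), (1, 0, 0), (0, 0, 1), 0.0),
        ((0, 1, 0), (1, 0, 0), (0, 0, 1), -90.0),
        ((1, 0, 0), (-1, 0, 0), (0, 0, 1), 180.0),
        # out-of-plane components are discarded by the projection
        (
            (1, 0, 0.5),
            (np.cos(np.radians(12)), np.sin(np.radians(12)), -0.3),
            (0, 0, 1),
            12.0,
        ),
    ],
)
def test_signed_projected_angle(v1, v2, n, expected):
    assert g.signed_projected_angle(v1, v2, n) == pytest.approx(expected, abs=1e-9)


def test_projected_angle_antisymmetry(rng):
    for _ in range(20):
        v1, v2 = rng.normal(size=(2, 3))
        n = rng.normal(size=3)
        a = g.signed_projected_angle(v1, v2, n)
        assert g.signed_projected_angle(v2, v1, n) == pytest.approx(-a, abs=1e-9) or (
            abs(a) == pytest.approx(180.0, abs=1e-9)
        )
        assert g.signed_projected_angle(v1, v2, -np.asarray(n)) == pytest.approx(
            -a, abs=1e-9
        ) or abs(a) == pytest.approx(180.0, abs=1e-9)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    _coord = st.floats(-50.0, 50.0, allow_nan=False)
    _vec = st.tuples(_coord, _coord, _coord).filter(
        lambda v: np.linalg.norm(v) > 1e-3
    )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(v1=_vec, v2=_vec, n=_vec)
    def test_projected_angle_antisymmetry_property(v1, v2, n):
        """signed_projected_angle(v1,v2,n) = -signed_projected_angle(v2,v1,n)
        away from the 180-degree branch cut and the normal direction."""
        nn = np.asarray(n) / np.linalg.norm(n)
        if min(
            np.linalg.norm(v1 - (v1 @ nn) * nn) for v1 in (np.asarray(v1), np.asarray(v2))
        ) < 1e-3:
            return  # projection undefined by contract
        a = g.signed_projected_angle(v1, v2, n)
        if abs(abs(a) - 180.0) < 1e-6:
            return  # the branch point maps to +180 from either side
        assert g.signed_projected_angle(v2, v1, n) == pytest.approx(-a, abs=1e-7)

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_projected_angle_undefined_for_parallel_vector():
    with pytest.raises(UndefinedProjectionError):
        g.signed_projected_angle((0, 0, 1), (1, 0, 0), (0, 0, 1))


# ---------------------------------------------------------------- collision


def test_sphere_pair_intersection():
    s1 = trimesh.creation.icosphere(3, 1.0)
    far = s1.copy()
    far.apply_translation([3, 0, 0])
    near = s1.copy()
    near.apply_translation([1, 0, 0])
    assert not g.meshes_intersect(s1, far).intersects
    rep = g.meshes_intersect(s1, near)
    assert rep.intersects and rep.pair_count > 0 and rep.witness is not None


def test_intersection_symmetry():
    s1 = trimesh.creation.icosphere(2, 1.0)
    s2 = s1.copy()
    s2.apply_translation([1.2, 0.3, -0.1])
    r12 = g.meshes_intersect(s1, s2)
    r21 = g.meshes_intersect(s2, s1)
    assert r12.intersects == r21.intersects
    assert r12.pair_count == r21.pair_count


def test_report_invariant():
    with pytest.raises(Exception):
        g.IntersectionReport(True, 0)
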