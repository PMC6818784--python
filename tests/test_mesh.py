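import numpy as np
import pytest

import lipmorph as lm
from lipmorph.mesh import MeshError, _kabsch


TETRA_OBJ = """\
v 0 0 0
v 1 0 0
v 0 1 0
v 0 0 1
f 1 2 3
f 1 2 4
f 1 3 4
f 2 3 4
"""


def test_load_obj_counts(tmp_path):
    p = tmp_path / "tet.obj"
    p.write_text(TETRA_OBJ)
    mesh = lm.load_mesh(p)
    assert mesh.n_vertices == 4
    assert mesh.n_faces == 4


def test_quad_face_rejected(tmp_path):
    p = tmp_path / "quad.obj"
    p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
    with pytest.raises(MeshError, match="triangulate"):
        lm.load_mesh(p)


@pytest.mark.parametrize("fmt", ["obj", "ply"])
def test_roundtrip(tmp_path, fmt):
    mesh = lm.TriMesh(
        np.array([[0, 0, 0], [1.25, 0, 0], [0, 2.5, 0.125]]), [[0, 1, 2]]
    )
    path = tmp_path / f"m.{fmt}"
    lm.save_mesh(mesh, path)
    back = lm.load_mesh(path)
    np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
    np.testing.assert_array_equal(back.faces, mesh.faces)


def test_ply_scalars_roundtrip(tmp_path):
    mesh = lm.TriMesh(np.eye(3), [[0, 1, 2]])
    scalars = np.array([0.1, 0.5, 0.925])
    path = tmp_path / "m.ply"
    lm.save_mesh(mesh, path, vertex_scalars=scalars)
    np.testing.assert_allclose(lm.load_vertex_scalars(path), scalars, atol=1e-7)


def test_scalar_length_mismatch(tmp_path):
    mesh = lm.TriMesh(np.eye(3), [[0, 1, 2]])
    with pytest.raises(MeshError, match="length"):
        lm.save_mesh(mesh, tmp_path / "m.ply", vertex_scalars=[1.0])


def test_trimesh_invariants_enforced():
    with pytest.raises(MeshError):
        lm.TriMesh(np.eye(3), [[0, 1, 1]])  # repeated vertex
    with pytest.raises(MeshError):
        lm.TriMesh(np.eye(3), [[0, 1, 5]])  # out of range
    with pytest.raises(MeshError):
        lm.TriMesh(np.eye(3), np.empty((0, 3), dtype=int))  # no faces


class TestLandmarks:
    def test_vertex_coincident_snaps_exactly(self, patch_with_landmarks):
        mesh, _ = patch_with_landmarks
        lms = lm.LandmarkSet.from_points({"sn": mesh.vertices[10]}, mesh)
        assert lms.vertex("sn") == 10
        np.testing.assert_allclose(lms.point("sn"), mesh.vertices[10])

    def test_eight_lip_names_load(self, tmp_path, patch_with_landmarks):
        mesh, lms = patch_with_landmarks
        rows = ["name,x,y,z"] + [
            f"{n},{p[0]},{p[1]},{p[2]}" for n, (p, _) in lms.entries.items()
        ]
        f = tmp_path / "lm.csv"
        f.write_text("\n".join(rows))
        back = lm.load_landmarks(f, mesh, snap_tolerance=3.0)
        assert len(back) == 8
        assert set(back.names()) == set(lm.LANDMARK_NAMES)

    def test_unknown_name_rejected(self, patch_with_landmarks):
        mesh, _ = patch_with_landmarks
        with pytest.raises(MeshError, match="unknown"):
            lm.LandmarkSet.from_points({"xyz": mesh.vertices[0]}, mesh)

    def test_far_point_rejected(self, patch_with_landmarks):
        mesh, _ = patch_with_landmarks
        with pytest.raises(MeshError, match="snap tolerance"):
            lm.LandmarkSet.from_points({"sn": [0, 0, 500.0]}, mesh)

    def test_duplicate_name_rejected(self, tmp_path, patch_with_landmarks):
        mesh, _ = patch_with_landmarks
        f = tmp_path / "lm.csv"
        f.write_text("name,x,y,z\nsn,0,24,5\nsn,0,24,5\n")
        with pytest.raises(MeshError, match="duplicate"):
            lm.load_landmarks(f, mesh, snap_tolerance=10.0)


class TestSmoothing:
    def test_zero_iterations_is_identity(self, patch_with_landmarks):
        mesh, _ = patch_with_landmarks
        out = lm.smooth_mesh(mesh, iterations=0)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_flat_grid_is_fixed_point(self):
        mesh, _ = lm.analytic_surface("plane", size=10, resolution=12)
        out = lm.smooth_mesh(mesh, iterations=5)
        np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-9)

    def test_counts_preserved_and_volume_drift_small(self):
        rng = np.random.default_rng(0)
        sphere, _ = lm.analytic_surface("sphere", size=10.0, resolution=3)
        noisy = lm.TriMesh(
            sphere.vertices
            + rng.normal(0, 0.2, sphere.vertices.shape),
            sphere.faces,
        )
        out = lm.smooth_mesh(noisy, iterations=10)
        assert out.n_vertices == noisy.n_vertices
        assert out.n_faces == noisy.n_faces
        drift = abs(out.volume_proxy() - noisy.volume_proxy())
        assert drift < 0.01 * abs(noisy.volume_proxy())

    def test_noisy_sphere_curvature_variance_decreases(self):
        rng = np.random.default_rng(1)
        sphere, _ = lm.analytic_surface("sphere", size=10.0, resolution=3)
        noisy = lm.TriMesh(
            sphere.vertices + rng.normal(0, 0.2, sphere.vertices.shape),
            sphere.faces,
        )
        before = lm.curvature_tensor_field(noisy).Ga
        out = lm.smooth_mesh(noisy, iterations=10)
        after = lm.curvature_tensor_field(out).Ga
        assert np.nanvar(after) < np.nanvar(before)

    def test_bad_strength_rejected(self, patch_with_landmarks):
        mesh, _ = patch_with_landmarks
        with pytest.raises(MeshError):
            lm.smooth_mesh(mesh, iterations=1, strength=1.5)


class TestAlignPose:
    def test_canonical_frame(self, patch_with_landmarks):
        mesh, lms = patch_with_landmarks
        out, olm = lm.align_pose(mesh, lms)
        np.testing.assert_allclose(olm.point("sn"), [0, 0, 0], atol=1e-9)
        chl, chr_ = olm.point("chL"), olm.point("chR")
        assert abs(chl[1] - chr_[1]) < 1e-9  # cheilion axis along x
        assert abs(chl[2] - chr_[2]) < 1e-9
        assert chr_[0] > chl[0]

    def test_idempotent(self, aligned_patch):
        mesh, lms = aligned_patch
        again, _ = lm.align_pose(mesh, lms)
        np.testing.assert_allclose(again.vertices, mesh.vertices, atol=1e-9)

    def test_invariance_under_rigid_motion(self, patch_with_landmarks):
        mesh, lms = patch_with_landmarks
        ref, _ = lm.align_pose(mesh, lms)
        moved = lm.TriMesh(mesh.vertices + np.array([5.0, 7.0, -3.0]), mesh.faces)
        mlm = lm.LandmarkSet(
            {k: (np.asarray(p) + [5.0, 7.0, -3.0], v) for k, (p, v) in lms.entries.items()}
        )
        out, _ = lm.align_pose(moved, mlm)
        np.testing.assert_allclose(out.vertices, ref.vertices, atol=1e-6)

    def test_rigidity(self, patch_with_landmarks):
        mesh, lms = patch_with_landmarks
        out, _ = lm.align_pose(mesh, lms)
        idx = np.array([0, 50, 500, 1000])
        before = np.linalg.norm(
            mesh.vertices[idx][:, None] - mesh.vertices[idx][None], axis=-1
        )
        after = np.linalg.norm(
            out.vertices[idx][:, None] - out.vertices[idx][None], axis=-1
        )
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_degenerate_frame_rejected(self, patch_with_landmarks):
        mesh, lms = patch_with_landmarks
        bad = lm.LandmarkSet(
            {
                "sn": lms.entries["sn"],
                "chL": lms.entries["chL"],
                "chR": lms.entries["chL"],
            }
        )
        with pytest.raises(MeshError, match="degenerate"):
            lm.align_pose(mesh, bad)


class TestRegularise:
    def test_identity_when_mesh_equals_template(self):
        template = lm.synthetic_template(nx=40, ny=24)
        out = lm.regularise_to_template(
            template.mesh, template.landmarks, template, k=1
        )
        np.testing.assert_allclose(out.vertices, template.mesh.vertices, atol=1e-9)
        np.testing.assert_array_equal(out.faces, template.mesh.faces)

    def test_default_template_has_7150_vertices(self):
        template = lm.synthetic_template()
        assert template.n_vertices == 7150

    def test_output_adopts_template_topology(self, patch_with_landmarks):
        mesh, lms = patch_with_landmarks
        template = lm.synthetic_template(nx=40, ny=24)
        out = lm.regularise_to_template(mesh, lms, template, k=3)
        assert out.n_vertices == template.n_vertices
        np.testing.assert_array_equal(out.faces, template.mesh.faces)

    def test_dense_plane_onto_coarse_plane(self):
        dense, _ = lm.analytic_surface("plane", size=10, resolution=40)
        coarse, _ = lm.analytic_surface("plane", size=10, resolution=8)
        lms_pts = {
            "sn": [5.0, 5.0, 0.0], "chL": [2.0, 2.0, 0.0], "chR": [8.0, 2.0, 0.0],
        }
        dl = lm.LandmarkSet.from_points(lms_pts, dense)
        cl = lm.LandmarkSet.from_points(lms_pts, coarse)
        out = lm.regularise_to_template(dense, dl, lm.Template(coarse, cl), k=3)
        assert np.abs(out.vertices[:, 2]).max() < 1e-6

    def test_k_too_large_rejected(self):
        template = lm.synthetic_template(nx=40, ny=24)
        tiny = lm.TriMesh(np.eye(3), [[0, 1, 2]])
        with pytest.raises(MeshError):
            lm.regularise_to_template(tiny, lm.LandmarkSet(), template, k=10)


def test_kabsch_recovers_rigid_transform():
    rng = np.random.default_rng(4)
    src = rng.normal(size=(20, 3))
    theta = 0.7
    R_true = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    dst = src @ R_true.T + [1.0, -2.0, 0.5]
    R, t = _kabsch(src, dst)
    np.testing.assert_allclose(R, R_true, atol=1e-9)
    np.testing.assert_allclose(t, [1.0, -2.0, 0.5], atol=1e-9)
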