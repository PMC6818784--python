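import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipmorph as lm
from lipmorph.descriptors import LEGAL_BINS, TRAITS, TraitDescriptor
from lipmorph.mesh import MeshError


class TestHistogramNormalise:
    def test_two_bin_example(self):
        np.testing.assert_allclose(
            lm.histogram_normalise([1, 1, 2, 3], 2), [0.5, 0.5]
        )

    def test_constant_input_mass_in_first_bin(self):
        out = lm.histogram_normalise([4.2] * 7, 5)
        np.testing.assert_allclose(out, [1, 0, 0, 0, 0])

    def test_empty_rejected(self):
        with pytest.raises(MeshError):
            lm.histogram_normalise([], 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=60
        ),
        b=st.integers(1, 25),
    )
    def test_sums_to_one_and_rightmost_edge_inclusive(self, values, b):
        out = lm.histogram_normalise(values, b)
        assert len(out) == b
        assert abs(out.sum() - 1.0) < 1e-9
        assert (out >= 0).all()


def _synthetic_field_and_path(n=60, seed=0):
    """A straight dense path over a random curvature field on a plane strip."""
    rng = np.random.default_rng(seed)
    mesh, _ = lm.analytic_surface("plane", size=10.0, resolution=40)
    k2 = rng.normal(0, 0.3, mesh.n_vertices)
    k1 = k2 + np.abs(rng.normal(0, 0.3, mesh.n_vertices))
    field = lm.derived_measures(k1, k2)
    field.vertices = mesh.vertices
    field.boundary = np.zeros(mesh.n_vertices, dtype=bool)
    path = lm.compute_path(mesh, 0, mesh.n_vertices - 1)
    return field, path


class TestPathDescriptor:
    @pytest.mark.parametrize("b", LEGAL_BINS)
    def test_length_is_4b(self, b):
        field, path = _synthetic_field_and_path()
        vec = lm.path_descriptor(field, path, b)
        assert len(vec) == 4 * b
        blocks = vec.reshape(4, b)
        np.testing.assert_allclose(blocks.sum(axis=1), 1.0, atol=1e-9)

    def test_flat_grid_gives_degenerate_histograms(self):
        mesh, _ = lm.analytic_surface("plane", size=10.0, resolution=20)
        field = lm.curvature_tensor_field(mesh)
        path = lm.compute_path(mesh, 0, mesh.n_vertices - 1)
        vec = lm.path_descriptor(field, path, 5, exclude_boundary=False)
        blocks = vec.reshape(4, 5)
        for block in blocks:
            np.testing.assert_allclose(block, [1, 0, 0, 0, 0], atol=1e-9)

    def test_b_exceeding_samples_rejected(self):
        field, path = _synthetic_field_and_path()
        with pytest.raises(MeshError, match="exceeds"):
            lm.path_descriptor(field, path, 1000)


class TestTraitDescriptor:
    @pytest.mark.parametrize(
        "trait,n_paths",
        [
            ("philtrum", 5),
            ("cupids_bow", 2),
            ("upper_lip_contour", 4),
            ("lower_lip_contour", 2),
            ("lip_chin", 1),
            ("lower_lip_tone", 5),
        ],
    )
    def test_table_path_counts(self, trait, n_paths):
        assert TRAITS[trait].n_paths == n_paths

    def test_philtrum_b5_gc_length(self, aligned_patch, patch_field):
        mesh, lms = aligned_patch
        d = lm.trait_descriptor(mesh, lms, patch_field, "philtrum", b=5)
        assert len(d.gc) == 4 * 5 * 5
        assert len(d.gd) == 5 and len(d.ed) == 5

    def test_cupids_bow_b10_gc_length(self, aligned_patch, patch_field):
        mesh, lms = aligned_patch
        d = lm.trait_descriptor(mesh, lms, patch_field, "cupids_bow", b=10)
        assert len(d.gc) == 80

    def test_illegal_b_rejected(self, aligned_patch, patch_field):
        mesh, lms = aligned_patch
        with pytest.raises(MeshError, match="b must be"):
            lm.trait_descriptor(mesh, lms, patch_field, "philtrum", b=7)

    def test_descriptor_dimension_formula(self):
        # dimension is a pure function of (trait, b, selection)
        for trait in TRAITS.values():
            for b in LEGAL_BINS:
                gc_dim = 4 * b * trait.n_paths
                for sel, extra in ((("GC",), 0), (("GC", "GD"), trait.n_paths),
                                   (("GC", "GD", "ED"), 2 * trait.n_paths)):
                    made = [
                        TraitDescriptor(
                            str(i), trait.name, b,
                            np.full(gc_dim, 1.0 / (4 * b)),
                            gd=np.arange(trait.n_paths, dtype=float) + i,
                            ed=np.arange(trait.n_paths, dtype=float),
                        )
                        for i in range(3)
                    ]
                    X = lm.combine_and_scale(made, sel)
                    assert X.shape == (3, gc_dim + extra)

    def test_rigid_motion_invariance(self, patch_config):
        mesh, lms, _ = lm.lip_patch(patch_config, 1)
        theta = 0.4
        R = np.array(
            [[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
             [-np.sin(theta), 0, np.cos(theta)]]
        )
        moved = lm.TriMesh(mesh.vertices @ R.T + [10.0, -5.0, 2.0], mesh.faces)
        mlm = lm.LandmarkSet(
            {k: (np.asarray(p) @ R.T + [10.0, -5.0, 2.0], v)
             for k, (p, v) in lms.entries.items()}
        )
        from lipmorph.pipeline import mesh_trait_descriptor

        d0 = mesh_trait_descriptor(mesh, lms, "philtrum", b=5, smooth_iterations=0)
        d1 = mesh_trait_descriptor(moved, mlm, "philtrum", b=5, smooth_iterations=0)
        np.testing.assert_allclose(d1.gc, d0.gc, atol=1e-6)
        np.testing.assert_allclose(d1.gd, d0.gd, atol=1e-6)
        np.testing.assert_allclose(d1.ed, d0.ed, atol=1e-6)


class TestDistanceFeatures:
    def test_closed_form_3_4_5(self):
        path = lm.GeodesicPath.from_points(
            [[0, 0, 0], [1, 2, 2]], ("a", "b"), "exact"
        )
        trait = lm.TraitDefinition("lip_chin", (("li", "pg"),))
        lms = lm.LandmarkSet(
            {"li": ([0, 0, 0], 0), "pg": ([1, 2, 2], 1)}
        )
        ed, gd = lm.distance_features(lms, trait, [path])
        assert np.isclose(ed[0], 3.0)
        assert gd[0] >= ed[0]

    def test_gd_at_least_ed_on_patch(self, aligned_patch, patch_field):
        mesh, lms = aligned_patch
        d = lm.trait_descriptor(mesh, lms, patch_field, "philtrum", b=5)
        assert (d.gd >= d.ed - 1e-9).all()

    def test_philtrum_has_five_of_each(self, aligned_patch, patch_field):
        mesh, lms = aligned_patch
        d = lm.trait_descriptor(mesh, lms, patch_field, "philtrum", b=5)
        assert len(d.ed) == 5 and len(d.gd) == 5

    def test_missing_landmark_rejected(self):
        trait = lm.TraitDefinition("lip_chin", (("li", "pg"),))
        with pytest.raises(MeshError, match="missing landmark"):
            lm.distance_features(lm.LandmarkSet(), trait, [])


class TestCombineAndScale:
    def _desc(self, mesh_id, gc, gd=None, ed=None):
        return TraitDescriptor(mesh_id, "t", 5, np.asarray(gc, float),
                               gd=gd if gd is None else np.asarray(gd, float),
                               ed=ed if ed is None else np.asarray(ed, float))

    def test_minmax_column(self):
        descs = [self._desc(str(i), [v]) for i, v in enumerate([2.0, 4.0, 6.0])]
        X = lm.combine_and_scale(descs, ("GC",))
        np.testing.assert_allclose(X[:, 0], [0, 0.5, 1.0])

    def test_constant_column_is_zero(self):
        descs = [self._desc(str(i), [3.0]) for i in range(4)]
        X = lm.combine_and_scale(descs, ("GC",))
        np.testing.assert_allclose(X, 0.0)

    def test_selection_width(self, aligned_patch, patch_field):
        mesh, lms = aligned_patch
        d = lm.trait_descriptor(mesh, lms, patch_field, "philtrum", b=5)
        X = lm.combine_and_scale([d, d], ("GC", "GD"))
        assert X.shape[1] == 100 + 5

    def test_single_mesh_rejected(self):
        with pytest.raises(MeshError, match="at least 2"):
            lm.combine_and_scale([self._desc("a", [1.0])], ("GC",))

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(0)
        descs = [self._desc(str(i), rng.normal(size=7)) for i in range(5)]
        X = lm.combine_and_scale(descs, ("GC",))
        assert X.min() >= 0 and X.max() <= 1


def test_feature_table_roundtrip(tmp_path, aligned_patch, patch_field):
    mesh, lms = aligned_patch
    d = lm.trait_descriptor(mesh, lms, patch_field, "cupids_bow", b=5)
    f = tmp_path / "feats.csv"
    from lipmorph.descriptors import save_features, load_features

    save_features(f, [d, d], block="GC")
    ids, trait, b, X = load_features(f)
    assert trait == "cupids_bow" and b == 5
    assert X.shape == (2, len(d.gc))
    np.testing.assert_allclose(X[0], d.gc, atol=1e-12)
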