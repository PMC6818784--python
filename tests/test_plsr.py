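import numpy as np
import pytest

import lipmorph as lm
from lipmorph.mesh import MeshError
from lipmorph.plsr import permutation_significance


class TestDummyEncode:
    def test_three_category_example(self):
        dm = lm.dummy_encode(["a", "b", "c", "a"])
        assert dm.reference == "a"
        np.testing.assert_array_equal(dm.values, [[0, 0], [1, 0], [0, 1], [0, 0]])

    def test_seven_categories_give_six_columns(self):
        dm = lm.dummy_encode(list(range(7)) * 3)
        assert dm.n_dummies == 6

    def test_two_categories_give_one_column(self):
        dm = lm.dummy_encode(["x", "y", "x"])
        assert dm.n_dummies == 1

    def test_row_structure(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["a", "b", "c", "d"], 40)
        dm = lm.dummy_encode(labels)
        assert (dm.values.sum(axis=1) <= 1).all()
        ref_rows = labels == dm.reference
        assert (dm.values[ref_rows] == 0).all()

    def test_single_category_rejected(self):
        with pytest.raises(MeshError):
            lm.dummy_encode(["a", "a"])


def _two_group_shapes(rng, n=40, V=60, effect=2.0, noise=0.1):
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    X = rng.normal(0, noise, (n, V, 3))
    region = slice(10, 20)
    X[n // 2:, region, 2] += effect
    return X.reshape(n, -1), labels, np.arange(10, 20)


class TestPlsrFit:
    def test_binary_dummy_recovers_group_mean_difference(self):
        rng = np.random.default_rng(1)
        X, labels, _ = _two_group_shapes(rng)
        dm = lm.dummy_encode(labels)
        coef = lm.plsr_fit(dm, X, n_components=1)
        diff = (
            X[labels == "b"].mean(axis=0) - X[labels == "a"].mean(axis=0)
        ).reshape(-1, 3)
        np.testing.assert_allclose(coef[0], diff, atol=1e-8)

    def test_injected_effect_magnitude_and_locality(self):
        rng = np.random.default_rng(2)
        X, labels, region = _two_group_shapes(rng, effect=2.0, noise=0.1)
        model = lm.CategoryShapeModel(X, labels)
        res = model.fit()
        mag = res.effects.magnitude[0]
        assert np.abs(mag[region] - 2.0).max() < 0.2
        others = np.setdiff1d(np.arange(60), region)
        assert mag[others].max() < 0.2

    def test_joint_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X, labels, _ = _two_group_shapes(rng)
        perm = rng.permutation(len(X))
        c1 = lm.plsr_fit(lm.dummy_encode(labels), X)
        c2 = lm.plsr_fit(lm.dummy_encode(labels[perm]), X[perm])
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_rank_deficient_rejected(self):
        X = np.random.default_rng(4).normal(size=(10, 9))
        Y = np.zeros((10, 2))
        Y[5:, 0] = 1
        Y[5:, 1] = 1  # duplicate column
        with pytest.raises(MeshError, match="rank"):
            lm.plsr_fit(Y, X)


class TestEffectMaps:
    def test_zero_coefficients_give_zero_maps(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 30))
        labels = np.array(["a", "b"] * 10)
        coef = np.zeros((1, 10, 3))
        emap = lm.effect_maps(coef, X, lm.dummy_encode(labels))
        assert emap.magnitude.max() == 0.0

    def test_single_dummy_partial_equals_multiple_r2(self):
        rng = np.random.default_rng(6)
        X, labels, _ = _two_group_shapes(rng)
        res = lm.CategoryShapeModel(X, labels).fit()
        np.testing.assert_allclose(
            res.effects.partial_r2[0], res.effects.multiple_r2, atol=1e-10
        )

    def test_r2_bounds_and_multiple_dominates_partials(self):
        rng = np.random.default_rng(7)
        n, V = 60, 40
        labels = rng.choice(["a", "b", "c"], n)
        X = rng.normal(size=(n, 3 * V))
        X[labels == "b", :30] += 1.0
        res = lm.CategoryShapeModel(X, labels).fit()
        e = res.effects
        assert (e.partial_r2 >= 0).all() and (e.partial_r2 <= 1).all()
        assert (e.multiple_r2 >= 0).all() and (e.multiple_r2 <= 1).all()
        assert (e.multiple_r2 + 1e-9 >= e.partial_r2).all()

    def test_top_r2_region_overlaps_injected(self):
        rng = np.random.default_rng(8)
        X, labels, region = _two_group_shapes(rng, V=100, effect=2.0, noise=0.2)
        res = lm.CategoryShapeModel(X, labels).fit()
        top = np.argsort(res.effects.multiple_r2)[-10:]
        jaccard = len(np.intersect1d(top, region)) / len(np.union1d(top, region))
        assert jaccard >= 0.8


class TestPermutationSignificance:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(9)
        X, labels, region = _two_group_shapes(rng, n=30, V=20)
        res = lm.CategoryShapeModel(X, labels).fit()
        p = res.permutation_test(n_permutations=99, rng=0)
        assert p.min() >= 1.0 / 100
        assert p[region].max() <= 0.05

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(10)
        n, V = 40, 60
        X = rng.normal(size=(n, 3 * V))
        labels = np.array(["a", "b"] * (n // 2))
        p = permutation_significance(X, lm.dummy_encode(labels),
                                     n_permutations=199, rng=1)
        from scipy import stats

        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_fixed_rng_reproducible(self):
        rng = np.random.default_rng(11)
        X, labels, _ = _two_group_shapes(rng, n=20, V=15)
        dm = lm.dummy_encode(labels)
        p1 = permutation_significance(X, dm, n_permutations=50, rng=42)
        p2 = permutation_significance(X, dm, n_permutations=50, rng=42)
        np.testing.assert_array_equal(p1, p2)


class TestExportHeatmap:
    def _fitted(self, tmp_path):
        rng = np.random.default_rng(12)
        mesh, _ = lm.analytic_surface("plane", size=10.0, resolution=5)
        V = mesh.n_vertices
        labels = np.array(["a"] * 10 + ["b"] * 10)
        X = rng.normal(0, 0.1, (20, V, 3))
        X[10:, :5, 2] += 2.0
        res = lm.CategoryShapeModel(X.reshape(20, -1), labels).fit()
        res.permutation_test(n_permutations=99, rng=0, per_dummy=True)
        return mesh, res.effects

    def test_scalar_roundtrip(self, tmp_path):
        mesh, emap = self._fitted(tmp_path)
        f = tmp_path / "mag.ply"
        lm.export_heatmap(mesh, emap, "magnitude", f)
        back = lm.load_vertex_scalars(f)
        np.testing.assert_allclose(back, emap.multiple_magnitude, atol=1e-6)

    def test_significance_two_colour_threshold(self, tmp_path):
        mesh, emap = self._fitted(tmp_path)
        emap.p_values = np.full(mesh.n_vertices, 0.001)
        emap.p_values[:3] = 0.0005
        f = tmp_path / "sig.ply"
        lm.export_heatmap(mesh, emap, "significance", f)
        text = f.read_text()
        body = [l for l in text.splitlines() if l and l[0].isdigit() or l[0] == "-"]
        # p exactly 0.001 is green (strict <); only the three sub-threshold
        # vertices are yellow
        yellow = [l for l in body if l.endswith("255 255 0")]
        assert len(yellow) == 3

    def test_count_mismatch_rejected(self, tmp_path):
        mesh, emap = self._fitted(tmp_path)
        small = lm.TriMesh(np.eye(3), [[0, 1, 2]])
        with pytest.raises(MeshError):
            lm.export_heatmap(small, emap, "magnitude", tmp_path / "x.ply")


def test_summary_mentions_key_quantities():
    rng = np.random.default_rng(13)
    X, labels, _ = _two_group_shapes(rng, n=20, V=15)
    res = lm.CategoryShapeModel(X, labels).fit()
    text = res.summary()
    assert "dummies: 1" in text
    assert "reference" in text
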