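"""Visualising category effects on registered meshes with PLSR.

Trait categories (manual or automatic) are dummy-encoded into C-1 indicator
columns and used as predictors of the dense shape matrix (each row the
concatenated x,y,z of all template vertices of one regularised mesh).  Partial
least squares regression yields per-vertex 3-D displacement coefficients per
dummy; from these the module derives per-vertex effect magnitudes, partial R^2
(variance explained by one dummy with the others held fixed), the multiple
(all-dummy) effect, and permutation p-values, and exports them as PLY heat
maps (two-colour significance maps threshold at p < 0.001).

A small statsmodels-flavoured wrapper, :class:`CategoryShapeModel`, bundles
the pipeline: ``CategoryShapeModel(shapes, labels).fit()`` returns a
:class:`CategoryShapeResults` with the estimates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .mesh import MeshError, TriMesh, save_mesh

__all__ = [
    "DummyMatrix",
    "EffectMap",
    "dummy_encode",
    "plsr_fit",
    "effect_maps",
    "permutation_significance",
    "export_heatmap",
    "CategoryShapeModel",
    "CategoryShapeResults",
]


@dataclass
class DummyMatrix:
    """0/1 indicators for the C-1 non-reference categories."""

    values: np.ndarray
    reference: object
    categories: list

    @property
    def n_dummies(self) -> int:
        return self.values.shape[1]


def dummy_encode(labels) -> DummyMatrix:
    """Encode categorical labels as C-1 dummies (reference = first sorted)."""
    labels = np.asarray(labels)
    categories = sorted(set(labels.tolist()))
    if len(categories) < 2:
        raise MeshError("dummy_encode needs >= 2 categories")
    reference = categories[0]
    cols = [np.asarray(labels == c, dtype=float) for c in categories[1:]]
    return DummyMatrix(np.column_stack(cols), reference, categories)


def _as_matrix(Y) -> np.ndarray:
    return Y.values if isinstance(Y, DummyMatrix) else np.asarray(Y, dtype=float)


def plsr_fit(Y, X, n_components: int | None = None) -> np.ndarray:
    """PLSR of shape (responses X, n x 3V) on dummies (predictors Y).

    Returns coefficients of shape (n_dummies, V, 3): per-vertex displacement
    in mm per unit of each dummy.  ``n_components`` defaults to
    min(n_dummies, 10, n - 1), which makes the fit full-rank (equivalent to
    least squares) for the few-category designs used here.
    """
    Yv = _as_matrix(Y)
    X = np.asarray(X, dtype=float)
    n, q = Yv.shape
    if X.shape[0] != n:
        raise MeshError("X and Y row counts differ")
    if X.shape[1] % 3 != 0:
        raise MeshError("shape matrix width must be 3V")
    if np.linalg.matrix_rank(Yv - Yv.mean(axis=0)) < q:
        raise MeshError("rank-deficient dummy matrix (duplicate columns?)")
    if n_components is None:
        n_components = min(q, 10, n - 1)
    if n < n_components + 1:
        raise MeshError("need n >= n_components + 1 samples")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Yv, X)
    coef = np.asarray(pls.coef_)  # (3V, q) in sklearn >= 1.1
    if coef.shape == (q, X.shape[1]):
        coef = coef.T
    V = X.shape[1] // 3
    return coef.T.reshape(q, V, 3)


@dataclass
class EffectMap:
    """Per-vertex effect summaries of the fitted category model."""

    magnitude: np.ndarray            # (q, V) mm per unit dummy
    partial_r2: np.ndarray           # (q, V) in [0, 1]
    multiple_magnitude: np.ndarray   # (V,) joint effect size
    multiple_r2: np.ndarray          # (V,) in [0, 1]
    p_values: np.ndarray | None = None          # (V,) multiple-effect p
    dummy_p_values: np.ndarray | None = None    # (q, V) per-dummy p
    categories: list = field(default_factory=list)


def _per_vertex_r2(Xc, Yc):
    """R^2 per vertex of the least-squares fit of Xc (n x 3V) on Yc (n x q)."""
    Q, _ = np.linalg.qr(Yc)
    proj = Q.T @ Xc
    ss_model_cols = (proj**2).sum(axis=0)
    ss_total_cols = (Xc**2).sum(axis=0)
    V = Xc.shape[1] // 3
    ss_model = ss_model_cols.reshape(V, 3).sum(axis=1)
    ss_total = ss_total_cols.reshape(V, 3).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, ss_model / ss_total, 0.0)
    return np.clip(r2, 0.0, 1.0)


def effect_maps(coefficients, X, Y) -> EffectMap:
    """Per-dummy magnitude and partial R^2 plus the joint (multiple) effect."""
    coefficients = np.asarray(coefficients, dtype=float)
    q, V, _ = coefficients.shape
    X = np.asarray(X, dtype=float)
    Yv = _as_matrix(Y)
    Xc = X - X.mean(axis=0)
    Yc = Yv - Yv.mean(axis=0)

    magnitude = np.linalg.norm(coefficients, axis=2)
    multiple_magnitude = np.sqrt((magnitude**2).sum(axis=0))
    multiple_r2 = _per_vertex_r2(Xc, Yc)

    partial = np.zeros((q, V))
    ss_full = _residual_ss(Xc, Yc)
    for j in range(q):
        reduced = np.delete(Yc, j, axis=1)
        if reduced.shape[1] == 0:
            ss_red = (Xc**2).reshape(len(X), V, 3).sum(axis=(0, 2))
        else:
            ss_red = _residual_ss(Xc, reduced)
        with np.errstate(invalid="ignore", divide="ignore"):
            pr2 = np.where(ss_red > 0, (ss_red - ss_full) / ss_red, 0.0)
        partial[j] = np.clip(pr2, 0.0, 1.0)
    cats = Y.categories[1:] if isinstance(Y, DummyMatrix) else list(range(q))
    return EffectMap(
        magnitude=magnitude,
        partial_r2=partial,
        multiple_magnitude=multiple_magnitude,
        multiple_r2=multiple_r2,
        categories=cats,
    )


def _residual_ss(Xc, Yc):
    Q, _ = np.linalg.qr(Yc)
    resid = Xc - Q @ (Q.T @ Xc)
    V = Xc.shape[1] // 3
    return (resid**2).sum(axis=0).reshape(V, 3).sum(axis=1)


def permutation_significance(
    X,
    Y,
    n_permutations: int = 1000,
    rng=0,
    per_dummy: bool = False,
):
    """Permutation p-values of the per-vertex R^2 statistic.

    Rows of Y are permuted jointly; the empirical one-sided p-value is
    (1 + #{permuted statistic >= observed}) / (n_permutations + 1), so the
    smallest attainable p is 1/(n_permutations + 1).  With ``per_dummy`` the
    same scheme is applied to each dummy's partial R^2 and a (q, V) array is
    returned alongside the multiple-effect p-values.
    """
    if n_permutations < 1:
        raise MeshError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    Yv = _as_matrix(Y)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Xc = X - X.mean(axis=0)
    Yc = Yv - Yv.mean(axis=0)
    n, q = Yc.shape
    V = X.shape[1] // 3

    obs = _per_vertex_r2(Xc, Yc)
    exceed = np.ones(V)  # the +1 of the add-one estimator
    if per_dummy:
        obs_partial = _observed_partials(Xc, Yc)
        exceed_partial = np.ones((q, V))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Yp = Yc[perm]
        exceed += _per_vertex_r2(Xc, Yp) >= obs
        if per_dummy:
            exceed_partial += _observed_partials(Xc, Yp) >= obs_partial
    p = exceed / (n_permutations + 1)
    if per_dummy:
        return p, exceed_partial / (n_permutations + 1)
    return p


def _observed_partials(Xc, Yc):
    q = Yc.shape[1]
    V = Xc.shape[1] // 3
    ss_full = _residual_ss(Xc, Yc)
    out = np.zeros((q, V))
    for j in range(q):
        reduced = np.delete(Yc, j, axis=1)
        if reduced.shape[1] == 0:
            ss_red = (Xc**2).sum(axis=0).reshape(V, 3).sum(axis=1)
        else:
            ss_red = _residual_ss(Xc, reduced)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[j] = np.where(ss_red > 0, (ss_red - ss_full) / ss_red, 0.0)
    return out


_SIG_THRESHOLD = 1e-3
_YELLOW = np.array([255, 255, 0], dtype=np.uint8)
_GREEN = np.array([0, 160, 0], dtype=np.uint8)


def export_heatmap(
    mesh: TriMesh,
    emap: EffectMap,
    layer: str,
    path,
    dummy: int | None = None,
) -> None:
    """Write an effect layer as a PLY heat map.

    ``magnitude`` and ``r2`` layers export the continuous value as the vertex
    quality plus a colour ramp; ``significance`` writes the two-colour map
    (yellow where p < 0.001, green otherwise).  ``dummy=None`` selects the
    multiple (all-dummy) effect.
    """
    if layer == "magnitude":
        values = emap.multiple_magnitude if dummy is None else emap.magnitude[dummy]
    elif layer == "r2":
        values = emap.multiple_r2 if dummy is None else emap.partial_r2[dummy]
    elif layer == "significance":
        if dummy is None:
            if emap.p_values is None:
                raise MeshError("no p-values on this EffectMap; run the permutation test")
            values = emap.p_values
        else:
            if emap.dummy_p_values is None:
                raise MeshError("no per-dummy p-values; run the permutation test with per_dummy")
            values = emap.dummy_p_values[dummy]
    else:
        raise MeshError(f"unknown layer {layer!r}")
    values = np.asarray(values, dtype=float)
    if len(values) != mesh.n_vertices:
        raise MeshError("effect map vertex count differs from the mesh")
    if layer == "significance":
        colors = np.where(
            (values < _SIG_THRESHOLD)[:, None], _YELLOW[None, :], _GREEN[None, :]
        ).astype(np.uint8)
    else:
        from matplotlib import cm

        lo, hi = float(values.min()), float(values.max())
        t = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
        colors = (np.asarray(cm.viridis(t))[:, :3] * 255).astype(np.uint8)
    save_mesh(mesh, path, format="ply", vertex_scalars=values, vertex_colors=colors)


# ---------------------------------------------------------------------------
# Model / Results wrapper
# ---------------------------------------------------------------------------


class CategoryShapeModel:
    """PLSR model of dense mesh shape against trait categories.

    Parameters
    ----------
    shapes : (n, 3V) or (n, V, 3) array
        Vertex coordinates of n meshes sharing the template topology.
    labels : length-n sequence
        Category label of each mesh.
    """

    def __init__(self, shapes, labels):
        shapes = np.asarray(shapes, dtype=float)
        if shapes.ndim == 3:
            shapes = shapes.reshape(len(shapes), -1)
        self.shapes = shapes
        self.labels = np.asarray(labels)
        if len(self.labels) != len(self.shapes):
            raise MeshError("labels and shapes disagree in length")
        self.dummies = dummy_encode(self.labels)

    @classmethod
    def from_meshes(cls, meshes, labels):
        shapes = np.stack([m.vertices.reshape(-1) for m in meshes])
        return cls(shapes, labels)

    def fit(self, n_components: int | None = None) -> "CategoryShapeResults":
        coef = plsr_fit(self.dummies, self.shapes, n_components=n_components)
        emap = effect_maps(coef, self.shapes, self.dummies)
        return CategoryShapeResults(self, coef, emap)


class CategoryShapeResults:
    """Fitted category-effect estimates with permutation inference."""

    def __init__(self, model, coefficients, emap):
        self.model = model
        self.coefficients = coefficients
        self.effects = emap

    def permutation_test(self, n_permutations: int = 1000, rng=0, per_dummy=False):
        res = permutation_significance(
            self.model.shapes,
            self.model.dummies,
            n_permutations=n_permutations,
            rng=rng,
            per_dummy=per_dummy,
        )
        if per_dummy:
            self.effects.p_values, self.effects.dummy_p_values = res
        else:
            self.effects.p_values = res
        return self.effects.p_values

    def summary(self) -> str:
        e = self.effects
        lines = [
            "Category shape effects (PLSR on dummy-encoded labels)",
            f"  n meshes: {len(self.model.shapes)}   "
            f"vertices: {self.model.shapes.shape[1] // 3}   "
            f"dummies: {self.model.dummies.n_dummies} "
            f"(reference: {self.model.dummies.reference!r})",
            "",
            f"{'dummy':>12} {'max |coef| (mm)':>16} {'max partial R2':>15}",
        ]
        for j, cat in enumerate(e.categories):
            lines.append(
                f"{str(cat):>12} {e.magnitude[j].max():>16.3f} "
                f"{e.partial_r2[j].max():>15.3f}"
            )
        lines.append(
            f"{'multiple':>12} {e.multiple_magnitude.max():>16.3f} "
            f"{e.multiple_r2.max():>15.3f}"
        )
        if e.p_values is not None:
            sig = float(np.mean(e.p_values < _SIG_THRESHOLD))
            lines.append(
                f"\n  vertices with multiple-effect p < 0.001: {100 * sig:.1f}%"
            )
        return "\n".join(lines)
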