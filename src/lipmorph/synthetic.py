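"""Synthetic oracle surfaces and parametric lip-patch cohorts.

Real clinical facial scans are access-restricted, so this module supplies two
kinds of stand-ins, both labelled synthetic:

* analytic surfaces (plane, sphere, cylinder, saddle) with closed-form
  principal curvatures, used as oracles for the curvature and geodesic
  estimators;
* parametric lip-region patches (~80 x 60 mm) whose category-dependent relief
  (philtrum groove depth/width, Cupid's-bow ridge, lower-lip bulge) is built
  from smooth windowed bumps that vanish, with their first derivatives, at
  every landmark position.  Landmark coordinates are therefore identical in
  expectation across categories, so inter-landmark Euclidean distances carry
  no category signal by construction — the category signal lives purely in
  surface curvature (and, weakly, in geodesic arc length).

Sign convention for curvatures: convex toward the outward surface normal is
positive (an outward-oriented sphere has k1 = k2 = +1/r).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import trimesh as _trimesh

from .mesh import LandmarkSet, MeshError, Template, TriMesh

__all__ = [
    "SyntheticConfig",
    "analytic_surface",
    "lip_patch",
    "cohort",
    "synthetic_template",
]


# ---------------------------------------------------------------------------
# Grid helper
# ---------------------------------------------------------------------------


def _grid_mesh(xs, ys, zfun, mesh_id="grid"):
    """Row-major triangulated height-field grid with consistent diagonals.

    Face winding gives normals along +z for a flat field.
    """
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = zfun(X, Y)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = i * ny + (j + 1)
            v10 = (i + 1) * ny + j
            v11 = (i + 1) * ny + (j + 1)
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return TriMesh(vertices, np.array(faces, dtype=np.int64), id=mesh_id)


# ---------------------------------------------------------------------------
# Analytic oracle surfaces
# ---------------------------------------------------------------------------


def analytic_surface(kind: str, size: float = 10.0, resolution: int = 20):
    """An analytic surface mesh plus its closed-form principal curvatures.

    Returns ``(mesh, curvature_fn)`` where ``curvature_fn(points) -> (k1, k2)``
    evaluates the exact curvatures at arbitrary surface points.  ``resolution``
    is the vertex count per side for the grid-based kinds and the icosphere
    subdivision level for the sphere.
    """
    if resolution < 3:
        raise MeshError("resolution must be >= 3")
    if kind == "plane":
        xs = np.linspace(0.0, size, resolution)
        mesh = _grid_mesh(xs, xs, lambda X, Y: np.zeros_like(X), "plane")

        def fn(points):
            n = len(np.atleast_2d(points))
            return np.zeros(n), np.zeros(n)

        return mesh, fn
    if kind == "sphere":
        r = size
        level = min(int(resolution), 7)
        tm = _trimesh.creation.icosphere(subdivisions=level, radius=r)
        mesh = TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), id="sphere")

        def fn(points):
            n = len(np.atleast_2d(points))
            return np.full(n, 1.0 / r), np.full(n, 1.0 / r)

        return mesh, fn
    if kind == "cylinder":
        r = size
        height = 4.0 * size
        thetas = np.linspace(0, 2 * np.pi, 4 * resolution, endpoint=False)
        zs = np.linspace(0, height, resolution)
        nt, nz = len(thetas), len(zs)
        T, Z = np.meshgrid(thetas, zs, indexing="ij")
        vertices = np.column_stack(
            [r * np.cos(T).ravel(), r * np.sin(T).ravel(), Z.ravel()]
        )
        faces = []
        for i in range(nt):
            i2 = (i + 1) % nt
            for j in range(nz - 1):
                v00 = i * nz + j
                v01 = i * nz + (j + 1)
                v10 = i2 * nz + j
                v11 = i2 * nz + (j + 1)
                faces.append([v00, v10, v11])
                faces.append([v00, v11, v01])
        mesh = TriMesh(vertices, np.array(faces, np.int64), id="cylinder")

        def fn(points):
            n = len(np.atleast_2d(points))
            return np.full(n, 1.0 / r), np.zeros(n)

        return mesh, fn
    if kind == "saddle":
        half = size / 2.0
        xs = np.linspace(-half, half, resolution)
        mesh = _grid_mesh(xs, xs, lambda X, Y: X * Y, "saddle")

        def fn(points):
            points = np.atleast_2d(np.asarray(points, dtype=float))
            x, y = points[:, 0], points[:, 1]
            w = 1.0 + x**2 + y**2
            H = x * y / w**1.5
            K = -1.0 / w**2
            root = np.sqrt(np.maximum(H**2 - K, 0.0))
            return H + root, H - root

        return mesh, fn
    raise MeshError(f"unsupported analytic surface kind {kind!r}")


# ---------------------------------------------------------------------------
# Lip patches
# ---------------------------------------------------------------------------

# landmark layout (x, y) on the patch, mm; sn at top centre, pg at the chin
_LANDMARK_XY = {
    "sn": (0.0, 24.0),
    "ls": (0.0, 8.0),
    "li": (0.0, -8.0),
    "cphL": (-7.0, 10.0),
    "cphR": (7.0, 10.0),
    "chL": (-26.0, -2.0),
    "chR": (26.0, -2.0),
    "pg": (0.0, -26.0),
}

_PATCH_X = 40.0  # half-width, mm
_PATCH_Y = 30.0  # half-height, mm


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic lip-trait cohort.

    ``category_params`` is a list (one dict per category) with keys
    ``groove_depth``, ``groove_width``, ``bow_amplitude``, ``bulge_height``
    (all mm); when omitted, defaults varying the trait-relevant parameter are
    generated.  ``resolution`` is the vertex count across the patch width.
    """

    trait: str = "philtrum"
    n_categories: int = 3
    n_per_category: int = 30
    resolution: int = 100
    noise_sigma: float = 0.08
    jitter_sigma: float = 0.0
    individual_sigma: float = 1.0
    seed: int = 0
    category_params: list | None = None

    def __post_init__(self):
        if self.noise_sigma < 0 or self.jitter_sigma < 0:
            raise MeshError("noise/jitter sigma must be >= 0")
        if self.n_per_category < 1 or self.n_categories < 1:
            raise MeshError("need >= 1 category and >= 1 mesh per category")
        if self.category_params is None:
            self.category_params = _default_category_params(
                self.trait, self.n_categories
            )
        if len(self.category_params) != self.n_categories:
            raise MeshError("one parameter set per category required")
        seen = {tuple(sorted(p.items())) for p in self.category_params}
        if len(seen) != self.n_categories:
            raise MeshError("category parameter vectors must be pairwise distinct")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _default_category_params(trait: str, n_categories: int) -> list:
    """Per-category relief parameters spanning the trait's clinical spectrum.

    The philtrum spectrum runs from a deep groove (positive depth) through a
    shallow groove to a convex, prominent philtrum (negative depth), so the
    categories differ strongly in surface curvature while their geodesic arc
    lengths — which grow with depth^2 regardless of sign — overlap heavily.
    """
    params = []
    for c in range(n_categories):
        p = {
            "groove_depth": 2.0,
            "groove_width": 4.5,
            "bow_amplitude": 1.2,
            "bulge_height": 0.6,
        }
        f = c / max(n_categories - 1, 1)
        if trait == "philtrum":
            p["groove_depth"] = 3.5 - 7.0 * f
            if abs(p["groove_depth"]) < 0.4:  # keep parameter vectors distinct
                p["groove_depth"] = 0.8
        elif trait in ("cupids_bow", "upper_lip_contour"):
            p["bow_amplitude"] = 0.4 + 2.2 * f
        else:  # lower_lip_contour, lip_chin, lower_lip_tone
            p["bulge_height"] = 0.4 + 2.0 * f
        params.append(p)
    return params


def _landmark_mask(X, Y, r0=1.5, r1=3.0):
    """Smoothstep factor that is 0 within r0 mm of every landmark, 1 beyond r1.

    Multiplying the category relief by this mask keeps the surface (and hence
    each landmark's position and its local projection facet) identical across
    categories in a whole neighbourhood of every landmark, so inter-landmark
    Euclidean distances carry no category signal even on a discretised mesh.
    """
    m = np.ones_like(X, dtype=float)
    for lx, ly in _LANDMARK_XY.values():
        rho = np.sqrt((X - lx) ** 2 + (Y - ly) ** 2)
        t = np.clip((rho - r0) / (r1 - r0), 0.0, 1.0)
        m = m * (t * t * (3.0 - 2.0 * t))
    return m


def _patch_height(X, Y, params):
    """Analytic patch height: smooth dome plus windowed category relief.

    Every relief term is masked to vanish in a disk around each landmark
    (see :func:`_landmark_mask`).
    """
    Z = 6.0 * np.exp(-(X**2) / 1400.0 - (Y**2) / 900.0)
    relief = np.zeros_like(Z)
    d, w = params["groove_depth"], params["groove_width"]
    a, h = params["bow_amplitude"], params["bulge_height"]
    # philtrum groove between ls (y=8) and sn (y=24), confined to |x| < 7
    gx = np.where(
        np.abs(X) < 7.0,
        np.cos(np.pi * X / 14.0) ** 2 * np.exp(-(X**2) / (2.0 * w**2)),
        0.0,
    )
    gy = np.where(
        (Y > 8.0) & (Y < 24.0), np.sin(np.pi * (Y - 8.0) / 16.0) ** 2, 0.0
    )
    relief = relief - d * gx * gy
    # Cupid's-bow ridge between the philtrum crests, above ls
    bx = np.where(np.abs(X) < 7.0, np.sin(np.pi * (X + 7.0) / 14.0) ** 2, 0.0)
    by = np.where(
        (Y > 9.0) & (Y < 13.0), np.sin(np.pi * (Y - 9.0) / 4.0) ** 2, 0.0
    )
    relief = relief + a * bx * by
    # lower-lip / mentolabial bulge between li (y=-8) and the chin
    ux = np.where(np.abs(X) < 12.0, np.cos(np.pi * X / 24.0) ** 2, 0.0)
    uy = np.where(
        (Y > -20.0) & (Y < -8.0), np.sin(np.pi * (Y + 20.0) / 12.0) ** 2, 0.0
    )
    relief = relief + h * ux * uy
    return Z + _landmark_mask(X, Y) * relief


_LF_MODES = ((1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (1, -1))


def _individual_field(rng, amplitude):
    """Per-mesh smooth low-frequency shape variation (category-independent).

    A random combination of long-wavelength cosine modes over the patch,
    standing in for the between-individual facial variability of a real
    cohort; RMS height ~= ``amplitude`` mm and wavelengths >= ~30 mm, so it
    survives denoising yet contributes negligible curvature.
    """
    k = len(_LF_MODES)
    coeffs = rng.normal(0.0, amplitude, size=k) / np.sqrt(k / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)

    def field(X, Y):
        Z = np.zeros(np.broadcast(X, Y).shape, dtype=float)
        for c, (i, j), ph in zip(coeffs, _LF_MODES, phases):
            Z = Z + c * np.cos(
                np.pi * (i * X / _PATCH_X + j * Y / _PATCH_Y) + ph
            )
        return Z

    return field


def lip_patch(config: SyntheticConfig, category: int, rng=None):
    """One synthetic lip patch: ``(TriMesh, LandmarkSet, label)``."""
    if not 0 <= category < config.n_categories:
        raise MeshError(f"invalid category index {category}")
    rng = np.random.default_rng(
        config.seed if rng is None else rng
    ) if not isinstance(rng, np.random.Generator) else rng
    params = config.category_params[category]
    nx = config.resolution
    ny = max(3, int(round(nx * _PATCH_Y / _PATCH_X)))
    xs = np.linspace(-_PATCH_X, _PATCH_X, nx)
    ys = np.linspace(-_PATCH_Y, _PATCH_Y, ny)
    if config.individual_sigma > 0:
        lf = _individual_field(rng, config.individual_sigma)
    else:
        lf = lambda X, Y: np.zeros(np.broadcast(X, Y).shape)  # noqa: E731
    mesh = _grid_mesh(xs, ys, lambda X, Y: _patch_height(X, Y, params) + lf(X, Y),
                      mesh_id=f"patch_c{category}")
    if config.noise_sigma > 0:
        noise = rng.normal(0.0, config.noise_sigma, mesh.n_vertices)
        mesh = TriMesh(
            mesh.vertices + np.column_stack([np.zeros((mesh.n_vertices, 2)), noise]),
            mesh.faces,
            id=mesh.id,
        )
    points = {}
    for name, (lx, ly) in _LANDMARK_XY.items():
        lz = float(
            _patch_height(np.array([[lx]]), np.array([[ly]]), params)[0, 0]
            + lf(np.array([[lx]]), np.array([[ly]]))[0, 0]
        )
        p = np.array([lx, ly, lz])
        if config.jitter_sigma > 0:
            p = p + rng.normal(0.0, config.jitter_sigma, 3)
        points[name] = p
    landmarks = LandmarkSet.from_points(points, mesh, snap_tolerance=3.0)
    return mesh, landmarks, category


def cohort(config: SyntheticConfig):
    """A full labelled cohort: ``(list of (mesh, landmarks), labels)``."""
    rng = np.random.default_rng(config.seed)
    items, labels = [], []
    for c in range(config.n_categories):
        for i in range(config.n_per_category):
            mesh, lm, label = lip_patch(config, c, rng=rng)
            mesh.id = f"c{c}_{i:03d}"
            items.append((mesh, lm))
            labels.append(label)
    return items, np.array(labels)


def synthetic_template(nx: int = 110, ny: int = 65) -> Template:
    """Noise-free mid-parameter patch as the regularisation template.

    The default grid is 110 x 65 = 7150 vertices, the fixed topology every
    scan is resampled onto.
    """
    params = {
        "groove_depth": 2.0,
        "groove_width": 4.0,
        "bow_amplitude": 0.8,
        "bulge_height": 0.6,
    }
    xs = np.linspace(-_PATCH_X, _PATCH_X, nx)
    ys = np.linspace(-_PATCH_Y, _PATCH_Y, ny)
    mesh = _grid_mesh(xs, ys, lambda X, Y: _patch_height(X, Y, params),
                      mesh_id="template")
    points = {}
    for name, (lx, ly) in _LANDMARK_XY.items():
        lz = float(_patch_height(np.array([[lx]]), np.array([[ly]]), params)[0, 0])
        points[name] = np.array([lx, ly, lz])
    landmarks = LandmarkSet.from_points(points, mesh, snap_tolerance=3.0)
    return Template(mesh, landmarks)
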