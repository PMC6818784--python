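"""Triangle-mesh and landmark handling for lip-region morphometrics.

Meshes are triangulated facial surfaces with coordinates in millimetres.
Landmarks are the eight soft-tissue points of the lip region (subnasale ``sn``,
labiale superius ``ls``, labiale inferius ``li``, crista philtri ``cphL``/``cphR``,
cheilion ``chL``/``chR`` and pogonion ``pg``), each snapped to its nearest mesh
vertex.  The module also provides light preprocessing: volume-preserving
Laplacian (Taubin-style) smoothing, a landmark-based canonical pose, and
resampling of a scan onto a fixed-topology template so that all meshes share
vertex correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy.spatial import cKDTree

LANDMARK_NAMES = ("sn", "ls", "li", "cphL", "cphR", "chL", "chR", "pg")

__all__ = [
    "LANDMARK_NAMES",
    "TriMesh",
    "LandmarkSet",
    "Template",
    "MeshError",
    "load_mesh",
    "save_mesh",
    "load_vertex_scalars",
    "load_landmarks",
    "smooth_mesh",
    "align_pose",
    "regularise_to_template",
]


class MeshError(ValueError):
    """Raised on malformed meshes, landmark files or preprocessing inputs."""


@dataclass
class TriMesh:
    """A triangulated surface: ``vertices`` (n, 3) in mm, ``faces`` (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) index array")
        if len(self.faces) < 1:
            raise MeshError("mesh has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshError("face with repeated vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def edges_unique(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def boundary_vertices(self) -> np.ndarray:
        """Indices of vertices lying on an open boundary edge."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])

    def volume_proxy(self) -> float:
        """Sum of signed tetrahedron volumes against the origin.

        For closed surfaces this is the enclosed volume; for open patches it
        serves as the drift proxy used by :func:`smooth_mesh`.
        """
        v0 = self.vertices[self.faces[:, 0]]
        v1 = self.vertices[self.faces[:, 1]]
        v2 = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


@dataclass
class LandmarkSet:
    """Named anatomical points bound to mesh vertices.

    ``entries`` maps a landmark name to ``(point, vertex_index)`` where point is
    the (possibly off-vertex) annotated position and vertex_index its nearest
    mesh vertex.
    """

    entries: dict = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def names(self):
        return list(self.entries)

    def point(self, name: str) -> np.ndarray:
        if name not in self.entries:
            raise MeshError(f"unknown landmark {name!r}")
        return np.asarray(self.entries[name][0], dtype=float)

    def vertex(self, name: str) -> int:
        if name not in self.entries:
            raise MeshError(f"unknown landmark {name!r}")
        return int(self.entries[name][1])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(
            {k: (np.asarray(p) @ R.T + t, v) for k, (p, v) in self.entries.items()}
        )

    @classmethod
    def from_points(
        cls, points: dict, mesh: TriMesh, snap_tolerance: float = 2.0
    ) -> "LandmarkSet":
        """Bind named points to their nearest mesh vertices.

        Raises on unknown names, duplicates (dict keys are unique already) and
        on points farther than ``snap_tolerance`` mm from the surface vertices.
        """
        tree = cKDTree(mesh.vertices)
        entries = {}
        for name, p in points.items():
            if name not in LANDMARK_NAMES:
                raise MeshError(f"unknown landmark name {name!r}")
            p = np.asarray(p, dtype=float).reshape(3)
            d, idx = tree.query(p)
            if d > snap_tolerance:
                raise MeshError(
                    f"landmark {name!r} lies {d:.2f} mm from the mesh "
                    f"(snap tolerance {snap_tolerance} mm)"
                )
            entries[name] = (p, int(idx))
        return cls(entries)


@dataclass
class Template:
    """Fixed-topology reference mesh with its own landmarks."""

    mesh: TriMesh
    landmarks: LandmarkSet

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_obj(path):
    vertices, faces = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                if len(idx) != 3:
                    raise MeshError(
                        "non-triangular face in OBJ file; triangulate first"
                    )
                faces.append([i - 1 if i > 0 else len(vertices) + i for i in idx])
    if not vertices or not faces:
        raise MeshError(f"empty or unreadable OBJ file: {path}")
    return np.array(vertices, float), np.array(faces, np.int64), None


def _read_ply(path):
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"ply"):
        raise MeshError(f"not a PLY file: {path}")
    header_end = raw.find(b"end_header\n")
    if header_end < 0:
        raise MeshError("malformed PLY header")
    header = raw[:header_end].decode("ascii", "replace").splitlines()
    fmt = next((l.split()[1] for l in header if l.startswith("format")), "ascii")
    if fmt != "ascii":
        tm = _trimesh.load(str(path), file_type="ply", process=False)
        if tm.faces.shape[1] != 3:
            raise MeshError("non-triangular face in PLY file; triangulate first")
        return np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64), None

    n_vert = n_face = 0
    props = []
    current = None
    for line in header:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "element":
            current = parts[1]
            if current == "vertex":
                n_vert = int(parts[2])
            elif current == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and current == "vertex" and parts[1] != "list":
            props.append(parts[2])
    body = raw[header_end + len(b"end_header\n"):].decode("ascii").split("\n")
    vert_rows = [body[i].split() for i in range(n_vert)]
    table = np.array(vert_rows, dtype=float)
    xyz = table[:, [props.index("x"), props.index("y"), props.index("z")]]
    scalars = None
    if "quality" in props:
        scalars = table[:, props.index("quality")]
    faces = []
    for i in range(n_vert, n_vert + n_face):
        row = body[i].split()
        cnt = int(row[0])
        if cnt != 3:
            raise MeshError("non-triangular face in PLY file; triangulate first")
        faces.append([int(x) for x in row[1:4]])
    if n_face == 0:
        raise MeshError(f"empty mesh in PLY file: {path}")
    return xyz, np.array(faces, np.int64), scalars


def load_mesh(path, format: str | None = None) -> TriMesh:
    """Read an OBJ or ascii/binary PLY file into a :class:`TriMesh`.

    Non-triangular faces raise :class:`MeshError` ("triangulate first") rather
    than being triangulated silently.
    """
    path = str(path)
    fmt = (format or path.rsplit(".", 1)[-1]).lower()
    if fmt == "obj":
        vertices, faces, _ = _read_obj(path)
    elif fmt == "ply":
        vertices, faces, _ = _read_ply(path)
    else:
        raise MeshError(f"unsupported mesh format {fmt!r}")
    name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return TriMesh(vertices, faces, id=name)


def load_vertex_scalars(path) -> np.ndarray:
    """Read the per-vertex ``quality`` property back from an ascii PLY file."""
    _, _, scalars = _read_ply(str(path))
    if scalars is None:
        raise MeshError(f"no per-vertex quality property in {path}")
    return scalars


def save_mesh(
    mesh: TriMesh,
    path,
    format: str | None = None,
    vertex_scalars=None,
    vertex_colors=None,
) -> None:
    """Write OBJ or ascii PLY; scalars become the PLY ``quality`` property and
    colours uchar ``red``/``green``/``blue``."""
    path = str(path)
    fmt = (format or path.rsplit(".", 1)[-1]).lower()
    if vertex_scalars is not None:
        vertex_scalars = np.asarray(vertex_scalars, dtype=float).ravel()
        if len(vertex_scalars) != mesh.n_vertices:
            raise MeshError(
                f"vertex_scalars length {len(vertex_scalars)} != "
                f"vertex count {mesh.n_vertices}"
            )
    if vertex_colors is not None:
        vertex_colors = np.asarray(vertex_colors, dtype=np.uint8).reshape(-1, 3)
        if len(vertex_colors) != mesh.n_vertices:
            raise MeshError("vertex_colors length mismatch")
    if fmt == "obj":
        if vertex_scalars is not None or vertex_colors is not None:
            raise MeshError("per-vertex scalars/colours require PLY output")
        with open(path, "w", encoding="utf-8") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif fmt == "ply":
        with open(path, "w", encoding="ascii") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            if vertex_scalars is not None:
                fh.write("property float quality\n")
            if vertex_colors is not None:
                fh.write(
                    "property uchar red\nproperty uchar green\nproperty uchar blue\n"
                )
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for i, v in enumerate(mesh.vertices):
                row = f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}"
                if vertex_scalars is not None:
                    row += f" {vertex_scalars[i]:.9g}"
                if vertex_colors is not None:
                    c = vertex_colors[i]
                    row += f" {c[0]} {c[1]} {c[2]}"
                fh.write(row + "\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise MeshError(f"unsupported mesh format {fmt!r}")


def load_landmarks(path, mesh: TriMesh, snap_tolerance: float = 2.0) -> LandmarkSet:
    """Read a ``name,x,y,z`` CSV and bind each landmark to its nearest vertex."""
    df = pd.read_csv(path)
    expected = {"name", "x", "y", "z"}
    if not expected.issubset(df.columns):
        raise MeshError(f"landmark CSV must have columns name,x,y,z (got {list(df.columns)})")
    if df["name"].duplicated().any():
        dup = df["name"][df["name"].duplicated()].iloc[0]
        raise MeshError(f"duplicate landmark name {dup!r}")
    points = {row["name"]: np.array([row.x, row.y, row.z]) for _, row in df.iterrows()}
    return LandmarkSet.from_points(points, mesh, snap_tolerance=snap_tolerance)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _uniform_adjacency(mesh: TriMesh):
    e = mesh.edges_unique()
    n = mesh.n_vertices
    from scipy.sparse import coo_matrix

    data = np.ones(2 * len(e))
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    return A, deg


def smooth_mesh(mesh: TriMesh, iterations: int, strength: float = 0.5) -> TriMesh:
    """Taubin-style two-step Laplacian smoothing with a volume-drift guard.

    Each iteration applies a uniform-weight Laplacian shrink step followed by an
    equal inflate step; boundary vertices are pinned.  Afterwards the mesh is
    rescaled about its centroid so the signed-volume proxy drifts by < 1 %.
    ``iterations=0`` returns the input unchanged.
    """
    if not (0.0 < strength <= 1.0):
        raise MeshError("strength must lie in (0, 1]")
    if iterations < 0:
        raise MeshError("iterations must be >= 0")
    if iterations == 0:
        return replace(mesh, vertices=mesh.vertices.copy(), faces=mesh.faces.copy())

    A, deg = _uniform_adjacency(mesh)
    interior = np.ones(mesh.n_vertices, dtype=bool)
    interior[mesh.boundary_vertices()] = False
    lam = 0.5 * strength
    v = mesh.vertices.copy()
    for _ in range(iterations):
        for step in (lam, -lam):
            mean = A @ v / deg[:, None]
            disp = mean - v
            v[interior] += step * disp[interior]
    out = TriMesh(v, mesh.faces.copy(), id=mesh.id)
    v0, v1 = mesh.volume_proxy(), out.volume_proxy()
    scale = float(np.ptp(mesh.vertices, axis=0).max())
    if abs(v0) > 1e-9 * scale**3 and v1 * v0 > 0:
        s = (v0 / v1) ** (1.0 / 3.0)
        centroid = out.vertices.mean(axis=0)
        out = TriMesh(centroid + (out.vertices - centroid) * s, out.faces, id=mesh.id)
    return out


def align_pose(mesh: TriMesh, landmarks: LandmarkSet):
    """Rigidly move the mesh into the canonical lip frame.

    Origin at subnasale ``sn``; the cheilion axis ``chL -> chR`` defines +x and
    the direction from the cheilion midpoint to ``sn`` defines +y (facial "up");
    +z completes a right-handed frame and points out of the face.
    """
    for name in ("sn", "chL", "chR"):
        if name not in landmarks:
            raise MeshError(f"align_pose requires landmark {name!r}")
    sn = landmarks.point("sn")
    chl, chr_ = landmarks.point("chL"), landmarks.point("chR")
    x = chr_ - chl
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise MeshError("degenerate frame: chL == chR")
    x = x / nx
    up = sn - 0.5 * (chl + chr_)
    up = up - x * (up @ x)
    nu = np.linalg.norm(up)
    if nu < 1e-9:
        raise MeshError("degenerate frame: sn collinear with cheilion axis")
    y = up / nu
    z = np.cross(x, y)
    R = np.vstack([x, y, z])  # world -> canonical
    new_vertices = (mesh.vertices - sn) @ R.T
    out = TriMesh(new_vertices, mesh.faces.copy(), id=mesh.id)
    lm = LandmarkSet(
        {k: ((np.asarray(p) - sn) @ R.T, v) for k, (p, v) in landmarks.entries.items()}
    )
    return out, lm


def _kabsch(src: np.ndarray, dst: np.ndarray):
    """Best rigid transform R, t with dst ~ src @ R.T + t."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - cs @ R.T
    return R, t


def regularise_to_template(
    mesh: TriMesh,
    landmarks: LandmarkSet,
    template: Template,
    k: int = 3,
    max_icp_iterations: int = 50,
    icp_tol: float = 1e-6,
) -> TriMesh:
    """Resample a scan onto the template topology.

    The template is rigidly registered to the mesh (landmark-initialised ICP,
    rigid only), then each registered template vertex is replaced by the
    inverse-distance-weighted mean of its ``k`` nearest scan vertices.  The
    output inherits the template's face list, giving dense correspondence
    across a sample.
    """
    if k < 1:
        raise MeshError("k must be >= 1")
    if k > mesh.n_vertices:
        raise MeshError("k larger than the input vertex count")
    common = [n for n in template.landmarks.names() if n in landmarks]
    if len(common) >= 3:
        src = np.array([template.landmarks.point(n) for n in common])
        dst = np.array([landmarks.point(n) for n in common])
        R, t = _kabsch(src, dst)
    else:
        R, t = np.eye(3), np.zeros(3)
    tverts = template.mesh.vertices @ R.T + t

    tree = cKDTree(mesh.vertices)
    prev_err = np.inf
    for _ in range(max_icp_iterations):
        d, idx = tree.query(tverts)
        err = float(d.mean())
        if prev_err - err < icp_tol:
            break
        R_step, t_step = _kabsch(tverts, mesh.vertices[idx])
        tverts = tverts @ R_step.T + t_step
        prev_err = err

    d, idx = tree.query(tverts, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    w = 1.0 / np.maximum(d, 1e-12)
    exact = d[:, 0] < 1e-12
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    new_vertices = np.einsum("nk,nkj->nj", w, mesh.vertices[idx])
    return TriMesh(new_vertices, template.mesh.faces.copy(), id=mesh.id)
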