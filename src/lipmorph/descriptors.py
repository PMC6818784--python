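"""Trait feature descriptors from geodesic paths and curvature fields.

Each morphological lip trait is defined by a fixed list of landmark-to-landmark
geodesic paths (the lower lip tone by a family of vertically offset paths).
Along every path the four curvature measures (M, Ga, C, Sh) are sampled at the
mesh vertices nearest the path points, histogram-normalised into b relative
frequencies each, and concatenated into a 4b-element block per path; the blocks
of all of a trait's paths form its geodesic-curvature (GC) descriptor.
Geodesic (GD) and straight-line Euclidean (ED) inter-landmark distances are
optional additional blocks, and a sample-level min-max scaling combines the
selected blocks into a classification matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .curvature import CurvatureField
from .geodesics import GeodesicPath, compute_path, lip_tone_paths
from .mesh import LandmarkSet, MeshError, TriMesh

__all__ = [
    "TraitDefinition",
    "TraitDescriptor",
    "TRAITS",
    "LEGAL_BINS",
    "histogram_normalise",
    "path_descriptor",
    "trait_paths",
    "trait_descriptor",
    "distance_features",
    "combine_and_scale",
    "save_features",
    "load_features",
]

LEGAL_BINS = (5, 10, 15, 20, 25)


@dataclass(frozen=True)
class TraitDefinition:
    """A named lip trait and the landmark pairs of its geodesic paths."""

    name: str
    path_specs: tuple
    lip_tone_family: bool = False

    @property
    def n_paths(self) -> int:
        return 5 if self.lip_tone_family else len(self.path_specs)


TRAITS = {
    "philtrum": TraitDefinition(
        "philtrum",
        (("sn", "cphL"), ("sn", "ls"), ("sn", "cphR"), ("cphL", "ls"), ("cphR", "ls")),
    ),
    "cupids_bow": TraitDefinition("cupids_bow", (("cphL", "ls"), ("ls", "cphR"))),
    "upper_lip_contour": TraitDefinition(
        "upper_lip_contour",
        (("chL", "cphL"), ("cphL", "ls"), ("ls", "cphR"), ("cphR", "chR")),
    ),
    "lower_lip_contour": TraitDefinition(
        "lower_lip_contour", (("chL", "li"), ("li", "chR"))
    ),
    "lip_chin": TraitDefinition("lip_chin", (("li", "pg"),)),
    "lower_lip_tone": TraitDefinition("lower_lip_tone", (), lip_tone_family=True),
}


@dataclass
class TraitDescriptor:
    """Fixed-length feature vector of one trait on one mesh."""

    mesh_id: str
    trait: str
    b: int
    gc: np.ndarray
    gd: np.ndarray | None = None
    ed: np.ndarray | None = None
    scaling: dict = field(default_factory=dict)


def histogram_normalise(values, b: int) -> np.ndarray:
    """Relative frequencies over b equal-width bins spanning [min, max].

    The rightmost edge is inclusive; a constant input puts all mass in the
    first bin.  The output always sums to one.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) == 0:
        raise MeshError("histogram_normalise: empty input")
    if b < 1:
        raise MeshError("histogram_normalise: b must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-300:
        out = np.zeros(b)
        out[0] = 1.0
        return out
    counts, _ = np.histogram(values, bins=b, range=(lo, hi))
    return counts / counts.sum()


def _path_sample_vertices(field: CurvatureField, path: GeodesicPath,
                          exclude_boundary: bool = True) -> np.ndarray:
    """Nearest mesh vertex of each path point, consecutive duplicates removed."""
    tree = cKDTree(field.vertices)
    _, idx = tree.query(path.points)
    idx = np.asarray(idx, dtype=int)
    keep = np.ones(len(idx), dtype=bool)
    keep[1:] = idx[1:] != idx[:-1]
    idx = idx[keep]
    if exclude_boundary and field.boundary is not None:
        interior = ~field.boundary[idx]
        if interior.any():
            idx = idx[interior]
    return idx


def path_descriptor(
    field: CurvatureField,
    path: GeodesicPath,
    b: int,
    exclude_boundary: bool = True,
) -> np.ndarray:
    """4b-element [M, Ga, C, Sh] histogram block for one path."""
    idx = _path_sample_vertices(field, path, exclude_boundary=exclude_boundary)
    if b > len(idx):
        raise MeshError(
            f"b={b} exceeds the number of distinct path sample vertices ({len(idx)})"
        )
    blocks = [
        histogram_normalise(field.M[idx], b),
        histogram_normalise(field.Ga[idx], b),
        histogram_normalise(field.C[idx], b),
        histogram_normalise(field.Sh[idx], b),
    ]
    return np.concatenate(blocks)


def trait_paths(
    mesh: TriMesh,
    landmarks: LandmarkSet,
    trait: TraitDefinition,
    method: str = "exact",
    n_tone_paths: int = 5,
    tone_spacing: float = 2.0,
) -> list:
    """The geodesic paths defining a trait, in definition order."""
    if trait.lip_tone_family:
        return lip_tone_paths(
            mesh, landmarks, n_paths=n_tone_paths, spacing=tone_spacing, method=method
        )
    paths = []
    for a, bname in trait.path_specs:
        for nm in (a, bname):
            if nm not in landmarks:
                raise MeshError(f"trait {trait.name!r} requires landmark {nm!r}")
        paths.append(compute_path(mesh, a, bname, method=method, landmarks=landmarks))
    return paths


def trait_descriptor(
    mesh: TriMesh,
    landmarks: LandmarkSet,
    field: CurvatureField,
    trait: TraitDefinition | str,
    b: int,
    method: str = "exact",
    with_distances: bool = True,
    paths: list | None = None,
) -> TraitDescriptor:
    """Full GC (+ GD/ED) descriptor of one trait on one mesh.

    ``paths`` may be supplied to avoid recomputing geodesics.
    """
    if isinstance(trait, str):
        trait = TRAITS[trait]
    if b not in LEGAL_BINS:
        raise MeshError(f"b must be one of {LEGAL_BINS}, got {b}")
    if paths is None:
        paths = trait_paths(mesh, landmarks, trait, method=method)
    gc = np.concatenate([path_descriptor(field, p, b) for p in paths])
    gd = ed = None
    if with_distances:
        ed, gd = distance_features(landmarks, trait, paths)
    return TraitDescriptor(mesh.id, trait.name, b, gc, gd=gd, ed=ed)


def distance_features(
    landmarks: LandmarkSet, trait: TraitDefinition | str, paths: list
):
    """(ED, GD): straight-line endpoint distances and geodesic path lengths.

    ED is the Euclidean distance between the two on-surface path endpoints
    (the landmark positions as realised on the mesh), which keeps GD >= ED an
    exact identity; GD is the geodesic polyline length.  Both follow the
    trait's path order.
    """
    if isinstance(trait, str):
        trait = TRAITS[trait]
    if not trait.lip_tone_family:
        for a, b in trait.path_specs:
            for nm in (a, b):
                if nm not in landmarks:
                    raise MeshError(f"missing landmark {nm!r}")
    if trait.n_paths != len(paths):
        raise MeshError(
            f"trait {trait.name!r} expects {trait.n_paths} paths, got {len(paths)}"
        )
    gd = np.array([p.length for p in paths])
    ed = np.array([np.linalg.norm(p.points[-1] - p.points[0]) for p in paths])
    return ed, gd


def combine_and_scale(
    descriptors: list,
    selection=("GC", "GD", "ED"),
) -> np.ndarray:
    """Stack selected blocks over a sample and min-max scale each column to [0, 1].

    Columns are ordered GC, GD, ED; constant columns map to zero.
    """
    if len(descriptors) < 2:
        raise MeshError("combine_and_scale needs at least 2 descriptors")
    selection = [s.upper() for s in selection]
    rows = []
    for d in descriptors:
        parts = []
        for s in selection:
            block = {"GC": d.gc, "GD": d.gd, "ED": d.ed}[s]
            if block is None:
                raise MeshError(f"descriptor for {d.mesh_id!r} lacks block {s}")
            parts.append(np.asarray(block, dtype=float).ravel())
        rows.append(np.concatenate(parts))
    dims = {len(r) for r in rows}
    if len(dims) != 1:
        raise MeshError("inconsistent descriptor dimensions across the sample")
    X = np.vstack(rows)
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    scaled = np.where(rng > 0, (X - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return scaled


def save_features(path, descriptors: list, block: str = "GC") -> None:
    """Write one block of a descriptor sample as a feature-table CSV."""
    rows = []
    for d in descriptors:
        vec = {"GC": d.gc, "GD": d.gd, "ED": d.ed}[block.upper()]
        rows.append([d.mesh_id, d.trait, d.b] + list(np.asarray(vec).ravel()))
    k = len(rows[0]) - 3
    cols = ["mesh_id", "trait", "b"] + [f"feature_{i}" for i in range(k)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def load_features(path):
    """Read a feature-table CSV back as (mesh_ids, trait, b, matrix)."""
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("feature_")]
    return (
        df["mesh_id"].tolist(),
        df["trait"].iloc[0],
        int(df["b"].iloc[0]),
        df[feat_cols].to_numpy(dtype=float),
    )
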