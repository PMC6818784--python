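"""Geodesic paths and distances on triangle meshes.

Two path engines are provided.  The ``exact`` engine initialises with an
edge-graph Dijkstra route and then shortens it to a locally shortest geodesic
by exact unfolding: runs of edge-crossing points between anchor vertices are
solved in closed form by flattening the crossed face strip into the plane, and
anchor vertices whose one-sided unfolded wedge angle is below pi are shortcut
across the wedge.  Because every accepted move strictly shortens the polyline,
the result is never longer than the Dijkstra route, and on developable regions
(a plane, an unrolled strip) it is exact.  The ``fast_marching`` engine solves
the eikonal equation with a first-order triangle update and traces the path by
descent on the resulting distance field; it is cheaper on dense meshes but
first-order accurate.

Paths are polylines whose points sit wherever the geodesic crosses mesh edges
(not only at vertices); endpoints may be landmarks, vertex indices, or raw
points projected onto the surface.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra
from scipy.spatial import cKDTree

from .mesh import LandmarkSet, MeshError, TriMesh

__all__ = [
    "GeodesicPath",
    "compute_path",
    "polyline_path",
    "lip_tone_paths",
    "edge_dijkstra_length",
    "project_point",
]

_EPS = 1e-10
_T_EPS = 1e-9


@dataclass
class GeodesicPath:
    """Ordered on-surface polyline between two endpoints, with its length."""

    points: np.ndarray
    endpoints: tuple
    length: float
    method: str

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @staticmethod
    def from_points(points, endpoints, method) -> "GeodesicPath":
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        return GeodesicPath(points, endpoints, float(seg.sum()), method)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="x,y,z", comments="")


# ---------------------------------------------------------------------------
# Surface connectivity cache
# ---------------------------------------------------------------------------


class _Surface:
    def __init__(self, mesh: TriMesh):
        self.V = mesh.vertices
        self.F = mesh.faces
        self.edge_faces: dict = {}
        self.vertex_faces: dict = {}
        for fi, (a, b, c) in enumerate(self.F):
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                self.edge_faces.setdefault(key, []).append(fi)
            for u in (a, b, c):
                self.vertex_faces.setdefault(int(u), []).append(fi)
        edges = np.array(list(self.edge_faces), dtype=np.int64)
        w = np.linalg.norm(self.V[edges[:, 0]] - self.V[edges[:, 1]], axis=1)
        n = len(self.V)
        self.graph = coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([edges[:, 0], edges[:, 1]]),
              np.concatenate([edges[:, 1], edges[:, 0]]))),
            shape=(n, n),
        ).tocsr()
        self._tree = None

    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.V)
        return self._tree

    # ---- path-point helpers.  A point is ('v', i) | ('e', a, b, t) | ('f', fi, xyz)
    def position(self, pt) -> np.ndarray:
        kind = pt[0]
        if kind == "v":
            return self.V[pt[1]]
        if kind == "e":
            _, a, b, t = pt
            return self.V[a] + t * (self.V[b] - self.V[a])
        return np.asarray(pt[2], dtype=float)

    def carrier_faces(self, pt):
        kind = pt[0]
        if kind == "v":
            return self.vertex_faces.get(int(pt[1]), [])
        if kind == "e":
            key = (pt[1], pt[2]) if pt[1] < pt[2] else (pt[2], pt[1])
            return self.edge_faces.get(key, [])
        return [pt[1]]

    def common_face(self, p1, p2):
        f2 = set(self.carrier_faces(p2))
        shared = [f for f in self.carrier_faces(p1) if f in f2]
        if not shared:
            return None
        return min(shared)


def _canon_edge_point(a, b, t):
    if a < b:
        return ("e", int(a), int(b), float(t))
    return ("e", int(b), int(a), float(1.0 - t))


# ---------------------------------------------------------------------------
# Endpoint resolution
# ---------------------------------------------------------------------------


def _closest_point_on_triangle(p, a, b, c):
    # Ericson, Real-Time Collision Detection, 5.1.5
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def project_point(mesh: TriMesh, point, surf: _Surface | None = None):
    """Project a point onto the mesh surface.

    Returns ``(path_point, distance)`` where path_point is a vertex, edge or
    face-interior surface point in the representation used by this module.
    Candidate faces are those incident to the few nearest vertices, which is
    robust for points close to the surface (the only supported use).
    """
    surf = surf or _Surface(mesh)
    p = np.asarray(point, dtype=float).reshape(3)
    k = min(6, len(surf.V))
    _, near = surf.tree().query(p, k=k)
    near = np.atleast_1d(near)
    best, best_d, best_f = None, np.inf, -1
    seen = set()
    for vi in near:
        for fi in surf.vertex_faces.get(int(vi), []):
            if fi in seen:
                continue
            seen.add(fi)
            a, b, c = surf.V[surf.F[fi]]
            q = _closest_point_on_triangle(p, a, b, c)
            d = np.linalg.norm(q - p)
            if d < best_d:
                best, best_d, best_f = q, d, fi
    fa, fb, fc = surf.F[best_f]
    for vi in (fa, fb, fc):
        if np.linalg.norm(surf.V[vi] - best) < 1e-9:
            return ("v", int(vi)), best_d
    for u, v in ((fa, fb), (fb, fc), (fc, fa)):
        ev = surf.V[v] - surf.V[u]
        t = (best - surf.V[u]) @ ev / (ev @ ev)
        if 0 <= t <= 1 and np.linalg.norm(surf.V[u] + t * ev - best) < 1e-9:
            return _canon_edge_point(u, v, t), best_d
    return ("f", int(best_f), best), best_d


def _resolve_endpoint(mesh, surf, endpoint, landmarks):
    if isinstance(endpoint, str):
        if landmarks is None or endpoint not in landmarks:
            raise MeshError(f"unknown landmark {endpoint!r}")
        # use the annotated position projected onto the surface, so that paths
        # start exactly at the landmark rather than at its snapped vertex
        pt, _ = project_point(mesh, landmarks.point(endpoint), surf)
        return pt, endpoint
    if isinstance(endpoint, (int, np.integer)):
        return ("v", int(endpoint)), int(endpoint)
    pt, _ = project_point(mesh, endpoint, surf)
    return pt, tuple(np.asarray(endpoint, float))


# ---------------------------------------------------------------------------
# Dijkstra initialisation / oracle
# ---------------------------------------------------------------------------


def _dijkstra_vertex_path(surf: _Surface, s: int, t: int):
    dist, pred = _sp_dijkstra(
        surf.graph, indices=s, return_predecessors=True, directed=False
    )
    if not np.isfinite(dist[t]):
        raise MeshError("endpoints lie in disconnected mesh components")
    path = [t]
    while path[-1] != s:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return path, float(dist[t])


def edge_dijkstra_length(mesh: TriMesh, src: int, dst: int) -> float:
    """Shortest path length restricted to mesh edges (upper-bound oracle)."""
    surf = _Surface(mesh)
    _, d = _dijkstra_vertex_path(surf, int(src), int(dst))
    return d


# ---------------------------------------------------------------------------
# Exact engine: strip unfolding + wedge shortcuts
# ---------------------------------------------------------------------------


def _embed_triangle(surf, fi):
    """2D layout of face fi: vertex order as stored, first vertex at origin."""
    a, b, c = surf.F[fi]
    A, B, C = surf.V[a], surf.V[b], surf.V[c]
    lab = np.linalg.norm(B - A)
    x = (B - A) / lab
    cx = (C - A) @ x
    cy = np.linalg.norm(C - A - cx * x)
    coords = {int(a): np.zeros(2), int(b): np.array([lab, 0.0]),
              int(c): np.array([cx, cy])}
    return coords


def _unfold_next(surf, coords, fi, shared):
    """Place the vertex of face fi not in ``shared``, given 2D coords of shared."""
    a, b = shared
    (w,) = [int(v) for v in surf.F[fi] if int(v) not in (int(a), int(b))]
    A2, B2 = coords[int(a)], coords[int(b)]
    A3, B3, W3 = surf.V[a], surf.V[b], surf.V[w]
    e = B2 - A2
    le = np.linalg.norm(e)
    ex = e / le
    ey = np.array([-ex[1], ex[0]])
    d_aw = W3 - A3
    eb = (B3 - A3) / le
    px = d_aw @ eb
    py = np.sqrt(max(d_aw @ d_aw - px * px, 0.0))
    # two mirror placements; caller picks the side
    return w, A2 + px * ex + py * ey, A2 + px * ex - py * ey


def _point_in_face_2d(surf, coords, fi, pt):
    """2D image of a path point lying in face fi with known vertex coords."""
    kind = pt[0]
    if kind == "v":
        return coords[int(pt[1])]
    if kind == "e":
        _, a, b, t = pt
        return coords[int(a)] + t * (coords[int(b)] - coords[int(a)])
    f = surf.F[fi]
    A, B, C = surf.V[f[0]], surf.V[f[1]], surf.V[f[2]]
    T = np.column_stack([B - A, C - A])
    lam, *_ = np.linalg.lstsq(T, np.asarray(pt[2]) - A, rcond=None)
    return (coords[int(f[0])]
            + lam[0] * (coords[int(f[1])] - coords[int(f[0])])
            + lam[1] * (coords[int(f[2])] - coords[int(f[0])]))


def _solve_run(surf, anchor_a, edge_pts, anchor_b):
    """Exactly re-solve a run of edge crossings between two anchors.

    Unfolds the crossed face strip into the plane and intersects the straight
    chord with each crossed edge.  Returns the new run (possibly introducing
    vertex anchors when an intersection clamps to an edge end) or None when
    the strip is inconsistent.
    """
    edges = []
    for p in edge_pts:
        key = (p[1], p[2])
        if not edges or edges[-1] != key:
            edges.append(key)
    strip = []
    prev = anchor_a
    for key in edges:
        e_pt = ("e", key[0], key[1], 0.5)
        f = surf.common_face(prev, e_pt)
        if f is None:
            return None
        strip.append((f, key))
        prev = e_pt
    f_last = surf.common_face(prev, anchor_b)
    if f_last is None:
        return None
    strip.append((f_last, None))

    coords = _embed_triangle(surf, strip[0][0])
    A2 = _point_in_face_2d(surf, coords, strip[0][0], anchor_a)
    edge2d = []
    prev_face = strip[0][0]
    for (face, key), (next_face, _) in zip(strip[:-1], strip[1:]):
        a, b = key
        if int(a) not in coords or int(b) not in coords:
            return None
        edge2d.append((key, coords[int(a)].copy(), coords[int(b)].copy()))
        if next_face != face:
            third_prev = [int(v) for v in surf.F[face] if int(v) not in key]
            w, p_pos, m_pos = _unfold_next(surf, coords, next_face, key)
            # place on the side opposite the previous face's third vertex
            a2, b2 = coords[int(a)], coords[int(b)]
            e = b2 - a2
            nrm = np.array([-e[1], e[0]])
            ref = coords[third_prev[0]] if third_prev else A2
            side_ref = (ref - a2) @ nrm
            side_p = (p_pos - a2) @ nrm
            coords[w] = m_pos if side_p * side_ref > 0 else p_pos
        prev_face = next_face
    B2 = _point_in_face_2d(surf, coords, strip[-1][0], anchor_b)

    if np.linalg.norm(B2 - A2) < _EPS:
        return []
    apexes = _funnel(A2, edge2d, B2)
    if apexes is None:
        return None
    # rebuild the run: apex vertices plus chord/portal crossings between them
    nodes = [(-1, A2, None)]
    for idx, vid, coord in apexes:
        nodes.append((idx, coord, ("v", int(vid))))
    nodes.append((len(edge2d), B2, None))
    result = []
    for (i0, P0, _), (i1, P1, pt1) in zip(nodes[:-1], nodes[1:]):
        for j in range(i0 + 1, i1):
            key, a2, b2 = edge2d[j]
            e = b2 - a2
            chord = P1 - P0
            det = chord[0] * (-e[1]) - (-e[0]) * chord[1]
            if abs(det) < 1e-14:
                # chord parallel to the portal: grazes an endpoint
                near = key[0] if np.linalg.norm(P0 - a2) < np.linalg.norm(P0 - b2) else key[1]
                result.append(("v", int(near)))
                continue
            rhs = a2 - P0
            t_edge = (chord[0] * rhs[1] - chord[1] * rhs[0]) / det
            if t_edge <= _T_EPS:
                result.append(("v", int(key[0])))
            elif t_edge >= 1.0 - _T_EPS:
                result.append(("v", int(key[1])))
            else:
                result.append(("e", key[0], key[1], float(t_edge)))
        if pt1 is not None:
            result.append(pt1)
    return result


def _tri2(a, b, c):
    """Twice the signed area of (a, b, c); positive when c is left of a->b."""
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _funnel(A2, portals, B2):
    """String-pulling through an unfolded portal sequence.

    ``portals`` are (key, a2, b2) with key the mesh vertex ids of the crossed
    edge.  Returns the taut-path apexes as (portal_index, vertex_id, coord),
    or None when the sleeve is inconsistent.
    """
    if not portals:
        return []
    # orient portals into consistent (left, right) pairs; consecutive crossed
    # edges share a mesh vertex, which keeps its side
    oriented = []
    key, a2, b2 = portals[0]
    if _tri2(A2, a2, b2) >= 0:
        oriented.append(((key[1], b2), (key[0], a2)))
    else:
        oriented.append(((key[0], a2), (key[1], b2)))
    for key, a2, b2 in portals[1:]:
        (lid, l2), (rid, r2) = oriented[-1]
        if key[0] == lid:
            oriented.append(((key[0], a2), (key[1], b2)))
        elif key[1] == lid:
            oriented.append(((key[1], b2), (key[0], a2)))
        elif key[0] == rid:
            oriented.append(((key[1], b2), (key[0], a2)))
        elif key[1] == rid:
            oriented.append(((key[0], a2), (key[1], b2)))
        else:
            return None
    oriented.append(((None, B2), (None, B2)))

    apex = A2
    left = right = A2
    left_id = right_id = None
    left_idx = right_idx = apex_idx = -1
    out = []
    i = 0
    guard = 0
    limit = 20 * len(oriented) + 100
    while i < len(oriented):
        guard += 1
        if guard > limit:
            return None
        (lid, l2), (rid, r2) = oriented[i]
        # tighten the right boundary: candidate is left of (or on) the right ray
        if _tri2(apex, right, r2) >= -1e-14:
            if np.array_equal(right, apex) or _tri2(apex, left, r2) < -1e-14:
                right, right_id, right_idx = r2, rid, i
            else:
                if left_id is None:
                    break  # the taut path has reached the end point
                out.append((left_idx, left_id, left))
                apex, apex_idx = left, left_idx
                left = right = apex
                left_id = right_id = None
                left_idx = right_idx = apex_idx
                i = apex_idx + 1
                continue
        # tighten the left boundary: candidate is right of (or on) the left ray
        if _tri2(apex, left, l2) <= 1e-14:
            if np.array_equal(left, apex) or _tri2(apex, right, l2) > 1e-14:
                left, left_id, left_idx = l2, lid, i
            else:
                if right_id is None:
                    break  # the taut path has reached the end point
                out.append((right_idx, right_id, right))
                apex, apex_idx = right, right_idx
                left = right = apex
                left_id = right_id = None
                left_idx = right_idx = apex_idx
                i = apex_idx + 1
                continue
        i += 1
    return out


def _vertex_fan(surf, v):
    """Ordered ring (u_0..u_k) and faces around v; closed=True for interior."""
    faces = surf.vertex_faces.get(int(v), [])
    ring_edges = {}
    for fi in faces:
        others = [int(u) for u in surf.F[fi] if int(u) != int(v)]
        ring_edges[fi] = others
    # build chain of faces, connected when they share a ring vertex
    neighbors = {}
    for fi, (a, b) in ring_edges.items():
        neighbors.setdefault(a, []).append(fi)
        neighbors.setdefault(b, []).append(fi)
    boundary_ring = [u for u, fs in neighbors.items() if len(fs) == 1]
    closed = len(boundary_ring) == 0
    if closed:
        start_face = faces[0]
        start_u = ring_edges[start_face][0]
    else:
        start_u = boundary_ring[0]
        start_face = neighbors[start_u][0]
    ring = [start_u]
    fan = []
    face, u = start_face, start_u
    used = set()
    while True:
        fan.append(face)
        used.add(face)
        a, b = ring_edges[face]
        u = b if a == u else a
        ring.append(u)
        nxt = [f for f in neighbors[u] if f != face and f not in used]
        if not nxt:
            break
        face, u = nxt[0], u
    return ring, fan, closed


def _wedge_arc(surf, v, fan_faces, ring, p_prev, p_next, f_prev, f_next):
    """Unfold a contiguous fan arc and return (angle, new points) or None."""
    try:
        i0 = fan_faces.index(f_prev)
        i1 = fan_faces.index(f_next)
    except ValueError:
        return None
    if i0 > i1:
        return None
    arc_faces = fan_faces[i0:i1 + 1]
    arc_ring = ring[i0:i1 + 2]
    Vv = surf.V[int(v)]
    # cumulative corner angles at v
    phis = [0.0]
    for fi, (ua, ub) in zip(arc_faces, zip(arc_ring[:-1], arc_ring[1:])):
        da = surf.V[ua] - Vv
        db = surf.V[ub] - Vv
        ca = da @ db / (np.linalg.norm(da) * np.linalg.norm(db))
        phis.append(phis[-1] + float(np.arccos(np.clip(ca, -1.0, 1.0))))
    ring2d = {u: np.linalg.norm(surf.V[u] - Vv) * np.array([np.cos(p), np.sin(p)])
              for u, p in zip(arc_ring, phis)}

    def embed(pt, face, ua, ub):
        coords = {int(v): np.zeros(2), ua: ring2d[ua], ub: ring2d[ub]}
        return _point_in_face_2d(surf, coords, face, pt)

    P = embed(p_prev, arc_faces[0], arc_ring[0], arc_ring[1])
    Q = embed(p_next, arc_faces[-1], arc_ring[-2], arc_ring[-1])

    def local_angle(point, base_dir):
        # angle of `point` from the ray `base_dir`, in [-pi, pi)
        c = base_dir[0] * point[1] - base_dir[1] * point[0]
        d = base_dir @ point
        return float(np.arctan2(c, d))

    # cumulative angles avoid atan2 wrap-around when the fan spans > pi
    th_p = local_angle(P, ring2d[arc_ring[0]])
    th_q = phis[-2] + local_angle(Q, ring2d[arc_ring[-2]])
    angle = th_q - th_p
    if angle < 0:
        return None
    if angle >= np.pi - 1e-12:
        return (angle, None)
    chord = Q - P
    new_pts = []
    for u, phi in zip(arc_ring[1:-1], phis[1:-1]):
        if phi <= th_p + 1e-12 or phi >= th_q - 1e-12:
            continue
        d = np.array([np.cos(phi), np.sin(phi)])
        M = np.column_stack([chord, -d])
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        if abs(det) < 1e-14:
            return (angle, None)
        rhs = -P
        s_ray = (M[0, 0] * rhs[1] - M[1, 0] * rhs[0]) / det
        L = np.linalg.norm(surf.V[u] - Vv)
        t = s_ray / L
        if t >= 1.0 - _T_EPS:
            new_pts.append(("v", int(u)))
        elif t > _T_EPS:
            new_pts.append(_canon_edge_point(int(v), int(u), t))
        else:
            return (angle, None)
    return (angle, new_pts)


def _shortcut_vertex(surf, v, p_prev, p_next):
    """Try to route the path across the flatter side of vertex v.

    Returns the replacement point list (may be empty) or None to keep v.
    """
    f_prev = surf.common_face(p_prev, ("v", int(v)))
    f_next = surf.common_face(p_next, ("v", int(v)))
    if f_prev is None or f_next is None:
        return None
    ring, fan, closed = _vertex_fan(surf, int(v))
    candidates = []
    orders = [(fan, ring)]
    orders.append((fan[::-1], ring[::-1]))
    if closed:
        for k in range(1, len(fan)):
            rf = fan[k:] + fan[:k]
            rr = ring[k:-1] + ring[: k + 1]
            orders.append((rf, rr))
            orders.append((rf[::-1], rr[::-1]))
    seen = set()
    for fan_o, ring_o in orders:
        key = (fan_o[0], fan_o[-1], len(fan_o))
        res = _wedge_arc(surf, v, fan_o, ring_o, p_prev, p_next, f_prev, f_next)
        if res is None:
            continue
        sig = (round(res[0], 12),)
        if sig in seen:
            continue
        seen.add(sig)
        candidates.append(res)
    if not candidates:
        return None
    angle, pts = min(candidates, key=lambda r: r[0])
    if pts is None:
        return None
    return pts


def _path_length(surf, pts):
    P = np.array([surf.position(p) for p in pts])
    return float(np.linalg.norm(np.diff(P, axis=0), axis=1).sum())


def _valid_chain(surf, pts):
    """Consecutive path points must lie on a common face."""
    return all(
        surf.common_face(a, b) is not None for a, b in zip(pts[:-1], pts[1:])
    )


def _dedupe(surf, pts):
    out = [pts[0]]
    for p in pts[1:]:
        if p == out[-1]:
            continue
        if np.linalg.norm(surf.position(p) - surf.position(out[-1])) < 1e-12:
            continue
        out.append(p)
    return out


def _straighten(surf, pts, max_iter=200, tol=1e-12):
    length = _path_length(surf, pts)
    for _ in range(max_iter):
        # wedge shortcuts at interior vertex points
        changed = False
        i = 1
        while i < len(pts) - 1:
            p = pts[i]
            if p[0] == "v":
                repl = _shortcut_vertex(surf, p[1], pts[i - 1], pts[i + 1])
                if repl is not None:
                    cand = pts[:i] + repl + pts[i + 1:]
                    cand = _dedupe(surf, cand)
                    new_len = _path_length(surf, cand)
                    if new_len < _path_length(surf, pts) - 1e-13 and _valid_chain(
                        surf, cand
                    ):
                        pts = cand
                        changed = True
                        i += max(len(repl), 1)
                        continue
            i += 1
        # exact strip re-solve of every edge-point run between anchors
        anchors = [j for j, p in enumerate(pts) if p[0] != "e"]
        if 0 not in anchors:
            anchors = [0] + anchors
        if len(pts) - 1 not in anchors:
            anchors.append(len(pts) - 1)
        new_pts = [pts[0]]
        for ja, jb in zip(anchors[:-1], anchors[1:]):
            run = pts[ja + 1: jb]
            if run:
                solved = _solve_run(surf, pts[ja], run, pts[jb])
                if solved is not None:
                    solved = _dedupe(surf, [pts[ja]] + solved + [pts[jb]])[1:-1]
                    old = _path_length(surf, [pts[ja]] + run + [pts[jb]])
                    new = _path_length(surf, [pts[ja]] + solved + [pts[jb]])
                    if new <= old + 1e-13 and _valid_chain(
                        surf, [pts[ja]] + solved + [pts[jb]]
                    ):
                        run = solved
                        if new < old - 1e-13:
                            changed = True
                new_pts.extend(run)
            new_pts.append(pts[jb])
        pts = _dedupe(surf, new_pts)
        new_length = _path_length(surf, pts)
        if not changed and length - new_length < tol * max(1.0, length):
            break
        length = new_length
    return pts


# ---------------------------------------------------------------------------
# Fast marching engine
# ---------------------------------------------------------------------------


def _fmm_distances(surf: _Surface, source: int) -> np.ndarray:
    n = len(surf.V)
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    finalized = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    V, F = surf.V, surf.F
    while heap:
        d, u = heapq.heappop(heap)
        if finalized[u] or d > dist[u]:
            continue
        finalized[u] = True
        for fi in surf.vertex_faces.get(int(u), []):
            tri = [int(x) for x in F[fi]]
            for c in tri:
                if finalized[c]:
                    continue
                a, b = [x for x in tri if x != c]
                dc = np.inf
                da, db = dist[a], dist[b]
                if np.isfinite(da) and np.isfinite(db):
                    dc = _fmm_update(V[c], V[a], V[b], da, db)
                if np.isfinite(da):
                    dc = min(dc, da + np.linalg.norm(V[c] - V[a]))
                if np.isfinite(db):
                    dc = min(dc, db + np.linalg.norm(V[c] - V[b]))
                if dc < dist[c]:
                    dist[c] = dc
                    heapq.heappush(heap, (dc, c))
    return dist


def _fmm_update(C, A, B, da, db):
    """Planar-wavefront two-point update for vertex C of triangle (C, A, B)."""
    e1, e2 = A - C, B - C
    x = e1 / np.linalg.norm(e1)
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if nn < 1e-15:
        return np.inf
    y = np.cross(n / nn, x)
    X = np.array([[e1 @ x, e2 @ x], [e1 @ y, e2 @ y]])
    try:
        Q = np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError:
        return np.inf
    one = np.ones(2)
    t = np.array([da, db])
    aa = one @ Q @ one
    bb = -2.0 * (one @ Q @ t)
    cc = t @ Q @ t - 1.0
    disc = bb * bb - 4 * aa * cc
    if disc < 0:
        return np.inf
    dc = (-bb + np.sqrt(disc)) / (2 * aa)
    # causality: descent direction must point into the triangle
    coeff = Q @ (dc * one - t)
    if dc >= max(da, db) and coeff[0] >= -1e-12 and coeff[1] >= -1e-12:
        return dc
    return np.inf


def _fmm_path(surf, src_v, dst_v):
    dist = _fmm_distances(surf, src_v)
    if not np.isfinite(dist[dst_v]):
        raise MeshError("endpoints lie in disconnected mesh components")
    # descend on the distance field over the vertex graph
    indptr, indices = surf.graph.indptr, surf.graph.indices
    path = [dst_v]
    cur = dst_v
    while cur != src_v:
        nbrs = indices[indptr[cur]:indptr[cur + 1]]
        nxt = int(nbrs[np.argmin(dist[nbrs])])
        if dist[nxt] >= dist[cur]:
            raise MeshError("fast-marching descent stalled")
        path.append(nxt)
        cur = nxt
    path.reverse()
    return [("v", int(i)) for i in path]


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def compute_path(
    mesh: TriMesh,
    src,
    dst,
    method: str = "exact",
    landmarks: LandmarkSet | None = None,
    _surf: _Surface | None = None,
) -> GeodesicPath:
    """Shortest on-surface path between two landmarks, vertices or points."""
    if method not in ("exact", "fast_marching"):
        raise MeshError(f"unknown geodesic method {method!r}")
    surf = _surf or _Surface(mesh)
    p_src, name_src = _resolve_endpoint(mesh, surf, src, landmarks)
    p_dst, name_dst = _resolve_endpoint(mesh, surf, dst, landmarks)
    if np.linalg.norm(surf.position(p_src) - surf.position(p_dst)) < 1e-12:
        raise MeshError("src and dst resolve to the same surface point")

    def near_vertex(pt):
        if pt[0] == "v":
            return int(pt[1])
        if pt[0] == "e":
            return int(pt[1] if pt[3] <= 0.5 else pt[2])
        fverts = surf.F[pt[1]]
        d = np.linalg.norm(surf.V[fverts] - surf.position(pt), axis=1)
        return int(fverts[np.argmin(d)])

    v_src, v_dst = near_vertex(p_src), near_vertex(p_dst)
    if method == "fast_marching":
        if v_src == v_dst:
            pts = [("v", v_src)]
        else:
            pts = _fmm_path(surf, v_src, v_dst)
    else:
        if v_src == v_dst:
            pts = [("v", v_src)]
        else:
            vpath, _ = _dijkstra_vertex_path(surf, v_src, v_dst)
            pts = [("v", int(i)) for i in vpath]
    if p_src[0] != "v" or p_src[1] != pts[0][1]:
        pts = [p_src] + pts
    if p_dst[0] != "v" or p_dst[1] != pts[-1][1]:
        pts = pts + [p_dst]
    pts = _dedupe(surf, pts)
    if method == "exact" and len(pts) > 2:
        pts = _straighten(surf, pts)
    P = np.array([surf.position(p) for p in pts])
    return GeodesicPath.from_points(P, (name_src, name_dst), method)


def polyline_path(
    mesh: TriMesh,
    waypoints,
    method: str = "exact",
    landmarks: LandmarkSet | None = None,
) -> GeodesicPath:
    """Concatenated geodesic through ordered waypoints (>= 2)."""
    if len(waypoints) < 2:
        raise MeshError("polyline_path needs at least 2 waypoints")
    surf = _Surface(mesh)
    segments = [
        compute_path(mesh, a, b, method=method, landmarks=landmarks, _surf=surf)
        for a, b in zip(waypoints[:-1], waypoints[1:])
    ]
    pts = [segments[0].points]
    for seg in segments[1:]:
        pts.append(seg.points[1:])  # drop duplicate junction point
    allpts = np.vstack(pts)
    ends = (segments[0].endpoints[0], segments[-1].endpoints[1])
    return GeodesicPath.from_points(allpts, ends, method)


def lip_tone_paths(
    mesh: TriMesh,
    landmarks: LandmarkSet,
    n_paths: int = 5,
    spacing: float = 2.0,
    method: str = "exact",
    project_tolerance: float = 5.0,
) -> list:
    """The lower-lip-tone path family: chL -> li -> chR plus offset copies.

    Requires the canonical pose (``align_pose``), in which "down" is -y.  Path
    ``i`` passes through the three waypoints shifted by ``i * spacing`` mm
    downwards and re-projected onto the surface; path 0 uses the landmarks
    themselves.
    """
    for name in ("chL", "li", "chR"):
        if name not in landmarks:
            raise MeshError(f"lip_tone_paths requires landmark {name!r}")
    surf = _Surface(mesh)
    base = np.array([landmarks.point(n) for n in ("chL", "li", "chR")])
    paths = []
    for i in range(n_paths):
        shifted = base - np.array([0.0, i * spacing, 0.0])
        waypoints = []
        for p in shifted:
            proj, d = project_point(mesh, p, surf)
            if d > project_tolerance:
                raise MeshError(
                    f"offset path {i}: point {p} is {d:.2f} mm off the surface "
                    f"(tolerance {project_tolerance} mm); patch too small"
                )
            waypoints.append(surf.position(proj))
        paths.append(polyline_path(mesh, waypoints, method=method))
    return paths
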