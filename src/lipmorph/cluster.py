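"""Automatic trait categorisation: k-means++ with restarts and K selection.

Lloyd's algorithm is initialised with the k-means++ rule (first centroid
uniform over the data, each next drawn with probability proportional to the
squared distance to the nearest chosen centroid), restarted many times and the
minimum-SSE model kept.  Three internal validity indices — silhouette (SI),
Dunn (DI) and Calinski-Harabasz (CH) — score candidate cluster counts, and a
repeated sweep over K reports how often each index prefers each K, from which
a stable category count is read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterModel",
    "ValiditySweep",
    "kmeanspp_init",
    "kmeans_fit",
    "validity_indices",
    "select_k",
]


@dataclass
class ClusterModel:
    """A fitted k-means solution (Lloyd fixed point, minimum SSE restart)."""

    K: int
    centroids: np.ndarray
    assignments: np.ndarray
    sse: float
    seed: int | None = None

    def recompute_sse(self, X) -> float:
        X = np.asarray(X, dtype=float)
        return float(
            ((X - self.centroids[self.assignments]) ** 2).sum()
        )


@dataclass
class ValiditySweep:
    """Per-repeat index values over a K range and the chosen-K percentages."""

    k_range: tuple
    indices: tuple = ("SI", "DI", "CH")
    scores: dict = field(default_factory=dict)   # index -> (repeats, nK) array
    chosen: dict = field(default_factory=dict)   # index -> (repeats,) chosen K
    percentages: dict = field(default_factory=dict)  # index -> {K: %}

    def best_k(self, index: str = "SI") -> int:
        pct = self.percentages[index]
        return max(pct, key=lambda k: pct[k])


def kmeanspp_init(X, K: int, rng, squared: bool = True) -> np.ndarray:
    """k-means++ seeding; returns K data points as initial centroids.

    ``squared=False`` weights by plain distance instead of the usual squared
    distance.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if K < 1 or K > n:
        raise ValueError(f"K must be in [1, {n}]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    centroids = np.empty((K, X.shape[1]))
    first = rng.integers(n)
    centroids[0] = X[first]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for i in range(1, K):
        w = d2 if squared else np.sqrt(d2)
        total = w.sum()
        if total <= 0:
            idx = rng.integers(n)  # all points coincide with chosen centroids
        else:
            idx = rng.choice(n, p=w / total)
        centroids[i] = X[idx]
        d2 = np.minimum(d2, ((X - centroids[i]) ** 2).sum(axis=1))
    return centroids


def _lloyd(X, centroids, max_iter=300):
    n, K = len(X), len(centroids)
    assign = np.full(n, -1)
    prev_sse = np.inf
    for _ in range(max_iter):
        d2 = cdist(X, centroids, "sqeuclidean")
        new_assign = d2.argmin(axis=1)
        sse = float(d2[np.arange(n), new_assign].sum())
        assert sse <= prev_sse + 1e-9, "Lloyd SSE increased"
        prev_sse = sse
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in range(K):
            members = X[assign == k]
            if len(members):
                centroids[k] = members.mean(axis=0)
            else:  # re-seed an emptied cluster from the farthest point
                far = int(
                    cdist(X, centroids, "sqeuclidean").min(axis=1).argmax()
                )
                centroids[k] = X[far]
    d2 = cdist(X, centroids, "sqeuclidean")
    assign = d2.argmin(axis=1)
    sse = float(d2[np.arange(n), assign].sum())
    return centroids, assign, sse


def kmeans_fit(X, K: int, rng=0, restarts: int = 100) -> ClusterModel:
    """Best-of-``restarts`` k-means++ / Lloyd fit (minimum SSE kept)."""
    X = np.asarray(X, dtype=float)
    if K > len(X):
        raise ValueError("K > number of points")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    best = None
    for _ in range(restarts):
        centroids = kmeanspp_init(X, K, rng)
        centroids, assign, sse = _lloyd(X, centroids.copy())
        if best is None or sse < best[2]:
            best = (centroids, assign, sse)
    return ClusterModel(K=K, centroids=best[0], assignments=best[1], sse=best[2])


def validity_indices(X, assignments):
    """(SI, DI, CH) for one clustering.

    SI is the per-point mean silhouette; a(i) averages distances within the
    point's own cluster excluding itself (singleton clusters give s(i) = 0),
    b(i) is the smallest mean distance to any other cluster.  DI divides the
    minimum pairwise inter-cluster distance by the maximum within-cluster
    diameter.  CH is trace(S_B)/trace(S_W) * (n - k)/(k - 1).
    """
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    k = len(labels)
    n = len(X)
    if k < 2:
        raise ValueError("validity indices need >= 2 clusters")
    D = cdist(X, X)

    # silhouette
    s = np.zeros(n)
    for i in range(n):
        own = assignments == assignments[i]
        n_own = own.sum()
        if n_own <= 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, assignments == c].mean() for c in labels if c != assignments[i])
        s[i] = (b - a) / max(a, b)
    si = float(s.mean())

    # Dunn
    min_inter = np.inf
    max_diam = 0.0
    masks = {c: assignments == c for c in labels}
    for ia, ca in enumerate(labels):
        da = D[masks[ca]][:, masks[ca]]
        if da.size:
            max_diam = max(max_diam, float(da.max()))
        for cb in labels[ia + 1:]:
            min_inter = min(min_inter, float(D[masks[ca]][:, masks[cb]].min()))
    di = float(min_inter / max_diam) if max_diam > 0 else np.inf

    # Calinski-Harabasz
    grand = X.mean(axis=0)
    ssb = sum(
        masks[c].sum() * ((X[masks[c]].mean(axis=0) - grand) ** 2).sum()
        for c in labels
    )
    ssw = sum(
        ((X[masks[c]] - X[masks[c]].mean(axis=0)) ** 2).sum() for c in labels
    )
    ch = float(ssb / ssw * (n - k) / (k - 1)) if ssw > 0 else np.inf
    return si, di, ch


def calinski_harabasz_literal(X, assignments):
    """CH with the (n-1)/(n-k) degrees-of-freedom reading."""
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    n, k = len(X), len(labels)
    grand = X.mean(axis=0)
    ssb = sum(
        (assignments == c).sum() * ((X[assignments == c].mean(axis=0) - grand) ** 2).sum()
        for c in labels
    )
    ssw = sum(
        ((X[assignments == c] - X[assignments == c].mean(axis=0)) ** 2).sum()
        for c in labels
    )
    return float(ssb / ssw * (n - 1) / (n - k)) if ssw > 0 else np.inf


def select_k(
    X,
    kmin: int = 2,
    kmax: int = 9,
    repeats: int = 50,
    rng=0,
    restarts: int = 100,
) -> ValiditySweep:
    """Repeated K sweep with all three validity indices.

    For each repeat and each K in [kmin, kmax] a best-of-``restarts`` k-means
    model is fitted and scored; the percentage table records how often each
    index's argmax lands on each K.
    """
    X = np.asarray(X, dtype=float)
    if kmax > len(X) - 1:
        raise ValueError("kmax must be <= n - 1")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate data: all points identical")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ks = list(range(kmin, kmax + 1))
    names = ("SI", "DI", "CH")
    scores = {nm: np.zeros((repeats, len(ks))) for nm in names}
    chosen = {nm: np.zeros(repeats, dtype=int) for nm in names}
    for r in range(repeats):
        for ki, K in enumerate(ks):
            model = kmeans_fit(X, K, rng=rng, restarts=restarts)
            si, di, ch = validity_indices(X, model.assignments)
            scores["SI"][r, ki] = si
            scores["DI"][r, ki] = di
            scores["CH"][r, ki] = ch
        for nm in names:
            chosen[nm][r] = ks[int(np.argmax(scores[nm][r]))]
    percentages = {
        nm: {K: 100.0 * float(np.mean(chosen[nm] == K)) for K in ks} for nm in names
    }
    return ValiditySweep(
        k_range=(kmin, kmax),
        scores=scores,
        chosen=chosen,
        percentages=percentages,
    )
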