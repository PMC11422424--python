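"""Clustering of participants from the DTW distance matrix.

Two algorithms, as in the source analysis: agglomerative hierarchical
clustering with the Ward.D2 linkage (Lance-Williams update on the
dissimilarities, operating on their squares), and k-means applied to the
rows of the distance matrix (each participant represented by its profile of
distances to everyone).  A k-medoids (PAM-style) alternative is available
behind a config switch for sensitivity analysis, since running k-means on a
dissimilarity matrix admits more than one reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans


@dataclass
class ClusterSolution:
    algorithm: str
    k: int
    ids: list[str]
    labels: np.ndarray  # contiguous labels 1..k, first-occurrence order

    def members(self, label: int) -> set[str]:
        return {pid for pid, lab in zip(self.ids, self.labels) if lab == label}

    def clusters(self) -> list[set[str]]:
        return [self.members(lab) for lab in range(1, self.k + 1)]


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diagonal(D)) > 1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be nonnegative")
    return D


def hclust_ward2(D: np.ndarray) -> np.ndarray:
    """Ward.D2 agglomeration; returns an (n-1) x 4 linkage table.

    Each row holds (child_a, child_b, merge height, merged size) with
    scipy's id convention (leaves 0..n-1, merge t creates id n+t).  The
    Lance-Williams update on squared dissimilarities is

        d(i u j, k)^2 = [ (n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2
                          - n_k d_ij^2 ] / (n_i + n_j + n_k),

    and ties are broken by the lexicographically smallest active pair.
    """
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    d2 = D.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    cluster_id = np.arange(n)
    Z = np.zeros((n - 1, 4))
    work = d2.copy()
    for step in range(n - 1):
        # mask lower triangle and inactive slots; row-major argmin gives the
        # lexicographically smallest minimizing pair
        masked = np.where(
            np.triu(np.ones_like(work, dtype=bool), k=1)
            & active[:, None]
            & active[None, :],
            work,
            np.inf,
        )
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        height = float(np.sqrt(work[i, j]))
        ni, nj = sizes[i], sizes[j]
        child_a, child_b = sorted((int(cluster_id[i]), int(cluster_id[j])))
        Z[step] = (child_a, child_b, height, ni + nj)
        # Lance-Williams Ward update into slot i
        others = active.copy()
        others[i] = others[j] = False
        nk = sizes[others]
        new_d2 = (
            (ni + nk) * work[i, others]
            + (nj + nk) * work[j, others]
            - nk * work[i, j]
        ) / (ni + nj + nk)
        work[i, others] = new_d2
        work[others, i] = new_d2
        active[j] = False
        sizes[i] = ni + nj
        cluster_id[i] = n + step
    return Z


def cut_tree(Z: np.ndarray, k: int, ids: list[str] | None = None) -> ClusterSolution:
    """Cut the merge tree into k clusters (undoing the last k-1 merges)."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside 1..{n}")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t in range(n - k):  # apply the first n-k merges
        a, b = int(Z[t, 0]), int(Z[t, 1])
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    labels = np.zeros(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    if ids is None:
        ids = [str(i) for i in range(n)]
    return ClusterSolution(algorithm="hierarchical", k=k, ids=list(ids), labels=labels)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.zeros_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def kmeans_rows(
    D: np.ndarray,
    k: int,
    n_init: int = 50,
    seed: int = 0,
    ids: list[str] | None = None,
) -> ClusterSolution:
    """k-means on the rows of the distance matrix (distance profiles)."""
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of observations {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=300,
        tol=1e-9,
        random_state=int(seed) % (2**32),
        algorithm="lloyd",
    )
    raw = km.fit_predict(D)
    labels = _relabel_first_occurrence(raw)
    if ids is None:
        ids = [str(i) for i in range(n)]
    return ClusterSolution(algorithm="kmeans", k=k, ids=list(ids), labels=labels)


def kmedoids(
    D: np.ndarray,
    k: int,
    n_init: int = 10,
    seed: int = 0,
    ids: list[str] | None = None,
    max_iter: int = 100,
) -> ClusterSolution:
    """PAM-style k-medoids on the precomputed distance matrix.

    Voronoi iteration from ``n_init`` random medoid sets; the lowest total
    within-cluster distance-to-medoid is kept.  Sensitivity alternative to
    :func:`kmeans_rows`.
    """
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of observations {n}")
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_labels = None
    for _ in range(n_init):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(max_iter):
            assign = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.where(assign == c)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        assign = np.argmin(D[:, medoids], axis=1)
        cost = float(D[np.arange(n), medoids[assign]].sum())
        if cost < best_cost:
            best_cost = cost
            best_labels = assign
    labels = _relabel_first_occurrence(best_labels)
    if ids is None:
        ids = [str(i) for i in range(n)]
    return ClusterSolution(algorithm="kmedoids", k=k, ids=list(ids), labels=labels)


def cluster_matrix(
    D: np.ndarray,
    algorithm: str,
    k: int,
    ids: list[str] | None = None,
    n_init: int = 50,
    seed: int = 0,
) -> ClusterSolution:
    """Dispatch to one clustering algorithm by name."""
    if algorithm == "hierarchical":
        return cut_tree(hclust_ward2(D), k, ids=ids)
    if algorithm == "kmeans":
        return kmeans_rows(D, k, n_init=n_init, seed=seed, ids=ids)
    if algorithm == "kmedoids":
        return kmedoids(D, k, n_init=max(1, n_init // 5), seed=seed, ids=ids)
    raise ValueError(f"unknown algorithm {algorithm!r}")
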