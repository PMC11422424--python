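"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: the Ward agglomerator
is a plain dict-based O(n^3) re-derivation of the Lance-Williams update,
and the partition helpers compare cluster solutions structurally.
"""

from __future__ import annotations

import numpy as np


def naive_ward_merges(D: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive Ward.D2 agglomeration: returns (members_a, members_b, height)."""
    n = D.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    sq: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sq[(i, j)] = float(D[i, j]) ** 2
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                d2 = sq[(i, j)]
                if best is None or d2 < best[0] - 1e-15:
                    best = (d2, i, j)
        d2_ij, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((a, b, float(np.sqrt(d2_ij))))
        ni, nj = len(a), len(b)
        new = next_id
        next_id += 1
        for k in sorted(clusters):
            if k in (i, j):
                continue
            nk = len(clusters[k])
            dik = sq[(min(i, k), max(i, k))]
            djk = sq[(min(j, k), max(j, k))]
            merged = ((ni + nk) * dik + (nj + nk) * djk - nk * d2_ij) / (
                ni + nj + nk
            )
            sq[(min(new, k), max(new, k))] = merged
        clusters[new] = a | b
        del clusters[i], clusters[j]
    return merges


def naive_ward_partition(D: np.ndarray, k: int) -> set[frozenset]:
    """Partition into k clusters by stopping the naive agglomeration early."""
    n = D.shape[0]
    merges = naive_ward_merges(D)
    clusters = [frozenset([i]) for i in range(n)]
    for a, b, _ in merges[: n - k]:
        clusters = [c for c in clusters if c != a and c != b] + [a | b]
    return set(clusters)


def partition_of(labels) -> set[frozenset]:
    """Set-of-frozensets view of a label vector (relabelling-invariant)."""
    groups: dict = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    return {frozenset(v) for v in groups.values()}
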