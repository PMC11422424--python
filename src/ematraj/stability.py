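"""Clusterwise stability by repeated 50 % subsampling and Jaccard matching.

For each number of clusters, the full-data solution is compared against
solutions recomputed on random half-samples (drawn without replacement):
every original cluster is matched to the best-overlapping cluster of the
subsample solution by Jaccard index, and its stability is the mean of those
best matches over resamples.  Values above 0.85 mark a highly stable
cluster; a whole solution is called stable when its least stable cluster
clears the threshold (configurable to the mean).  Resamples in which an
original cluster has no members are skipped for that cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterSolution, cluster_matrix


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; both-empty is defined as 0 with a warning."""
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


@dataclass
class StabilityReport:
    algorithm: str
    k: int
    n_resamples: int
    subsample_fraction: float
    seed: int
    mean_jaccard: np.ndarray = field(default_factory=lambda: np.array([]))
    n_skipped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def aggregate(self, how: str = "min") -> float:
        if how == "min":
            return float(np.min(self.mean_jaccard))
        if how == "mean":
            return float(np.mean(self.mean_jaccard))
        raise ValueError(f"unknown aggregation {how!r}")


def clusterwise_stability(
    D: np.ndarray,
    algorithm: str,
    k: int,
    n_resamples: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    ids: list[str] | None = None,
    n_init: int = 10,
    full_solution: ClusterSolution | None = None,
) -> StabilityReport:
    """Mean best-match Jaccard per full-data cluster over subsample refits."""
    n = D.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if full_solution is None:
        full_solution = cluster_matrix(D, algorithm, k, ids=ids, n_init=50, seed=seed)
    full_clusters = full_solution.clusters()
    sums = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    skipped = np.zeros(k, dtype=int)
    rng = np.random.default_rng(seed)
    size = math.ceil(fraction * n)
    resample_seeds = rng.integers(0, 2**31, size=n_resamples)
    for b in range(n_resamples):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        if k > size:
            warnings.warn(
                f"resample {b}: k={k} exceeds subsample size {size}; skipped",
                stacklevel=2,
            )
            skipped += 1
            continue
        sub_ids = [ids[i] for i in idx]
        sub_D = D[np.ix_(idx, idx)]
        sub_solution = cluster_matrix(
            sub_D, algorithm, k, ids=sub_ids, n_init=n_init,
            seed=int(resample_seeds[b]),
        )
        sub_clusters = sub_solution.clusters()
        in_sample = set(sub_ids)
        for ci, cluster in enumerate(full_clusters):
            inter = cluster & in_sample
            if not inter:
                skipped[ci] += 1
                continue
            best = max(jaccard(inter, s) for s in sub_clusters)
            sums[ci] += best
            counts[ci] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return StabilityReport(
        algorithm=algorithm,
        k=k,
        n_resamples=n_resamples,
        subsample_fraction=fraction,
        seed=seed,
        mean_jaccard=means,
        n_skipped=skipped,
    )


def stability_scan(
    D: np.ndarray,
    algorithms: tuple[str, ...] = ("hierarchical", "kmeans"),
    k_range: tuple[int, ...] = tuple(range(2, 11)),
    n_resamples: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    ids: list[str] | None = None,
    n_init: int = 10,
) -> list[StabilityReport]:
    """One stability report per (algorithm, k), with identical resampling
    seeds across k so solutions are compared on the same subsamples."""
    reports = []
    for ai, algorithm in enumerate(algorithms):
        algo_seed = int(
            np.random.SeedSequence(seed, spawn_key=(ai,)).generate_state(1)[0]
            % (2**31)
        )
        for k in k_range:
            reports.append(
                clusterwise_stability(
                    D,
                    algorithm,
                    k,
                    n_resamples=n_resamples,
                    fraction=fraction,
                    seed=algo_seed,
                    ids=ids,
                    n_init=n_init,
                )
            )
    return reports


@dataclass
class KSelection:
    stable: list[tuple[str, int]]
    primary: tuple[str, int] | None

    @property
    def selected_k(self) -> int | None:
        return self.primary[1] if self.primary else None


def select_k(
    reports: list[StabilityReport],
    threshold: float = 0.85,
    aggregate: str = "min",
) -> KSelection:
    """Return all highly stable (algorithm, k); the smallest k is primary."""
    if not reports:
        raise ValueError("no stability reports supplied")
    stable = [
        (r.algorithm, r.k)
        for r in reports
        if r.mean_jaccard.size and r.aggregate(aggregate) > threshold
    ]
    if not stable:
        warnings.warn("no cluster solution exceeds the stability threshold",
                      stacklevel=2)
        return KSelection(stable=[], primary=None)
    primary = min(stable, key=lambda ak: (ak[1], ak[0]))
    return KSelection(stable=stable, primary=primary)
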