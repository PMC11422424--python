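"""Banded dynamic time warping with the symmetric (symmetricP0) step pattern.

The recursion is the classic symmetric one — diagonal steps weighted 2,
horizontal/vertical steps weighted 1, local cost |x_i - y_j| — restricted
to the Sakoe-Chiba band |i - j| <= w:

    g(1,1) = 2 d(1,1)
    g(i,j) = min( g(i-1,j-1) + 2 d(i,j),
                  g(i-1,j)   +   d(i,j),
                  g(i,j-1)   +   d(i,j) )

Distances are returned unnormalized by default: all trajectories here share
length 42, so the (n+m) path normalization is a constant factor that cannot
affect clustering.  A ``normalize`` flag divides by n+m for unequal-length
use.  A brute-force path-enumeration oracle pins the semantics on small
instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

_INF = math.inf


@dataclass(frozen=True)
class DtwConfig:
    """Band half-width and step pattern of the DTW alignment."""

    window: int = 2
    step_pattern: str = "symmetricP0"
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.step_pattern != "symmetricP0":
            raise ValueError(f"unsupported step pattern {self.step_pattern!r}")


def dtw_distance(x, y, config: DtwConfig = DtwConfig()) -> float:
    """Banded symmetric DTW distance between two complete series."""
    x = [float(v) for v in np.asarray(x).ravel()]
    y = [float(v) for v in np.asarray(y).ravel()]
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty series")
    w = config.window
    if abs(n - m) > w:
        raise ValueError("band excludes endpoint: |len(x) - len(y)| > window")
    prev = [_INF] * m
    cur = [_INF] * m
    for i in range(n):
        xi = x[i]
        lo = max(0, i - w)
        hi = min(m - 1, i + w)
        cur = [_INF] * m
        for j in range(lo, hi + 1):
            d = abs(xi - y[j])
            if i == 0 and j == 0:
                cur[0] = 2.0 * d
                continue
            diag = prev[j - 1] if (i > 0 and j > 0) else _INF
            up = prev[j] if i > 0 else _INF
            left = cur[j - 1] if j > 0 else _INF
            best = min(diag + 2.0 * d, up + d, left + d)
            cur[j] = best
        prev = cur
    dist = cur[m - 1]
    if not math.isfinite(dist):
        raise ValueError("no admissible warping path within the band")
    if config.normalize:
        dist /= n + m
    return dist


def pairwise_dtw(
    trajectories: pd.DataFrame | np.ndarray,
    config: DtwConfig = DtwConfig(),
) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of pairwise DTW distances between trajectories.

    ``trajectories`` is a participants x slots frame (or array); rows must
    be complete.  Only the upper triangle is computed and mirrored.
    """
    if isinstance(trajectories, pd.DataFrame):
        ids = [str(i) for i in trajectories.index]
        values = trajectories.to_numpy(dtype=float)
    else:
        values = np.asarray(trajectories, dtype=float)
        ids = [str(i) for i in range(values.shape[0])]
    if np.isnan(values).any():
        raise ValueError("trajectories must be complete (no missing values)")
    n = values.shape[0]
    series = [list(map(float, row)) for row in values]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(series[i], series[j], config)
    return ids, D


def dtw_bruteforce_oracle(x, y, config: DtwConfig = DtwConfig()) -> float:
    """Exhaustive enumeration of all banded warping paths (test utility).

    Definitional oracle: explores every monotone path of the step pattern
    within the band and returns the minimal cumulative cost.  Limited to
    n*m <= 64 cells.
    """
    x = [float(v) for v in np.asarray(x).ravel()]
    y = [float(v) for v in np.asarray(y).ravel()]
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty series")
    if n * m > 64:
        raise ValueError("instance too large for brute-force enumeration")
    w = config.window
    if abs(n - m) > w:
        raise ValueError("band excludes endpoint: |len(x) - len(y)| > window")

    best = [_INF]

    def walk(i: int, j: int, cost: float) -> None:
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj, wgt in ((1, 1, 2.0), (1, 0, 1.0), (0, 1, 1.0)):
            ni, nj = i + di, j + dj
            if ni >= n or nj >= m or abs(ni - nj) > w:
                continue
            walk(ni, nj, cost + wgt * abs(x[ni] - y[nj]))

    if abs(0 - 0) <= w:
        walk(0, 0, 2.0 * abs(x[0] - y[0]))
    dist = best[0]
    if not math.isfinite(dist):
        raise ValueError("no admissible warping path within the band")
    if config.normalize:
        dist /= n + m
    return dist
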