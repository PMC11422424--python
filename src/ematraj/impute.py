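"""Iterative random-forest imputation of slot grids and the composite score.

The imputation follows the missForest scheme: missing cells are first
filled with the participant's own mean for that item (falling back to the
slot mean when a participant observed nothing on an item), then columns are
revisited in order of increasing missingness, each regressed on all other
slots with a random forest fitted on the rows where the column was
observed.  Iteration stops when the normalised change

    delta = sum((new - old)^2) / sum(new^2)     over originally-missing cells

first increases, and the previous iterate is returned.  Observed cells are
never altered; imputed values are clamped to the 1-7 rating range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

RATING_MIN, RATING_MAX = 1.0, 7.0


@dataclass
class ImputationReport:
    item: str
    pct_missing: float
    iterations: int
    delta_trace: list[float] = field(default_factory=list)


def initial_impute(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with the row (participant) mean for the item.

    Rows without any observed value fall back to the column (slot) mean.
    """
    values = matrix.to_numpy(dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError("item matrix is fully missing; nothing to impute from")
    out = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(values, axis=1)
        col_means = np.nanmean(values, axis=0)
    # slots never observed anywhere: fall back to grand mean
    grand = np.nanmean(values)
    col_means = np.where(np.isnan(col_means), grand, col_means)
    for i in range(out.shape[0]):
        miss = np.isnan(out[i])
        if not miss.any():
            continue
        fill = row_means[i] if not math.isnan(row_means[i]) else None
        out[i, miss] = col_means[miss] if fill is None else fill
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rf_impute(
    matrix: pd.DataFrame,
    n_trees: int = 100,
    seed: int = 0,
    max_iter: int = 10,
    max_features: int | None = None,
) -> tuple[pd.DataFrame, int, list[float]]:
    """missForest-style iterative random-forest imputation of one item matrix.

    Returns ``(imputed, iterations, delta_trace)``; ``iterations`` counts
    accepted refinement rounds (0 when nothing is missing or the first
    round already increased delta relative to the mean-imputation start).
    """
    values = matrix.to_numpy(dtype=float)
    miss_mask = np.isnan(values)
    if not miss_mask.any():
        return matrix.copy(), 0, []
    if max_features is None:
        max_features = max(1, int(math.sqrt(matrix.shape[1] - 1)))

    current = initial_impute(matrix).to_numpy(dtype=float)
    n_rows, n_cols = current.shape
    col_missing = miss_mask.sum(axis=0)
    # visit columns with missing cells in order of ascending missingness
    visit = sorted(
        (j for j in range(n_cols) if col_missing[j] > 0),
        key=lambda j: (col_missing[j], j),
    )
    fully_missing = [j for j in visit if col_missing[j] == n_rows]
    if fully_missing:
        warnings.warn(
            f"column(s) {fully_missing} have no observed values; keeping "
            "initial imputation for them",
            stacklevel=2,
        )
        visit = [j for j in visit if col_missing[j] < n_rows]

    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.generate_state(max_iter * max(1, len(visit))) % (2**31)

    delta_prev = math.inf
    trace: list[float] = []
    accepted = current
    iterations = 0
    for it in range(max_iter):
        new = current.copy()
        for rank, j in enumerate(visit):
            obs = ~miss_mask[:, j]
            others = np.delete(np.arange(n_cols), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,
                random_state=int(tree_seeds[it * len(visit) + rank]),
                n_jobs=1,
            )
            rf.fit(new[obs][:, others], new[obs, j])
            pred = rf.predict(new[miss_mask[:, j]][:, others])
            new[miss_mask[:, j], j] = np.clip(pred, RATING_MIN, RATING_MAX)
        num = float(np.sum((new[miss_mask] - current[miss_mask]) ** 2))
        den = float(np.sum(new[miss_mask] ** 2))
        delta = num / den if den > 0 else 0.0
        trace.append(delta)
        if delta >= delta_prev:
            break
        accepted = new
        iterations = it + 1
        delta_prev = delta
        current = new
    out = matrix.to_numpy(dtype=float).copy()
    out[miss_mask] = accepted[miss_mask]  # observed cells bit-identical
    return (
        pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        iterations,
        trace,
    )


def impute_all_items(
    grids: dict[str, pd.DataFrame],
    n_trees: int = 100,
    seed: int = 0,
    max_iter: int = 10,
) -> tuple[dict[str, pd.DataFrame], list[ImputationReport]]:
    """Impute each item matrix with its own derived seed; report per item."""
    ss = np.random.SeedSequence(seed)
    item_seeds = ss.generate_state(len(grids)) % (2**31)
    completed, reports = {}, []
    for (item, mat), child in zip(sorted(grids.items()), item_seeds):
        pct = float(np.isnan(mat.to_numpy(dtype=float)).mean() * 100.0)
        imp, iters, trace = rf_impute(
            mat, n_trees=n_trees, seed=int(child), max_iter=max_iter
        )
        completed[item] = imp
        reports.append(
            ImputationReport(
                item=item, pct_missing=pct, iterations=iters, delta_trace=trace
            )
        )
    return completed, reports


def composite_score(item_matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean of the five imputed item values, per participant and slot.

    All matrices must be complete with identical participant sets.
    """
    mats = list(item_matrices.values())
    if not mats:
        raise ValueError("no item matrices supplied")
    base_index = mats[0].index
    for m in mats[1:]:
        if set(m.index) != set(base_index):
            raise ValueError("participant sets differ between item matrices")
    stacked = np.stack([m.loc[base_index].to_numpy(dtype=float) for m in mats])
    if np.isnan(stacked).any():
        raise ValueError("item matrices must be complete before compositing")
    comp = stacked.mean(axis=0)
    return pd.DataFrame(comp, index=base_index, columns=mats[0].columns)
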