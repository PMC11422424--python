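"""Reading and writing of the pipeline's file formats.

The canonical exchange format is long-format CSV with header
``participant_id, study, group, day, time, item, rating`` — one row per
item per beep, empty rating meaning missing.  Wide CSVs carry slot grids,
composite trajectories and distance matrices; YAML carries configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EMA_COLUMNS = ("participant_id", "study", "group", "day", "time", "item", "rating")


def read_ema_csv(path: str) -> pd.DataFrame:
    """Read long-format EMA records, validating ratings row by row."""
    df = pd.read_csv(path, dtype={"participant_id": str, "time": str, "item": str})
    missing = set(EMA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed header: missing column(s) {sorted(missing)}")
    ratings = pd.to_numeric(df["rating"], errors="coerce")
    bad = df["rating"].notna() & ratings.isna()
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(f"non-numeric rating at row {row}")
    out_of_range = ratings.notna() & ((ratings < 1) | (ratings > 7))
    if out_of_range.any():
        row = int(df.index[out_of_range][0]) + 2
        raise ValueError(f"rating outside 1..7 at row {row}")
    df["rating"] = ratings
    df["day"] = df["day"].astype(int)
    if (~df["day"].between(1, 7)).any():
        row = int(df.index[~df["day"].between(1, 7)][0]) + 2
        raise ValueError(f"day outside 1..7 at row {row}")
    return df[list(EMA_COLUMNS)]


def write_ema_csv(records: pd.DataFrame, path: str) -> None:
    """Write long-format EMA records; missing ratings become empty fields."""
    out = records[list(EMA_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format="%g")


def write_wide_csv(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, float_format="%.6g")


def read_wide_csv(path: str, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_distance_matrix(ids: list[str], D: np.ndarray, path: str) -> None:
    pd.DataFrame(D, index=ids, columns=ids).to_csv(path, float_format="%.6g")


def read_distance_matrix(path: str) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)
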