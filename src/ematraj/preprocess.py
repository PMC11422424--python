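"""Compliance filtering and slot-grid harmonization of EMA records.

Two beep designs with different daily windows are harmonized onto a common
grid of six 2-hour slots per day over 7 days (42 slots): slot 1 before noon,
then 12:00-14:00, 14:00-16:00, 16:00-18:00, 18:00-20:00 and 20:00 onward.
Intervals are half-open with the lower bound inclusive.  Ratings landing
after 22:00 (possible under design A, which beeps until 22:30) are kept in
slot 6 rather than discarded, and flagged in the log.  Multiple ratings of
the same item within one participant-day-slot are mean-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ITEMS, N_DAYS, N_SLOTS, SLOTS_PER_DAY
from .simulate import BeepSchedule

#: Upper bounds (minutes from midnight, exclusive except the last) of slots 1-5.
_SLOT_BOUNDS = (12 * 60, 14 * 60, 16 * 60, 18 * 60, 20 * 60)


def parse_clock(time_str: str) -> int:
    """Parse 'HH:MM' into minutes from midnight."""
    try:
        hh, mm = time_str.strip().split(":")
        minutes = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed clock time {time_str!r}") from exc
    if not (0 <= minutes <= 24 * 60):
        raise ValueError(f"clock time {time_str!r} outside 00:00-24:00")
    return minutes


def assign_slot(minutes: int) -> int:
    """Map minutes-from-midnight to slot 1-6 (lower-bound-inclusive bins)."""
    if not (0 <= minutes <= 24 * 60):
        raise ValueError(f"time {minutes} min outside 00:00-24:00")
    for slot, bound in enumerate(_SLOT_BOUNDS, start=1):
        if minutes < bound:
            return slot
    return 6


def slot_index(day: int, slot: int) -> int:
    """0-based position of (day 1-7, slot 1-6) in the 42-slot vector."""
    if not (1 <= day <= N_DAYS):
        raise ValueError(f"day {day} outside 1-{N_DAYS}")
    if not (1 <= slot <= SLOTS_PER_DAY):
        raise ValueError(f"slot {slot} outside 1-{SLOTS_PER_DAY}")
    return (day - 1) * SLOTS_PER_DAY + (slot - 1)


SLOT_COLUMNS = tuple(f"s{i + 1:02d}" for i in range(N_SLOTS))


@dataclass
class ComplianceResult:
    included: list[str]
    log: pd.DataFrame = field(default_factory=pd.DataFrame)


def answered_beep_counts(records: pd.DataFrame) -> pd.Series:
    """Beeps per participant with at least one non-missing item rating."""
    answered = records.dropna(subset=["rating"])
    if answered.empty:
        return pd.Series(dtype=int)
    return answered.groupby("participant_id").apply(
        lambda g: g[["day", "time"]].drop_duplicates().shape[0],
        include_groups=False,
    )


def filter_compliance(
    records: pd.DataFrame,
    schedules: dict[str, BeepSchedule] | None = None,
    presented_beeps: dict[str, int] | None = None,
    min_response_rate: float = 1.0 / 3.0,
) -> ComplianceResult:
    """Retain participants who answered at least ``min_response_rate`` of
    their presented beeps (boundary inclusive).

    Presented-beep counts come from ``schedules`` (synthetic data) or a
    plain ``presented_beeps`` mapping (real data); one of the two is
    required for every participant present in ``records``.
    """
    counts: dict[str, int] = {}
    if schedules:
        counts.update({pid: s.n_beeps for pid, s in schedules.items()})
    if presented_beeps:
        counts.update(presented_beeps)
    participants = list(pd.unique(records["participant_id"]))
    missing = [p for p in participants if p not in counts]
    if missing:
        raise ValueError(
            f"no presented-beep count for participant(s) {missing[:5]}"
        )
    answered = answered_beep_counts(records)
    included, log_rows = [], []
    for pid in participants:
        n_pres = counts[pid]
        n_ans = int(answered.get(pid, 0))
        rate = n_ans / n_pres if n_pres > 0 else 0.0
        if rate >= min_response_rate:
            included.append(pid)
        else:
            log_rows.append(
                {
                    "participant_id": pid,
                    "reason": "low_compliance",
                    "answered": n_ans,
                    "presented": n_pres,
                    "response_rate": rate,
                }
            )
    log = pd.DataFrame(
        log_rows,
        columns=["participant_id", "reason", "answered", "presented", "response_rate"],
    )
    return ComplianceResult(included=included, log=log)


def extract_psychotic_items(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict records to the five psychotic-symptom analysis items.

    Unknown item ids are dropped with a warning; recognised records pass
    through unchanged (count conservation over the five items).
    """
    known = records["item"].isin(ITEMS)
    unknown_items = sorted(set(records.loc[~known, "item"]))
    if unknown_items:
        import warnings

        warnings.warn(
            f"dropping unknown item(s): {unknown_items}", stacklevel=2
        )
    return records.loc[known].reset_index(drop=True)


def assign_slots(records: pd.DataFrame) -> pd.DataFrame:
    """Map records onto the 42-slot grid, averaging within-slot duplicates.

    Returns a wide frame indexed by (participant_id, item) with columns
    s01..s42; empty slots are NaN.  Every participant present yields a row
    for each of the five analysis items, observed or not.
    """
    recs = records.dropna(subset=["rating"]).copy()
    if not recs.empty:
        recs["minutes"] = recs["time"].map(parse_clock)
        recs["slot"] = recs["minutes"].map(assign_slot)
        recs["pos"] = [
            slot_index(d, s) for d, s in zip(recs["day"].astype(int), recs["slot"])
        ]
        means = recs.groupby(["participant_id", "item", "pos"])["rating"].mean()
    else:
        means = pd.Series(dtype=float)
    participants = sorted(pd.unique(records["participant_id"]))
    index = pd.MultiIndex.from_product(
        [participants, list(ITEMS)], names=["participant_id", "item"]
    )
    grid = pd.DataFrame(np.nan, index=index, columns=list(SLOT_COLUMNS))
    for (pid, item, pos), value in means.items():
        grid.loc[(pid, item), SLOT_COLUMNS[pos]] = value
    return grid


def item_matrix(grid: pd.DataFrame, item: str) -> pd.DataFrame:
    """Extract one item's participants x 42 matrix from the slot grid."""
    if item not in ITEMS:
        raise ValueError(f"unknown item {item!r}")
    sub = grid.xs(item, level="item")
    return sub.copy()
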