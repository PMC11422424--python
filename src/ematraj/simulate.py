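"""Synthetic EMA cohorts with known latent subgroup structure.

The generator emulates the pooled two-study design the analysis assumes:
healthy controls (HC), first-degree relatives (RE) and outpatients with a
psychotic disorder (PD) are sampled under one of two beep designs
(design A: up to 10 beeps/day, 08:00-22:30; design B: up to 6 beeps/day,
10:00-22:00) over 7 consecutive days.  Each participant carries a latent
severity class (low/high); PD participants are high-symptom with a larger
probability than the other groups, producing the high-symptom subgroup
concentrated in PD that the clustering stage is meant to recover.

Ratings follow a latent AR(1) process per participant,

    z_t = mu_class + phi * (z_{t-1} - mu_class) + eps_t,   eps ~ N(0, sigma^2),

mapped to the 1-7 Likert scale item-wise through

    rating = clamp(round(1 + loading * max(z_t, 0)), 1, 7),

which reproduces the strong floor effect of psychotic-symptom EMA items in
non-symptomatic participants.  Missingness is applied either per record
(MCAR, single items dropped) or per beep (compliance, whole questionnaires
dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ITEMS, N_DAYS

#: Beep design windows in minutes-from-midnight and daily caps.
DESIGNS = {
    "designA": {"start": 8 * 60, "end": 22 * 60 + 30, "cap": 10},
    "designB": {"start": 10 * 60, "end": 22 * 60, "cap": 6},
}

MIN_GAP_MIN = 30


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort.

    Defaults mirror the pooled analysis sample: 25 HC, 20 RE and 55 PD,
    with roughly 12/55 PD and 3/45 non-PD participants in the latent
    high-symptom class.
    """

    n_hc: int = 25
    n_re: int = 20
    n_pd: int = 55
    high_symptom_fraction_pd: float = 0.22
    high_symptom_fraction_other: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_re, self.n_pd) < 0:
            raise ValueError("group counts must be >= 0")
        if self.n_hc + self.n_re + self.n_pd <= 0:
            raise ValueError("empty cohort")
        if self.n_hc + self.n_re + self.n_pd < 2:
            raise ValueError("cohort must contain at least 2 participants")
        for frac in (self.high_symptom_fraction_pd, self.high_symptom_fraction_other):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("high-symptom fractions must lie in [0, 1]")


@dataclass(frozen=True)
class TrajectoryModelParams:
    """Latent AR(1) trajectory model and ordinal mapping parameters."""

    mean_low: float = 0.0
    mean_high: float = 3.0
    ar1_coefficient: float = 0.5
    item_loadings: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    noise_sd: float = 0.5
    missing_rate: float = 0.35
    missing_mechanism: str = "MCAR"  # "MCAR" or "compliance"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if len(self.item_loadings) != len(ITEMS):
            raise ValueError(f"need {len(ITEMS)} item loadings")
        if any(l <= 0 for l in self.item_loadings):
            raise ValueError("item loadings must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "compliance"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'compliance'")
        if self.mean_high <= self.mean_low:
            raise ValueError("high-class mean must exceed low-class mean")


@dataclass
class BeepSchedule:
    """Per-participant beep times: (day 1-7, minutes from midnight)."""

    participant_id: str
    design_tag: str
    times: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_beeps(self) -> int:
        return len(self.times)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a participant table with group labels and latent classes.

    PD participants fall in the high-symptom class with probability
    ``high_symptom_fraction_pd``, others with ``high_symptom_fraction_other``.
    PD participants are split between the two beep designs (emulating the
    two recruitment arms); HC and RE all follow design A.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    groups = ["HC"] * spec.n_hc + ["RE"] * spec.n_re + ["PD"] * spec.n_pd
    n = len(groups)
    width = max(3, len(str(n)))
    for i, group in enumerate(groups):
        pid = f"P{i + 1:0{width}d}"
        p_high = (
            spec.high_symptom_fraction_pd
            if group == "PD"
            else spec.high_symptom_fraction_other
        )
        latent = "high" if rng.random() < p_high else "low"
        if group == "PD":
            design = "designB" if rng.random() < 26.0 / 55.0 else "designA"
        else:
            design = "designA"
        study = "studyA" if design == "designA" else "studyB"
        rows.append(
            {
                "participant_id": pid,
                "study": study,
                "group": group,
                "design": design,
                "latent_class": latent,
            }
        )
    return pd.DataFrame(rows)


def generate_schedule(
    design_tag: str,
    n_days: int = N_DAYS,
    beeps_per_day: int | None = None,
    seed: int = 0,
    participant_id: str = "",
) -> BeepSchedule:
    """Draw a pseudo-random beep schedule within the design window.

    Beeps are uniform over the admissible window subject to a minimum
    30-minute gap, at minute resolution, strictly increasing within a day.
    """
    if design_tag not in DESIGNS:
        raise ValueError(f"unknown design {design_tag!r}")
    design = DESIGNS[design_tag]
    if beeps_per_day is None:
        beeps_per_day = design["cap"]
    if beeps_per_day > design["cap"]:
        raise ValueError(
            f"{design_tag} allows at most {design['cap']} beeps/day, got {beeps_per_day}"
        )
    if beeps_per_day < 1:
        raise ValueError("beeps_per_day must be >= 1")
    window = design["end"] - design["start"]
    slack = window - (beeps_per_day - 1) * MIN_GAP_MIN
    if slack < 0:
        raise ValueError("window too short for requested beeps with 30-min gaps")
    rng = np.random.default_rng(seed)
    times: list[tuple[int, int]] = []
    for day in range(1, n_days + 1):
        # sorted integer offsets + i*gap gives exact uniform-with-gap sampling
        offsets = np.sort(rng.integers(0, slack + 1, size=beeps_per_day))
        for i, off in enumerate(offsets):
            times.append((day, int(design["start"] + off + i * MIN_GAP_MIN)))
    return BeepSchedule(participant_id=participant_id, design_tag=design_tag, times=times)


def _minutes_to_hhmm(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def generate_schedules(
    cohort: pd.DataFrame, seed: int = 0, beeps_per_day: dict[str, int] | None = None
) -> dict[str, BeepSchedule]:
    """One schedule per cohort participant, each with its own derived seed."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(cohort)) % (2**31)
    schedules = {}
    for row, child in zip(cohort.itertuples(index=False), child_seeds):
        bpd = None if beeps_per_day is None else beeps_per_day.get(row.design)
        schedules[row.participant_id] = generate_schedule(
            row.design,
            beeps_per_day=bpd,
            seed=int(child),
            participant_id=row.participant_id,
        )
    return schedules


def generate_ema_records(
    cohort: pd.DataFrame,
    schedules: dict[str, BeepSchedule],
    params: TrajectoryModelParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate long-format EMA records for every scheduled beep.

    Returns one row per item per beep; missing ratings are NaN.  The latent
    AR(1) state is initialised at its stationary distribution.
    """
    missing = set(cohort["participant_id"]) - set(schedules)
    if missing:
        raise ValueError(f"missing schedule for participants: {sorted(missing)[:5]}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(cohort)) % (2**31)
    loadings = np.asarray(params.item_loadings)
    frames = []
    for row, child in zip(cohort.itertuples(index=False), child_seeds):
        rng = np.random.default_rng(int(child))
        sched = schedules[row.participant_id]
        n_beeps = sched.n_beeps
        mu = params.mean_high if row.latent_class == "high" else params.mean_low
        phi = params.ar1_coefficient
        sd = params.noise_sd
        z = np.empty(n_beeps)
        stat_sd = sd / math.sqrt(1.0 - phi**2) if sd > 0 else 0.0
        z[0] = mu + rng.normal(0.0, stat_sd) if stat_sd > 0 else mu
        eps = rng.normal(0.0, sd, size=n_beeps) if sd > 0 else np.zeros(n_beeps)
        for t in range(1, n_beeps):
            z[t] = mu + phi * (z[t - 1] - mu) + eps[t]
        pos = np.maximum(z, 0.0)
        # beeps x items ordinal ratings
        ratings = np.clip(np.rint(1.0 + np.outer(pos, loadings)), 1, 7)
        if params.missing_mechanism == "compliance":
            beep_missing = rng.random(n_beeps) < params.missing_rate
            mask = np.repeat(beep_missing[:, None], len(ITEMS), axis=1)
        else:
            mask = rng.random(ratings.shape) < params.missing_rate
        ratings = ratings.astype(float)
        ratings[mask] = np.nan
        days = [d for d, _ in sched.times]
        clocks = [_minutes_to_hhmm(m) for _, m in sched.times]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": row.participant_id,
                    "study": row.study,
                    "group": row.group,
                    "day": np.repeat(days, len(ITEMS)),
                    "time": np.repeat(clocks, len(ITEMS)),
                    "item": np.tile(ITEMS, n_beeps),
                    "rating": ratings.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    spec: CohortSpec | None = None,
    params: TrajectoryModelParams | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, BeepSchedule]]:
    """Convenience wrapper: cohort + schedules + records in one call.

    Returns ``(records, cohort, schedules)``.  ``seed`` overrides the
    cohort-spec seed and drives schedules and records through fixed
    sub-seeds.
    """
    spec = spec or CohortSpec()
    params = params or TrajectoryModelParams()
    if seed is not None:
        spec = CohortSpec(
            n_hc=spec.n_hc,
            n_re=spec.n_re,
            n_pd=spec.n_pd,
            high_symptom_fraction_pd=spec.high_symptom_fraction_pd,
            high_symptom_fraction_other=spec.high_symptom_fraction_other,
            seed=seed,
        )
    cohort = generate_cohort(spec)
    schedules = generate_schedules(cohort, seed=spec.seed + 1)
    records = generate_ema_records(cohort, schedules, params, seed=spec.seed + 2)
    return records, cohort, schedules
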