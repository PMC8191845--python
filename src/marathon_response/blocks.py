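"""4-week training-block aggregation.

Workouts are assigned to four consecutive 4-week blocks counted back from
the marathon's first GPS timestamp (a week is a fixed 604,800 s; no
calendar alignment).  Block summaries hold the scalar sums (training time,
distance, long-workout counts), the block-best 10-km velocity, the pooled
duration distributions over relative velocity and relative HR with their
probability/cumulative forms, the distribution means, and the shares of
training time in the three intensity zones:

* LIT        — below the marathon velocity (relative velocity <= 1.0)
* threshold  — between 1.0 and 1.2
* HIT        — above 1.2

The same aggregation applied to *all* in-window workouts yields the
subject's overall training statistics (block index 0 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import (
    HIT_EDGE_IDX,
    HR_EDGES,
    LIT_EDGE_IDX,
    VEL_EDGES,
    DurationDistribution,
    WorkoutFeatures,
)

WEEK_S = 604_800
BLOCK_S = 4 * WEEK_S


def assign_block(workout_start: int, marathon_start: int) -> int | None:
    """Training-block index (1..4) for a workout, or None if out of window.

    With delta = marathon_start - workout_start: block 1 covers
    12w <= delta < 16w, …, block 4 covers 0 < delta < 4w.  Workouts at or
    after the marathon start, or 16+ weeks before it, fall outside.
    """
    delta = marathon_start - workout_start
    if delta <= 0 or delta >= 16 * WEEK_S:
        return None
    return 4 - int(delta // BLOCK_S)


def to_probability(durations: np.ndarray) -> np.ndarray:
    """Probability distribution: bin durations over total time."""
    total = durations.sum()
    if total <= 0:
        raise ValueError("cannot normalize an empty duration distribution")
    return durations / total


def to_cumulative(p: np.ndarray) -> np.ndarray:
    """Cumulative distribution (running sum over bins in edge order)."""
    return np.cumsum(p)


def bin_representatives(edges: np.ndarray) -> np.ndarray:
    """Representative value per bin for distribution means.

    Interior bins use their midpoint; the open-ended first and last bins
    clamp to their single closed edge.
    """
    mids = (edges[:-1] + edges[1:]) / 2.0
    return np.concatenate(([edges[0]], mids, [edges[-1]]))


def distribution_mean(p: np.ndarray, edges: np.ndarray) -> float:
    """Mean of a probability distribution under the bin representatives."""
    return float(np.dot(bin_representatives(edges), p))


def zone_shares(f_vel: np.ndarray) -> tuple[float, float, float]:
    """(LIT, threshold, HIT) time shares from the cumulative velocity
    distribution, split at the bin edges 1.0 and 1.2."""
    lit = float(f_vel[LIT_EDGE_IDX])
    thr = float(f_vel[HIT_EDGE_IDX] - f_vel[LIT_EDGE_IDX])
    hit = float(1.0 - f_vel[HIT_EDGE_IDX])
    return lit, thr, hit


@dataclass
class BlockSummary:
    """Aggregates of one training block (block 0 = overall 16 weeks)."""

    block: int
    n_workouts: int
    t_hours: float
    d_km: float
    n_t90: int
    n_d15: int
    v10: float | None
    hr10_at_best: float | None  # mean HR of the workout achieving v10
    vel_durations: np.ndarray
    hr_durations: np.ndarray
    p_vel: np.ndarray | None
    f_vel: np.ndarray | None
    p_hr: np.ndarray | None
    f_hr: np.ndarray | None
    v_bar: float | None
    hr_bar: float | None
    lit: float | None
    threshold: float | None
    hit: float | None

    @property
    def empty(self) -> bool:
        return self.n_workouts == 0


def aggregate_block(features: Sequence[WorkoutFeatures], block: int) -> BlockSummary:
    """Aggregate the workouts of one block (empty blocks yield a flagged
    summary with zero sums and absent distribution statistics)."""
    n = len(features)
    t_hours = sum(f.t_min for f in features) / 60.0
    d_km = sum(f.d_km for f in features)
    n_t90 = sum(f.i_t90 for f in features)
    n_d15 = sum(f.i_d15 for f in features)

    v10, hr10_at_best = None, None
    for f in features:
        if f.v10 is not None and (v10 is None or f.v10 > v10):
            v10, hr10_at_best = f.v10, f.hr10

    vel_dur = np.zeros(len(VEL_EDGES) + 1)
    hr_dur = np.zeros(len(HR_EDGES) + 1)
    for f in features:
        vel_dur += f.vel_dist.durations
        hr_dur += f.hr_dist.durations

    p_vel = f_vel = p_hr = f_hr = None
    v_bar = hr_bar = lit = thr = hit = None
    if vel_dur.sum() > 0:
        p_vel = to_probability(vel_dur)
        f_vel = to_cumulative(p_vel)
        v_bar = distribution_mean(p_vel, VEL_EDGES)
        lit, thr, hit = zone_shares(f_vel)
    if hr_dur.sum() > 0:
        p_hr = to_probability(hr_dur)
        f_hr = to_cumulative(p_hr)
        hr_bar = distribution_mean(p_hr, HR_EDGES)

    return BlockSummary(
        block=block,
        n_workouts=n,
        t_hours=t_hours,
        d_km=d_km,
        n_t90=n_t90,
        n_d15=n_d15,
        v10=v10,
        hr10_at_best=hr10_at_best,
        vel_durations=vel_dur,
        hr_durations=hr_dur,
        p_vel=p_vel,
        f_vel=f_vel,
        p_hr=p_hr,
        f_hr=f_hr,
        v_bar=v_bar,
        hr_bar=hr_bar,
        lit=lit,
        threshold=thr,
        hit=hit,
    )


def aggregate_blocks(
    features: Sequence[WorkoutFeatures], marathon_start: int
) -> tuple[list[BlockSummary], BlockSummary]:
    """Split in-window workouts into blocks 1..4 and aggregate each, plus
    the overall summary over all in-window workouts (block 0)."""
    by_block: dict[int, list[WorkoutFeatures]] = {1: [], 2: [], 3: [], 4: []}
    in_window: list[WorkoutFeatures] = []
    for f in features:
        b = assign_block(f.start_time, marathon_start)
        if b is not None:
            by_block[b].append(f)
            in_window.append(f)
    blocks = [aggregate_block(by_block[b], b) for b in (1, 2, 3, 4)]
    overall = aggregate_block(in_window, 0)
    return blocks, overall
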