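"""Subject-level metrics and the cohort filter cascade.

Per subject this module derives the marathon performance (T_mp, v_mp), the
surrogate maximal heart rate (median of the five highest recorded HR
samples), the 4-week block summaries, and the training-response deltas
(Δv10, Δv̄, Δh̄r = block 4 minus block 1).

The filter cascade runs in a fixed order, each stage logging its
exclusions:

1. eligibility — exactly one marathon-distance workout (41–43 km), at
   least 16 training workouts inside the 16-week window, GPS *and* HR in
   every workout;
2. IQR — subjects whose T_mp, total distance, total duration, or hr_max
   lies beyond 1.5·IQR outside the quartiles of the eligible cohort are
   dropped (single pass, fences from the pre-filter cohort, inclusive
   bounds);
3. effort — the block-best 10-km runs of blocks 1 and 4 must have been
   performed at a mean heart rate of at least 0.8·hr_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import features as ft
from .blocks import BlockSummary, aggregate_blocks, assign_block
from .stream_io import WorkoutStream

log = logging.getLogger(__name__)

MARATHON_KM_MIN = 41.0
MARATHON_KM_MAX = 43.0
EFFORT_FRACTION = 0.8
IQR_FACTOR = 1.5
#: Subject parameters screened by the IQR filter.
IQR_PARAMS = ("t_mp", "d_km", "t_hours", "hr_max")


class NotAMarathonError(ValueError):
    """Workout distance outside the accepted 41–43 km marathon band."""


class InsufficientHRError(ValueError):
    """Fewer than five HR samples across the observation period."""


@dataclass
class SubjectSummary:
    """Everything the grouping and statistics stages need for one subject."""

    subject_id: str
    marathon_start: int
    t_mp: float  # marathon performance time [s]
    v_mp: float  # average marathon velocity [m/s]
    hr_max: float  # surrogate maximal HR [bpm]
    n_workouts: int
    t_hours: float
    d_km: float
    n_t90: int
    n_d15: int
    v10_overall: float | None
    v_bar_overall: float | None
    hr_bar_overall: float | None
    lit: float | None
    threshold: float | None
    hit: float | None
    blocks: list[BlockSummary]
    overall: BlockSummary
    delta_v10: float | None
    delta_v_bar: float | None
    delta_hr_bar: float | None
    filter_flags: set = field(default_factory=set)


def marathon_performance(marathon: WorkoutStream) -> tuple[float, float]:
    """(T_mp [s], v_mp [m/s]) from the marathon workout's GPS channel."""
    d_km, _ = ft.total_distance(marathon.lat, marathon.lon)
    if not (MARATHON_KM_MIN <= d_km <= MARATHON_KM_MAX):
        raise NotAMarathonError(f"marathon distance {d_km:.1f} km outside [41, 43]")
    t_mp = float(marathon.gps_t[-1] - marathon.gps_t[0])
    return t_mp, d_km * 1000.0 / t_mp


def training_hr_max(hr_values: Iterable[np.ndarray]) -> float:
    """Median of the five highest HR samples over the whole observation
    period (robust surrogate for the maximal heart rate)."""
    arrays = [np.asarray(a, dtype=float) for a in hr_values]
    allhr = np.concatenate([a for a in arrays if a.size]) if arrays else np.empty(0)
    if allhr.size < 5:
        raise InsufficientHRError(f"only {allhr.size} HR samples, need >= 5")
    top5 = np.partition(allhr, -5)[-5:]
    return float(np.median(top5))


def response_metrics(
    blocks: Sequence[BlockSummary],
) -> tuple[float | None, float | None, float | None]:
    """(Δv10, Δv̄, Δh̄r) as block-4 minus block-1 differences.

    Δv10 is None when either block lacks a 10-km effort; the mean deltas
    are None when either block is empty.
    """
    b1, b4 = blocks[0], blocks[3]
    dv10 = None
    if b1.v10 is not None and b4.v10 is not None:
        dv10 = b4.v10 - b1.v10
    dvbar = None if b1.v_bar is None or b4.v_bar is None else b4.v_bar - b1.v_bar
    dhrbar = None if b1.hr_bar is None or b4.hr_bar is None else b4.hr_bar - b1.hr_bar
    return dv10, dvbar, dhrbar


def find_marathon(
    streams: Sequence[WorkoutStream], distances_km: Sequence[float]
) -> tuple[int | None, str | None]:
    """Index of the single marathon-distance workout, or (None, reason)."""
    idx = [i for i, d in enumerate(distances_km) if MARATHON_KM_MIN <= d <= MARATHON_KM_MAX]
    if len(idx) == 0:
        return None, "no_marathon"
    if len(idx) > 1:
        return None, "multiple_marathons"
    return idx[0], None


def eligibility_filter(
    streams: Sequence[WorkoutStream],
    distances_km: Sequence[float] | None = None,
    marathon_date_range: tuple[int, int] | None = None,
) -> tuple[bool, str | None, int | None]:
    """Apply the subject-selection criteria.

    Returns (passed, fail_reason, marathon_index).  Criteria: exactly one
    41–43 km workout; >= 16 other workouts starting inside the 16-week
    window before it; both channels non-empty in every workout.  An
    optional UTC ``marathon_date_range`` restricts when the marathon may
    have been run (off by default; calendar criteria are metadata, not
    physiology).
    """
    if distances_km is None:
        distances_km = [ft.total_distance(s.lat, s.lon)[0] for s in streams]
    m_idx, reason = find_marathon(streams, distances_km)
    if m_idx is None:
        return False, reason, None
    if marathon_date_range is not None:
        lo, hi = marathon_date_range
        if not (lo <= streams[m_idx].start_time <= hi):
            return False, "marathon_outside_date_range", m_idx
    if any(s.n_hr == 0 for s in streams):
        return False, "missing_channel", m_idx
    marathon_start = streams[m_idx].start_time
    n_in_window = sum(
        1
        for i, s in enumerate(streams)
        if i != m_idx and assign_block(s.start_time, marathon_start) is not None
    )
    if n_in_window < 16:
        return False, "too_few_workouts", m_idx
    return True, None, m_idx


def extract_subject(
    subject_id: str,
    streams: Sequence[WorkoutStream],
    hr_max_includes_marathon: bool = True,
    spike_filter: bool = False,
) -> tuple[dict | None, str | None, list[ft.WorkoutFeatures] | None]:
    """Eligibility check plus subject constants and per-workout features.

    Returns (constants, None, features-of-training-workouts) for an
    eligible subject or (None, reason, None) otherwise.  Constants:
    marathon_start, t_mp, v_mp, hr_max.  The marathon workout itself is
    excluded from the training features (it is the outcome being
    predicted, not training).
    """
    distances = [ft.total_distance(s.lat, s.lon)[0] for s in streams]
    ok, reason, m_idx = eligibility_filter(streams, distances)
    if not ok:
        return None, reason, None
    marathon = streams[m_idx]
    t_mp, v_mp = marathon_performance(marathon)
    hr_sources = [
        s.hr for i, s in enumerate(streams) if hr_max_includes_marathon or i != m_idx
    ]
    hr_max = training_hr_max(hr_sources)
    feats = [
        ft.compute_workout_features(s, v_mp, hr_max, spike_filter=spike_filter)
        for i, s in enumerate(streams)
        if i != m_idx
    ]
    constants = {
        "subject_id": subject_id,
        "marathon_start": marathon.start_time,
        "t_mp": t_mp,
        "v_mp": v_mp,
        "hr_max": hr_max,
    }
    return constants, None, feats


def assemble_summary(constants: dict, feats: Sequence[ft.WorkoutFeatures]) -> SubjectSummary:
    """Block aggregation and response deltas from extracted features."""
    blocks, overall = aggregate_blocks(feats, constants["marathon_start"])
    dv10, dvbar, dhrbar = response_metrics(blocks)
    return SubjectSummary(
        subject_id=constants["subject_id"],
        marathon_start=constants["marathon_start"],
        t_mp=constants["t_mp"],
        v_mp=constants["v_mp"],
        hr_max=constants["hr_max"],
        n_workouts=overall.n_workouts,
        t_hours=overall.t_hours,
        d_km=overall.d_km,
        n_t90=overall.n_t90,
        n_d15=overall.n_d15,
        v10_overall=overall.v10,
        v_bar_overall=overall.v_bar,
        hr_bar_overall=overall.hr_bar,
        lit=overall.lit,
        threshold=overall.threshold,
        hit=overall.hit,
        blocks=blocks,
        overall=overall,
        delta_v10=dv10,
        delta_v_bar=dvbar,
        delta_hr_bar=dhrbar,
    )


def build_subject_summary(
    subject_id: str,
    streams: Sequence[WorkoutStream],
    hr_max_includes_marathon: bool = True,
    spike_filter: bool = False,
) -> tuple[SubjectSummary | None, str | None]:
    """Eligibility plus full per-subject metric extraction.

    Returns (summary, None) for an eligible subject or (None, reason)
    otherwise.
    """
    constants, reason, feats = extract_subject(
        subject_id, streams,
        hr_max_includes_marathon=hr_max_includes_marathon,
        spike_filter=spike_filter,
    )
    if constants is None:
        return None, reason
    return assemble_summary(constants, feats), None


def iqr_fences(values: np.ndarray, factor: float = IQR_FACTOR) -> tuple[float, float]:
    """Inclusive Tukey fences [Q1 - f·IQR, Q3 + f·IQR] with linearly
    interpolated quartiles."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return float(q1 - factor * iqr), float(q3 + factor * iqr)


def iqr_filter(
    summaries: Sequence[SubjectSummary],
) -> tuple[list[SubjectSummary], list[tuple[str, str]]]:
    """Single-pass IQR outlier exclusion over (T_mp, D, T, hr_max).

    Fences are computed once on the incoming (eligible) cohort; a subject
    is excluded if *any* of the four parameters falls outside its fences.
    Returns (kept, [(subject_id, offending-params-reason), ...]).
    """
    if len(summaries) < 4:
        return list(summaries), []
    table = {
        "t_mp": np.array([s.t_mp for s in summaries]),
        "d_km": np.array([s.d_km for s in summaries]),
        "t_hours": np.array([s.t_hours for s in summaries]),
        "hr_max": np.array([s.hr_max for s in summaries]),
    }
    fences = {k: iqr_fences(v) for k, v in table.items()}
    kept, excluded = [], []
    for i, s in enumerate(summaries):
        bad = [
            k for k in IQR_PARAMS
            if not (fences[k][0] <= table[k][i] <= fences[k][1])
        ]
        if bad:
            s.filter_flags.add("iqr_excluded")
            excluded.append((s.subject_id, "iqr_outlier:" + "+".join(bad)))
        else:
            kept.append(s)
    if excluded:
        log.info("IQR filter excluded %d of %d subjects", len(excluded), len(summaries))
    return kept, excluded


def effort_filter(summary: SubjectSummary) -> bool:
    """True iff the block-best 10-km runs of blocks 1 and 4 both reached a
    mean HR of at least 0.8·hr_max (inclusive bound)."""
    for b in (summary.blocks[0], summary.blocks[3]):
        if b.v10 is None or b.hr10_at_best is None:
            return False
        if b.hr10_at_best < EFFORT_FRACTION * summary.hr_max:
            return False
    return True


def apply_filter_cascade(
    summaries_or_exclusions: Sequence[tuple[str, SubjectSummary | None, str | None]],
) -> tuple[list[SubjectSummary], pd.DataFrame]:
    """Run IQR and effort stages after eligibility, collecting a log.

    Input rows are (subject_id, summary-or-None, eligibility-reason).
    Returns (surviving summaries, exclusion log with stage and reason).
    """
    rows = []
    eligible: list[SubjectSummary] = []
    for sid, summ, reason in summaries_or_exclusions:
        if summ is None:
            rows.append({"subject_id": sid, "stage": "eligibility", "reason": reason})
        else:
            eligible.append(summ)
    kept, iqr_excluded = iqr_filter(eligible)
    rows += [
        {"subject_id": sid, "stage": "iqr", "reason": reason}
        for sid, reason in iqr_excluded
    ]
    final = []
    for s in kept:
        if effort_filter(s):
            final.append(s)
        else:
            s.filter_flags.add("effort_excluded")
            rows.append(
                {"subject_id": s.subject_id, "stage": "effort", "reason": "hr10_below_0.8_hrmax"}
            )
    log.info(
        "filter cascade: %d eligible, %d after IQR, %d after effort",
        len(eligible), len(kept), len(final),
    )
    return final, pd.DataFrame(rows, columns=["subject_id", "stage", "reason"])
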