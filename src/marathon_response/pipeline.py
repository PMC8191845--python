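"""End-to-end orchestration: streams -> features -> blocks -> filters ->
groups -> statistics -> plausibility.

Two entry paths share all stage logic: an in-memory path over
:class:`~marathon_response.simulate.SimSubject` collections (used by the
test-suite and the acceptance script) and a file-based path used by the
CLI, whose intermediate artifacts are plain CSV so every stage can be
rerun independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .grouping import assign_groups
from .simulate import SimConfig, SimSubject, iter_subjects, truth_table
from .stream_io import WorkoutStream, write_table
from .subjects import SubjectSummary, apply_filter_cascade, build_subject_summary

log = logging.getLogger(__name__)

#: 16-week training parameters entering the two-way ANOVA (workout counts
#: W, I_T90, I_D15 are excluded as non-continuous).
TWO_WAY_PARAMS = {
    "t_hours": "t_hours",
    "d_km": "d_km",
    "hr_bar": "hr_bar_overall",
    "v_bar": "v_bar_overall",
    "v10": "v10_overall",
    "lit": "lit",
    "threshold": "threshold",
    "hit": "hit",
}


@dataclass
class CohortResult:
    """All artifacts of one pipeline run."""

    summaries: list[SubjectSummary]  # subjects surviving all filters
    subject_table: pd.DataFrame  # one row per surviving subject, with groups
    block_table: pd.DataFrame  # one row per (subject, block 0..4)
    exclusions: pd.DataFrame
    one_way_table: pd.DataFrame
    two_way_table: pd.DataFrame
    rm_table: pd.DataFrame
    plausibility: st.PlausibilityReport | None


def summary_row(s: SubjectSummary) -> dict:
    return {
        "subject_id": s.subject_id,
        "marathon_start": s.marathon_start,
        "t_mp": s.t_mp,
        "v_mp": s.v_mp,
        "hr_max": s.hr_max,
        "n_workouts": s.n_workouts,
        "t_hours": s.t_hours,
        "d_km": s.d_km,
        "n_t90": s.n_t90,
        "n_d15": s.n_d15,
        "v10_overall": s.v10_overall,
        "v_bar_overall": s.v_bar_overall,
        "hr_bar_overall": s.hr_bar_overall,
        "lit": s.lit,
        "threshold": s.threshold,
        "hit": s.hit,
        "v10_tb1": s.blocks[0].v10,
        "v10_tb4": s.blocks[3].v10,
        "delta_v10": s.delta_v10,
        "delta_v_bar": s.delta_v_bar,
        "delta_hr_bar": s.delta_hr_bar,
    }


def block_rows(s: SubjectSummary) -> list[dict]:
    rows = []
    for b in [*s.blocks, s.overall]:
        rows.append({
            "subject_id": s.subject_id,
            "block": b.block,  # 0 = overall
            "is_overall": int(b.block == 0),
            "n_workouts": b.n_workouts,
            "t_hours": b.t_hours,
            "d_km": b.d_km,
            "n_t90": b.n_t90,
            "n_d15": b.n_d15,
            "v10": b.v10,
            "hr10_at_best": b.hr10_at_best,
            "v_bar": b.v_bar,
            "hr_bar": b.hr_bar,
            "lit": b.lit,
            "threshold": b.threshold,
            "hit": b.hit,
        })
    return rows


def run_statistics(
    subject_table: pd.DataFrame, block_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All three ANOVA families on a grouped cohort.

    Returns tidy (one_way, two_way, repeated_measures) tables with one row
    per (parameter, effect): sums of squares, df, F, p, partial η² and the
    significance-gated star code.
    """
    def _row(param, res: st.AnovaResult, extra=None):
        d = {
            "parameter": param,
            "effect": res.effect,
            "ss_effect": res.ss_effect,
            "ss_error": res.ss_error,
            "df_effect": res.df_effect,
            "df_error": res.df_error,
            "F": res.f,
            "p": res.p,
            "partial_eta2": res.partial_eta2,
            "stars": res.stars,
        }
        if res.p_gg is not None:
            d["p_gg"] = res.p_gg
        if extra:
            d.update(extra)
        return d

    one_way = []
    for param in ("delta_v_bar", "delta_hr_bar"):
        try:
            res = st.one_way_anova(subject_table[param], subject_table["response"])
        except st.DegenerateInputError as err:
            log.warning("one-way ANOVA on %s skipped: %s", param, err)
            continue
        one_way.append(_row(param, res))

    two_way = []
    for param, col in TWO_WAY_PARAMS.items():
        try:
            results = st.two_way_anova(subject_table, col, "response", "marathon")
        except st.DegenerateInputError as err:
            log.warning("two-way ANOVA on %s skipped: %s", param, err)
            continue
        for res in results.values():
            two_way.append(_row(param, res))

    # repeated measures: zone share over blocks 1..4, per response stratum
    # and per (response, marathon) cell; subjects with empty blocks drop out
    rm = []
    blocks14 = block_table[block_table["block"].between(1, 4)]
    groups = subject_table[["subject_id", "response", "marathon"]]
    merged = blocks14.merge(groups, on="subject_id")
    complete = merged.groupby("subject_id")["block"].transform("size") == 4
    merged = merged[complete & merged["lit"].notna()]
    strata = [("response", [r]) for r in ("low", "moderate", "high")]
    for zone in ("lit", "threshold", "hit"):
        for _, resp in strata:
            sub = merged[merged["response"].isin(resp)]
            if sub["subject_id"].nunique() < 2:
                continue
            try:
                res = st.rm_anova(sub, zone, "block", "subject_id")
            except st.DegenerateInputError as err:
                log.warning("RM ANOVA %s/%s skipped: %s", zone, resp, err)
                continue
            rm.append(_row(zone, res, {"response": resp[0], "marathon": "all"}))
        for resp in ("low", "moderate", "high"):
            for mar in ("slow", "medium", "fast"):
                sub = merged[(merged["response"] == resp) & (merged["marathon"] == mar)]
                if sub["subject_id"].nunique() < 2:
                    continue
                try:
                    res = st.rm_anova(sub, zone, "block", "subject_id")
                except st.DegenerateInputError as err:
                    continue
                rm.append(_row(zone, res, {"response": resp, "marathon": mar}))
    return pd.DataFrame(one_way), pd.DataFrame(two_way), pd.DataFrame(rm)


def analyze_summaries(
    triples: Sequence[tuple[str, SubjectSummary | None, str | None]],
    with_plausibility: bool = True,
) -> CohortResult:
    """Filter cascade + grouping + statistics over per-subject summaries."""
    final, exclusions = apply_filter_cascade(triples)
    if not final:
        return CohortResult(
            summaries=[], subject_table=pd.DataFrame(), block_table=pd.DataFrame(),
            exclusions=exclusions, one_way_table=pd.DataFrame(),
            two_way_table=pd.DataFrame(), rm_table=pd.DataFrame(), plausibility=None,
        )
    subject_table = pd.DataFrame([summary_row(s) for s in final])
    block_table = pd.DataFrame([r for s in final for r in block_rows(s)])
    groups = assign_groups(
        subject_table["v10_tb1"].to_numpy(),
        subject_table["delta_v10"].to_numpy(),
        subject_table["t_mp"].to_numpy(),
    )
    for k, v in groups.items():
        subject_table[k] = v
    if len(subject_table) >= 4 and subject_table["response"].nunique() > 1:
        one_way, two_way, rm = run_statistics(subject_table, block_table)
    else:
        log.warning("too few subjects for statistics stage")
        one_way = two_way = rm = pd.DataFrame()
    plaus = None
    if with_plausibility and len(subject_table) >= 3:
        plaus = st.plausibility_report(
            subject_table["t_mp"].to_numpy(),
            subject_table["hr_max"].to_numpy(),
            subject_table["delta_v10"].to_numpy(),
            subject_table["v10_overall"].to_numpy(),
            subject_table["v_mp"].to_numpy(),
            subject_table["marathon_start"].to_numpy(),
        )
    return CohortResult(
        summaries=final,
        subject_table=subject_table,
        block_table=block_table,
        exclusions=exclusions,
        one_way_table=one_way,
        two_way_table=two_way,
        rm_table=rm,
        plausibility=plaus,
    )


def analyze_streams(
    cohort: Iterable[tuple[str, Sequence[WorkoutStream]]],
    hr_max_includes_marathon: bool = True,
    spike_filter: bool = False,
    with_plausibility: bool = True,
) -> CohortResult:
    """Full pipeline over raw workout streams, one subject at a time."""
    triples = []
    for subject_id, streams in cohort:
        summary, reason = build_subject_summary(
            subject_id, streams,
            hr_max_includes_marathon=hr_max_includes_marathon,
            spike_filter=spike_filter,
        )
        triples.append((subject_id, summary, reason))
    return analyze_summaries(triples, with_plausibility=with_plausibility)


def _lighten(w):
    """Drop the sample arrays of a simulated workout, keeping start time,
    kind and the true zone seconds (enough for block-level truth)."""
    from .simulate import SimWorkout

    light_stream = WorkoutStream(
        w.stream.subject_id, w.stream.workout_id,
        w.stream.gps_t[:2].copy(), w.stream.lat[:2].copy(), w.stream.lon[:2].copy(),
    )
    return SimWorkout(stream=light_stream, kind=w.kind, week=w.week,
                      zone_seconds=w.zone_seconds)


def run_simulated(
    config: SimConfig,
    violations: dict[int, str] | None = None,
    keep_streams: bool = False,
    **flags,
) -> tuple[CohortResult, pd.DataFrame, list[SimSubject]]:
    """Simulate a cohort and push it through the full pipeline.

    Returns (pipeline result, truth table, simulated subjects).  Sample
    arrays are dropped subject-by-subject unless ``keep_streams``, leaving
    only the ground-truth annotations needed for recovery checks.
    """
    triples, subjects = [], []
    for sub in iter_subjects(config, violations):
        summary, reason = build_subject_summary(
            sub.params.subject_id, [w.stream for w in sub.workouts], **flags
        )
        triples.append((sub.params.subject_id, summary, reason))
        if not keep_streams:
            sub.workouts = [_lighten(w) for w in sub.workouts]
        subjects.append(sub)
    truth = truth_table([s.params for s in subjects])
    return analyze_summaries(triples), truth, subjects


def write_artifacts(result: CohortResult, outdir: str | Path) -> None:
    """Write every pipeline table as CSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.subject_table.to_csv(outdir / "subjects.csv", index=False, float_format="%.10g")
    result.block_table.to_csv(outdir / "blocks.csv", index=False, float_format="%.10g")
    result.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    result.one_way_table.to_csv(outdir / "anova_one_way.csv", index=False, float_format="%.10g")
    result.two_way_table.to_csv(outdir / "anova_two_way.csv", index=False, float_format="%.10g")
    result.rm_table.to_csv(outdir / "anova_repeated_measures.csv", index=False, float_format="%.10g")
    if result.plausibility is not None:
        p = result.plausibility
        counts_t, edges_t = p.t_mp_hist
        counts_h, edges_h = p.hr_max_hist
        write_table(
            [{
                "pearson_r": p.pearson_r, "slope": p.slope, "intercept": p.intercept,
                "weekend_share": p.weekend_share,
            }],
            outdir / "plausibility.csv",
        )
        write_table(
            [{"bin_start_s": a, "count": c} for a, c in zip(edges_t[:-1], counts_t)],
            outdir / "hist_t_mp.csv", columns=["bin_start_s", "count"],
        )
        write_table(
            [{"bin_start_bpm": a, "count": c} for a, c in zip(edges_h[:-1], counts_h)],
            outdir / "hist_hr_max.csv", columns=["bin_start_bpm", "count"],
        )
        write_table(
            [{"rank": i, "delta_v10": v} for i, v in enumerate(p.delta_v10_sorted)],
            outdir / "delta_v10_sorted.csv", columns=["rank", "delta_v10"],
        )
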