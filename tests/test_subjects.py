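"""Subject constants, response deltas, and the filter cascade."""

import numpy as np
import pytest

from marathon_response.blocks import WEEK_S, BlockSummary
from marathon_response.features import VEL_EDGES, HR_EDGES
from marathon_response.subjects import (
    InsufficientHRError,
    NotAMarathonError,
    SubjectSummary,
    apply_filter_cascade,
    effort_filter,
    eligibility_filter,
    iqr_fences,
    iqr_filter,
    marathon_performance,
    response_metrics,
    training_hr_max,
)

from conftest import east_stream

M = 10_000_000


def marathon_stream(total_m=42_200.0, duration_s=14_400, t0=M, hr=True):
    n = 100
    speeds = np.full(n, total_m / duration_s)
    s = east_stream(speeds, dt=duration_s // n, t0=t0,
                    hr=[150.0] * 5 if hr else None, hr_dt=duration_s // 5)
    return s


class TestMarathonPerformance:
    def test_typical_marathon(self):
        t_mp, v_mp = marathon_performance(marathon_stream())
        assert t_mp == pytest.approx(14_400, abs=1)
        assert v_mp == pytest.approx(42_200 / 14_400, rel=1e-6)

    def test_too_short_raises(self):
        with pytest.raises(NotAMarathonError):
            marathon_performance(marathon_stream(total_m=40_900))

    def test_upper_band_accepted(self):
        _, v_mp = marathon_performance(marathon_stream(total_m=43_000))
        assert v_mp == pytest.approx(43_000 / 14_400, rel=1e-6)


class TestTrainingHrMax:
    def test_median_of_top_five(self):
        hr = np.array([120.0, 200, 198, 197, 196, 195, 130, 150])
        assert training_hr_max([hr]) == 197.0

    def test_constant_samples(self):
        assert training_hr_max([np.full(20, 180.0)]) == 180.0

    def test_exactly_five_samples(self):
        assert training_hr_max([np.array([150.0, 160, 170, 180, 190])]) == 170.0

    def test_across_multiple_workouts(self):
        assert training_hr_max([np.array([200.0, 198]), np.array([197.0, 196, 195])]) == 197.0

    def test_too_few_raises(self):
        with pytest.raises(InsufficientHRError):
            training_hr_max([np.array([150.0, 160, 170])])


def _block(v10=None, hr10=None, v_bar=None, hr_bar=None, block=1):
    nb = len(VEL_EDGES) + 1
    return BlockSummary(
        block=block, n_workouts=1, t_hours=1.0, d_km=10.0, n_t90=0, n_d15=0,
        v10=v10, hr10_at_best=hr10,
        vel_durations=np.zeros(nb), hr_durations=np.zeros(len(HR_EDGES) + 1),
        p_vel=None, f_vel=None, p_hr=None, f_hr=None,
        v_bar=v_bar, hr_bar=hr_bar, lit=None, threshold=None, hit=None,
    )


class TestResponseMetrics:
    def test_positive_improvement(self):
        blocks = [_block(v10=3.0, v_bar=1.0, hr_bar=0.8), _block(), _block(),
                  _block(v10=3.5, v_bar=1.1, hr_bar=0.82, block=4)]
        dv10, dvbar, dhrbar = response_metrics(blocks)
        assert dv10 == pytest.approx(0.5)
        assert dvbar == pytest.approx(0.1)
        assert dhrbar == pytest.approx(0.02)

    def test_identical_blocks_zero_delta(self):
        b = _block(v10=3.0, v_bar=1.05, hr_bar=0.8)
        b4 = _block(v10=3.0, v_bar=1.05, hr_bar=0.8, block=4)
        assert response_metrics([b, b, b, b4]) == pytest.approx((0.0, 0.0, 0.0))

    def test_negative_mean_velocity_delta(self):
        blocks = [_block(v10=3.0, v_bar=1.05), _block(), _block(),
                  _block(v10=3.0, v_bar=0.98, block=4)]
        assert response_metrics(blocks)[1] == pytest.approx(-0.07)

    def test_missing_v10_undefined(self):
        blocks = [_block(v10=None), _block(), _block(), _block(v10=3.5, block=4)]
        assert response_metrics(blocks)[0] is None


def _training_workout(t0):
    return east_stream([3.0] * 30, dt=10, t0=t0, hr=[150.0] * 10, hr_dt=30)


class TestEligibility:
    def _streams(self, n_training, with_hr=True, with_marathon=True):
        streams = []
        for k in range(n_training):
            week = k % 16
            t0 = M - (16 - week) * WEEK_S + 3600 * (1 + k // 16)
            streams.append(_training_workout(t0))
        if not with_hr and streams:
            streams[0] = east_stream([3.0] * 30, dt=10, t0=streams[0].start_time)
        if with_marathon:
            streams.append(marathon_stream(t0=M))
        return streams

    def test_sixteen_workouts_plus_marathon_pass(self):
        ok, reason, m_idx = eligibility_filter(self._streams(16))
        assert ok and reason is None and m_idx == 16

    def test_fifteen_workouts_fail(self):
        ok, reason, _ = eligibility_filter(self._streams(15))
        assert not ok and reason == "too_few_workouts"

    def test_missing_hr_channel_fails(self):
        ok, reason, _ = eligibility_filter(self._streams(16, with_hr=False))
        assert not ok and reason == "missing_channel"

    def test_no_marathon_fails(self):
        ok, reason, _ = eligibility_filter(self._streams(16, with_marathon=False))
        assert not ok and reason == "no_marathon"

    def test_marathon_date_range_filter(self):
        streams = self._streams(16)
        ok, reason, _ = eligibility_filter(
            streams, marathon_date_range=(M - 10, M + 10))
        assert ok
        ok, reason, _ = eligibility_filter(
            streams, marathon_date_range=(0, M - 100))
        assert not ok and reason == "marathon_outside_date_range"

    def test_two_marathons_fail(self):
        streams = self._streams(16)
        streams.append(marathon_stream(t0=M - 6 * WEEK_S))
        ok, reason, _ = eligibility_filter(streams)
        assert not ok and reason == "multiple_marathons"


def _summary(sid="s", t_mp=14_000.0, d_km=500.0, t_hours=55.0, hr_max=190.0,
             blocks=None):
    if blocks is None:
        blocks = [_block(v10=3.0, hr10=170.0), _block(block=2), _block(block=3),
                  _block(v10=3.2, hr10=170.0, block=4)]
    return SubjectSummary(
        subject_id=sid, marathon_start=M, t_mp=t_mp, v_mp=3.0, hr_max=hr_max,
        n_workouts=40, t_hours=t_hours, d_km=d_km, n_t90=5, n_d15=5,
        v10_overall=3.2, v_bar_overall=1.0, hr_bar_overall=0.8,
        lit=0.5, threshold=0.4, hit=0.1,
        blocks=blocks, overall=blocks[0], delta_v10=0.2,
        delta_v_bar=0.01, delta_hr_bar=0.0,
    )


class TestIqrFilter:
    def test_gross_outlier_excluded(self):
        t_mps = list(np.linspace(12_000, 16_000, 19)) + [140_000.0]
        summaries = [_summary(sid=f"s{i}", t_mp=t) for i, t in enumerate(t_mps)]
        kept, excluded = iqr_filter(summaries)
        # independent check against linearly interpolated quartile fences
        lo, hi = iqr_fences(np.array(t_mps))
        assert [sid for sid, _ in excluded] == ["s19"]
        assert t_mps[-1] > hi and all(lo <= t <= hi for t in t_mps[:-1])
        assert len(kept) == 19

    def test_identical_subjects_all_kept(self):
        summaries = [_summary(sid=f"s{i}") for i in range(10)]
        kept, excluded = iqr_filter(summaries)
        assert len(kept) == 10 and not excluded

    def test_single_parameter_outlier_excluded(self):
        summaries = [_summary(sid=f"s{i}", hr_max=185 + (i % 5)) for i in range(19)]
        summaries.append(_summary(sid="odd", hr_max=260.0))
        kept, excluded = iqr_filter(summaries)
        assert [sid for sid, _ in excluded] == ["odd"]
        assert "hr_max" in excluded[0][1]


class TestEffortFilter:
    def test_inclusive_bound_passes(self):
        s = _summary(blocks=[
            _block(v10=3.0, hr10=0.80 * 190.0), _block(block=2), _block(block=3),
            _block(v10=3.2, hr10=0.80 * 190.0, block=4),
        ])
        assert effort_filter(s)

    def test_just_below_bound_fails(self):
        s = _summary(blocks=[
            _block(v10=3.0, hr10=0.80 * 190.0), _block(block=2), _block(block=3),
            _block(v10=3.2, hr10=0.79 * 190.0, block=4),
        ])
        assert not effort_filter(s)

    def test_missing_10k_in_first_block_fails(self):
        s = _summary(blocks=[
            _block(v10=None), _block(block=2), _block(block=3),
            _block(v10=3.2, hr10=180.0, block=4),
        ])
        assert not effort_filter(s)


class TestCascade:
    def test_stage_order_and_log(self):
        triples = [
            ("bad", None, "no_marathon"),
            *[(f"s{i}", _summary(sid=f"s{i}"), None) for i in range(6)],
            ("outlier", _summary(sid="outlier", t_mp=140_000.0), None),
            ("lazy", _summary(sid="lazy", blocks=[
                _block(v10=3.0, hr10=0.5 * 190.0), _block(block=2),
                _block(block=3), _block(v10=3.2, hr10=180.0, block=4),
            ]), None),
        ]
        final, log = apply_filter_cascade(triples)
        assert {s.subject_id for s in final} == {f"s{i}" for i in range(6)}
        stages = dict(zip(log["subject_id"], log["stage"]))
        assert stages == {"bad": "eligibility", "outlier": "iqr", "lazy": "effort"}
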