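"""Per-workout feature extraction.

From a cleaned workout stream this module derives the scalar training
descriptors (duration, distance, long-workout indicators, fastest 10-km
segment and its average heart rate) and the duration distributions over
relative velocity and relative heart rate that all later aggregation
stages consume.

Velocity is normalized by the subject's average marathon velocity v_mp,
heart rate by the surrogate maximal training heart rate hr_max.  The
relative-velocity histogram spans 0.54–1.80 in width-0.02 bins with
open-ended first and last bins; the relative-HR histogram spans 0.50–1.00
the same way.  Bins accumulate *time* (seconds), not sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stream_io import WorkoutStream

#: Mean Earth radius [m]; great-circle distances live on this sphere.
EARTH_RADIUS_M = 6_371_008.8

#: Closed bin edges of the relative-velocity duration distribution.
#: Bin 0 is (-inf, 0.54]; bin k is (edge_{k-1}, edge_k]; the last bin is
#: (1.80, inf).  65 bins in total.
VEL_EDGES = np.round(np.linspace(0.54, 1.80, 64), 10)

#: Closed bin edges of the relative-HR duration distribution (27 bins).
HR_EDGES = np.round(np.linspace(0.50, 1.00, 26), 10)

#: Velocity-bin edge indices of the intensity-zone boundaries v_mp and
#: 1.2*v_mp (used by block aggregation's zone shares).
LIT_EDGE_IDX = int(np.searchsorted(VEL_EDGES, 1.0))
HIT_EDGE_IDX = int(np.searchsorted(VEL_EDGES, 1.2))

#: Optional spike cap: GPS-velocity samples above this are implausible for
#: running and can be dropped behind a flag (off by default).
SPIKE_CAP_MS = 12.5


@dataclass
class DurationDistribution:
    """Seconds of workout time per (relative-unit) bin."""

    edges: np.ndarray
    durations: np.ndarray

    @property
    def total_seconds(self) -> float:
        return float(self.durations.sum())


@dataclass
class WorkoutFeatures:
    """All per-workout quantities used downstream."""

    workout_id: str
    start_time: int
    t_min: float  # workout duration T_i [min]
    i_t90: int  # 1 iff T_i >= 90 min
    d_km: float  # total distance D_i [km]
    i_d15: int  # 1 iff D_i >= 15 km
    v10: float | None  # best 10-km velocity [m/s], None if D_i < 10 km
    v10_window: tuple[int, int] | None  # [t_start, t_end] of that segment
    hr10: float | None  # mean HR [bpm] in the best 10-km window
    vel_dist: DurationDistribution
    hr_dist: DurationDistribution
    has_hr: bool


def great_circle_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle (haversine) distance in meters; vectorized."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def segment_distances(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Distances [m] between consecutive GPS fixes (length n-1)."""
    return np.atleast_1d(great_circle_distance(lat[:-1], lon[:-1], lat[1:], lon[1:]))


def workout_duration(stream: WorkoutStream) -> tuple[float, int]:
    """Duration T_i [min] from first/last GPS timestamp, and the >=90-min flag."""
    t_min = (stream.gps_t[-1] - stream.gps_t[0]) / 60.0
    return t_min, int(t_min >= 90.0)


def velocity_stream(
    gps_t: np.ndarray, lat: np.ndarray, lon: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-interval velocity from consecutive GPS fixes.

    Returns (v [m/s], dt [s], t_end) with one element per consecutive pair.
    """
    d = segment_distances(lat, lon)
    dt = np.diff(gps_t).astype(float)
    return d / dt, dt, gps_t[1:]


def total_distance(lat: np.ndarray, lon: np.ndarray) -> tuple[float, int]:
    """Total distance D_i [km] and the >=15-km flag."""
    d_km = float(segment_distances(lat, lon).sum()) / 1000.0
    return d_km, int(d_km >= 15.0)


def best_10k(
    gps_t: np.ndarray,
    lat: np.ndarray | None = None,
    lon: np.ndarray | None = None,
    seg_m: np.ndarray | None = None,
) -> tuple[float, tuple[int, int]] | None:
    """Fastest contiguous >=10-km segment of a workout.

    Over all contiguous sample windows whose cumulative distance reaches
    10 km, returns the one with the smallest elapsed time (ties broken by
    earliest start) as (v10, (t_start, t_end)).  The velocity divides the
    realized window distance (>= 10 km) by the elapsed time, so sampling
    quantization can only bias the estimate downward.  Returns None when
    the workout is shorter than 10 km.
    """
    if seg_m is None:
        seg_m = segment_distances(lat, lon)
    c = np.concatenate(([0.0], np.cumsum(seg_m)))
    if c[-1] < 10_000.0:
        return None
    # for each window end j: the latest start i with c[j] - c[i] >= 10 km
    starts = np.searchsorted(c, c - 10_000.0, side="right") - 1
    valid = starts >= 0
    ends = np.nonzero(valid)[0]
    starts = starts[valid]
    elapsed = (gps_t[ends] - gps_t[starts]).astype(float)
    best = elapsed == elapsed.min()
    # tie on elapsed time -> earliest start
    k = np.argmin(gps_t[starts[best]])
    i, j = int(starts[best][k]), int(ends[best][k])
    v10 = (c[j] - c[i]) / (gps_t[j] - gps_t[i])
    return float(v10), (int(gps_t[i]), int(gps_t[j]))


def mean_hr_in_window(
    hr_t: np.ndarray, hr: np.ndarray, window: tuple[int, int]
) -> float | None:
    """Arithmetic mean of HR samples with t in [t_start, t_end]; None if empty."""
    t0, t1 = window
    mask = (hr_t >= t0) & (hr_t <= t1)
    if not mask.any():
        return None
    return float(hr[mask].mean())


def duration_distribution(
    x: np.ndarray, dt: np.ndarray, edges: np.ndarray
) -> DurationDistribution:
    """Accumulate interval durations into left-open/right-closed bins.

    Bin 0 collects x <= edges[0]; bin k collects edges[k-1] < x <= edges[k];
    the final open bin collects x > edges[-1].  The summed durations equal
    the summed input dt exactly.
    """
    idx = np.searchsorted(edges, x, side="left")
    durations = np.bincount(idx, weights=dt, minlength=len(edges) + 1)
    return DurationDistribution(edges, durations)


def compute_workout_features(
    stream: WorkoutStream,
    v_mp: float,
    hr_max: float,
    spike_filter: bool = False,
) -> WorkoutFeatures:
    """Extract all per-workout features given the subject's normalizers.

    With ``spike_filter`` enabled, GPS intervals faster than 12.5 m/s are
    dropped from the velocity distribution and the distance sum (default:
    keep everything, mirroring the raw-stream convention).
    """
    t_min, i_t90 = workout_duration(stream)
    seg = segment_distances(stream.lat, stream.lon)
    dt = np.diff(stream.gps_t).astype(float)
    v = seg / dt
    if spike_filter:
        ok = v <= SPIKE_CAP_MS
        seg, dt, v = seg[ok], dt[ok], v[ok]
        gps_t = np.concatenate(([stream.gps_t[0]], stream.gps_t[1:][ok]))
    else:
        gps_t = stream.gps_t
    d_km = float(seg.sum()) / 1000.0
    i_d15 = int(d_km >= 15.0)

    res = best_10k(gps_t, seg_m=seg) if d_km >= 10.0 else None
    if res is not None:
        v10, window = res
        hr10 = mean_hr_in_window(stream.hr_t, stream.hr, window)
    else:
        v10, window, hr10 = None, None, None

    vel_dist = duration_distribution(v / v_mp, dt, VEL_EDGES)
    # HR convention mirrors GPS: sample n is weighted by t_n - t_{n-1}
    # (the first sample contributes no time)
    if stream.n_hr >= 2:
        hr_dt = np.diff(stream.hr_t).astype(float)
        hr_dist = duration_distribution(stream.hr[1:] / hr_max, hr_dt, HR_EDGES)
    else:
        hr_dist = DurationDistribution(HR_EDGES, np.zeros(len(HR_EDGES) + 1))
    return WorkoutFeatures(
        workout_id=stream.workout_id,
        start_time=stream.start_time,
        t_min=t_min,
        i_t90=i_t90,
        d_km=d_km,
        i_d15=i_d15,
        v10=v10,
        v10_window=window,
        hr10=hr10,
        vel_dist=vel_dist,
        hr_dist=hr_dist,
        has_hr=stream.n_hr > 0,
    )
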