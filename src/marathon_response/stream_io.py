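"""Reading and writing workout streams and tabular outputs.

A workout is a pair of independently sampled channels sharing a UTC time
base: GPS fixes (latitude/longitude in degrees) and heart-rate samples
(bpm).  The canonical interchange format is a long-format CSV with header
``t,lat,lon,hr`` where GPS-only rows leave ``hr`` empty and HR-only rows
leave ``lat``/``lon`` empty.  GPX 1.1 (with the common track-point
extension carrying heart rate) is supported as a convenience reader.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

log = logging.getLogger(__name__)

HR_MIN_BPM = 25.0
HR_MAX_BPM = 250.0


class FormatError(ValueError):
    """Input file does not conform to the expected format."""


class MalformedWorkoutError(ValueError):
    """Workout lacks the minimum usable data (fewer than 2 valid GPS fixes)."""


@dataclass
class WorkoutStream:
    """One workout: cleaned GPS and heart-rate channels.

    Timestamps are integer seconds UTC, strictly increasing within each
    channel.  The two channels may have different sampling rates.
    """

    subject_id: str
    workout_id: str
    gps_t: np.ndarray  # int64 seconds
    lat: np.ndarray  # degrees
    lon: np.ndarray  # degrees
    hr_t: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    hr: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_gps(self) -> int:
        return len(self.gps_t)

    @property
    def n_hr(self) -> int:
        return len(self.hr_t)

    @property
    def start_time(self) -> int:
        return int(self.gps_t[0])


def _clean_channel(t: np.ndarray, *values: np.ndarray) -> tuple[np.ndarray, ...]:
    """Floor timestamps to seconds, drop duplicate and non-monotone rows.

    Keeps the first occurrence of a timestamp and any row whose timestamp
    exceeds the running maximum of previously kept rows.
    """
    t = np.floor(np.asarray(t, dtype=float)).astype(np.int64)
    if len(t) == 0:
        return (t,) + tuple(np.asarray(v, dtype=float) for v in values)
    # a row survives iff its timestamp beats the running max of all earlier
    # rows (dropped rows never carry the running max, so this is exact)
    running = np.maximum.accumulate(t)
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = t[1:] > running[:-1]
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d duplicate/non-monotone samples", dropped)
    return (t[keep],) + tuple(np.asarray(v, dtype=float)[keep] for v in values)


def make_stream(
    subject_id: str,
    workout_id: str,
    gps_t: Sequence[float],
    lat: Sequence[float],
    lon: Sequence[float],
    hr_t: Sequence[float] = (),
    hr: Sequence[float] = (),
) -> WorkoutStream:
    """Build a cleaned :class:`WorkoutStream` from raw sample arrays.

    Cleaning: timestamps floored to integer seconds; within each channel
    duplicate timestamps collapse to the first occurrence and rows that go
    back in time are dropped; HR samples outside (25, 250) bpm are dropped
    with a logged count.  Raises :class:`MalformedWorkoutError` if fewer
    than 2 valid GPS fixes remain.
    """
    gt, la, lo = _clean_channel(np.asarray(gps_t), np.asarray(lat), np.asarray(lon))
    ok = np.isfinite(la) & np.isfinite(lo)
    gt, la, lo = gt[ok], la[ok], lo[ok]
    if np.any((np.abs(la) > 90) | (np.abs(lo) > 180)):
        raise FormatError("latitude/longitude out of range")
    if len(gt) < 2:
        raise MalformedWorkoutError(
            f"workout {workout_id}: fewer than 2 valid GPS samples"
        )
    ht, hv = _clean_channel(np.asarray(hr_t), np.asarray(hr))
    in_range = (hv > HR_MIN_BPM) & (hv < HR_MAX_BPM)
    n_bad = int((~in_range).sum())
    if n_bad:
        log.info("dropped %d out-of-range HR samples", n_bad)
    return WorkoutStream(subject_id, workout_id, gt, la, lo, ht[in_range], hv[in_range])


def clean_stream(stream: WorkoutStream) -> WorkoutStream:
    """Re-apply the cleaning contract; idempotent on already-clean streams."""
    return make_stream(
        stream.subject_id,
        stream.workout_id,
        stream.gps_t,
        stream.lat,
        stream.lon,
        stream.hr_t,
        stream.hr,
    )


def read_workout_csv(
    path: str | Path, subject_id: str = "", workout_id: str | None = None
) -> WorkoutStream:
    """Read the canonical per-workout CSV ``t,lat,lon,hr``."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:4]) != ["t", "lat", "lon", "hr"]:
        raise FormatError(f"{path}: expected header t,lat,lon,hr, got {list(df.columns)}")
    gps = df.dropna(subset=["lat", "lon"])
    hr = df.dropna(subset=["hr"])
    return make_stream(
        subject_id,
        workout_id if workout_id is not None else path.stem,
        gps["t"].to_numpy(),
        gps["lat"].to_numpy(),
        gps["lon"].to_numpy(),
        hr["t"].to_numpy(),
        hr["hr"].to_numpy(),
    )


def write_workout_csv(stream: WorkoutStream, path: str | Path) -> None:
    """Write a stream to the canonical CSV, merging channels on timestamp."""
    g = pd.DataFrame({"t": stream.gps_t, "lat": stream.lat, "lon": stream.lon})
    h = pd.DataFrame({"t": stream.hr_t, "hr": stream.hr})
    df = g.merge(h, on="t", how="outer").sort_values("t")
    df.to_csv(path, index=False, float_format="%.10g")


_GPX_NS = {
    "gpx": "http://www.topografix.com/GPX/1/1",
    "tpx": "http://www.garmin.com/xmlschemas/TrackPointExtension/v1",
}


def read_gpx(
    path: str | Path, subject_id: str = "", workout_id: str | None = None
) -> WorkoutStream:
    """Read a GPX 1.1 track; heart rate from the track-point extension.

    Same cleaning contract as :func:`read_workout_csv`.  Track points
    without a heart-rate extension contribute only to the GPS channel.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    pts = tree.findall(".//gpx:trk//gpx:trkpt", _GPX_NS)
    if not pts:
        raise FormatError(f"{path}: no track points found")
    gt, la, lo, ht, hv = [], [], [], [], []
    for pt in pts:
        time_el = pt.find("gpx:time", _GPX_NS)
        if time_el is None or time_el.text is None:
            continue
        t = pd.Timestamp(time_el.text)
        if t.tzinfo is None:
            t = t.tz_localize("UTC")
        ts = t.timestamp()
        gt.append(ts)
        la.append(float(pt.get("lat")))
        lo.append(float(pt.get("lon")))
        hr_el = pt.find(".//tpx:hr", _GPX_NS)
        if hr_el is not None and hr_el.text is not None:
            ht.append(ts)
            hv.append(float(hr_el.text))
    return make_stream(
        subject_id,
        workout_id if workout_id is not None else path.stem,
        gt, la, lo, ht, hv,
    )


def write_table(rows: Iterable[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Write homogeneous dict rows as CSV with ≥9 significant digits.

    All rows must share one schema; an empty row set yields a header-only
    file (``columns`` required in that case).
    """
    rows = list(rows)
    if rows:
        keys = list(rows[0].keys())
        for r in rows[1:]:
            if list(r.keys()) != keys:
                raise ValueError(f"row schema mismatch: {list(r.keys())} != {keys}")
        df = pd.DataFrame(rows, columns=keys)
    else:
        if columns is None:
            raise ValueError("empty row set needs explicit columns")
        df = pd.DataFrame(columns=columns)
    df.to_csv(path, index=False, float_format="%.10g")


def write_manifest(records: Iterable[dict], path: str | Path) -> None:
    """Write a cohort manifest as JSON Lines (one workout per record)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
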