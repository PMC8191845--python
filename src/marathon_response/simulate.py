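"""Synthetic marathon-training cohort with known ground truth.

Real fitness-app archives of marathon preparations are proprietary, so
every downstream stage is validated on simulated runners whose true
response, intensity mixture and fitness trajectory are known.  The
generator emulates the population structure the analysis assumes:

* three marathon-performance tiers (slow / medium / fast) that differ in
  marathon velocity, weekly training volume and LIT/threshold/HIT
  intensity mixture — magnitudes follow the published cohort means
  (fast runners ≈ (0.63, 0.31, 0.06) shares, slow ≈ (0.29, 0.47, 0.24),
  ≈ 41–53 workouts and 53–63 h over 16 weeks);
* three response tiers (low / moderate / high) with true 16-week 10-km
  velocity improvements of −0.05 / +0.15 / +0.40 m/s by default;
* a linear fitness trajectory: the subject's true best-10-km velocity in
  training week w (0..15) is v10_start + response_delta · w/15, probed by
  deterministic 10.5-km time trials in weeks 0 and 15 so both the first
  and last 4-week block contain a maximal-effort 10-km run;
* workouts as piecewise-constant-speed segments: zone time allocated in
  the subject's intensity-mixture proportions and laid out as short fast
  intervals separated by LIT recovery, multiplied by AR(1) speed jitter;
* heart rate driven by relative velocity,
  hr(t) = hr_rest + (hr_max_true − hr_rest) · clip(0.3 + 0.5·ṽ(t), 0, 1)
  plus Gaussian noise, clamped to hr_max_true;
* GPS tracks running due east from a random mid-latitude anchor with
  slowly varying (AR(1)) positional noise, sampled at 1–5 s.

Everything is a pure function of the configured seed, with per-subject
substreams keyed by subject index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .stream_io import WorkoutStream, make_stream

RESPONSE_TIERS = ("low", "moderate", "high")
PERF_TIERS = ("slow", "medium", "fast")
ZONES = ("lit", "threshold", "hit")

#: Relative-velocity band each zone's segment targets are drawn from.
#: Kept clear of the 1.0 / 1.2 zone edges so jitter rarely crosses them.
ZONE_BANDS = {"lit": (0.70, 0.92), "threshold": (1.04, 1.16), "hit": (1.26, 1.44)}

#: meters per degree of latitude on the mean-Earth-radius sphere
M_PER_DEG = 6_371_008.8 * np.pi / 180.0

DEFAULT_MARATHON_DATE = int(
    datetime(2018, 10, 7, 9, 0, tzinfo=timezone.utc).timestamp()
)  # a Sunday morning

#: response-tier -> (mean, sd) of the true 16-week Δv10 [m/s]
DEFAULT_TIER_DELTAS = {
    "low": (-0.05, 0.03),
    "moderate": (0.15, 0.03),
    "high": (0.40, 0.05),
}

#: perf-tier -> distribution parameters of marathon velocity [m/s],
#: workouts/week, workout duration [min] and (LIT, thr, HIT) mixture
DEFAULT_PERF_PARAMS = {
    "slow": dict(marathon_v=(2.55, 0.12), weekly=(2.6, 0.6), duration_min=(78, 10),
                 mixture=(0.29, 0.47, 0.24), v10_ratio=(1.25, 0.025)),
    "medium": dict(marathon_v=(2.95, 0.12), weekly=(2.8, 0.6), duration_min=(76, 10),
                   mixture=(0.47, 0.43, 0.10), v10_ratio=(1.16, 0.025)),
    "fast": dict(marathon_v=(3.35, 0.12), weekly=(3.2, 0.6), duration_min=(72, 10),
                 mixture=(0.63, 0.31, 0.06), v10_ratio=(1.13, 0.025)),
}

VIOLATIONS = ("short_marathon", "few_workouts", "low_effort", "slow_marathon_outlier")


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass
class SimConfig:
    """Cohort-level simulation settings (the defaults are the study
    conditions; see docs/methods.md)."""

    n_subjects: int = 90
    seed: int = 0
    sampling_interval_gps: int = 1  # [s]
    sampling_interval_hr: int = 1  # [s]
    gps_noise_sd: float = 0.5  # stationary sd of positional noise [m]
    gps_noise_rho: float = 0.98  # AR(1) coefficient of positional noise
    speed_jitter_sd: float = 0.02  # AR(1) innovation sd, fraction of target speed
    speed_jitter_rho: float = 0.9
    hr_noise_sd: float = 2.0  # [bpm]
    mixture_concentration: float = 40.0  # Dirichlet concentration of mixtures
    tier_deltas: dict = field(default_factory=lambda: dict(DEFAULT_TIER_DELTAS))
    perf_volume_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_PERF_PARAMS.items()
    })
    marathon_date: int = DEFAULT_MARATHON_DATE
    #: clamp subject-parameter draws to mean ± k·sd (None = untruncated)
    param_truncation_sigmas: float | None = None
    #: place the volume-determining parameters (weekly rate, workout
    #: duration, marathon velocity, hr_max) on deterministic grids instead
    #: of sampling them.  A designed cohort with bounded, uniform support
    #: sits strictly inside the Tukey fences of the IQR screen whatever
    #: the seed — the construction behind "built to pass all filters".
    designed_volume_grid: bool = False
    #: deal response tiers round-robin across the v10_start rank order
    #: within each perf tier (balanced design for decile-stratified grouping)
    balance_response_by_v10: bool = True
    #: high-response subjects shift 0.30 of their time share from LIT to
    #: threshold across the four blocks (ramped-intensity study condition)
    block_ramp_high_tier: bool = False

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.sampling_interval_gps <= 0 or self.sampling_interval_hr <= 0:
            raise ConfigError("sampling intervals must be positive")
        for tier in RESPONSE_TIERS:
            if tier not in self.tier_deltas:
                raise ConfigError(f"missing tier_deltas entry for {tier!r}")
        for perf in PERF_TIERS:
            if perf not in self.perf_volume_params:
                raise ConfigError(f"missing perf_volume_params entry for {perf!r}")


@dataclass
class SubjectParams:
    """True (latent) characteristics of one simulated runner."""

    subject_id: str
    v10_start: float  # true best-10k velocity at week 0 [m/s]
    response_delta: float  # true change over the 16 weeks [m/s]
    response_tier: str
    perf_tier: str
    weekly_workouts: float  # average workouts per week (rate)
    mean_workout_duration: float  # [min]
    intensity_mixture: tuple[float, float, float]  # (LIT, thr, HIT), sums to 1
    hr_rest: float
    hr_max_true: float
    hr_noise_sd: float
    marathon_velocity_true: float  # [m/s]

    def __post_init__(self):
        if abs(sum(self.intensity_mixture) - 1.0) > 1e-9:
            raise ValueError("intensity_mixture must sum to 1")
        if self.v10_start <= 0:
            raise ValueError("v10_start must be positive")
        if self.hr_rest >= self.hr_max_true:
            raise ValueError("hr_rest must be below hr_max_true")
        if self.weekly_workouts < 1:
            raise ValueError("weekly_workouts must be >= 1")

    def fitness(self, week: int) -> float:
        """True best-10k velocity in training week ``week`` (0..15)."""
        return self.v10_start + self.response_delta * week / 15.0


@dataclass
class SimWorkout:
    """A simulated workout stream plus its ground-truth annotation."""

    stream: WorkoutStream
    kind: str  # regular | time_trial | marathon
    week: int | None
    zone_seconds: np.ndarray  # true seconds in (LIT, thr, HIT)


@dataclass
class SimSubject:
    params: SubjectParams
    workouts: list[SimWorkout]
    violation: str | None = None


def sample_subject_params(
    config: SimConfig, tier: str, perf: str, rng: np.random.Generator,
    subject_id: str = "s0",
) -> SubjectParams:
    """Draw one subject's latent parameters for a (response, perf) cell."""
    if tier not in RESPONSE_TIERS:
        raise ConfigError(f"unknown response tier {tier!r}")
    if perf not in PERF_TIERS:
        raise ConfigError(f"unknown perf tier {perf!r}")
    pv = config.perf_volume_params[perf]
    k = config.param_truncation_sigmas

    def draw(mean, sd):
        x = rng.normal(mean, sd)
        if k is not None:
            x = float(np.clip(x, mean - k * sd, mean + k * sd))
        return float(x)

    mv = max(0.5, draw(*pv["marathon_v"]))
    weekly = float(np.clip(draw(*pv["weekly"]), 1.0, 7.0))
    duration = float(np.clip(draw(*pv["duration_min"]), 30.0, 150.0))
    mixture = rng.dirichlet(np.asarray(pv["mixture"]) * config.mixture_concentration)
    delta = draw(*config.tier_deltas[tier])
    # best-10k velocity sits above marathon velocity by a tier-dependent
    # ratio (recreational marathoners race far below their 10-km speed)
    v10_start = mv * max(1.02, draw(*pv.get("v10_ratio", (1.16, 0.025))))
    hr_rest = float(np.clip(draw(55.0, 5.0), 40.0, 75.0))
    hr_max = float(np.clip(draw(190.0, 7.0), 160.0, 215.0))
    return SubjectParams(
        subject_id=subject_id,
        v10_start=v10_start,
        response_delta=delta,
        response_tier=tier,
        perf_tier=perf,
        weekly_workouts=weekly,
        mean_workout_duration=duration,
        intensity_mixture=tuple(mixture / mixture.sum()),
        hr_rest=hr_rest,
        hr_max_true=hr_max,
        hr_noise_sd=config.hr_noise_sd,
        marathon_velocity_true=mv,
    )


def _ar1(n: int, rho: float, innov_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series of length n."""
    if n == 0 or innov_sd == 0.0:
        return np.zeros(n)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, innov_sd / np.sqrt(max(1e-12, 1.0 - rho**2)))
    return lfilter([1.0], [1.0, -rho], e)


def _block_mixture(params: SubjectParams, config: SimConfig, week: int) -> np.ndarray:
    """Per-block zone mixture; high responders ramp LIT -> threshold when
    the ramped-intensity condition is on."""
    mix = np.asarray(params.intensity_mixture, dtype=float)
    if config.block_ramp_high_tier and params.response_tier == "high":
        block = week // 4  # 0..3
        shift = 0.15 - 0.10 * block  # +0.15, +0.05, -0.05, -0.15 to LIT
        mix = mix + np.array([shift, -shift * 2.0 / 3.0, -shift / 3.0])
        mix = np.clip(mix, 0.02, None)
        mix = mix / mix.sum()
    return mix


def _split(total_s: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total_s`` seconds into n positive integer pieces with mild
    random variation (exact sum preserved)."""
    if n <= 1:
        return np.array([total_s])
    w = rng.dirichlet(np.full(n, 8.0))
    lens = np.maximum(1, np.floor(w * total_s)).astype(int)
    lens[-1] += total_s - lens.sum()
    while lens[-1] < 1:
        lens[np.argmax(lens)] += lens[-1] - 1
        lens[-1] = 1
    return lens


def _plan_segments(
    mix: np.ndarray, target_s: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment plan (relative speeds, lengths [s], zone indices) for a
    regular workout.

    Fast (threshold/HIT) work is laid out as ~5-min intervals separated
    by LIT recovery pieces.  Runners do exceed their 10-km pace in short
    intervals, but the interleaving keeps every sustained ~10-km stretch
    near the workout's mixture mean — well below their current best-10-km
    velocity — so time trials remain each block's fastest 10-km effort.
    Total time in zone follows the mixture exactly up to rounding.
    """
    lit_s = int(round(mix[0] * target_s))
    fast_s = target_s - lit_s
    if fast_s < 60:  # essentially pure LIT
        return (
            np.array([rng.uniform(*ZONE_BANDS["lit"])]),
            np.array([target_s]),
            np.array([0]),
        )
    n_fast = max(1, int(round(fast_s / 300.0)))
    thr_share = mix[1] / max(1e-12, mix[1] + mix[2])
    n_thr = int(round(n_fast * thr_share))
    fast_zones = np.array([1] * n_thr + [2] * (n_fast - n_thr))
    rng.shuffle(fast_zones)
    fast_lens = _split(fast_s, n_fast, rng)
    if lit_s < n_fast + 1:  # not enough LIT to separate: all-fast workout
        zones, lens = fast_zones, fast_lens
    else:
        lit_lens = _split(lit_s, n_fast + 1, rng)
        zones = np.empty(2 * n_fast + 1, dtype=int)
        lens = np.empty(2 * n_fast + 1, dtype=int)
        zones[0::2], lens[0::2] = 0, lit_lens
        zones[1::2], lens[1::2] = fast_zones, fast_lens
    rel = np.array([rng.uniform(*ZONE_BANDS[ZONES[z]]) for z in zones])
    return rel, lens, zones


def simulate_workout(
    config: SimConfig,
    params: SubjectParams,
    start_time: int,
    week_index: int | None,
    kind: str,
    rng: np.random.Generator,
    duration_min: float | None = None,
    distance_override_m: float | None = None,
    trial_speed_override: float | None = None,
    hr_drive_override: float | None = None,
) -> SimWorkout:
    """Simulate one workout stream.

    * ``regular`` — piecewise-constant segments (3–7 min) whose zones are
      drawn from the intensity mixture, for the requested duration;
    * ``time_trial`` — 10.5 km at the subject's current true fitness;
    * ``marathon`` — 42.2 km at the true marathon velocity.

    Speeds carry multiplicative AR(1) jitter; GPS positions advance due
    east with AR(1) positional noise; HR follows the relative-velocity
    drive model.  Returns the stream plus true seconds per intensity zone.
    """
    mv = params.marathon_velocity_true
    dt = int(config.sampling_interval_gps)

    if kind == "marathon":
        distance = distance_override_m if distance_override_m is not None else 42_200.0
        seg_rel = np.array([1.0])
    elif kind == "time_trial":
        distance = distance_override_m if distance_override_m is not None else 10_500.0
        speed = (
            trial_speed_override
            if trial_speed_override is not None
            else params.fitness(week_index)
        )
        seg_rel = np.array([speed / mv])
    elif kind == "regular":
        if duration_min is None or duration_min <= 0:
            raise ValueError("regular workout needs a positive duration")
        distance = None
        target_s = int(round(duration_min * 60))
        mix = _block_mixture(params, config, week_index)
        seg_rel, seg_len, seg_zones = _plan_segments(mix, target_s, rng)
    else:
        raise ConfigError(f"unknown workout kind {kind!r}")

    if distance is not None:
        # distance-terminated: provision intervals generously, cut at target
        v_nom = seg_rel[0] * mv
        n_max = int(np.ceil(distance / (v_nom * dt) * 1.10)) + 10
        per_interval_rel = np.full(n_max, seg_rel[0])
    else:
        n_int = np.maximum(1, (seg_len / dt)).astype(int)
        per_interval_rel = np.repeat(seg_rel, n_int)

    n = len(per_interval_rel)
    jitter = _ar1(n, config.speed_jitter_rho, config.speed_jitter_sd, rng)
    v = np.maximum(0.3, per_interval_rel * mv * (1.0 + jitter))

    if distance is not None:
        cum = np.cumsum(v * dt)
        cut = int(np.searchsorted(cum, distance)) + 1
        v = v[:cut]
        per_interval_rel = per_interval_rel[:cut]
        n = len(v)

    # GPS track: due east from a random mid-latitude anchor
    east = np.concatenate(([0.0], np.cumsum(v * dt)))
    noise_e = _ar1(
        n + 1, config.gps_noise_rho,
        config.gps_noise_sd * np.sqrt(max(1e-12, 1.0 - config.gps_noise_rho**2)),
        rng,
    )
    noise_n = _ar1(
        n + 1, config.gps_noise_rho,
        config.gps_noise_sd * np.sqrt(max(1e-12, 1.0 - config.gps_noise_rho**2)),
        rng,
    )
    lat0 = rng.uniform(-45.0, 45.0)
    lon0 = rng.uniform(-170.0, 160.0)
    lat = lat0 + (noise_n) / M_PER_DEG
    lon = lon0 + (east + noise_e) / (M_PER_DEG * np.cos(np.radians(lat0)))
    gps_t = start_time + np.arange(n + 1, dtype=np.int64) * dt

    # HR channel: relative-velocity drive + noise, clamped at hr_max_true
    hr_dt = int(config.sampling_interval_hr)
    end = int(gps_t[-1])
    hr_t = np.arange(start_time, end + 1, hr_dt, dtype=np.int64)
    idx = np.clip((hr_t - start_time) // dt, 0, n - 1)
    v_rel_true = v[idx] / mv
    if hr_drive_override is not None:
        drive = np.full(len(hr_t), hr_drive_override)
    else:
        drive = np.clip(0.3 + 0.5 * v_rel_true, 0.0, 1.0)
    hr = (
        params.hr_rest
        + (params.hr_max_true - params.hr_rest) * drive
        + rng.normal(0.0, params.hr_noise_sd, size=len(hr_t))
    )
    hr = np.clip(hr, 30.0, params.hr_max_true)

    # truth annotation: zone of each interval's realized true speed
    # (relative to the true marathon velocity, zone edges 1.0 / 1.2)
    per_interval_zone = np.searchsorted(np.array([1.0, 1.2]), v / mv, side="left")
    zone_seconds = np.bincount(per_interval_zone, minlength=3).astype(float) * dt

    stream = make_stream(
        params.subject_id,
        f"{params.subject_id}_w{start_time}",
        gps_t, lat, lon, hr_t, hr,
    )
    return SimWorkout(stream=stream, kind=kind, week=week_index, zone_seconds=zone_seconds)


def _schedule_weeks(
    params: SubjectParams, config: SimConfig, rng: np.random.Generator,
    skip_week: int | None = None,
) -> list[tuple[int, int]]:
    """(week, start_time) pairs: weekly_workouts per week on distinct days,
    start hours 7–20 UTC, sorted; the marathon week boundary is the
    marathon start itself."""
    out = []
    for week in range(16):
        if week == skip_week:
            continue
        week_start = config.marathon_date - (16 - week) * 604_800
        base = int(np.floor(params.weekly_workouts))
        frac = params.weekly_workouts - base
        n_w = min(7, base + int(rng.uniform() < frac))
        days = np.sort(rng.choice(7, size=n_w, replace=False))
        for d in days:
            hour = rng.uniform(7.0, 20.0)
            out.append((week, int(week_start + d * 86_400 + round(hour * 3600))))
    return out


def simulate_subject(
    config: SimConfig,
    params: SubjectParams,
    rng: np.random.Generator,
    violation: str | None = None,
) -> SimSubject:
    """Simulate the full 16-week history (plus marathon) of one subject.

    ``violation`` injects a known filter breach: ``short_marathon`` (40 km
    race), ``few_workouts`` (15 in-window workouts), ``low_effort`` (the
    10-km test runs are performed at an easy heart rate far below
    0.8 hr_max) or ``slow_marathon_outlier`` (10x marathon time).
    """
    if violation is not None and violation not in VIOLATIONS:
        raise ConfigError(f"unknown violation {violation!r}")
    p = params
    if violation == "few_workouts":
        p = replace(p, weekly_workouts=1.0)
    if violation == "slow_marathon_outlier":
        p = replace(
            p,
            marathon_velocity_true=p.marathon_velocity_true / 10.0,
            v10_start=p.v10_start / 10.0,
            response_delta=p.response_delta / 10.0,
        )

    skip = 7 if violation == "few_workouts" else None
    schedule = _schedule_weeks(p, config, rng, skip_week=skip)
    trial_weeks = {0, 15}
    done_trial: set[int] = set()
    workouts: list[SimWorkout] = []
    for week, start in schedule:
        if week in trial_weeks and week not in done_trial:
            done_trial.add(week)
            # a low-effort violator cruises the test runs at an easy HR
            # (drive 0.55 ~ 65% hr_max), well below the 0.8 hr_max bar
            w = simulate_workout(
                config, p, start, week, "time_trial", rng,
                hr_drive_override=0.55 if violation == "low_effort" else None,
            )
        else:
            dur = float(np.clip(
                rng.normal(p.mean_workout_duration, 0.15 * p.mean_workout_duration),
                20.0, 180.0,
            ))
            w = simulate_workout(config, p, start, week, "regular", rng, duration_min=dur)
        workouts.append(w)

    marathon_dist = 40_000.0 if violation == "short_marathon" else 42_200.0
    workouts.append(
        simulate_workout(
            config, p, config.marathon_date, None, "marathon", rng,
            distance_override_m=marathon_dist,
        )
    )
    return SimSubject(params=p, workouts=workouts, violation=violation)


def recovery_config(seed: int, n_subjects: int = 90) -> SimConfig:
    """Parameter-recovery study conditions: 90 subjects (30 per response
    tier), 1 Hz sampling, low measurement noise."""
    return SimConfig(
        n_subjects=n_subjects,
        seed=seed,
        speed_jitter_sd=0.005,
        gps_noise_sd=0.0,
        hr_noise_sd=1.0,
    )


def ramped_intensity_config(seed: int, n_subjects: int = 90) -> SimConfig:
    """Ramped-intensity study conditions: as the recovery cohort, but
    high responders shift training time from LIT toward threshold across
    the four blocks."""
    cfg = recovery_config(seed, n_subjects)
    cfg.block_ramp_high_tier = True
    return cfg


def cascade_config(seed: int, n_subjects: int = 60) -> SimConfig:
    """Filter-cascade study conditions: a homogeneous background cohort
    (medium performance tier only, tight volume spread) so that injected
    violators are the only subjects any filter stage touches."""
    medium = dict(DEFAULT_PERF_PARAMS["medium"])
    return SimConfig(
        n_subjects=n_subjects,
        seed=seed,
        sampling_interval_gps=5,
        sampling_interval_hr=5,
        perf_volume_params={k: dict(medium) for k in PERF_TIERS},
        mixture_concentration=300.0,
        designed_volume_grid=True,
    )


def _subject_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    """Per-subject substream, keyed by subject index (iteration-order
    independent)."""
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


def plan_cohort(config: SimConfig) -> list[SubjectParams]:
    """Draw all subjects' latent parameters.

    Response/perf cells are assigned cyclically (balanced counts).  With
    ``balance_response_by_v10`` the (tier, response_delta) pairs are
    re-dealt round-robin across the v10_start rank order within each perf
    tier, so every starting-fitness neighbourhood contains a balanced
    response-tier mix (marginal distributions are unchanged).
    """
    config.validate()
    cells = [(t, pf) for t in RESPONSE_TIERS for pf in PERF_TIERS]
    params: list[SubjectParams] = []
    for i in range(config.n_subjects):
        tier, perf = cells[i % len(cells)]
        rng = _subject_rng(config.seed, i, 1)
        params.append(sample_subject_params(config, tier, perf, rng, subject_id=f"s{i:04d}"))
    if config.balance_response_by_v10:
        ranked = sorted(range(len(params)), key=lambda i: (params[i].v10_start, i))
        pools = {
            t: [(q.response_tier, q.response_delta)
                for q in params if q.response_tier == t]
            for t in RESPONSE_TIERS
        }
        order = [t for t in RESPONSE_TIERS if pools[t]]
        k = 0
        for i in ranked:
            while not pools[order[k % len(order)]]:
                k += 1
            tier, delta = pools[order[k % len(order)]].pop(0)
            k += 1
            params[i] = replace(params[i], response_tier=tier, response_delta=delta)
    if config.designed_volume_grid:
        n = config.n_subjects
        durations = np.linspace(68.0, 84.0, n)
        # aligned grids: every screened parameter (T, D, T_mp, hr_max) is
        # then monotone in the grid index, i.e. near-uniform, and the
        # Tukey fences cover the whole range with ~2x margin
        mvs = np.linspace(2.83, 3.07, n)
        hr_maxes = np.linspace(183.0, 197.0, n)
        for i in range(n):
            ratio = params[i].v10_start / params[i].marathon_velocity_true
            params[i] = replace(
                params[i],
                weekly_workouts=3.0,
                mean_workout_duration=float(durations[i]),
                marathon_velocity_true=float(mvs[i]),
                v10_start=float(ratio * mvs[i]),
                hr_max_true=float(hr_maxes[i]),
            )
    return params


def iter_subjects(
    config: SimConfig, violations: dict[int, str] | None = None
) -> Iterator[SimSubject]:
    """Lazily simulate the cohort subject by subject (memory-friendly)."""
    violations = violations or {}
    for i, p in enumerate(plan_cohort(config)):
        rng = _subject_rng(config.seed, i, 2)
        yield simulate_subject(config, p, rng, violation=violations.get(i))


def truth_table(subjects: Sequence[SimSubject] | Sequence[SubjectParams]) -> pd.DataFrame:
    """Ground-truth table, one row per subject."""
    rows = []
    for s in subjects:
        p = s.params if isinstance(s, SimSubject) else s
        rows.append({
            "subject_id": p.subject_id,
            "response_tier": p.response_tier,
            "perf_tier": p.perf_tier,
            "lit_true": p.intensity_mixture[0],
            "threshold_true": p.intensity_mixture[1],
            "hit_true": p.intensity_mixture[2],
            "v10_start": p.v10_start,
            "response_delta": p.response_delta,
            "marathon_velocity_true": p.marathon_velocity_true,
            "hr_max_true": p.hr_max_true,
        })
    df = pd.DataFrame(rows)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in truth table")
    return df


def simulate_cohort(
    config: SimConfig, violations: dict[int, str] | None = None
) -> tuple[list[SimSubject], pd.DataFrame]:
    """Materialize the whole cohort plus its truth table."""
    subjects = list(iter_subjects(config, violations))
    return subjects, truth_table(subjects)


def true_block_zone_shares(subject: SimSubject, marathon_start: int) -> pd.DataFrame:
    """Planned zone shares per 4-week block from the generator's
    annotations (the recovery target for the pipeline's measured shares)."""
    from .blocks import assign_block

    acc = {b: np.zeros(3) for b in (1, 2, 3, 4)}
    for w in subject.workouts:
        if w.kind == "marathon":
            continue
        b = assign_block(w.stream.start_time, marathon_start)
        if b is not None:
            acc[b] += w.zone_seconds
    rows = []
    for b in (1, 2, 3, 4):
        tot = acc[b].sum()
        share = acc[b] / tot if tot > 0 else np.full(3, np.nan)
        rows.append({
            "block": b, "lit_true": share[0],
            "threshold_true": share[1], "hit_true": share[2],
        })
    return pd.DataFrame(rows)
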