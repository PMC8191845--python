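# Methods

This note documents the analysis model, the synthetic-cohort generator
that stands in for proprietary fitness-app data, the numerical choices,
and what passing the validation suite does and does not demonstrate.

## Analysis model

A subject's record is a set of workouts, each a pair of independently
sampled channels sharing a UTC time base: GPS fixes (latitude/longitude,
degrees) and heart rate (bpm).  Nothing else — no device metadata, no
elevation, no self-report — enters the analysis.

**Distances and velocities.** Consecutive GPS fixes are joined by
great-circle (haversine) distance on a sphere of mean Earth radius
6,371,008.8 m.  Velocity is per-interval distance over per-interval time;
the analysis is sampling-rate agnostic because every histogram is
duration-weighted: an interval of `dt` seconds deposits `dt` seconds in
the bin of its value, never a count.  The interval's value is the sample
at its end, for both channels.

**Fastest 10-km segment.** Over all contiguous sample windows whose
cumulative distance reaches 10 km, the window with the smallest elapsed
time wins (ties to the earliest start).  The search is a vectorized
two-pointer sweep over the cumulative distance (O(n)); the test-suite
holds it to an exhaustive O(n²) oracle on hundreds of simulated
workouts, with exact agreement required.  The window ends at the first
sample where cumulative distance ≥ 10 km, without sub-sample
interpolation, and the velocity divides the *realized* window distance
(≥ 10 km) by the elapsed time.  Quantization therefore biases v10
downward, never upward; at 1 Hz the bias is below 0.01 m/s.  A workout
shorter than 10 km has no v10.

**Relative units.** Velocity is normalized by the subject's average
marathon velocity v_mp, heart rate by hr_max, the median of the five
highest HR samples in the observation period (robust to single-sample
spikes).  hr_max includes the marathon's samples by default — race HR
peaks are plausible maxima — behind a flag.  The relative-velocity
histogram spans 0.54–1.80 in width-0.02 bins, left-open/right-closed,
with open-ended first and last bins (65 bins; the first bin catches
everything at or below 0.54, the last everything above 1.80); the
relative-HR histogram spans 0.50–1.00 the same way (27 bins).  The
intensity-zone boundaries 1.0 and 1.2 are exact bin edges, so zone
shares are exact reads of the cumulative distribution.

**Blocks and response.** Four 4-week blocks are counted back from the
marathon's first GPS timestamp in fixed 604,800-second weeks with no
calendar or timezone alignment; a workout at exactly 16 weeks out, or at
or after the marathon start, is out of window.  The marathon itself is
excluded from all training aggregates: it is the outcome being
predicted, not training.  Block distribution means use the bin midpoint
as representative, with the open-ended first/last bins clamped to their
single closed edge (0.54 / 1.80; HR 0.50 / 1.00) — unbiased under
within-bin uniformity.  Empty blocks are retained (flagged) so block
indexing stays 1–4; subjects with incomplete block profiles drop out of
the repeated-measures analysis only.

**Filters.** The cascade is eligibility → IQR → effort, each stage
logging subject, stage and reason.  IQR fences are Tukey fences
(quartiles by linear interpolation, factor 1.5, inclusive bounds)
computed once on the eligible cohort — a single pass, not iterated.  The
effort filter reads the mean HR of the workout that *achieves* the
block-best v10 (consistent with the block-best definition) and requires
≥ 0.8·hr_max in blocks 1 and 4, inclusive.  An optional marathon
date-range criterion exists but is off by default: calendar windows are
metadata, not physiology.  The anonymizing coordinate offset present in
real exports is a no-op for every feature here (all features are
relative distances), so it is not modeled.

**Grouping.** Response is rank-based within starting-fitness strata:
decile edges at the 10th–90th percentiles of v10,tb1 (right-closed,
ties to the lower decile), then 33.3/66.6 percentile cuts of Δv10
inside each decile, ≤-comparisons at the cuts.  A decile with fewer than
3 subjects falls back to cohort-wide cuts (logged).  Deciles are
computed on the post-filter cohort, the population actually grouped.
Marathon groups are cohort-wide T_mp terciles (lower time = faster).

**Statistics.** One-way ANOVA for the response deltas; two-way ANOVA
with Type II sums of squares for the unbalanced response × marathon
design; one-factor repeated-measures ANOVA for zone shares over blocks,
reporting the uncorrected p alongside a Greenhouse–Geisser corrected p
(stars use the uncorrected one).  Partial η² is always computed as
SS_effect/(SS_effect + SS_error); the p < 0.05 gate affects only the
star display, never the reported value.  No multiple-testing correction
is applied across the ANOVA family.  The ANOVA implementations are
library-backed (pingouin for one-way and repeated measures, statsmodels
for the Type II two-way); the test-suite checks each against an
explicit sums-of-squares or nested-model-comparison oracle to 1e-8.

## The synthetic cohort

The generator produces the population structure the analysis assumes,
with every latent quantity recorded for recovery tests.

* **Performance tiers** (slow/medium/fast) set marathon velocity
  (2.55 / 2.95 / 3.35 ± 0.12 m/s → mean finish times ≈ 4.6 / 4.0 / 3.5 h),
  weekly workout rate (2.6 / 2.8 / 3.2 ± 0.6 per week, realized as a
  Bernoulli-rounded per-week count ≥ 1), workout duration
  (78 / 76 / 72 ± 10 min) and the (LIT, threshold, HIT) mixture —
  (0.29, 0.47, 0.24), (0.47, 0.43, 0.10), (0.63, 0.31, 0.06) — drawn per
  subject from a Dirichlet around the tier mean.  These magnitudes match
  the published population means for recreational marathon cohorts:
  faster finishers train more and far more polarized.
* **Response tiers** (low/moderate/high) set the true 16-week change of
  the best-10-km velocity: −0.05 / +0.15 / +0.40 ± 0.03–0.05 m/s.  The
  fitness trajectory is linear in the week index w = 0..15,
  v10(w) = v10_start + Δ·w/15, so the week-0 and week-15 time trials
  bracket exactly the full true response and the pipeline's Δv10 is
  unbiased for it.  Time trials (10.5 km at current fitness) are
  scheduled deterministically in weeks 0 and 15, guaranteeing a
  maximal-effort 10-km run in blocks 1 and 4.
* **Starting fitness** is v10_start = ratio·v_mp with a tier-dependent
  ratio (slow 1.25, medium 1.16, fast 1.13 ± 0.025): recreational
  marathoners race far below their 10-km speed, elites much closer.
  This is also what keeps the simulated world self-consistent — see the
  interval structure below.
* **Workout construction.** A regular workout is a sequence of
  piecewise-constant-speed segments.  Zone time is allocated exactly in
  the subject's mixture proportions, then laid out as ~5-min
  fast (threshold/HIT) intervals separated by LIT recovery pieces, with
  in-zone speeds uniform over bands (0.70–0.92, 1.04–1.16, 1.26–1.44
  relative to v_mp) that stay clear of the 1.0/1.2 zone edges.  The
  interleaving is the physiological constraint that runners exceed their
  10-km pace only in short intervals: it keeps every sustained ~10-km
  stretch of a training run near the workout's mixture mean and hence
  below current fitness, so the time trials are each block's fastest
  10-km efforts.  Speeds carry multiplicative AR(1) jitter (coefficient
  0.9, innovation 2 % of target by default).
* **Signals.** GPS tracks run due east from a random mid-latitude anchor
  (meters → degrees by local equirectangular scaling, which makes
  great-circle step lengths analytically checkable); positional noise is
  a slowly varying AR(1) offset (0.5 m stationary sd, coefficient 0.98 —
  white positional noise of realistic amplitude would swamp per-second
  velocities, which is why consumer devices smooth it).  Heart rate
  follows hr(t) = hr_rest + (hr_max_true − hr_rest)·clip(0.3 + 0.5·ṽ(t), 0, 1)
  plus Gaussian noise (2 bpm), clamped at hr_max_true.  Default sampling
  is 1 s for both channels; any 1–5 s interval is supported.
* **Truth annotations.** Each workout records its true seconds per
  intensity zone from the realized instantaneous speed (relative to the
  true marathon velocity), and the cohort truth table records tier,
  mixture, v10_start, Δ and hr_max_true per subject.
* **Determinism.** All draws flow from one seed through per-subject
  substreams keyed by subject index, so cohorts are byte-identical
  across reruns and independent of iteration order.
* **Balanced dealing.** Response tiers are dealt round-robin across the
  cohort's v10_start rank order (marginal distributions unchanged).
  This is a designed-balance choice: the decile-stratified tercile
  grouping estimates tier membership from within-decile ranks, and an
  unbalanced tier composition inside a decile caps the achievable
  agreement regardless of measurement precision.  With dealing, every
  decile contains a near-exact third of each tier.
* **Violation injection** for filter tests: a 40-km "marathon"
  (eligibility), 15 in-window workouts (eligibility), a runner who
  cruises the 10-km test runs at an easy heart rate (constant drive
  0.55 ≈ 65 % of hr_max, far below the 0.8 bar; effort), and a
  10× marathon-time outlier (IQR).

### Study conditions

Named presets freeze the conditions the validation suite and
`scripts/acceptance.py` run under:

* `recovery_config(seed)` — 90 subjects (30 per response tier crossed
  evenly with performance tiers), 1 Hz sampling, low noise (0.5 % jitter
  innovation, no positional noise, 1 bpm HR noise).
* `ramped_intensity_config(seed)` — the same, but high responders shift
  0.30 of their time share out of LIT across the four blocks (two thirds
  into threshold, one third into HIT), emulating a cohort whose
  responders progressively ramp training intensity.
* `cascade_config(seed)` — 60 runners for the filter-cascade check, with
  the volume-determining parameters (weekly rate, workout duration,
  marathon velocity, hr_max) on aligned deterministic grids rather than
  sampled.  The Tukey-fence screen flags ≈ 0.7 % of any normal-tailed
  sample no matter the size, so a cohort that is guaranteed to "pass all
  filters" must have bounded, near-uniform parameter support; the grid
  construction provides exactly that, and the injected violators are then
  the only subjects any stage touches.

## What the simulation does and does not show

The generator reproduces the *statistical structure* the pipeline must
detect: tiered response probed by bracketing trials, volume and
intensity mixtures that differ by performance tier but not by response
tier, HR driven by relative velocity, heterogeneous sampling.  Passing
the suite therefore shows the pipeline measures what the data contain —
it does not show the pipeline would be robust to everything real
exports contain.  Not modeled: elevation and incline, GPS dropout and
multipath, pauses and walking breaks, cadence/power channels, cardiac
drift, weather, injury, or cardiovascular adaptation (simulated HR
tracks current speed, so a responder's heart rate does not drop at
fixed speed as fitness improves; consequently the synthetic cohort
shows a response-group difference in Δh̄r that real cohorts, where
fitness lowers HR at a given speed, largely cancel out).  Conclusions
about real data rest on the plausibility checks (distribution shapes,
the v10–v_mp correlation, the weekend share of marathon starts), not on
the simulator.

## Numerical choices and problem sizes

* Bin membership: value ≤ first edge → open first bin; edge_{k−1} <
  value ≤ edge_k → bin k; value > last edge → open last bin.  Summed
  bin durations equal summed interval durations exactly.
* The velocity histogram has 65 bins: 63 interior width-0.02 bins from
  0.54 to 1.80 plus the two open-ended bins, mirroring the 27-bin HR
  scheme; the zone edges 1.0/1.2 and the 0.54–1.80 span are what the
  downstream analysis consumes.
* Quartiles/percentiles everywhere use linear interpolation between
  order statistics (numpy default); all cut-point comparisons are ≤.
* Cleaning: timestamps floored to integer seconds; duplicate timestamps
  collapse to the first occurrence; rows that go back in time are
  dropped; HR outside (25, 250) bpm is dropped; all with logged counts.
  Cleaning is idempotent.
* An optional velocity-spike cap (drop intervals > 12.5 m/s) exists
  behind a flag and is off by default.
* Validation problem sizes: the recovery and ramped cohorts use 90
  subjects at 1 Hz (≈ 4,500 workouts, ≈ 2×10⁷ samples, about 7 s per
  cohort on one core); the conservation suite uses 100 subjects at 5 s
  sampling; oracle equivalence uses 200 workouts at 5 s.  These sizes
  give the group-level contrasts comfortable statistical room while
  keeping the whole suite around half a minute.

## Known limitations

* The best-10k window never interpolates inside a sampling interval, so
  v10 carries a small negative quantization bias (bounded by one
  interval's share of the window; ≈ 0.01 m/s at 1 Hz, larger at 5 s).
* The IQR screen assumes a roughly unimodal eligible cohort; on very
  heterogeneous cohorts it can trim legitimate low-volume runners.
* Repeated-measures stars use the uncorrected p; the
  Greenhouse–Geisser p is reported alongside but sphericity violations
  are not otherwise acted on.
* With fewer than three subjects in a velocity decile the response cuts
  fall back to cohort-wide percentiles, weakening the
  similar-starting-fitness interpretation for those subjects.
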