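# marathon-response

Retrospective analysis of marathon training and its response from raw
wearable-sensor workout streams — GPS fixes and heart-rate samples — over
the 16 weeks leading up to a marathon, validated end-to-end on a
synthetic runner cohort with known ground truth.

## The analysis

For each runner the pipeline derives, from nothing but timestamped
(lat, lon) and heart-rate samples:

* **Subject constants** — the average marathon velocity
  v_mp = D_marathon / T_mp (the race is the single 41–43 km workout),
  and a surrogate maximal heart rate hr_max = median of the five highest
  recorded HR samples.
* **Per-workout features** — duration T_i with a ≥90-min indicator,
  great-circle distance D_i with a ≥15-km indicator, the fastest
  contiguous 10-km segment v10,i with its mean heart rate h̄r10,i, and
  *duration distributions*: histograms where each bin accumulates the
  time spent at a relative velocity ṽ = v/v_mp (bins of width 0.02 from
  0.54 to 1.80, open-ended ends) or relative heart rate hr/hr_max
  (0.50 to 1.00).
* **Training blocks** — four consecutive 4-week blocks counted back from
  the marathon start.  Per block: summed volume, the block-best
  v10,tb = max v10,i, probability and cumulative forms P, F of the pooled
  duration distributions, the normalized means v̄ = Σ ṽ·P[ṽ] and h̄r,
  and the time shares of the three intensity zones
  LIT (ṽ ≤ 1), threshold (1 < ṽ ≤ 1.2), HIT (ṽ > 1.2),
  read off the cumulative distribution: LIT = F[1.0],
  threshold = F[1.2] − F[1.0], HIT = 1 − F[1.2].
* **Training response** — Δv10 = v10,tb4 − v10,tb1, plus Δv̄ and Δh̄r.
* **Filters** — eligibility (one marathon, ≥16 in-window workouts, both
  channels present), a 1.5·IQR outlier screen on (T_mp, D, T, hr_max),
  and an effort filter requiring the block-best 10-km runs of blocks 1
  and 4 to reach ≥ 0.8·hr_max.
* **Groups** — response terciles of Δv10 computed *within deciles of
  v10,tb1* (so response is judged against peers of similar starting
  fitness), and fast/medium/slow marathon groups from T_mp terciles.
* **Statistics** — one-way ANOVA of Δv̄/Δh̄r across response groups,
  two-way (response × marathon, Type II) ANOVA of the training
  parameters with partial η² = SS_effect/(SS_effect+SS_error), and
  repeated-measures ANOVA of the zone shares over the four blocks, with
  effect sizes star-coded (\*: 0.01 ≤ η² < 0.05, \*\*: 0.05 ≤ η² < 0.12,
  \*\*\*: η² ≥ 0.12) when p < 0.05.

Because real fitness-app archives are proprietary, the package ships a
first-class simulator (`marathon_response.simulate`) that generates
cohorts with tiered training response, performance-dependent volume and
intensity mixtures, a velocity-driven heart-rate model and realistic GPS
sampling — together with the ground truth needed to test every stage.

## Worked example

```python
from marathon_response.pipeline import run_simulated
from marathon_response.simulate import recovery_config

result, truth, _ = run_simulated(recovery_config(seed=1))
st = result.subject_table.merge(truth, on="subject_id")
err = (st["delta_v10"] - st["response_delta"]).abs()
print(len(st), "subjects kept")
print(f"max |Δv10 error| {err.max():.4f} m/s")
print(f"response-group agreement {(st.response == st.response_tier).mean():.1%}")
print(result.two_way_table.query("parameter == 'lit'")
      [["effect", "partial_eta2", "stars"]].round(3))
```

prints

```
90 subjects kept
max |Δv10 error| 0.0110 m/s
response-group agreement 95.6%
         effect  partial_eta2 stars
15     response         0.011
16     marathon         0.708   ***
17  interaction         0.017
```

— the pipeline recovers each runner's true 16-week 10-km improvement to
about a hundredth of a m/s, reassigns 95% of runners to their true
response tier, and finds that LIT share differs strongly between
marathon-performance groups (η² = 0.71) but barely between response
groups, matching the qualitative structure the analysis is designed to
expose.

The same run is available as a narrative sequence of scripts:

```sh
python analysis/01_simulate_cohort.py     # cohort design + ground truth
python analysis/02_run_pipeline.py        # features, blocks, filters
python analysis/03_group_assignment.py    # response x marathon groups
python analysis/04_group_statistics.py    # ANOVA tables with partial eta^2
python analysis/05_plausibility_report.py # histograms, v10-v_mp regression
python analysis/06_parameter_recovery.py  # measured vs true response
```

each writing small tables under `results/`.  A `marathon-response` CLI
(`simulate / extract / aggregate / filter / group / stats / report /
all`) runs the same stages over CSV/GPX files on disk.

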