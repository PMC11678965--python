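# tuglab

Test–retest reliability analysis of instrumented mobility tasks (Timed Up
and Go, cognitive TUG, and a 32-foot walk with three turns) from wearable
6-axis IMU signals, with a fully synthetic data generator so every stage is
testable offline.

The pipeline:

1. **`tuglab.synth`** — simulates 100 Hz triaxial accelerometer + gyroscope
   recordings with the task structure (chair transitions, 8-foot walk
   bouts, ~180° raised-cosine turns), four named group profiles
   (control/mild/moderate/severe), per-participant speed offsets, a trial-2
   learning/fatigue multiplier, and ground-truth annotations; also draws
   two-trial measure tables from the additive model
   `Y_ij = mu + p_i + t_j + e_ij`.
2. **`tuglab.segment`** — trapezoidal integration of yaw velocity to
   angular position, turn detection on monotone angle sweeps (≥ 90° by
   default), TUG segmentation into six subtasks, and the 32-foot walk split
   into two 16-foot walk/turn/walk trials omitting the middle turn.
3. **`tuglab.features`** — per-trial measures: durations; step counts,
   step/stride timing, autocorrelation step/stride regularity and step
   symmetry (vertical and anteroposterior); Welch-PSD peak amplitude,
   width, slope; transition range/jerk/SD/median; turn step count, yaw
   amplitude and dominant frequency.
4. **`tuglab.reliability`** — two-way absolute-agreement single-measure ICC
   (with McGraw–Wong F-based 95% CI), SEM = SD·√(1−ICC),
   MDC = SEM·1.96·√2, signed relative change between trials, and
   Bland–Altman limits of agreement with exact-t confidence intervals.
5. **`tuglab.mlpipe`** — diagnostic modelling protocol: random-forest
   feature ranking, elbow cutoff, forward AIC selection (out-of-bag
   likelihood), five replicates of stratified 5-fold CV with majority-class
   undersampling and per-participant majority voting; plus the
   duration-only logistic baseline and the trial-set comparison table.
6. **`tuglab.report`** — end-to-end orchestration and summary artifacts,
   including the ICC-vs-RC "paradox" table that flags groups with high ICC
   and simultaneously high relative change.

## CLI

```sh
tuglab simulate --out-dir run --n-per-group 10 --seed 1
tuglab segment --manifest run/manifest.csv --out run/segments.csv
tuglab extract --segments run/segments.csv --manifest run/manifest.csv --out run/measures.csv
tuglab reliability --measures run/measures.csv --out run/reliability.csv
tuglab ml-eval --measures run/measures.csv --manifest run/manifest.csv \
    --task TUG --group severe --feature-set trial1 --trees 500 --seed 1 --out eval.json
tuglab compare --evals run/eval --out comparison.csv
tuglab run --config config.yaml        # whole pipeline from a YAML config
```

Recordings are plain CSV (`time_s, acc_v, acc_ml, acc_ap, gyr_yaw,
gyr_pitch, gyr_roll`, g and deg/s) with a manifest
(`participant_id, group, task, trial, path`).

## Notes

- All simulator parameter defaults (`src/tuglab/data/group_profiles.yaml`)
  are artifact choices tuned for qualitative structure, not measured
  values.
- Measure definitions are documented stand-ins where the underlying
  source specifies only a measure family; the measure count is
  schema-driven and configurable.
- The forest "AIC" uses out-of-bag class probabilities clipped to
  [1e-6, 1-1e-6] with the feature count as the parameter count — a
  documented, seeded convention.
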