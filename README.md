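# fallkit

Analysis pipeline for a wearable inertial-sensor fall-risk test battery.
Five body-worn IMUs (low back, both upper legs, both lower legs, 100 Hz)
plus two tablet-app subtests yield a catalogue of 155 scalar measures per
subject across seven subtests; measures are screened univariately
(two-sample t-test + ROC) and fed to six cross-validated classifiers that
separate retrospective fallers from non-fallers.

Because no public recording of the original cohort exists, the package ships
a first-class synthetic-data module that generates signal-level sessions with
known ground truth (gait events, turn windows, sit-to-stand boundaries,
prescribed sway RMS) and feature-level cohorts with configurable per-group
means/SDs, so the whole pipeline is testable offline.

## Modules

| module | role |
| --- | --- |
| `fallkit.core_io` | domain types, session CSV format, faller labelling rule |
| `fallkit.synthetic_data` | IMU session simulators + ground truth, feature-level cohorts |
| `fallkit.preprocess` | zero-phase Butterworth low-pass, derivatives, tilt angles |
| `fallkit.features` | measure catalogue (155 ids), gait-event/turn detection, per-subtest extraction |
| `fallkit.stats_screen` | pooled t-tests, ROC AUC (Hanley–McNeil CI), screening, MDA ranking |
| `fallkit.classify` | six models, repeated stratified 10-fold CV, model comparison |
| `fallkit.cli` / `fallkit.config` | orchestration, YAML config, reporting |

## Command line

```bash
fallkit simulate battery --seed 3 --out scratch/sim    # sessions + app logs
fallkit extract --sessions scratch/sim --out scratch/features.csv
fallkit simulate cohort --seed 1 --out scratch/cohort  # feature-level cohort
fallkit screen --features scratch/cohort/cohort_features.csv --out scratch/screening.csv
fallkit classify --features scratch/cohort/cohort_features.csv --out scratch/eval.json
fallkit catalogue --out scratch/catalogue.csv          # 155 measures, 38 screened
fallkit run-all --seed 5 --out scratch/demo            # full synthetic demo pipeline
```

`run-all` simulates a small cohort of complete batteries, extracts all 155
measures per subject, screens them, cross-validates the six classifiers and
writes `features.csv`, `screening.csv`, `evaluation.json` and a human-readable
`report.txt`. Identical config + seed gives byte-identical outputs.

## Session file format

UTF-8 CSV, one file per subject × subtest, metadata in leading `#` YAML
lines (`subject_id`, `subtest`, `sampling_rate`, `walkway_distance_m`, ...),
columns `time_s, location, acc_x..z [m/s^2], gyro_x..z [deg/s]` and optional
`mag_x..z`, `roll_deg, pitch_deg, yaw_deg`. Axis convention: x =
anteroposterior, y = mediolateral, z = vertical (upright). Angular velocity
is normalized to deg/s on load (`gyro_unit: rad/s` in the format spec
converts).
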