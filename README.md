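# zuptgait

Foot-mounted IMU gait analysis in Python: a ZUPT-aided error-state Kalman
filter over strapdown integration, a synthetic walking-data simulator with
vendor-style sensor artifacts, spatio-temporal gait parameter extraction,
and agreement statistics against reference stride tables.

## What's inside

| Module | Purpose |
| --- | --- |
| `zuptgait.imu_records` | Data model + I/O for unified IMU CSVs (`t,ax,ay,az,gx,gy,gz`) and reference stride tables; unit normalization; gap detection |
| `zuptgait.synthetic_gait` | Ground-truth walking trajectories (exactly stationary stances, minimum-jerk swings, clearance arc, sagittal pitch profile), inverse-strapdown conversion to ideal IMU signals, artifact injection (noise, bias, gain error, ±range clipping, packet loss, timestamp jitter) |
| `zuptgait.signal_qc` | Empirical sampling-rate distributions, stationary baselines, saturation detection |
| `zuptgait.zupt_eskf` | Rodrigues attitude update, explicit-Euler strapdown, windowed zero-velocity detector, 9-state (attitude/velocity/position error) Kalman filter with zero-velocity corrections |
| `zuptgait.gait_params` | Peak-detection gait events on raw angular velocity, stride segmentation, turning-stride exclusion, cadence |
| `zuptgait.agreement_eval` | First-stride synchronization, greedy IC-time stride matching, Pearson/OLS regression, Bland–Altman limits of agreement, K-Means + silhouette left/right-consistency screen |
| `zuptgait.cli_config` / `zuptgait.cli` | Flat namespaced configuration and the `zuptgait` command-line pipeline |
| `zuptgait.experiments` | End-to-end simulate→analyze→match helpers shared by tests and reports |

## CLI

```bash
# synthesize a walk (unified CSV + truth stride table)
zuptgait simulate --out sim/ --seed 1            # optional --spec spec.yaml

# raw-data quality report
zuptgait qc --in sim/rec.csv --report qc.json

# filter + stride table
zuptgait analyze --in sim/rec.csv --out strides.csv --states states.csv

# compare stride tables
zuptgait evaluate --measured strides.csv --reference sim/truth_strides.csv \
    --report eval.json

# everything at once
zuptgait run --in sim/rec.csv --reference sim/truth_strides.csv --out analysis/
```

All tunables live in a flat YAML config (`--config cfg.yaml`) with
namespaced keys (`zupt.gyro_threshold`, `eskf.sigma_accel`, `match.tol`,
…). `zuptgait run --print-config` echoes every key with its default and
unit. Recordings with gaps beyond `eskf.max_gap` abort with a data-loss
error listing the gap intervals (exit code 2); `eskf.bridge_gaps: true`
linearly interpolates holes of up to 3 samples.

Simulation specs for `simulate` use `gait.*` / `artifact.*` keys, e.g.:

```yaml
gait.n_strides: 50
gait.stride_length_mean: 1.2
gait.turn_every: 10
artifact.accel_noise_sd: 0.02
artifact.clip_accel_range: 4.0
artifact.packet_loss_fraction: 0.0
```

## Conventions

- Internal units are SI (m/s², rad/s); 1 g = 9.80665 m/s².
- Global frame is z-up; sensor frame right-handed; times are seconds from
  recording start (epoch offsets kept as metadata).
- All randomness flows from explicit seeds; identical seeds give
  byte-identical outputs.
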