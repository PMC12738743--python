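# nfmotion

Movement-quality analysis for wearable IMU recordings of two standardized
motor tasks — seated foot stomping (FS) and hand pronation–supination
(HPS) — together with subthalamic beta-band power analysis for DBS-based
neurofeedback sessions, and the paired statistics connecting the two.
A synthetic-data module generates IMU and LFP recordings with known
ground truth so the entire pipeline is testable offline by parameter
recovery.

## What's inside

| module | contents |
|---|---|
| `nfmotion.synth` | seeded generators: stomp pulse trains (closed-form step heights/velocities, injectable halts, amplitude decrement), alternating wrist-rotation pulses, LFP with 1/f background + segment-modulated beta sinusoid, paired cohorts with known effect size |
| `nfmotion.imu` | quaternion sensor→global frame transform, g→m/s² conversion + gravity compensation, zero-phase 0.5 Hz high-pass, polyphase downsampling to 50 Hz, active-movement segmentation |
| `nfmotion.kinematics` | peak detection, double integration with per-segment zero-velocity updates, single integration for angular displacement, per-movement segments (amplitude, peak speed) |
| `nfmotion.metrics` | the full metric set: magnitude, rate, mean peak velocity, mean amplitude, total displacement, spectral arc length, log-dimensionless jerk, halts (μ+2σ rule), mean intervals, amplitude change and slope |
| `nfmotion.lfp` | feedback band (beta-peak ± 2.5 Hz), per-block median normalization, block summaries (% change vs baseline), Welch beta-peak validation, complex-Morlet TFR (cmor 0.5–5.0) with Savitzky–Golay smoothing, responder classification, Δβ change scores |
| `nfmotion.stats` | exact two-sided paired Wilcoxon signed-rank test (DP over mid-ranks, tie-exact), paired Cohen's d_z with percentile bootstrap CIs, paired TOST equivalence (±0.3·SD(pre)), z-scored correlation/regression with task factor, change-score coupling, prespecified analysis sets (all / responders / leave-one-out) |
| `nfmotion.io`, `nfmotion.protocol`, `nfmotion.pipeline`, `nfmotion.cli` | CSV/JSON/YAML formats, the 4-block session protocol template, the end-to-end report pipeline, and the CLI |

## CLI

```bash
nfmotion simulate fs   --seed 1 --out fs.csv
nfmotion simulate hps  --seed 1 --out hps.csv
nfmotion simulate lfp  --seed 1 --beta-peak-hz 20.51 --out lfp.json
nfmotion metrics --imu fs.csv --out metrics.tsv
nfmotion lfp --session lfp.json --out blocks.tsv
nfmotion stats --metrics paired.tsv --non-responders P01,P09 --out stats.tsv
nfmotion report --seed 1 --out run/          # full synthetic-cohort report
```

`report` writes `metrics.tsv` (participant / task / phase / metric /
value), `blocks.tsv` (per-segment normalized beta power), `stats.tsv`
(Wilcoxon W, exact p, SMD with bootstrap CI per analysis set) and a
`run.log` carrying the resolved-config hash. Runs are deterministic
given `--seed`.

## Conventions

- Quaternions: Hamilton, scalar-first, active rotation sensor→global.
- On-disk units: acceleration in g, angular velocity in °/s; SI after
  preprocessing. Gravity constant 9.81 m/s².
- Time: seconds from session start; segment windows half-open [start, end).
- All randomness flows from explicit seeds via `numpy.random.Generator`.
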