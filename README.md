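# thighgait

Detection of the four gait events — initial contact (IC), opposite toe off
(OTO), opposite initial contact (OIC), and toe off (TO) — from a **single
thigh-mounted IMU**, plus the temporal gait parameters they enable
(stance/swing, symmetry index, single/double limb support), an evaluation
layer against reference event tables, and a synthetic gait-signal simulator
that provides exact ground-truth events so the whole pipeline is testable
without experimental data.

## How it works

1. **Feature signals** (`thighgait.signal_model`): the vertical acceleration
   is band-passed (2nd-order Butterworth, zero-phase) around its dominant
   spectral frequency ± 0.5 Hz (`az_bp`); the pitch angular velocity is
   low-passed at 3 Hz (`gy_lp3`). The dominant frequency is estimated from
   the zero-padded magnitude spectrum with parabolic peak refinement.
2. **Event rules** (`thighgait.event_detection`):
   - **TO** — sub-threshold local minimum of the raw pitch rate;
   - **IC** — supra-threshold vertical-acceleration peak inside a window
     bounded by adjacent `az_bp` minima, gated by an anterior–posterior
     acceleration spike when present;
   - **OTO** — first pitch-rate peak after IC plus a configurable delay;
   - **OIC** — first (+)→(−) zero crossing of `gy_lp3` after OTO.
   Thresholds are calibrated by exhaustive grid search against reference
   events (lexicographic objective: matching F1, then mean |error|, then
   distance to the grid centre).
3. **Parameters** (`thighgait.gait_parameters`): per-cycle stance, swing,
   symmetry, single and double limb support percentages, stride time,
   cadence; with exact identities stance + swing = 100 and
   stance = SLS + 2·DLS.
4. **Evaluation** (`thighgait.evaluation`): greedy nearest-neighbour event
   matching, error in ms (detected − reference; negative = early) and as a
   percentage of the enclosing reference gait cycle, 3×IQR outlier
   flagging, and calculated-minus-measured parameter error tables.
5. **Simulator** (`thighgait.simulator`): a seeded, parametric stride
   timeline rendered into six-axis signals whose morphology places every
   detector trigger at an exactly known time (monotone piecewise-cubic
   pitch-rate waveform; two-per-stride vertical-acceleration oscillation
   with impact pulses at IC/OIC).

## CLI

```sh
# synthetic dataset (IMU CSV + ground-truth events + spec provenance)
thighgait simulate --seed 42 --n-strides 20 --noise-rel 0.1 --out-dir data/

# calibrate thresholds against reference events
thighgait calibrate --recording data/imu.csv --reference data/events_truth.csv \
    --out config.yaml --report calibration.json

# detect events (and per-cycle parameters)
thighgait detect data/imu.csv --config config.yaml \
    --out events.csv --params params.csv --manifest manifest.json

# parameters from an existing events table
thighgait params events.csv --out params.csv

# score detected events against a reference table
thighgait evaluate events.csv data/events_truth.csv --out-prefix report
```

IMU CSV schema: `t,acc_x,acc_y,acc_z,gyro_x,gyro_y,gyro_z` (`t` in seconds,
optional); source units (`g`, `deg/s`) are declared in the config YAML and
converted to m/s² and rad/s at load. For left-side sensors the pitch rate
is negated at load so one detector serves both legs.

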