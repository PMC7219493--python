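# dropsleeve

Analytics for an instrumented eye-drop bottle sleeve that monitors medication
adherence. Poor adherence to glaucoma eye drops is a major modifiable cause of
vision loss, and unlike smart pill bottles, a sensing sleeve can verify that
liquid medication was *actually dispensed*: a reed switch reports the cap
state, an IMU reports bottle orientation and motion, and a two-plate
capacitive sensor wrapped around the bottle tracks the fluid level.

`dropsleeve` implements the computational core of such a system as a tested
library and CLI:

* a **seeded scenario simulator** that stands in for the hardware, generating
  multichannel sensor logs (accelerometer, gyroscope, magnetometer, reed
  switch, 10 Hz capacitance) with ground-truth labels for scripted tasks —
  walking, dispensing standing/reclined, cap-off without dispensing, shaking,
  and "simulated use" (raising the bottle to the eye without releasing fluid);
* **fluid-level calibration and estimation** from the linear capacitance law

  `C = R·V + C_empty`

  where `V` is the remaining volume (mL), `R` (pF/mL) bundles the
  medication/air dielectric ratio with bottle geometry, and `C_empty` (pF) is
  the empty-bottle reading — fitted by ordinary least squares and inverted
  with clamping to the bottle's physical range;
* a **bench resolution analysis** using a two-sided *exact* Mann–Whitney U
  test (full enumeration over rank assignments, mid-ranks for ties) on
  replicate readings at a ladder of fill levels;
* **use-event detection** on cap-off episodes, both rule-based (tilt within
  100°–260° of upright *and* ≥4 consecutive positive capacitance increments —
  the squeeze signature) and machine-learned (descriptive-statistics features
  per channel, random forest by default, stratified k-fold cross-validation,
  per-sensor information-gain ranking);
* **evaluation metrics** (TPR/FPR, precision, recall, F1, MCC, ROC area) and a
  **duty-cycle power budget** with constant-voltage battery-lifetime
  estimation.

## Worked example

Simulate the ten-subject controlled protocol (six tasks per subject → 100 use
and 100 non-use cap-off episodes) and evaluate both detectors:

```sh
$ dropsleeve protocol --seed 0
{
  "episodes": {"use": 100, "non_use": 100},
  "rule": {"tpr": 0.93, "fpr": 0.22, "precision": 0.81, "recall": 0.93,
           "f1": 0.87, "mcc": 0.72, "roc_area": 0.85, "degenerate": []},
  "ml":   {"tpr": 1.0, "fpr": 0.0, "precision": 1.0, "recall": 1.0,
           "f1": 1.0, "mcc": 1.0, "roc_area": 1.0, "degenerate": []}
}
```

The rule-based detector misses the weak/slow squeezes some subjects produce
(TPR 0.93) and is fooled by cap-removal squeezes near horizontal (FPR 0.22),
while the learned detector separates the simulated episodes cleanly — the
same direction seen on real subject data, where the learned detector also
dominates the rules on both rates.

Simulate a seven-hour work day with hourly dispenses and one 30-minute
transport block (fluid readings are gated on the bottle being upright and
stationary every 30 min):

```sh
$ dropsleeve day --seed 0
{
  "use_events_detected": 7,
  "level_readings": 13,
  "level_marks": 14,
  "final_volume_mL": 9.44
}
```

All 7 dispenses are detected; the transport block suppresses exactly one of
the 14 half-hour level readings; the bottle ends the day 0.56 mL lighter
(7 doses × 2 drops × 0.04 mL).

Power budget for the prototype board and its 3.7 V / 85 mAh cell:

```sh
$ dropsleeve power-budget
{
  "average_power_mW": {"nRF51422 (MCU)": 3.327, "BNO080 (IMU)": 5.074,
                       "FDC1004 (Capacitance)": 0.109, "Bluetooth (BLE)": 9.605},
  "total_mW": 18.115,
  "battery_life_h": 17.36
}
```

Other subcommands: `simulate`, `calibrate`, `resolution`, `train`, `detect`,
`evaluate`, `rank-features` (see `dropsleeve --help`).

## Documentation

The model, its assumptions, parameter defaults, and known limitations are
described in [docs/methods.md](docs/methods.md).
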