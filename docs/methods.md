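# Methods

## Sensing model

The sleeve wraps a 15 mL prescription eye-drop bottle. Two copper plates
around the bottle act as parallel capacitors, one over the medication column
and one over the air column, so total capacitance is linear in the remaining
volume:

    C_total = C_medication + C_air = R·V + C_empty

with default forward-model constants `R = 0.56 pF/mL` and
`C_empty = 5.15 pF`. The converter samples at 10 Hz. A reed switch (actuated
by bar magnets in the cap) reports the cap state; a BNO080-class IMU supplies
3-axis accelerometer, gyroscope and magnetometer channels.

Orientation convention: the bottle's +z axis points down when upright, so the
resting z-axis acceleration is +g (9.80665 m/s²). Tilt is the signed rotation
about the bottle's horizontal x-axis recovered as `atan2(ay, az)` mapped to
[0°, 360°): upright = 0°, fully inverted = 180°. A signed angle is required
because the rule detector's acceptance window (100°–260°) is wider than a
half-turn, which an unsigned tilt angle cannot express. Samples near free
fall (|a| ≤ 1 m/s²) have undefined orientation and return NaN.

## Synthetic sensor streams

The simulator renders scenario scripts (ordered task lists) into uniformly
sampled logs at 50 Hz for the motion channels, with the 10 Hz capacitance
channel zero-order-held onto the common grid. Dispensing produces, in order:
cap-off, a smoothstep flip to the subject's tilt angle (the angle derivative
supplies the gyroscope transient at flip start and end), a capacitance step
down on inversion (fluid leaves the sensed volume into the nozzle; −0.8 pF
default), a gradual rise while the bottle is squeezed (+0.5 pF over 1 s
default), a sharp suction dip after release (−0.4 pF for 0.3 s), the volume
decrement (0.04 mL per drop, 2 drops per use by default), the flip back, and
cap-on. "Simulated use" renders the same flip with no squeeze rise and no
suction dip. Walking, shaking and transport are oscillatory accelerometer/
gyroscope activity with the cap on. Signature *shapes* are the contract;
all magnitudes are free parameters in `SignalConfig`.

Two hardware-motivated cap-off effects are also modelled: the removed cap
carries the reed-switch magnets and moves freely in the subject's hand, so a
smooth large-amplitude disturbance corrupts the magnetometer whenever the cap
is off; and hand tremor (the target population is 65+) jitters the gyroscope
during handling. Both degrade the class information those sensors carry in
exactly the windows the classifier sees, which is why orientation
(accelerometer) and capacitance dominate the information-gain ranking.

### Noise model

Two distinct noise scales are deliberately separated:

* **Stream noise** — white converter noise of 0.004 pF SD plus 0.01 pF ADC
  quantization per 10 Hz sample. Because the white noise sits below the
  quantization step, a *flat* capacitance channel produces mostly zero first
  differences, so the rule detector's "≥4 consecutive strictly positive
  increments" test almost never fires on noise, while a genuine squeeze
  (≈0.05 pF per sample) always clears it. A single large iid per-sample
  noise would instead make four-sample positive runs a coin-flip occurrence
  in any window and destroy the rule detector entirely.
* **Bench replicate noise** — 0.055 pF SD between steady-state readings of
  the same fill level, dominated by refill and repositioning variability
  between trials rather than converter noise. This drives calibration and
  resolution studies. The value was calibrated against the exact-test oracle
  so that, at five replicates, 0.4 mL level separations are reliably
  significant while 0.2 mL separations are not — the empirically reported
  operating point of the physical sensor.

Determinism: all draws flow through one `numpy` generator seeded by the
scenario, so a fixed (script, seed) pair reproduces the CSV log byte for
byte.

### Subject variability

Per-subject handling spread (`SubjectProfile.sample`) applies log-normal
multipliers to flip speed (σ=0.2), squeeze amplitude (σ=0.25) and episode
pacing (σ=0.15), draws an idiosyncratic dispensing tilt in [150°, 225°], and
adds three behavioural confounders observed in practice: with probability
0.08 a use event has a weak and slow squeeze (quarter amplitude over 2.5×
duration — below the quantization step per sample, so the rule detector
misses it, while total capacitance excursion, suction dip and duration still
mark it for the learned detector); with probability 0.25 a simulated-use
episode includes a small squeeze artifact while aiming; and with probability
0.10 a cap-off-no-dispense episode includes a near-horizontal tilt excursion
with a removal squeeze. The base simulator defaults are clean — variability
is opt-in and used by the protocol experiment runner.

## Fluid level

Calibration is ordinary least squares of capacitance on volume
(`scipy.stats.linregress`); at least two distinct volumes are required.
Estimation inverts the line and clamps to [0, capacity] with a flag, since
field readings can wander below `C_empty`. Level sampling is gated: a reading
is taken only when ≥30 min have elapsed since the last one and over the
trailing 5 s window the mean z-acceleration is within ±0.5 m/s² of +g with
per-axis SD < 0.3 m/s² (the stationarity thresholds are design choices
exposed as arguments).

## Exact Mann–Whitney test

With five replicates per level, normal approximations are inappropriate, so
the two-sided test enumerates the exact permutation distribution of the rank
sum over all C(n+m, n) assignments of rank positions (a fixed-size
subset-sum dynamic programme over doubled mid-ranks, exact in the presence
of ties; group sizes ≤ 12). The two-sided p-value is `min(1, 2·min(P(W ≤ w),
P(W ≥ w)))`. Resolution is the smallest level separation from which every
pairwise comparison at that or any larger separation has p < 0.05; no
multiple-comparison correction is applied, matching the bench protocol's
per-pair assessment.

## Event detection

Episodes are maximal cap-off runs; runs shorter than 0.5 s are discarded as
switch bounce. The rule detector labels an episode *use* iff some sample's
tilt lies in [100°, 260°] and the native-rate capacitance channel contains a
run of ≥4 strictly positive first differences. Features are seven descriptive
statistics (mean, SD, min, max, range, total absolute variation Σ|Δx|, sign
changes about the mean) for each of the nine IMU axes and the capacitance
channel, plus episode duration and mean/max tilt — 73 features. Total
absolute variation is the feature that captures small squeeze fluctuations a
min/max range misses, and it dominates the capacitance ranking.

Classifiers: random forest (100 trees; the production detector), linear-kernel
SVM, logistic regression, Gaussian naive Bayes, and a decision tree as the
nearest standard analogue of a rule-list/decision-table learner. Skill is
assessed by stratified 10-fold cross-validation with pooled out-of-fold
confusion counts; when k exceeds the minority class count (e.g. leave-one-out)
plain shuffled k-fold is used. Information gain is
`H(class) − H(class | feature)` after 10-bin equal-frequency discretization;
a sensor's score is the mean over its features (orientation features count as
accelerometer; episode duration is clock-derived and excluded).

A note on metric definitions: recall is TP/(TP+FN) (equal to TPR), precision
is TP/(TP+FP), F1 is their harmonic mean, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Zero denominators
return a 0 sentinel with the metric named in a `degenerate` flag.

## Power budget

A component's average draw is `idle·(1−duty) + active·duty` (mW); lifetime is
`V·Q / ΣP̄` hours under a constant-voltage energy model with no discharge
curve, matching how such budgets are tabulated. On the built-in prototype
table the computed BLE average (9.61 mW) differs slightly from the 9.5 mW its
published row tabulates — the calculator always reports computed values, and
the published per-component averages (summing to 18.0 mW, hence 17.5 h on a
3.7 V / 85 mAh cell) are kept alongside as data.

## Experiment runners and problem sizes

The protocol experiment simulates 10 subjects × six tasks (100 use, 100
non-use episodes, ~5 min of signal per subject at 50 Hz), evaluates the rule
detector directly and the learned detector by cross-validation. The day
experiment simulates 7 hours with hourly dispenses and one 30-minute
transport block, detects events with a random forest trained on a separately
seeded protocol dataset, and applies the 30-minute sampling gate (14 marks,
of which transport suppresses exactly one). These sizes match the study
conditions being emulated and keep a full run to seconds.

## What the synthetic data does and does not show

The generator reproduces the *signatures* detectors rely on and their
described failure modes, not the physics: no fluid dynamics (inversion and
suction are steps/dips of configured size), no temperature or drift in the
capacitance channel, no BLE transport effects, idealized reed-switch edges,
and subject variability that is parametric rather than learned from humans.
Passing tests therefore demonstrate the correctness of the pipeline and the
qualitative behaviour of the detectors under the modelled effects; absolute
detection rates on real patients cannot be inferred from them. The learned
detector's near-perfect cross-validated scores on synthetic episodes reflect
the cleanliness of the modelled classes, which is why its comparison against
the rule detector is asserted only as a dominance direction, not as specific
rates.

## Known limitations

* The exact test is limited to group sizes ≤ 12 by design.
* `SVC(probability=True)` is deprecated upstream; the SVM scores will need a
  calibrated-classifier wrapper in future scikit-learn versions.
* The magnetometer disturbance and tremor models are first-order stand-ins;
  they exist to give the sensor-ranking analysis realistic contrast.
* Orientation uses only `atan2(ay, az)`; rotation about the bottle's own
  x-axis is the simulator's flip convention, and real devices would fuse all
  three axes.
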