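"""Scenario-scripted synthetic sensor streams for an instrumented eye-drop bottle.

The simulator emulates the multichannel log produced by a sensing sleeve that
slides over a prescription eye-drop bottle: a 3-axis accelerometer, gyroscope
and magnetometer (IMU), a reed switch reporting the cap state, and a two-plate
capacitive fluid-level sensor read at 10 Hz.  A scenario is an ordered list of
tasks (walking, dispensing while standing or reclined, removing the cap
without dispensing, shaking, "simulated use" with no fluid released, idling).
Each task stamps its characteristic signatures onto the channels:

* upright rest: z-axis acceleration ~ +g (the bottle's +z axis points down);
* dispensing: cap off, a flip to ~180 deg with gyroscope transients at flip
  start/end, a capacitance step down on inversion (fluid leaves the sensed
  volume into the nozzle), a gradual capacitance rise while the bottle is
  squeezed, and a sharp suction dip when the squeeze is released;
* simulated use: the same flip but no squeeze rise and no suction dip;
* walking/shaking: oscillatory accelerometer/gyroscope activity, cap on.

Capacitance follows the parallel-plate model C = R*V + C_empty, where V is the
remaining medication volume, R bundles the dielectric ratio with the bottle
geometry, and C_empty is the empty-bottle reading.  The stream channel adds
white converter noise and ADC quantization; bench-style replicate readings
(used for calibration and resolution studies) instead carry a larger
trial-to-trial SD dominated by refill/repositioning variability.

Every random draw goes through one seeded generator, so a fixed
(script, seed) pair reproduces the log byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

GRAVITY_MS2 = 9.80665
CAP_RATE_HZ = 10.0  # capacitance-to-digital converter sampling rate

LOG_COLUMNS = [
    "t_s", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz",
    "cap_on", "cap_pF",
]

#: ambient magnetic field in the upright bottle frame (arbitrary units)
_MAG_FIELD = np.array([18.0, 4.0, -42.0])

DISPENSE_KINDS = frozenset({"dispense_standing", "dispense_reclined"})
CAP_OFF_KINDS = DISPENSE_KINDS | {"cap_off_no_dispense", "simulated_use"}
TASK_KINDS = CAP_OFF_KINDS | {"walk", "shake", "idle_upright", "idle_transport"}

_DEFAULT_DURATION_S = {
    "walk": 60.0,
    "dispense_standing": 12.0,
    "dispense_reclined": 12.0,
    "cap_off_no_dispense": 6.0,
    "shake": 5.0,
    "simulated_use": 10.0,
    "idle_upright": 10.0,
    "idle_transport": 60.0,
}


@dataclass(frozen=True)
class BottleSpec:
    """Geometry and fill state of the monitored bottle.

    ``slope_pF_per_mL`` and ``c_empty_pF`` are the forward-model constants of
    the linear capacitance-volume law C = R*V + C_empty.
    """

    capacity_mL: float = 15.0
    slope_pF_per_mL: float = 0.56
    c_empty_pF: float = 5.15
    drop_volume_mL: float = 0.04
    initial_volume_mL: float = 10.0

    def __post_init__(self) -> None:
        if self.capacity_mL <= 0 or self.slope_pF_per_mL <= 0 or self.c_empty_pF <= 0:
            raise ValueError("capacity, slope and empty capacitance must be positive")
        if not 0.0 <= self.initial_volume_mL <= self.capacity_mL:
            raise ValueError(
                f"initial volume {self.initial_volume_mL} mL outside "
                f"[0, {self.capacity_mL}] mL"
            )


@dataclass(frozen=True)
class SignalConfig:
    """Free amplitude/noise parameters of the synthetic signatures.

    Shapes of the signatures are the contract; magnitudes are tunable.
    ``cap_noise_sd_pF`` is per-sample converter noise on the 10 Hz stream
    (kept below the quantization step ``cap_quant_pF`` so a flat channel
    yields mostly zero first differences); ``bench_noise_sd_pF`` is the
    trial-to-trial SD of steady-state bench readings.
    """

    cap_noise_sd_pF: float = 0.004
    cap_quant_pF: float = 0.01
    bench_noise_sd_pF: float = 0.055
    accel_noise_sd: float = 0.15       # m/s^2
    gyro_noise_sd: float = 2.0         # deg/s
    mag_noise_sd: float = 0.3
    inversion_offset_pF: float = -0.8  # step when the bottle tips past horizontal
    squeeze_rise_pF: float = 0.5       # gradual rise while squeezing
    squeeze_rise_s: float = 1.0
    suction_drop_pF: float = -0.4      # sharp dip after the squeeze is released
    suction_dip_s: float = 0.3
    flip_duration_s: float = 0.5
    #: magnetometer disturbance while the cap is off: the removed cap carries
    #: the reed-switch bar magnets, so it corrupts the field nearby
    cap_magnet_disturbance: float = 25.0
    #: hand-tremor angular jitter while the bottle is handled cap-off (deg/s)
    tremor_gyro_sd: float = 20.0


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject handling variability applied on top of a scenario.

    Defaults are the clean laboratory signatures (no jitter, no confounders).
    ``sample`` draws a realistic participant: log-normal multipliers on flip
    speed, squeeze amplitude and episode pacing, an idiosyncratic dispensing
    tilt, occasional weak/slow squeezes (which real detectors miss), and
    occasional cap-removal squeeze artifacts near horizontal (which fool a
    rule that only looks for a capacitance rise at a tilted orientation).
    """

    flip_speed_mult: float = 1.0
    squeeze_amp_mult: float = 1.0
    duration_mult: float = 1.0
    tilt_deg: float = 185.0
    weak_squeeze_prob: float = 0.0
    removal_artifact_prob: float = 0.0
    tilt_excursion_prob: float = 0.0

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "SubjectProfile":
        return cls(
            flip_speed_mult=float(np.clip(rng.lognormal(0.0, 0.2), 0.6, 1.8)),
            squeeze_amp_mult=float(np.clip(rng.lognormal(0.0, 0.25), 0.5, 2.0)),
            duration_mult=float(np.clip(rng.lognormal(0.0, 0.15), 0.8, 1.5)),
            tilt_deg=float(rng.uniform(150.0, 225.0)),
            weak_squeeze_prob=0.08,
            removal_artifact_prob=0.25,
            tilt_excursion_prob=0.10,
        )


@dataclass(frozen=True)
class TaskSpec:
    """One scripted task: what the subject does, for how long, how often."""

    kind: str
    duration_s: float | None = None
    repeats: int = 1
    drops_dispensed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.kind!r}")
        dur = self.duration_s if self.duration_s is not None else _DEFAULT_DURATION_S[self.kind]
        if dur <= 0:
            raise ValueError("task duration must be strictly positive")
        object.__setattr__(self, "duration_s", float(dur))
        drops = self.drops_dispensed
        if drops is None:
            drops = 2 if self.kind in DISPENSE_KINDS else 0
        if drops < 0:
            raise ValueError("drops_dispensed must be >= 0")
        if drops > 0 and self.kind not in DISPENSE_KINDS:
            raise ValueError(f"task {self.kind!r} cannot dispense drops")
        if self.kind in DISPENSE_KINDS and drops == 0:
            raise ValueError("dispense tasks must dispense at least one drop")
        object.__setattr__(self, "drops_dispensed", int(drops))
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class ScenarioScript:
    """An ordered task list plus sampling configuration and master seed."""

    tasks: tuple[TaskSpec, ...]
    sample_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        tasks = tuple(self.tasks)
        if not tasks:
            raise ValueError("scenario must contain at least one task")
        if self.sample_rate_hz < CAP_RATE_HZ:
            raise ValueError(f"sample rate must be >= {CAP_RATE_HZ} Hz")
        object.__setattr__(self, "tasks", tasks)


@dataclass
class SensorLog:
    """Uniformly sampled multichannel record of one bottle session."""

    t: np.ndarray                 # s
    accel: np.ndarray             # (n, 3) m/s^2
    gyro: np.ndarray              # (n, 3) deg/s
    mag: np.ndarray               # (n, 3) arbitrary units
    cap_on: np.ndarray            # bool reed-switch state
    capacitance: np.ndarray       # pF, zero-order-held 10 Hz channel
    sample_rate_hz: float
    cap_rate_hz: float = CAP_RATE_HZ

    def __len__(self) -> int:
        return len(self.t)

    @property
    def cap_stride(self) -> int:
        """Motion samples per capacitance update."""
        return max(1, int(round(self.sample_rate_hz / self.cap_rate_hz)))

    def slice(self, i0: int, i1: int) -> "SensorLog":
        return SensorLog(
            t=self.t[i0:i1], accel=self.accel[i0:i1], gyro=self.gyro[i0:i1],
            mag=self.mag[i0:i1], cap_on=self.cap_on[i0:i1],
            capacitance=self.capacitance[i0:i1],
            sample_rate_hz=self.sample_rate_hz, cap_rate_hz=self.cap_rate_hz,
        )

    def cap_channel(self) -> np.ndarray:
        """Capacitance at its native 10 Hz rate (one value per converter update)."""
        return self.capacitance[:: self.cap_stride]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t,
            "ax": self.accel[:, 0], "ay": self.accel[:, 1], "az": self.accel[:, 2],
            "gx": self.gyro[:, 0], "gy": self.gyro[:, 1], "gz": self.gyro[:, 2],
            "mx": self.mag[:, 0], "my": self.mag[:, 1], "mz": self.mag[:, 2],
            "cap_on": self.cap_on.astype(int),
            "cap_pF": self.capacitance,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SensorLog":
        t = df["t_s"].to_numpy(float)
        if len(t) > 1:
            fs = 1.0 / float(np.median(np.diff(t)))
        else:
            fs = CAP_RATE_HZ
        return cls(
            t=t,
            accel=df[["ax", "ay", "az"]].to_numpy(float),
            gyro=df[["gx", "gy", "gz"]].to_numpy(float),
            mag=df[["mx", "my", "mz"]].to_numpy(float),
            cap_on=df["cap_on"].to_numpy(int).astype(bool),
            capacitance=df["cap_pF"].to_numpy(float),
            sample_rate_hz=float(round(fs, 6)),
        )


@dataclass(frozen=True)
class GroundTruthEvent:
    t_start: float
    t_end: float
    label: str  # "use" | "non_use"


@dataclass
class GroundTruth:
    """Labelled cap-off episodes and the true fluid-volume timeline."""

    events: list[GroundTruthEvent]
    volume_timeline: list[tuple[float, float]]  # (t, mL remaining)

    def to_json(self) -> str:
        return json.dumps({
            "events": [dataclasses.asdict(e) for e in self.events],
            "volume_timeline": [[t, v] for t, v in self.volume_timeline],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            events=[GroundTruthEvent(**e) for e in obj["events"]],
            volume_timeline=[(float(t), float(v)) for t, v in obj["volume_timeline"]],
        )


def capacitance_forward(
    volume_mL: float,
    bottle: BottleSpec = BottleSpec(),
    squeeze: float = 0.0,
    inverted: bool = False,
    config: SignalConfig = SignalConfig(),
) -> float:
    """Noise-free capacitance reading for a given fluid volume and bottle state.

    Upright and unsqueezed this is exactly R*V + C_empty.  Inversion shifts
    the reading down by a fluid-redistribution offset; squeezing adds a
    perturbation that increases monotonically with squeeze effort in [0, 1].
    """
    if volume_mL < 0:
        raise ValueError(f"volume must be non-negative, got {volume_mL}")
    if volume_mL > bottle.capacity_mL:
        raise ValueError(
            f"volume {volume_mL} mL exceeds bottle capacity {bottle.capacity_mL} mL"
        )
    c = bottle.slope_pF_per_mL * volume_mL + bottle.c_empty_pF
    if inverted:
        c += config.inversion_offset_pF
    c += float(squeeze) * config.squeeze_rise_pF
    return float(c)


def bench_capacitance_readings(
    volumes_mL: Sequence[float],
    replicates: int,
    noise_sd_pF: float | None = None,
    seed: int = 0,
    bottle: BottleSpec = BottleSpec(),
    config: SignalConfig = SignalConfig(),
) -> pd.DataFrame:
    """Replicate steady-state upright bench readings at given fill levels.

    Emulates the bench protocol: the bottle is filled to each level, left
    upright, and a steady-state capacitance is logged per trial.  The noise SD
    is per replicate (trial-to-trial refill/repositioning variability), not
    per raw converter sample.
    """
    if noise_sd_pF is None:
        noise_sd_pF = config.bench_noise_sd_pF
    if noise_sd_pF <= 0:
        raise ValueError("noise SD must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for v in volumes_mL:
        base = capacitance_forward(v, bottle=bottle, config=config)
        for r in range(replicates):
            rows.append((float(v), r, base + rng.normal(0.0, noise_sd_pF)))
    return pd.DataFrame(rows, columns=["volume_mL", "replicate", "cap_pF"])


class _ScenarioBuilder:
    """Accumulates per-sample channel primitives task by task.

    Channels are assembled from: tilt angle theta (deg, rotation about the
    bottle's horizontal x-axis; 0 = upright, 180 = inverted), cap state,
    a capacitance perturbation track (squeeze/suction/artifacts, pF), extra
    oscillatory accel/gyro activity, and the per-sample true volume.
    """

    def __init__(self, script: ScenarioScript, bottle: BottleSpec,
                 config: SignalConfig, profile: SubjectProfile,
                 rng: np.random.Generator):
        self.fs = script.sample_rate_hz
        self.dt = 1.0 / self.fs
        self.bottle = bottle
        self.cfg = config
        self.profile = profile
        self.rng = rng
        self.theta: list[np.ndarray] = []
        self.cap_on: list[np.ndarray] = []
        self.cap_extra: list[np.ndarray] = []
        self.acc_extra: list[np.ndarray] = []
        self.gyr_extra: list[np.ndarray] = []
        self.volume: list[np.ndarray] = []
        self.n = 0
        self.v = bottle.initial_volume_mL
        self.events: list[tuple[int, int, str]] = []  # sample-index spans
        self.vol_points: list[tuple[int, float]] = [(0, self.v)]

    # -- primitives ---------------------------------------------------------

    def _nsamp(self, dur_s: float) -> int:
        return max(1, int(round(dur_s * self.fs)))

    def _osc(self, n: int, amp: float, freq: float) -> tuple[np.ndarray, np.ndarray]:
        """Oscillatory accel (m/s^2) and gyro (deg/s) activity, per-axis phases."""
        if amp == 0.0:
            z = np.zeros((n, 3))
            return z, z.copy()
        t = np.arange(n) * self.dt
        phases = self.rng.uniform(0, 2 * np.pi, size=3)
        weights = np.array([1.0, 0.8, 0.6])
        acc = amp * weights * np.sin(2 * np.pi * freq * t[:, None] + phases)
        gph = self.rng.uniform(0, 2 * np.pi, size=3)
        gyr = amp * 12.0 * weights * np.sin(2 * np.pi * freq * t[:, None] + gph)
        return acc, gyr

    def _seg(self, n: int, theta, cap_on: bool, cap_extra=None,
             acc=None, gyr=None) -> None:
        theta = np.broadcast_to(np.asarray(theta, float), (n,)).copy()
        self.theta.append(theta)
        self.cap_on.append(np.full(n, cap_on))
        self.cap_extra.append(
            np.zeros(n) if cap_extra is None
            else np.broadcast_to(np.asarray(cap_extra, float), (n,)).copy())
        self.acc_extra.append(np.zeros((n, 3)) if acc is None else acc)
        self.gyr_extra.append(np.zeros((n, 3)) if gyr is None else gyr)
        self.volume.append(np.full(n, self.v))
        self.n += n

    def _idle(self, dur_s: float, cap_on: bool = True, theta: float = 0.0,
              osc_amp: float = 0.0, osc_freq: float = 1.0) -> None:
        n = self._nsamp(dur_s)
        acc, gyr = self._osc(n, osc_amp, osc_freq)
        self._seg(n, theta, cap_on, acc=acc, gyr=gyr)

    def _ramp_theta(self, dur_s: float, a: float, b: float, cap_on: bool) -> None:
        """Smoothstep tilt from a to b degrees; its derivative supplies the
        gyroscope transient at flip start/end."""
        n = self._nsamp(dur_s)
        s = np.linspace(0.0, 1.0, n)
        smooth = s * s * (3 - 2 * s)
        self._seg(n, a + (b - a) * smooth, cap_on)

    # -- task renderers -----------------------------------------------------

    def add_task(self, task: TaskSpec) -> None:
        for _ in range(task.repeats):
            getattr(self, f"_task_{task.kind}")(task)

    def _task_idle_upright(self, task: TaskSpec) -> None:
        self._idle(task.duration_s)

    def _task_idle_transport(self, task: TaskSpec) -> None:
        self._idle(task.duration_s, osc_amp=0.8,
                   osc_freq=self.rng.uniform(1.6, 2.4))

    def _task_walk(self, task: TaskSpec) -> None:
        n = self._nsamp(task.duration_s)
        freq = self.rng.uniform(1.6, 2.0)
        acc, gyr = self._osc(n, 2.5, freq)
        t = np.arange(n) * self.dt
        wobble = 8.0 * np.sin(2 * np.pi * 0.4 * t + self.rng.uniform(0, 2 * np.pi))
        self._seg(n, wobble, True, acc=acc, gyr=gyr)

    def _task_shake(self, task: TaskSpec) -> None:
        self._idle(task.duration_s, osc_amp=8.0,
                   osc_freq=self.rng.uniform(6.0, 9.0))

    def _pad_to(self, target_n: int) -> None:
        if self.n < target_n:
            self._seg(target_n - self.n, 0.0, True)

    def _dispense(self, task: TaskSpec, reclined: bool) -> None:
        p, cfg, rng = self.profile, self.cfg, self.rng
        target_n = self.n + self._nsamp(task.duration_s)
        du = p.duration_mult
        flip = cfg.flip_duration_s / p.flip_speed_mult * (1.3 if reclined else 1.0)
        tilt = float(np.clip(p.tilt_deg + rng.normal(0.0, 8.0), 110.0, 250.0))
        weak = rng.random() < p.weak_squeeze_prob
        amp = cfg.squeeze_rise_pF * p.squeeze_amp_mult * float(
            np.clip(rng.lognormal(0.0, 0.15), 0.7, 1.4))
        sq_dur = max(0.5, cfg.squeeze_rise_s * du)
        suction = cfg.suction_drop_pF
        if weak:
            amp *= 0.25
            sq_dur *= 2.5
            suction *= 0.25

        drops = task.drops_dispensed
        needed = drops * self.bottle.drop_volume_mL
        if needed > self.v + 1e-12:
            raise ValueError(
                f"cannot dispense {drops} drops ({needed:.3f} mL): only "
                f"{self.v:.3f} mL remaining (short {needed - self.v:.3f} mL)"
            )

        self._idle(1.0 * du)                      # cap still on
        i0 = self.n
        self._idle(0.4 * du, cap_on=False)        # handling after cap removal
        self._ramp_theta(flip, 0.0, tilt, cap_on=False)
        self._idle(0.4 * du, cap_on=False, theta=tilt)
        n_sq = self._nsamp(sq_dur)                # gradual squeeze rise
        self._seg(n_sq, tilt, False, cap_extra=np.linspace(0.0, amp, n_sq))
        self.v -= needed                          # droplets leave at release
        n_dip = self._nsamp(cfg.suction_dip_s)    # sharp post-squeeze suction dip
        self._seg(n_dip, tilt, False, cap_extra=np.full(n_dip, suction))
        self.vol_points.append((self.n, self.v))
        self._idle(0.3 * du, cap_on=False, theta=tilt)
        self._ramp_theta(flip, tilt, 0.0, cap_on=False)
        self._idle(0.4 * du, cap_on=False)
        self.events.append((i0, self.n, "use"))
        self._pad_to(target_n)

    def _task_dispense_standing(self, task: TaskSpec) -> None:
        self._dispense(task, reclined=False)

    def _task_dispense_reclined(self, task: TaskSpec) -> None:
        self._dispense(task, reclined=True)

    def _task_simulated_use(self, task: TaskSpec) -> None:
        p, cfg, rng = self.profile, self.cfg, self.rng
        target_n = self.n + self._nsamp(task.duration_s)
        du = p.duration_mult
        flip = cfg.flip_duration_s / p.flip_speed_mult
        tilt = float(np.clip(p.tilt_deg + rng.normal(0.0, 8.0), 110.0, 250.0))
        artifact = rng.random() < p.removal_artifact_prob

        self._idle(1.0 * du)
        i0 = self.n
        self._idle(0.4 * du, cap_on=False)
        self._ramp_theta(flip, 0.0, tilt, cap_on=False)
        if artifact:
            # squeezing the bottle while aiming, without releasing fluid
            self._idle(0.3 * du, cap_on=False, theta=tilt)
            n_a = self._nsamp(0.6)
            a_amp = 0.2 * float(np.clip(rng.lognormal(0.0, 0.2), 0.7, 1.5))
            self._seg(n_a, tilt, False, cap_extra=np.linspace(0.0, a_amp, n_a))
            self._idle(0.5 * du, cap_on=False, theta=tilt)
        else:
            self._idle(1.2 * du, cap_on=False, theta=tilt)
        self._ramp_theta(flip, tilt, 0.0, cap_on=False)
        self._idle(0.4 * du, cap_on=False)
        self.events.append((i0, self.n, "non_use"))
        self._pad_to(target_n)

    def _task_cap_off_no_dispense(self, task: TaskSpec) -> None:
        p, rng = self.profile, self.rng
        target_n = self.n + self._nsamp(task.duration_s)
        du = p.duration_mult
        excursion = rng.random() < p.tilt_excursion_prob

        self._idle(1.0 * du)
        i0 = self.n
        if excursion:
            # cap twisted off with the bottle raised near horizontal while
            # squeezing it for grip: brief tilt past 100 deg plus a small rise
            tilt = float(rng.uniform(103.0, 118.0))
            self._ramp_theta(0.35, 0.0, tilt, cap_on=False)
            n_r = self._nsamp(0.5)
            self._seg(n_r, tilt, False, cap_extra=np.linspace(0.0, 0.15, n_r))
            self._idle(0.3, cap_on=False, theta=tilt)
            self._ramp_theta(0.35, tilt, 0.0, cap_on=False)
            self._idle(1.5 * du, cap_on=False)
        else:
            self._idle(3.0 * du, cap_on=False)
        self.events.append((i0, self.n, "non_use"))
        self._pad_to(target_n)

    # -- assembly -----------------------------------------------------------

    def build(self) -> tuple[SensorLog, GroundTruth]:
        cfg, rng = self.cfg, self.rng
        theta = np.concatenate(self.theta)
        cap_on = np.concatenate(self.cap_on)
        cap_extra = np.concatenate(self.cap_extra)
        acc_extra = np.vstack(self.acc_extra)
        gyr_extra = np.vstack(self.gyr_extra)
        volume = np.concatenate(self.volume)
        n = self.n
        t = np.arange(n) * self.dt

        th = np.radians(theta)
        accel = acc_extra + rng.normal(0.0, cfg.accel_noise_sd, (n, 3))
        accel[:, 1] += GRAVITY_MS2 * np.sin(th)
        accel[:, 2] += GRAVITY_MS2 * np.cos(th)

        gyro = gyr_extra + rng.normal(0.0, cfg.gyro_noise_sd, (n, 3))
        gyro[:, 0] += np.gradient(theta, self.dt)

        mag = rng.normal(0.0, cfg.mag_noise_sd, (n, 3))
        mag[:, 0] += _MAG_FIELD[0]
        mag[:, 1] += _MAG_FIELD[1] * np.cos(th) + _MAG_FIELD[2] * np.sin(th)
        mag[:, 2] += -_MAG_FIELD[1] * np.sin(th) + _MAG_FIELD[2] * np.cos(th)

        # cap-off handling effects: the removed cap (holding the reed-switch
        # magnets) moves freely near the sleeve and swamps the magnetometer,
        # and hand tremor jitters the gyroscope while the bottle is held
        off = ~cap_on
        if off.any():
            kern = np.ones(max(1, int(round(0.5 * self.fs))))
            kern /= len(kern)
            for j in range(3):
                wander = np.convolve(rng.normal(0.0, 1.0, n), kern, mode="same")
                sd = wander.std() or 1.0
                mag[:, j] += cfg.cap_magnet_disturbance * (wander / sd) * off
            tremor = rng.normal(0.0, cfg.tremor_gyro_sd, (n, 3))
            gyro += tremor * off[:, None]

        stride = max(1, int(round(self.fs / CAP_RATE_HZ)))
        idx = np.arange(0, n, stride)
        inverted = (theta[idx] % 360.0 > 90.0) & (theta[idx] % 360.0 < 270.0)
        c = (self.bottle.slope_pF_per_mL * volume[idx] + self.bottle.c_empty_pF
             + cfg.inversion_offset_pF * inverted
             + cap_extra[idx]
             + rng.normal(0.0, cfg.cap_noise_sd_pF, len(idx)))
        q = cfg.cap_quant_pF
        c = np.round(c / q) * q
        capacitance = np.repeat(c, stride)[:n]

        log = SensorLog(t=t, accel=accel, gyro=gyro, mag=mag,
                        cap_on=cap_on, capacitance=capacitance,
                        sample_rate_hz=self.fs)
        events = [GroundTruthEvent(t_start=i0 * self.dt, t_end=i1 * self.dt,
                                   label=lab)
                  for i0, i1, lab in self.events]
        timeline = [(i * self.dt, v) for i, v in self.vol_points]
        if not timeline or timeline[-1][1] != self.v:
            timeline.append((t[-1], self.v))
        return log, GroundTruth(events=events, volume_timeline=timeline)


def simulate_scenario(
    script: ScenarioScript,
    bottle: BottleSpec = BottleSpec(),
    config: SignalConfig = SignalConfig(),
    profile: SubjectProfile | None = None,
) -> tuple[SensorLog, GroundTruth]:
    """Render a scenario script into a sensor log plus ground-truth labels.

    A fixed (script, seed) pair yields an identical log; subject-level
    variability is injected explicitly through ``profile``.
    """
    rng = np.random.default_rng(script.seed)
    builder = _ScenarioBuilder(script, bottle, config,
                               profile or SubjectProfile(), rng)
    for task in script.tasks:
        builder.add_task(task)
    return builder.build()


# -- CSV / YAML / JSON plumbing ---------------------------------------------

def write_log(log: SensorLog, path) -> None:
    log.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_log(path) -> SensorLog:
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed sensor log: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError("sensor log is empty")
    if df["cap_pF"].isna().any():
        raise ValueError("sensor log contains NaN capacitance readings")
    return SensorLog.from_frame(df)


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(gt.to_json())


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json(fh.read())


def load_scenario(path) -> ScenarioScript:
    """Read a scenario script from YAML ({sample_rate_hz, seed, tasks: [...]})."""
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    tasks = tuple(TaskSpec(**task) for task in obj["tasks"])
    return ScenarioScript(tasks=tasks,
                          sample_rate_hz=float(obj.get("sample_rate_hz", 50.0)),
                          seed=int(obj.get("seed", 0)))


def save_scenario(script: ScenarioScript, path) -> None:
    obj = {
        "sample_rate_hz": script.sample_rate_hz,
        "seed": script.seed,
        "tasks": [dataclasses.asdict(task) for task in script.tasks],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
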