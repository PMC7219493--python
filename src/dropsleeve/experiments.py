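"""End-to-end experiment runners: the multi-subject protocol and the day trial.

``run_protocol_experiment`` emulates the controlled evaluation: ten virtual
subjects each perform the six scripted tasks (one minute of walking, five
standing dispenses, five cap removals without dispensing, five shakes, five
simulated uses, five reclined dispenses), producing 100 use and 100 non-use
cap-off episodes.  Both detectors are then evaluated on the labelled episodes:
the rule-based detector directly, the machine-learned detector through
stratified k-fold cross-validation.

``run_day_experiment`` emulates a work day: hourly dispenses over seven hours
with one 30-minute transport block, a random-forest detector trained on a
protocol dataset, and fluid-level readings gated on the bottle being upright
and stationary every 30 minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .events import (ClassifierModel, EpisodeWindow, UseEvent, crossvalidate,
                     detect_events, features_table, rule_based_classify,
                     segment_episodes, train_classifier)
from .fluidlevel import CalibrationModel, estimate_volume, should_sample_level
from .metrics import ConfusionCounts, MetricsReport, compute_metrics, roc_curve
from .sim import (BottleSpec, GroundTruth, ScenarioScript, SensorLog,
                  SignalConfig, SubjectProfile, TaskSpec, simulate_scenario)

#: the six scripted tasks of the controlled protocol, in order
PROTOCOL_TASKS: tuple[TaskSpec, ...] = (
    TaskSpec("walk", duration_s=60.0),
    TaskSpec("dispense_standing", repeats=5, drops_dispensed=2),
    TaskSpec("cap_off_no_dispense", repeats=5),
    TaskSpec("shake", repeats=5),
    TaskSpec("simulated_use", repeats=5),
    TaskSpec("dispense_reclined", repeats=5, drops_dispensed=2),
)


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_subjects: int = 10
    sample_rate_hz: float = 50.0
    algorithm: str = "random_forest"
    detector: str = "ml"                 # day-run detector: "ml" | "rule"
    k_folds: int = 10
    subject_variability: bool = True
    day_hours: int = 7
    drops_per_use: int = 2
    outdir: str | None = None
    bottle: BottleSpec = field(default_factory=BottleSpec)
    signal: SignalConfig = field(default_factory=SignalConfig)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


@dataclass
class ProtocolResult:
    rule_report: MetricsReport
    ml_report: MetricsReport
    n_use: int
    n_non_use: int
    manifest: dict


@dataclass
class DayResult:
    events: list[UseEvent]
    level_readings: list[dict]
    n_level_marks: int
    ground_truth: GroundTruth
    manifest: dict

    @property
    def n_use_events(self) -> int:
        return sum(1 for e in self.events if e.label == "use")


def _label_windows(windows: list[EpisodeWindow], gt: GroundTruth) -> list[str]:
    """Assign each segmented window the ground-truth label of the event it
    overlaps (by window midpoint)."""
    labels = []
    for w in windows:
        mid = 0.5 * (w.t_start + w.t_end)
        lab = None
        for e in gt.events:
            if e.t_start - 0.5 <= mid <= e.t_end + 0.5:
                lab = e.label
                break
        if lab is None:
            raise RuntimeError(f"window at t={mid:.1f}s matches no ground-truth event")
        labels.append(lab)
    return labels


def simulate_protocol_dataset(config: ExperimentConfig
                              ) -> tuple[pd.DataFrame, np.ndarray,
                                         list[EpisodeWindow]]:
    """Simulate the full multi-subject protocol and featurize its episodes."""
    rng = np.random.default_rng(config.seed)
    all_windows: list[EpisodeWindow] = []
    all_labels: list[str] = []
    for _ in range(config.n_subjects):
        subj_seed = int(rng.integers(2 ** 31 - 1))
        profile = (SubjectProfile.sample(np.random.default_rng(subj_seed))
                   if config.subject_variability else SubjectProfile())
        script = ScenarioScript(tasks=PROTOCOL_TASKS,
                                sample_rate_hz=config.sample_rate_hz,
                                seed=subj_seed)
        log, gt = simulate_scenario(script, bottle=config.bottle,
                                    config=config.signal, profile=profile)
        windows = segment_episodes(log)
        all_labels.extend(_label_windows(windows, gt))
        all_windows.extend(windows)
    features = features_table(all_windows)
    return features, np.asarray(all_labels), all_windows


def evaluate_rule(windows: list[EpisodeWindow], labels: np.ndarray
                  ) -> MetricsReport:
    pred = np.array([rule_based_classify(w).label for w in windows])
    scores = (pred == "use").astype(float)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == "use") & (labels == "use"))),
        fp=int(np.sum((pred == "use") & (labels != "use"))),
        tn=int(np.sum((pred != "use") & (labels != "use"))),
        fn=int(np.sum((pred != "use") & (labels == "use"))),
    )
    try:
        _, _, area = roc_curve(scores, labels)
    except ValueError:
        area = None
    return compute_metrics(counts, roc_area=area)


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2))


def run_protocol_experiment(config: ExperimentConfig) -> ProtocolResult:
    """Simulate the protocol and evaluate both detectors on its 200 episodes."""
    features, labels, windows = simulate_protocol_dataset(config)
    rule_report = evaluate_rule(windows, labels)
    ml_report = crossvalidate(features, labels, algorithm=config.algorithm,
                              k=config.k_folds, seed=config.seed)
    result = ProtocolResult(
        rule_report=rule_report, ml_report=ml_report,
        n_use=int(np.sum(labels == "use")),
        n_non_use=int(np.sum(labels != "use")),
        manifest=config.manifest(),
    )
    if config.outdir:
        out = Path(config.outdir)
        _write_json(out / "manifest.json", result.manifest)
        _write_json(out / "rule_report.json", rule_report.to_dict())
        _write_json(out / "ml_report.json", ml_report.to_dict())
    return result


def build_day_script(config: ExperimentConfig, seed: int) -> ScenarioScript:
    """Hourly-dispense day timeline with one 30-minute transport block.

    Each hour block is exactly 3600 s (idle 1700 s, a 12 s dispense slot,
    idle remainder); the transport block replaces idle time in the fourth
    hour; a 60 s tail keeps the final half-hour sampling mark inside the log.
    """
    tasks: list[TaskSpec] = []
    for hour in range(config.day_hours):
        tasks.append(TaskSpec("idle_upright", duration_s=1700.0))
        tasks.append(TaskSpec("dispense_standing", duration_s=12.0,
                              drops_dispensed=config.drops_per_use))
        if hour == 3:
            tasks.append(TaskSpec("idle_transport", duration_s=1800.0))
            tasks.append(TaskSpec("idle_upright", duration_s=88.0))
        else:
            tasks.append(TaskSpec("idle_upright", duration_s=1888.0))
    tasks.append(TaskSpec("idle_upright", duration_s=60.0))
    return ScenarioScript(tasks=tuple(tasks),
                          sample_rate_hz=config.sample_rate_hz, seed=seed)


def gated_level_readings(log: SensorLog, model: CalibrationModel,
                         capacity_mL: float = 15.0,
                         interval_s: float = 1800.0) -> tuple[list[dict], int]:
    """Walk the log in 30-minute marks applying the upright/stationary gate.

    Returns the recorded readings and the number of marks inspected.
    """
    readings: list[dict] = []
    last_t = 0.0
    n_marks = 0
    fs = log.sample_rate_hz
    mark = interval_s
    while mark <= float(log.t[-1]) + 0.5 / fs:
        n_marks += 1
        i = min(len(log) - 1, int(round(mark * fs)))
        tail = log.slice(max(0, i - int(round(30 * fs))), i + 1)
        if should_sample_level(tail, last_t, min_interval_s=interval_s):
            cap = float(log.capacitance[i])
            est = estimate_volume(cap, model, capacity_mL=capacity_mL)
            readings.append({"t_s": float(log.t[i]), "cap_pF": cap,
                             "volume_est_mL": est.volume_mL,
                             "clamped": est.clamped})
            last_t = float(log.t[i])
        mark += interval_s
    return readings, n_marks


def train_protocol_detector(config: ExperimentConfig) -> ClassifierModel:
    """Random-forest detector trained on a full protocol dataset (the model a
    deployed sleeve would carry)."""
    train_cfg = dataclasses.replace(config, seed=config.seed + 101,
                                    outdir=None)
    features, labels, _ = simulate_protocol_dataset(train_cfg)
    return train_classifier(features, labels, algorithm=config.algorithm,
                            seed=config.seed)


def run_day_experiment(config: ExperimentConfig) -> DayResult:
    """Simulate a seven-hour day of hourly dispenses and detect its events."""
    script = build_day_script(config, seed=config.seed + 1)
    log, gt = simulate_scenario(script, bottle=config.bottle,
                                config=config.signal)
    detector: ClassifierModel | str
    detector = ("rule" if config.detector == "rule"
                else train_protocol_detector(config))
    events = detect_events(log, detector)
    calib = CalibrationModel(R=config.bottle.slope_pF_per_mL,
                             c_empty=config.bottle.c_empty_pF, r_squared=1.0)
    readings, n_marks = gated_level_readings(
        log, calib, capacity_mL=config.bottle.capacity_mL)
    result = DayResult(events=events, level_readings=readings,
                       n_level_marks=n_marks, ground_truth=gt,
                       manifest=config.manifest())
    if config.outdir:
        out = Path(config.outdir)
        _write_json(out / "manifest.json", result.manifest)
        _write_json(out / "adherence_log.json",
                    [e.to_dict() for e in events])
        _write_json(out / "level_readings.json", readings)
    return result
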