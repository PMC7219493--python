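"""Cap-off episode segmentation, featurization, and use-event detection.

The detection pipeline mirrors the on-device logic: the reed switch gates
everything (an episode is one maximal cap-off run), each episode is condensed
into descriptive statistics per channel, and a classifier labels it ``use``
(medication actually dispensed) or ``non_use``.

Two detectors are provided:

* a rule-based detector — the episode counts as use when the bottle tilts
  into the 100-260 degree window at some sample AND the capacitance channel
  shows at least four consecutive strictly positive first differences (the
  squeeze signature);
* supervised classifiers (random forest by default) trained on the feature
  vectors, with stratified k-fold cross-validation and per-sensor
  information-gain ranking for feature/sensor importance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import ConfusionCounts, MetricsReport, compute_metrics, roc_curve
from .sim import SensorLog

POSITIVE_LABEL = "use"
NEGATIVE_LABEL = "non_use"

#: rule-based orientation window (degrees from upright about the vertical axis)
RULE_ANGLE_WINDOW = (100.0, 260.0)
#: minimum consecutive strictly positive capacitance increments for the rule
RULE_MIN_RUN = 4

_CHANNEL_STATS = ("mean", "sd", "min", "max", "range", "sum_abs_diff",
                  "n_sign_changes")
ALGORITHMS = ("random_forest", "svm", "logistic", "naive_bayes",
              "decision_table")


@dataclass
class EpisodeWindow:
    """One maximal cap-off run of the log."""

    t_start: float
    t_end: float
    samples: SensorLog
    cap_off: bool = True

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class UseEvent:
    timestamp: float
    label: str             # "use" | "non_use"
    score: float           # P(use) in [0, 1]
    detector: str          # "rule" | "ml"

    def to_dict(self) -> dict:
        return {"timestamp": self.timestamp, "label": self.label,
                "score": self.score, "detector": self.detector}


@dataclass
class ClassifierModel:
    """Fitted episode classifier plus the metadata needed to reuse it."""

    estimator: object
    feature_names: list[str]
    algorithm: str
    version: str = "dropsleeve-0.1.0"

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        return features[self.feature_names].to_numpy(float)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._matrix(features))

    def predict_score(self, features: pd.DataFrame) -> np.ndarray:
        """P(use) per episode."""
        proba = self.estimator.predict_proba(self._matrix(features))
        pos = list(self.estimator.classes_).index(POSITIVE_LABEL)
        return proba[:, pos]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        return joblib.load(path)


def segment_episodes(log: SensorLog, min_duration_s: float = 0.5) -> list[EpisodeWindow]:
    """One window per maximal cap-off run; sub-``min_duration_s`` runs are
    discarded as reed-switch bounce."""
    off = ~np.asarray(log.cap_on, bool)
    if not off.any():
        return []
    edges = np.flatnonzero(np.diff(off.astype(np.int8)))
    starts = list(np.flatnonzero(off[:1]) if off[0] else [])
    starts += [int(i) + 1 for i in edges if not off[i]]
    ends = [int(i) + 1 for i in edges if off[i]]
    if off[-1]:
        ends.append(len(off))
    windows = []
    for i0, i1 in zip(sorted(starts), sorted(ends)):
        if (i1 - i0) / log.sample_rate_hz >= min_duration_s:
            windows.append(EpisodeWindow(t_start=float(log.t[i0]),
                                         t_end=float(log.t[i1 - 1]),
                                         samples=log.slice(i0, i1)))
    return windows


def orientation_angle(accel) -> np.ndarray | float:
    """Tilt about the bottle's horizontal x-axis, degrees in [0, 360).

    Convention: upright (gravity on +z) is 0 deg, fully inverted 180 deg, and
    the signed rotation is recovered from atan2(ay, az) so the window
    100-260 deg (wider than a half-turn) is meaningful.  Near free fall
    (|a| <= 1 m/s^2) the orientation is undefined and NaN is returned.
    """
    a = np.asarray(accel, float)
    scalar = a.ndim == 1
    a = np.atleast_2d(a)
    norm = np.linalg.norm(a, axis=1)
    ang = np.degrees(np.arctan2(a[:, 1], a[:, 2])) % 360.0
    ang = np.where(norm > 1.0, ang, np.nan)
    return float(ang[0]) if scalar else ang


def longest_positive_run(values: np.ndarray) -> int:
    """Length of the longest run of consecutive strictly positive first
    differences of ``values``."""
    d = np.diff(np.asarray(values, float))
    best = run = 0
    for x in d:
        run = run + 1 if x > 0 else 0
        best = max(best, run)
    return best


def rule_based_classify(window: EpisodeWindow,
                        angle_window: tuple[float, float] = RULE_ANGLE_WINDOW,
                        min_run: int = RULE_MIN_RUN) -> UseEvent:
    """Threshold rules on one cap-off episode.

    Use requires (the cap being off is guaranteed by the windowing) a sample
    with orientation inside ``angle_window`` and a run of at least ``min_run``
    strictly positive increments in the native-rate capacitance channel.
    """
    ang = orientation_angle(window.samples.accel)
    tilted = bool(np.any((ang >= angle_window[0]) & (ang <= angle_window[1])))
    cap = window.samples.cap_channel()
    squeeze = longest_positive_run(cap) >= min_run
    is_use = tilted and squeeze
    return UseEvent(timestamp=window.t_start,
                    label=POSITIVE_LABEL if is_use else NEGATIVE_LABEL,
                    score=1.0 if is_use else 0.0, detector="rule")


def _sign_changes(x: np.ndarray) -> int:
    s = np.sign(x - x.mean())
    s = s[s != 0]
    return int(np.count_nonzero(np.diff(s))) if s.size else 0


def _channel_features(name: str, x: np.ndarray, out: dict) -> None:
    out[f"{name}_mean"] = float(x.mean())
    out[f"{name}_sd"] = float(x.std())
    out[f"{name}_min"] = float(x.min())
    out[f"{name}_max"] = float(x.max())
    out[f"{name}_range"] = float(x.max() - x.min())
    out[f"{name}_sum_abs_diff"] = float(np.abs(np.diff(x)).sum()) if x.size > 1 else 0.0
    out[f"{name}_n_sign_changes"] = _sign_changes(x)


def extract_features(window: EpisodeWindow) -> pd.Series:
    """Descriptive-statistics featurization of one episode.

    Seven statistics per channel (means, spreads, extrema, total absolute
    variation, sign changes) across the nine IMU axes and the native-rate
    capacitance channel, plus episode duration and the mean/max tilt angle.
    The total-absolute-variation feature is what captures the small squeeze
    fluctuations a min/max range misses.
    """
    s = window.samples
    out: dict[str, float] = {}
    for j, name in enumerate(("ax", "ay", "az")):
        _channel_features(name, s.accel[:, j], out)
    for j, name in enumerate(("gx", "gy", "gz")):
        _channel_features(name, s.gyro[:, j], out)
    for j, name in enumerate(("mx", "my", "mz")):
        _channel_features(name, s.mag[:, j], out)
    _channel_features("cap", s.cap_channel(), out)
    out["duration_s"] = window.duration_s
    ang = orientation_angle(s.accel)
    ang = ang[np.isfinite(ang)]
    out["orient_mean"] = float(ang.mean()) if ang.size else 0.0
    out["orient_max"] = float(ang.max()) if ang.size else 0.0
    return pd.Series(out)


def features_table(windows: Sequence[EpisodeWindow]) -> pd.DataFrame:
    return pd.DataFrame([extract_features(w) for w in windows])


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if algorithm == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="linear", probability=True,
                                 random_state=seed))
    if algorithm == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000))
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "decision_table":
        # nearest standard analogue of a rule-list learner
        return DecisionTreeClassifier(random_state=seed, min_samples_leaf=2)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train_classifier(features: pd.DataFrame, labels: Sequence[str],
                     algorithm: str = "random_forest",
                     seed: int = 0) -> ClassifierModel:
    """Fit an episode classifier on labelled feature vectors."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    est = _make_estimator(algorithm, seed)
    est.fit(features.to_numpy(float), y)
    return ClassifierModel(estimator=est,
                           feature_names=list(features.columns),
                           algorithm=algorithm)


def crossvalidate(features: pd.DataFrame, labels: Sequence[str],
                  algorithm: str = "random_forest", k: int = 10,
                  seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Out-of-fold predictions are pooled into a single confusion matrix (and a
    pooled score vector for the ROC area).  When ``k`` exceeds the minority
    class count — e.g. leave-one-out — plain shuffled k-fold is used instead,
    since stratification is impossible there.
    """
    y = np.asarray(labels)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k cannot exceed the number of episodes")
    if np.unique(y).size < 2:
        raise ValueError("cross-validation requires both classes")
    X = features
    min_class = int(pd.Series(y).value_counts().min())
    if k <= min_class:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(n, dtype=object)
    score = np.full(n, np.nan)
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        if np.unique(y[tr]).size < 2:   # tiny-k edge: degenerate training fold
            pred[te] = pd.Series(y[tr]).mode()[0]
            score[te] = float(y[tr][0] == POSITIVE_LABEL)
            continue
        model = train_classifier(X.iloc[tr], y[tr], algorithm=algorithm,
                                 seed=seed + fold)
        pred[te] = model.predict(X.iloc[te])
        score[te] = model.predict_score(X.iloc[te])
    counts = ConfusionCounts(
        tp=int(np.sum((pred == POSITIVE_LABEL) & (y == POSITIVE_LABEL))),
        fp=int(np.sum((pred == POSITIVE_LABEL) & (y != POSITIVE_LABEL))),
        tn=int(np.sum((pred != POSITIVE_LABEL) & (y != POSITIVE_LABEL))),
        fn=int(np.sum((pred != POSITIVE_LABEL) & (y == POSITIVE_LABEL))),
    )
    try:
        _, _, area = roc_curve(score, y)
    except ValueError:
        area = None
    return compute_metrics(counts, roc_area=area)


# -- information gain ---------------------------------------------------------

#: feature-name prefix -> physical sensor (orientation derives from the
#: accelerometer; episode duration is clock-derived and not a sensor)
_SENSOR_OF_PREFIX = {
    "ax": "accelerometer", "ay": "accelerometer", "az": "accelerometer",
    "orient": "accelerometer",
    "gx": "gyroscope", "gy": "gyroscope", "gz": "gyroscope",
    "mx": "magnetometer", "my": "magnetometer", "mz": "magnetometer",
    "cap": "capacitance",
}


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _binned(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency discretization into at most ``bins`` bins."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def information_gain(features: pd.DataFrame, labels: Sequence[str],
                     bins: int = 10) -> tuple[pd.Series, pd.Series]:
    """Class-entropy reduction per feature and averaged per sensor.

    IG(f) = H(class) - H(class | f binned into ``bins`` equal-frequency bins).
    The per-sensor score is the mean IG over that sensor's features; sensors
    are returned ranked best first.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("information gain needs at least two classes")
    h_class = _entropy(y)
    ig = {}
    for name in features.columns:
        codes = _binned(features[name].to_numpy(float), bins)
        h_cond = 0.0
        for b in np.unique(codes):
            mask = codes == b
            h_cond += mask.mean() * _entropy(y[mask])
        ig[name] = h_class - h_cond
    per_feature = pd.Series(ig).sort_values(ascending=False)
    sensor_values: dict[str, list[float]] = {}
    for name, value in ig.items():
        prefix = name.split("_")[0]
        sensor = _SENSOR_OF_PREFIX.get(prefix)
        if sensor is not None:
            sensor_values.setdefault(sensor, []).append(value)
    per_sensor = pd.Series({s: float(np.mean(v))
                            for s, v in sensor_values.items()})
    return per_feature, per_sensor.sort_values(ascending=False)


def detect_events(log: SensorLog,
                  model: ClassifierModel | str = "rule",
                  min_duration_s: float = 0.5) -> list[UseEvent]:
    """Segment a log and classify every cap-off episode.

    ``model`` is either the string ``"rule"`` or a fitted ClassifierModel.
    Returns one timestamped event per episode (a JSON-serializable adherence
    log once ``to_dict`` is applied).
    """
    windows = segment_episodes(log, min_duration_s=min_duration_s)
    if not windows:
        return []
    if isinstance(model, str):
        if model != "rule":
            raise ValueError("model must be 'rule' or a ClassifierModel")
        return [rule_based_classify(w) for w in windows]
    feats = features_table(windows)
    labels = model.predict(feats)
    scores = model.predict_score(feats)
    return [UseEvent(timestamp=w.t_start, label=str(lab), score=float(sc),
                     detector="ml")
            for w, lab, sc in zip(windows, labels, scores)]


def write_event_log(events: Sequence[UseEvent], path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=2)
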