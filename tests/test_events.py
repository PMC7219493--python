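import numpy as np
import pandas as pd
import pytest

from conftest import make_window_log
from dropsleeve.events import (EpisodeWindow, crossvalidate, detect_events,
                               extract_features, features_table,
                               information_gain, orientation_angle,
                               rule_based_classify, segment_episodes,
                               train_classifier)
from dropsleeve.metrics import ConfusionCounts, compute_metrics
from dropsleeve.sim import ScenarioScript, TaskSpec, simulate_scenario


def window_from(cap, theta=0.0):
    log = make_window_log(cap, theta_deg=theta)
    return EpisodeWindow(t_start=float(log.t[0]), t_end=float(log.t[-1]),
                         samples=log)


class TestSegmentation:
    def test_cap_always_on_yields_nothing(self):
        log = make_window_log(np.full(50, 5.15), cap_on=True)
        assert segment_episodes(log) == []

    def test_three_dispenses_three_windows(self):
        script = ScenarioScript(tasks=(TaskSpec("dispense_standing", repeats=3),),
                                seed=4)
        log, gt = simulate_scenario(script)
        wins = segment_episodes(log)
        assert len(wins) == 3 == len(gt.events)
        # windows align with ground-truth spans
        for w, e in zip(wins, gt.events):
            assert w.t_start == pytest.approx(e.t_start, abs=0.1)

    def test_switch_bounce_discarded(self):
        log = make_window_log(np.full(100, 5.15), cap_on=True,
                              sample_rate_hz=50.0)
        log.cap_on[40:42] = False  # 2-sample glitch at 50 Hz
        assert segment_episodes(log) == []


class TestOrientation:
    @pytest.mark.parametrize("accel,expected", [
        ((0.0, 0.0, 9.8), 0.0),
        ((0.0, 0.0, -9.8), 180.0),
        ((0.0, 9.8, 0.0), 90.0),
        ((0.0, -9.8, 0.0), 270.0),
    ])
    def test_reference_orientations(self, accel, expected):
        assert orientation_angle(np.array(accel)) == pytest.approx(expected)

    def test_free_fall_is_undefined(self):
        assert np.isnan(orientation_angle(np.array([0.0, 0.1, 0.2])))


class TestRuleDetector:
    def test_inverted_with_rise_is_use(self):
        cap = np.array([10.0, 10.0, 10.1, 10.2, 10.3, 10.4, 10.5, 10.5])
        ev = rule_based_classify(window_from(cap, theta=180.0))
        assert ev.label == "use" and ev.score == 1.0

    def test_boundary_angle_excluded(self):
        cap = np.array([10.0, 10.1, 10.2, 10.3, 10.4, 10.5])
        ev = rule_based_classify(window_from(cap, theta=90.0))
        assert ev.label == "non_use"

    def test_three_sample_rise_insufficient(self):
        cap = np.array([10.0, 10.1, 10.2, 10.3, 10.3, 10.2])  # 3 increments
        ev = rule_based_classify(window_from(cap, theta=180.0))
        assert ev.label == "non_use"

    def test_pure_function(self):
        cap = np.array([10.0, 10.1, 10.2, 10.3, 10.4, 10.5])
        w = window_from(cap, theta=180.0)
        assert rule_based_classify(w) == rule_based_classify(w)


class TestFeatures:
    def test_constant_channel_statistics(self):
        f = extract_features(window_from(np.full(20, 5.15)))
        assert f["cap_sum_abs_diff"] == 0.0
        assert f["cap_sd"] == pytest.approx(0.0, abs=1e-12)
        assert f["cap_range"] == 0.0

    def test_hand_computed_cap_statistics(self):
        f = extract_features(window_from(np.array([5.0, 5.2, 5.1])))
        assert f["cap_sum_abs_diff"] == pytest.approx(0.3)
        assert f["cap_range"] == pytest.approx(0.2)

    def test_accel_flip_range(self):
        w = window_from(np.full(10, 5.15),
                        theta=np.array([0.0] * 5 + [180.0] * 5))
        f = extract_features(w)
        assert f["az_range"] == pytest.approx(2 * 9.80665, abs=1e-6)

    def test_sum_abs_diff_dominates_range(self, protocol_dataset):
        features, _, _ = protocol_dataset
        for ch in ("cap", "az", "gx"):
            assert (features[f"{ch}_sum_abs_diff"]
                    >= features[f"{ch}_range"] - 1e-9).all()

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(5, 1, 20)
            f = extract_features(window_from(x))
            assert f["cap_sum_abs_diff"] == pytest.approx(
                sum(abs(x[i + 1] - x[i]) for i in range(19)))
            assert f["cap_range"] == pytest.approx(max(x) - min(x))
            assert f["cap_mean"] == pytest.approx(np.mean(x))
            assert f["cap_sd"] == pytest.approx(np.std(x))


def _toy_separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "f1": np.r_[rng.normal(0, 0.3, n // 2), rng.normal(3, 0.3, n // 2)],
        "f2": rng.normal(0, 1, n),
    })
    y = np.array(["non_use"] * (n // 2) + ["use"] * (n // 2))
    return X, y


class TestClassifiers:
    @pytest.mark.parametrize("algorithm", ["random_forest", "svm", "logistic",
                                           "naive_bayes", "decision_table"])
    def test_separable_training_set_is_learned(self, algorithm):
        X, y = _toy_separable()
        model = train_classifier(X, y, algorithm=algorithm, seed=0)
        assert (model.predict(X) == y).all()
        assert model.predict_score(X)[y == "use"].mean() > 0.5

    def test_single_class_rejected(self):
        X, _ = _toy_separable()
        with pytest.raises(ValueError):
            train_classifier(X, ["use"] * len(X))

    def test_shuffled_labels_have_no_skill(self):
        X, y = _toy_separable(n=60)
        rng = np.random.default_rng(5)
        y = rng.permutation(y)
        report = crossvalidate(X, y, k=5, seed=5)
        assert abs(report.mcc) < 0.4

    def test_crossvalidate_consistent_with_metrics_module(self, protocol_dataset):
        features, labels, _ = protocol_dataset
        report = crossvalidate(features, labels, k=10, seed=0)
        # recompute from the implied pooled counts
        n_pos = int(np.sum(labels == "use"))
        n_neg = len(labels) - n_pos
        tp = round(report.tpr * n_pos)
        fp = round(report.fpr * n_neg)
        again = compute_metrics(ConfusionCounts(tp=tp, fp=fp,
                                                tn=n_neg - fp, fn=n_pos - tp))
        assert report.precision == pytest.approx(again.precision)
        assert report.f1 == pytest.approx(again.f1)
        assert report.mcc == pytest.approx(again.mcc)

    def test_leave_one_out_runs(self):
        X, y = _toy_separable(n=14)
        report = crossvalidate(X, y, k=14, seed=0)
        assert report.tpr == 1.0

    def test_bad_k_rejected(self):
        X, y = _toy_separable()
        with pytest.raises(ValueError):
            crossvalidate(X, y, k=1)
        with pytest.raises(ValueError):
            crossvalidate(X, y, k=len(X) + 1)


class TestInformationGain:
    def test_feature_identical_to_label_gains_class_entropy(self):
        y = np.array(["use"] * 30 + ["non_use"] * 10)
        X = pd.DataFrame({"cap_perfect": (y == "use").astype(float)})
        per_feature, _ = information_gain(X, y)
        h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert per_feature["cap_perfect"] == pytest.approx(h)

    def test_independent_feature_gains_nothing(self):
        rng = np.random.default_rng(2)
        y = np.array(["use", "non_use"] * 100)
        X = pd.DataFrame({"cap_noise": rng.uniform(0, 1, 200)})
        per_feature, _ = information_gain(X, y)
        assert per_feature["cap_noise"] < 0.05

    def test_constant_labels_rejected(self):
        X = pd.DataFrame({"cap_x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            information_gain(X, ["use", "use", "use"])


class TestDetectEvents:
    def test_no_cap_removal_no_events(self):
        script = ScenarioScript(tasks=(TaskSpec("shake", repeats=3),), seed=2)
        log, _ = simulate_scenario(script)
        assert detect_events(log, "rule") == []

    def test_rule_detector_on_simulated_day_fragment(self):
        tasks = (TaskSpec("idle_upright", duration_s=5.0),
                 TaskSpec("dispense_standing", repeats=2),
                 TaskSpec("simulated_use", repeats=1))
        log, _ = simulate_scenario(ScenarioScript(tasks=tasks, seed=3))
        events = detect_events(log, "rule")
        assert [e.label for e in events] == ["use", "use", "non_use"]
        assert all(e.detector == "rule" for e in events)

    def test_ml_detector_events_are_serializable(self, protocol_dataset):
        features, labels, _ = protocol_dataset
        model = train_classifier(features, labels, seed=0)
        tasks = (TaskSpec("dispense_standing", repeats=1),)
        log, _ = simulate_scenario(ScenarioScript(tasks=tasks, seed=21))
        events = detect_events(log, model)
        assert len(events) == 1
        d = events[0].to_dict()
        assert d["label"] == "use" and 0.0 <= d["score"] <= 1.0
        assert d["detector"] == "ml"
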