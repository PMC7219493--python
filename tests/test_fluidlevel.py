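import itertools

import numpy as np
import pytest
from scipy import stats

from dropsleeve.fluidlevel import (CalibrationModel, estimate_volume,
                                   fit_calibration, mann_whitney_exact,
                                   resolution_analysis, should_sample_level)
from dropsleeve.sim import (BottleSpec, ScenarioScript, TaskSpec,
                            bench_capacitance_readings, simulate_scenario)


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate every assignment of mid-rank positions."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    n = len(x)
    obs = ranks[:n].sum()
    sums = np.array([sum(c) for c in itertools.combinations(ranks, n)])
    p_le = np.mean(sums <= obs + 1e-9)
    p_ge = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestCalibration:
    def test_noiseless_line_recovered_exactly(self):
        v = np.arange(0.0, 16.0)
        c = 0.56 * v + 5.15
        m = fit_calibration(v, c)
        assert m.R == pytest.approx(0.56)
        assert m.c_empty == pytest.approx(5.15)
        assert m.r_squared == pytest.approx(1.0)

    def test_two_point_slope_matches_hand_ols(self):
        m = fit_calibration([0.0, 10.0], [5.15, 10.75])
        assert m.R == pytest.approx(0.56)

    def test_duplicated_points_match_two_point_slope(self):
        m = fit_calibration([0, 0, 0, 10, 10, 10],
                            [5.15, 5.15, 5.15, 10.75, 10.75, 10.75])
        assert m.R == pytest.approx(0.56)

    def test_identical_volumes_singular(self):
        with pytest.raises(ValueError, match="singular"):
            fit_calibration([5.0, 5.0, 5.0], [8.0, 8.1, 7.9])

    def test_bench_fit_near_true_relationship(self):
        df = bench_capacitance_readings(np.arange(16.0), replicates=5, seed=3)
        m = fit_calibration(df.volume_mL, df.cap_pF)
        assert m.R == pytest.approx(0.56, abs=0.02)
        assert m.c_empty == pytest.approx(5.15, abs=0.1)
        assert m.r_squared > 0.99


class TestVolumeEstimation:
    model = CalibrationModel(R=0.56, c_empty=5.15, r_squared=1.0)

    def test_intercept_maps_to_empty(self):
        est = estimate_volume(5.15, self.model)
        assert est.volume_mL == pytest.approx(0.0)
        assert not est.clamped

    def test_full_bottle(self):
        est = estimate_volume(13.55, self.model)
        assert est.volume_mL == pytest.approx(15.0)

    def test_below_empty_clamps(self):
        est = estimate_volume(4.0, self.model)
        assert est.volume_mL == 0.0
        assert est.clamped

    def test_round_trip_through_forward_model(self):
        from dropsleeve.sim import capacitance_forward
        for v in np.linspace(0, 15, 7):
            c = capacitance_forward(v)
            assert estimate_volume(c, self.model).volume_mL == pytest.approx(v)


class TestExactMannWhitney:
    def test_complete_separation_five_vs_five(self):
        p = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_identical_multisets_give_one(self):
        assert mann_whitney_exact([1, 2, 3], [1, 2, 3]) == 1.0

    def test_shifted_three_vs_three(self):
        assert mann_whitney_exact([1, 2, 3], [101, 102, 103]) == pytest.approx(2 / 20)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1, 2])

    def test_oversize_groups_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact(list(range(13)), [1, 2, 3])

    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_brute_force_enumeration(self, tied):
        rng = np.random.default_rng(17 if tied else 18)
        for _ in range(40):
            n, m = rng.integers(2, 7, size=2)
            if tied:
                x = rng.integers(0, 4, n).astype(float)
                y = rng.integers(1, 5, m).astype(float)
            else:
                x = rng.normal(0, 1, n)
                y = rng.normal(0.8, 1, m)
            assert mann_whitney_exact(x, y) == pytest.approx(
                brute_force_mw_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 5)
            expected = stats.mannwhitneyu(x, y, method="exact",
                                          alternative="two-sided").pvalue
            assert mann_whitney_exact(x, y) == pytest.approx(expected)


class TestResolutionAnalysis:
    def test_same_level_not_significant(self):
        res = resolution_analysis([7.0, 7.0 + 1e-12, 8.0], replicates=5, seed=4)
        p = res.pairwise_p[(7.0, 7.0 + 1e-12)]
        assert p > 0.05

    def test_vanishing_noise_resolves_smallest_increment(self):
        levels = np.round(np.arange(8.0, 6.99, -0.2), 1)
        res = resolution_analysis(levels, replicates=5, noise_sd_pF=1e-6, seed=1)
        assert res.resolution_mL == pytest.approx(0.2)

    def test_monotone_power_in_separation(self):
        """Fraction of significant pairs never decreases with separation."""
        levels = np.round(np.arange(8.0, 5.99, -0.2), 1)
        fracs = {}
        for seed in range(5):
            res = resolution_analysis(levels, replicates=5, seed=seed)
            for (a, b), p in res.pairwise_p.items():
                s = round(abs(a - b), 9)
                fracs.setdefault(s, []).append(p < 0.05)
        seps = sorted(fracs)
        rates = [np.mean(fracs[s]) for s in seps]
        assert all(r2 >= r1 - 1e-12 for r1, r2 in zip(rates, rates[1:]))

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            resolution_analysis([7.0, 8.0], noise_sd_pF=0.0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            resolution_analysis([7.0, 8.0], replicates=2)


class TestSamplingGate:
    def _log(self, kind, duration):
        script = ScenarioScript(tasks=(TaskSpec(kind, duration_s=duration),),
                                seed=6)
        return simulate_scenario(script)[0]

    def test_upright_after_interval_samples(self):
        log = self._log("idle_upright", 40.0)
        # pretend the log tail sits 31 minutes after the previous reading
        log.t += 31 * 60.0
        assert should_sample_level(log, last_sample_t=0.0)

    def test_too_soon_does_not_sample(self):
        log = self._log("idle_upright", 40.0)
        log.t += 10 * 60.0
        assert not should_sample_level(log, last_sample_t=0.0)

    def test_moving_bottle_does_not_sample(self):
        log = self._log("idle_transport", 40.0)
        log.t += 31 * 60.0
        assert not should_sample_level(log, last_sample_t=0.0)

    def test_inverted_bottle_does_not_sample(self):
        log = self._log("idle_upright", 40.0)
        log.accel[:, 2] *= -1.0
        log.t += 31 * 60.0
        assert not should_sample_level(log, last_sample_t=0.0)
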