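"""Capacitive fluid-level calibration, inversion, gating and resolution analysis.

The sensor obeys a linear law C = R*V + C_empty, so calibration is an
ordinary least-squares fit of capacitance on volume and level estimation is
the inverse map (C - C_empty)/R, clamped to the physical range of the bottle.

Sensor resolution is established the way the bench protocol does it: replicate
steady-state readings are simulated at a ladder of fill levels and every pair
of levels is compared with a two-sided *exact* Mann-Whitney U test (appropriate
for five replicates per level; no multiple-comparison correction, each pair is
assessed separately).  The resolution is the smallest level separation at
which every pairwise comparison is significant at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .sim import (GRAVITY_MS2, BottleSpec, SensorLog, SignalConfig,
                  bench_capacitance_readings)

#: largest per-group size for which the exact rank test is enumerated
EXACT_LIMIT = 12


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear capacitance-volume relationship."""

    R: float            # slope, pF/mL
    c_empty: float      # intercept, pF
    r_squared: float

    def __post_init__(self) -> None:
        if self.R <= 0 or self.c_empty <= 0:
            raise ValueError("calibration slope and intercept must be positive")

    def capacitance(self, volume_mL: float) -> float:
        return self.R * volume_mL + self.c_empty

    def to_json(self) -> str:
        return json.dumps({"R": self.R, "Cempty": self.c_empty,
                           "r_squared": self.r_squared}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        obj = json.loads(text)
        return cls(R=obj["R"], c_empty=obj["Cempty"],
                   r_squared=obj["r_squared"])


class VolumeEstimate(NamedTuple):
    volume_mL: float
    clamped: bool


@dataclass(frozen=True)
class LevelReading:
    t: float
    capacitance: float
    volume_est: float


@dataclass
class ResolutionResult:
    increments_mL: list[float]
    pairwise_p: dict[tuple[float, float], float]
    resolution_mL: float | None  # None when no separation separates reliably
    alpha: float = 0.05

    def all_significant(self, separation_mL: float, tol: float = 1e-9) -> bool:
        ps = [p for (a, b), p in self.pairwise_p.items()
              if abs(abs(a - b) - separation_mL) < tol]
        return bool(ps) and all(p < self.alpha for p in ps)


def fit_calibration(volumes_mL: Sequence[float],
                    capacitances_pF: Sequence[float]) -> CalibrationModel:
    """Ordinary least-squares fit of capacitance on volume.

    Requires at least two distinct volumes; a single repeated volume makes the
    design singular.
    """
    v = np.asarray(volumes_mL, float)
    c = np.asarray(capacitances_pF, float)
    if v.shape != c.shape or v.size < 2:
        raise ValueError("need matching volume/capacitance arrays of length >= 2")
    if np.unique(v).size < 2:
        raise ValueError("singular fit: all volumes are identical")
    fit = stats.linregress(v, c)
    return CalibrationModel(R=float(fit.slope), c_empty=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2))


def estimate_volume(capacitance_pF: float, model: CalibrationModel,
                    capacity_mL: float = 15.0) -> VolumeEstimate:
    """Invert the calibration; readings outside the bottle's range clamp."""
    raw = (capacitance_pF - model.c_empty) / model.R
    clamped = raw < 0.0 or raw > capacity_mL
    return VolumeEstimate(float(np.clip(raw, 0.0, capacity_mL)), clamped)


def _rank_sum_distribution(ranks2: np.ndarray, n: int) -> np.ndarray:
    """Counts of n-subsets of ``ranks2`` (integer 2x mid-ranks) by subset sum.

    Classic fixed-size subset-sum dynamic programme; the returned array is the
    exact permutation distribution of the doubled rank sum under the null that
    group membership is exchangeable.  Counts stay below 2**53 for the sizes
    admitted here, so float64 arithmetic is exact.
    """
    total = int(ranks2.sum())
    dp = np.zeros((n + 1, total + 1))
    dp[0, 0] = 1.0
    for v in ranks2:
        v = int(v)
        for k in range(n, 0, -1):
            if v == 0:
                dp[k] += dp[k - 1]
            else:
                dp[k, v:] += dp[k - 1, :-v]
    return dp[n]


def mann_whitney_exact(x: Sequence[float], y: Sequence[float],
                       alternative: str = "two-sided") -> float:
    """Two-sided exact Mann-Whitney p-value by full enumeration.

    Ties are handled with mid-ranks and the permutation distribution is
    enumerated over all C(n+m, n) assignments of rank positions, so the test
    stays exact in the presence of ties.  Restricted to the small-sample
    regime (n, m <= 12) the test is meant for.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    n, m = x.size, y.size
    if n > EXACT_LIMIT or m > EXACT_LIMIT:
        raise ValueError(f"exact enumeration supports group sizes <= {EXACT_LIMIT}")
    ranks = stats.rankdata(np.concatenate([x, y]))
    ranks2 = np.rint(2.0 * ranks).astype(int)   # mid-ranks doubled -> integers
    obs = int(np.rint(2.0 * ranks[:n].sum()))
    dist = _rank_sum_distribution(ranks2, n)
    total = dist.sum()
    p_le = dist[: obs + 1].sum() / total
    p_ge = dist[obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def resolution_analysis(levels_mL: Sequence[float], replicates: int = 5,
                        noise_sd_pF: float | None = None, seed: int = 0,
                        bottle: BottleSpec = BottleSpec(),
                        config: SignalConfig = SignalConfig(),
                        alpha: float = 0.05) -> ResolutionResult:
    """Bench resolution study on simulated replicate readings.

    Simulates ``replicates`` steady-state upright readings per fill level via
    the forward model, runs the exact two-sided Mann-Whitney test on every
    pair of levels (no multiple-comparison correction) and reports the
    smallest separation from which every comparison at that or any larger
    separation is significant.
    """
    if replicates < 3:
        raise ValueError("need at least 3 replicates per level")
    levels = [float(v) for v in levels_mL]
    if len(set(levels)) < 2:
        raise ValueError("need at least two distinct levels")
    if noise_sd_pF is None:
        noise_sd_pF = config.bench_noise_sd_pF
    if noise_sd_pF <= 0:
        raise ValueError("noise SD must be positive")

    readings = bench_capacitance_readings(levels, replicates,
                                          noise_sd_pF=noise_sd_pF, seed=seed,
                                          bottle=bottle, config=config)
    groups = {v: readings.loc[readings.volume_mL == v, "cap_pF"].to_numpy()
              for v in levels}
    pairwise: dict[tuple[float, float], float] = {}
    for a, b in itertools.combinations(sorted(set(levels)), 2):
        pairwise[(a, b)] = mann_whitney_exact(groups[a], groups[b])

    seps = sorted({round(abs(a - b), 9) for a, b in pairwise})
    sig_by_sep = {}
    for s in seps:
        ps = [p for (a, b), p in pairwise.items() if round(abs(a - b), 9) == s]
        sig_by_sep[s] = all(p < alpha for p in ps)
    resolution = None
    for s in reversed(seps):              # largest separation first
        if sig_by_sep[s]:
            resolution = s
        else:
            break
    return ResolutionResult(increments_mL=seps, pairwise_p=pairwise,
                            resolution_mL=resolution, alpha=alpha)


def should_sample_level(log_tail: SensorLog, last_sample_t: float,
                        min_interval_s: float = 1800.0,
                        window_s: float = 5.0,
                        az_tol: float = 0.5,
                        stationary_sd: float = 0.3) -> bool:
    """Gate for the 30-minute fluid-level measurement.

    True when at least ``min_interval_s`` elapsed since the previous reading
    and, over the trailing ``window_s`` window, the bottle is upright (mean
    z-axis acceleration within ``az_tol`` of +g) and stationary (per-axis
    acceleration SD below ``stationary_sd``).
    """
    if len(log_tail) == 0:
        return False
    now = float(log_tail.t[-1])
    if now - last_sample_t < min_interval_s:
        return False
    nwin = max(1, int(round(window_s * log_tail.sample_rate_hz)))
    acc = log_tail.accel[-nwin:]
    upright = abs(float(acc[:, 2].mean()) - GRAVITY_MS2) <= az_tol
    stationary = float(acc.std(axis=0).max()) < stationary_sd
    return upright and stationary
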