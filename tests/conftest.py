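import numpy as np
import pytest

from dropsleeve.experiments import ExperimentConfig, simulate_protocol_dataset
from dropsleeve.sim import CAP_RATE_HZ, GRAVITY_MS2, SensorLog


@pytest.fixture(scope="session")
def protocol_dataset():
    """One simulated 10-subject protocol (features, labels, windows), shared
    across tests to keep the suite fast."""
    return simulate_protocol_dataset(ExperimentConfig(seed=0))


def make_window_log(capacitance, theta_deg=0.0, sample_rate_hz=CAP_RATE_HZ,
                    cap_on=False):
    """Hand-built cap-off log segment: tilt angle fixed or per-sample,
    capacitance given at the native converter rate."""
    cap = np.asarray(capacitance, float)
    n = cap.size
    theta = np.broadcast_to(np.radians(np.asarray(theta_deg, float)), (n,))
    accel = np.zeros((n, 3))
    accel[:, 1] = GRAVITY_MS2 * np.sin(theta)
    accel[:, 2] = GRAVITY_MS2 * np.cos(theta)
    return SensorLog(
        t=np.arange(n) / sample_rate_hz,
        accel=accel,
        gyro=np.zeros((n, 3)),
        mag=np.zeros((n, 3)),
        cap_on=np.full(n, cap_on),
        capacitance=cap,
        sample_rate_hz=sample_rate_hz,
    )
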