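import numpy as np
import pytest

from organoidgrowth.fitting import CellNumberSeries, FitResult
from organoidgrowth.models import GrowthModelSpec, carrying_capacity


GOMPERTZ = GrowthModelSpec("gompertz")


def make_gompertz_fit(track_id, a, b, tau=0.0, phi2=1e-6, k=3):
    """FitResult constructed directly from parameters (bypasses the
    optimizer); used to test summary statistics in isolation."""
    from organoidgrowth.models import B_FLOOR

    theta = np.array([a, max(b, B_FLOOR)])
    return FitResult(
        track_id=track_id, spec=GOMPERTZ, theta_hat=theta, tau_hat=tau,
        phi2=phi2, sigma2_hat=phi2 / k, n_starts=1, converged_fraction=1.0,
        K_hat=carrying_capacity(GOMPERTZ, theta),
        is_exponential=(b <= B_FLOOR),
    )


@pytest.fixture(scope="session")
def exp_series():
    """Noise-free exponential series: one doubling per day, tau = 1."""
    return CellNumberSeries("exp1", [0.0, 3.0, 5.0], [2.0, 16.0, 64.0])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
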