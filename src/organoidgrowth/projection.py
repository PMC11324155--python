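"""Monte-Carlo projection of cohort growth beyond the experiment.

Fitted Gompertz parameter sets (a, b, tau) are resampled jointly with
replacement from the cohort's empirical distribution — preserving the
strong observed a-b dependence — and each sampled organoid's trajectory
N(tau + day) (from a single cell at model time 0 = Day -tau) is evaluated
on an experiment-day grid, by default Days 0..20.  The cohort projection
is the pointwise median with 5th/95th-percentile bands.

A rough clinical time scaling divides in-vitro days by the ratio of a
clinical tumor doubling time to the model-estimated in-vitro doubling
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import FitResult

__all__ = [
    "ProjectionResult",
    "sample_parameter_sets",
    "project_cohort",
    "invitro_to_patient_time",
]


@dataclass(frozen=True)
class ProjectionResult:
    """Pointwise median and percentile curves of sampled trajectories."""

    days: np.ndarray
    median: np.ndarray
    lower: np.ndarray  # 5th percentile
    upper: np.ndarray  # 95th percentile
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.median + 1e-12)
                and np.all(self.median <= self.upper + 1e-12)):
            raise ValueError("percentile curves must be ordered")


def sample_parameter_sets(
    fits: Sequence[FitResult],
    n: int = 100_000,
    seed: int = 0,
    include_tau: bool = True,
) -> np.ndarray:
    """Resample fitted Gompertz (a, b, tau) triplets jointly with
    replacement.

    Joint empirical resampling preserves the observed a-b correlation.
    With ``include_tau=False`` the dormancy times are all set to zero
    (sampling the (a, b) pairs only)."""
    gf = [f for f in fits if f.spec.family == "gompertz"]
    if not gf:
        raise ValueError("no Gompertz fits to sample from")
    if n < 1:
        raise ValueError("n must be positive")
    triplets = np.array(
        [[f.params["a"], f.params["b"], f.tau_hat if include_tau else 0.0]
         for f in gf]
    )
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    idx = rng.integers(0, len(triplets), size=n)
    return triplets[idx]


def _gompertz_curves(samples: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Trajectories N(tau + day) for each (a, b, tau) row; (n, len(days))."""
    a = samples[:, [0]]
    b = samples[:, [1]]
    tau = samples[:, [2]]
    t = tau + days[None, :]
    expo = (a / b) * (-np.expm1(-b * t))
    return np.exp(np.minimum(expo, 700.0))


def project_cohort(
    samples: np.ndarray,
    grid: Sequence[float] | None = None,
    seed: int = 0,
) -> ProjectionResult:
    """Pointwise median and 5th/95th-percentile curves over sampled
    Gompertz trajectories, indexed by experiment day (default Days 0..20).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be (n, 3) rows of (a, b, tau)")
    days = np.arange(21.0) if grid is None else np.asarray(grid, dtype=float)
    curves = _gompertz_curves(samples, days)
    med, lo, hi = np.percentile(curves, [50, 5, 95], axis=0)
    return ProjectionResult(
        days=days, median=med, lower=lo, upper=hi,
        n_samples=samples.shape[0], seed=seed,
    )


def invitro_to_patient_time(
    days_in_vitro: float,
    clinical_doubling: float,
    model_doubling: float,
) -> float:
    """Patient-equivalent years for an in-vitro duration, scaling by the
    ratio of the clinical to the in-vitro (model) doubling time; reported
    to one decimal.

    E.g. with a clinical colorectal doubling time of 211 days and an
    in-vitro model doubling time of 2.6 days, 20 in-vitro days correspond
    to 20 * (211 / 2.6) / 365 = 4.4 years.
    """
    if min(days_in_vitro, clinical_doubling, model_doubling) <= 0:
        raise ValueError("all inputs must be positive")
    years = days_in_vitro * (clinical_doubling / model_doubling) / 365.0
    return round(years, 1)
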