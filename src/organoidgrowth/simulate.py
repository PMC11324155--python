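"""Synthetic organoid-tracking cohorts with realistic statistical structure.

The generator emulates the tracking-table exports the pipeline consumes,
with the population structure reported for colon-cancer organoid cohorts:
lognormally distributed initial growth rates a, decay rates b correlated
with a on the log scale, a subpopulation of purely exponential organoids
(b = 0), per-organoid dormancy times tau on [0, tau_max] with skewed or
bimodal shapes, observation noise, and contamination objects (dead
tracks, sub-threshold debris, shrinking tracks, merge-like artifacts)
that exercise the filter cascade.

Cell counts follow the Gompertz law N(tau + day) from a single cell and
are converted to projected areas through the inverse of the
area->volume->cells calibration chain, so a noise-free cohort round-trips
exactly through the conversion step.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .filtering import OrganoidTrack
from .geometry import DEFAULT_RHO, CalibrationConstant, EllipsoidAreaModel, cells_to_area
from .models import GrowthModelSpec

__all__ = [
    "CohortConfig",
    "PRESETS",
    "generate_cohort",
    "generate_calibration_dataset",
]

_TAU_SHAPES = ("skew_low", "skew_high", "bimodal", "uniform")

_GOMPERTZ = GrowthModelSpec("gompertz")


@dataclass(frozen=True)
class CohortConfig:
    """Generative description of one synthetic patient cohort.

    Defaults give a mid-sized cohort on the three-day imaging grid
    {0, 3, 5} with a ~ lognormal (median 1/day, matching reported initial
    doubling times of ~16 hours and Day-5 sizes of 1e2-1e4 cells; sd 0.25
    dex, spanning roughly an order of magnitude), ~15% exponential
    organoids, an a-b log-scale correlation near 0.8, and 5%
    multiplicative measurement noise.
    """

    n_organoids: int = 300
    day_grid: tuple[float, ...] = (0.0, 3.0, 5.0)
    tau_max: float = 4.0
    log10_a: tuple[float, float] = (0.0, 0.25)
    fraction_exponential: float = 0.15
    #: Gaussian-copula coupling between exponential status and -log10(a):
    #: 0 = independent assignment; the default concentrates exponential
    #: organoids at smaller growth rates (as observed in real cohorts)
    #: while preserving the exact overall fraction and the lognormal
    #: marginal of a.
    exp_rate_coupling: float = 0.8
    #: (intercept, slope, residual sd) of log10(b) | log10(a)
    log_b_given_a: tuple[float, float, float] = (-0.7, 1.0, 0.19)
    tau_distribution: str = "skew_low"
    noise_kind: str = "multiplicative"
    noise_level: float = 0.05
    rho: float = DEFAULT_RHO
    #: contamination rates as fractions of n_organoids, added as extra objects
    rate_dead: float = 0.0
    rate_debris: float = 0.0
    rate_nonmonotone: float = 0.0
    rate_merge: float = 0.0
    well_radius: float = 3000.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_organoids < 0:
            bad.append("n_organoids must be nonnegative")
        if len(self.day_grid) < 2 or self.day_grid[0] != 0:
            bad.append("day_grid must start at 0 with at least two days")
        if any(np.diff(self.day_grid) <= 0):
            bad.append("day_grid must be strictly increasing")
        if self.tau_max < 0:
            bad.append("tau_max must be nonnegative")
        if not 0 <= self.fraction_exponential <= 1:
            bad.append("fraction_exponential must be in [0, 1]")
        if not 0 <= self.exp_rate_coupling < 1:
            bad.append("exp_rate_coupling must be in [0, 1)")
        if self.log10_a[1] < 0 or self.log_b_given_a[2] < 0:
            bad.append("standard deviations must be nonnegative")
        if self.tau_distribution not in _TAU_SHAPES:
            bad.append(f"tau_distribution must be one of {_TAU_SHAPES}")
        if self.noise_kind not in ("additive", "multiplicative"):
            bad.append("noise_kind must be 'additive' or 'multiplicative'")
        if self.noise_level < 0:
            bad.append("noise_level must be nonnegative")
        if self.rho <= 0:
            bad.append("rho must be positive")
        for name in ("rate_dead", "rate_debris", "rate_nonmonotone", "rate_merge"):
            if not 0 <= getattr(self, name):
                bad.append(f"{name} must be nonnegative")
        if bad:
            raise ValueError("invalid CohortConfig: " + "; ".join(bad))


#: Demonstration presets differing in tau shape, spread of log10(a) and the
#: exponential fraction; they are qualitative, not calibrated to any
#: particular experimental dataset.
PRESETS: dict[str, CohortConfig] = {
    "uk-like": CohortConfig(
        log10_a=(0.05, 0.22), fraction_exponential=0.248,
        tau_distribution="skew_high",
    ),
    "up-like": CohortConfig(
        log10_a=(0.0, 0.25), fraction_exponential=0.107,
        tau_distribution="skew_low",
    ),
    "us-like": CohortConfig(
        log10_a=(-0.15, 0.35), fraction_exponential=0.162,
        tau_distribution="bimodal",
    ),
}


def _draw_tau(rng: np.random.Generator, shape: str, n: int, tau_max: float) -> np.ndarray:
    if shape == "uniform":
        u = rng.uniform(0, 1, n)
    elif shape == "skew_low":
        u = rng.beta(1, 3, n)
    elif shape == "skew_high":
        u = rng.beta(3, 1, n)
    else:  # bimodal: equal mixture of the two skews
        low = rng.beta(1, 3, n)
        high = rng.beta(3, 1, n)
        u = np.where(rng.random(n) < 0.5, low, high)
    return u * tau_max


def _gompertz_counts(a, b, tau, days):
    """Noise-free counts N(tau + day) from a single cell; b = 0 rows are
    purely exponential."""
    t = tau[:, None] + np.asarray(days)[None, :]
    a = a[:, None]
    b = b[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        expo = np.where(b > 0, (a / b) * (-np.expm1(-b * t)), a * t)
    return np.exp(np.minimum(expo, 700.0))


def generate_cohort(config: CohortConfig) -> tuple[list[OrganoidTrack], pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns the observable tracks plus a hidden ground-truth table with
    one row per object: its class ("organoid", or a contamination class),
    and for organoids the generating (a, b, tau) and exponential flag.
    Contamination objects are constructed to fail exactly one filter
    stage, so filter accounting can be checked exactly.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(int(config.seed)))
    days = np.asarray(config.day_grid, dtype=float)
    cal = CalibrationConstant(config.rho, "estimated", 0) \
        if config.rho != DEFAULT_RHO else CalibrationConstant()
    geom = EllipsoidAreaModel()

    n = config.n_organoids
    mu, sd = config.log10_a
    z = rng.normal(0.0, 1.0, n)
    a = 10.0 ** (mu + sd * z)
    # exponential status via a Gaussian copula against the rate quantile:
    # marginal P(exponential) is exactly fraction_exponential while larger
    # rates are (for coupling > 0) less likely to be exponential
    from scipy.stats import norm as _norm

    f = config.fraction_exponential
    rho_c = config.exp_rate_coupling
    if f >= 1.0:
        is_exp = np.ones(n, bool)
    elif f <= 0.0:
        is_exp = np.zeros(n, bool)
    else:
        eps = rng.normal(0.0, 1.0, n)
        w = rho_c * z + math.sqrt(1.0 - rho_c**2) * eps
        is_exp = w < _norm.ppf(f)
    c0, c1, c2 = config.log_b_given_a
    b = 10.0 ** (c0 + c1 * np.log10(a) + rng.normal(0.0, c2, n))
    b = np.where(is_exp, 0.0, b)
    tau = _draw_tau(rng, config.tau_distribution, n, config.tau_max)

    counts = _gompertz_counts(a, b, tau, days)
    if config.noise_level > 0:
        eps = rng.standard_normal(counts.shape)
        if config.noise_kind == "multiplicative":
            counts = counts * (1.0 + config.noise_level * eps)
        else:
            counts = counts + config.noise_level * eps
    counts = np.maximum(counts, 1e-6)
    areas = cells_to_area(counts, cal, geom)

    tracks: list[OrganoidTrack] = []
    truth_rows: list[dict] = []
    k = days.size

    def _position(r_scale=1.0):
        radius = config.well_radius * np.sqrt(rng.random()) * r_scale
        angle = rng.uniform(0, 2 * np.pi)
        center = radius * np.array([np.cos(angle), np.sin(angle)])
        jitter = rng.normal(0, 3.0, (k, 2))  # small day-to-day drift, um
        return center[None, :] + jitter

    for i in range(n):
        tid = f"org{i:05d}"
        tracks.append(OrganoidTrack(
            track_id=tid, days=days, areas=areas[i],
            alive=np.ones(k, bool), position=_position(),
        ))
        truth_rows.append({
            "track_id": tid, "kind": "organoid", "a": a[i], "b": b[i],
            "tau": tau[i], "is_exponential": bool(is_exp[i]),
        })

    def _add_contaminant(kind: str, idx: int):
        tid = f"{kind}{idx:05d}"
        base = 600.0 * (1.0 + 0.3 * rng.random())
        grow = base * (1.5 ** np.arange(k))  # clean increasing areas
        alive = np.ones(k, bool)
        areas_c = grow
        if kind == "dead":
            alive = np.ones(k, bool)
            alive[rng.integers(1, k)] = False
        elif kind == "debris":
            areas_c = grow.copy()
            areas_c[rng.integers(0, k)] = rng.uniform(50.0, 299.0)
        elif kind == "nonmonotone":
            areas_c = grow.copy()
            j = rng.integers(1, k)
            areas_c[j] = areas_c[j - 1] * 0.7  # shrinks once, stays >= 300
        elif kind == "merge":
            areas_c = grow.copy()
            areas_c[-1] = areas_c[-2] * 40.0  # implausible 40-fold jump
        tracks.append(OrganoidTrack(
            track_id=tid, days=days, areas=areas_c, alive=alive,
            position=_position(),
        ))
        truth_rows.append({
            "track_id": tid, "kind": kind, "a": np.nan, "b": np.nan,
            "tau": np.nan, "is_exponential": False,
        })

    for kind, rate in (("dead", config.rate_dead),
                       ("debris", config.rate_debris),
                       ("nonmonotone", config.rate_nonmonotone),
                       ("merge", config.rate_merge)):
        for idx in range(round(rate * n)):
            _add_contaminant(kind, idx)

    return tracks, pd.DataFrame(truth_rows)


def generate_calibration_dataset(
    n: int,
    rho: float = DEFAULT_RHO,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (volume, live-cell count) observations across days
    {0, 1, 3, 6}, emulating a GFP-labelled dataset with direct counts.

    Volumes are counts * rho * (1 + noise); counts follow random Gompertz
    draws.  Supports round-trip testing of the calibration estimator.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if rho <= 0:
        raise ValueError("rho must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    days = np.array([0.0, 1.0, 3.0, 6.0])
    a = 10.0 ** rng.normal(0.0, 0.25, n)
    b = 10.0 ** (-0.7 + np.log10(a) + rng.normal(0.0, 0.19, n))
    tau = rng.uniform(0.0, 7.0, n)
    counts = _gompertz_counts(a, b, tau, days)
    noise = 1.0 + noise_cv * rng.standard_normal(counts.shape)
    volumes = counts * rho * np.maximum(noise, 1e-3)
    rows = []
    for i in range(n):
        for j, d in enumerate(days):
            rows.append({
                "track_id": f"cal{i:05d}", "day": d,
                "volume_um3": volumes[i, j], "live_cells": counts[i, j],
            })
    return pd.DataFrame(rows)
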