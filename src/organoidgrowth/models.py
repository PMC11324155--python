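"""Classical growth laws for organoid cell-number dynamics.

Each model describes N(t), the number of live cells in an organoid, through
an autonomous ODE with closed-form solution.  Two families are unconstrained
(exponential, power law) and grow without bound; three are sigmoidal
(Gompertz, logistic, von Bertalanffy) and saturate at a carrying capacity K.

All rates are per day and times are in days.  The analysis uses nine model
variants: exponential, power law with exponent gamma in {1/2, 2/3, 3/4},
Gompertz, logistic, and von Bertalanffy with gamma in {1/2, 2/3, 3/4}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthModelSpec",
    "Trajectory",
    "ANALYSIS_VARIANTS",
    "B_FLOOR",
    "K_CAP",
    "evaluate_trajectory",
    "general_rhs",
    "gompertz_limit_approximation",
    "gompertz_alt_parameters",
    "carrying_capacity",
    "growth_rate_at",
    "doubling_time",
]

#: Lower bound for the Gompertz decay rate b (per day).  A fit sitting at
#: this floor is classified as an "exponential organoid"; the Gompertz
#: formula is still evaluated with the full expression at the floor.
B_FLOOR = 1e-4

#: Carrying capacities above this cell count are reported as the cap.
K_CAP = 1e10

_ALLOWED_GAMMAS = (0.5, 2.0 / 3.0, 0.75)

_DEFAULT_RATE_BOUNDS = (1e-4, 10.0)
_DEFAULT_K_BOUNDS = (1.0 + 1e-6, K_CAP)

_FAMILIES = (
    "exponential",
    "power_law",
    "gompertz",
    "gompertz_alt",
    "logistic",
    "von_bertalanffy",
)


@dataclass(frozen=True)
class GrowthModelSpec:
    """One growth-model variant: a family plus (where relevant) a fixed
    power-law exponent gamma.

    Parameters are the *free* shape/rate parameters of the family; the
    dormancy time tau is handled by the fitting layer and is not part of
    this spec.
    """

    family: str
    gamma: float | None = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family in ("power_law", "von_bertalanffy"):
            if self.gamma is None or not any(
                math.isclose(self.gamma, g) for g in _ALLOWED_GAMMAS
            ):
                raise ValueError(
                    f"{self.family} requires gamma in {{1/2, 2/3, 3/4}}, "
                    f"got {self.gamma!r}"
                )
        elif self.gamma is not None:
            raise ValueError(f"{self.family} does not accept a gamma exponent")
        defaults = self._default_bounds()
        merged = {**defaults, **dict(self.bounds)}
        object.__setattr__(self, "bounds", merged)

    def _default_bounds(self) -> dict[str, tuple[float, float]]:
        r = _DEFAULT_RATE_BOUNDS
        if self.family in ("exponential", "power_law"):
            return {"a": r}
        if self.family in ("gompertz", "von_bertalanffy"):
            return {"a": r, "b": r}
        if self.family == "logistic":
            return {"a": r, "K": _DEFAULT_K_BOUNDS}
        # gompertz_alt: initial rate alpha and carrying capacity K
        return {"alpha": r, "K": _DEFAULT_K_BOUNDS}

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    @property
    def n_free_params(self) -> int:
        """Free parameters excluding the dormancy time tau."""
        return len(self.bounds)

    @property
    def label(self) -> str:
        if self.gamma is None:
            return self.family
        frac = {0.5: "1/2", 2.0 / 3.0: "2/3", 0.75: "3/4"}
        key = min(frac, key=lambda g: abs(g - self.gamma))
        return f"{self.family} {frac[key]}"

    def validate_params(self, params: Sequence[float]) -> np.ndarray:
        theta = np.asarray(params, dtype=float)
        if theta.shape != (self.n_free_params,):
            raise ValueError(
                f"{self.label} expects {self.n_free_params} parameters "
                f"{self.param_names}, got shape {theta.shape}"
            )
        for value, name in zip(theta, self.param_names):
            lo, hi = self.bounds[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"parameter {name}={value} outside bounds [{lo}, {hi}]"
                )
        return theta


def analysis_variants() -> tuple[GrowthModelSpec, ...]:
    """The nine model variants compared in the analysis."""
    out = [GrowthModelSpec("exponential")]
    out += [GrowthModelSpec("power_law", g) for g in _ALLOWED_GAMMAS]
    out += [GrowthModelSpec("gompertz"), GrowthModelSpec("logistic")]
    out += [GrowthModelSpec("von_bertalanffy", g) for g in _ALLOWED_GAMMAS]
    return tuple(out)


ANALYSIS_VARIANTS = analysis_variants()


@dataclass(frozen=True)
class Trajectory:
    """A model-generated time series of live-cell counts."""

    times: np.ndarray
    values: np.ndarray
    N0: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(v > 0)):
            raise ValueError("values must be finite and positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def _closed_form(
    spec: GrowthModelSpec, theta: np.ndarray, N0: float, t: np.ndarray
) -> np.ndarray:
    fam = spec.family
    if fam == "exponential":
        (a,) = theta
        return N0 * np.exp(a * t)
    if fam == "power_law":
        (a,) = theta
        g = spec.gamma
        return (N0 ** (1 - g) + (1 - g) * a * t) ** (1.0 / (1 - g))
    if fam == "gompertz":
        a, b = theta
        # exponent computed in log space to avoid overflow for tiny b
        expo = (a / b) * (-np.expm1(-b * t))
        return N0 * np.exp(np.minimum(expo, 700.0))
    if fam == "gompertz_alt":
        alpha, K = theta
        if K <= 0:
            raise ValueError("gompertz_alt requires K > 0")
        return K * np.exp(np.log(N0 / K) * np.exp(-alpha * t))
    if fam == "logistic":
        a, K = theta
        if K <= 0:
            raise ValueError("logistic requires K > 0")
        return N0 * K / (N0 + (K - N0) * np.exp(-a * t))
    if fam == "von_bertalanffy":
        a, b = theta
        g = spec.gamma
        q = 1 - g
        return ((a / b) + (N0**q - a / b) * np.exp(-q * b * t)) ** (1.0 / q)
    raise AssertionError(fam)


def evaluate_trajectory(
    spec: GrowthModelSpec,
    params: Sequence[float],
    N0: float,
    times: Sequence[float],
) -> Trajectory:
    """Evaluate a model's closed-form solution N(t) from N(0) = N0.

    No numerical integration is performed; each family's explicit solution
    is used directly.
    """
    theta = spec.validate_params(params)
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    values = _closed_form(spec, theta, float(N0), t)
    return Trajectory(times=t, values=values, N0=float(N0))


def general_rhs(N: float, a: float, b: float, gamma: float, delta: float) -> float:
    """Right-hand side a*N**gamma - b*N**delta of the unifying growth ODE.

    Every family except Gompertz is a specialization: b=0, gamma=1 gives
    exponential; b=a/K, gamma=1, delta=2 gives logistic; delta=1 with
    0 < gamma < 1 gives von Bertalanffy.  Gompertz arises only as the
    gamma -> delta limit (see :func:`gompertz_limit_approximation`).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if a <= 0 or b < 0:
        raise ValueError("require a > 0 and b >= 0")
    if gamma >= delta:
        raise ValueError("require gamma < delta (the limit is handled separately)")
    return a * N**gamma - b * N**delta


def gompertz_limit_approximation(
    delta: float, epsilon: float, a: float, b: float
) -> tuple[float, float]:
    """Reparametrized coefficients (c, d) under which the unifying ODE with
    gamma = delta - epsilon approaches a Gompertz law as epsilon -> 0.

    Rewriting a*N**gamma - b*N**delta as
    c*N**delta - d*N**(delta-eps)*(N**eps - 1)/eps gives c = a - b and
    d = a*epsilon; the epsilon -> 0 limit is c*N**delta - d*N**delta*log(N),
    the Gompertz form when delta = 1 (initial rate alpha = d,
    K = exp(c/d)).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not a > b >= 0:
        raise ValueError("require a > b >= 0")
    c = a - b
    d = a * epsilon
    return c, d


def gompertz_alt_parameters(a: float, b: float, N0: float = 1.0) -> tuple[float, float]:
    """Convert Gompertz (a, b) to the (alpha, K) parametrization.

    alpha = b and K = N0 * exp(a/b); the two closed forms are identical.
    """
    if b <= 0:
        raise ValueError("conversion requires b > 0")
    return b, N0 * math.exp(min(a / b, 700.0))


def carrying_capacity(
    spec: GrowthModelSpec, params: Sequence[float], N0: float = 1.0
) -> float:
    """Asymptotic cell count of a model, capped at 1e10 cells.

    Unconstrained families (exponential, power law) return ``inf``; so does
    Gompertz / von Bertalanffy with b = 0 (accepted here even though the
    fitting bounds keep b at or above the floor).
    """
    theta = np.asarray(params, dtype=float)
    if theta.shape != (spec.n_free_params,):
        raise ValueError(
            f"{spec.label} expects {spec.n_free_params} parameters"
        )
    fam = spec.family
    if fam in ("exponential", "power_law"):
        return math.inf
    if fam == "gompertz":
        a, b = theta
        if b == 0:
            return math.inf
        log_k = math.log(N0) + a / b  # natural-log space, overflow-safe
        return K_CAP if log_k > math.log(K_CAP) else math.exp(log_k)
    if fam == "von_bertalanffy":
        a, b = theta
        if b == 0:
            return math.inf
        log_k = math.log(a / b) / (1 - spec.gamma)
        return K_CAP if log_k > math.log(K_CAP) else math.exp(log_k)
    # logistic / gompertz_alt carry K directly
    K = theta[list(spec.param_names).index("K")]
    return min(K, K_CAP)


def growth_rate_at(a: float, b: float, t: float) -> float:
    """Instantaneous exponential growth rate a*exp(-b*t) of a Gompertz
    organoid at model time t (per day)."""
    if a <= 0 or b < 0 or t < 0:
        raise ValueError("require a > 0, b >= 0, t >= 0")
    return a * math.exp(-b * t)


def doubling_time(
    a: float, b: float, t: float = 0.0, method: str = "exact"
) -> float:
    """Time for a Gompertz organoid to double from model time t.

    method="instantaneous" returns ln 2 / (a e^{-bt}), the doubling time of
    the frozen current rate.  method="exact" (default) solves
    N(t + D) = 2 N(t) on the Gompertz solution:
    D = -(1/b) ln(1 - b ln2 / (a e^{-bt})), with limit ln2/a as b -> 0.
    Returns ``inf`` when the trajectory never doubles from time t.
    """
    rate = growth_rate_at(a, b, t)
    if method == "instantaneous":
        return math.log(2) / rate
    if method != "exact":
        raise ValueError("method must be 'exact' or 'instantaneous'")
    if b == 0:
        return math.log(2) / a
    arg = 1.0 - b * math.log(2) / rate
    if arg <= 0:
        return math.inf
    return -math.log(arg) / b
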