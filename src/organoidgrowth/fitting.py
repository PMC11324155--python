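"""Per-organoid least-squares fitting of growth models with a dormancy time.

Each organoid is assumed to start growing from a single cell (N0 = 1) at
experiment Day -tau, where the dormancy time tau is an organoid-specific
free parameter in [0, tau_max] (tau_max = 4 days for a {0, 3, 5} day grid,
7 for a {0, 1, 3, 6} grid).  Model time 0 is Day -tau, so the model
prediction for an observation on Day t_i is N(tau + t_i).

For cell-number estimates n_1..n_k on Days t_1..t_k, the parameters are
estimated by minimizing the sum of squared errors

    phi^2(theta, tau) = sum_i (n_i - N(tau + t_i; theta))^2,

which is the maximum-likelihood estimate under i.i.d. additive Gaussian
errors; the error-variance MLE is sigma^2 = phi^2 / k.  A logarithmic
variant (residuals on log counts, i.e. multiplicative errors) is selected
with ``scale="log"``.

The objective is smooth but multimodal in (theta, tau), so each fit runs
``n_starts`` bounded local optimizations — one deterministic heuristic
start followed by seeded random starts (log-uniform for rate/capacity
parameters, uniform for tau) — and keeps the best optimum.  The local
solver is a bounds-projected Levenberg-Marquardt iteration with analytic
Jacobians, vectorized across starts (and across organoids in
:func:`fit_cohort`), which makes cohort-scale multi-start fitting cheap.
A fixed iteration budget keeps each start's trajectory independent of how
fits are batched, so `fit_organoid` and `fit_cohort` agree bit-for-bit.

phi^2 is floored at 1e-6 and treated as effectively zero there.  A
Gompertz fit whose decay rate b sits at its 1e-4 floor is classified as an
"exponential organoid".
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import B_FLOOR, GrowthModelSpec, carrying_capacity

__all__ = [
    "PHI2_FLOOR",
    "CellNumberSeries",
    "FitResult",
    "sse_objective",
    "log_likelihood",
    "fit_organoid",
    "fit_cohort",
    "classify_exponential",
]

#: Smallest possible value for the squared fitting error phi^2.
PHI2_FLOOR = 1e-6

#: A fitted b within this distance of the floor counts as at-floor.
_FLOOR_TOL = 1e-10

_LN10 = math.log(10.0)

#: Levenberg-Marquardt iteration budget per fit (fixed, not adaptive, so
#: batched and single fits follow identical per-start trajectories).
_N_ITER = 160


@dataclass(frozen=True)
class CellNumberSeries:
    """Estimated live-cell numbers for one organoid at its observation days."""

    track_id: str
    days: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if d.ndim != 1 or c.shape != d.shape:
            raise ValueError("days and counts must be matching 1-D arrays")
        if d.size < 2:
            raise ValueError("a series needs at least two observation days")
        if not np.all(np.diff(d) > 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(c > 0):
            raise ValueError("counts must be strictly positive")
        object.__setattr__(self, "days", d)
        object.__setattr__(self, "counts", c)

    @property
    def k(self) -> int:
        return self.days.size


@dataclass(frozen=True)
class FitResult:
    """Outcome of one (organoid, model) fit."""

    track_id: str
    spec: GrowthModelSpec
    theta_hat: np.ndarray
    tau_hat: float
    phi2: float
    sigma2_hat: float
    n_starts: int
    converged_fraction: float
    K_hat: float
    is_exponential: bool
    scale: str = "linear"
    at_bounds: tuple[str, ...] = field(default_factory=tuple)
    success: bool = True

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names, map(float, self.theta_hat)))


# ---------------------------------------------------------------------------
# closed forms and their parameter derivatives
# ---------------------------------------------------------------------------

def _family_eval(spec, N0, theta_cols, t, with_jac):
    """Predictions (and optionally derivatives wrt natural parameters and
    tau) for a batch.  ``theta_cols`` is a list of (S, 1) natural-parameter
    columns; ``t`` is the (S, k) matrix of model times tau + day."""
    fam, g = spec.family, spec.gamma
    if fam == "exponential":
        (a,) = theta_cols
        N = N0 * np.exp(np.minimum(a * t, 700.0))
        if not with_jac:
            return N, None
        return N, [t * N, a * N]  # d/da, d/dtau
    if fam == "power_law":
        (a,) = theta_cols
        q = 1.0 - g
        base = N0**q + q * a * t
        N = base ** (1.0 / q)
        if not with_jac:
            return N, None
        Ng = base ** (g / q)  # = N**gamma
        return N, [t * Ng, a * Ng]
    if fam == "gompertz":
        a, b = theta_cols
        E = np.exp(-b * t)
        u = -np.expm1(-b * t)  # 1 - e^{-bt}
        N = N0 * np.exp(np.minimum((a / b) * u, 700.0))
        if not with_jac:
            return N, None
        dN_da = N * u / b
        dN_db = N * a * (t * E / b - u / b**2)
        dN_dtau = N * a * E
        return N, [dN_da, dN_db, dN_dtau]
    if fam == "logistic":
        a, K = theta_cols
        E = np.exp(-a * t)
        D = N0 + (K - N0) * E
        N = N0 * K / D
        if not with_jac:
            return N, None
        dN_da = N0 * K * (K - N0) * t * E / D**2
        dN_dK = N0 * (D - K * E) / D**2
        dN_dtau = a * N * (1.0 - N / K)
        return N, [dN_da, dN_dK, dN_dtau]
    if fam == "von_bertalanffy":
        a, b = theta_cols
        q = 1.0 - g
        E = np.exp(-q * b * t)
        u = 1.0 - E
        base = np.maximum((a / b) * u + N0**q * E, 1e-300)
        N = base ** (1.0 / q)
        if not with_jac:
            return N, None
        Nq = base ** (1.0 / q - 1.0)  # N^{1-q} = N^gamma
        dbase_da = u / b
        dbase_db = -(a / b**2) * u + ((a / b) - N0**q) * q * t * E
        dN_da = (1.0 / q) * Nq * dbase_da
        dN_db = (1.0 / q) * Nq * dbase_db
        dN_dtau = a * Nq - b * N
        return N, [dN_da, dN_db, dN_dtau]
    if fam == "gompertz_alt":
        alpha, K = theta_cols
        E = np.exp(-alpha * t)
        N = K * np.exp(np.log(N0 / K) * E)
        if not with_jac:
            return N, None
        dN_dalpha = -N * np.log(N0 / K) * t * E
        dN_dK = (N / K) * (1.0 - E)
        dN_dtau = alpha * np.log(K / N) * N
        return N, [dN_dalpha, dN_dK, dN_dtau]
    raise AssertionError(fam)  # pragma: no cover


def sse_objective(
    spec: GrowthModelSpec,
    theta: Sequence[float],
    tau: float,
    series: CellNumberSeries,
    N0: float = 1.0,
    scale: str = "linear",
) -> float:
    """Sum of squared errors phi^2(theta, tau), before flooring.

    Non-finite model evaluations yield a large finite penalty rather than
    an exception, so optimizers can recover from wild parameter regions.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free_params,):
        raise ValueError(f"{spec.label} expects {spec.n_free_params} parameters")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    cols = [np.full((1, 1), v) for v in theta]
    t = (tau + series.days)[None, :]
    with np.errstate(all="ignore"):
        pred, _ = _family_eval(spec, N0, cols, t, with_jac=False)
        if scale == "log":
            res = np.log(series.counts) - np.log(np.maximum(pred[0], 1e-300))
        else:
            res = series.counts - pred[0]
    res = np.nan_to_num(res, nan=1e12, posinf=1e12, neginf=-1e12)
    return float(np.dot(res, res))


def log_likelihood(
    spec: GrowthModelSpec,
    theta: Sequence[float],
    tau: float,
    sigma: float,
    series: CellNumberSeries,
    N0: float = 1.0,
) -> float:
    """Gaussian log-likelihood -(k/2) log(2 pi sigma^2) - phi^2/(2 sigma^2).

    Maximizing over sigma at fixed (theta, tau) gives sigma^2 = phi^2 / k.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = series.k
    phi2 = sse_objective(spec, theta, tau, series, N0)
    return -0.5 * k * math.log(2 * math.pi * sigma**2) - phi2 / (2 * sigma**2)


# ---------------------------------------------------------------------------
# batched multi-start optimizer
# ---------------------------------------------------------------------------

def _batch_residuals(spec, N0, Z, t, counts, use_log, with_jac):
    """Residuals (S, k) and z-space Jacobian (S, k, P) at z-points Z.

    z-space is log10 for the model parameters and linear for tau."""
    P = Z.shape[1]
    nat = [10.0 ** Z[:, [j]] for j in range(P - 1)]
    with np.errstate(all="ignore"):
        pred, grads = _family_eval(spec, N0, nat, t, with_jac)
        if use_log:
            res = np.log(counts) - np.log(np.maximum(pred, 1e-300))
        else:
            res = counts - pred
    res = np.nan_to_num(res, nan=1e12, posinf=1e12, neginf=-1e12)
    if not with_jac:
        return res, None
    J = np.empty(res.shape + (P,))
    for j in range(P):
        dN = grads[j]
        scale_j = nat[j] * _LN10 if j < P - 1 else 1.0
        dr = -dN * scale_j
        if use_log:
            dr = dr / np.maximum(pred, 1e-300)
        J[:, :, j] = dr
    J = np.nan_to_num(J, nan=0.0, posinf=1e150, neginf=-1e150)
    return res, J


def _projected_lm(spec, N0, Z0, lo_z, hi_z, t_fn, counts, use_log):
    """Bounds-projected Levenberg-Marquardt on a batch of start points.

    ``t_fn(tau_col)`` maps the (S, 1) tau column to the (S, k) model-time
    matrix.  Runs a fixed iteration budget; each row's trajectory depends
    only on its own start point."""
    Z = Z0.copy()
    S, P = Z.shape
    lam = np.full(S, 1e-3)
    eye = np.eye(P)

    def cost_at(Zx):
        res, _ = _batch_residuals(
            spec, N0, Zx, t_fn(Zx[:, [P - 1]]), counts, use_log, False
        )
        with np.errstate(over="ignore"):
            c = np.einsum("ij,ij->i", res, res)
        return np.where(np.isfinite(c), c, np.inf)

    def lm_loop(Z, cost, lam, n_iter):
        for _ in range(n_iter):
            res, J = _batch_residuals(
                spec, N0, Z, t_fn(Z[:, [P - 1]]), counts, use_log, True
            )
            with np.errstate(over="ignore", invalid="ignore"):
                JtJ = np.einsum("ikp,ikq->ipq", J, J)
                g = np.einsum("ikp,ik->ip", J, res)
            JtJ = np.nan_to_num(JtJ, nan=0.0, posinf=1e300, neginf=-1e300)
            g = np.nan_to_num(g, nan=0.0, posinf=1e300, neginf=-1e300)
            diag = np.maximum(np.einsum("ipp->ip", JtJ), 1e-12)
            A = JtJ + lam[:, None, None] * (diag[:, :, None] * eye) + 1e-14 * eye
            try:
                step = -np.linalg.solve(A, g[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:  # pragma: no cover
                step = np.zeros_like(g)
            step = np.nan_to_num(step, nan=0.0)
            trial = np.clip(Z + step, lo_z, hi_z)
            trial_cost = cost_at(trial)
            accept = trial_cost < cost
            Z[accept] = trial[accept]
            cost[accept] = trial_cost[accept]
            lam = np.where(accept, np.maximum(lam * 0.3, 1e-12), lam * 5.0)
            lam = np.minimum(lam, 1e14)
        return Z, cost, lam

    cost = cost_at(Z)
    Z, cost, lam = lm_loop(Z, cost, lam, _N_ITER)

    # bound-face polish: optima that stall just inside a box face (e.g. the
    # decay-rate floor of effectively exponential organoids) are restarted
    # briefly from the exactly-snapped point and kept when not worse
    span = hi_z - lo_z
    snapped = Z.copy()
    snapped = np.where(Z - lo_z < 1e-3 * span, lo_z, snapped)
    snapped = np.where(hi_z - Z < 1e-3 * span, hi_z, snapped)
    moved = np.any(snapped != Z, axis=1)
    if np.any(moved):
        Zs = snapped.copy()
        cs = cost_at(Zs)
        Zs, cs, _ = lm_loop(Zs, cs, np.full(S, 1e-3), 40)
        better = cs <= cost
        Z[better] = Zs[better]
        cost[better] = cs[better]
    return Z, cost


def _heuristic_start(days, counts, spec, tau_max, lo, hi):
    """Deterministic first start: exponential rate from the log-linear
    slope, tau from the Day-0 size, other parameters at mild defaults."""
    slope = np.polyfit(days, np.log(counts), 1)[0]
    a0 = float(np.clip(slope, 1.5 * lo[0], hi[0] / 2))
    tau0 = float(np.clip(math.log(max(counts[0], 1.0)) / a0, 0.0, tau_max))
    start = [a0]
    for name in spec.param_names[1:]:
        if name == "K":
            start.append(float(np.clip(2.0 * counts.max(), 2.0, 1e9)))
        else:  # decay-rate parameter
            start.append(0.05)
    start.append(tau0)
    return np.clip(np.asarray(start), lo, hi)


def _z_bounds(spec, tau_max):
    names = list(spec.param_names)
    lo_nat = np.array([spec.bounds[p][0] for p in names] + [0.0])
    hi_nat = np.array([spec.bounds[p][1] for p in names] + [tau_max])
    lo_z = np.concatenate([np.log10(lo_nat[:-1]), [0.0]])
    hi_z = np.concatenate([np.log10(hi_nat[:-1]), [tau_max]])
    return names, lo_nat, hi_nat, lo_z, hi_z


def _starts_for(series, spec, tau_max, n_starts, rng, lo_nat, hi_nat, lo_z, hi_z):
    """Deterministic heuristic starts followed by a sequential stream of
    random starts, so the first n of n+1 starts coincide (nested streams).

    For two-parameter families a second heuristic start sits at the
    exponential-like limit (decay rate at its floor; carrying capacity at
    its ceiling for the logistic), so the expected subpopulation of
    effectively exponential organoids is always probed."""
    P = lo_z.size
    Z0 = np.empty((n_starts, P))
    x0 = _heuristic_start(series.days, series.counts, spec, tau_max, lo_nat, hi_nat)
    Z0[0, :-1] = np.log10(x0[:-1])
    Z0[0, -1] = x0[-1]
    n_det = 1
    if spec.n_free_params == 2 and n_starts >= 2:
        x1 = x0.copy()
        x1[1] = hi_nat[1] if spec.param_names[1] == "K" else lo_nat[1]
        Z0[1, :-1] = np.log10(x1[:-1])
        Z0[1, -1] = x1[-1]
        n_det = 2
    for s in range(n_det, n_starts):
        Z0[s] = lo_z + rng.random(P) * (hi_z - lo_z)
    return Z0


def _finalize(series, spec, names, lo_nat, hi_nat, lo_z, hi_z,
              z_best, cost_best, n_starts, n_ok, tau_max, scale):
    theta_hat = 10.0 ** z_best[:-1]
    tau_hat = float(z_best[-1])
    at = []
    for i, name in enumerate(names + ["tau"]):
        span = max(hi_z[i] - lo_z[i], 1.0)
        if z_best[i] - lo_z[i] <= 1e-9 * span:
            if i < len(names):
                theta_hat[i] = lo_nat[i]
            else:
                tau_hat = 0.0
            at.append(f"{name}:lower")
        elif hi_z[i] - z_best[i] <= 1e-9 * span:
            if i < len(names):
                theta_hat[i] = hi_nat[i]
            else:
                tau_hat = tau_max
            at.append(f"{name}:upper")
    phi2 = max(float(cost_best), PHI2_FLOOR)
    is_exp = False
    if spec.family == "gompertz":
        is_exp = abs(theta_hat[names.index("b")] - B_FLOOR) <= _FLOOR_TOL
    return FitResult(
        track_id=series.track_id, spec=spec, theta_hat=theta_hat,
        tau_hat=tau_hat, phi2=phi2, sigma2_hat=phi2 / series.k,
        n_starts=n_starts, converged_fraction=n_ok / n_starts,
        K_hat=carrying_capacity(spec, theta_hat),
        is_exponential=is_exp, scale=scale, at_bounds=tuple(at),
    )


def _rng_from(seed):
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def fit_organoid(
    series: CellNumberSeries,
    spec: GrowthModelSpec,
    tau_max: float = 4.0,
    n_starts: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    scale: str = "linear",
) -> FitResult:
    """Fit one growth model to one organoid by multi-start bounded least
    squares over (theta, tau), starting from a single cell (N0 = 1).

    Deterministic given (series, spec, seed, n_starts); the best phi^2 is
    nonincreasing in n_starts because random starts form a sequential
    stream."""
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    if tau_max < 0:
        raise ValueError("tau_max must be nonnegative")
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    n_free = spec.n_free_params + 1
    if series.k < n_free:
        warnings.warn(
            f"{series.track_id}: {series.k} datapoints for {n_free} free "
            "parameters; the optimum is not unique", stacklevel=2,
        )
    names, lo_nat, hi_nat, lo_z, hi_z = _z_bounds(spec, tau_max)
    rng = _rng_from(seed)
    Z0 = _starts_for(series, spec, tau_max, n_starts, rng, lo_nat, hi_nat, lo_z, hi_z)
    days = series.days

    def t_fn(tau_col):
        return tau_col + days[None, :]

    Z, cost = _projected_lm(
        spec, 1.0, Z0, lo_z, hi_z, t_fn, series.counts[None, :], scale == "log"
    )
    n_ok = int(np.isfinite(cost).sum())
    best = int(np.argmin(cost))
    return _finalize(series, spec, names, lo_nat, hi_nat, lo_z, hi_z,
                     Z[best], cost[best], n_starts, n_ok, tau_max, scale)


def _substream(master_seed: int, track_id: str, model_index: int) -> np.random.SeedSequence:
    """Independent, order-invariant seed substream per (organoid, model)."""
    return np.random.SeedSequence(
        (int(master_seed), zlib.crc32(str(track_id).encode()), model_index)
    )


def fit_cohort(
    series_list: Sequence[CellNumberSeries],
    specs: Sequence[GrowthModelSpec] | None = None,
    tau_max: float = 4.0,
    n_starts: int = 1000,
    seed: int = 0,
    scale: str = "linear",
) -> list[FitResult]:
    """Fit every model in ``specs`` (default: the nine analysis variants)
    to every organoid.

    A master seed spawns one independent random substream per (organoid,
    model) pair, so results do not depend on iteration order, and
    organoids sharing a day grid are optimized as one vectorized batch.
    Results are identical to calling :func:`fit_organoid` per pair with
    the corresponding substream."""
    from .models import ANALYSIS_VARIANTS

    if specs is None:
        specs = ANALYSIS_VARIANTS
    results: dict[tuple[int, int], FitResult] = {}
    by_grid: dict[tuple, list[int]] = {}
    for i, s in enumerate(series_list):
        by_grid.setdefault(tuple(s.days), []).append(i)

    for j, spec in enumerate(specs):
        names, lo_nat, hi_nat, lo_z, hi_z = _z_bounds(spec, tau_max)
        for grid, idxs in by_grid.items():
            days = np.asarray(grid)
            Z0_rows, counts_rows = [], []
            for i in idxs:
                s = series_list[i]
                rng = _rng_from(_substream(seed, s.track_id, j))
                Z0_rows.append(_starts_for(
                    s, spec, tau_max, n_starts, rng, lo_nat, hi_nat, lo_z, hi_z
                ))
                counts_rows.append(np.repeat(s.counts[None, :], n_starts, axis=0))
            Z0 = np.concatenate(Z0_rows)
            counts = np.concatenate(counts_rows)

            def t_fn(tau_col):
                return tau_col + days[None, :]

            Z, cost = _projected_lm(
                spec, 1.0, Z0, lo_z, hi_z, t_fn, counts, scale == "log"
            )
            cost = cost.reshape(len(idxs), n_starts)
            Z = Z.reshape(len(idxs), n_starts, -1)
            for m, i in enumerate(idxs):
                best = int(np.argmin(cost[m]))
                n_ok = int(np.isfinite(cost[m]).sum())
                results[(i, j)] = _finalize(
                    series_list[i], spec, names, lo_nat, hi_nat, lo_z, hi_z,
                    Z[m, best], cost[m, best], n_starts, n_ok, tau_max, scale,
                )
    return [results[(i, j)] for i in range(len(series_list))
            for j in range(len(specs))]


def classify_exponential(fit: FitResult) -> bool:
    """True iff a Gompertz fit's decay rate b sits at its 1e-4 floor."""
    if fit.spec.family != "gompertz":
        raise ValueError("exponential classification applies to Gompertz fits")
    return abs(fit.params["b"] - B_FLOOR) <= _FLOOR_TOL
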