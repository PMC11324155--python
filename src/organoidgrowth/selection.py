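"""BIC-based ranking of growth models across a dataset.

For the additive-Gaussian error model with k datapoints per organoid and
p model parameters (counting the dormancy time tau; p = 2 for the
unconstrained exponential/power-law models, 3 for the constrained
Gompertz/logistic/von Bertalanffy models), the BIC with the error
variance profiled out is

    BIC = k (1 + log 2*pi) + k log(phi^2 / k) + (p + 1) log k,

with natural logarithms; the +1 counts the error s.d. sigma among the
estimated parameters.  The lowest mean BIC across organoids marks the
most parsimonious model.

A simpler, interpretable metric is the normalized fitting error: the sum
of squared residuals divided by the mean observed cell number of the
organoid.  Rankings also report each model's mean normalized error
relative to the Gompertz model's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import PHI2_FLOOR, CellNumberSeries, FitResult

__all__ = [
    "ModelRanking",
    "compute_bic",
    "bic_of_fit",
    "normalized_error",
    "normalized_error_of_fit",
    "rank_models",
]


@dataclass(frozen=True)
class ModelRanking:
    """Dataset-level mean BIC / mean normalized error per model."""

    table: pd.DataFrame  # index: model label; columns: mean_bic, mean_norm_error, rel_error_to_gompertz
    best_model: str
    n_organoids: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelRanking(best={self.best_model!r}, n={self.n_organoids})\n{self.table}"


def compute_bic(phi2: float, k: int, p: int) -> float:
    """BIC from the floored SSE phi^2, k datapoints, p model parameters
    (including tau; sigma adds the +1)."""
    if phi2 < PHI2_FLOOR:
        raise ValueError(f"phi2 must be floored at {PHI2_FLOOR} by the fitter")
    if k < 2:
        raise ValueError("k must be at least 2")
    if p not in (2, 3):
        raise ValueError("p must be 2 (unconstrained) or 3 (constrained)")
    return k * (1 + math.log(2 * math.pi)) + k * math.log(phi2 / k) + (p + 1) * math.log(k)


def _n_params(fit: FitResult) -> int:
    return fit.spec.n_free_params + 1  # + tau


def bic_of_fit(fit: FitResult, k: int) -> float:
    return compute_bic(fit.phi2, k, _n_params(fit))


def normalized_error(
    series: CellNumberSeries,
    predictions: Sequence[float],
    kind: str = "sse_over_mean",
) -> float:
    """Fit-quality metric normalized by the organoid's mean observed cell
    number (organoid sizes vary across orders of magnitude).

    The default divides the sum of squared residuals by the mean count.
    ``kind="rmse_over_mean"`` instead divides the root-mean-square residual
    by the mean count, a dimensionless relative error."""
    pred = np.asarray(predictions, dtype=float)
    if pred.shape != series.counts.shape:
        raise ValueError("predictions must align with the series days")
    resid = series.counts - pred
    sse = float(np.dot(resid, resid))
    if kind == "sse_over_mean":
        return sse / series.counts.mean()
    if kind == "rmse_over_mean":
        return math.sqrt(sse / series.k) / series.counts.mean()
    raise ValueError("kind must be 'sse_over_mean' or 'rmse_over_mean'")


def normalized_error_of_fit(fit: FitResult, series: CellNumberSeries) -> float:
    """Normalized error computed from a fit's floored phi^2 (linear scale)."""
    return float(fit.phi2 / series.counts.mean())


def rank_models(
    fits: Sequence[FitResult],
    series_list: Sequence[CellNumberSeries],
) -> ModelRanking:
    """Average BIC and normalized error across organoids per model and
    select the minimum-mean-BIC model.

    Requires a fit for every (organoid, model) combination present.  Ties
    in mean BIC are broken toward fewer parameters, then alphabetically.
    """
    by_id = {s.track_id: s for s in series_list}
    rows = []
    for f in fits:
        if f.track_id not in by_id:
            raise ValueError(f"no series for fitted track {f.track_id!r}")
        s = by_id[f.track_id]
        rows.append({
            "track_id": f.track_id,
            "model": f.spec.label,
            "p": _n_params(f),
            "bic": bic_of_fit(f, s.k),
            "norm_error": normalized_error_of_fit(f, s),
        })
    df = pd.DataFrame(rows)
    counts = df.groupby("model")["track_id"].nunique()
    n_org = df["track_id"].nunique()
    gaps = counts[counts != n_org]
    if len(gaps):
        raise ValueError(f"missing fits for some organoids: {dict(gaps)}")
    if df.duplicated(["track_id", "model"]).any():
        raise ValueError("duplicate (organoid, model) fits")

    agg = df.groupby("model").agg(
        mean_bic=("bic", "mean"),
        mean_norm_error=("norm_error", "mean"),
        p=("p", "first"),
    )
    if "gompertz" in agg.index:
        agg["rel_error_to_gompertz"] = (
            agg["mean_norm_error"] / agg.loc["gompertz", "mean_norm_error"]
        )
    else:
        agg["rel_error_to_gompertz"] = np.nan
    # parsimony tie-break: among minimal mean BIC, fewest parameters, then name
    min_bic = agg["mean_bic"].min()
    tied = agg[np.isclose(agg["mean_bic"], min_bic, rtol=0, atol=1e-12)]
    best_model = tied.reset_index().sort_values(["p", "model"]).iloc[0]["model"]
    table = agg.drop(columns="p")
    return ModelRanking(table=table, best_model=best_model, n_organoids=n_org)
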