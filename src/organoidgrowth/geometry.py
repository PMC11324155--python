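"""Area -> volume -> live-cell-number conversion.

A tracked organoid is observed as a 2-D projected area A (um^2).  Assuming
the organoid is an ellipsoid whose projection is an ellipse with axes a, b
(A = pi*a*b) and whose third axis is the geometric mean c = sqrt(a*b), the
volume is

    V = (4/3) * pi * a * b * c = (4 / (3 * sqrt(pi))) * A**(3/2).

Volumes are converted to live-cell estimates by dividing by a calibration
constant rho (um^3 per live cell); the default rho = 7208 um^3/cell is the
median Day-0 volume-per-cell ratio measured on a GFP-labelled reference
dataset with direct cell counts.  Cell-number estimates are kept as
positive reals: they enter the growth models as noisy continuous
measurements, not observed integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_RHO",
    "DEFAULT_COEFFICIENT",
    "CalibrationConstant",
    "EllipsoidAreaModel",
    "area_to_volume",
    "volume_to_cells",
    "cells_to_area",
    "area_to_cells",
    "estimate_calibration",
]

#: Default volume per live cell, um^3/cell.
DEFAULT_RHO = 7208.0

#: 4 / (3 sqrt(pi)): the ellipsoid coefficient in V = coeff * A^(3/2).
DEFAULT_COEFFICIENT = 4.0 / (3.0 * math.sqrt(math.pi))


@dataclass(frozen=True)
class CalibrationConstant:
    """Volume-per-live-cell calibration (um^3/cell)."""

    rho: float = DEFAULT_RHO
    source: str = "default_7208"
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.source not in ("default_7208", "estimated"):
            raise ValueError("source must be 'default_7208' or 'estimated'")


@dataclass(frozen=True)
class EllipsoidAreaModel:
    """Conversion V = conversion_coefficient * A^(3/2)."""

    conversion_coefficient: float = DEFAULT_COEFFICIENT

    def __post_init__(self) -> None:
        if self.conversion_coefficient <= 0:
            raise ValueError("conversion coefficient must be positive")


def area_to_volume(
    A: float | np.ndarray, model: EllipsoidAreaModel | None = None
) -> float | np.ndarray:
    """Projected area (um^2) to ellipsoid volume (um^3)."""
    model = model or EllipsoidAreaModel()
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("area must be nonnegative")
    out = model.conversion_coefficient * A**1.5
    return float(out) if out.ndim == 0 else out


def volume_to_cells(
    V: float | np.ndarray, cal: CalibrationConstant | None = None
) -> float | np.ndarray:
    """Volume (um^3) to estimated live-cell count (positive real)."""
    cal = cal or CalibrationConstant()
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("volume must be nonnegative")
    out = V / cal.rho
    return float(out) if out.ndim == 0 else out


def area_to_cells(
    A: float | np.ndarray,
    cal: CalibrationConstant | None = None,
    model: EllipsoidAreaModel | None = None,
) -> float | np.ndarray:
    """Convenience chain area -> volume -> cells."""
    return volume_to_cells(area_to_volume(A, model), cal)


def cells_to_area(
    n: float | np.ndarray,
    cal: CalibrationConstant | None = None,
    model: EllipsoidAreaModel | None = None,
) -> float | np.ndarray:
    """Exact inverse of the area -> cells chain: A = (n*rho/coeff)^(2/3)."""
    cal = cal or CalibrationConstant()
    model = model or EllipsoidAreaModel()
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("cell count must be nonnegative")
    out = (n * cal.rho / model.conversion_coefficient) ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def estimate_calibration(
    pairs: Iterable[Sequence[float]],
) -> CalibrationConstant:
    """Median volume/cell ratio over paired (volume um^3, live-cell count)
    observations, typically taken on the first imaging day."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one (volume, count) pair is required")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (volume, count) 2-tuples")
    if np.any(arr <= 0):
        raise ValueError("volumes and counts must be positive")
    ratios = arr[:, 0] / arr[:, 1]
    return CalibrationConstant(
        rho=float(np.median(ratios)), source="estimated", n_pairs=len(ratios)
    )
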