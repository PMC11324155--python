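"""Quality-control cascade for tracked organoid objects.

Tracked objects exported by the imaging step include dead objects, small
cell clusters and debris, shrinking tracks, and occasional segmentation
errors (two overlapping organoids merged into one track, or one organoid
split into several).  Before growth models are fit, tracks pass a
sequential filter cascade:

1. remove objects classified dead on any observation day after the first;
2. remove objects whose projected area falls below ``min_area`` (default
   300 um^2) on any observation day;
3. remove objects whose estimated cell number is not strictly increasing
   between every consecutive pair of days (the models describe growing
   organoids);
4. optionally remove objects flagged by the segmentation-artifact
   heuristic (off by default).

Each stage sees only the survivors of the previous stage, so the per-stage
removal counts in the :class:`FilterReport` sum exactly to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fitting import CellNumberSeries
from .geometry import CalibrationConstant, EllipsoidAreaModel, area_to_cells

__all__ = [
    "DEFAULT_MIN_AREA",
    "OrganoidTrack",
    "FilterReport",
    "ArtifactParams",
    "apply_filters",
    "flag_segmentation_artifacts",
]

#: Minimum projected area (um^2) for an object to count as an organoid.
DEFAULT_MIN_AREA = 300.0


@dataclass(frozen=True)
class OrganoidTrack:
    """One tracked object's time series of areas, viability and position."""

    track_id: str
    days: np.ndarray
    areas: np.ndarray
    alive: np.ndarray
    position: np.ndarray | None = None
    morphology: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        alive = np.asarray(self.alive, dtype=bool)
        if days.ndim != 1 or areas.shape != days.shape or alive.shape != days.shape:
            raise ValueError("days, areas and alive must be matching 1-D arrays")
        if days.size > 1 and not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(areas < 0):
            raise ValueError("areas must be nonnegative")
        pos = self.position
        if pos is not None:
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (days.size, 2):
                raise ValueError("position must be (n_days, 2)")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "alive", alive)
        object.__setattr__(self, "position", pos)

    def to_series(
        self,
        cal: CalibrationConstant | None = None,
        model: EllipsoidAreaModel | None = None,
    ) -> CellNumberSeries:
        counts = np.maximum(area_to_cells(self.areas, cal, model), 1e-12)
        return CellNumberSeries(self.track_id, self.days, counts)


@dataclass(frozen=True)
class FilterReport:
    """Per-stage accounting of the filter cascade."""

    input: int
    removed_dead: int
    removed_small: int
    removed_nonmonotone: int
    removed_artifact: int
    retained: int

    def __post_init__(self) -> None:
        removed = (
            self.removed_dead
            + self.removed_small
            + self.removed_nonmonotone
            + self.removed_artifact
        )
        if self.input != self.retained + removed:
            raise ValueError("filter report counts do not sum to the input count")

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "removed_dead": self.removed_dead,
            "removed_small": self.removed_small,
            "removed_nonmonotone": self.removed_nonmonotone,
            "removed_artifact": self.removed_artifact,
            "retained": self.retained,
        }


@dataclass(frozen=True)
class ArtifactParams:
    """Thresholds for the segmentation-artifact heuristic."""

    jump_ratio: float = 20.0
    max_displacement: float = 100.0

    def __post_init__(self) -> None:
        if self.jump_ratio <= 1:
            raise ValueError("jump_ratio must exceed 1")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")


def flag_segmentation_artifacts(
    tracks: Sequence[OrganoidTrack],
    jump_ratio: float = 20.0,
    max_displacement: float = 100.0,
) -> set[str]:
    """Flag tracks consistent with merge/split segmentation errors.

    A track is flagged if its area changes by more than ``jump_ratio``-fold
    between consecutive days (in either direction) or its centroid moves
    more than ``max_displacement`` um between consecutive days.
    """
    params = ArtifactParams(jump_ratio, max_displacement)
    flagged: set[str] = set()
    for tr in tracks:
        a = np.maximum(tr.areas, 1e-12)
        ratios = a[1:] / a[:-1]
        if np.any(np.maximum(ratios, 1.0 / ratios) > params.jump_ratio):
            flagged.add(tr.track_id)
            continue
        if tr.position is not None:
            step = np.linalg.norm(np.diff(tr.position, axis=0), axis=1)
            if np.any(step > params.max_displacement):
                flagged.add(tr.track_id)
    return flagged


def apply_filters(
    tracks: Sequence[OrganoidTrack],
    min_area: float = DEFAULT_MIN_AREA,
    series: Sequence[CellNumberSeries] | None = None,
    artifact_params: ArtifactParams | None = None,
) -> tuple[list[OrganoidTrack], FilterReport]:
    """Run the sequential filter cascade and account for every removal.

    ``series`` supplies the estimated cell numbers used by the monotone
    stage; when omitted they are derived from the areas with the default
    calibration (equivalent for the default conversion, which is strictly
    increasing in area).  The artifact stage runs only when
    ``artifact_params`` is given.
    """
    if series is not None:
        if len(series) != len(tracks):
            raise ValueError("series must align one-to-one with tracks")
        by_id = {s.track_id: s for s in series}
        missing = [t.track_id for t in tracks if t.track_id not in by_id]
        if missing:
            raise ValueError(f"series missing for tracks: {missing[:5]}")
    else:
        by_id = {t.track_id: t.to_series() for t in tracks}

    n_input = len(tracks)

    survivors = [t for t in tracks if bool(np.all(t.alive[1:]))]
    n_dead = n_input - len(survivors)

    after_small = [t for t in survivors if bool(np.all(t.areas >= min_area))]
    n_small = len(survivors) - len(after_small)

    after_mono = [
        t
        for t in after_small
        if bool(np.all(np.diff(by_id[t.track_id].counts) > 0))
    ]
    n_mono = len(after_small) - len(after_mono)

    n_artifact = 0
    retained = after_mono
    if artifact_params is not None:
        flagged = flag_segmentation_artifacts(
            after_mono,
            artifact_params.jump_ratio,
            artifact_params.max_displacement,
        )
        retained = [t for t in after_mono if t.track_id not in flagged]
        n_artifact = len(after_mono) - len(retained)

    report = FilterReport(
        input=n_input,
        removed_dead=n_dead,
        removed_small=n_small,
        removed_nonmonotone=n_mono,
        removed_artifact=n_artifact,
        retained=len(retained),
    )
    return retained, report
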