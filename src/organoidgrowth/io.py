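"""Reading/writing tracking tables and results; pipeline orchestration.

The interchange format is a long-format CSV (one row per tracked object
per observation day) with columns ``track_id, day, area_um2, alive, x, y``
plus optional morphology columns; spreadsheet (.xlsx) input is also
accepted.  Every output file carries a small ``#``-prefixed metadata
header (tool version, master seed, config hash) so runs are traceable,
and floats are written with 12 significant digits so identical runs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .filtering import ArtifactParams, OrganoidTrack, apply_filters
from .fitting import FitResult, fit_cohort
from .geometry import CalibrationConstant, EllipsoidAreaModel
from .heterogeneity import summarize_cohort
from .models import ANALYSIS_VARIANTS
from .projection import project_cohort, sample_parameter_sets
from .selection import rank_models
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger("organoidgrowth")

__all__ = [
    "REQUIRED_COLUMNS",
    "MORPHOLOGY_COLUMNS",
    "read_tracking_table",
    "tracks_to_table",
    "fits_to_frame",
    "write_results",
    "read_results",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("track_id", "day", "area_um2", "alive", "x", "y")
MORPHOLOGY_COLUMNS = ("sphericity", "shape_factor", "convexity")


def _read_any(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path, comment="#")


def read_tracking_table(
    path: str | Path, schema: Sequence[float] | None = None
) -> list[OrganoidTrack]:
    """Read and validate a long-format tracking table into tracks.

    ``schema`` is the expected day grid; every track must have exactly
    those observation days.
    """
    df = _read_any(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracking table missing required columns: {missing}")
    if df.duplicated(["track_id", "day"]).any():
        dup = df[df.duplicated(["track_id", "day"])].iloc[0]
        raise ValueError(
            f"duplicate (track_id, day) pair: ({dup['track_id']}, {dup['day']})"
        )
    for col in ("day", "area_um2", "x", "y"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(df.index[bad][0]) + 2  # 1-based, after header
            raise ValueError(f"unparseable {col!r} near line {line}") from exc
    if (df["area_um2"] < 0).any():
        raise ValueError("areas must be nonnegative")
    schema_arr = None if schema is None else np.asarray(sorted(schema), float)

    tracks = []
    morph_cols = [c for c in MORPHOLOGY_COLUMNS if c in df.columns]
    for tid, g in df.sort_values("day").groupby("track_id", sort=True):
        days = g["day"].to_numpy(float)
        if schema_arr is not None and (
            days.size != schema_arr.size or not np.allclose(days, schema_arr)
        ):
            raise ValueError(
                f"track {tid!r} has days {days.tolist()}, expected "
                f"{schema_arr.tolist()}"
            )
        tracks.append(OrganoidTrack(
            track_id=str(tid),
            days=days,
            areas=g["area_um2"].to_numpy(float),
            alive=g["alive"].astype(bool).to_numpy(),
            position=g[["x", "y"]].to_numpy(float),
            morphology={c: g[c].to_numpy(float) for c in morph_cols} or None,
        ))
    return tracks


def tracks_to_table(tracks: Sequence[OrganoidTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i, d in enumerate(tr.days):
            row = {
                "track_id": tr.track_id, "day": d, "area_um2": tr.areas[i],
                "alive": bool(tr.alive[i]),
                "x": tr.position[i, 0] if tr.position is not None else 0.0,
                "y": tr.position[i, 1] if tr.position is not None else 0.0,
            }
            if tr.morphology:
                for cname, vals in tr.morphology.items():
                    row[cname] = vals[i]
            rows.append(row)
    return pd.DataFrame(rows)


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """One row per (organoid, model) fit."""
    rows = []
    for f in fits:
        row = {
            "track_id": f.track_id, "model": f.spec.label,
            "tau_hat": f.tau_hat, "phi2": f.phi2,
            "sigma2_hat": f.sigma2_hat, "K_hat": f.K_hat,
            "is_exponential": f.is_exponential, "n_starts": f.n_starts,
            "converged_fraction": f.converged_fraction, "scale": f.scale,
            "at_bounds": ";".join(f.at_bounds),
        }
        for name, value in f.params.items():
            row[f"param_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def _metadata_header(seed, config) -> str:
    cfg_hash = ""
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        cfg_hash = hashlib.sha256(blob).hexdigest()[:16]
    lines = [f"# organoidgrowth {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash:
        lines.append(f"# config_hash: {cfg_hash}")
    return "\n".join(lines) + "\n"


def write_results(
    obj: pd.DataFrame | dict,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a result table (CSV) or report (JSON) with a metadata header.

    Floats in CSVs are written with 12 significant digits; identical
    seed/config give byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = _metadata_header(seed, config)
    if isinstance(obj, pd.DataFrame):
        buf = _io.StringIO()
        obj.to_csv(buf, index=False, float_format="%.12g")
        path.write_text(header + buf.getvalue())
    else:
        meta = {"tool": f"organoidgrowth {__version__}", "seed": seed}
        path.write_text(json.dumps({"metadata": meta, "results": obj},
                                   indent=2, default=str) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(
    config: CohortConfig | None = None,
    tracks: Sequence[OrganoidTrack] | None = None,
    outdir: str | Path | None = None,
    min_area: float = 300.0,
    artifact_params: ArtifactParams | None = None,
    calibration: CalibrationConstant | None = None,
    area_model: EllipsoidAreaModel | None = None,
    n_starts: int = 1000,
    seed: int = 0,
    scale: str = "linear",
    projection_samples: int = 100_000,
) -> dict:
    """Run simulate -> filter -> convert -> fit -> rank -> heterogeneity ->
    project (starting from provided tracks when given) and return all
    artifacts; optionally write them under ``outdir``.
    """
    artifacts: dict = {}
    if tracks is None:
        if config is None:
            config = CohortConfig(seed=seed)
        config.validate()
        tracks, truth = generate_cohort(config)
        artifacts["truth"] = truth
        logger.info("simulate: %d objects", len(tracks))
    tau_max = config.tau_max if config is not None else 4.0

    retained, report = apply_filters(tracks, min_area=min_area,
                                     artifact_params=artifact_params)
    logger.info("filter: %s", report.as_dict())
    artifacts["filter_report"] = report

    series = [t.to_series(calibration, area_model) for t in retained]
    artifacts["series"] = series

    fits = fit_cohort(series, ANALYSIS_VARIANTS, tau_max=tau_max,
                      n_starts=n_starts, seed=seed, scale=scale)
    artifacts["fits"] = fits
    logger.info("fit: %d results", len(fits))

    artifacts["ranking"] = rank_models(fits, series)
    gomp = [f for f in fits if f.spec.family == "gompertz"]
    artifacts["heterogeneity"] = summarize_cohort(gomp, tau_max=tau_max)
    samples = sample_parameter_sets(gomp, n=projection_samples, seed=seed)
    artifacts["projection"] = project_cohort(samples, seed=seed)

    if outdir is not None:
        outdir = Path(outdir)
        cfg = config.__dict__ if config is not None else None
        write_results(tracks_to_table(tracks), outdir / "tracks.csv", seed, cfg)
        if "truth" in artifacts:
            write_results(artifacts["truth"], outdir / "truth.csv", seed, cfg)
        write_results(dict(artifacts["filter_report"].as_dict()),
                      outdir / "filter_report.json", seed, cfg)
        write_results(fits_to_frame(fits), outdir / "fits.csv", seed, cfg)
        write_results(artifacts["ranking"].table.reset_index(),
                      outdir / "ranking.csv", seed, cfg)
        write_results(artifacts["heterogeneity"].as_dict(),
                      outdir / "heterogeneity.json", seed, cfg)
        proj = artifacts["projection"]
        write_results(
            pd.DataFrame({"day": proj.days, "median": proj.median,
                          "p5": proj.lower, "p95": proj.upper}),
            outdir / "projection.csv", seed, cfg)
    return artifacts
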