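"""File I/O: TIFF stacks, CSV traces and tables, JSON models and reports.

All intermediates are plain text or TIFF so every stage is independently
inspectable.  Conventions (written into file headers where possible):
time columns in seconds, diameters in micrometers, velocities in mm/s.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .behavior import BehaviorSegmentation, TriggeredAverage
from .diameter import DiameterTrace, VesselMovie
from .errors import InvalidParameterError
from .linescan import LinescanImage, VelocityEstimate

__all__ = [
    "write_movie",
    "read_movie",
    "write_linescan",
    "read_linescan",
    "write_trace_csv",
    "read_trace_csv",
    "write_diameter_trace",
    "read_diameter_trace",
    "write_velocity_estimates",
    "write_segmentation",
    "read_segmentation",
    "write_lta",
    "write_cohort",
    "read_cohort",
    "write_json",
    "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"input file not found: {path}")
    return json.loads(path.read_text())


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_movie(path: str | Path, movie: VesselMovie) -> Path:
    """TIFF stack plus a JSON sidecar with calibration and ground truth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    write_json(_sidecar(path), {
        "pixel_size_um": movie.pixel_size,
        "frame_rate_hz": movie.frame_rate,
        "vessel_class": movie.vessel_class,
        "roi": movie.roi,
        "axis_line": movie.axis_line,
        "ground_truth": movie.ground_truth,
    })
    return path


def read_movie(path: str | Path) -> VesselMovie:
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"input file not found: {path}")
    frames = tifffile.imread(path)
    meta = read_json(_sidecar(path))
    axis = meta.get("axis_line")
    return VesselMovie(
        frames=np.asarray(frames, dtype=float),
        pixel_size=meta["pixel_size_um"],
        frame_rate=meta["frame_rate_hz"],
        vessel_class=meta.get("vessel_class", "pial"),
        roi=tuple(meta["roi"]) if meta.get("roi") else None,
        axis_line=tuple(map(tuple, axis)) if axis else None,
        ground_truth=meta.get("ground_truth"),
    )


def write_linescan(path: str | Path, scan: LinescanImage) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, scan.image.astype(np.float32))
    write_json(_sidecar(path), {
        "pixel_size_um": scan.pixel_size,
        "line_rate_hz": scan.line_rate,
        "metadata": scan.metadata,
        "ground_truth": scan.ground_truth,
    })
    return path


def read_linescan(path: str | Path) -> LinescanImage:
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"input file not found: {path}")
    image = tifffile.imread(path)
    meta = read_json(_sidecar(path))
    return LinescanImage(
        image=np.asarray(image, dtype=float),
        pixel_size=meta["pixel_size_um"],
        line_rate=meta["line_rate_hz"],
        ground_truth=meta.get("ground_truth"),
    )


# ---------------------------------------------------------------------------
# traces and tables
# ---------------------------------------------------------------------------

def write_trace_csv(path: str | Path, times: np.ndarray, values: np.ndarray,
                    value_name: str = "value") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": times, value_name: values}).to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"input file not found: {path}")
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_diameter_trace(path: str | Path, trace: DiameterTrace) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = trace.values.size
    pd.DataFrame({
        "frame": np.arange(n),
        "time_s": trace.times,
        "diameter_um": trace.values,
        "despiked": trace.despiked_mask.astype(int),
    }).to_csv(path, index=False)
    return path


def read_diameter_trace(path: str | Path, frame_rate: float | None = None) -> DiameterTrace:
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"input file not found: {path}")
    df = pd.read_csv(path)
    if frame_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        frame_rate = 1.0 / float(np.median(dt))
    return DiameterTrace(
        values=df["diameter_um"].to_numpy(float),
        frame_rate=frame_rate,
        despiked_mask=df["despiked"].to_numpy(bool) if "despiked" in df else None,
    )


def write_velocity_estimates(path: str | Path, estimates: list[VelocityEstimate]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        {"window_start_s": e.window_start, "velocity_mm_s": e.velocity,
         "angle_deg": e.angle, "separability": e.separability}
        for e in estimates
    ]).to_csv(path, index=False)
    return path


def write_segmentation(path: str | Path, seg: BehaviorSegmentation) -> Path:
    return write_json(path, {
        "sample_rate_hz": seg.sample_rate,
        "events_s": seg.events,
        "stationary_periods_s": seg.stationary_periods,
    })


def read_segmentation(path: str | Path, n_samples: int) -> BehaviorSegmentation:
    meta = read_json(path)
    fs = meta["sample_rate_hz"]
    moving = np.zeros(n_samples, dtype=bool)
    for a, b in meta["events_s"]:
        moving[int(a * fs) : int(b * fs)] = True
    return BehaviorSegmentation(
        moving=moving, sample_rate=fs,
        events=[tuple(e) for e in meta["events_s"]],
        stationary_periods=[tuple(p) for p in meta["stationary_periods_s"]],
    )


def write_lta(path: str | Path, lta: TriggeredAverage) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "rel_time_s": lta.rel_time,
        "mean": lta.mean,
        "sem": lta.sem,
        "n": lta.n_events,
    }).to_csv(path, index=False)
    return path


def write_cohort(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"input file not found: {path}")
    return pd.read_csv(path)
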