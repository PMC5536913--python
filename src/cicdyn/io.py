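"""Reading and writing of the pipeline's file formats.

Space-time matrices travel as CSV: first column ``position`` holds the
fractional egg-length grid, remaining columns are one frame each with the
frame time in minutes as header (UTF-8, '.' decimal).  Movies travel as
multi-frame grayscale TIFF stacks, one embryo per file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import EmbryoMovie, SpaceTimeMatrix


def write_space_time_csv(stm: SpaceTimeMatrix, path) -> None:
    df = pd.DataFrame(stm.values, columns=[f"{t:.6g}" for t in stm.times])
    df.insert(0, "position", stm.positions)
    df.to_csv(path, index=False)


def read_space_time_csv(path) -> SpaceTimeMatrix:
    df = pd.read_csv(path)
    if "position" not in df.columns:
        raise ValueError("space-time CSV must have a 'position' column")
    positions = df.pop("position").to_numpy(dtype=float)
    times = np.array([float(c) for c in df.columns])
    return SpaceTimeMatrix(values=df.to_numpy(dtype=float), positions=positions,
                           times=times)


def write_movie_tiff(movie: EmbryoMovie, path) -> None:
    tifffile.imwrite(
        path,
        movie.frames.astype(np.float32),
        metadata={"frame_interval_s": movie.frame_interval},
    )


def read_movie_tiff(path, frame_interval: float = 30.0) -> EmbryoMovie:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        meta = tif.shaped_metadata
        if meta and "frame_interval_s" in meta[0]:
            frame_interval = float(meta[0]["frame_interval_s"])
    return EmbryoMovie(frames=np.clip(frames, 0.0, None),
                       frame_interval=frame_interval)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results_json(results: dict, path) -> None:
    """Per-embryo analysis results (singular values, accuracy ratio,
    lambda fit, recovery tau, ...) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(results), indent=2))


def read_results_json(path) -> dict:
    return json.loads(Path(path).read_text())
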