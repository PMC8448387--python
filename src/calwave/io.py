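"""Reading and writing movies, z-stacks, and result tables.

Movies and stacks travel as multi-page 16-bit grayscale TIFFs with a JSON
sidecar carrying the acquisition metadata (frame interval, pixel size,
stimulus frame and site; voxel size for stacks).  The co-label channel is a
separate single-page TIFF.  Tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .wave import Movie


def _to_uint16(a: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(a), 0, 65535).astype(np.uint16)


def save_movie(movie: Movie, path: str | Path) -> None:
    """Write ``<path>.tif``, ``<path>.json`` and, if present, ``<path>_ch2.tif``."""
    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"), _to_uint16(movie.frames))
    meta = {"frame_interval": movie.frame_interval,
            "pixel_size": movie.pixel_size,
            "stim_frame": movie.stim_frame,
            "stim_site": list(movie.stim_site)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if movie.channel2 is not None:
        tifffile.imwrite(path.parent / (path.stem + "_ch2.tif"),
                         _to_uint16(movie.channel2))


def load_movie(path: str | Path) -> Movie:
    """Load a movie written by :func:`save_movie`."""
    path = Path(path)
    frames = tifffile.imread(path.with_suffix(".tif")).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    ch2_path = path.parent / (path.stem + "_ch2.tif")
    channel2 = (tifffile.imread(ch2_path).astype(np.float64)
                if ch2_path.exists() else None)
    return Movie(frames=frames, frame_interval=meta["frame_interval"],
                 pixel_size=meta["pixel_size"], stim_frame=meta["stim_frame"],
                 stim_site=tuple(meta["stim_site"]), channel2=channel2)


def save_stack(stack: np.ndarray, voxel_size: float, path: str | Path) -> None:
    """Write a z-stack TIFF with a voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"), _to_uint16(stack))
    path.with_suffix(".json").write_text(
        json.dumps({"voxel_size": voxel_size}))


def load_stack(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    stack = tifffile.imread(path.with_suffix(".tif")).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return stack, meta["voxel_size"]


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
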