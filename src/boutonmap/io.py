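"""File-format boundaries: TIFF movies, JSON protocols, CSV tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .stimuli import StimulusGrid, StimulusSchedule
from .synth import MovieStack

__all__ = [
    "write_movie",
    "read_movie",
    "write_label_image",
    "read_label_image",
    "write_json",
    "read_json",
    "sha256_file",
]


def write_movie(path: str | Path, movie: MovieStack) -> None:
    """Multi-page TIFF; the frame rate travels in the ImageJ metadata."""
    tifffile.imwrite(
        path,
        np.asarray(movie.frames, np.float32),
        imagej=True,
        metadata={"axes": "TYX", "finterval": 1.0 / movie.frame_rate},
    )


def read_movie(path: str | Path, frame_rate: float | None = None) -> MovieStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        if frame_rate is None:
            meta = tf.imagej_metadata or {}
            finterval = meta.get("finterval")
            frame_rate = 1.0 / finterval if finterval else 30.0
    return MovieStack(frames, frame_rate=frame_rate)


def write_label_image(path: str | Path, label_image: np.ndarray) -> None:
    tifffile.imwrite(path, label_image.astype(np.int32))


def read_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_grid(path: str | Path, grid: StimulusGrid) -> None:
    Path(path).write_text(grid.to_json() + "\n")


def read_grid(path: str | Path) -> StimulusGrid:
    return StimulusGrid.from_json(Path(path).read_text())


def write_schedule(path: str | Path, schedule: StimulusSchedule) -> None:
    Path(path).write_text(schedule.to_json() + "\n")


def read_schedule(path: str | Path) -> StimulusSchedule:
    return StimulusSchedule.from_json(Path(path).read_text())
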