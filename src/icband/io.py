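"""File formats: multi-page TIFF movies, TIFF label masks, CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import MovieStack, RoiMaskSet
from .preprocess import MotionTrace


def write_movie(path: str | Path, movie: MovieStack) -> None:
    tifffile.imwrite(path, movie.data.astype(np.float32),
                     metadata={"frame_rate": movie.frame_rate,
                               "steps": list(movie.steps)})


def read_movie(path: str | Path, frame_rate: float | None = None) -> MovieStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frame_rate is None:
        frame_rate = float(meta.get("frame_rate", 10.0))
    return MovieStack(np.asarray(data, dtype=np.float64), frame_rate=frame_rate,
                      steps=tuple(meta.get("steps", ())))


def write_masks(path: str | Path, masks: RoiMaskSet) -> None:
    tifffile.imwrite(path, masks.labels.astype(np.uint8))


def read_masks(path: str | Path) -> RoiMaskSet:
    return RoiMaskSet(tifffile.imread(path).astype(np.int8))


def write_motion(path: str | Path, motion: MotionTrace) -> None:
    motion.table.to_csv(path, index=False)


def read_motion(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path)
    trace = MotionTrace(df[["dy", "dx"]].to_numpy())
    return trace


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
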