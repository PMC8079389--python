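"""Core containers shared by every analysis stage.

A movie is stored frames-first, ``(n_frames, n_rows, n_cols)``, at a fixed
frame rate.  Region masks are a single integer label image: 0 marks pixels
excluded from all analysis, and the named labels below mark the left and
right inferior-colliculus (IC) hemispheres plus the surrounding
"outside-ROI" region whose mean trace serves as the control regressor in
partial-correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Mask labels.  OUTSIDE is retained through masking because its mean trace
#: is the control regressor for partial correlations.
LEFT, RIGHT, OUTSIDE = 1, 2, 3


def frame_window(first: int, last: int) -> slice:
    """Translate a 1-based inclusive frame window into a Python slice.

    Published frame windows such as "frames 11-15" count frames from 1;
    internally frames are 0-based, so ``frame_window(11, 15)`` is
    ``slice(10, 15)`` (five frames).
    """
    if first < 1 or last < first:
        raise ValueError(f"invalid 1-based frame window ({first}, {last})")
    return slice(first - 1, last)


@dataclass
class MovieStack:
    """Fluorescence movie: raw a.u. or ΔF/F0 after normalization.

    ``steps`` records the preprocessing provenance; each pipeline stage
    refuses to run twice on the same stack.
    """

    data: np.ndarray  # (n_frames, n_rows, n_cols), float
    frame_rate: float = 10.0
    steps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be (frames, rows, cols)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_frames / self.frame_rate

    def with_data(self, data: np.ndarray, step: str | None = None) -> "MovieStack":
        steps = self.steps + (step,) if step else self.steps
        return MovieStack(data, frame_rate=self.frame_rate, steps=steps)

    def require_not_done(self, step: str) -> None:
        if step in self.steps:
            raise RuntimeError(f"preprocessing step {step!r} already applied")


@dataclass
class RoiMaskSet:
    """Labeled region masks on the movie's pixel grid."""

    labels: np.ndarray  # (n_rows, n_cols) int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D image")

    @property
    def left(self) -> np.ndarray:
        return self.labels == LEFT

    @property
    def right(self) -> np.ndarray:
        return self.labels == RIGHT

    @property
    def outside(self) -> np.ndarray:
        return self.labels == OUTSIDE

    @property
    def ic(self) -> np.ndarray:
        """Both IC hemispheres."""
        return self.left | self.right

    @property
    def analyzed(self) -> np.ndarray:
        """All pixels kept by masking (IC plus the outside-ROI control)."""
        return self.labels > 0

    def hemisphere(self, side: str) -> np.ndarray:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        raise ValueError(f"unknown hemisphere {side!r}")

    def midline_col(self) -> float:
        """Column coordinate of the vertical mirror axis of the hemispheres.

        The axis sits halfway between the column centroids of the two
        hemisphere masks; for exactly mirror-symmetric masks this recovers
        the true midline.
        """
        if not self.left.any() or not self.right.any():
            raise ValueError("both hemisphere masks must be non-empty")
        cl = np.nonzero(self.left)[1].mean()
        cr = np.nonzero(self.right)[1].mean()
        return (cl + cr) / 2.0

    def mirrored(self, mask: np.ndarray) -> np.ndarray:
        """Reflect a boolean mask across the detected midline."""
        rows, cols = np.nonzero(mask)
        mcols = np.round(2.0 * self.midline_col() - cols).astype(int)
        ok = (mcols >= 0) & (mcols < self.labels.shape[1])
        out = np.zeros_like(mask, dtype=bool)
        out[rows[ok], mcols[ok]] = True
        return out


__all__ = [
    "LEFT",
    "RIGHT",
    "OUTSIDE",
    "MovieStack",
    "RoiMaskSet",
    "frame_window",
    "replace",
    "field",
]
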