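"""Seven-step movie preprocessing chain.

Order: (1) photobleach correction, (2) subpixel rigid registration,
(3) Gaussian smoothing, (4) ROI masking and (5) 2x2 average-pooling,
(6) SVD denoising, (7) ΔF/F0 normalization against a per-pixel 5th-
percentile baseline.  Masked-out pixels become NaN and every later
statistic ignores them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, ndimage
from skimage.registration import phase_cross_correlation

from .core import MovieStack, RoiMaskSet

log = logging.getLogger(__name__)

#: Frames whose registration shift exceeds this amplitude (px) are treated
#: as motion-corrupted and excluded from correlations and event summaries.
MOTION_THRESHOLD_PX = 0.5


@dataclass
class BleachFit:
    """Single-term exponential fit A·exp(-t/τ) to the frame-mean trace."""

    amplitude: float
    tau_frames: float        # inf when degenerate
    residual_rms: float
    degenerate: bool = False

    @property
    def rate(self) -> float:
        return 0.0 if self.degenerate else 1.0 / self.tau_frames


class MotionTrace:
    """Per-frame registration shifts with a corrupted-frame flag."""

    def __init__(self, shifts: np.ndarray, threshold: float = MOTION_THRESHOLD_PX):
        shifts = np.asarray(shifts, dtype=float)
        amp = np.hypot(shifts[:, 0], shifts[:, 1])
        self.table = pd.DataFrame({
            "frame": np.arange(len(shifts)),
            "dy": shifts[:, 0],
            "dx": shifts[:, 1],
            "amplitude": amp,
            "corrupted": amp > threshold,
        })
        self.threshold = threshold

    @property
    def shifts(self) -> np.ndarray:
        return self.table[["dy", "dx"]].to_numpy()

    @property
    def corrupted(self) -> np.ndarray:
        return self.table["corrupted"].to_numpy()

    @classmethod
    def clean(cls, n_frames: int) -> "MotionTrace":
        return cls(np.zeros((n_frames, 2)))


def correct_photobleach(movie: MovieStack) -> tuple[MovieStack, BleachFit]:
    """Divide out a single-exponential bleaching trend.

    The trend f(t) = A·exp(-t/τ) is fit to the frame-mean fluorescence by
    log-linear least squares; each frame is divided by f(t)/f(0), so the
    frame-0 intensity scale is preserved.  A non-decaying trace makes the
    fit degenerate and the movie is returned unchanged with a flag.
    """
    movie.require_not_done("photobleach")
    if movie.n_frames < 10:
        raise ValueError("photobleach correction needs at least 10 frames")
    m = np.nanmean(movie.data, axis=(1, 2))
    if np.any(m <= 0):
        raise ValueError("frame means must be positive for the exponential fit")
    t = np.arange(movie.n_frames, dtype=float)
    slope, intercept = np.polyfit(t, np.log(m), 1)
    if slope >= 0:
        log.warning("frame-mean trace is not decaying; bleach fit degenerate")
        fit = BleachFit(amplitude=float(m[0]), tau_frames=np.inf,
                        residual_rms=0.0, degenerate=True)
        return movie.with_data(movie.data.copy(), "photobleach"), fit
    tau = -1.0 / slope
    amp = float(np.exp(intercept))
    trend = amp * np.exp(-t / tau)
    resid = float(np.sqrt(np.mean((m - trend) ** 2)))
    corrected = movie.data * (trend[0] / trend)[:, None, None]
    return movie.with_data(corrected, "photobleach"), BleachFit(amp, float(tau), resid)


def register_frames(
    movie: MovieStack,
    reference: int | None = None,
    upsample_factor: int = 50,
    threshold: float = MOTION_THRESHOLD_PX,
) -> tuple[MovieStack, MotionTrace]:
    """Subpixel rigid registration by Fourier phase correlation.

    Each frame is registered against the session-mean frame (or the given
    reference frame index).  Frames are mean-subtracted and Hann-windowed
    before correlation to suppress boundary leakage, then shifted with
    edge-replicating cubic interpolation.  Frames moving more than
    ``threshold`` px are flagged corrupted for downstream exclusion.
    """
    movie.require_not_done("register")
    if reference is not None and not 0 <= reference < movie.n_frames:
        raise ValueError("reference frame out of range")
    ref = movie.data[reference] if reference is not None else movie.data.mean(axis=0)
    window = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    ref_w = (ref - ref.mean()) * window
    out = np.empty_like(movie.data, dtype=np.float64)
    shifts = np.zeros((movie.n_frames, 2))
    for i in range(movie.n_frames):
        frame = movie.data[i]
        if not frame.any() or frame.std() == 0:
            out[i] = frame  # no structure to register against
            continue
        shift, _, _ = phase_cross_correlation(ref_w, (frame - frame.mean()) * window,
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        shifts[i] = shift
        out[i] = ndimage.shift(frame, shift, order=3, mode="nearest") if shift.any() else frame
    trace = MotionTrace(shifts, threshold=threshold)
    return movie.with_data(out, "register"), trace


def smooth_frames(movie: MovieStack, sigma: float = 1.0) -> MovieStack:
    """Per-frame 2-D Gaussian smoothing with a normalized kernel."""
    movie.require_not_done("smooth")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = ndimage.gaussian_filter(movie.data.astype(np.float64),
                                  sigma=(0, sigma, sigma), truncate=4.0)
    return movie.with_data(out, "smooth")


def mask_and_downsample(
    movie: MovieStack, masks: RoiMaskSet
) -> tuple[MovieStack, RoiMaskSet]:
    """Apply the ROI mask and average-pool 2x2 blocks.

    Excluded (label 0) pixels become NaN; a pooled block averages its
    in-mask members only and is NaN when all four are excluded.  Odd
    trailing rows/columns are dropped with a warning.  The label image is
    pooled alongside the data (majority label among in-mask members).
    """
    movie.require_not_done("mask_downsample")
    if masks.labels.shape != movie.frame_shape:
        raise ValueError("mask dimensions do not match movie")
    n_rows, n_cols = movie.frame_shape
    if n_rows % 2 or n_cols % 2:
        log.warning("odd movie dimensions %s; dropping trailing row/col",
                    (n_rows, n_cols))
    r2, c2 = n_rows // 2, n_cols // 2
    data = movie.data[:, : 2 * r2, : 2 * c2].astype(np.float64, copy=True)
    labels = masks.labels[: 2 * r2, : 2 * c2]
    data[:, labels == 0] = np.nan

    blocks = data.reshape(movie.n_frames, r2, 2, c2, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        pooled = np.nanmean(blocks, axis=(2, 4))

    lab_blocks = labels.reshape(r2, 2, c2, 2).transpose(0, 2, 1, 3).reshape(r2, c2, 4)
    pooled_labels = np.zeros((r2, c2), dtype=masks.labels.dtype)
    max_label = int(lab_blocks.max(initial=0))
    if max_label >= 1:
        counts = np.stack([(lab_blocks == k).sum(axis=2)
                           for k in range(1, max_label + 1)], axis=0)
        best = counts.argmax(axis=0) + 1
        pooled_labels = np.where(counts.sum(axis=0) > 0, best, 0).astype(masks.labels.dtype)
    return movie.with_data(pooled, "mask_downsample"), RoiMaskSet(pooled_labels)


def svd_denoise(
    movie: MovieStack,
    rank: int | None = None,
    variance_fraction: float = 0.90,
) -> MovieStack:
    """Low-rank reconstruction of the pixels-by-frames matrix.

    The matrix is centered per pixel (the static image carries no noise
    worth modeling), decomposed, and rebuilt from the leading ``rank``
    singular components — or from enough components to explain
    ``variance_fraction`` of the temporal variance when no rank is given.
    Masked (NaN) pixels are left untouched.
    """
    movie.require_not_done("svd")
    flat = movie.data.reshape(movie.n_frames, -1)
    valid = ~np.isnan(flat).any(axis=0)
    x = flat[:, valid]
    if x.shape[1] == 0:
        raise ValueError("no valid pixels to denoise")
    mean = x.mean(axis=0)
    x = x - mean
    u, s, vt = linalg.svd(x, full_matrices=False)
    if rank is None:
        energy = np.cumsum(s**2) / np.sum(s**2)
        rank = int(np.searchsorted(energy, variance_fraction) + 1)
    if rank > len(s):
        log.warning("requested rank %d exceeds matrix rank %d; keeping all",
                    rank, len(s))
        rank = len(s)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
    out = flat.copy()
    out[:, valid] = recon + mean
    return movie.with_data(out.reshape(movie.data.shape), "svd")


def normalize_dff(movie: MovieStack, f0_percentile: float = 5.0) -> MovieStack:
    """Per-pixel ΔF/F0 with F0 the given percentile of the pixel's trace.

    The percentile uses linear interpolation between order statistics.
    Raises if any in-mask pixel has a nonpositive baseline.
    """
    movie.require_not_done("dff")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        f0 = np.nanpercentile(movie.data, f0_percentile, axis=0)
    bad = (f0 <= 0) & ~np.isnan(f0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"nonpositive F0 at pixel (row={r}, col={c})")
    return movie.with_data((movie.data - f0) / f0, "dff")


def preprocess_movie(
    movie: MovieStack,
    masks: RoiMaskSet,
    smooth_sigma: float = 1.0,
    f0_percentile: float = 5.0,
    svd_rank: int | None = None,
    svd_variance: float = 0.90,
    register: bool = True,
    normalize: bool = True,
) -> tuple[MovieStack, RoiMaskSet, MotionTrace, BleachFit]:
    """Run the full chain (1)-(7) and return the processed ΔF/F0 movie,
    the pooled masks, the motion trace (on the original grid) and the
    bleach fit.  ``normalize=False`` stops after denoising, as used for
    evoked sessions where ΔF/F0 is taken per trial-average instead."""
    movie, fit = correct_photobleach(movie)
    if register:
        movie, motion = register_frames(movie)
    else:
        motion = MotionTrace.clean(movie.n_frames)
    movie = smooth_frames(movie, sigma=smooth_sigma)
    movie, masks_ds = mask_and_downsample(movie, masks)
    movie = svd_denoise(movie, rank=svd_rank, variance_fraction=svd_variance)
    if normalize:
        movie = normalize_dff(movie, f0_percentile=f0_percentile)
    return movie, masks_ds, motion, fit
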