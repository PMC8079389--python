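"""Line-scan reduction and spatiotemporal peak detection.

A movie is reduced to a 2-D line-scan map (tonotopic position x time) by
averaging over the direction parallel to the major axis of spontaneous
bands.  Peaks are local maxima along both the spatial and the temporal
direction simultaneously; events below 5% ΔF/F0 are discarded.  Event
half-widths are full widths at half maximum (FWHM) on the smoothed map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import MovieStack
from .preprocess import MotionTrace

#: Events must reach this ΔF/F0 to be retained.
AMP_THRESHOLD = 0.05


@dataclass
class LineScanMap:
    """ΔF/F0 indexed (tonotopic position bin, frame)."""

    values: np.ndarray          # (n_bins, n_frames)
    frame_rate: float
    axis_angle: float = 0.0     # degrees, major axis relative to the row axis
    rectangle: tuple[int, int, int, int] | None = None  # (r0, c0, r1, c1)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EventCatalog:
    """Detected events plus the record context needed for summaries."""

    events: pd.DataFrame   # frame, position, amplitude, fwhm_t_frames,
    #                        fwhm_x_bins, edge, censored
    record_minutes: float
    frame_rate: float
    ic_width_bins: int

    @property
    def retained(self) -> pd.DataFrame:
        if self.events.empty:
            return self.events
        return self.events[~self.events.censored]


@dataclass
class EventSummary:
    """The five spatiotemporal statistics of a recording."""

    frequency_per_min: float
    mean_duration_s: float
    mean_ipi_s: float
    normalized_bandwidth: float
    mean_amplitude: float


def estimate_axis_angle(movie: MovieStack, hemi_mask: np.ndarray) -> float:
    """Orientation (degrees from the row axis) of the thresholded
    mean-activity image within one hemisphere; a logged, overridable
    default for the line-scan direction."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_img = np.nanmean(np.where(hemi_mask[None], movie.data, np.nan), axis=0)
    mean_img = np.nan_to_num(mean_img)
    thr = mean_img > np.percentile(mean_img[hemi_mask], 75)
    ys, xs = np.nonzero(thr)
    if len(ys) < 3:
        return 0.0
    cov = np.cov(np.stack([ys - ys.mean(), xs - xs.mean()]))
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, np.argmax(vals)]
    return float(np.degrees(np.arctan2(major[1], major[0])))


def compute_line_scan(
    movie: MovieStack,
    rectangle: tuple[int, int, int, int],
    axis_angle: float = 0.0,
) -> LineScanMap:
    """Average a rectangular crop along the band major axis.

    The rectangle is (r0, c0, r1, c1), end-exclusive, on the movie grid;
    when ``axis_angle`` is nonzero each frame is first rotated by
    ``-axis_angle`` about the rectangle center so the major axis aligns
    with the rows.  Output is (cross-axis extent, n_frames); NaN (masked)
    pixels are ignored in the averages.
    """
    r0, c0, r1, c1 = rectangle
    n_rows, n_cols = movie.frame_shape
    if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
        raise ValueError(f"rectangle {rectangle} outside movie bounds")
    data = movie.data
    if axis_angle:
        data = np.stack([
            _rotate_about(frame, -axis_angle, ((r0 + r1) / 2, (c0 + c1) / 2))
            for frame in data
        ])
    crop = data[:, r0:r1, c0:c1]
    counts = np.sum(~np.isnan(crop), axis=1)
    if np.any(counts.max(axis=0) < 3):
        raise ValueError("rectangle has lines with fewer than 3 in-mask pixels")
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(crop, axis=1)   # (n_frames, n_cross_bins)
    return LineScanMap(np.nan_to_num(profile).T, movie.frame_rate,
                       axis_angle=axis_angle, rectangle=rectangle)


def _rotate_about(frame: np.ndarray, angle: float, center: tuple[float, float]) -> np.ndarray:
    filled = np.nan_to_num(frame)
    mask = (~np.isnan(frame)).astype(float)
    shift = np.asarray(center) - (np.asarray(frame.shape) - 1) / 2
    moved = ndimage.shift(filled, -shift, order=1, mode="nearest")
    mmask = ndimage.shift(mask, -shift, order=1, mode="constant")
    rot = ndimage.rotate(moved, angle, reshape=False, order=1, mode="nearest")
    rmask = ndimage.rotate(mmask, angle, reshape=False, order=1, mode="constant")
    out = ndimage.shift(rot, shift, order=1, mode="nearest")
    omask = ndimage.shift(rmask, shift, order=1, mode="constant")
    out[omask < 0.5] = np.nan
    return out


def local_maxima_1d(v: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; for a plateau the first index of
    the run counts, provided the neighbouring runs are lower (record ends
    count as minus infinity)."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return np.array([], dtype=int)
    # run-length encode
    change = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate([[0], change])
    vals = v[starts]
    prev = np.concatenate([[-np.inf], vals[:-1]])
    nxt = np.concatenate([vals[1:], [-np.inf]])
    return starts[(vals > prev) & (vals > nxt)]


def _prominence_base(profile: np.ndarray, peak: int) -> float:
    """Local baseline of a peak: the higher of the two side minima, each
    taken between the peak and the nearest sample exceeding it (or the
    record edge) — the base used for peak prominence."""
    bases = []
    for step in (-1, 1):
        lo = profile[peak]
        i = peak + step
        while 0 <= i < len(profile) and profile[i] <= profile[peak]:
            lo = min(lo, profile[i])
            i += step
        bases.append(lo)
    return max(bases)


def _fwhm(profile: np.ndarray, peak: int) -> tuple[float, bool]:
    """Full width of the peak at half its local height.

    The reference level sits halfway between the peak and its prominence
    base, which keeps widths unbiased when events ride on overlapping
    tails or a slow pedestal.  Crossings are linearly interpolated; when
    one side is clipped by the record edge the available side is doubled
    and the event flagged ``edge``.
    """
    half = (profile[peak] + _prominence_base(profile, peak)) / 2.0
    left = right = np.nan
    for i in range(peak - 1, -1, -1):
        if profile[i] < half:
            left = i + (half - profile[i]) / (profile[i + 1] - profile[i])
            break
    for i in range(peak + 1, len(profile)):
        if profile[i] < half:
            right = i - (half - profile[i]) / (profile[i - 1] - profile[i])
            break
    if np.isnan(left) and np.isnan(right):
        return float(len(profile)), True
    if np.isnan(left):
        return 2.0 * (right - peak), True
    if np.isnan(right):
        return 2.0 * (peak - left), True
    return float(right - left), False


def detect_band_peaks(
    lsmap: LineScanMap,
    amp_threshold: float = AMP_THRESHOLD,
    smooth: int = 5,
) -> EventCatalog:
    """Detect spatiotemporal peaks on a line-scan map.

    The map is smoothed with a ``smooth`` x ``smooth`` mean filter; 1-D
    local maxima are found independently along the spatial direction (per
    frame) and the temporal direction (per position bin), and a peak is
    retained where both scans coincide and the smoothed value reaches
    ``amp_threshold``.
    """
    if amp_threshold <= 0:
        raise ValueError("amplitude threshold must be positive")
    if not np.all(np.isfinite(lsmap.values)):
        raise ValueError("line-scan map must be finite")
    sm = ndimage.uniform_filter(lsmap.values, size=smooth, mode="nearest")

    spatial = np.zeros_like(sm, dtype=bool)
    for t in range(sm.shape[1]):
        spatial[local_maxima_1d(sm[:, t]), t] = True
    temporal = np.zeros_like(sm, dtype=bool)
    for x in range(sm.shape[0]):
        temporal[x, local_maxima_1d(sm[x, :])] = True
    peaks = spatial & temporal & (sm >= amp_threshold)

    rows = []
    for x, t in zip(*np.nonzero(peaks)):
        fw_t, edge_t = _fwhm(sm[x, :], t)
        fw_x, edge_x = _fwhm(sm[:, t], x)
        rows.append(dict(frame=int(t), position=int(x), amplitude=float(sm[x, t]),
                         fwhm_t_frames=fw_t, fwhm_x_bins=fw_x,
                         edge=bool(edge_t or edge_x), censored=False))
    cols = ["frame", "position", "amplitude", "fwhm_t_frames", "fwhm_x_bins",
            "edge", "censored"]
    events = pd.DataFrame(rows, columns=cols)
    minutes = lsmap.n_frames / lsmap.frame_rate / 60.0
    return EventCatalog(events, record_minutes=minutes,
                        frame_rate=lsmap.frame_rate, ic_width_bins=lsmap.n_bins)


def censor_motion_events(catalog: EventCatalog, motion: MotionTrace) -> EventCatalog:
    """Flag events whose temporal FWHM interval overlaps any
    motion-corrupted frame; flagged events are excluded from summaries."""
    corrupted = np.flatnonzero(motion.corrupted)
    events = catalog.events.copy()
    if len(corrupted) and not events.empty:
        lo = events.frame - events.fwhm_t_frames / 2.0
        hi = events.frame + events.fwhm_t_frames / 2.0
        hit = [bool(np.any((corrupted >= l) & (corrupted <= h)))
               for l, h in zip(lo, hi)]
        events.loc[:, "censored"] = np.asarray(hit) | events.censored
    return EventCatalog(events, catalog.record_minutes, catalog.frame_rate,
                        catalog.ic_width_bins)


def summarize_events(catalog: EventCatalog) -> EventSummary:
    """Frequency (events/min), mean duration (s, temporal FWHM), mean
    inter-peak interval (s; same-frame peaks collapse to one event), mean
    spatial FWHM normalized by IC width, and mean peak amplitude."""
    if catalog.record_minutes <= 0:
        raise ValueError("record length must be positive")
    ev = catalog.retained
    if ev.empty:
        return EventSummary(0.0, np.nan, np.nan, np.nan, np.nan)
    freq = len(ev) / catalog.record_minutes
    duration = float(ev.fwhm_t_frames.mean()) / catalog.frame_rate
    frames = np.unique(ev.frame.to_numpy())
    ipi = float(np.diff(frames).mean()) / catalog.frame_rate if len(frames) > 1 else np.nan
    bandwidth = float(ev.fwhm_x_bins.mean()) / catalog.ic_width_bins
    amp = float(ev.amplitude.mean())
    return EventSummary(freq, duration, ipi, bandwidth, amp)
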