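"""Bilateral partial-correlation analysis.

All seed-based and global bilateral correlations are first-order partial
Pearson correlations controlling for the mean fluorescence trace over
all pixels outside the IC, which regresses out non-specific whole-brain
fluctuations.  Motion-corrupted frames are excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import MovieStack, RoiMaskSet
from .preprocess import MotionTrace

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scalar partial correlation


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    identical to the Pearson correlation of the residuals of x and y
    after regressing each on z.  A constant control falls back to the
    plain Pearson correlation with a logged note.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)) or len(x) < 3:
        raise ValueError("traces must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("x and y must be non-constant")
    if z.std() == 0:
        log.info("constant control trace; falling back to plain Pearson")
        return _pearson(x, y)
    r_xy, r_xz, r_yz = _pearson(x, y), _pearson(x, z), _pearson(y, z)
    if abs(r_xz) >= 1.0 - 1e-14 or abs(r_yz) >= 1.0 - 1e-14:
        raise ValueError("partial correlation undefined: |r| with control is 1")
    return float((r_xy - r_xz * r_yz)
                 / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


# ---------------------------------------------------------------------------
# Traces


def _good_frames(movie: MovieStack, motion: MotionTrace | None) -> np.ndarray:
    if motion is None:
        return np.ones(movie.n_frames, dtype=bool)
    good = ~motion.corrupted
    if not good.any():
        raise ValueError("all frames are motion-corrupted")
    return good


def region_trace(movie: MovieStack, mask: np.ndarray) -> np.ndarray:
    """Mean trace over the in-mask, in-ROI (non-NaN) pixels."""
    if not mask.any():
        raise ValueError("empty region mask")
    sub = movie.data[:, mask]
    return np.nanmean(sub, axis=1)


def outside_trace(movie: MovieStack, masks: RoiMaskSet) -> np.ndarray:
    """The control regressor: mean trace over all pixels outside the IC."""
    if not masks.outside.any():
        raise ValueError("no outside-ROI region: the partial-correlation "
                         "control regressor requires one")
    return region_trace(movie, masks.outside)


# ---------------------------------------------------------------------------
# Global bilateral correlation


def global_bilateral_correlation(
    movie: MovieStack,
    masks: RoiMaskSet,
    motion: MotionTrace | None = None,
) -> float:
    """Partial correlation between the two hemisphere-mean traces,
    controlling for the outside-ROI mean trace, on non-corrupted frames."""
    good = _good_frames(movie, motion)
    left = region_trace(movie, masks.left)[good]
    right = region_trace(movie, masks.right)[good]
    ctrl = outside_trace(movie, masks)[good]
    return partial_correlation(left, right, ctrl)


# ---------------------------------------------------------------------------
# Seed-based correlation maps


@dataclass
class CorrelationMap:
    """Per-pixel partial correlation with respect to one seed.

    Out-of-ROI pixels are NaN.  ``partial=False`` records that the map
    was computed with plain Pearson correlations (demonstration mode).
    """

    values: np.ndarray            # (n_rows, n_cols), NaN outside ROI
    seed: tuple[int, int]
    partial: bool = True

    def finite_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


def seed_correlation_map(
    movie: MovieStack,
    seed: tuple[int, int],
    masks: RoiMaskSet,
    motion: MotionTrace | None = None,
    partial: bool = True,
    target_mask: np.ndarray | None = None,
) -> CorrelationMap:
    """Correlation of every in-ROI pixel trace with the seed trace.

    Partial correlations control for the outside-ROI mean trace; the map
    value at the seed itself is exactly 1.  ``target_mask`` restricts the
    mapped pixels (default: both IC hemispheres).
    """
    if target_mask is None:
        target_mask = masks.ic
    if not target_mask[seed]:
        raise ValueError(f"seed {seed} outside the analyzed ROI")
    good = _good_frames(movie, motion)
    data = movie.data[good][:, target_mask]       # (n_good, n_px)
    seed_flat = np.flatnonzero(target_mask.ravel())
    seed_idx = int(np.searchsorted(seed_flat, seed[0] * movie.frame_shape[1] + seed[1]))
    x = data[:, seed_idx]
    if np.isnan(x).any():
        raise ValueError(f"seed {seed} has masked (NaN) samples")

    xc = x - x.mean()
    dc = data - data.mean(axis=0)
    sx = np.sqrt(xc @ xc)
    sd = np.sqrt(np.nansum(dc * dc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_xy = np.nansum(dc * xc[:, None], axis=0) / (sx * sd)
    if partial:
        z = outside_trace(movie, masks)[good]
        zc = z - z.mean()
        sz = np.sqrt(zc @ zc)
        r_xz = float(xc @ zc / (sx * sz))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_yz = np.nansum(dc * zc[:, None], axis=0) / (sd * sz)
            vals = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    else:
        vals = r_xy
    vals = np.clip(vals, -1.0, 1.0)       # guard rounding at |r| = 1

    out = np.full(movie.frame_shape, np.nan)
    out[target_mask] = vals
    out[seed] = 1.0
    return CorrelationMap(out, seed=seed, partial=partial)


# ---------------------------------------------------------------------------
# Seed grid


@dataclass
class SeedGrid:
    """Evenly spaced seed lattice covering the downsampled field."""

    seeds: np.ndarray    # (n, 2) int (row, col)
    n_grid_rows: int
    n_grid_cols: int

    def in_roi(self, mask: np.ndarray) -> np.ndarray:
        keep = mask[self.seeds[:, 0], self.seeds[:, 1]]
        return self.seeds[keep]


def build_seed_grid(field_shape: tuple[int, int], n: int = 1000) -> SeedGrid:
    """Near-square lattice of at least ``n`` seeds with spacing as uniform
    as the field aspect ratio allows; deterministic."""
    if n < 1:
        raise ValueError("need at least one seed")
    n_rows, n_cols = field_shape
    if n == 1:
        return SeedGrid(np.array([[n_rows // 2, n_cols // 2]]), 1, 1)
    gc = int(np.ceil(np.sqrt(n * n_cols / n_rows)))
    gr = int(np.ceil(n / gc))
    rr = np.round(np.linspace(0, n_rows - 1, gr)).astype(int)
    cc = np.round(np.linspace(0, n_cols - 1, gc)).astype(int)
    seeds = np.array([(r, c) for r in rr for c in cc])
    return SeedGrid(seeds, gr, gc)


# ---------------------------------------------------------------------------
# Regional quantities


def max_symmetric_region_correlation(
    cmap: CorrelationMap,
    region: np.ndarray,
    filter_size: int = 5,
) -> tuple[float, tuple[int, int]]:
    """Maximum neighborhood-mean correlation within a region.

    Each region pixel is scored by the mean correlation over its
    ``filter_size`` x ``filter_size`` neighborhood, counting in-ROI
    members only; returns the best score and its pixel (ties resolved to
    the smallest row, then column).
    """
    if not region.any():
        raise ValueError("empty region")
    vals = np.nan_to_num(cmap.values)
    ok = cmap.finite_mask().astype(float)
    ksum = ndimage.uniform_filter(vals * ok, size=filter_size, mode="constant")
    kcnt = ndimage.uniform_filter(ok, size=filter_size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        score = ksum / kcnt
    score[~region | (kcnt == 0)] = -np.inf
    idx = int(np.argmax(score))          # row-major: first max is smallest row, col
    loc = np.unravel_index(idx, score.shape)
    return float(score[loc]), (int(loc[0]), int(loc[1]))


def symmetric_contra_roi(masks: RoiMaskSet, seed: tuple[int, int]) -> np.ndarray:
    """The contralateral region symmetric to the seed's hemisphere,
    obtained by reflecting that hemisphere mask across the midline."""
    side = "left" if masks.left[seed] else "right" if masks.right[seed] else None
    if side is None:
        raise ValueError(f"seed {seed} is not inside a hemisphere mask")
    contra = masks.right if side == "left" else masks.left
    return masks.mirrored(masks.hemisphere(side)) & contra


@dataclass
class RegionProps:
    """Shape of the high-correlation region around a seed."""

    eccentricity: float   # fitted-ellipse aspect ratio a/b >= 1
    proportion: float     # region area / hemisphere area
    threshold: float
    area_px: int


def correlation_region_properties(
    cmap: CorrelationMap,
    masks: RoiMaskSet,
    threshold: float = 0.95,
) -> RegionProps:
    """Ellipse aspect ratio and relative area of the seed-connected
    component of pixels with r > threshold."""
    supra = np.nan_to_num(cmap.values, nan=-np.inf) > threshold
    labels = measure.label(supra, connectivity=2)
    lab = labels[cmap.seed]
    if lab == 0:
        raise ValueError("no suprathreshold component contains the seed")
    comp = labels == lab
    props = measure.regionprops(comp.astype(int))[0]
    minor = max(props.axis_minor_length, 1e-9)
    side = "left" if masks.left[cmap.seed] else "right"
    hemi_area = int(masks.hemisphere(side).sum())
    return RegionProps(eccentricity=float(props.axis_major_length / minor),
                       proportion=float(comp.sum() / hemi_area),
                       threshold=threshold, area_px=int(comp.sum()))


# ---------------------------------------------------------------------------
# Representative seeds and bilateral statistics


def _band_count(cmap: CorrelationMap, hemi: np.ndarray, threshold: float) -> int:
    """Number of distinct high-correlation bands in one hemisphere:
    connected components of the thresholded map, ignoring tiny specks."""
    supra = (np.nan_to_num(cmap.values, nan=-np.inf) > threshold) & hemi
    labels = measure.label(supra, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= 3))


def select_representative_seeds(
    movie: MovieStack,
    masks: RoiMaskSet,
    motion: MotionTrace | None = None,
    band_threshold: float = 0.6,
    side: str = "left",
    step: int = 3,
) -> dict[str, tuple[int, int] | None]:
    """Pick the low-/mid-/high-frequency representative seeds.

    Seeds march medial-to-lateral along the hemisphere's central transect.
    The low seed is the most medial one whose ipsilateral suprathreshold
    pattern shows a single band; mid sits ``step`` grid steps more lateral
    where two bands appear, and high ``step`` steps beyond that.  Missing
    patterns yield None for the slot.
    """
    hemi = masks.hemisphere(side)
    rows, cols = np.nonzero(hemi)
    row = int(round(rows.mean()))
    row_cols = np.sort(cols[rows == row])
    if side == "left":
        row_cols = row_cols[::-1]        # medial (near midline) first
    counts = {}

    def bands(col: int) -> int:
        if (row, col) not in counts:
            cmap = seed_correlation_map(movie, (row, int(col)), masks, motion)
            counts[(row, col)] = _band_count(cmap, hemi, band_threshold)
        return counts[(row, col)]

    out: dict[str, tuple[int, int] | None] = {"low": None, "mid": None, "high": None}
    i_low = next((i for i, c in enumerate(row_cols) if bands(c) == 1), None)
    if i_low is None:
        return out
    out["low"] = (row, int(row_cols[i_low]))
    i_mid = next((i for i in range(i_low + step, len(row_cols))
                  if bands(row_cols[i]) == 2), None)
    if i_mid is None:
        return out
    out["mid"] = (row, int(row_cols[i_mid]))
    i_high = next((i for i in range(i_mid + step, len(row_cols))
                   if bands(row_cols[i]) == 2), None)
    if i_high is not None:
        out["high"] = (row, int(row_cols[i_high]))
    return out


@dataclass
class BilateralStats:
    """Global bilateral correlation plus seed-based bilateral correlations
    (SbBC) at the three representative seeds."""

    global_r: float
    sbbc: dict[str, float]        # low/mid/high -> max contra correlation
    max_locations: dict[str, tuple[int, int]]

    @property
    def sbbc_averaged(self) -> float:
        vals = [v for v in self.sbbc.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan


def bilateral_stats(
    movie: MovieStack,
    masks: RoiMaskSet,
    motion: MotionTrace | None = None,
    seeds: dict[str, tuple[int, int] | None] | None = None,
    band_threshold: float = 0.6,
) -> BilateralStats:
    """Global bilateral correlation and SbBC at representative seeds.

    SbBC for a seed is the maximum 5x5 neighborhood-mean correlation in
    the contralateral region symmetric to the seed's hemisphere.
    """
    global_r = global_bilateral_correlation(movie, masks, motion)
    if seeds is None:
        seeds = select_representative_seeds(movie, masks, motion,
                                            band_threshold=band_threshold)
    sbbc: dict[str, float] = {}
    locs: dict[str, tuple[int, int]] = {}
    for name, seed in seeds.items():
        if seed is None:
            sbbc[name] = np.nan
            continue
        cmap = seed_correlation_map(movie, seed, masks, motion)
        region = symmetric_contra_roi(masks, seed)
        sbbc[name], locs[name] = max_symmetric_region_correlation(cmap, region)
    return BilateralStats(global_r=global_r, sbbc=sbbc, max_locations=locs)
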