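"""Synthetic wide-field movies with known ground truth.

The generator emulates the statistical structure of spontaneous calcium
activity on the dorsal surface of the developing inferior colliculus:
discrete band-shaped events elongated along the anteroposterior (major)
axis with Gaussian-confined spread along the mediolateral (tonotopic)
axis, rendered as a single band medially and dual reversal-symmetric
bands more laterally, with Poisson event timing, a fast rise and a slow
GCaMP6s-like exponential decay.  A coupling probability ``c`` controls
how often an event is mirrored at the homologous tonotopic position of
the other hemisphere — the phenomenological stand-in for efferent-mediated
bilateral coupling.  Optional bleaching, rigid motion, global background
fluctuation and additive noise exercise the preprocessing and
partial-correlation controls downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LEFT, OUTSIDE, RIGHT, MovieStack, RoiMaskSet


@dataclass
class SyntheticSpontConfig:
    """Parameters of a spontaneous-activity simulation.

    Tonotopic coordinate ``p`` runs from 0 at the medial edge of a
    hemisphere (future low-frequency zone) to 1 at the lateral edge.
    ``band_halfwidth`` is the Gaussian sigma of the band's cross-axis
    profile as a fraction of the tonotopic extent.
    """

    frame_rate: float = 10.0          # Hz
    duration: float = 300.0           # s
    fov: tuple[int, int] = (64, 96)   # (rows, cols)
    event_rate: float = 6.0           # events/min per hemisphere
    coupling: float = 0.5             # P(event mirrored contralaterally)
    mirror_time_jitter: int = 0       # frames
    mirror_pos_jitter: float = 0.0    # fraction of tonotopic extent
    band_halfwidth: float = 0.10      # Gaussian sigma, fraction of extent
    p_split: float = 0.33             # single- vs dual-band boundary
    amp_mu: float = math.log(0.20)    # lognormal location of peak ΔF/F0
    amp_sigma: float = 0.3            # lognormal shape
    decay_tau: float = 1.5            # s, GCaMP6s-like decay
    rise_frames: int = 1
    baseline: float = 100.0           # a.u.
    baseline_contrast: float = 0.1    # static texture contrast (anatomy stand-in)
    noise_sigma: float = 0.5          # a.u., i.i.d. additive
    bleach_tau: float | None = None   # s; None disables bleaching
    motion_amp: float = 0.0           # px, sd of per-frame random shifts
    background_amp: float = 0.3       # a.u., sd of slow global fluctuation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if self.event_rate < 0:
            raise ValueError("event_rate must be nonnegative")
        if self.band_halfwidth <= 0:
            raise ValueError("band_halfwidth must be positive")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.fov[0] < 16 or self.fov[1] < 24:
            raise ValueError(f"fov {self.fov} too small for hemisphere geometry")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """True event stream and artifact parameters of a synthetic movie."""

    events: pd.DataFrame       # event_id, hemisphere, frame, p, amplitude, partner_id
    shifts: np.ndarray | None  # (n_frames, 2) true (dy, dx), or None
    bleach_tau_frames: float | None

    def hemisphere_events(self, side: str) -> pd.DataFrame:
        key = {"left": "L", "right": "R"}[side]
        return self.events[self.events.hemisphere == key]


# ---------------------------------------------------------------------------
# Geometry


def hemisphere_masks(fov: tuple[int, int]) -> RoiMaskSet:
    """Two mirror-symmetric elliptical hemisphere masks about a vertical
    midline, with everything else labeled as the outside-ROI control region."""
    n_rows, n_cols = fov
    half = n_cols // 2
    rr, cc = np.mgrid[0:n_rows, 0:half]
    cy = (n_rows - 1) / 2.0
    cx = (half - 1) / 2.0
    a_row = 0.42 * n_rows           # semi-axis along the major (row) axis
    a_col = 0.40 * half             # semi-axis along the tonotopic axis
    left_half = ((rr - cy) / a_row) ** 2 + ((cc - cx) / a_col) ** 2 <= 1.0

    labels = np.full((n_rows, n_cols), OUTSIDE, dtype=np.int8)
    labels[:, :half][left_half] = LEFT
    labels[:, n_cols - half:][left_half[:, ::-1]] = RIGHT
    return RoiMaskSet(labels)


def _tonotopic_coord(masks: RoiMaskSet, side: str) -> tuple[np.ndarray, float]:
    """Per-column tonotopic coordinate of one hemisphere (0 medial, 1
    lateral) and the extent of the tonotopic axis in pixels."""
    hemi = masks.hemisphere(side)
    cols = np.nonzero(hemi)[1]
    medial = cols.max() if side == "left" else cols.min()
    lateral = cols.min() if side == "left" else cols.max()
    extent = abs(float(lateral - medial))
    col_idx = np.arange(masks.labels.shape[1])
    p = np.abs(col_idx - medial) / extent
    return p, extent


def band_profile(masks: RoiMaskSet, side: str, p: float, sigma_frac: float,
                 p_split: float) -> np.ndarray:
    """Spatial footprint of one event: homogeneous along the major axis,
    Gaussian across the tonotopic axis; dual reversal-symmetric bands for
    events lateral to ``p_split``."""
    coord, _ = _tonotopic_coord(masks, side)
    centers = [p]
    if p >= p_split:
        # Mirror position within the reversed (lateral) tonotopic gradient.
        centers.append(1.0 + p_split - p)
    prof_cols = np.zeros_like(coord)
    for c in centers:
        prof_cols = np.maximum(prof_cols, np.exp(-((coord - c) ** 2) / (2 * sigma_frac**2)))
    out = np.zeros(masks.labels.shape, dtype=np.float64)
    hemi = masks.hemisphere(side)
    out[hemi] = prof_cols[np.nonzero(hemi)[1]]
    return out


def tonotopic_pixel(masks: RoiMaskSet, side: str, p: float) -> tuple[int, int]:
    """(row, col) of the point at tonotopic coordinate ``p`` on the
    hemisphere's central transect."""
    coord, _ = _tonotopic_coord(masks, side)
    hemi = masks.hemisphere(side)
    rows, cols = np.nonzero(hemi)
    row = int(round(rows.mean()))
    in_row = cols[rows == row]
    best = in_row[np.argmin(np.abs(coord[in_row] - p))]
    return row, int(best)


# ---------------------------------------------------------------------------
# Temporal kernel


def calcium_kernel(rise_frames: int, tau_frames: float, tol: float = 1e-2) -> np.ndarray:
    """Linear rise to 1 over ``rise_frames`` then exponential decay,
    truncated once the tail falls below ``tol``."""
    rise = np.linspace(0.0, 1.0, rise_frames + 1)[1:]
    n_decay = max(1, int(math.ceil(-tau_frames * math.log(tol))))
    decay = np.exp(-np.arange(1, n_decay + 1) / tau_frames)
    return np.concatenate([rise, decay])


def baseline_texture(fov: tuple[int, int], contrast: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Static multiplicative baseline pattern (mean 1) standing in for
    anatomical structure — the spatial contrast that rigid registration
    locks onto.  Built mirror-symmetric about the midline so that perfect
    bilateral coupling leaves the movie reflection-invariant."""
    if contrast <= 0:
        return np.ones(fov)
    n_rows, n_cols = fov
    half_cols = (n_cols + 1) // 2
    raw = rng.standard_normal((n_rows, half_cols))
    smooth = ndimage.gaussian_filter(raw, sigma=1.5, mode="reflect")
    smooth *= contrast / smooth.std()
    tex = np.empty(fov)
    tex[:, :half_cols] = smooth
    tex[:, n_cols - half_cols:] = smooth[:, ::-1]
    return 1.0 + tex - tex.mean()


# ---------------------------------------------------------------------------
# Spontaneous movies


def _draw_events(cfg: SyntheticSpontConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Poisson event streams: shared (mirrored) events at rate λ·c and
    independent events at rate λ·(1−c) per hemisphere, so each hemisphere
    sees rate λ and a fraction c of its events has a contralateral partner."""
    minutes = cfg.duration / 60.0
    n_shared = rng.poisson(cfg.event_rate * cfg.coupling * minutes)
    n_only = rng.poisson(cfg.event_rate * (1.0 - cfg.coupling) * minutes, size=2)

    rows: list[dict] = []
    eid = 0
    for _ in range(n_shared):
        frame = int(rng.integers(0, cfg.n_frames))
        p = float(rng.uniform())
        amp = float(rng.lognormal(cfg.amp_mu, cfg.amp_sigma))
        dt = int(rng.integers(-cfg.mirror_time_jitter, cfg.mirror_time_jitter + 1))
        dp = float(rng.uniform(-cfg.mirror_pos_jitter, cfg.mirror_pos_jitter))
        rows.append(dict(event_id=eid, hemisphere="L", frame=frame, p=p,
                         amplitude=amp, partner_id=eid + 1))
        rows.append(dict(event_id=eid + 1, hemisphere="R",
                         frame=int(np.clip(frame + dt, 0, cfg.n_frames - 1)),
                         p=float(np.clip(p + dp, 0.0, 1.0)),
                         amplitude=amp, partner_id=eid))
        eid += 2
    for side, n in zip("LR", n_only):
        for _ in range(n):
            rows.append(dict(event_id=eid, hemisphere=side,
                             frame=int(rng.integers(0, cfg.n_frames)),
                             p=float(rng.uniform()),
                             amplitude=float(rng.lognormal(cfg.amp_mu, cfg.amp_sigma)),
                             partner_id=-1))
            eid += 1
    cols = ["event_id", "hemisphere", "frame", "p", "amplitude", "partner_id"]
    df = pd.DataFrame(rows, columns=cols)
    return df.astype({"event_id": int, "frame": int, "partner_id": int})


def _render_events(cfg: SyntheticSpontConfig, masks: RoiMaskSet,
                   events: pd.DataFrame) -> np.ndarray:
    """ΔF/F0 activity tensor from an event table."""
    activity = np.zeros((cfg.n_frames,) + cfg.fov, dtype=np.float64)
    tau_frames = cfg.decay_tau * cfg.frame_rate
    kernel = calcium_kernel(cfg.rise_frames, tau_frames)
    side_name = {"L": "left", "R": "right"}
    for ev in events.itertuples():
        prof = band_profile(masks, side_name[ev.hemisphere], ev.p,
                            cfg.band_halfwidth, cfg.p_split)
        t0 = ev.frame - (cfg.rise_frames - 1)  # kernel peak lands on ev.frame
        k0 = max(0, -t0)
        t_lo = max(0, t0)
        t_hi = min(cfg.n_frames, t0 + len(kernel))
        seg = kernel[k0:k0 + (t_hi - t_lo)]
        activity[t_lo:t_hi] += ev.amplitude * seg[:, None, None] * prof[None]
    return activity


def generate_spontaneous_movie(
    cfg: SyntheticSpontConfig,
) -> tuple[MovieStack, RoiMaskSet, GroundTruth]:
    """Simulate a spontaneous-activity session.

    Returns the raw-fluorescence movie (baseline × (1 + ΔF/F0 activity)
    plus artifacts), the mask set, and the ground truth.  Identical config
    (including seed) yields bit-identical output.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_events, rng_bg, rng_art, rng_tex = [np.random.default_rng(s)
                                            for s in ss.spawn(4)]

    masks = hemisphere_masks(cfg.fov)
    events = _draw_events(cfg, rng_events)
    activity = _render_events(cfg, masks, events)
    base_img = cfg.baseline * baseline_texture(cfg.fov, cfg.baseline_contrast,
                                               rng_tex)
    data = base_img[None] * (1.0 + activity)

    if cfg.background_amp > 0:
        # Slow global fluctuation added everywhere, including outside the
        # ROI — the signal the partial-correlation control must remove.
        raw = rng_bg.standard_normal(cfg.n_frames)
        slow = ndimage.gaussian_filter1d(raw, sigma=5.0)
        slow *= cfg.background_amp / slow.std()
        data += slow[:, None, None]

    shifts = None
    if cfg.motion_amp > 0:
        shifts = rng_art.normal(0.0, cfg.motion_amp, size=(cfg.n_frames, 2))
        shifts = np.clip(shifts, -3.0, 3.0)

    bleach_tau_frames = (cfg.bleach_tau * cfg.frame_rate
                         if cfg.bleach_tau is not None else None)
    movie = MovieStack(data, frame_rate=cfg.frame_rate)
    movie = inject_artifacts(movie, bleach_tau_frames=bleach_tau_frames,
                             shifts=shifts, noise_sigma=cfg.noise_sigma,
                             rng=rng_art)
    truth = GroundTruth(events=events, shifts=shifts,
                        bleach_tau_frames=bleach_tau_frames)
    return movie, masks, truth


# ---------------------------------------------------------------------------
# Artifacts


def inject_artifacts(
    movie: MovieStack,
    bleach_tau_frames: float | None = None,
    shifts: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MovieStack:
    """Apply bleaching, rigid motion and additive noise to a movie.

    Bleaching multiplies frame ``t`` by ``exp(-t/τ_b)``; shifts are rigid
    translations with edge-replicating boundary fill; noise is i.i.d.
    Gaussian.  With everything disabled this is the identity.
    """
    data = movie.data.astype(np.float64, copy=True)
    n = movie.n_frames

    if bleach_tau_frames is not None:
        if bleach_tau_frames <= 0:
            raise ValueError("bleach tau must be positive")
        data *= np.exp(-np.arange(n) / bleach_tau_frames)[:, None, None]

    if shifts is not None:
        shifts = np.asarray(shifts, dtype=float)
        if not np.all(np.isfinite(shifts)):
            raise ValueError("shifts must be finite")
        margin = min(movie.frame_shape) // 4
        if np.abs(shifts).max() > margin:
            raise ValueError("shift magnitude exceeds field-of-view margin")
        for t in range(n):
            if np.any(shifts[t]):
                data[t] = ndimage.shift(data[t], shifts[t], order=3, mode="nearest")

    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sigma, size=data.shape)

    return movie.with_data(data)


# ---------------------------------------------------------------------------
# Evoked sessions


@dataclass
class ToneTuning:
    """Per-frequency ground truth of an evoked simulation: tonotopic band
    center and true auditory threshold (dB SPL) for each stimulus frequency."""

    centers: dict[float, float]      # frequency kHz -> tonotopic p in [0, 1]
    thresholds: dict[float, float]   # frequency kHz -> true threshold dB SPL
    amp_max: float = 0.15            # saturating response amplitude, ΔF/F0
    slope_db: float = 6.0            # sigmoid slope, dB

    def amplitude(self, freq: float, spl: float) -> float:
        """Saturating response: a logistic in SPL that crosses 2% ΔF/F0
        exactly at the frequency's true threshold."""
        if self.amp_max <= 0:
            return 0.0
        thr = self.thresholds[freq]
        mid = thr + self.slope_db * math.log(self.amp_max / 0.02 - 1.0)
        return self.amp_max / (1.0 + math.exp(-(spl - mid) / self.slope_db))


def generate_evoked_session(
    protocol,
    tuning: ToneTuning,
    fov: tuple[int, int] = (48, 72),
    baseline: float = 100.0,
    noise_sigma: float = 0.5,
    decay_tau: float = 1.5,
    session: int = 0,
    seed: int = 0,
) -> tuple[MovieStack, RoiMaskSet, pd.DataFrame]:
    """Simulate one stimulation session following ``protocol``.

    Each trial occupies exactly the protocol's per-trial frame count; the
    response is a band at the stimulated frequency's tonotopic center in
    both hemispheres, rising at stimulus onset and decaying with the
    calcium time constant.  Returns the raw movie, masks and a trial log
    (session, trial, frequency_kHz, SPL_dB, start_frame).
    """
    missing = set(protocol.frequencies) - set(tuning.centers)
    if missing or set(protocol.frequencies) - set(tuning.thresholds):
        raise ValueError("tuning frequencies do not match protocol frequencies")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(session + 1)[-1])
    masks = hemisphere_masks(fov)
    order = protocol.session_order(session)
    fpt = protocol.frames_per_trial
    n_frames = fpt * len(order)
    activity = np.zeros((n_frames, *fov), dtype=np.float64)
    kernel = calcium_kernel(1, decay_tau * protocol.frame_rate)

    log_rows = []
    onset = protocol.pre_frames  # 0-based index of the first stimulus frame
    for i, (freq, spl) in enumerate(order):
        start = i * fpt
        log_rows.append(dict(session=session, trial=i, frequency_kHz=freq,
                             SPL_dB=spl, start_frame=start))
        amp = tuning.amplitude(freq, spl)
        if amp <= 0:
            continue
        p = tuning.centers[freq]
        prof = sum(band_profile(masks, s, p, 0.06, p_split=2.0)
                   for s in ("left", "right"))
        t0 = start + onset
        seg = kernel[: min(len(kernel), start + fpt - t0)]
        activity[t0:t0 + len(seg)] += amp * seg[:, None, None] * prof[None]

    data = baseline * (1.0 + activity)
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, size=data.shape)
    movie = MovieStack(data, frame_rate=protocol.frame_rate)
    return movie, masks, pd.DataFrame(log_rows)
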