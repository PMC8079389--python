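"""Tone-evoked response analysis and auditory-threshold calling.

The stimulation protocol presents sinusoidal amplitude-modulated (SAM)
tones at 7 frequencies (4-32 kHz in half-octave steps) x 12 sound levels
(96 down to 8 dB SPL in 8-dB decrements) = 84 combinations per session,
each trial spanning exactly 50 frames at 10 Hz (1 s pre, 0.5 s stimulus,
3.5 s post).  Trials sharing a frequency-SPL combination are averaged
frame-wise across sessions; responses are ΔF/F0 against the 10 pre-
stimulus frames; the threshold for a frequency is the lowest SPL whose
pooled response curve crosses 2% ΔF/F0 during frames 11-20 (1-based).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MovieStack, frame_window

log = logging.getLogger(__name__)

#: Sentinel threshold for frequencies with no responding SPL.
NO_RESPONSE = "no response"

STIM_WINDOW = frame_window(11, 15)      # frames with the acoustic stimulus
RESPONSE_WINDOW = frame_window(11, 20)  # threshold-crossing search window
BASELINE_WINDOW = frame_window(1, 10)


def half_octave_frequencies(lo: float = 4.0, hi: float = 32.0) -> tuple[float, ...]:
    freqs = []
    f = lo
    while f <= hi * (1 + 1e-9):
        freqs.append(round(f, 6))
        f *= np.sqrt(2.0)
    return tuple(freqs)


@dataclass
class StimulusProtocol:
    """SAM-tone stimulation protocol bookkeeping.

    The SAM waveform itself (modulation depth 1, 10 Hz) is metadata only;
    no audio is rendered.
    """

    frequencies: tuple[float, ...] = field(default_factory=half_octave_frequencies)
    levels: tuple[int, ...] = tuple(range(96, 7, -8))
    frame_rate: float = 10.0
    pre_s: float = 1.0
    stim_s: float = 0.5
    post_s: float = 3.5
    seed: int = 0
    modulation_depth: float = 1.0
    modulation_freq: float = 10.0

    @property
    def combinations(self) -> list[tuple[float, int]]:
        return [(f, l) for f in self.frequencies for l in self.levels]

    @property
    def n_combinations(self) -> int:
        return len(self.frequencies) * len(self.levels)

    @property
    def trial_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_s * self.frame_rate))

    @property
    def pre_frames(self) -> int:
        return int(round(self.pre_s * self.frame_rate))

    @property
    def frames_per_session(self) -> int:
        return self.n_combinations * self.frames_per_trial

    def session_order(self, session: int) -> list[tuple[float, int]]:
        """Random presentation order for one session, reproducible from
        the protocol seed."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, session]))
        combos = self.combinations
        return [combos[i] for i in rng.permutation(len(combos))]


def build_stimulus_protocol(seed: int = 0) -> StimulusProtocol:
    """The standard protocol: 4-32 kHz half-octave frequencies crossed
    with 96..8 dB SPL in 8-dB decrements, 50-frame trials at 10 Hz."""
    return StimulusProtocol(seed=seed)


# ---------------------------------------------------------------------------
# Trial averaging


@dataclass
class ResponseTensor:
    """Frame-wise trial averages per frequency-SPL combination."""

    entries: dict[tuple[float, int], np.ndarray]   # (fpt, rows, cols)
    counts: dict[tuple[float, int], int]
    frame_rate: float
    is_dff: bool = False


def average_trials(
    sessions: list[tuple[MovieStack, pd.DataFrame]],
    protocol: StimulusProtocol,
) -> ResponseTensor:
    """Sort trials from all sessions into frequency-SPL groups and average
    frame-wise within each group.

    Each trial-log row (frequency_kHz, SPL_dB, start_frame) maps a
    ``frames_per_trial`` window of its session movie to a combination.
    """
    fpt = protocol.frames_per_trial
    sums: dict[tuple[float, int], np.ndarray] = {}
    counts: dict[tuple[float, int], int] = {}
    for movie, trial_log in sessions:
        starts = np.sort(trial_log.start_frame.to_numpy())
        if np.any(np.diff(starts) < fpt):
            raise ValueError("overlapping trial windows in trial log")
        for row in trial_log.itertuples():
            key = (float(row.frequency_kHz), int(row.SPL_dB))
            s = int(row.start_frame)
            if s + fpt > movie.n_frames:
                raise ValueError(f"trial at frame {s} exceeds movie length")
            clip = movie.data[s:s + fpt].astype(np.float64)
            if key in sums:
                sums[key] += clip
                counts[key] += 1
            else:
                sums[key] = clip.copy()
                counts[key] = 1
    missing = [k for k in protocol.combinations if k not in sums]
    if missing:
        raise ValueError(f"no trials for combination(s) {missing[:3]}"
                         + ("..." if len(missing) > 3 else ""))
    entries = {k: sums[k] / counts[k] for k in sums}
    return ResponseTensor(entries, counts, protocol.frame_rate)


def evoked_dff(tensor: ResponseTensor) -> ResponseTensor:
    """ΔF/F0 per pixel against the mean of the 10 pre-stimulus frames."""
    if tensor.is_dff:
        raise RuntimeError("tensor already normalized")
    out = {}
    for key, entry in tensor.entries.items():
        if entry.shape[0] < 11:
            raise ValueError("entries need at least 11 frames")
        f0 = entry[BASELINE_WINDOW].mean(axis=0)
        if np.any(f0 <= 0):
            raise ValueError(f"nonpositive baseline in combination {key}")
        out[key] = (entry - f0) / f0
    return ResponseTensor(out, dict(tensor.counts), tensor.frame_rate, is_dff=True)


# ---------------------------------------------------------------------------
# Response curves and thresholds


def pooled_response_curve(
    entry: np.ndarray,
    corr_threshold: float = 0.997,
) -> tuple[np.ndarray, tuple[int, int], np.ndarray]:
    """Population response curve of one trial-averaged ΔF/F0 entry.

    The pixel with the maximum ΔF/F0 during the stimulus frames (11-15,
    1-based) seeds a plain Pearson correlation map over the entry; pixels
    correlating above ``corr_threshold`` with the seed trace are pooled
    and their mean trace returned, along with the seed pixel and the
    pooled-region mask.
    """
    stim = entry[STIM_WINDOW]
    flat_idx = int(np.argmax(np.nan_to_num(stim, nan=-np.inf).max(axis=0)))
    seed = np.unravel_index(flat_idx, entry.shape[1:])

    traces = entry.reshape(entry.shape[0], -1)
    x = traces[:, flat_idx]
    xc = x - x.mean()
    tc = traces - traces.mean(axis=0)
    denom = np.sqrt((tc**2).sum(axis=0)) * np.sqrt(xc @ xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc * xc[:, None]).sum(axis=0) / denom
    region = (r > corr_threshold).reshape(entry.shape[1:])
    region[seed] = True
    curve = entry[:, region].mean(axis=1)
    return curve, (int(seed[0]), int(seed[1])), region


@dataclass
class ThresholdTable:
    """Per-frequency auditory thresholds and response-curve peaks."""

    table: pd.DataFrame   # frequency_kHz, threshold_dB (NaN = no response)
    peaks: pd.DataFrame   # frequency_kHz, SPL_dB, peak_dff

    def threshold(self, freq: float) -> float | str:
        row = self.table[self.table.frequency_kHz == freq]
        v = float(row.threshold_dB.iloc[0])
        return NO_RESPONSE if np.isnan(v) else v


def determine_threshold(
    curves: dict[int, np.ndarray],
    criterion: float = 0.02,
    window: slice = RESPONSE_WINDOW,
) -> tuple[float, dict[int, float]]:
    """Lowest responding SPL for one frequency.

    A level responds when its pooled curve reaches ``criterion`` ΔF/F0
    anywhere in the response window (frames 11-20, 1-based).  Returns
    (threshold or NaN, per-level peak response).  Non-monotone responding
    patterns keep the literal lowest responding SPL, with a warning.
    """
    peaks = {spl: float(np.max(curve[window])) for spl, curve in curves.items()}
    responding = sorted(spl for spl, p in peaks.items() if p >= criterion)
    if not responding:
        return np.nan, peaks
    threshold = float(responding[0])
    levels = sorted(peaks)
    non_resp_above = [l for l in levels if l > threshold and peaks[l] < criterion]
    if non_resp_above:
        log.warning("non-monotone response pattern: no response at %s dB "
                    "above threshold %s dB", non_resp_above, threshold)
    return threshold, peaks


def threshold_table(
    tensor: ResponseTensor,
    protocol: StimulusProtocol,
    criterion: float = 0.02,
    corr_threshold: float = 0.997,
) -> ThresholdTable:
    """Pool response curves and call thresholds for every frequency."""
    if not tensor.is_dff:
        raise ValueError("threshold calling requires a ΔF/F0 tensor")
    rows, peak_rows = [], []
    for freq in protocol.frequencies:
        curves = {}
        for spl in protocol.levels:
            curve, _, _ = pooled_response_curve(tensor.entries[(freq, spl)],
                                                corr_threshold)
            curves[spl] = curve
        thr, peaks = determine_threshold(curves, criterion=criterion)
        rows.append(dict(frequency_kHz=freq, threshold_dB=thr))
        peak_rows += [dict(frequency_kHz=freq, SPL_dB=spl, peak_dff=p)
                      for spl, p in sorted(peaks.items())]
    return ThresholdTable(pd.DataFrame(rows), pd.DataFrame(peak_rows))


def response_image(entry: np.ndarray) -> np.ndarray:
    """Average response image: per-pixel mean of ΔF/F0 over the stimulus
    frames (11-15, 1-based)."""
    return entry[STIM_WINDOW].mean(axis=0)
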