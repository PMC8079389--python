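"""End-to-end workflows: spontaneous-coupling and evoked-threshold analyses.

Each run writes its tabular outputs as CSV plus a JSON manifest recording
every parameter, so a rerun with the same configuration and inputs
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import correlation as corr
from . import diffusion, evoked, io, linescan, preprocess
from .config import AnalysisConfig
from .core import MovieStack, RoiMaskSet

log = logging.getLogger(__name__)


def _write_manifest(out: Path, cfg: AnalysisConfig, stage: str, extra: dict) -> None:
    d = dataclasses.asdict(cfg)
    manifest = {"stage": stage, "version": __version__, "config": d, **extra}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_spontaneous_pipeline(
    cfg: AnalysisConfig,
    movie: MovieStack | None = None,
    masks: RoiMaskSet | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Preprocess a spontaneous movie, then detect events, quantify
    bilateral correlations, and embed pixels with a diffusion map.

    Inputs come from ``cfg.movie``/``cfg.masks`` unless passed directly.
    Returns the in-memory results and writes CSV artifacts plus a
    manifest under ``out_dir``.
    """
    if movie is None:
        if cfg.movie is None:
            raise ValueError("no movie given (config.movie is unset)")
        movie = io.read_movie(cfg.movie)
    if masks is None:
        if cfg.masks is None:
            raise ValueError("no masks given (config.masks is unset)")
        masks = io.read_masks(cfg.masks)
    if not masks.outside.any():
        raise ValueError("masks lack an outside-ROI label: the partial-"
                         "correlation control regressor requires one")
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *a, **k):
        try:
            return fn(*a, **k)
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed on movie of shape {movie.data.shape}: {exc}"
            ) from exc

    dff, masks_ds, motion, fit = stage("preprocess", preprocess.preprocess_movie,
                                       movie, masks,
                                       smooth_sigma=cfg.smooth_sigma,
                                       f0_percentile=cfg.f0_percentile,
                                       svd_rank=cfg.svd_rank,
                                       svd_variance=cfg.svd_variance,
                                       register=cfg.register)

    # Line-scan events in the left hemisphere
    hemi = masks_ds.left
    rows, cols = np.nonzero(hemi)
    rect = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    angle = linescan.estimate_axis_angle(dff, hemi)
    log.info("line-scan rectangle %s, axis angle %.1f deg", rect, angle)
    lsmap = stage("linescan", linescan.compute_line_scan, dff, rect, 0.0)
    catalog = stage("events", linescan.detect_band_peaks, lsmap,
                    amp_threshold=cfg.event_threshold, smooth=cfg.event_smooth)
    catalog = linescan.censor_motion_events(catalog, motion)
    summary = linescan.summarize_events(catalog)

    seeds = stage("seeds", corr.select_representative_seeds, dff, masks_ds,
                  motion, band_threshold=cfg.band_threshold)
    stats = stage("bilateral", corr.bilateral_stats, dff, masks_ds, motion,
                  seeds=seeds)
    region_props = None
    if seeds["low"] is not None:
        cmap = corr.seed_correlation_map(dff, seeds["low"], masks_ds, motion)
        try:
            region_props = corr.correlation_region_properties(
                cmap, masks_ds, threshold=cfg.region_threshold)
        except ValueError:
            log.warning("no suprathreshold region at the low seed")

    embedding = stage("embed", diffusion.embed_movie, dff, masks_ds.ic,
                      t=cfg.diffusion_time)

    # artifacts on disk
    io.write_table(out / "events.csv", catalog.events)
    io.write_table(out / "event_summary.csv",
                   pd.DataFrame([dataclasses.asdict(summary)]))
    bil = pd.DataFrame([{"global_r": stats.global_r,
                         **{f"sbbc_{k}": v for k, v in stats.sbbc.items()},
                         "sbbc_averaged": stats.sbbc_averaged}])
    io.write_table(out / "bilateral.csv", bil)
    if region_props is not None:
        io.write_table(out / "region_props.csv",
                       pd.DataFrame([dataclasses.asdict(region_props)]))
    emb = pd.DataFrame(np.c_[embedding.pixels, embedding.coords],
                       columns=["row", "col", "coord1", "coord2", "coord3"])
    io.write_table(out / "embedding.csv", emb)
    io.write_motion(out / "motion.csv", motion)
    _write_manifest(out, cfg, "spontaneous",
                    {"bleach_fit": dataclasses.asdict(fit),
                     "line_scan_rectangle": list(rect),
                     "axis_angle_estimate": angle,
                     "representative_seeds": {k: list(v) if v else None
                                              for k, v in seeds.items()}})
    return dict(summary=summary, stats=stats, region_props=region_props,
                embedding=embedding, catalog=catalog, motion=motion,
                bleach_fit=fit, dff=dff, masks=masks_ds, seeds=seeds)


def run_evoked_pipeline(
    cfg: AnalysisConfig,
    sessions: list[tuple[MovieStack, pd.DataFrame]],
    protocol: evoked.StimulusProtocol | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Average trials per frequency-SPL condition, normalize, pool
    response curves and call per-frequency auditory thresholds."""
    if protocol is None:
        protocol = evoked.build_stimulus_protocol(seed=cfg.seed)
    fpt = protocol.frames_per_trial
    for movie, trial_log in sessions:
        if movie.n_frames < trial_log.start_frame.max() + fpt:
            raise ValueError("trial log exceeds session movie frame count")
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tensor = evoked.average_trials(sessions, protocol)
    tensor = evoked.evoked_dff(tensor)
    table = evoked.threshold_table(tensor, protocol,
                                   criterion=cfg.response_criterion,
                                   corr_threshold=cfg.pooling_correlation)
    images = {key: evoked.response_image(entry)
              for key, entry in tensor.entries.items()}

    io.write_table(out / "thresholds.csv", table.table)
    io.write_table(out / "response_peaks.csv", table.peaks)
    _write_manifest(out, cfg, "evoked",
                    {"n_sessions": len(sessions),
                     "combinations": protocol.n_combinations,
                     "frames_per_trial": fpt})
    return dict(thresholds=table, tensor=tensor, images=images,
                protocol=protocol)
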