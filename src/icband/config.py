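"""Run configuration: one source of truth for every tunable.

Defaults are the constants used consistently across the study's
analyses (smoothing sigma 1 px, 2x2 pooling, 5th-percentile F0, 5%
ΔF/F0 event threshold, 0.5 px motion threshold, 1000 seeds, 0.95
region threshold, 0.997 pooling correlation, 2% response criterion,
frame windows 11-15 / 11-20, baseline frames 1-10).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # preprocessing
    smooth_sigma: float = 1.0          # px
    pool_size: int = 2                 # average-pooling filter
    f0_percentile: float = 5.0
    motion_threshold: float = 0.5      # px
    svd_variance: float = 0.90
    svd_rank: int | None = None
    register: bool = True
    # event detection
    event_threshold: float = 0.05      # ΔF/F0
    event_smooth: int = 5              # spatiotemporal mean filter size
    # correlation
    seed_count: int = 1000
    region_threshold: float = 0.95
    band_threshold: float = 0.6        # representative-seed band visibility
    neighborhood: int = 5              # max-correlation averaging filter
    # diffusion embedding
    diffusion_time: int = 1
    # evoked analysis
    pooling_correlation: float = 0.997
    response_criterion: float = 0.02   # ΔF/F0
    stim_window: tuple[int, int] = (11, 15)     # 1-based inclusive
    response_window: tuple[int, int] = (11, 20)
    baseline_window: tuple[int, int] = (1, 10)
    # run
    seed: int = 0
    movie: str | None = None
    masks: str | None = None
    out_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(names)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)
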