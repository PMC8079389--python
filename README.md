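# icband

Analysis of bilateral spontaneous and tone-evoked activity in wide-field
calcium-imaging movies of the developing auditory midbrain.

Before hearing onset, the inferior colliculus (IC) generates spontaneous
calcium transients that appear as discrete bands — elongated along the
anteroposterior axis, confined along the future tonotopic axis — and the
two hemispheres produce these events in near-mirror synchrony.  `icband`
implements the analysis chain used to quantify that phenomenology:

- **preprocess** — photobleach correction, subpixel rigid registration
  (frames moving > 0.5 px flagged and censored), Gaussian smoothing,
  ROI masking, 2×2 pooling, SVD denoising, and ΔF/F0 normalization
  against a per-pixel 5th-percentile baseline.
- **linescan** — reduction to position × time line-scan maps, detection
  of spatiotemporal peaks (coincident 1-D maxima over space and time,
  ≥ 5% ΔF/F0 after 5×5 smoothing), and the five event statistics:
  frequency, duration, inter-peak interval, normalized bandwidth, peak
  amplitude.
- **correlation** — partial Pearson correlations controlling for the
  mean trace outside the IC (removing non-specific global fluctuations):
  global bilateral correlation between hemisphere-mean traces, dense
  seed-based maps, maximum symmetric-region correlation (SbBC),
  high-correlation region shape (ellipse a/b, relative area), and
  representative low/mid/high-frequency seed selection.
- **diffusion** — diffusion-map embedding of pixels by activity
  similarity (Gaussian affinity with adaptive scale σ = 2 × std of
  pairwise distances; eigenfunctions of the Markov matrix), which
  resolves the IC's mirror-symmetric functional domains from spontaneous
  activity alone.
- **evoked** — the 84-combination SAM-tone protocol (4–32 kHz in
  half-octave steps × 96→8 dB SPL in 8-dB decrements; 50-frame trials at
  10 Hz), trial averaging, pooled response curves from the r > 0.997
  region around the max-responding pixel, and per-frequency auditory
  thresholds (lowest SPL whose curve crosses 2% ΔF/F0 in frames 11–20).
- **synthetic** — a seeded generator of spontaneous and evoked movies
  with known ground truth: Poisson band events with single-medial /
  dual-lateral (tonotopic-reversal) geometry, GCaMP6s-like kinetics, a
  bilateral coupling probability `c`, plus bleaching, motion, global
  background, and noise artifacts.  Every analysis stage has a recovery
  test against this generator.

The key quantity throughout is the partial correlation

    r_xy·z = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))

between traces x and y controlling the outside-ROI mean z, and the
coupling summary statistics built on it (global bilateral r; SbBC = the
maximum 5×5 neighborhood-mean correlation in the contralateral region
symmetric to the seed's hemisphere).

## Worked example

Simulate a fully coupled 5-minute session and quantify bilateral
coupling:

```python
from icband import synthetic, preprocess, correlation as corr

cfg = synthetic.SyntheticSpontConfig(duration=300.0, coupling=1.0, seed=5)
movie, masks, truth = synthetic.generate_spontaneous_movie(cfg)

dff, masks_ds, motion, fit = preprocess.preprocess_movie(movie, masks)
stats = corr.bilateral_stats(dff, masks_ds, motion)
print(f"global bilateral r = {stats.global_r:.4f}")
print(f"SbBC low/mid/high  = { {k: round(v, 4) for k, v in stats.sbbc.items()} }")
print(f"averaged SbBC      = {stats.sbbc_averaged:.4f}")
```

Output:

```
global bilateral r = 1.0000
SbBC low/mid/high  = {'low': 0.9918, 'mid': 0.7407, 'high': 0.922}
averaged SbBC      = 0.8848
```

With every event mirrored (`coupling=1.0`) the hemisphere-mean traces
are nearly identical, so the global bilateral correlation is ≈ 1 even
though the movie carries noise, a global background fluctuation, and a
static anatomical texture; the seed-based values are high wherever the
mirrored band falls inside the symmetric contralateral region.  Rerun
with `coupling=0.0` and the global correlation drops to ≈ 0 while event
rate and amplitude are unchanged — coupling and activity level are
independent knobs.

The same pipeline is available from the shell:

```sh
icband simulate --seed 11 --duration 120 --coupling 1.0 --out session/
icband bilateral --movie session/movie.tif --mask session/masks.tif
icband run-spont --movie session/movie.tif --mask session/masks.tif --out results/
```

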