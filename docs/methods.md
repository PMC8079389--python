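# Methods

`icband` analyzes wide-field calcium-imaging movies of the dorsal surface
of the developing inferior colliculus (IC), where spontaneous activity
before hearing onset appears as discrete band-shaped transients and the
two hemispheres fire in near-mirror synchrony.  The package implements the
full analysis chain — preprocessing, line-scan event detection, bilateral
partial-correlation mapping, diffusion-map embedding, and tone-evoked
threshold calling — together with a synthetic movie generator that
emulates the data's statistical structure, so that every stage can be
verified against known ground truth without access to raw recordings.

## The synthetic generator

### What it emulates

A spontaneous event is a band: homogeneous along the anteroposterior
(major) axis of a hemisphere and Gaussian-confined along the mediolateral
(tonotopic) axis.  An event carries a tonotopic coordinate `p ∈ [0, 1]`
(0 = medial, the future low-frequency zone).  Medial events (`p <
p_split`, default 0.33) render a single band; more lateral events render
a dual band, the partner placed at the reversal-symmetric position
`p' = 1 + p_split − p`, mimicking the mirror-reversed tonotopic gradients
of the dorsal IC.  The quantitative fold geometry is the package's own
choice; only the single-medial / dual-lateral phenomenology is
constrained by observation.

Event timing is Poisson at rate λ (default 6 events/min per hemisphere).
Bilateral coupling is a single probability `c`: shared events occur at
rate λ·c and appear in both hemispheres at the homologous tonotopic
position (optionally jittered in time and position), independent events
at rate λ·(1−c) per side.  Each hemisphere therefore sees rate λ at any
`c`, so activity level and coupling are dissociated — the synthetic
analog of manipulations that abolish bilateral correlation without
changing event statistics.

Temporal kernel: linear rise over 1 frame, exponential decay with
τ = 1.5 s at 10 Hz — a GCaMP6s-like transient.  Peak ΔF/F0 amplitudes
are lognormal (median 0.20, shape 0.3).  This calibration makes typical
*measured* peaks sit clearly above the 5% ΔF/F0 detection threshold: at
desk-scale pixel grids the prescribed 5×5 spatiotemporal smoothing
attenuates the sharp single-frame rise by roughly 0.45×, so a lower
median would park half the population at the threshold and confound
rate-recovery tests with threshold censoring.

The raw movie is `F_b(x, y) · (1 + activity)` where `F_b` is a static,
mirror-symmetric smooth random texture (10% contrast around 100 a.u.)
standing in for anatomical structure — it is what rigid registration
locks onto, and its mirror symmetry keeps the `c = 1`, zero-noise movie
exactly invariant under midline reflection plus hemisphere swap.
Artifacts are layered on top in a fixed order: multiplicative
single-exponential bleaching `exp(−t/τ_b)`, rigid per-frame translations
(cubic interpolation, edge-replicating fill), and i.i.d. Gaussian noise
(default σ 0.5 a.u.).  A slow global fluctuation (Gaussian-filtered
noise, default σ 0.3 a.u.) is added everywhere, *including outside the
IC* — this is the non-specific whole-brain signal that the
partial-correlation control is designed to remove, and it also keeps the
outside-ROI control trace a well-defined regressor after low-rank
denoising.

Evoked sessions follow the stimulation protocol exactly: 84
frequency–SPL combinations per session in seeded random order, 50 frames
per trial (1 s pre, 0.5 s stimulus, 3.5 s post at 10 Hz).  The response
is a band at the stimulated frequency's tonotopic center in both
hemispheres whose amplitude is a logistic function of SPL, parameterized
to cross 2% ΔF/F0 exactly at the configured true threshold (saturation
0.15 ΔF/F0, slope 6 dB).

### What it does not emulate

No biophysics: coupling is a phenomenological probability, not a cochlear
or efferent model.  Noise is Gaussian rather than photon-limited; motion
is purely translational; bleaching is a single exponential; the baseline
texture is a stationary random field, not vasculature.  Passing
recovery tests therefore demonstrates that the analysis correctly
inverts its own generative assumptions at realistic signal-to-noise, not
that it is robust to every failure mode of real recordings.

## Preprocessing

Seven steps in fixed order, each refusing to run twice (provenance flags
on the movie object):

1. **Photobleach correction** — single-term exponential `A·exp(−t/τ)`
   fit to the frame-mean trace by log-linear least squares; each frame is
   *divided* by `f(t)/f(0)`.  Whether the original pipeline corrected
   subtractively or divisively is not documented; divisive correction is
   used because the bleaching process is multiplicative in gain.
   A non-decaying trace returns the movie unchanged with a degenerate
   flag.
2. **Rigid registration** — Fourier phase correlation against the
   session-mean frame (or a chosen reference), 50× upsampled for
   subpixel precision.  Frames are mean-subtracted and Hann-windowed
   before correlation; without apodization, spectral leakage from the
   non-periodic boundary limits accuracy to ≈0.3 px on smooth images,
   with it the recovery error on known shifts stays below 0.1 px.
   Frames whose shift amplitude exceeds 0.5 px are flagged corrupted and
   excluded from all correlation and event summaries downstream.
3. **Gaussian smoothing** — σ = 1 px per frame, kernel truncated at 4σ.
4. **ROI masking** — out-of-mask pixels become NaN and every later
   statistic ignores them.  The mask keeps the IC hemispheres *and* the
   outside-ROI region: the latter's mean trace is the control regressor.
5. **2×2 average pooling** — blocks straddling the mask average their
   in-mask members only; odd trailing rows/columns are dropped with a
   warning.  Labels pool by majority.
6. **SVD denoising** — the frames × pixels matrix is centered per pixel,
   decomposed, and rebuilt from the components explaining 90% of the
   temporal variance (rank overridable).  Centering matters: on raw
   values the static baseline dominates the spectrum and a variance
   criterion collapses everything to rank 1, which makes all traces
   perfectly correlated.
7. **ΔF/F0** — per pixel against the 5th percentile of its trace
   (linear interpolation between order statistics).

## Event detection and statistics

A rectangular region is reduced to a line-scan map (tonotopic position ×
time) by averaging along the band major axis; the axis angle can be
estimated from the orientation of the thresholded mean-activity image
but is always logged and overridable.  The map is smoothed with a 5×5
mean filter; 1-D local maxima are found independently along space (per
frame) and time (per position) — plateaus resolve to their first index —
and a peak is kept where both scans coincide and the smoothed value
reaches 5% ΔF/F0.

Widths are full widths at half maximum measured on the smoothed map,
with the reference level halfway between the peak and its *prominence
base* (the higher of the two side minima).  For an isolated peak on a
quiet baseline this equals FWHM above zero; under realistic event rates
it removes the pedestal contributed by overlapping decay tails and the
slow global background, which otherwise inflates widths by ~15%.  Events
whose half-height window is clipped by the record edge keep twice the
measurable side and carry an `edge` flag.

Summary statistics: event frequency (retained events per minute), mean
duration (temporal FWHM in seconds), mean inter-peak interval
(same-frame peaks collapse to one event so intervals are never zero),
normalized bandwidth (spatial FWHM / IC width), and mean peak amplitude.
Events overlapping any motion-corrupted frame are censored from all
summaries.

## Bilateral correlation analysis

All correlations are first-order partial Pearson correlations
controlling for the mean trace over all pixels outside the IC, computed
on non-corrupted frames.  A constant control falls back to plain Pearson
with a logged note; a control perfectly collinear with an input is an
error.  The scalar formula is cross-checked against residual regression
to 1e-10 in the tests.

- **Global bilateral correlation**: partial correlation between the two
  hemisphere-mean traces.
- **Seed maps**: partial correlation of each in-ROI pixel against a seed
  pixel, vectorized over the field; the seed maps to exactly 1.
- **SbBC** (seed-based bilateral correlation): each pixel of the
  contralateral region symmetric to the seed's hemisphere (obtained by
  reflecting that hemisphere across the midline — the symmetry axis of
  the two hemisphere masks, replacing the original workflow's manually
  drawn ROIs) is scored by its 5×5 in-ROI neighborhood mean; the best
  score is reported, ties resolving to the smallest row then column.
- **Region properties**: the seed-connected component of pixels with
  r > 0.95, its second-moment ellipse aspect ratio a/b, and its area
  relative to the hemisphere.
- **Representative seeds**: marching medial→lateral along the
  hemisphere's central transect, the low-frequency seed is the most
  medial whose thresholded (r > 0.6, configurable; the level defining a
  "visible" band is not documented) ipsilateral pattern forms one
  connected band; the mid and high seeds sit ≥3 steps further lateral
  where two bands appear.  Steps count pixel columns on the downsampled
  grid, the resolution at which the original seed lattice (1000 seeds)
  is spaced.

## Diffusion-map embedding

Pixel traces are nodes of a weighted graph with Gaussian affinity
`W_ij = exp(−d_ij²/σ²)`, `d` the Euclidean distance between traces and
σ = 2 × the standard deviation of all pairwise distances (adaptive to
the data landscape; the kernel has no factor 2 in the denominator so
this σ rule is well defined).  Eigenpairs of the row-normalized Markov
matrix are computed through the symmetric conjugate `D^{-1/2} W D^{-1/2}`
with a dense solver (the analysis runs on the downsampled field, ≤ ~3000
pixels).  Diffusion coordinates are `λ_k^t v_k` for the first three
nontrivial eigenpairs, t = 1 by default.  On fully coupled synthetic
movies, mirrored tonotopic columns across the hemispheres land nearer
each other in diffusion space than permuted pairings (permutation test in
the suite) — the synthetic analog of resolving mirror-symmetric
functional domains from spontaneous activity alone.

## Evoked thresholds

Trials sharing a frequency–SPL combination are averaged frame-wise
across sessions; ΔF/F0 is then taken against the mean of the 10
pre-stimulus frames of each averaged entry.  Frame windows quoted
1-based ("frames 11–15") map to 0-based slices via `frame_window`,
which is itself under test.  For each entry, the pixel maximal during
the stimulus frames (11–15) seeds a plain Pearson correlation map on the
averaged entry — at the 0.997 pooling level partial control is
unnecessary because averaging has already suppressed uncorrelated
fluctuations — and the mean trace over the r > 0.997 region is the
response curve.  A level responds when that curve reaches 2% ΔF/F0
anywhere in frames 11–20; the threshold is the lowest responding SPL,
applied literally even for non-monotone patterns (with a warning), and a
sentinel marks frequencies with no response.  Response images average
frames 11–15.

At zero noise the pooled region includes the band's faint Gaussian tails
(everything correlates perfectly), which dilutes the curve and shifts
all called thresholds up by a constant ~2 steps while preserving
ordering; with realistic noise the 0.997 region tightens to the band
core and recovery is within one 8-dB step of the configured truth.

## Numerical choices and degenerate inputs

- Coordinates are (row, col), 0-based, row 0 at the top; frames 0-based
  internally with 1-based published windows translated explicitly.
- Percentiles interpolate linearly between order statistics.
- 1-D maxima on plateaus take the first index; neighborhood-mean and
  argmax ties resolve in row-major order.
- Correlations are clipped to [−1, 1] against rounding at |r| = 1.
- Bleach fits reject records shorter than 10 frames; all-zero frames
  register with zero shift; empty event catalogs summarize to frequency
  0 with undefined (NaN) shape statistics.

## Problem sizes

The test suite and the acceptance script run the generator at desk
scale: fields of view of 24×36 to 64×96 pixels and records of 1–30
minutes, chosen so each recovery experiment has enough events or frames
for its statistical tolerance (e.g. rate recovery uses a 30-minute
record, ≈180 events, so 3 standard errors is ±22%) while the full suite
stays fast.  The analysis code itself is size-agnostic.

## Known limitations

- The dense eigensolver bounds the embedding to a few thousand pixels;
  larger fields should be pooled first (the pipeline does).
- Registration assumes translational motion; rotation or non-rigid
  deformation becomes residual error and, beyond 0.5 px, frame censoring.
- The bleach model is single-exponential by specification; two-component
  decays leave a residual trend (reported in the fit's residual RMS).
- Representative-seed selection assumes the band-count phenotype exists;
  movies without dual-band structure report explicit not-found slots.
- The evoked threshold rule is a literal lowest-responding-SPL call; it
  does not require sustained crossings (single-sample crossing suffices),
  matching the documented criterion.
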