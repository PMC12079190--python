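# Methods

`fusact` implements the analysis chain of bedside functional ultrasound
(fUS) neuroimaging: ultrafast plane-wave acquisitions are turned into
power-Doppler image series, conditioned, and regressed voxel by voxel
against a hemodynamic model of a block-design stimulus, yielding
FDR-thresholded activation maps and ROI-level response statistics. A
seeded phantom generator reproduces the acquisition and the auditory
experiment so that every stage is testable without patient data.

## Doppler core

**Acquisition model.** Frames are compounded coherently over 7 plane-wave
angles (−6°…6°), triple temporally averaged to a 500 Hz compound frame
rate (pulse repetition frequency = 7 × 3 × 500 = 10.5 kHz), and grouped
into non-overlapping 250-frame blocks, so the power-Doppler output rate
is 500/250 = 2 Hz. Blocks are aligned to acquisition start; block
timestamps are block centers.

**Clutter filtering.** Each block is rearranged into the Casorati matrix
(space × slow-time, row-major over (z, x); the reshape is round-trip
tested). The filter removes the `k = floor(f · nt)` lowest-order singular
components with `f = 0.13` — the rank-based reading of a "13 %"
threshold, standard in ultrafast Doppler, with conservative `floor`
rounding. The decomposition is computed in float64 through the nt × nt
Gram matrix (exact for the full singular spectrum, and much cheaper than
a dense SVD when pixels ≫ frames); the spectrum and removed count are
recorded per block. The threshold is applied per block (each block gets
its own adaptive subspace); a single global decomposition is not
offered. Power Doppler is the per-pixel temporal mean of the squared
magnitude of the filtered block. No spectral wall filter is applied
beyond the SVD. The PRF is always the exact derived product (10.5 kHz
at the defaults), never a rounded nominal value.

**Numerical tolerances.** Filter output matches explicit top-k
outer-product subtraction to < 1e-8 relative Frobenius error; the sum of
squared singular values matches the block's squared Frobenius norm to
< 1e-10 relative.

## Preprocessing

Fixed order, logged in the output metadata: motion correction → spatial
smoothing → voxel normalization → temporal smoothing.

* **Motion correction** registers every PD frame to a reference frame by
  subpixel translation (upsampled phase cross-correlation, factor 20),
  a deliberate simplification of clinical nonrigid schemes; externally
  computed displacement fields can be injected. Translation at the 2 Hz
  block level can only address motion that is quasi-static within a
  block; this is the method's main known limitation (see below).
* **Spatial smoothing**: per-frame 2-D Gaussian, σ = 1 pixel, reflective
  boundaries (σ is in pixels; the source gives no units).
* **Normalization**: per voxel, percent change
  `100 (x − μ_ref)/μ_ref` against the 20-s prestimulus baseline window
  (a zero-mean `demean` mode is available; the reference window is
  configurable and logged). Voxels with non-positive reference means are
  flagged invalid and excluded downstream.
* **Temporal smoothing**: centered 5-point moving average; edges use
  shrinking windows so constants are preserved.

## Activation mapping

**Hemodynamic model.** The delayed-gamma response
`h(t) = ((t−δ)/τ)^{n−1} e^{−(t−δ)/τ}` for `t ≥ δ` (0 before), with
τ = 0.7 s, δ = 1.5 s, n = 3, normalized to unit peak at
`δ + (n−1)τ = 2.9 s`. The exact parameterization conventions differ
across the literature; this form maps the three parameters directly and
is isolated behind one function. Unit-peak normalization makes the task
coefficient interpretable as peak percent change.

**Design and fit.** The task regressor is the stimulus boxcar convolved
with the kernel at the block rate, peak-normalized; an intercept is
always included and a linear drift column is available but off by
default (no confounds are modeled). The GLM is ordinary least squares
per voxel with a two-sided Student-t on the task coefficient
(a positive-only masking option exists).

**Known-filter variance correction.** The 5-point moving average is a
linear operator K the pipeline itself applies; ignoring it inflates
naive t-scores by roughly √5 for low-frequency regressors. When fitting
smoothed data the GLM therefore uses `Var(β̂) = σ² (X⁺ V X⁺ᵀ)` with
`V = KKᵀ`, `σ̂² = e'e / tr(RV)`, and Satterthwaite effective degrees of
freedom `tr(RV)² / tr(RVRV)` — the classical known-autocorrelation
correction for self-applied smoothing. Unknown noise autocorrelation is
deliberately not modeled (no prewhitening).

**Thresholding.** Benjamini–Hochberg FDR over valid voxels at q = 1e-3,
with the uncorrected p < 1e-3 mask also recorded, since sources are
ambiguous about whether the headline threshold is corrected. NaNs
propagate and are never discoveries.

## ROI statistics

ROIs are ≈ 2 mm × 2 mm rectangles (half-open pixel windows derived from
the grid spacing). The ROI time course spatially averages the
*conditioned raw-unit* series (motion-corrected, smoothed) and then
converts to percent change against the baseline window — ratio of means.
The alternative (averaging per-voxel percent maps) is badly conditioned:
sub-pixel vessel displacement sweeps blood across near-zero-baseline
voxels and single voxels can contribute thousands of percent. The ratio
of means is also exactly invariant to affine rescaling of the PD series.

Response statistics compare samples inside stimulation windows lagged by
the HRF peak time (2.9 s default, configurable) against rest samples
(pooled rest by default; prestimulus-baseline-only available), with a
two-sided Welch t-test (Student's pooled variant selectable). Both a
p < 0.001 and a stricter p < 1e-5 significance flag are reported, along
with per-stimulus means and the baseline z-score course
(`z = (x − μ_base)/σ_base`, sample std).

Automatic ROI placement scans all candidate windows whose mean PD
intensity exceeds the 70th percentile of window means (well-defined
vasculature), scoring each window by the *vascularity-weighted* mean
t-score (reactive: maximal; nonreactive: minimal |t|). Weighting by PD
matters: the ROI time course is dominated by the bright pixels, and an
unweighted mean would rank nearly empty windows whose few bright pixels
are strongly reactive as "nonreactive". Selected windows never overlap;
ties break by (z, x) corner order; an all-zero t-map falls back to
vascular-intensity ordering with a warning.

## Quality metrics

CNR uses `20 log10((μ_s − μ_b)/σ_b)` on linear-power PD images
(amplitude convention; a `10 log10` power convention is selectable) and
the convention used is always recorded — a dB figure is only meaningful
together with its definition. FWHM interpolates half-maximum crossings
linearly on a sampled profile after subtracting the profile's edge
median as background; sub-sample widths are flagged.

## Synthetic phantom

The generator emulates the auditory experiment: 20 s baseline, three 5-s
stimuli separated by 20-s rests (onsets 20/45/70 s, 95 s total, 190
blocks at 2 Hz).

* **Tissue clutter**: a smooth positive amplitude map (default mean 30,
  ±20 % smooth spatial variation) times `1 + Σ_j c_j P_j(z,x) g_j(t)`
  with two smooth random spatial patterns and two slowly varying
  temporal components (relative size 0.02) — exactly rank ≤ 3 before
  motion, so SVD behavior is provable.
* **Blood**: connected tube-shaped vessel segments (widths 4–8 px,
  placed disjointly with a 4-px margin so reactive/nonreactive ground
  truth is unambiguous), axial velocities 5–15 mm/s — safely below the
  slow-time aliasing bound `c·rate/(4 f_c) ≈ 24.7 mm/s` at 7.8 MHz.
  Each vessel pixel carries
  `a √(1+ΔCBV(t)) · g_p(t) · e^{i(2π f_d t + φ_p)}` with
  `f_d = 2 v f_c / c` on the 500 Hz clock and `g_p` a unit-power complex
  AR(1) speckle envelope (lag-1 correlation 0.2 at 500 Hz). The speckle
  term is essential: fully coherent blood would concentrate each vessel
  into one dominant singular component that a rank-32 cutoff would
  delete; decorrelating speckle spreads blood energy across the
  singular-value bulk, as in real ultrafast Doppler. Speckle can be
  disabled (`speckle_correlation=None`) for analytic Doppler-phase
  scenes. Default blood amplitude 0.15 versus compounded noise
  σ_eff ≈ 0.022 (≈ 17 dB per frame).
* **Activation**: `ΔCBV(t) = effect_size × (boxcar ⊛ HRF)`,
  peak-normalized, on the first vessel's pixels; amplitude scales as
  `√(1+ΔCBV)` so power Doppler scales exactly as `1+ΔCBV`. Default
  effect size 0.10 (the scale of reported ROI changes).
* **Noise**: complex white Gaussian, σ = 0.1 per pre-averaging frame
  (σ/√21 on the compounded fast path).
* **Motion**: default smooth-nonrigid, ≤ 1 px, a smooth two-tone
  waveform around 0.3 Hz scaling a smooth random displacement pattern
  (16-px correlation length); frame 0 is at zero displacement. A rigid
  mode exercises the corrector; displacement fields are refreshed at
  20 Hz and held constant in between (motion is ~0.3 Hz; finer sampling
  changes nothing at the pixel scale). Motion displaces the smooth
  tissue field by bilinear resampling and each vessel's *amplitude
  envelope* (square root of the displaced volume fraction); the speckle
  process stays attached to the vessel, because interpolating a
  spatially white speckle field would spuriously destroy its power
  (E|Σ wᵢ gᵢ|² = Σ wᵢ², down to 0.25 at half-pixel shifts).

**Two generation paths.** `simulate_angle_frames` emits exact per-angle
frames at the pre-averaging clock (1500 Hz × 7 angles) and is meant for
short sequences; `simulate_compounded` exploits that the deterministic
signal is constant across angles and within an averaging triple (the
Doppler clock is the compound clock), so compounding + averaging reduces
exactly to simulation at 500 Hz with noise σ/√21 — this path makes
full-protocol runs tractable (a 95-s, 64×64 run is ~1.5 GB of complex64
frames). Both are bit-reproducible from their seed.

**ROI-scale generator.** `simulate_roi_timecourse` produces
percent-change time courses with a step (or HRF-shaped) response of a
chosen magnitude inside the lagged stimulation windows plus white noise
(default 0.5 %/block, the ROI-averaged fluctuation scale of the default
phantom). Effect-recovery calibration uses the step shape, for which the
window-mean estimator is exactly unbiased; an HRF-shaped response's
window mean is structurally ~10–15 % below its peak-normalized
amplitude, which is a property of the estimand, not an estimator bias.

**What the phantom does not emulate.** Speckle from tissue parenchyma,
depth-dependent attenuation and aberration through the cranial window,
pulsatile (cardiac-gated) flow, vessel networks with branching geometry,
out-of-plane motion, and physiological low-frequency oscillations.
Passing tests therefore demonstrate the correctness and calibration of
the *pipeline*, not clinical performance on patient data.

## Problem sizes and defaults in tests

Unit tests use 16–48 px grids and sub-second protocols; full-protocol
(95 s) checks run at 32–64 px. The acceptance script averages contrast
over 10 single-block phantoms and reports the worst-case reactive-ROI
p-value across 10 full-protocol phantoms at the 64×64 default.

## Known limitations

* **Clutter-filter cross-talk.** The rank cut removes a fixed
  `floor(0.13·nt)` of the block's *adaptive* singular subspace. When one
  vessel's power rises (activation), its components crowd the cut and
  less of every other vessel's energy is removed, inducing a small
  stimulus-locked response on non-activated vessels. On the default
  64×64 grid this coupling is well below the voxelwise detection
  threshold, but it grows as the vessel pixel count approaches the
  250-frame block length (a caveat for strongly scaled-down phantoms,
  characterized by a dedicated test), and it contributes a percent-scale
  bias to "nonreactive" ROI statistics on crowded scenes.
* **Motion-induced drift.** Residual nonrigid drift after translation
  correction is an unmodeled slow noise component: it makes null
  voxelwise t-scores conservative and, when it happens to correlate with
  the task, can flag vessel-border voxels. ROI statistics are robust to
  it (ratio of means); voxelwise calibration tests therefore run on
  motion-free scenes while the motion regime is exercised by the
  corrector tests and the ROI statistics.
* Translation-only motion correction cannot undo nonrigid or
  within-block motion; rapid motion (≳ 1 px within a 0.5-s block) smears
  vessel edges irreversibly at the PD level.
* The GLM ignores unknown noise autocorrelation (only the self-applied
  smoothing filter is corrected for); physiological noise would make the
  nominal p-values optimistic on real data.
* The per-block SVD threshold is global and fixed (13 %); no adaptive or
  spatially varying thresholding.
* The gamma-HRF parameterization is one of several in use; alternative
  conventions require only replacing `gamma_hrf`.
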