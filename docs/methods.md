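# Methods

This note documents the generative model of the synthetic BOLD phantoms,
the analysis conventions, the numerical choices, and what the validation
does and does not demonstrate.

## Phantom generative model

### Acquisition geometry and scales

Two presets fix the problem sizes. The **full** preset matches the emulated
acquisition: 64×64×22 voxels of 0.391×0.391×1 mm, TR 2 s, three stimulus
sets (3000 volumes, 100 min), 300-volume resting-state runs, 202 atlas
structures. The **desk** preset, used by the tests, the analysis drivers
and the acceptance script, keeps the full temporal design of one stimulus
set (1020 volumes, 2040 s) on a 32×32×8 grid with 40 structures. All
replication counts quoted below are the package's chosen problem sizes.

### Stimulation protocol

Eight temperatures, 40–54 °C in 2 °C steps. Each stimulus lasts 20 s (5 s
ramp + 15 s plateau) and is followed by 220 s rest; sessions start with a
120 s lead-in. Every set presents each temperature exactly once in a
pseudo-random order, re-drawn so that consecutive sets never repeat a
temperature across the boundary (for eight distinct temperatures the
rejection loop always terminates). The predictor boxcar spans the full
20 s by default; a plateau-only option exists because it is not decidable
from the emulated protocol whether the ramp should be modelled.

### Hemodynamic response

The two-gamma kernel uses gamma densities with scale = dispersion and shape
chosen so the density **mode** equals the stated peak time
(shape = (peak − onset)/dispersion + 1): response peak 16 s, undershoot
peak 40 s, unit dispersions, undershoot ratio 1, normalized to unit
maximum. Anchoring the mode (rather than shape = peak/dispersion, whose
mode lands at peak − dispersion) is what makes the sampled kernel's argmax
land exactly on 16 s.

### Effect models

Responsive structures are the members of two functional groups (a
somatosensory-cortical and a thalamic subnetwork). The **baseline**
amplitude curve is 0 up to 48 °C and rises linearly to `amp_max = 1.5 %`
BOLD at 54 °C — so 48 °C behaves as a null temperature, matching the
observation that group differences appear only from 50 °C. The **rtx**
curve is 0 everywhere except a 0.3 % term at 54 °C (a slight,
non-significant 54 °C rise is part of the emulated phenomenon).

Noise: per-voxel stationary AR(1) Gaussian noise (σ = 1 % signal, ρ = 0.3),
a per-voxel linear drift (uniform slope scale 0.5 % per run), and a shared
global AR(1) signal (σ = 0.3 %). These are the minimal components that
exercise high-pass filtering and global regression.

Stimulus responses carry **per-event, per-subnetwork variability**: a
multiplicative gain jitter (σ = 0.3) and an onset latency jitter
(σ = 0.75 s), drawn independently per event for each responsive functional
group. Without such variability the planted response is a rank-one signal
that global-mean regression removes exactly, leaving no stimulus-driven
connectivity for the network stage to detect — no group difference in
functional connectivity could exist even in principle. The chosen
magnitudes sit in the range reported for trial-to-trial BOLD variability;
they were fixed once as part of the study conditions. Because both the gain
and the latency scale with the amplitude curve, within-subnetwork
connectivity grows with temperature in the baseline group and stays flat
under rtx.

Resting-state phantoms plant a structure-level correlation matrix (default:
r = 0.4 within each functional group) through shared latents added to every
voxel of a structure, plus the same drift/global/AR(1) noise. The planted
matrix is recorded in the provenance. Voxel noise attenuates the *voxel-level*
correlation relative to the planted latent correlation; recovery checks at
a stated r therefore use noise-free phantoms.

Determinism: every generator consumes a single `numpy` Generator seeded by
the caller; identical seeds give bit-identical outputs. Jitter draws happen
regardless of whether a term is active, so the noise stream does not depend
on the effect model.

## Analysis conventions

* **Preprocessing order** (fixed): stimulus runs — pairwise volume
  averaging (TR 2 s → TR_eff 4 s), discard 2 volumes, slice-time
  correction (cubic spline; phantoms are generated without slice offsets,
  so the pipeline default is `none`), optional rigid motion correction
  (phantoms are motion-free by default), 2-pixel in-plane Gaussian
  smoothing, temporal high-pass. Resting-state runs — discard, slice-time,
  motion, 0.1 Hz FFT low-pass. Each operation tracks the acquisition clock
  (`tr`, `t0`) so designs and event windows stay aligned.
* **High-pass filter**: one joint projection out of the linear trend and
  all Fourier components strictly below `cycles`/run-duration (the
  "linear + FFT cycles" composite collapses to this single idempotent
  operator; a sequential detrend-then-FFT implementation leaks ramp energy
  into the passband). The cycle count is scale-dependent to keep the
  *cutoff frequency* fixed: 9 cycles over the 6000 s full-scale run
  = 1.5 mHz, hence 3 cycles over the 2040 s desk run. The 12 s FWHM kernel
  figure is carried as provenance only.
* **GLM**: voxel time courses are converted to % change about their
  temporal mean; regressors have unit peak, so betas read directly as peak
  %BOLD. Design columns are filtered with the same high-pass operator as
  the data, and when the series was pairwise-averaged the regressor is
  averaged over the two constituent acquisition times rather than
  point-sampled (both choices remove filter- and averaging-induced beta
  bias; recovery on noiseless phantoms is then exact to <0.01 %). Serial
  correlation is not modelled (no prewhitening); with AR(1) noise at
  TR_eff = 4 s the voxel-wise type-I error stays within the tested band,
  but this is a calibration caveat, not a guarantee.
* **Event-related metrics**: windows span 10 points before stimulus onset,
  ceil(20 s / TR_eff) = 5 during, 10 after; traces are % change from the
  window's own pre-stimulus mean; the response amplitude is the maximum of
  the during+post segment (sign preserved). On noisy data this maximum has
  a positive floor (the expected maximum of the window noise), which is
  why low temperatures show ≈0.4 % "amplitude" rather than 0 — the same
  behaviour real recordings show.
* **Network traces**: the connectivity stage uses whole-parcel mean time
  courses (not FDR-restricted voxel sets), because empty FDR masks at low
  temperatures and in the rtx group would leave entire group-by-temperature
  cells undefined. Global-mean regression is applied **per temperature
  window**: over a whole task run the global mean is dominated by the
  stimulus response, so a single run-level regression removes the shared
  noise component unevenly between groups and manufactures spurious
  group differences at every edge, including null temperatures.
* **k-standardization** keeps exactly N·k/2 (symmetric) or N·k (directed)
  strongest positive edges; ties break deterministically by ascending
  index; undersupply keeps all positive edges with a warning.
* **Small-world indices** follow the binary formulation: C is the mean
  local clustering coefficient, L the mean shortest path over connected
  ordered pairs (unreachable pairs excluded and flagged, since
  k-standardized graphs can fragment); the reference is the mean over 100
  uniform G(n, m) graphs with matched node and edge counts.
* **Multi-seed matrices** average Fisher-z values (z-then-average, the
  stated processing order) of all structure voxels; a variant restricted to
  FDR-significant voxels sits behind a flag. Seeds are spheres centered on
  the in-parcel voxel nearest the parcel's center of mass — snapping to the
  grid handles non-convex parcels and keeps the 1.173 mm sphere inside one
  1 mm slice.
* **NBS**: component size is the number of edges (extent); node count is
  available as an option. p = (permutations with ≥ observed size)/n_perm,
  so p-values are multiples of 1/n_perm; the (b+1)/(m+1) variant is a flag.
  Unpaired permutations preserve the 18/9 group sizes; the paired engine
  sign-flips within pairs; both report excluded zero-variance elements.
  The discrete max-component statistic makes the test conservative on very
  small graphs (heavy ties); calibration is therefore assessed at the
  study's own graph size (40 nodes).

## Validation: problem sizes and what passing shows

The test suite checks, among others: protocol invariants over seeds
(property tests), HRF timing against fine-grid oracles, BH-FDR /
clustering / path-length / Tukey decisions against independent brute-force
implementations (1000 random instances each; 100 for Tukey, whose
studentized-range evaluations dominate runtime), noiseless parameter
recovery (betas within 1 %, event-related amplitudes within 2 % of the
sampled-convolution oracle, planted resting correlation within ±0.05 at
3000 volumes), type-I calibration of the GLM voxel test, NBS, paired
permutation test and ANOVA (nominal 5 % ± 3 %; 200–300 replications with
n_perm = 200, scaled from 1000), and the end-to-end emulation: over 25
seeded desk-scale cohort replications, NBS detection pooled over
50/52/54 °C ≥ 90 % and false detection pooled over 40–48 °C ≤ 10 %. The
pooled-rate formulation is used because a joint per-replication criterion
("no false positive at any of five null temperatures") would be failed
≈23 % of the time by an exactly calibrated test at α = 0.05.

The parameter-recovery checks run the temporal chain without spatial
smoothing: smoothing deliberately trades spatial specificity, and mixing
across parcel boundaries dilutes boundary-structure betas by up to ~20 % —
a partial-volume property of the operator, not an estimation error.

What passing does **not** show: the phantoms have Gaussian AR(1) noise,
no physiological (cardiac/respiratory) fluctuations, no motion unless
injected, no susceptibility artifacts, and a literal box-plus-HRF response;
calibration and recovery results transfer to real data only to the extent
these assumptions hold. The amplitude floor of the max-based response
metric, the global-regression caveats and the unmodelled serial
correlation are the main places where real-data behaviour will deviate
quantitatively.

## Known limitations

* Motion correction is a simplified rigid-body implementation (negative
  MSE metric, Powell refinement, trilinear resampling) — adequate for the
  motion-free phantoms and the injected-shift tests, not a replacement for
  a production registration tool.
* The 6-DOF registration operates on identical-grid volumes; nonlinear
  warping and manual adjustment loops are out of scope.
* At high temperatures the global-regression residuals retain part of the
  shared noise in the responding group (the global mean is then
  response-dominated), so the detected NBS components extend beyond the
  planted subnetworks; detection *specificity across temperatures* is the
  validated property, not edge-level localization.
* ANOVA/Tukey p-values rely on scipy's studentized-range distribution,
  which is numerically slow; large simulation counts around Tukey are
  intentionally avoided.
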