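# Methods

`tremorsync` quantifies whether rhythmic stimulation (transcranial
alternating current through different electrode montages, or photic
flicker) entrains physiological tremor, and models where the stimulation
current actually flows. This note documents the models, the tunable
parameters, the numerical choices, and what the synthetic data can and
cannot show.

## Phase-stability analysis

### Signal chain

Each 180 s condition block of tri-axial accelerometry is processed as:

1. **Principal-component reduction.** The three mean-centered axes are
   projected onto the top eigenvector of their covariance. This selects
   the plane of maximal tremor power and makes the analysis insensitive
   to sensor orientation. The loading sign is fixed (largest-magnitude
   loading positive) so reruns are deterministic.
2. **Spectral peak.** Thomson's multitaper estimator with `K = 12` DPSS
   tapers; the time-bandwidth product is taken as `NW = (K+1)/2` (the
   standard relation `K = 2NW − 1` inverted, since only `K` is
   prescribed), giving a resolution of `2NW/T ≈ 0.07` Hz on a 180 s
   block. The peak is the power argmax inside a configurable 4–14 Hz
   physiological-tremor band — an automated stand-in for reading the
   spectrum by eye, which needs a band to exclude low-frequency drift —
   rounded to 0.1 Hz, ties toward the lower frequency.
3. **Zero-phase band-pass.** Separate third-order Butterworth high- and
   low-pass filters at peak ± 1 Hz (a 2 Hz design passband), each applied
   forward and backward (`sosfiltfilt`). The net phase response is
   identically zero, so instantaneous-phase estimates carry no filter
   delay. Forward-backward application squares each magnitude response;
   cutoffs are applied as designed, with no compensation, so the absolute
   passband gain of the cascade is ≈ 0.46 at the center frequency. A
   constant gain is irrelevant downstream: phase is unaffected and every
   amplitude quantity is normalized per block. The filter is re-centered
   on each block's own peak, so modest between-block frequency shifts do
   not masquerade as entrainment changes.
4. **Edge trimming.** The first and last 2 s of the filtered block are
   discarded (filter + Hilbert transients). Optionally the full 10 s
   stimulation ramp can be excluded (`exclude_ramp`); the default
   analyzes the whole block minus the trim.
5. **Analytic signal.** Hilbert transform; instantaneous phase wrapped to
   (−π, π], envelope = modulus.
6. **Box–Cox stabilization.** The envelope is variance-stabilized per
   block with exponent λ chosen by profile maximum likelihood on a grid
   λ ∈ [−2, 2] in steps of 0.01 (`(x^λ − 1)/λ`, `ln x` at λ = 0).
   The phase is untouched. The alternative operation order (transforming
   the signal before envelope extraction) is ill-defined for a zero-mean
   band-passed series, whose values are not positive; the
   `stabilize_envelope` flag therefore toggles stabilization off rather
   than reordering it.

### PSI and profiles

The phase synchronization index of a phase-difference series φ_t is the
magnitude of its mean unit phasor, `PSI = |mean(exp(iφ_t))|` — 0 for a
uniform phase-difference, 1 for a constant one (the standard
phase-locking-value normalization). Likelihood histograms stratify φ_t
into 20 uniform bins of (−π, π], with half-open `(left, right]` bins so
the wrap convention and the binning agree exactly.

Because tremor need not sit exactly on the stimulation frequency, phase
stability is profiled against artificial sinusoidal references
(phase `2πft`; the initial phase is irrelevant by rotation invariance) on
a 0–20 Hz grid in 0.1 Hz steps (201 points), then smoothed with a 1 Hz
kernel, reflecting at the grid edges. The smoothed maximum per block is
the entrainment measure; its frequency is recorded, ties toward the lower
frequency. Per condition the block maxima are averaged and expressed as a
percent change against the averaged sham blocks — sham supplies the
chance level that a finite block length produces even without coupling.

**Smoothing kernel.** The default kernel is a Gaussian whose FWHM equals
the configured 1 Hz width (a boxcar is selectable). The choice matters
for strongly entrained data: phase-locking to a fixed-frequency reference
concentrates the profile in a single 0.1 Hz bin (the intrinsic width of
PSI against a detuned reference is ~1/T ≈ 0.006 Hz), and averaging with a
flat 11-point window then leaves the smoothed maximum equally likely
anywhere within ±0.5 Hz of the true peak. A peaked kernel keeps the
regularization while leaving the argmax well defined. A side effect worth
knowing: a perfectly locked block has its single-bin stability flattened
by any 1 Hz smoothing, so smoothed maxima are numerically small (~0.1)
even when the raw locking is ~0.95; all comparisons (percent change
versus sham, monotonicity in coupling) are unaffected because sham blocks
are flattened identically.

**Amplitude modulation.** The stabilized envelope is averaged within each
phase-difference bin (mean per bin; bins with no samples contribute
zero), the bin means are normalized to a probability distribution, and
the magnitude of its circular mean over bin centers is the
amplitude-modulation PSI. Because the Box–Cox output can be negative, the
stabilized envelope is shifted by its minimum before binning. The
reference phase is the analytic phase of the recorded stimulation or
photic channel (band-passed at the stimulation frequency) whenever that
channel is active in steady state; blocks without an active waveform
(sham after ramp-down, the initial recording) fall back to the artificial
reference at the nominal frequency.

### Analysis rate

Recordings are simulated/acquired at 2048 Hz; the analysis chain
optionally decimates (anti-aliased, zero-phase) to 256 Hz first. All
quantities of interest live below 20 Hz, so the decimated rate is
transparent to the results; the test suite and the worked examples run at
256 Hz. Problem sizes used by the end-to-end checks: 20 synthetic
subjects × 13 blocks of 180 s for the discrimination test, 20 seeds per
coupling gain for the monotonicity test, 10 seeds for frequency recovery.

## Synthetic tremor generator

The generator emulates the statistical structure the analysis assumes,
not limb biomechanics:

- **Phase dynamics** (Euler–Maruyama at the recording rate):
  `dθ = 2π f(t) dt + 2π κ(t) sin(φ_stim − θ) dt + 2π s_j dW`, a
  Kuramoto-style forced oscillator. `f(t)` is the subject's base frequency
  plus a slow Ornstein–Uhlenbeck drift; `s_j` is the phase-diffusion
  intensity; κ is the coupling gain toward the stimulation phase (in Hz —
  the maximum frequency pull), scaled by the normalized stimulation
  amplitude so sham blocks are forced only during their brief ramp.
- **Envelope**: a reflected Ornstein–Uhlenbeck process (|OU|), giving the
  positive right-skewed amplitudes the Box–Cox stage expects.
- **Projection**: the oscillation `env(t)·cos θ(t)` is projected onto the
  three accelerometer axes through a fixed unit vector dominated by z
  (mirroring sensor placement in the plane of maximal tremor), plus white
  sensor noise per axis.
- **Waveforms**: tACS is a sinusoid with no DC offset, 2000 µA
  peak-to-peak, 10 s linear ramp-up; sham holds for a further 10 s and
  ramps down, staying at zero afterwards. Photic stimulation is a strictly
  periodic rectangular pulse train (5% duty) at the stimulation
  frequency, coupled through its fundamental phase with a separate,
  weaker gain.
- **Subjects**: base frequency drawn from Normal(8.28, 1.52²) Hz
  truncated to [4, 14] — the group SD reconstructed from the reported
  SEM 0.44 Hz at N = 12. The stimulation frequency is the base frequency
  rounded to 0.1 Hz. A full experiment is one 360 s stimulation-free
  initial recording plus two independently shuffled cycles of the six
  conditions (four tACS montages, sham, photic), 180 s each, with a
  ground-truth table of the gains and seeds actually used.

Default parameter conventions (the study reports none of these; each was
chosen once as a plausible value and is configurable):

| parameter | default | units | note |
| --- | --- | --- | --- |
| `freq_jitter_sd` | 0.1 | Hz·s^−1/2 | phase-diffusion intensity; sets the tremor linewidth and the chance-level PSI |
| `drift_sd`, `drift_tau_s` | 0.02, 20 | Hz, s | slow frequency wander |
| `env_mean`, `env_sd`, `env_tau_s` | 1.0, 0.35, 4 | a.u., a.u., s | envelope OU |
| `noise_sd` | 0.05 | a.u. | per-axis sensor noise |
| `kappa` per condition | RSh 0.1, photic 0.05, else 0 | Hz | emulates the reported pattern: entrainment through the contralateral-shoulder return, weaker photic entrainment |

**What passing tests do and do not show.** The generator produces
phase/amplitude structure with controllable ground-truth coupling; it has
no biomechanical resonance, no EMG, no movement artifacts, and its
tremor line (set by `freq_jitter_sd`) is narrower than real physiological
tremor so that the prescribed coupling-gain grid {0…0.2} spans the full
uncoupled-to-locked range. Passing the end-to-end checks therefore shows
the *pipeline* is correct and discriminating under its own model
assumptions — not that real tremor entrains, which only the original
recordings could show.

## Current-density solver

The quasi-static montage problem `∇·(σ∇φ) = 0` is discretized by finite
volumes on the voxel grid: each voxel is a control volume and face fluxes
use the harmonic mean of the adjoining conductivities, which is exact for
layered media and keeps the normal current continuous across tissue
interfaces. This replaces a tetrahedral FEM workflow deliberately: for
the isotropic quasi-static problem at phantom scale the two agree, and
the voxel scheme is radically simpler and directly testable against
closed forms (parallel plate, layered slab, two-shell sphere series).

- Electrodes are Dirichlet voxel pads (+1 V source, −1 V return) placed
  over a 2 mm saline layer inserted between the pad footprint and the
  skin surface, following the surface curvature column by column.
- Air is a true conductivity (10⁻⁴ S/m), not an excluded domain, so no
  boundary needs special casing; one or two voxels of air padding make
  the exterior effectively insulating. Tissue conductivities (S/m):
  skin 0.43, bone 0.0064, CSF 1.79, gray 0.33, white 0.142, saline
  0.367, tissue-average 0.08.
- The symmetric positive-definite system over non-electrode voxels is
  solved by Jacobi-preconditioned conjugate gradients from a zero initial
  guess, relative residual 10⁻⁸ by default; non-convergence raises with
  the achieved residual. `E = −∇φ` by central differences, `J = σE`.
- The injected current is the net discrete flux out of the source pad,
  computed with the same face conductances as the solver, so discrete
  conservation holds to solver tolerance for any closed electrode-free
  region. Solutions are rescaled to a nominal 1 mA injection purely by
  this computed current (linearity); no assumed load resistance enters.
- The alternating stimulation current scales the steady-state map
  sinusoidally in time, so one solve characterizes the cycle.

Grid convergence is verified on the two-shell sphere (error vs the
Legendre-series solution drops from ~4% at 4 mm voxels to ~0.9% at 2 mm);
the parallel-plate configuration cannot show convergence because its
exact solution is linear and is reproduced at machine precision on every
grid.

The phantoms are synthetic stand-ins (concentric ellipsoids, optional
neck-and-shoulders block at tissue-average conductivity). Single-subject
results that depend on a segmented MRI — e.g. hemisphere-specific
contrasts between shoulder-return montages — are out of reach of these
phantoms by construction; the module provides the operators (ROI means,
montage contrasts) that such comparisons require.

## Group statistics

Per-subject percent changes are summarized by two-tailed one-sample
Student's t contrasts against zero with Cohen's d (`d = mean/sd`).
Ordinal phosphene-style ratings use the Wilcoxon signed-rank test with
the statistic defined as the sum of positive ranks (zeros dropped,
midranks for ties); for n ≤ 25 the two-sided p-value is exact, from the
full sign-assignment distribution computed by dynamic programming, and
larger samples use the tie-corrected normal approximation.
Benjamini–Hochberg step-up adjustment is applied within a user-declared
family of comparisons (which p-values form a family is an analysis
decision, not a property of the data). Omnibus repeated-measures
machinery (ANOVA, Mauchly, Shapiro–Wilk) is intentionally delegated to
stock statistics packages; this module emits the tidy per-condition
tables they consume.

## Degenerate inputs and tie-breaking

- Constant series have no phase: rejected (`DegenerateInputError`).
- Box–Cox requires strictly positive input; a configurable shift is
  available, and zero envelopes are rejected rather than silently
  shifted.
- Profile and peak argmax ties resolve to the lowest frequency.
- Empty phase-difference series, empty ROI masks, zero sham baselines,
  zero-variance contrast inputs and all-zero rating vectors are errors,
  not NaNs; the one exception is the amplitude-modulation PSI inside the
  block pipeline, which records NaN rather than discarding the block.
- All stochastic stages are driven by explicit integer seeds; the same
  seed reproduces a block bit-exactly.

## Known limitations

- The generator's phase oscillator cannot produce harmonic entrainment
  (locking at rational frequency ratios), so the profile's ability to
  detect it is untested.
- The amplitude-modulation reference for sham blocks is a convention
  (artificial reference at the nominal frequency); observed amp-mod PSI
  values for sham should be interpreted as chance level only.
- The finite-volume solver is isotropic; anisotropic conductivity
  tensors (e.g. white-matter tracts) are out of scope.
- Electrode pads are voxelized; footprint areas are accurate only to one
  voxel ring, and very small pads on coarse grids act as point sources.
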