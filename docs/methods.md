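# Methods

`dualswift` simulates and analyses a dual-field-of-view (dual-FOV) zero-TE
MB-SWIFT fMRI experiment of the rat brain and lumbar spinal cord at desk
scale.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Acquisition model

The sequence excites two distant FOVs in strict alternation: one
repetition-time *pair* (`tr_pair`, default 1.94 ms) holds one
excitation/readout per FOV at the same readout-gradient orientation, with
the gradient amplitude rescaled in inverse proportion to the FOV size
between the two spokes (`gradient_scale`, normalised so the largest FOV
gets 1).  One image volume is `n_spokes_per_volume` (default 1547)
orientations — a single pole-to-pole spherical spiral with equal-area
polar steps and an azimuth increment chosen for near-constant
nearest-neighbour arc length (spacing CV ≈ 0.03 at 1547 spokes).  The
same orientation set repeats every volume; with defaults one volume takes
1547 × 1.94 ms ≈ 3.0 s and a 248-volume run 12 min 24 s.

The gapped, frequency-swept excitation is not Bloch-simulated.  Each spoke
is an instantaneous center-out Fourier readout of the current truth
volume; the pulse fine structure survives as (a) timing arithmetic
(gaps, pulse elements, sweep range BW/32), (b) an optional multiplicative
per-spoke "pulse profile" that the reconstruction's deconvolution step
must undo, and (c) an optional per-FOV frequency-offset phase ramp across
the 670 µs readout.  Samples per spoke are `samples_per_gap ×
oversampling` (64 with defaults), from k = 0 to the grid Nyquist radius
`matrix_size / (2 · fov_size)`.  Complex Gaussian noise is added in
k-space (SD = `noise_sd` × mean |DC|), matching where measurement noise
actually enters; an optional coupling coefficient leaks a fraction of the
other coil's signal.

### Non-uniform Fourier operators

Two interchangeable operators evaluate the type-II NUDFT (`nufft` module):
an exact brute-force operator, and a Kaiser–Bessel gridding NUFFT
(oversampling 1.5, kernel width 5, image-domain deapodization, the adjoint
being the exact conjugate transpose of the forward).  The gridding
operator matches the exact transform to ~4 × 10⁻⁴ relative (width 6:
~6 × 10⁻⁵) at a small fraction of the cost and is the default at every
grid size; the exact operator is the oracle in the test suite.  Both
accept a stack of volumes per call so a whole time series is transformed
per BLAS/FFT invocation.

## Phantom and functional model

FOV 0 is an ellipsoidal head with a smooth ±10% intensity texture, a
lateralised "cortical" spherical ROI and a midline posterior "cerebellar"
ROI; FOV 1 is a cylindrical cord segment with a unilateral right-dorsal
ROI.  Geometry scales with the matrix size; ROI radii never fall below
2.5 voxels because smaller blobs are dominated by partial-volume dilution
at the reconstruction's resolution.

The stimulation paradigm is 60 s rest then 6 × (24 s on + 90 s off),
744 s in total (248 volumes at 3 s).  The hemodynamic kernel is a
gamma density moment-matched to a delay (mean) of 2.8 s and a variation
(SD) of 1.4 s — shape k = 4, scale θ = 0.7 s, mode 2.1 s.  The voxel
model is

    s_v(t) = baseline_v · (1 + effect · mask_v · r(t)),

with r the boxcar ⊗ IRF response rescaled to unit peak, so `effect` is
directly the peak fractional signal change (defaults 0.5% brain, 1.0%
cord).  Functional contrast in this sequence arises from inflow of
unsaturated blood; no quantitative inflow model exists, so the contrast is
injected phenomenologically.  A per-FOV `latency_shift` (default 9 s for
the cord) delays r(t), emulating the slower spinal hemodynamics; motion
events are cumulative integer-voxel translations applied volume-wise.

## Reconstruction

Per volume: RF-pulse deconvolution (regularised division by the pulse
profile, Tikhonov floor 10⁻⁶; identity for a flat profile) → spoke-end
apodization (cosine taper over the outer 25% of each spoke down to 0.2,
DC untouched; controls Gibbs ringing at the cost of smoothing) →
FISTA with 13 iterations.

The data term is density-compensation-weighted least squares
½‖W^½(Ax − y)‖² with W ∝ |k|² (k = 0 takes the first nonzero weight).
Plain least squares was tried first and stalls within the fixed 13
iterations (NRMSE 0.16 versus 0.006 on the 16³ noise-free benchmark)
because the radial system is strongly ill-conditioned; the |k|² weighting
acts as a standard Jacobi-type preconditioner and is the package default
(`ReconParams.dcf_weighted=False` restores plain LSQ).  The proximal step
is non-negativity projection (an optional ℓ1 soft-threshold is off by
default); initialisation is the density-compensated adjoint image rescaled
to the least-squares optimal amplitude; the step size is 1/L with L from
seeded power iteration (≤50 iterations, tolerance 10⁻³).  The monotone
FISTA variant keeps the best iterate seen, so the recorded objective trace
is non-increasing by construction.

On the 16³ benchmark (3× angular oversampling, i.e. 3πN² ≈ 2412 spokes,
noise-free) the 13-iteration reconstruction reaches NRMSE 0.006 against a
band-limited truth.  The truth is mildly smoothed (Gaussian σ = 0.7
voxel) for this benchmark only: the raw phantom holds ~17% RMS spectral
energy outside the sampled |k| ≤ 0.5 sphere — k-space corners no radial
trajectory reaches — which is an object-representation floor unrelated to
algorithm convergence.

## Preprocessing

Motion is estimated as the intensity-weighted center-of-mass displacement
in three dimensions and corrected by translation-only subvoxel
Fourier-shift registration to the first volume (rotations are reported as
zero; the phantom injects translations only, and the interface leaves room
for an external rigid registration).  Residual artefacts are removed by
spatial ICA (FastICA, 15 components, seeded): a component is labelled
motion when (1) the maximum |Pearson r| between its time course and one of
the three center-of-mass traces **exceeds** 0.75, or (2) **more than** 70%
of its suprathreshold map voxels (|z| > 2) lie on the object's 1-voxel
edge shell or outside the mask.  Both thresholds are strict inequalities
(deterministic tie-break); the |z| > 2 map threshold is the package's
reading of "spatial map voxels".  Labelled components (plus an intercept)
are regressed out voxelwise; voxel means are preserved.

High-pass filtering projects out discrete-cosine drift terms with
frequency below 0.01 Hz (14 basis functions for 248 volumes at 3 s),
restoring the temporal mean afterwards.  The paradigm's fundamental
(1/114 Hz ≈ 0.0088 Hz) lies *below* this cutoff: the filter removes
~28% of the task regressor's norm.  The GLM therefore filters data and
design identically (unbiased, with reduced efficiency), and the
percent-signal-change time courses are extracted from the *unfiltered*
cleaned series.  Autocorrelation is removed by per-voxel single-pass
Cochrane–Orcutt AR(1) prewhitening estimated from first-pass OLS
residuals (|φ| clipped at 0.99).

## Statistics

The subject-level GLM regresses each voxel on the unit-peak boxcar ⊗ IRF
regressor plus intercept; t statistics map to z through matched tail
probabilities (log-survival-function arithmetic, capped at |z| = 38).
The design models a per-FOV response latency (default 0 s brain, 9 s
cord): after the 0.01 Hz high-pass an unshifted regressor retains only
r ≈ 0.30 with a 9 s-delayed response, so a latency-matched regressor —
standard practice in spinal-cord fMRI — is what keeps the cord testable.
Clusters are 6-connected components of {z > 3.1}, reported with size,
peak z, mean z and centroid.

TFCE is computed by explicit threshold summation, TFCE(v) = Σ_h
e(h,v)^E h^H dh with E = 0.5, H = 2 and dh = 1% of the map maximum
(coarser steps are used in the Monte-Carlo calibrations; permutation
validity does not depend on dh).  Group inference is a one-sample
sign-flip test: the statistic is the TFCE-enhanced group t map, the
FWE-corrected p at a voxel is the fraction of flips whose maximum
statistic reaches the observed value (exhaustive 2ⁿ flips for n ≤ 12
subjects, so p-values lie on a 1/256 grid at n = 8), and p < 0.05 is
significant.

ROI time courses are expressed in percent change against the initial
60 s rest.  Peak latency is estimated at volume-TR resolution by matching
the block-triggered average against integer-volume shifts of the modelled
single-block response and adding the template's own time to 95% of peak.
A plain argmax (and a bare 95%-crossing) proved noise-fragile because the
boxcar ⊗ IRF response plateaus near its maximum — the IRF's mass is
spent within ~8 s while the block lasts 24 s — leaving the plateau within
about two noise SDs of the peak.  Template matching uses the whole curve
and recovers an injected 9 s inter-FOV shift exactly at 3 s resolution.
Paired peak-latency comparisons use a paired t test with a zero-variance
guard.

## Standard synthetic case and problem sizes

The calibrated desk-scale conditions (`scaled_config`): 32³ matrix,
480 spokes per volume with `tr_pair` raised to 12.5 ms/spoke-pair
equivalent so the volume TR stays 3 s, 32 samples per spoke (the k-max is
unchanged; this keeps 2× radial oversampling at 32³), 248 volumes,
k-space noise SD 2 × 10⁻⁴ of mean |DC|, cumulative motion events of ±2
voxels in z at volumes 80 and 160, effects 0.5%/1.0%, cord latency 9 s.
The noise level was calibrated once so that the single-subject cortical
cluster falls in the plausible published range for this preparation
(~18–39 voxels, mean z ~4.3–5.8) and then frozen.  Under these conditions
the chain recovers 0.46–0.57% for the injected 0.5% (brain) and
0.89–0.91% for the injected 1.0% (cord) — the shortfall is deterministic
partial-volume dilution, not noise — and the 9 s latency difference
exactly.  One subject runs in ~3 minutes on one CPU; the permutation
calibration (200 null experiments × 256 flips on 6³ maps) takes ~1
minute.

## What the synthetic experiments do not show

The phantoms have no physiology: no respiratory/cardiac noise (RETROICOR
is out of scope), no inflow physics, no susceptibility or relaxation
effects, no rotational motion, no inter-subject anatomical variability
(multi-subject runs differ only by seed, sharing one space, so no
co-registration step exists).  Passing tests therefore demonstrate the
correctness and calibration of the computational chain — sampling,
reconstruction, preprocessing, inference — under its own generative
model, not performance on real scanner data.

## Known limitations

- Translation-only motion correction; rotations pass through.
- The ICA motion classifier is validated on planted fixtures and the
  standard case; FastICA convergence on rank-deficient inputs falls back
  with a warning.
- The k-space "gap" structure of the gapped pulse is not mapped to missing
  sample positions; spokes are contiguous center-out reads.
- Exhaustive sign-flipping is exact only for n ≤ 12; beyond that a seeded
  random subset (identity included) is used.
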