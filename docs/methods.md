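# Methods

This note documents the models, parameters and numerical choices behind
`lumbobold`, in the order data flows through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Synthetic phantom

### Geometry

The phantom grid is 48×48×15 voxels at 1×1×5 mm (a reduced-FOV axial EPI
stack of the lumbosacral cord); pipeline-level tests and the
desk-scale analyses use a 32×32×10 grid with the same construction. The
cord is a circular cylinder whose radius tapers linearly from the conus
tip (1.6 mm at slice 1) to its maximum (4.0 mm) at the lumbosacral-
enlargement (LSE) landmark slice, then shrinks mildly rostrally
(3.4 mm at the top slice); the LSE slice is therefore the unique area
maximum, which the rostrocaudal alignment relies on. Gray matter is a
butterfly (two ventral horns, two dorsal horns, a central commissure)
scaled with the local cord radius; white matter is the cord complement.
CSF is an annulus separated from the cord by a 0.5-mm gap (thickness
3 mm — wide enough that one-voxel in-plane erosion leaves a usable
noise ROI). A medioventral "vein" compartment sits on the anterior
midline. Slices between tip and top carry neurological-level labels
L3…S2 (rostral to caudal) in five contiguous bins.

Masks are rasterized by the pixel-center-inside test; for a 4-mm radius
on a 1-mm grid the count (49) differs from πr² (50.27) by ≈1.3 voxels,
the expected O(perimeter) rasterization error. Tests compare against a
per-pixel counting oracle exactly and bound |count − πr²| ≤ 2.

### Signal model

Voxel signal is the spoiled-GRE steady state
`S0·sin(α)(1−e)/(1−cos α·e)·exp(−TE·R2*(t))` with `e = exp(−TR/T1)`,
T1 = 994 ms for all tissues, and baseline T2* of 41.3 ms (GM), 38 ms
(WM), 120 ms (CSF). The GM value is a cervical-cord literature number;
no lumbosacral measurement exists, so it is an explicit assumption.
Task activation subtracts `ΔR2*·x(t)` from the target voxels' R2*
(ΔR2* in s⁻¹, bookkeeping in ms⁻¹), with x(t) either the exact {0,1}
boxcar or the canonical-HRF-convolved response. In HRF mode x(t) is not
clipped to [0,1]: the small negative excursions are the post-stimulus
undershoot, and truncating them would bias the matched-basis GLM fit
(clipping was measured to produce a 9 % coefficient error on noiseless
data; unclipped < 0.5 %).

The four presets reproduce the acquisition table: TE 20/28/35/42 ms,
TR 1460/1190/1290/1400 ms, Ernst flip angles 77/72/74/76° from T1 =
994 ms, partial Fourier 6/8, 6/8, 7/8, none, and task/rest volume
counts 411/505/466/429 and 247/303/280/258 (600-s and 360-s runs).
Partial Fourier is emulated as a 1-D Gaussian blur along the
phase-encode (anterior-posterior) axis, FWHM 1.5 voxels for 6/8 and
1.2 for 7/8 — an image-domain stand-in for the acquisition's
smoothness; no k-space or distortion simulation is attempted.

The vein compartment receives an effective
`ΔR2*_vein = 1000·k/TE²` (1/s), so its fractional plateau contrast
≈ k/TE_ms falls off with TE. A weight of k/TE on ΔR2* itself would
cancel in the contrast (which scales with TE·ΔR2*) and could not
reproduce the stronger short-TE vein signal the model is meant to
emulate.

### Noise model and defaults

* thermal: additive Gaussian, SD 30 (signal units). Calibrated so the
  rest-run cord tSNR the QC analysis computes lands in the 10–16 range
  across presets, decreasing with TE — the magnitude a spine-coil
  lumbosacral acquisition yields. Gaussian rather than Rician; at these
  SNRs the difference is negligible.
* respiration: 0.25 Hz sinusoid with a per-volume random-walk phase
  jitter (SD 0.15 rad), amplitude growing linearly from 2 (caudal) to 6
  (rostral) signal units — rostral slices sit closer to the lungs. The
  cord receives 0.5× the CSF amplitude. A fraction (default 0.7) of the
  cord component is *common* with the CSF; common and tissue-specific
  parts have independently jittered phases so they decorrelate, which is
  what makes CSF-derived aCompCor regressors effective by construction.
* drift: 0.2 %/min multiplicative.
* motion: optional per-volume rigid trajectory plus a
  respiration-locked per-slice y-translation ramp (zero caudally,
  maximal rostrally), applied by linear-interpolation resampling; the
  truth record stores every applied parameter.
* spikes: multiplicative bursts on listed volumes.

All randomness flows from one `NoiseSpec.seed` through a
`SeedSequence` split into named streams (respiration, thermal, spare),
so identical seeds give bitwise-identical runs and single components
can be toggled without perturbing the rest.

What the phantom does **not** emulate: EPI distortion and fieldmap
effects, fold-over artifacts, GRAPPA/OVS artifacts, cardiac pulsation,
susceptibility dropout, realistic anatomy (the cord is circular).
Passing tests therefore demonstrate the statistical machinery under the
pipeline's own assumptions, not robustness to every artifact of real
cord EPI.

## 2. Design arithmetic

Volume counts are the smallest N with N·TR ≥ run duration (dummy
volumes excluded). The Ernst angle is `acos(exp(−TR/T1))`. The paradigm
alternates 15-s rest/motion blocks starting with rest (40 blocks in the
full protocol; desk-scale analyses use 20, see section 6).

The HRF basis is the canonical double-gamma (peak 6 s, undershoot 16 s,
ratio 1/6) plus its temporal- and dispersion-derivative companions —
same dimensionality and span purpose as an optimal-basis triple; the
exact kernels of such toolkits are not published, so the canonical
triple is used and the kernels are configurable. Normalization: the
canonical kernel is scaled so the response to a single 15-s block peaks
at 1; thus the first regressor's coefficient (β₁, the COPE) is
approximately the plateau signal change. Regressors are built by
fine-grid (dt = 50 ms) convolution of the boxcar and sampled at volume
start times k·TR; no slice-timing correction anywhere.

High-pass filtering removes discrete-cosine components with period
longer than 100 s by orthogonal projection (mean preserved), applied
identically to data and design. This is a deterministic stand-in with
the same cutoff semantics as the common tool-specific filters.

## 3. Preprocessing

Volume-wise motion correction registers each volume to the mean volume
(mean-squares cost, bounded Powell search, linear resampling), 6 DOF by
default with 3-DOF (translation) and 2-DOF (in-plane) modes; phantom
motion is dominantly translational, and the desk-scale analyses use the
in-plane mode for speed. Slice-wise correction then estimates per-slice
(dx, dy) within a 20-mm-radius cylinder around the cord centerline and
shrinks each volume's slice trajectory toward its first-order polynomial
in slice index: `reg = (raw + λ·poly)/(1+λ)`, λ = 1 by default (λ = 0
raw, λ = ∞ pure polynomial) — breathing shifts rostral slices more, so
a linear-in-z model is the natural regularizer.

DVARS is the spatial RMS of the successive-volume difference within the
cord mask. A volume t ≥ 1 is an outlier when its incoming transition
exceeds Q75 + 1.5·IQR (linear-interpolation quantiles, the common
default — the rule is threshold-sensitive so the convention is fixed
and tested); the first volume is never flagged. Runs with outlier rate
> 20 % are excluded. Outlier volumes are kept in the GLM via one-hot
spike regressors rather than deletion.

tSNR (rest runs only) is mean/SD after linear detrending (line removed,
mean kept); zero-variance voxels are reported missing rather than
infinite, so noiseless phantoms do not overflow summaries. Slice
summaries use the cord mask eroded by one voxel in-plane and are keyed
by signed distance from the LSE slice. Smoothing is an anisotropic
Gaussian, FWHM 1×1×5 mm (σ = FWHM/2.3548 per axis).

## 4. Nuisance model and GLM

aCompCor: per slice, CSF voxel series (true CSF mask eroded one voxel
in-plane, mirroring the exclusion of the CSF–cord interface) are
demeaned and variance-normalized, and the first five principal
components (unit-variance time courses, ordered by explained variance)
become slice-wise regressors. Variance normalization is the standard
variant; it is switchable. Components are not orthogonalized against
the task regressors. The per-slice nuisance block is [5 PCs | slice-wise
dx, dy | spike columns]; smooth columns are demeaned, spikes stay
one-hot, and collinear or null columns are dropped with a warning.

The run-level GLM fits, per slice, [3 task columns | nuisance block] to
every voxel series, high-pass filtering data and design identically and
demeaning the design after filtering (the constant lives in the stored
mean image, which the effect-size reconstruction needs). Prewhitening
is voxel-wise AR(1) (one Cochrane–Orcutt pass): ρ from the lag-1
autocorrelation of OLS residuals with the standard small-sample bias
correction ρ + (1+3ρ)/n (without which the nominal-0.01 type-I error
measures ≈ 0.016 instead of ≈ 0.010 on AR(1) noise), then data and
design transformed (first row scaled by √(1−ρ²)) and refit. β₁ is the
COPE; its variance uses dof = n − rank(X) − (filter dimensions) − 1,
counting the projected-out DCT components — this deviates from a naive
n − rank(X) because the filter genuinely removes dimensions. z comes
from the two-sided quantile transform of t through the normal.
Residuals are stored in unwhitened space (filtered data minus fitted
model), which is what the denoised reconstruction sums.

Subject-level combination is inverse-variance fixed effects
(cope = Σc/v / Σ1/v, varcope = 1/Σ1/v); with equal variances this is
the run mean. Equal weighting versus inverse-variance is not
distinguishable from the study description; inverse-variance is the
standard fixed-effects contract.

## 5. Group inference and quantification

The group statistic is a one-sample pseudo-t with the sample-variance
map Gaussian-smoothed at FWHM 5 mm inside the analysis mask (kernel
renormalized at mask edges). Sign-flip permutation enumerates all 2^n
flips exhaustively for n ≤ 14 (identity first; the n = 12 case gives
4096) and samples without replacement beyond. TFCE uses the canonical
E = 0.5, H = 2, 100 equal threshold steps, 26-connectivity; the
comparison at each threshold is tolerant to one ulp so the peak voxel is
always included in the top step. p_FWE is the fraction of permutation
maxima ≥ the observed TFCE value (identity counted, so p ≥ 1/n_perms);
maps are thresholded at 0.05/0.01/0.001.

The cross-sectional atlas splits the cord into RV/RD/LV/LD quadrants at
the cord center row and column (both excluded — a one-voxel gap) plus a
medioventral inverse-pyramid wedge (base half-width 1.5 mm at the
anterior cord edge, depth 2.5 mm, never crossing the center line) carved
out of the ventral sectors; the wedge vertices are free parameters since
only the shape, not coordinates, is specified anywhere. Activity tables
report mean t and suprathreshold ratio per sector (over L3–S2) and per
level (full cross-section). Rostrocaudal pooling across subjects uses
the two-landmark piecewise-linear slice mapping (cord tip and LSE slice
onto template landmarks).

BOLD effect size: the denoised series β₁·c₁(t) + mean + residuals is
averaged in the ROI, split into 15-s blocks by volume start time (a
volume belongs to the block containing its start), the first three
volumes of each block dropped, and reported as
100·(mean_motion − mean_rest)/mean_rest — normalization by the rest
mean, with the grand-mean alternative switchable. Dice of two empty
thresholded maps is defined as 0. Split-half reliability runs the full
group inference separately per run half.

## 6. Validation configurations and problem sizes

Two analysis configurations exist deliberately:

* **Study model** (default): HRF-basis GLM, smoothing, full nuisance
  model — what one would run on real data.
* **Physics validation**: boxcar phantom response *and* matched boxcar
  task regressor, no smoothing, no nuisance — used for closed-form
  checks. With an HRF basis fit to boxcar data, the derivative
  regressors absorb sustained block-mean signal (15-s blocks never
  reach hemodynamic steady state) and the denoised reconstruction,
  which excludes their contribution, under-recovers the block
  difference by roughly half; smoothing further dilutes the small
  (35-voxel) target by ≈12 %. The physics configuration removes both
  confounds so the recovered effect equals exp(TE·ΔR2*)−1 up to the
  high-pass filter's edge effect (measured 0.574 % vs 0.580 % at
  TE 42). The TE-sweep check additionally uses partial-Fourier-free
  sequence variants, because the 6/8 and 7/8 presets' phase-axis blur
  dilutes the target by construction; the presets still show the
  monotone TE trend.

Desk-scale problem sizes (chosen once as the package's simulation
conditions): 32×32×10 grid, 20-block (300-s) paradigm — half the full
protocol. Very short paradigms (10 blocks) were found to leave too few
task cycles for stable run-level variance estimation, inflating and
destabilizing the null false-positive rate; 20 blocks restores
calibration. Null calibration uses 3 task-free subjects × 4 presets × 2
task runs; the group FWE check uses 200 simulated null cohorts of 8
subjects on 4×4×2 grids with 15 TFCE steps (TFCE discretization is
stable to < 2 % against step doubling, so the reduced step count only
speeds the loop).

The demonstration scripts `analysis/03` and `analysis/05` inject a
task ΔR2* of 0.45 s⁻¹ — roughly three times the physiological
0.1377 s⁻¹ — because a 6-subject cohort with half-length runs at
realistic tSNR detects nothing at the physiological amplitude (the
full-protocol sample, twice the subjects and twice the run length, is
what makes that effect detectable). The stronger injection makes the
inference machinery's behavior visible at desk scale; every physics
and acceptance check uses 0.1377 s⁻¹ unchanged.

## 7. Known limitations

* The AR(1) prewhitener only approximates the narrowband respiratory
  residual; an AR(2) variant was prototyped and did not improve null
  calibration, so the simpler model stands.
* Slice-coordinate (1-D) alignment replaces full template
  normalization; all synthetic subjects share one grid, so
  cross-subject warping is the identity by construction.
* The rigid-transform inverse is first-order in the rotations
  (exact for translations); phantom rotations are ≤ 3°.
* Dice, sector and effect-size statistics assume the analysis and
  truth grids coincide — there is no resampling chain between native
  and template space as a scanner study would need.
* The false-positive ceiling of task-free runs reflects the phantom's
  noise model; real cord data carry cardiac and susceptibility
  components the phantom does not model.
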