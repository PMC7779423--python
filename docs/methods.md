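# Methods

## Problem and model

Diffusion MRI series are acquired as stacks of EPI slices (or multiband
slice groups, "excitations"); subject motion between excitations
scatters the slices in space and, through rotation, scatters the
effective diffusion-encoding directions.  `shardrecon` treats motion
correction as a slice-to-volume inverse problem: a multi-shell signal
representation **x** and a per-excitation rigid motion trace μ are
estimated jointly so that the forward model

    ŷ_s = B_s · M(μ_s) · Q_s(μ_s) · x

best explains every acquired slice group *s*.  Here Q_s projects the
representation to the dMRI contrast of the excitation's shell and its
motion-reoriented gradient direction, M(μ_s) resamples the subject-frame
image onto the scanner grid by Keys cubic interpolation (a = −1/2, zero
outside the grid), and B_s convolves along scanner-z with the combined
slice-profile/interpolation kernel and picks out the excitation's
slices.

The representation is SHARD — spherical harmonics and radial
decomposition: per shell a real, even-order, orthonormal SH basis
(MRtrix-compatible ordering: ℓ ascending, m = −ℓ…ℓ; for m<0 the basis
function is √2·Im Y_ℓ^|m|, for m>0 √2·Re Y_ℓ^m), linked across shells by
an SVD-derived orthonormal radial basis per even band.  The radial
matrices are learned from the data (stack band coefficients across
shells for all in-mask voxels, zero rows for shells whose ℓmax is below
the band, keep leading left singular vectors; sign fixed so each
column's largest-magnitude entry is positive).  Total rank
r = Σ_ℓ n_ℓ(2ℓ+1); the neonatal-protocol configuration (ℓmax 0/4/6/8
over 4 shells, full retention) gives r = 89, and the truncated
registration basis (3/2/1 components in bands ℓ = 0/2/4) gives 22.

## Reconstruction step

Given the trace and per-excitation weights w_s, the coefficients solve

    min_x (1/n_v) Σ_s w_s ‖y_s − R_s x‖² + λ²‖Lx‖² + ζ²‖Zx‖²

with L the 7-point Laplacian scaled per axis by 1/voxel² (units mm⁻²)
and Z the 8th-order binomial derivative along z (dimensionless); both
use reflective boundaries, which keeps them symmetric and avoids
penalizing tissue at the grid edge.  Defaults λ = ζ = 10⁻³.  The normal
equations are solved matrix-free with conjugate gradients; per
excitation a sparse B_s·M(μ_s) matrix is assembled once per trace
update, so a CG iteration is a chain of sparse mat-vecs and small dense
projections.  Weight placement follows the normal-equations form (a
single w_s on R_sᵀR_s and R_sᵀy_s), and the 1/n_v factor is folded into
the operator so λ and ζ keep their intended scale.  Stopping: iteration
cap (3 per epoch, 10 for the final solve) with a relative-residual 1e-8
safeguard.

## Registration step

Each excitation (or whole volume, in early epochs) is aligned to a 3-D
prediction of its contrast rendered from the rank-reduced
reconstruction at the direction reoriented by the previous pose
estimate; the prediction is held fixed during the optimization.  Poses
live in se(3) ([tx,ty,tz,rx,ry,rz], exact closed-form exp/log, rotations
acting about the FOV center); a Levenberg–Marquardt loop builds the
analytic Jacobian from the interpolated image gradient and the
generator action on the sampled points (left-composed increments), with
a closed-form intensity scale α_s per evaluation (alignment only, never
used in the reconstruction).  Numerical safeguards, chosen here because
the damping schedule is not prescribed: multiplicative damping (×10 on
reject, ÷10 on accept, floor 1e-6), damping diagonal floored at 1e-3 of
the largest curvature (bounds steps along nearly flat pose directions),
per-step caps (0.3 rad / 20 mm), and a trust region around the
initialization for thin-stack (excitation-level) registrations
(4 mm / 0.05 rad) — a 2-slice stack constrains six parameters weakly
and an unconstrained descent can overfit noise at a distant optimum.

Multi-scale strategy: the registration source is smoothed with a FWHM
annealed from 3 to 1 voxel across epochs.  Two desk-scale adaptations
(see Limitations): the smoothing is applied in-plane and to *both* the
source and the data slices, so the two images carry matched blur at
every scale (through-plane both already carry the slice-profile blur);
and the first epoch estimates translations only, seeded by intensity
centroids (whole-FOV capture), with one pose per volume.  b=0
excitations register against the ℓ=0 (spherical-mean-like) contrast.

## Temporal filter and outlier model

Estimated traces pass a two-stage filter.  Stage 1 solves, exactly and
per pose component, the tridiagonal system
μ′_t = w_t μ_t + (1−w_t)·½(μ′_{t−1}+μ′_{t+1}), with endpoints using
their single neighbor with the full (1−w) weight; it replaces
low-weight poses by their neighbors' average.  Stage 2 is a running
median (window 5, shrinking symmetric windows at the edges) that
removes spot noise while preserving genuine motion steps.

Outlier weights come from per-excitation residual RMSE inside the brain
mask, modeled per shell as a two-class Gaussian mixture on log-RMSE.
EM is initialized at the (median, MAD) of log-RMSE for the inlier class
and at median + log 3 (the 3× rule, multiplicative on the log scale)
for the outlier class, mixing 0.9/0.1, tolerance 1e-8, 100 iterations;
classes are re-sorted so the higher mean is the outlier and the inlier
posterior becomes the weight.  Two degeneracy guards return all-one
weights: zero MAD, and heavily overlapping fitted components
(Ashman's D = √2·|Δmean|/√(σ₀²+σ₁²) below 2), the latter because EM on
a unimodal residual distribution would otherwise split one cluster and
needlessly discard data.  Optional per-slice-position prior weights
multiply in (minimum over a group's slices).

## Epoch schedule

Initialization: zero motion, uniform weights, and coefficients
warm-started from the static volume-wise per-shell SH fit (the
zero-motion solution; the first CG solve refines it under the current
trace).  Each epoch then runs: reconstruction (3 CG iterations,
warm-started) → outlier reweighting from the CG residuals → SHARD basis
refit from the current reconstruction → registration (volume-level for
2 epochs, excitation-level for 3) → two-stage temporal filter.  A final
10-iteration reconstruction produces the output.  The order follows the
integration scheme in which weights are updated from the reconstruction
residuals before registration, so the same epoch's temporal filter can
use them.

## Synthetic validation data

The generator emulates a motion-corruption study on a digital phantom:

* **Phantom** (default 24³ voxels at 1.5 mm; shells b = 0/1000/2600
  s/mm² with 4/16/24 volumes interleaved across the series): per-voxel
  multi-tensor signal with two anisotropic compartments (a gently
  curving bundle along x and a tilted through-plane bundle; λ∥ = 1.7,
  λ⊥ = 0.25 ×10⁻³ mm²/s), an isotropic compartment (0.8×10⁻³ mm²/s),
  asymmetric ventricle-like isotropic pockets, a smooth asymmetric
  proton-density gradient plus folding-scale texture (σ ≈ 1.1 voxel,
  ±18%), and a smooth signal taper over ~2 voxels outside the
  ellipsoidal mask.  The asymmetry and fine texture are deliberate:
  rigid registration of real brains is anchored by exactly such
  structure, and a smooth symmetric blob makes in-plane rotation
  unidentifiable.  b=0 volumes equal s0 inside the mask.
* **Motion**: a mean-reverting random walk in se(3) — Gaussian steps of
  0.3 mm / 0.3° per excitation, scaled ×4 inside burst intervals seeded
  at 5% per excitation (geometric mean length 3), and a weak per-step
  pull (0.02) toward the rest pose.  The reversion bounds the total
  excursion the way sleeping subjects return to rest, so the trace
  reproduces both reference statistics of observed motion: slice-to-
  slice stdev ≈ 0.5 mm/0.5° and excursion stdev ≈ 2.5 mm/2.9° (an
  unbounded walk at this step size would drift ~9 mm, beyond both the
  observed envelope and the phantom FOV).
* **Ground truth**: the clean series is first "acquired" motion-free
  through the forward model (slice-profile blur included) and
  reconstructed once with the standard regularized solver; that
  reconstruction is the generating representation — validation
  references are reconstructions, not raw images — and every corrupted
  excitation is rendered from it at its pose, with gradient
  reorientation and slice-profile convolution.
* **Corruption**: 10% of excitations are multiplied by smooth in-plane
  bias fields with values in [0.1, 0.8] (dropout / spin history);
  i.i.d. Gaussian noise at 0.5% of the mean in-mask b=0 signal is
  added everywhere.

Evaluation: trace RMSE per Lie-algebra component after removing each
trace's global mean pose (the gauge freedom between independent
reconstructions); signal RMSE over in-mask voxels and volumes after
rigid re-alignment by the recovered-vs-true mean pose, normalized to
the mean in-mask b=0 signal (1/SNR units).

What the generator does not emulate: susceptibility distortion (inputs
are assumed unwarped upstream), Rician noise statistics, spin-history
temporal correlations, eddy currents, and — importantly — the size and
structural richness of a real brain.  Passing tests on the phantom
demonstrate the correctness and stability of the estimation machinery,
not clinical-grade accuracy.

## Problem sizes and numerical choices

The default test and validation sizes are 16³/24³ phantoms with 29–44
volumes and 232–528 excitations; the tiny dense-oracle problems use 6³
grids where the full system matrix is assembled explicitly.  Shell
clustering assigns a b-value to the lower shell on ties; per-shell SH
fits are unweighted least squares and require at least as many
directions as coefficients; the combined through-plane kernel is
computed by trapezoid quadrature on a fine grid and normalized to unit
sum (preserves the spherical-mean intensity scale); taps below 1e-5 of
the maximum are trimmed.  The coefficient ordering is (ℓ ascending,
radial component, m); radial orthonormality makes shell↔basis
projections exact transposes of each other.

## Known limitations

The desk-scale validation is information-poorer than the setting the
method was designed for: multiband-2 excitations carry 2 thin slices of
a 24-voxel object, against 4 slices of a ~128-voxel brain in a neonatal
protocol, and the sparse direction sets (16/24 per shell) mean the
rank-reduced registration basis almost interpolates each volume's own
data.  Two consequences, measured with oracle experiments in
development and visible in the validation numbers: (i) per-excitation
rotation identifiability is a few tenths of a degree at best, and
(ii) the joint reconstruction–registration iteration is self-anchoring
— registration against a consensus built from the current pose
estimates re-finds those estimates, so residual trace error contracts
by only a few percent per epoch at this motion-to-object ratio.  With
the fixed 2+3-epoch schedule the recovered traces therefore retain
roughly 3× the trace error that the same machinery achieves per
registration when given ground-truth targets.  On motion-free input
the same anchoring is benign (the truth is the fixed point) and the
pipeline holds the trace below 0.01 voxel translation.  Affine motion
(eddy currents), B0 field handling, and voxel-level outlier maps are
out of scope.
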