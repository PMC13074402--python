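# Methods

## Problem setting

MRI acquires complex-valued samples of the image's 2D Fourier transform
(k-space) on a Cartesian grid, one phase-encode line per repetition (TR),
through L receiver coils with spatially varying complex sensitivities
S_l(x, y).  Measurement noise is modeled, as is standard after
prewhitening, as i.i.d. circular complex Gaussian with variance sigma^2 per
sample and no interchannel correlation.  Repeating ("averaging") line m
q_m times reduces its noise variance to sigma^2 / q_m at a cost of q_m TRs.

This package studies a constrained experiment-design question: with the
total TR count fixed at that of a reference scan (N0 lines, uniform w0-fold
averaging), how should one choose

* the acquisition grid size N <= N0 (spatial resolution),
* the per-line averaging pattern, and
* the parameters of the denoising/reconstruction method

to best reproduce a high-resolution reference image?  Shrinking the grid
buys averaging time and additionally narrows the readout bandwidth, which
improves SNR like extra averaging; both effects are folded into *effective
averages* w_m = q_m * N0 / N, so every feasible continuous design satisfies
sum_m w_m = w0 * N0^2 / N and the simulated data are

    d = s_N + (1 / sqrt(w)) * z,      Var(d - s)_m = sigma^2 / w_m,

with s_N the centered N x N crop of the noise-free k-space and z a fixed
master noise realization drawn on the N0 grid and cropped per candidate N,
so that all candidate designs see the same noise vectors.

## Bilevel design

For each candidate N the *inner* problem jointly fits the reconstruction
parameters p and (in nonuniform mode) the pattern w by projected minibatch
SGD on the summed squared error against the *matched-resolution* reference
r^N (crop, zero-pad, inverse FFT, SENSE coil combination); the *outer*
problem scores each trained design against the *full-resolution* reference
r^{N0} with the same noise realizations and keeps the argmin by brute-force
search.  The two levels keep the inner fit a pure denoising task while the
final selection still pays for lost resolution.

Pattern steps normalize the w-gradient to unit l2 norm, then project onto
the budget hyperplane {sum w = w0 N0^2/N} (closed form: add beta/N with
beta the budget residual), with entries floored at 1e-3 effective averages
and the deficit redistributed over the free entries.  After the joint
epochs the pattern is rounded to integer actual averages by
nearest-integer rounding plus greedy unit corrections; each correction
changes the line with the smallest l1-cost increase, ties preferring lines
near the k-space center (center distance |m + 1/2| on the even grid,
remaining ties toward the smaller index).  Separability and piecewise
linearity of the cost make this greedy scheme globally optimal, which the
tests confirm by exhaustive enumeration on small instances.  Rounding keeps
every line measured at least once; undersampled patterns are outside the
design space.

## Reconstruction families

All reconstructors map N-grid data to an N0 x N0 complex image, so designs
at different resolutions are directly comparable.

**Apodized** - multiply the data by a real positive N x N window, zero-pad,
inverse FFT, SENSE-combine.  The window values are the trainable
parameters (floored at 1e-6 under projected steps).  The pipeline is linear
in the windowed data, so MSE gradients with respect to the window and w
have closed adjoint forms.

**SENSE-TV** - solve

    argmin_x  sum_m w_m ||(E x - d)_m||_2^2 + lambda * ||D x||_1

with E = coil-sensitivity modulation, unitary FFT, and central N x N
sampling; D = periodic first differences (both directions, complex-magnitude
l1).  The per-line weights w_m make the data term the negative
log-likelihood under the averaged-noise model (an option reproduces the
literal squared-weight reading).  The solver is ADMM with split z = Dx:
CG solves the x-update normal equations (10 inner iterations, tolerance
1e-8), complex soft-thresholding updates z, with over-relaxation
(alpha = 1.85) and a fixed count of 50 iterations so the reconstruction is
a deterministic program.  Initialization is a deterministic warm start (a
ridge-like CG solve of the data term followed by one shrinkage); with a
zero start, 50 iterations leave a measurably larger objective gap on some
multicoil instances.  The penalty rho is an algorithmic constant: the
default matches the geometric mean of the data and TV curvature scales,
rho = 6 * sqrt(lambda * mean(w) * mean|S|^2), calibrated once against a
high-accuracy reference solver; per-setting grid tuning (by NRMSE against a
reference slice, or by the objective itself when no reference exists) is
provided and frozen thereafter.  The trainable parameter is log(lambda),
keeping lambda positive under gradient steps.

**CNN plugin** - any network honoring the channel contract (input: 2L
real/imaginary planes of the per-channel zero-padded Fourier images;
output: 2 planes of the combined image) can be registered.  The built-in
trainable network is a compact 3x3-conv/ReLU stack (base width 16, periodic
padding, He initialization) with hand-written backpropagation; a weight-free
stub reproducing exact SENSE coil combination serves as a contract oracle.
This is a desk-scale stand-in honoring the interface of image-domain
learned reconstruction, not a large U-Net replication.

## Gradients

No automatic-differentiation framework is used.  Three gradient routes are
implemented and cross-checked:

* analytic adjoint-mode expressions for the linear apodized reconstructor;
* forward-mode tangent propagation through the unrolled ADMM for SENSE-TV
  (the CG solve is differentiated implicitly, dx = A^{-1}(db - dA x); the
  soft-threshold derivative is exact almost everywhere), giving
  d(loss)/d log(lambda) at ~1.1x the cost of one reconstruction and the
  full w-gradient at ~N tangent passes;
* manual backpropagation for the CNN, with the chain to w running through
  the noise scaling of the input images.

The central finite-difference fallback (default steps 1e-3 in log lambda,
1e-2 in w) is mandatory and used for verification.  Two caveats matter when
comparing routes: the implicit CG derivative is exact only when the inner
solve reaches tolerance (use ~20 CG iterations on verification instances),
and the loss is piecewise smooth — at coarse FD steps the stencil straddles
soft-threshold/ReLU kinks and the FD error decays only linearly in the
step, so verification uses steps in the convergent regime (3e-5 / 3e-4 for
SENSE-TV).

## Synthetic data and SNR calibration

The generator emulates the features of T1-weighted multicoil brain slices
that drive acquisition design: nested wavy-ellipse anatomy with
white-matter (0.75), gray-matter (0.5), and CSF-like (0.2) relative
magnitudes, thin bright curvilinear vascular-like structures (quadratic
curves, 1-2 voxel widths) that populate high spatial frequencies, mild
smooth intensity shading, a smooth random phase map, and Gaussian-lobed
coil sensitivities with low-order polynomial phase placed on a circle
(single-coil mode returns S = 1).  K-space comes from the discrete Fourier
transform of the voxelized phantom, so crop/zero-pad identities are exact
on the grid.  Each dataset is normalized by one scalar so the maximum
voxel magnitude across channels is 1.  What the phantoms do *not* emulate:
anatomical variability beyond randomized geometry, relaxation or
off-resonance contrast physics, readout oversampling chains, and residual
"hidden" noise in the references — so passing tests demonstrate the
correctness and qualitative behavior of the design machinery, not clinical
performance.

Noise levels are specified as target SNRs in a central white-matter disk
under the reference acquisition (full grid, uniform w0-fold averaging,
conventional Fourier + SENSE reconstruction).  The noise denominator is the
per-component (real/imaginary) standard deviation of noise-only combined
images, estimated by Monte Carlo; this convention is exactly linear in
sigma (so sigma ∝ 1/SNR holds identically) and coincides with the
magnitude-image noise std outside the Rayleigh regime.  One measurement at
sigma = 1 therefore fixes the calibration.

## Study conditions and schedules

Desk-scale study conditions: N0 = 64, L = 4, T = 32 phantoms (80/10/10
train/val/test), w0 = 8, SNR targets {2, 10}, candidate grids at
30-100% of N0 ({20, 26, 32, 38, 44, 52, 58, 64}).  The SENSE-TV sweep uses
a reduced cohort (T = 6) and candidate set ({32, 64}) because each
reconstruction runs a 50-iteration iterative solver.  Full-scale geometry
(320 grid, 16 coils, thousands of slices) remains configurable but is not
exercised by the test suite.

Published-style schedules are the defaults (SENSE-TV uniform: SGD on
log lambda, lr 0.01, decay 0.9, 10 epochs, batch 8; nonuniform: 45 joint +
5 refine epochs, lr_w 0.01 with decay 0.99; CNN: Adam 3e-4).  Two desk-scale
re-tunings were necessary, chosen by stability scans on training traces
before any acceptance measurement: (1) the apodized window uses Adam
(lr 0.02, decay 0.99) because the window-loss curvature spans roughly four
decades between the DC and edge k-space coordinates, which no single SGD
step size can serve; (2) the desk SENSE-TV study uses Adam on log lambda
(lr 0.15, 8 epochs, batch 2, lambda init 1) because batch-summed gradients
at this scale push lambda into its saturation zone under the published SGD
step.

## Numerical conventions

Centered grids (index m in {-N/2, ..., N/2-1}, DC at array position N/2)
with unitary FFTs throughout, so Parseval identities are exact and
energy-based tests are scale-free.  Coil combination is the unit-gain SENSE
formula sum conj(S) f / sum |S|^2 with an 1e-8 floor on the denominator.
NRMSE follows the estimate-normalized convention ||x - r|| / ||x|| (the
reference-normalized variant is a switch); SSIM is computed on magnitude
images, 11 x 11 Gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic
range set by the reference's maximum magnitude — which makes SSIM
asymmetric in its arguments by construction.

## Solver accuracy boundary

The 50-iteration ADMM objective is verified against an independent
Chambolle-Pock primal-dual solver run to ~1e-8 relative accuracy on random
16 x 16 instances with lambda in [0.02, 0.15] (the regularizer's operating
range at unit image scale), with the penalty selected over a small grid by
the objective itself.  The worst random instances sit right at a relative
gap of about 1e-5 — per-instance rho scans show this is the genuine
50-iteration convergence floor (no penalty, relaxation, or inner-CG budget
moves it), so measured maxima fluctuate around that value across instance
families.  For lambda above roughly 0.2 the fixed iteration budget cannot
approach that accuracy at any penalty; heavier regularization needs more
iterations.

## Known limitations

* The inner problem is nonconvex in (p, w); trained patterns are local
  minima, and different seeds can select neighboring grid sizes near flat
  outer-loss optima.
* The desk-scale low-frequency averaging concentration is mild (the
  normalized-gradient steps move the pattern by at most lr_w per step);
  the trend direction, not its magnitude, is the tested claim.
* MSE/NRMSE/SSIM undervalue resolution loss, so the selected grid sizes
  inherit the metrics' resolution insensitivity; alternative losses are
  exposed as configuration hooks but not validated.
* CNN training at desk scale uses few epochs and a small network; it
  demonstrates the interface and gradient plumbing, not learned-recon
  performance.
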