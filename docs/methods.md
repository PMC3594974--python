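# Methods

This note records the model, the numerical choices, and the design
decisions behind `odfstar`, in the order the pipeline uses them.

## Signal model and the CSA-ODF map

Each voxel's diffusion-weighted signal is assumed monoexponential in
the b-value, `s(u) = s0 exp(-b d(u))`, with `d` the apparent
diffusivity along unit direction `u`. The constant-solid-angle ODF is
obtained from the double-log transformed signal `y = ln(-ln(s/s0))` by
applying the Laplace–Beltrami operator and the Funk–Radon transform and
adding the isotropic term `1/(4 pi)`. In the real symmetric SH basis
(even degrees only; Condon–Shortley phase; index order `(l, m)` with
`l = 0, 2, ..., order` and `m = -l..l`, so order 4 has 15 functions)
both operators are diagonal, and the map from signal coefficients `c`
to ODF coefficients `c'` is per-coefficient:

    c'_1 = 1/(2 sqrt(pi)),
    c'_j = -1/(16 pi^2) * 2 pi P_l(0) * l(l+1) * c_j     (l > 0).

Two facts are enforced by tests: the `l > 0` multipliers agree with the
equivalent closed-form product `-(1/(8 pi)) (-1)^{l/2} [1*3*...*(l+1)] /
[2*4*...*(l-2)]` (3/(8 pi) at l = 2, -15/(16 pi) at l = 4), and the
constant `l = 0` term makes every reconstructed ODF integrate to 1
regardless of the data.

**Clipping.** The double-log transform diverges as `s/s0` approaches 0
or 1, so the ratio is clipped to `[clip_eps, 1 - clip_eps]` with
`clip_eps = 1e-4` by default. Clipped measurements receive a very large
propagated variance and are therefore effectively down-weighted by the
fit — the desired behavior for out-of-range samples.

**Noise variance.** `Var(s)` is one scalar per acquisition. The
default estimate is the variance of background voxels of the b = 0
image; simulation experiments pass the generator's true value. The
per-measurement variance of `y` uses first-order propagation,
`sigma^2 = Var(s) / (s^2 ln^2(s/s0))`, evaluated at the measured
(clipped) signal. Evaluating it at the measured rather than the true
signal couples the weight to the noise realization and makes the
standardized residuals slightly under-dispersed (a few percent); we
keep the measured-signal form because it is the only online-feasible
plain plug-in, and the resulting detector errs on the conservative
side (see Calibration below).

**Regularization.** The fit penalizes `lambda * c^T L c` with
`L = diag(l^2 (l+1)^2)` and `lambda = 0.006`, the standard
Laplace–Beltrami weight for order-4 fits of this kind; `s0` from
multiple b = 0 volumes is their arithmetic mean.

## Incremental reconstruction

The regularized weighted least-squares objective is minimized online by
a per-voxel Kalman filter with static state (the SH coefficients):

    V[k]     = B[k] P[k-1] B[k]^T + sigma^2[k]
    g[k]     = P[k-1] B[k]^T / V[k]
    gamma[k] = y[k] - B[k] c[k-1]
    c[k]     = c[k-1] + g[k] gamma[k]
    P[k]     = (I - g[k] B[k]) P[k-1]

initialized with `c[0]` the prior mean and
`P[0] = (prior_cov^-1 + lambda L)^-1`. The covariance update is carried
in Joseph form, which is algebraically identical but keeps `P`
symmetric PSD in floating point. With any prior the final estimate is
the batch solution of the corresponding penalized objective; with the
default diffuse prior (`tau^2 = 1e4` per coefficient) it matches the
batch fit without prior to better than 1e-6 relative error, the
package's central correctness oracle (tested per voxel on a
200-direction acquisition). The expected mean squared error of the ODF
coefficients is the trace of `P` propagated through the (diagonal)
signal-to-ODF map; it is non-increasing in the number of volumes.

**Prior.** The library default is a zero-mean diffuse prior — it
assumes nothing and reproduces the batch fit. For residual monitoring,
however, the prior matters: the innovation variance `V` is calibrated
(i.e. `gamma/sqrt(V)` is standard normal under the null) only when the
prior covariance matches the actual dispersion of coefficients across
the monitored ensemble. With a diffuse prior the early-scan `V` is
grossly over-predicted and the variance test is blind for the first
~20 volumes. The simulation experiments therefore initialize from
*population moments* — `E[c]` and `Cov(c)` estimated by an OLS fit of
the phantom's noiseless signals over the brain mask, standing in for
the atlas or pilot-scan information a scanner deployment would use.
This is the initialization the incremental system actually prescribes,
and it is what makes a no-delay test usable from the first volumes.

**Monitored voxels.** `M = 500` voxels drawn uniformly at random
(seeded) within the brain mask; only these need filter state for
detection, so detection experiments run the bank on the monitored
subset (`reconstruct_all=False`).

## Motion detectors

**STAR.** At each volume the `M` innovations are standardized by their
own predicted variances, `u_j = gamma_j / sqrt(V_j)`, and pooled into
the centered sum of squares `T = sum u_j^2 - (sum u_j)^2 / M`. Under
the null `T ~ chi^2_{M-1}` exactly when the residuals are Gaussian at
the predicted variances; the decision uses the normal approximation
`z = (T - (M-1)) / sqrt(2(M-1))` against `Phi^{-1}(1 - alpha)` (1.64 at
alpha = 0.05). Standardizing per voxel (rather than dividing the raw
sum by a single `V`) preserves the chi-square null when `V` varies
across voxels and reduces to the single-variance form when it does
not. Centering makes the statistic insensitive to a common-mode shift
of all residuals (exactly so for equal variances); scaling all
residuals by `c` scales `T` by `c^2`. One volume, no delay.

**GLRT.** A coefficient jump `p` at instant `theta` reaches the
innovation at volume `k` through `G(k, theta) = B[k] (I -
sum_{j=theta}^{k-1} g[j] G(j, theta))`, `G(theta, theta) = B[theta]`.
For each candidate `theta`, `p` is estimated by weighted least squares
over volumes `theta..k` and plugged into `l = sum gamma V^-1 G p_hat`,
which equals `b^T A^-1 b` with `A = sum G^T V^-1 G`, `b = sum G^T V^-1
gamma` — twice the maximized Gaussian log-likelihood ratio (verified
against a brute-force scalar expansion to 1e-8). Per-voxel statistics
at a shared candidate grid are summed (independent-voxel likelihood);
`theta_hat` is the argmax, smallest on ties; candidates are limited to
a trailing window (default 25 volumes) to bound cost. `A` is full rank
only once `k - theta >= 15` (the model dimension at order 4), so the
test reports "not computable" below that delay instead of guessing —
this is the structural weakness that motivates STAR. No analytic
threshold exists; experiments calibrate it on null replicates at the
target false-positive rate.

## Simulator

Multi-tensor phantoms with monoexponential decay per compartment.
The pseudo-brain phantom is an ellipsoidal "brain" (s0 = 1 inside, 0
outside, 2 mm isotropic voxels) containing a high-FA (0.8) ring of
tangentially oriented prolate tensors whose orientation varies smoothly
with position, a low-FA (0.25) core and rim, MD = 0.7e-3 mm^2/s
everywhere. The ellipsoid keeps a background margin inside the field
of view so that rigid resampling never clips tissue at the volume
boundary (resampling fills out-of-volume samples with zero; tissue at
the edge would otherwise flip to zero under arbitrarily small rotations
and produce an artificial motion signature).

Gradient schemes are greedy farthest-point orderings (projective
metric) of an oversampled golden-angle spiral on the hemisphere: every
prefix is near-uniform — each prefix's minimal pairwise line angle
stays above half the asymptotic optimal packing angle — which is what
makes partial reconstructions meaningful. b = 0 volumes (default 25)
come first.

A rigid motion at DWI volume `theta` is injected exactly as the
physics dictates: volumes `k >= theta` are synthesized with rotated
gradient directions `R g[k]` (the scanner still reports the nominal
table) and resampled through `(R, t)` with trilinear interpolation and
zero padding; all volumes are then Rician corrupted,
`sqrt((s + n1)^2 + n2^2)`, with `sigma = s0/SNR` (SNR defined on the
b = 0 image; default 20). Defaults mirror the simulation study:
rotation about the left-right axis, 3 degrees, motion at volume 20,
GLRT delay 3. Everything is deterministic given the seed.

**Study scale.** Detection experiments use a 32x32x16 phantom. The
monitored-voxel count `M` drives the statistic's null distribution, but
the *alternative* depends on the jump amplitudes, and the resampling
component of a rotation scales with the lever arm (a voxel at radius
`r` moves `~ r * angle`); a very small grid therefore understates
detectability relative to a full 128x128x64 head. 32x32x16 is the
smallest grid at which a 2-degree rotation remains reliably detectable
(true positive rate near 0.9 at the 5% threshold) while keeping a
replicate under a second.

## Experiments

One decision per simulated acquisition: STAR is read out at the motion volume `theta` (its no-delay
operating point), the GLRT at `theta + delay`; null replicates are read
out at the same volumes. The calibration experiment (100 null + 100
motion runs, 2 degrees at volume 18, SNR 20, M = 500, threshold 1.64)
fixes only the rotation magnitude, so each motion replicate draws a
uniformly random rotation axis — single-volume sensitivity depends
strongly on the angle between the decision-volume gradient and the
axis, and marginalizing that nuisance is the faithful reading of "100
experiments rotated by 2 degrees". Under these conditions the
empirical false positive rate is 0–3% (slightly conservative, from the
measured-signal variance plug-in and the order-4 truncation) and the
true positive rate ~0.9.

The power sweeps fix the false positive rate at 5% by calibrating each
method's threshold on its null arm per condition, then report TPR
across SNR, rotation magnitude, GLRT delay, and motion instant; GLRT
cells below its admissible delay are recorded as not computable. ROC
curves sweep thresholds over the pooled statistics and are monotone
from (0,0) to (1,1) by construction.

## What the synthetic data does and does not show

The phantom reproduces the features the detectors actually exploit —
anisotropic monoexponential signals with spatially varying orientation,
tissue/background contrast, Rician noise at scanner-like SNR, and the
exact gradient-rotation + resampling signature of a rigid motion. It
omits physiological noise, eddy-current and susceptibility distortion,
intra-volume (per-slice) motion, signal dropout, and the rich intensity
texture of real brains; real-data false-positive rates can therefore be
less conservative than the simulated ones, and the population prior
would have to come from an atlas or pilot scan rather than from the
imaged subject's own noiseless field. Passing tests demonstrate the
statistical machinery at its operating points, not scanner-grade
validation.

## Known limitations

* Single-shell, monoexponential CSA only; no ODF sharpening.
* One abrupt motion per acquisition is the tested regime; the
  detectors flag but do not segment multiple change points, and the
  package does not correct motion (re-registration / gradient
  reorientation after a detection are out of scope).
* The GLRT statistic is the plug-in form (twice the maximized LLR);
  only threshold conventions differ from the halved variant, and all
  thresholds are calibrated empirically.
* `Var(s)` is one scalar per acquisition (no per-slice or spatially
  varying noise).
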