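# odfstar

Online reconstruction of the constant-solid-angle orientation
distribution function (CSA-ODF) from diffusion MRI, with online
detection of subject motion from the reconstruction residuals.

High angular resolution diffusion imaging (HARDI) acquires one
diffusion-weighted volume per gradient direction — often 100–300
volumes, tens of minutes in the scanner — and subjects move. `odfstar`
is for researchers who want scan-time feedback: it reconstructs the ODF
incrementally as volumes arrive, and monitors the reconstruction's
innovations to flag a rigid head motion the moment it corrupts the
data, with no extra hardware, navigators, or scan time.

## The model

Under a monoexponential signal decay `s(u) = s0 exp(-b d(u))`, the ODF
in constant solid angle is

    psi(u) = 1/(4 pi) + 1/(16 pi^2) * FRT{ Delta_b  y }(u),
    y = ln(-ln(s / s0)),

where `FRT` is the Funk–Radon transform and `Delta_b` the
Laplace–Beltrami operator, both diagonal in the real symmetric
spherical-harmonic (SH) basis (eigenvalues `2 pi P_l(0)` and `-l(l+1)`).
The SH coefficients `c` of `y` are fitted by heteroscedastic,
Laplace–Beltrami–regularized least squares,

    min_c (y - B c)^T Sigma^-1 (y - B c) + lambda c^T L c,

with per-measurement variances `sigma^2[k] = Var(s) / (s^2 ln^2(s/s0))`
from first-order propagation through the double-log transform. Because
the objective is quadratic, it can be minimized **online** by a
per-voxel Kalman filter: one scalar update per voxel per volume, whose
final estimate equals the batch fit.

The filter's innovations `gamma[k] = y[k] - B[k] c[k-1]` with predicted
variances `V[k]` feed two motion detectors:

* **STAR** (statistical analysis of residuals): pools the standardized
  innovations of `M` monitored voxels at the current volume into the
  centered sum of squares `T`, which is `chi^2_{M-1}` under the
  no-motion null; for large `M`, `z = (T - (M-1)) / sqrt(2(M-1))` is
  compared to the normal quantile (1.64 at a 5% false-positive rate).
  STAR decides at the current volume — no detection delay.
* **GLRT** (generalized likelihood ratio test): propagates a candidate
  coefficient jump at instant `theta` through the filter recursion,
  estimates it by weighted least squares, and thresholds the plug-in
  likelihood ratio. The estimate needs at least as many post-change
  volumes as SH coefficients (15 at order 4), so the GLRT carries an
  intrinsic delay and cannot react to motion near the start of a scan.

A multi-tensor phantom simulator (incremental gradient schemes, rigid
motion injected as gradient rotation + volume resampling, Rician noise)
generates the synthetic acquisitions used for calibration and power
experiments.

## Worked example

Simulate a 32x32x16 pseudo-brain acquired along a 200-direction
incremental scheme at b = 1000 s/mm2 and SNR 20, with a 3-degree head
rotation after 19 diffusion volumes, then reconstruct online and
monitor the residuals:

```python
import numpy as np
from odfstar import detect, evaluate, simulate
from odfstar.config import ReconConfig
from odfstar.kalman import run_volume_stream
from odfstar.sh_ops import build_sh_model

phantom = simulate.make_pseudo_brain_phantom(grid_shape=(32, 32, 16), seed=0)
scheme = simulate.make_incremental_scheme(200, bvalue=1000.0, n_b0=25, seed=0)
motion = simulate.RigidMotion(theta=20, rotation=simulate.rotation_matrix([0, 0, 1], 3.0))
acq = simulate.synthesize_dwi(phantom, scheme, motion=motion, snr=20.0, seed=42)

model = build_sh_model(4)                                  # 15 coefficients
prior = evaluate.population_prior(phantom, scheme, model)  # E[c], Cov(c)
config = ReconConfig(n_monitor=500, noise_var=acq.noise_sigma**2, seed=42)
result = run_volume_stream(
    (acq.data[..., v] for v in range(scheme.n_volumes)),
    scheme, phantom.mask, config=config, reconstruct_all=False,
    prior_mean=prior[0], prior_cov=prior[1],
)
events, trace = detect.monitor(result.history.records(), alpha=0.05)
```

Output of this run:

```
STAR z at volumes 17..22: [-0.9  -0.3  -0.4  13.04  9.8   9.08]
max |z| before motion: 2.94   z at motion volume 20: 13.04
expected ODF MSE after 10 / 50 / 200 volumes: 7.48e-03 / 2.22e-03 / 7.73e-04
```

The statistic sits near zero while the subject is still, jumps to
z = 13 at the exact motion volume (threshold 1.64), and stays elevated
afterwards; isolated single-volume crossings earlier in the trace are
the expected 5% per-volume false-alarm rate of the no-delay test. The
expected mean squared error of the ODF coefficients (from the filter
covariance) falls monotonically as volumes accrue.

The same pipeline is available from the shell:

```bash
odfstar simulate out/sim --angle 3 --theta 20 --snr 20 --seed 42
odfstar monitor  out/sim out/report --n-monitor 500 --seed 42
odfstar evaluate out/sweeps --n-null 100 --n-alt 50 --snr 20 --snr 10 --angle 1 --angle 3
```

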