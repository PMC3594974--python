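"""Incremental per-voxel reconstruction of the CSA-ODF with a Kalman filter.

Each voxel carries a linear-Gaussian state: the SH coefficients ``c`` of
the transformed signal ``y``.  Every new diffusion-weighted volume
contributes one scalar measurement per voxel, ``y[k] = B[k] c + noise``
with ``B[k]`` the basis row of the k-th gradient direction and noise
variance ``sigma2[k]`` from the first-order propagation of the DWI noise
through the double-log transform.  The update is the standard Kalman /
recursive-least-squares recursion

    V[k]     = B[k] P[k-1] B[k]^T + sigma2[k]
    g[k]     = P[k-1] B[k]^T / V[k]
    gamma[k] = y[k] - B[k] c[k-1]
    c[k]     = c[k-1] + g[k] gamma[k]
    P[k]     = (I - g[k] B[k]) P[k-1]

initialized from a Gaussian prior with covariance shrunk by the
Laplace-Beltrami penalty, ``P[0] = (prior_cov^-1 + lambda L)^-1``.  With
a diffuse prior the final estimate equals the batch regularized fit, so
the filter is an exact online implementation of the offline
reconstruction.  The innovations ``gamma[k]`` and their predicted
variances ``V[k]`` are the raw material of the motion detectors.

Covariances are propagated in Joseph form, which keeps ``P`` symmetric
positive semidefinite in floating point.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from . import csa_transform
from .config import ReconConfig
from .sh_ops import SHModel, design_matrix

__all__ = [
    "KalmanState",
    "ResidualRecord",
    "MonitorHistory",
    "init_state",
    "update",
    "expected_odf_mse",
    "KalmanBank",
    "run_volume_stream",
    "StreamResult",
]


@dataclasses.dataclass
class KalmanState:
    """Per-voxel filter state: SH estimate ``c``, covariance ``P``, step count."""

    c: np.ndarray
    P: np.ndarray
    k: int
    lambda_reg: float


@dataclasses.dataclass
class ResidualRecord:
    """Innovations of one volume at the monitored voxels.

    ``gamma[m]`` is the one-step prediction error of voxel ``voxel_ids[m]``
    at volume ``k``; ``V[m]`` its variance as predicted by the filter.
    """

    k: int
    voxel_ids: np.ndarray
    gamma: np.ndarray
    V: np.ndarray


@dataclasses.dataclass
class MonitorHistory:
    """Stacked per-volume filter quantities at the monitored voxels.

    Arrays are indexed ``[k, m]`` (volume, monitored voxel); ``gain`` has a
    trailing coefficient axis and ``B`` holds the shared design rows.  This
    is everything the GLRT needs to propagate candidate jumps.
    """

    voxel_ids: np.ndarray
    B: np.ndarray          # (N, n_coeffs)
    gamma: np.ndarray      # (N, M)
    V: np.ndarray          # (N, M)
    gain: np.ndarray       # (N, M, n_coeffs)
    sigma2: np.ndarray     # (N, M) measurement variances used by the filter

    @property
    def n_volumes(self) -> int:
        return self.B.shape[0]

    def record(self, k: int) -> ResidualRecord:
        return ResidualRecord(k=k, voxel_ids=self.voxel_ids, gamma=self.gamma[k], V=self.V[k])

    def records(self) -> Iterable[ResidualRecord]:
        return (self.record(k) for k in range(self.n_volumes))


def init_state(
    model: SHModel,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    lambda_reg: float,
) -> KalmanState:
    """Initialize the filter from a Gaussian prior plus the LB penalty."""
    prior_cov = np.asarray(prior_cov, dtype=float)
    try:
        np.linalg.cholesky(prior_cov)
    except np.linalg.LinAlgError:
        raise ValueError("prior_cov must be symmetric positive definite") from None
    info = np.linalg.inv(prior_cov) + lambda_reg * np.diag(model.reg_diag)
    P0 = np.linalg.inv(info)
    return KalmanState(
        c=np.array(prior_mean, dtype=float),
        P=0.5 * (P0 + P0.T),
        k=0,
        lambda_reg=lambda_reg,
    )


def update(
    state: KalmanState, b_row: np.ndarray, y_k: float, sigma2_k: float
) -> tuple[KalmanState, float, float]:
    """Assimilate one scalar measurement; returns (new state, gamma, V).

    ``gamma`` is the innovation computed with the pre-update estimate.
    """
    if sigma2_k <= 0:
        raise ValueError(f"sigma2_k must be positive, got {sigma2_k}")
    b = np.asarray(b_row, dtype=float)
    Pb = state.P @ b
    V = float(b @ Pb + sigma2_k)
    if V <= 0:
        raise FloatingPointError(
            f"non-positive innovation variance V={V} at step {state.k + 1}; "
            f"diag(P)={np.diag(state.P)}"
        )
    g = Pb / V
    gamma = float(y_k - b @ state.c)
    c_new = state.c + g * gamma
    # Joseph form: (I - g b^T) P (I - g b^T)^T + sigma2 g g^T
    IgB = np.eye(b.size) - np.outer(g, b)
    P_new = IgB @ state.P @ IgB.T + sigma2_k * np.outer(g, g)
    return (
        KalmanState(c=c_new, P=0.5 * (P_new + P_new.T), k=state.k + 1, lambda_reg=state.lambda_reg),
        gamma,
        V,
    )


def expected_odf_mse(state: KalmanState, model: SHModel) -> float:
    """Expected mean squared error of the ODF coefficients, Tr(F^T L^T P L F).

    ``F`` and ``L`` are the diagonal Funk-Radon / Laplace-Beltrami
    operators scaled as in the signal-to-ODF coefficient map, so this is
    the trace of the covariance of ``c'`` implied by the filter
    covariance ``P``.
    """
    scale = csa_transform.odf_scale_vector(model)
    return float(np.sum(scale**2 * np.diag(state.P)))


class KalmanBank:
    """Vectorized bank of independent per-voxel Kalman filters.

    Holds ``n_voxels`` states updated in lockstep, one shared design row
    per volume but per-voxel measurements and noise variances.  This is
    the engine behind the volume-stream reconstruction and the
    simulation experiments.
    """

    def __init__(
        self,
        model: SHModel,
        n_voxels: int,
        lambda_reg: float,
        prior_var: float = 1e4,
        prior_mean: np.ndarray | None = None,
        prior_cov: np.ndarray | None = None,
    ):
        n = model.n_coeffs
        self.model = model
        self.lambda_reg = lambda_reg
        if prior_cov is None:
            P0 = np.diag(1.0 / (1.0 / prior_var + lambda_reg * model.reg_diag))
        else:
            P0 = np.linalg.inv(np.linalg.inv(prior_cov) + lambda_reg * np.diag(model.reg_diag))
            P0 = 0.5 * (P0 + P0.T)
        self.C = np.zeros((n_voxels, n))
        if prior_mean is not None:
            self.C[:] = np.asarray(prior_mean, dtype=float)
        self.P = np.zeros((n_voxels, n, n))
        self.P[:] = P0
        self.k = 0

    @property
    def n_voxels(self) -> int:
        return self.C.shape[0]

    def update(
        self, b_row: np.ndarray, y: np.ndarray, sigma2: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One volume for all voxels; returns (gamma, V, gain) arrays."""
        b = np.asarray(b_row, dtype=float)
        Pb = self.P @ b                     # (M, n)
        V = Pb @ b + sigma2                 # (M,)
        if np.any(V <= 0):
            raise FloatingPointError(f"non-positive innovation variance at volume {self.k + 1}")
        g = Pb / V[:, None]                 # (M, n)
        gamma = y - self.C @ b              # (M,)
        self.C += g * gamma[:, None]
        # Joseph form, batched over voxels.
        IgB = -g[:, :, None] * b[None, None, :]
        idx = np.arange(b.size)
        IgB[:, idx, idx] += 1.0
        P = IgB @ self.P @ IgB.transpose(0, 2, 1)
        P += sigma2[:, None, None] * (g[:, :, None] * g[:, None, :])
        self.P = 0.5 * (P + P.transpose(0, 2, 1))
        self.k += 1
        return gamma, V, g

    def state(self, voxel: int) -> KalmanState:
        return KalmanState(
            c=self.C[voxel].copy(), P=self.P[voxel].copy(), k=self.k, lambda_reg=self.lambda_reg
        )


@dataclasses.dataclass
class StreamResult:
    """Output of a full online reconstruction pass."""

    odf_coeffs: np.ndarray       # (X, Y, Z, n_coeffs) SH coefficients of psi
    signal_coeffs: np.ndarray    # (X, Y, Z, n_coeffs) SH coefficients of y
    history: MonitorHistory
    mse_trace: np.ndarray        # expected ODF MSE averaged over monitored voxels, per volume
    s0: np.ndarray               # (X, Y, Z) mean b=0 image
    noise_var: float


def _estimate_noise_var(b0: np.ndarray, mask: np.ndarray) -> float:
    """Background-voxel variance of the b=0 image (fallback noise estimate)."""
    background = b0[~mask]
    background = background[np.isfinite(background)]
    if background.size < 10:
        raise ValueError("too few background voxels to estimate the noise variance")
    return float(np.var(background))


def run_volume_stream(
    volumes: Iterable[np.ndarray],
    scheme,
    mask: np.ndarray,
    config: ReconConfig | None = None,
    monitor_voxels: Sequence[int] | None = None,
    model: SHModel | None = None,
    reconstruct_all: bool = True,
    prior_mean: np.ndarray | None = None,
    prior_cov: np.ndarray | None = None,
) -> StreamResult:
    """Run the per-voxel Kalman reconstruction over a stream of volumes.

    Parameters
    ----------
    volumes : iterable of 3D arrays
        Volumes in acquisition order (b=0 volumes first, as in the
        gradient scheme).  b=0 volumes are averaged into ``s0``; each
        diffusion-weighted volume triggers one filter update per masked
        voxel.
    scheme : GradientScheme
        Ordered b-values and unit directions matching the stream.
    mask : 3D bool array
        Voxels to reconstruct.
    monitor_voxels : sequence of int, optional
        Flat indices *into the masked voxel list* whose innovations are
        recorded for the detectors; default samples ``config.n_monitor``
        voxels uniformly without replacement (seeded).
    reconstruct_all : bool
        When False only the monitored voxels are filtered (sufficient
        for detection experiments, much cheaper); the returned
        coefficient images are then zero outside the monitored voxels.
    prior_mean, prior_cov : arrays, optional
        Population prior on the SH coefficients (shared across voxels),
        e.g. from an atlas or pilot fit; default is a zero-mean diffuse
        prior with variance ``config.prior_var``.  An informative prior
        keeps the innovation variances calibrated from the very first
        volumes.
    """
    from .sh_ops import build_sh_model  # local import to avoid cycles at module load

    config = config or ReconConfig()
    model = model or build_sh_model(config.order)
    mask = np.asarray(mask, dtype=bool)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("mask is empty")

    is_b0 = scheme.b0_mask()
    dwi_dirs = scheme.bvecs[~is_b0]
    B = design_matrix(model, dwi_dirs)
    n_dwi = B.shape[0]

    rng = np.random.default_rng(config.seed)
    if monitor_voxels is None:
        m = min(config.n_monitor, n_mask)
        monitor_voxels = np.sort(rng.choice(n_mask, size=m, replace=False))
    monitor_voxels = np.asarray(monitor_voxels, dtype=int)
    M = monitor_voxels.size

    mask_flat = np.flatnonzero(mask.ravel())
    if reconstruct_all:
        active = mask_flat  # flat image indices of every filtered voxel
        hist_idx = monitor_voxels
    else:
        active = mask_flat[monitor_voxels]
        hist_idx = np.arange(M)

    bank = KalmanBank(
        model,
        active.size,
        config.lambda_reg,
        config.prior_var,
        prior_mean=prior_mean,
        prior_cov=prior_cov,
    )
    history = MonitorHistory(
        voxel_ids=monitor_voxels,
        B=B,
        gamma=np.empty((n_dwi, M)),
        V=np.empty((n_dwi, M)),
        gain=np.empty((n_dwi, M, model.n_coeffs)),
        sigma2=np.empty((n_dwi, M)),
    )
    mse_trace = np.empty(n_dwi)
    scale2 = csa_transform.odf_scale_vector(model) ** 2

    s0_sum = None
    n_b0_seen = 0
    noise_var = config.noise_var
    s0_masked = None
    k_dwi = 0
    n_volumes = 0
    for vol_idx, vol in enumerate(volumes):
        vol = np.asarray(vol, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"volume shape {vol.shape} does not match mask shape {mask.shape}")
        n_volumes += 1
        if vol_idx >= len(is_b0):
            raise ValueError("more volumes than entries in the gradient scheme")
        if is_b0[vol_idx]:
            if k_dwi > 0:
                raise ValueError("b=0 volumes must precede the diffusion-weighted block")
            s0_sum = vol.copy() if s0_sum is None else s0_sum + vol
            n_b0_seen += 1
            continue
        if s0_sum is None:
            raise ValueError("no b=0 volume found before the first DWI volume")
        if s0_masked is None:
            s0_img = s0_sum / n_b0_seen
            s0_masked = s0_img.ravel()[active]
            if noise_var is None:
                noise_var = _estimate_noise_var(s0_img, mask)
        s = vol.ravel()[active]
        ratio = np.clip(s / s0_masked, config.clip_eps, 1.0 - config.clip_eps)
        log_e = np.log(ratio)
        y = np.log(-log_e)
        sigma2 = noise_var / (s0_masked * ratio) ** 2 / log_e**2
        gamma, V, g = bank.update(B[k_dwi], y, sigma2)
        history.gamma[k_dwi] = gamma[hist_idx]
        history.V[k_dwi] = V[hist_idx]
        history.gain[k_dwi] = g[hist_idx]
        history.sigma2[k_dwi] = sigma2[hist_idx]
        diagP = bank.P[hist_idx].diagonal(axis1=1, axis2=2)
        mse_trace[k_dwi] = float(np.mean(diagP @ scale2))
        k_dwi += 1

    if k_dwi != n_dwi:
        raise ValueError(f"scheme lists {n_dwi} DWI volumes but the stream supplied {k_dwi}")

    shape = mask.shape
    signal_coeffs = np.zeros((mask.size, model.n_coeffs))
    signal_coeffs[active] = bank.C
    signal_coeffs = signal_coeffs.reshape(shape + (model.n_coeffs,))
    odf = csa_transform.signal_to_odf_coeffs(bank.C, model)
    odf_coeffs = np.zeros((mask.size, model.n_coeffs))
    odf_coeffs[active] = odf.c_prime
    odf_coeffs = odf_coeffs.reshape(shape + (model.n_coeffs,))
    s0_img = s0_sum / n_b0_seen if s0_sum is not None else np.zeros(shape)
    return StreamResult(
        odf_coeffs=odf_coeffs,
        signal_coeffs=signal_coeffs,
        history=history,
        mse_trace=mse_trace,
        s0=s0_img,
        noise_var=float(noise_var),
    )
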