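"""Constant-solid-angle signal transform and ODF coefficient mapping.

Under a monoexponential decay ``s(u) = s0 * exp(-b d(u))`` the
constant-solid-angle ODF is

    psi(u) = 1/(4*pi) + 1/(16*pi^2) * FRT{ LB[ ln(-ln(s/s0)) ] }(u)

with FRT the Funk-Radon transform and LB the Laplace-Beltrami operator.
The pipeline therefore works on the double-log transformed signal
``y = ln(-ln(s/s0))``, fits its spherical-harmonic coefficients ``c`` by
regularized heteroscedastic least squares, and maps them to ODF
coefficients ``c'`` through the diagonal operator spectra:

    c'_1 = 1/(2*sqrt(pi))                          (l = 0)
    c'_j = -1/(16*pi^2) * 2*pi*P_l(0) * l(l+1) * c_j   (l > 0)

The l=0 ODF coefficient is data independent, which guarantees that the
reconstructed psi always integrates to 1 over the sphere.

The double-log transform distorts the noise: first-order error
propagation gives the per-measurement variance

    sigma^2[k] = Var(s[k]) / ( s[k]^2 * ln^2(s[k]/s0) ),

minimal near ``s/s0 = 1/e`` and diverging toward 0 and 1, hence the
clipping of ``s/s0`` to ``[clip_eps, 1 - clip_eps]``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import scipy.linalg

from .sh_ops import SHModel, design_matrix

__all__ = [
    "TransformedSignal",
    "OdfCoefficients",
    "transform_signal",
    "batch_fit",
    "odf_scale_vector",
    "signal_to_odf_coeffs",
    "evaluate_odf",
]

logger = logging.getLogger(__name__)

#: l=0 ODF coefficient; with the orthonormal basis (Y_0 = 1/(2 sqrt(pi)))
#: it evaluates to the isotropic value 1/(4 pi).
C0_ODF = 1.0 / (2.0 * np.sqrt(np.pi))


@dataclasses.dataclass
class TransformedSignal:
    """Double-log transformed signal with propagated variances.

    ``y[k] = ln(-ln(e[k]))`` where ``e[k]`` is the normalized signal
    clipped away from {0, 1}; ``sigma2[k]`` is the first-order variance
    of ``y[k]``; ``clip_mask[k]`` flags measurements that were clipped.
    """

    y: np.ndarray
    sigma2: np.ndarray
    clip_mask: np.ndarray


@dataclasses.dataclass
class OdfCoefficients:
    """SH coefficients of the constant-solid-angle ODF (units sr^-1)."""

    c_prime: np.ndarray


def transform_signal(
    s, s0: float, noise_var: float, clip_eps: float = 1e-4
) -> TransformedSignal:
    """Apply the double-log transform with first-order variance propagation.

    Parameters
    ----------
    s : array_like
        Non-negative diffusion-weighted measurements.
    s0 : float
        Non-diffusion-weighted reference signal (> 0).
    noise_var : float
        Variance of the DWI noise, one scalar for the whole volume.
    clip_eps : float
        The ratio s/s0 is clipped to ``[clip_eps, 1-clip_eps]``.
    """
    if s0 <= 0:
        raise ValueError(f"s0 must be positive, got {s0}")
    if noise_var <= 0:
        raise ValueError(f"noise_var must be positive, got {noise_var}")
    if not 0.0 < clip_eps < 0.5:
        raise ValueError(f"clip_eps must lie in (0, 0.5), got {clip_eps}")

    s = np.asarray(s, dtype=float)
    ratio = s / s0
    e = np.clip(ratio, clip_eps, 1.0 - clip_eps)
    clip_mask = e != ratio
    if clip_mask.all() and clip_mask.size:
        logger.warning("all %d measurements clipped before the double-log transform", s.size)

    log_e = np.log(e)
    y = np.log(-log_e)
    sigma2 = noise_var / (s0 * e) ** 2 / log_e**2
    return TransformedSignal(y=y, sigma2=sigma2, clip_mask=clip_mask)


def batch_fit(ts: TransformedSignal, B: np.ndarray, model: SHModel, lambda_reg: float) -> np.ndarray:
    """Regularized heteroscedastic least-squares fit of the SH coefficients.

    Minimizes ``(y - Bc)^T Sigma^-1 (y - Bc) + lambda * c^T L c`` with
    ``Sigma = diag(sigma2)`` and ``L = diag(l_j^2 (l_j+1)^2)``; this is
    the offline oracle that the Kalman filter reproduces incrementally.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    w = 1.0 / ts.sigma2
    Bw = B * w[:, None]
    normal = B.T @ Bw + lambda_reg * np.diag(model.reg_diag)
    rhs = Bw.T @ ts.y
    try:
        return scipy.linalg.solve(normal, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            f"singular normal matrix (N={B.shape[0]}, n_coeffs={B.shape[1]}, "
            f"lambda={lambda_reg}); cond(B)={np.linalg.cond(B):.3e}"
        ) from err


def odf_scale_vector(model: SHModel) -> np.ndarray:
    """Per-coefficient multiplier taking signal SH coefficients to ODF ones.

    Entry j is ``-1/(16*pi^2) * F_diag[j] * l_j(l_j+1)`` for l_j > 0 and
    0 for the l=0 coefficient (whose ODF value is the fixed constant).
    """
    scale = -(model.F_diag * (-model.L_diag)) / (16.0 * np.pi**2)
    scale[model.degree_of == 0] = 0.0
    return scale


def signal_to_odf_coeffs(c: np.ndarray, model: SHModel) -> OdfCoefficients:
    """Map fitted signal coefficients to constant-solid-angle ODF coefficients."""
    c = np.asarray(c, dtype=float)
    if c.shape[-1] != model.n_coeffs:
        raise ValueError(
            f"coefficient vector has length {c.shape[-1]}, model expects {model.n_coeffs}"
        )
    c_prime = c * odf_scale_vector(model)
    c_prime[..., 0] = C0_ODF
    return OdfCoefficients(c_prime=c_prime)


def evaluate_odf(odf: OdfCoefficients, directions, model: SHModel) -> np.ndarray:
    """Evaluate psi at unit directions by SH synthesis (antipodally symmetric)."""
    B = design_matrix(model, directions)
    return B @ odf.c_prime
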