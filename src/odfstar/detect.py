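"""Online motion detectors built on the Kalman filter innovations.

Subject motion at volume ``theta`` shifts every voxel's SH state by some
jump ``p``, which propagates into the subsequent innovations.  Two
detectors consume the per-volume innovations ``gamma`` and predicted
variances ``V`` of the monitored voxels:

STAR (STatistical Analysis of Residuals)
    A one-sided variance test on the *current* volume only, hence no
    detection delay.  With M monitored voxels the statistic

        T = sum_j gamma_j^2 / V_j - ( sum_j gamma_j / sqrt(V_j) )^2 / M

    is the centered sum of squares of the standardized innovations and
    follows chi^2_{M-1} under the no-motion null.  For large M it is
    standardized as  z = (T - (M-1)) / sqrt(2(M-1))  ~  N(0,1), and
    motion is declared when z exceeds the normal quantile of the target
    false-positive rate (1.64 at alpha = 0.05).  Standardizing each
    voxel by its own predicted variance keeps the chi-square null exact
    even though V varies across voxels; when all V are equal the
    statistic reduces to the single-variance form.

GLRT (generalized likelihood ratio test)
    The classical change detector for linear-Gaussian systems.  A jump
    ``p`` at time ``theta`` enters the innovation at time ``k`` through
    the propagation row

        G(k, theta) = B[k] ( I - sum_{j=theta}^{k-1} g[j] G(j, theta) ),
        G(theta, theta) = B[theta],

    where ``g[j]`` is the Kalman gain.  For each candidate theta the
    jump is estimated by weighted least squares,

        p_hat = ( sum_j G^T V^-1 G )^-1  sum_j G^T V^-1 gamma,

    and plugged into the log-likelihood-ratio statistic
    ``l = sum_j gamma V^-1 G p_hat`` (twice the maximized Gaussian
    log-likelihood ratio).  The least-squares system is full rank only
    once ``k - theta >= n_coeffs`` scalar measurements have accrued, so
    the test carries an intrinsic delay equal to the model dimension (15
    at SH order 4) and cannot be computed for motion near the start of
    the scan.  Per-voxel statistics at a shared candidate theta are
    summed (independent-voxel likelihood) to form the volume-level
    statistic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kalman import MonitorHistory, ResidualRecord

__all__ = [
    "MotionEvent",
    "star_threshold",
    "star_statistic",
    "star_step",
    "glrt_statistic",
    "glrt_step",
    "monitor",
]


@dataclasses.dataclass
class MotionEvent:
    """Decision of one detector at one volume.

    ``computable`` is False when the GLRT least-squares system is rank
    deficient (too few post-change measurements); ``theta_hat`` is the
    maximum-likelihood change instant (GLRT only).
    """

    detected: bool
    k_detect: int
    statistic: float
    threshold: float
    method: str
    theta_hat: int | None = None
    computable: bool = True


def star_threshold(alpha: float) -> float:
    """Normal-approximation threshold of the standardized STAR statistic."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return float(norm.ppf(1.0 - alpha))


def star_statistic(gamma: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Return (T, z): the chi^2_{M-1} statistic and its normal standardization."""
    gamma = np.asarray(gamma, dtype=float)
    V = np.asarray(V, dtype=float)
    M = gamma.size
    if M < 2:
        raise ValueError(f"STAR needs at least 2 monitored voxels, got {M}")
    if np.any(V <= 0):
        raise ValueError("predicted variances must be positive")
    u = gamma / np.sqrt(V)
    T = float(u @ u - u.sum() ** 2 / M)
    z = (T - (M - 1)) / np.sqrt(2.0 * (M - 1))
    return T, z


def star_step(record: ResidualRecord, alpha: float = 0.05) -> MotionEvent:
    """STAR decision from the current volume's residual record (no delay)."""
    _, z = star_statistic(record.gamma, record.V)
    thr = star_threshold(alpha)
    return MotionEvent(
        detected=z > thr, k_detect=record.k, statistic=z, threshold=thr, method="STAR"
    )


def _glrt_candidate(history: MonitorHistory, k: int, theta: int) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate the per-voxel WLS system (A, b) for a jump at ``theta``.

    Runs the jump-propagation recursion from theta to k; returns
    ``A`` of shape (M, n, n) and ``b`` of shape (M, n) with
    A = sum G^T V^-1 G and b = sum G^T V^-1 gamma.
    """
    B = history.B
    n = B.shape[1]
    M = history.V.shape[1]
    S = np.zeros((M, n, n))
    A = np.zeros((M, n, n))
    b = np.zeros((M, n))
    for j in range(theta, k + 1):
        # G(j, theta) = B[j] (I - S) per voxel
        G = B[j][None, :] - np.einsum("i,mik->mk", B[j], S)
        w = 1.0 / history.V[j]
        A += w[:, None, None] * (G[:, :, None] * G[:, None, :])
        b += (w * history.gamma[j])[:, None] * G
        if j < k:
            S += history.gain[j][:, :, None] * G[:, None, :]
    return A, b


def glrt_statistic(history: MonitorHistory, k: int, theta: int) -> float:
    """Volume-level GLRT statistic for a candidate change at ``theta``.

    Sums the per-voxel plug-in log-likelihood ratios ``b^T A^-1 b``.
    Raises ``np.linalg.LinAlgError`` if the WLS system is singular.
    """
    A, b = _glrt_candidate(history, k, theta)
    try:
        p_hat = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        conds = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"singular GLRT normal matrix at k={k}, theta={theta}; "
            f"max condition number {np.max(conds):.3e}"
        ) from None
    return float(np.sum(b * p_hat))


def glrt_step(
    history: MonitorHistory,
    k: int,
    threshold: float,
    window: int = 25,
    min_delay: int | None = None,
) -> MotionEvent:
    """GLRT decision at volume ``k`` scanning candidate change instants.

    Candidates are restricted to the last ``window`` volumes and to
    instants with ``k - theta >= min_delay`` (default: the number of SH
    coefficients, the rank requirement of the jump estimate).  When no
    candidate is admissible the event is returned as not computable.
    """
    n = history.B.shape[1]
    if min_delay is None:
        min_delay = n
    theta_max = k - min_delay
    theta_min = max(0, k - window + 1)
    if theta_max < theta_min:
        return MotionEvent(
            detected=False,
            k_detect=k,
            statistic=np.nan,
            threshold=threshold,
            method="GLRT",
            theta_hat=None,
            computable=False,
        )
    best_l, best_theta = -np.inf, None
    for theta in range(theta_min, theta_max + 1):
        l_theta = glrt_statistic(history, k, theta)
        if l_theta > best_l + 0.0:  # strict: ties keep the smallest theta
            best_l, best_theta = l_theta, theta
    return MotionEvent(
        detected=best_l > threshold,
        k_detect=k,
        statistic=best_l,
        threshold=threshold,
        method="GLRT",
        theta_hat=best_theta,
    )


def monitor(
    records,
    history: MonitorHistory | None = None,
    alpha: float = 0.05,
    glrt_threshold: float | None = None,
    window: int = 25,
    k_min: int = 0,
) -> tuple[list[MotionEvent], pd.DataFrame]:
    """Run STAR (and GLRT when a history is given) over a residual stream.

    Parameters
    ----------
    records : iterable of ResidualRecord
        Per-volume residual records in increasing ``k`` order.
    history : MonitorHistory, optional
        Full filter history; required for the GLRT.
    k_min : int
        First volume at which decisions are taken (earlier volumes are
        prior dominated and their statistics recorded but not tested).

    Returns
    -------
    events : list of MotionEvent
        All threshold crossings, both methods.
    trace : DataFrame
        One row per volume with the statistics and decisions.
    """
    events: list[MotionEvent] = []
    rows = []
    last_k = -1
    for record in records:
        if record.k <= last_k:
            raise ValueError(f"records out of order: k={record.k} after k={last_k}")
        last_k = record.k
        star_ev = star_step(record, alpha)
        row = {
            "k": record.k,
            "star_z": star_ev.statistic,
            "star_threshold": star_ev.threshold,
            "star_detected": star_ev.detected and record.k >= k_min,
        }
        if star_ev.detected and record.k >= k_min:
            events.append(star_ev)
        if history is not None and glrt_threshold is not None:
            glrt_ev = glrt_step(history, record.k, glrt_threshold, window=window)
            row.update(
                {
                    "glrt_l": glrt_ev.statistic,
                    "glrt_threshold": glrt_ev.threshold,
                    "glrt_computable": glrt_ev.computable,
                    "glrt_theta_hat": glrt_ev.theta_hat,
                    "glrt_detected": glrt_ev.detected and record.k >= k_min,
                }
            )
            if glrt_ev.detected and record.k >= k_min:
                events.append(glrt_ev)
        rows.append(row)
    return events, pd.DataFrame(rows)
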