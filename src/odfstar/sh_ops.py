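"""Real symmetric spherical-harmonic basis and its spectral operators.

Antipodally symmetric functions on the sphere (diffusion signals, ODFs)
are expanded in the real symmetric spherical-harmonic basis: only even
degrees ``l`` appear, and for each ``l`` the ``2l+1`` orders ``m`` are
combined into real-valued functions.  The coefficient index ``j`` runs
over ``(l, m)`` pairs in the order

    (0,0), (2,-2), (2,-1), (2,0), (2,1), (2,2), (4,-4), ..., (4,4), ...

so the degree sequence is ``l_j = 0, 2,2,2,2,2, 4,4,...`` and an even
order ``L`` gives ``(L+1)(L+2)/2`` coefficients (order 4 -> 15).

The real basis functions are built from the complex spherical harmonics
``Y_l^m`` (Condon-Shortley phase included, as in ``scipy.special``):

    m < 0:  sqrt(2) * (-1)^m * Im(Y_l^|m|)
    m = 0:  Y_l^0  (real)
    m > 0:  sqrt(2) * (-1)^m * Re(Y_l^m)

This basis is orthonormal on the sphere, and both spherical operators
used by the constant-solid-angle ODF mapping are diagonal in it:

* Funk-Radon transform (great-circle integral): eigenvalue 2*pi*P_l(0),
  with P_l the Legendre polynomial;
* Laplace-Beltrami operator: eigenvalue -l(l+1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = ["SHModel", "build_sh_model", "design_matrix", "funk_radon_diag"]

_MAX_ORDER = 12


@dataclasses.dataclass(frozen=True)
class SHModel:
    """A real symmetric SH basis of a given even order with operator spectra.

    Attributes
    ----------
    order : int
        Maximum (even) harmonic degree.
    n_coeffs : int
        Number of basis functions, ``(order+1)(order+2)/2``.
    lm : ndarray of shape (n_coeffs, 2)
        The ``(l, m)`` pair of each coefficient, in index order.
    degree_of : ndarray of shape (n_coeffs,)
        Harmonic degree ``l_j`` of each coefficient.
    F_diag : ndarray
        Funk-Radon eigenvalues ``2*pi*P_{l_j}(0)``.
    L_diag : ndarray
        Laplace-Beltrami eigenvalues ``-l_j(l_j+1)``.
    reg_diag : ndarray
        Diagonal of the Laplace-Beltrami regularization matrix,
        ``l_j^2 (l_j+1)^2`` (the squared operator).
    """

    order: int
    n_coeffs: int
    lm: np.ndarray
    degree_of: np.ndarray
    F_diag: np.ndarray
    L_diag: np.ndarray
    reg_diag: np.ndarray


def build_sh_model(order: int) -> SHModel:
    """Build the real symmetric SH model of the given even order.

    Parameters
    ----------
    order : int
        Even harmonic order, ``2 <= order <= 12``.
    """
    if not isinstance(order, (int, np.integer)):
        raise ValueError(f"order must be an integer, got {order!r}")
    if order < 2 or order % 2 != 0:
        raise ValueError(f"order must be a positive even integer >= 2, got {order}")
    if order > _MAX_ORDER:
        raise ValueError(f"order {order} exceeds the supported maximum {_MAX_ORDER}")

    lm = np.array([(l, m) for l in range(0, order + 1, 2) for m in range(-l, l + 1)])
    degree = lm[:, 0]
    f_diag = 2.0 * np.pi * eval_legendre(degree, 0.0)
    l_diag = -degree * (degree + 1.0)
    return SHModel(
        order=int(order),
        n_coeffs=lm.shape[0],
        lm=lm,
        degree_of=degree,
        F_diag=f_diag,
        L_diag=l_diag,
        reg_diag=l_diag**2,
    )


def _check_unit(directions: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise ValueError("directions must be 3-vectors")
    norms = np.linalg.norm(directions, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(f"directions must be unit vectors (max |norm-1| = {worst:.2e})")
    return directions


def design_matrix(model: SHModel, directions) -> np.ndarray:
    """Evaluate every basis function at each unit direction.

    Returns the N x n_coeffs matrix whose row k contains the basis
    functions evaluated at ``directions[k]``.  Because only even degrees
    are present, rows for ``u`` and ``-u`` are identical.
    """
    u = _check_unit(directions)
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(u[:, 1], u[:, 0])

    B = np.empty((u.shape[0], model.n_coeffs))
    for j, (l, m) in enumerate(model.lm):
        y = sph_harm_y(int(l), int(abs(m)), theta, phi)
        if m < 0:
            B[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
        elif m == 0:
            B[:, j] = y.real
        else:
            B[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
    return B


def funk_radon_diag(model: SHModel) -> np.ndarray:
    """Diagonal of the Funk-Radon transform: ``2*pi*P_{l_j}(0)`` per coefficient."""
    return model.F_diag.copy()
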