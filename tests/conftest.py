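import numpy as np
import pytest

from odfstar import simulate
from odfstar.sh_ops import build_sh_model, design_matrix


@pytest.fixture(scope="session")
def model4():
    return build_sh_model(4)


@pytest.fixture(scope="session")
def sphere_quadrature():
    """Gauss-Legendre x uniform-phi product quadrature on the sphere.

    Exact for spherical polynomials up to degree ~47, ample for products
    of order-4 basis functions; returns (directions, weights) with
    weights summing to 4*pi.
    """
    x, w = np.polynomial.legendre.leggauss(24)
    n_phi = 48
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    theta = np.arccos(x)
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1
    ).reshape(-1, 3)
    weights = np.repeat(w, n_phi) * (2.0 * np.pi / n_phi)
    return dirs, weights


@pytest.fixture(scope="session")
def random_directions():
    rng = np.random.default_rng(11)
    u = rng.normal(size=(200, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def design200(model4, random_directions):
    return design_matrix(model4, random_directions)


@pytest.fixture(scope="session")
def tiny_scheme():
    """Small incremental scheme for fast pipeline tests."""
    return simulate.make_incremental_scheme(32, bvalue=1000.0, n_b0=4, seed=1)


@pytest.fixture(scope="session")
def tiny_phantom():
    return simulate.make_pseudo_brain_phantom(grid_shape=(12, 12, 6), seed=1)
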