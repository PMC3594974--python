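"""Synthetic motion-corrupted HARDI acquisitions.

The generator mirrors the semi-artificial validation protocol of the
detection experiments: a multi-tensor phantom produces noiseless
monoexponential signals along an incrementally ordered gradient scheme;
a rigid motion at volume ``theta`` is injected by (i) rotating the
diffusion gradients actually *used for synthesis* from ``theta`` on
(the scanner still believes the nominal table) and (ii) resampling
volumes ``theta..N`` through the rigid transform; finally every volume
is corrupted by Rician noise,  s_noisy = sqrt((s + n1)^2 + n2^2)  with
n1, n2 ~ N(0, sigma^2) and SNR defined as s0 / sigma on the b=0 image.

Default experimental conditions (rotation about the left-right axis,
SNR 20, 200 directions at b = 1000 s/mm^2) follow the simulation study
the detectors were calibrated on.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage

__all__ = [
    "GradientScheme",
    "RigidMotion",
    "Phantom",
    "SimulatedAcquisition",
    "make_incremental_scheme",
    "tensor_from_fa_md",
    "make_crossing_phantom",
    "make_pseudo_brain_phantom",
    "rotation_matrix",
    "synthesize_dwi",
]


@dataclasses.dataclass
class GradientScheme:
    """Ordered diffusion gradient table.

    ``bvals`` in s/mm^2; ``bvecs`` unit 3-vectors (zero rows allowed for
    b=0 entries).  ``order_incremental`` marks schemes whose every prefix
    of directions is near-uniform on the sphere, the property that makes
    online reconstruction meaningful.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    order_incremental: bool = False

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must have shape (len(bvals), 3)")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = ~self.b0_mask()
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-8):
            raise ValueError("diffusion-weighted bvecs must be unit vectors")

    def b0_mask(self, b0_threshold: float = 50.0) -> np.ndarray:
        return self.bvals < b0_threshold

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask().sum())

    def dwi_directions(self) -> np.ndarray:
        return self.bvecs[~self.b0_mask()]


@dataclasses.dataclass
class RigidMotion:
    """A single abrupt rigid motion: onset volume, rotation, translation (mm).

    ``theta`` indexes the diffusion-weighted sequence (1-based): DWI
    volumes ``k >= theta`` are acquired after the motion.
    """

    theta: int
    rotation: np.ndarray
    translation: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-10
        ):
            raise ValueError("rotation must be a proper orthonormal matrix")


@dataclasses.dataclass
class Phantom:
    """Multi-tensor field: per-voxel mixtures of Gaussian diffusion tensors.

    ``tensors`` has shape (X, Y, Z, n_comp, 3, 3) in mm^2/s and
    ``weights`` (X, Y, Z, n_comp) summing to 1 inside the mask.
    """

    weights: np.ndarray
    tensors: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    voxel_size: float = 2.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclasses.dataclass
class SimulatedAcquisition:
    """A synthetic 4D acquisition plus its ground truth.

    ``scheme`` is the *nominal* gradient table (what the scanner
    believes); the rotated directions actually used for synthesis after
    the motion are in ``effective_bvecs``.
    """

    data: np.ndarray
    scheme: GradientScheme
    effective_bvecs: np.ndarray
    motion: RigidMotion | None
    snr: float
    noise_sigma: float
    seed: int


def _spiral_hemisphere(n: int) -> np.ndarray:
    """Generalized-spiral (golden-angle) points on the upper hemisphere."""
    k = np.arange(n)
    z = 1.0 - (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_incremental_scheme(
    n_directions: int, bvalue: float = 1000.0, n_b0: int = 25, seed: int = 0
) -> GradientScheme:
    """Incrementally ordered gradient scheme with b=0 volumes first.

    Directions are chosen by greedy farthest-point (projective metric,
    i.e. modulo sign) selection from a 4x oversampled generalized-spiral
    candidate set on the hemisphere.  The greedy order makes every
    prefix well spread — the property that lets the ODF be reconstructed
    meaningfully while the acquisition is still running — and the
    oversampling keeps the complete set close to a uniform antipodal
    packing.  Deterministic given the seed (which picks the start).
    """
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions")
    cand = _spiral_hemisphere(4 * n_directions)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(cand.shape[0]))

    chosen = [start]
    # min projective distance of every candidate to the chosen set
    d = np.arccos(np.clip(np.abs(cand @ cand[start]), 0.0, 1.0))
    while len(chosen) < n_directions:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.arccos(np.clip(np.abs(cand @ cand[nxt]), 0.0, 1.0)))
    ordered = cand[chosen]

    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), ordered])
    return GradientScheme(bvals=bvals, bvecs=bvecs, order_incremental=True)


def min_projective_angle(directions: np.ndarray) -> float:
    """Minimal pairwise angle between diffusion *lines* (sign-invariant), radians."""
    dots = np.abs(directions @ directions.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.arccos(np.clip(dots.max(), 0.0, 1.0)))


def tensor_from_fa_md(fa: float, md: float, axis: np.ndarray) -> np.ndarray:
    """Axially symmetric (prolate) diffusion tensor with given FA, MD, axis.

    Eigenvalues are ``md*(1+2f), md*(1-f), md*(1-f)`` with ``f`` solving
    the FA equation for prolate tensors; FA in [0, 1), MD in mm^2/s.
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError(f"FA must lie in [0, 1), got {fa}")
    if md <= 0:
        raise ValueError(f"MD must be positive, got {md}")
    f = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam_par = md * (1.0 + 2.0 * f)
    lam_perp = md * (1.0 - f)
    if lam_perp <= 0:
        raise ValueError(f"FA={fa} not realizable with positive eigenvalues")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(axis, axis)


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def make_crossing_phantom(
    angle_deg: float,
    grid_shape: tuple[int, int, int] = (12, 12, 4),
    fa: float = 0.8,
    md: float = 0.7e-3,
    seed: int = 0,
) -> Phantom:
    """Two fiber bundles crossing at ``angle_deg`` in the axial plane.

    The central region mixes the two tensors with equal weights; the
    surrounding mask voxels carry a single tensor (alternating bundle),
    mimicking the classic crossing-fiber test object.
    """
    if not 0.0 < angle_deg <= 90.0:
        raise ValueError(f"crossing angle must lie in (0, 90], got {angle_deg}")
    half = np.deg2rad(angle_deg) / 2.0
    ax1 = np.array([np.cos(half), np.sin(half), 0.0])
    ax2 = np.array([np.cos(half), -np.sin(half), 0.0])
    D1 = tensor_from_fa_md(fa, md, ax1)
    D2 = tensor_from_fa_md(fa, md, ax2)

    X, Y, Z = grid_shape
    mask = np.ones(grid_shape, dtype=bool)
    weights = np.zeros(grid_shape + (2,))
    tensors = np.zeros(grid_shape + (2, 3, 3))
    tensors[..., 0, :, :] = D1
    tensors[..., 1, :, :] = D2

    xs = np.arange(X)[:, None, None]
    ys = np.arange(Y)[None, :, None]
    center = (np.array([X, Y]) - 1) / 2.0
    in_cross = (np.abs(xs - center[0]) <= X // 4) & (np.abs(ys - center[1]) <= Y // 4)
    in_cross = np.broadcast_to(in_cross, grid_shape)
    weights[in_cross] = [0.5, 0.5]
    arm1 = ~in_cross & (np.broadcast_to(xs + ys, grid_shape) % 2 == 0)
    weights[arm1] = [1.0, 0.0]
    weights[~in_cross & ~arm1] = [0.0, 1.0]

    s0 = np.where(mask, 1.0, 0.0)
    return Phantom(weights=weights, tensors=tensors, s0=s0, mask=mask)


def make_pseudo_brain_phantom(
    grid_shape: tuple[int, int, int] = (24, 24, 12),
    fa_wm: float = 0.8,
    md: float = 0.7e-3,
    voxel_size: float = 2.0,
    seed: int = 0,
) -> Phantom:
    """Smooth ellipsoidal tensor field with ring-like anisotropic tracts.

    An ellipsoidal "brain" mask contains a high-FA ring of tangentially
    oriented fibers (orientation varying smoothly with position, as in
    real white matter), a low-FA core and rim, and zero signal outside.
    The spatial structure gives both gradient-rotation and image-
    resampling components of a motion their realistic signatures.  The
    ellipsoid keeps a margin of background around the brain, as in a
    real field of view, so rigid resampling never clips tissue at the
    volume boundary.
    """
    X, Y, Z = grid_shape
    ii, jj, kk = np.meshgrid(np.arange(X), np.arange(Y), np.arange(Z), indexing="ij")
    c = (np.array(grid_shape) - 1) / 2.0
    x = (ii - c[0]) / (0.40 * (X - 1))
    y = (jj - c[1]) / (0.40 * (Y - 1))
    z = (kk - c[2]) / (0.40 * (Z - 1))
    r2 = x**2 + y**2 + z**2
    mask = r2 <= 1.0

    # tangential in-plane orientation with a smooth out-of-plane tilt
    phi = np.arctan2(jj - c[1], ii - c[0])
    tilt = 0.4 * z
    ex = -np.sin(phi) * np.cos(tilt)
    ey = np.cos(phi) * np.cos(tilt)
    ez = np.sin(tilt)
    axes = np.stack([ex, ey, ez], axis=-1)
    axes /= np.linalg.norm(axes, axis=-1, keepdims=True)

    rho = np.sqrt(x**2 + y**2)
    fa = np.where((rho > 0.25) & (rho < 0.85), fa_wm, 0.25)
    fa = np.where(mask, fa, 0.0)

    f = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam_par = md * (1.0 + 2.0 * f)
    lam_perp = md * (1.0 - f)
    outer = axes[..., :, None] * axes[..., None, :]
    tensors = lam_perp[..., None, None] * np.eye(3) + (lam_par - lam_perp)[
        ..., None, None
    ] * outer
    tensors = tensors[..., None, :, :]  # single component
    weights = np.ones(grid_shape + (1,))
    s0 = np.where(mask, 1.0, 0.0)
    return Phantom(
        weights=weights, tensors=tensors, s0=s0, mask=mask, voxel_size=voxel_size
    )


def noiseless_mask_signals(phantom: Phantom, scheme: GradientScheme) -> np.ndarray:
    """Noiseless DWI signals at the mask voxels, shape (n_dwi, n_mask).

    Normalized by ``s0`` (monoexponential multi-tensor attenuation);
    useful for population statistics and analytic oracles.
    """
    flat = phantom.mask.ravel()
    W = phantom.weights.reshape(-1, phantom.weights.shape[-1])[flat]
    D = phantom.tensors.reshape(-1, phantom.tensors.shape[-3], 3, 3)[flat]
    dirs = scheme.dwi_directions()
    bvals = scheme.bvals[~scheme.b0_mask()]
    out = np.empty((len(dirs), int(flat.sum())))
    for k, (b, g) in enumerate(zip(bvals, dirs)):
        gdg = np.einsum("vtij,i,j->vt", D, g, g)
        out[k] = np.einsum("vt,vt->v", W, np.exp(-b * gdg))
    return out


def _noiseless_signal(phantom: Phantom, bvalue: float, direction: np.ndarray) -> np.ndarray:
    """Monoexponential multi-tensor signal volume for one gradient direction."""
    g = np.asarray(direction, dtype=float)
    gdg = np.einsum("...tij,i,j->...t", phantom.tensors, g, g)
    return phantom.s0 * np.einsum("...t,...t->...", phantom.weights, np.exp(-bvalue * gdg))


def _resample_rigid(volume: np.ndarray, motion: RigidMotion, voxel_size: float) -> np.ndarray:
    """Apply the rigid transform to the image content (trilinear, zero padded)."""
    R = motion.rotation
    center = (np.array(volume.shape) - 1) / 2.0
    # moved image I'(x) = I(R^T (x - c - t/vs) + c) in voxel coordinates
    matrix = R.T
    offset = center - R.T @ (center + motion.translation / voxel_size)
    return scipy.ndimage.affine_transform(
        volume, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )


def synthesize_dwi(
    phantom: Phantom,
    scheme: GradientScheme,
    motion: RigidMotion | None = None,
    snr: float = 20.0,
    seed: int = 0,
) -> SimulatedAcquisition:
    """Synthesize a 4D acquisition with optional rigid motion and Rician noise.

    Volumes follow the scheme order (b=0 block first).  For DWI index
    ``k >= motion.theta`` the synthesis direction is ``R g[k]`` and the
    noiseless volume is resampled through ``(R, t)``; all volumes are
    then Rician corrupted with ``sigma = s0_max / snr`` (``snr=inf`` for
    noiseless output).  The returned scheme is the nominal one.
    """
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    is_b0 = scheme.b0_mask()
    n_b0 = int(is_b0.sum())
    if motion is not None and not 1 <= motion.theta <= scheme.n_volumes - n_b0:
        raise ValueError(
            f"motion.theta={motion.theta} outside the DWI sequence "
            f"(1..{scheme.n_volumes - n_b0})"
        )

    rng = np.random.default_rng(seed)
    data = np.empty(phantom.shape + (scheme.n_volumes,))
    effective = scheme.bvecs.copy()
    k_dwi = 0
    for v in range(scheme.n_volumes):
        if is_b0[v]:
            vol = phantom.s0.copy()
        else:
            k_dwi += 1
            g = scheme.bvecs[v]
            moved = motion is not None and k_dwi >= motion.theta
            if moved:
                g = motion.rotation @ g
                effective[v] = g
            vol = _noiseless_signal(phantom, scheme.bvals[v], g)
            if moved:
                vol = _resample_rigid(vol, motion, phantom.voxel_size)
        data[..., v] = vol

    s0_level = float(phantom.s0[phantom.mask].max()) if phantom.mask.any() else 1.0
    sigma = 0.0 if np.isinf(snr) else s0_level / snr
    if sigma > 0:
        n1 = rng.normal(scale=sigma, size=data.shape)
        n2 = rng.normal(scale=sigma, size=data.shape)
        data = np.hypot(data + n1, n2)
    return SimulatedAcquisition(
        data=data,
        scheme=scheme,
        effective_bvecs=effective,
        motion=motion,
        snr=float(snr),
        noise_sigma=float(sigma),
        seed=seed,
    )
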