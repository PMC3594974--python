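"""Resolved run configuration shared by the reconstruction and detection pipeline."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class ReconConfig:
    """Parameters of the online reconstruction / detection pipeline.

    Attributes
    ----------
    order:
        Even spherical-harmonic order of the signal fit (default 4,
        15 coefficients).
    lambda_reg:
        Laplace-Beltrami regularization weight of the signal fit.
    clip_eps:
        The normalized signal s/s0 is clipped to ``[clip_eps, 1-clip_eps]``
        before the double-log transform, which diverges at both ends.
    prior_var:
        Diagonal variance tau^2 of the diffuse Gaussian prior on the SH
        coefficients.  Large values make the incremental estimate match the
        batch regularized least-squares fit.
    alpha:
        Target false-positive rate of the STAR test.
    n_monitor:
        Number of voxels whose residuals are monitored for detection.
    window:
        Number of trailing volumes scanned for the GLRT candidate change
        instant.
    noise_var:
        DWI noise variance Var(s[k]) for the whole volume; ``None`` means
        estimate from background voxels of the b=0 image.
    seed:
        Seed for every stochastic choice (monitored-voxel selection, ...).
    """

    order: int = 4
    lambda_reg: float = 0.006
    clip_eps: float = 1e-4
    prior_var: float = 1e4
    alpha: float = 0.05
    n_monitor: int = 500
    window: int = 25
    noise_var: float | None = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_file(cls, path: str | Path) -> "ReconConfig":
        text = Path(path).read_text()
        if str(path).endswith(".toml"):
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls(**data)
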