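"""Diffusion tensor fitting and scalar metrics.

Log-linear ordinary-least-squares estimation of the symmetric 3x3 tensor
from single-shell DWI signals, and the eigenvalue-based scalar maps
(fractional anisotropy, mean diffusivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, UnderdeterminedError

log = logging.getLogger(__name__)

# Unique-element order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
_TRIU = ([0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2])


def tensors_to_matrices(six: np.ndarray) -> np.ndarray:
    """(..., 6) unique elements -> (..., 3, 3) symmetric matrices."""
    six = np.asarray(six, dtype=float)
    m = np.zeros(six.shape[:-1] + (3, 3))
    m[..., 0, 0] = six[..., 0]
    m[..., 1, 1] = six[..., 1]
    m[..., 2, 2] = six[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = six[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = six[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = six[..., 5]
    return m


def matrices_to_tensors(m: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) unique elements."""
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., i, j] for i, j in zip(*_TRIU)], axis=-1)


@dataclass
class DwiProtocol:
    """Acquisition protocol: b-values (s/mm^2) and unit gradient directions.

    The study protocol is 30 directions at b = 1000 s/mm^2 plus one b = 0
    volume; :func:`make_protocol` builds such a scheme synthetically.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.b_values.ndim != 1:
            raise ConfigError("b_values must be one-dimensional")
        if self.directions.shape != (len(self.b_values), 3):
            raise ConfigError("directions must be (N, 3) matching b_values")
        if np.any(self.b_values < 0):
            raise ConfigError("b-values must be non-negative")
        if not np.any(self.b_values == 0):
            raise ConfigError("protocol needs at least one b=0 volume")
        dwi = self.b_values > 0
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ConfigError("gradient directions must be unit vectors")
        if np.linalg.matrix_rank(self.design_matrix()[dwi]) < 6:
            raise UnderdeterminedError(
                "fewer than 6 independent gradient directions"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.b_values)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    def design_matrix(self) -> np.ndarray:
        """Rows -b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]."""
        g = self.directions
        quad = np.stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ],
            axis=1,
        )
        return -self.b_values[:, None] * quad


def make_protocol(n_directions: int = 30, b: float = 1000.0) -> DwiProtocol:
    """Deterministic single-shell protocol: one b=0 plus a Fibonacci sphere."""
    i = np.arange(n_directions) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n_directions
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    b_values = np.concatenate([[0.0], np.full(n_directions, float(b))])
    directions = np.vstack([[0.0, 0.0, 0.0], dirs])
    return DwiProtocol(b_values, directions)


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric tensors (mm^2/s) on a grid with a world affine."""

    tensors: np.ndarray  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    fitted: np.ndarray  # (...) bool: voxels with a valid fit
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.fitted = np.asarray(self.fitted, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.shape[-1] != 6:
            raise ConfigError("tensors must have 6 unique elements on the last axis")
        if self.fitted.shape != self.tensors.shape[:-1]:
            raise ConfigError("fitted mask shape mismatch")

    def matrices(self) -> np.ndarray:
        return tensors_to_matrices(self.tensors)

    def eigenvalues(self, clamp: bool = False) -> np.ndarray:
        """Eigenvalues in non-increasing order; optionally clamped at 0.

        Clamping is applied before metric computation; the number of voxels
        touched is logged because it flags noisy fits.
        """
        lam = np.linalg.eigvalsh(self.matrices())[..., ::-1]
        if clamp:
            n_neg = int(np.count_nonzero(np.any(lam < 0, axis=-1)))
            if n_neg:
                log.warning("clamped negative eigenvalues in %d voxels", n_neg)
            lam = np.clip(lam, 0.0, None)
        return lam


@dataclass
class ScalarVolume:
    """Scalar field on a voxel grid with a world affine (NIfTI convention)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ConfigError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ConfigError("affine is singular")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def fit_tensor(signals: np.ndarray, protocol: DwiProtocol,
               affine: np.ndarray | None = None) -> DiffusionTensorField:
    """Log-linear OLS tensor fit.

    Per voxel solves ln(S/S0) = -b g^T D g in least squares over the six
    unique tensor elements.  Multiple b=0 volumes are averaged into S0.
    Voxels with any non-positive signal are marked unfitted and get a zero
    tensor.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != protocol.n_volumes:
        raise ConfigError(
            f"signals have {signals.shape[-1]} volumes, protocol has "
            f"{protocol.n_volumes}"
        )
    b0 = protocol.b0_mask
    dwi = ~b0
    s0 = signals[..., b0].mean(axis=-1)
    fitted = np.all(signals > 0, axis=-1) & (s0 > 0)

    design = protocol.design_matrix()[dwi]  # (M, 6)
    pinv = np.linalg.pinv(design)  # (6, M)
    shape = signals.shape[:-1]
    tensors = np.zeros(shape + (6,))
    if np.any(fitted):
        s = signals[fitted][:, dwi]
        y = np.log(s / s0[fitted][:, None])
        tensors[fitted] = y @ pinv.T
    return DiffusionTensorField(
        tensors, fitted, np.eye(4) if affine is None else affine
    )


def _fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    lam = np.clip(lam, 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)  # zero tensor -> FA 0 by definition
    return np.clip(fa, 0.0, 1.0)


def fractional_anisotropy(f: DiffusionTensorField) -> ScalarVolume:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, from clamped eigenvalues."""
    fa = _fa_from_eigenvalues(f.eigenvalues(clamp=True))
    fa[~f.fitted] = 0.0
    return ScalarVolume(fa, f.affine)


def mean_diffusivity(f: DiffusionTensorField) -> ScalarVolume:
    """MD = (lambda1 + lambda2 + lambda3) / 3 from clamped eigenvalues."""
    md = f.eigenvalues(clamp=True).mean(axis=-1)
    md[~f.fitted] = 0.0
    return ScalarVolume(md, f.affine)
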