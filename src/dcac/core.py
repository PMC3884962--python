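"""Building blocks of the depth-aware two-phase convex active contour model.

The model assumes the ideal image is a piecewise-constant field multiplied by
a depth-only bias ``gamma**z`` (fluorescence fall-off with imaging depth), so
the two ideal phase images are ``I1 = c1 * gamma**z`` and ``I2 = c2 * gamma**z``.
Segmentation minimises, over a relaxed partition ``u`` in [0, 1],

    E(c1, c2, u) = TV(u) + lam * sum (I0 - I1)^2 u + lam * sum (I0 - I2)^2 (1 - u)

with an isotropic discrete total variation (forward differences, Neumann
boundaries).  This module provides the closed-form intensity estimators, the
residual field, the isotropic shrinkage operator, the Gauss-Seidel sweep and
the Bregman update used by the Split Bregman solver in :mod:`dcac.segment`.

Stencil conventions (used consistently throughout):

* gradient: forward differences, last entry along each axis zero (Neumann);
* divergence (in the Gauss-Seidel source term): backward differences with
  zero padding at the leading face — the exact negative adjoint of the
  gradient above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DegeneratePartitionError",
    "DepthBiasModel",
    "bias_at",
    "estimate_intensities",
    "residual_field",
    "shrink",
    "forward_gradient",
    "backward_divergence",
    "total_variation",
    "energy",
    "gauss_seidel_sweep",
    "bregman_update",
    "threshold_partition",
]


class DegeneratePartitionError(ValueError):
    """Raised when a soft region is empty and its intensity is undefined."""


@dataclass(frozen=True)
class DepthBiasModel:
    """Depth-dependent multiplicative bias ``gamma**z``.

    ``z`` is the integer slice index (page index), not physical depth;
    ``gamma = 1`` means no fall-off.  Values lie in (0, 1] and are
    non-increasing in depth.
    """

    gamma: float = 1.0

    def __post_init__(self) -> None:
        g = float(self.gamma)
        if not (0.0 < g <= 1.0):
            raise ValueError(f"gamma must be in (0, 1], got {g}")
        object.__setattr__(self, "gamma", g)

    def profile(self, nz: int) -> np.ndarray:
        """Bias values ``gamma**z`` for z = 0 .. nz-1."""
        return self.gamma ** np.arange(nz, dtype=np.float64)

    def field(self, shape: tuple[int, int, int]) -> np.ndarray:
        """The bias broadcast over a (nz, ny, nx) grid."""
        return np.broadcast_to(self.profile(shape[0])[:, None, None], shape)


def bias_at(bias: DepthBiasModel, z: int) -> float:
    """Bias value ``gamma**z`` at slice index *z* (z >= 0)."""
    if z < 0 or int(z) != z:
        raise ValueError(f"slice index must be a non-negative integer, got {z!r}")
    return float(bias.gamma ** int(z))


def _as_values(image) -> np.ndarray:
    values = getattr(image, "values", image)
    return np.asarray(values, dtype=np.float64)


def estimate_intensities(image, u: np.ndarray, bias: DepthBiasModel) -> tuple[float, float]:
    """Closed-form phase intensities given the current soft partition.

    Setting the first variation of the energy with respect to c1, c2 to zero
    gives the bias-weighted projections

        c1 = sum(u * I0 * g) / sum(u * g^2),
        c2 = sum((1-u) * I0 * g) / sum((1-u) * g^2),   g = gamma**z.

    At gamma = 1 these reduce to plain region means (the global Chan-Vese
    estimators).

    Raises
    ------
    DegeneratePartitionError
        If either soft region is (numerically) empty, naming the collapsed
        phase.
    """
    img = _as_values(image)
    u = np.asarray(u, dtype=np.float64)
    if img.shape != u.shape:
        raise ValueError(f"image shape {img.shape} != partition shape {u.shape}")
    g = bias.field(img.shape)
    g2 = g * g
    total = float(g2.sum())
    den1 = float((u * g2).sum())
    den2 = total - den1
    tiny = 1e-12 * total
    if den1 <= tiny:
        raise DegeneratePartitionError("foreground phase collapsed (sum u * gamma^2z ~ 0)")
    if den2 <= tiny:
        raise DegeneratePartitionError("background phase collapsed (sum (1-u) * gamma^2z ~ 0)")
    ig = img * g
    num1 = float((u * ig).sum())
    num2 = float(ig.sum()) - num1
    return num1 / den1, num2 / den2


def residual_field(image, c1: float, c2: float, bias: DepthBiasModel) -> np.ndarray:
    """Per-voxel fidelity residual ``(I0 - c1 g)^2 - (I0 - c2 g)^2``.

    Negative where the voxel is closer to the foreground ideal image,
    positive where closer to the background one.
    """
    img = _as_values(image)
    g = bias.field(img.shape)
    r1 = img - c1 * g
    r2 = img - c2 * g
    return r1 * r1 - r2 * r2


def shrink(v: np.ndarray, t: float) -> np.ndarray:
    """Isotropic vector soft-threshold ``v/|v| * max(|v| - t, 0)``.

    Operates on a stacked vector field of shape (3, nz, ny, nx) (or a single
    3-vector).  Returns the zero vector wherever |v| <= t, including v = 0
    (no 0/0).  Non-expansive: |shrink(v, t)| <= |v|.
    """
    if t < 0:
        raise ValueError(f"shrink threshold must be >= 0, got {t}")
    v = np.asarray(v, dtype=np.float64)
    mag = np.sqrt((v * v).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > t, (mag - t) / np.where(mag > 0, mag, 1.0), 0.0)
    return v * scale


def forward_gradient(u: np.ndarray) -> np.ndarray:
    """Forward-difference gradient, Neumann: zero on each trailing face."""
    u = np.asarray(u, dtype=np.float64)
    g = np.zeros((3,) + u.shape)
    g[0, :-1] = u[1:] - u[:-1]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    g[2, :, :, :-1] = u[:, :, 1:] - u[:, :, :-1]
    return g


def backward_divergence(v: np.ndarray) -> np.ndarray:
    """Backward-difference divergence, the negative adjoint of
    :func:`forward_gradient` (zero padding at each leading face)."""
    v = np.asarray(v, dtype=np.float64)
    div = np.zeros(v.shape[1:])
    div[0] += v[0, 0]
    div[1:] += v[0, 1:] - v[0, :-1]
    div[:, 0] += v[1, :, 0]
    div[:, 1:] += v[1, :, 1:] - v[1, :, :-1]
    div[:, :, 0] += v[2, :, :, 0]
    div[:, :, 1:] += v[2, :, :, 1:] - v[2, :, :, :-1]
    return div


def total_variation(u: np.ndarray) -> float:
    """Isotropic discrete TV: sum of |forward gradient| over voxels."""
    g = forward_gradient(u)
    return float(np.sqrt((g * g).sum(axis=0)).sum())


def energy(image, u: np.ndarray, c1: float, c2: float, lam: float,
           bias: DepthBiasModel) -> float:
    """Full model energy TV(u) + lam * weighted squared-fidelity terms."""
    img = _as_values(image)
    u = np.asarray(u, dtype=np.float64)
    g = bias.field(img.shape)
    r1 = img - c1 * g
    r2 = img - c2 * g
    fidelity = float((r1 * r1 * u).sum() + (r2 * r2 * (1.0 - u)).sum())
    return total_variation(u) + lam * fidelity


@njit(cache=True)
def _gs_sweeps(u, zeta, er, lam_over_mu, n_sweeps):  # pragma: no cover - numba
    nz, ny, nx = u.shape
    for _ in range(n_sweeps):
        for z in range(nz):
            zm = z - 1 if z > 0 else 0
            zp = z + 1 if z < nz - 1 else nz - 1
            for y in range(ny):
                ym = y - 1 if y > 0 else 0
                yp = y + 1 if y < ny - 1 else ny - 1
                for x in range(nx):
                    xm = x - 1 if x > 0 else 0
                    xp = x + 1 if x < nx - 1 else nx - 1
                    phi = (
                        u[zm, y, x] + u[zp, y, x]
                        + u[z, ym, x] + u[z, yp, x]
                        + u[z, y, xm] + u[z, y, xp]
                        + zeta[z, y, x] - lam_over_mu * er[z, y, x]
                    ) / 6.0
                    if phi < 0.0:
                        phi = 0.0
                    elif phi > 1.0:
                        phi = 1.0
                    u[z, y, x] = phi


def gauss_seidel_sweep(u: np.ndarray, d: np.ndarray, b: np.ndarray,
                       e_r: np.ndarray, lam: float, mu: float,
                       n_sweeps: int = 1) -> np.ndarray:
    """In-place lexicographic (z, y, x) Gauss-Seidel sweeps for the u-subproblem.

    Each voxel is replaced by the clamped average of its six face neighbours
    (already-updated values are used within a sweep; boundary neighbours read
    the replicated edge) plus the divergence source term
    ``zeta = div(b - d)`` minus ``(lam/mu) * e_r``, then clamped to [0, 1].

    Returns *u* (modified in place, as float64 C-contiguous).
    """
    u = np.ascontiguousarray(u, dtype=np.float64)
    zeta = backward_divergence(np.asarray(b, dtype=np.float64)
                               - np.asarray(d, dtype=np.float64))
    _gs_sweeps(u, np.ascontiguousarray(zeta),
               np.ascontiguousarray(e_r, dtype=np.float64),
               float(lam) / float(mu), int(n_sweeps))
    return u


def bregman_update(b: np.ndarray, u: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Bregman vector update ``b <- b + grad(u) - d`` (componentwise)."""
    return np.asarray(b, dtype=np.float64) + forward_gradient(u) - np.asarray(d, dtype=np.float64)


def threshold_partition(u: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Binary mask {u > alpha} (strict inequality; u = alpha is excluded)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return np.asarray(u) > alpha
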