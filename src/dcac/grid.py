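"""Voxel-grid containers.

Arrays are indexed ``(z, y, x)``; ``z = 0`` is the shallowest slice (closest
to the objective) and imaging depth increases with ``z``.  Physical voxel
spacing is carried as ``(dz, dy, dx)`` in micrometres and is never used by the
solver stencils — it matters only for volumetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default voxel spacing (dz, dy, dx) in micrometres: 12.9 um between optical
#: slices, 1.75 um in-plane.
DEFAULT_SPACING: tuple[float, float, float] = (12.9, 1.75, 1.75)


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components (dz, dy, dx), got {spacing!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive, got {spacing!r}")
    return spacing


@dataclass
class VoxelGrid:
    """A 3D scalar intensity field with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Non-negative finite intensities.  Integer inputs are converted to
        float64 without rescaling.
    spacing : tuple of float
        (dz, dy, dx) in micrometres, all strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if v.size and v.min() < 0:
            raise ValueError("volume contains negative intensities")
        self.values = v
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def nz(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryMask:
    """A boolean segmentation mask on the same lattice as its source grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x), got ndim={v.ndim}")
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be two-valued (boolean or {0,1})")
            v = v.astype(bool)
        self.values = v
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))
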