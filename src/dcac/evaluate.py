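"""Segmentation evaluation: Dice overlap, physical volumes, gamma calibration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .grid import BinaryMask, VoxelGrid

__all__ = ["dice_coefficient", "region_volume", "fit_gamma", "SegmentationReport"]


def _mask_values(mask) -> np.ndarray:
    return np.asarray(getattr(mask, "values", mask), dtype=bool)


def dice_coefficient(s1: BinaryMask | np.ndarray, s2: BinaryMask | np.ndarray) -> float:
    """Dice similarity 2|S1 ∩ S2| / (|S1| + |S2|), in [0, 1].

    0 is complete dissimilarity, 1 complete agreement.  Two empty masks are
    in complete agreement, so the empty-vs-empty value is 1 (limit
    convention).  Symmetric in its arguments.
    """
    a = _mask_values(s1)
    b = _mask_values(s2)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size_sum = int(a.sum()) + int(b.sum())
    if size_sum == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / size_sum


def region_volume(mask: BinaryMask | np.ndarray, spacing=None) -> float:
    """Physical volume of the foreground in mm^3.

    Voxel-count volumetry: count(True) * dz*dy*dx um^3 * 1e-9.  Additive over
    disjoint masks.
    """
    values = _mask_values(mask)
    if spacing is None:
        spacing = getattr(mask, "spacing", None)
        if spacing is None:
            raise ValueError("spacing required for a bare array mask")
    dz, dy, dx = (float(s) for s in spacing)
    if dz <= 0 or dy <= 0 or dx <= 0:
        raise ValueError(f"spacing must be strictly positive, got {(dz, dy, dx)}")
    return int(np.count_nonzero(values)) * dz * dy * dx * 1e-9


def fit_gamma(image: VoxelGrid | np.ndarray, mask: BinaryMask | np.ndarray | None = None) -> float:
    """Calibrate the depth decay constant from the stack itself.

    Least-squares slope s of log(per-slice median intensity) against slice
    index z; returns exp(s) clamped to (0, 1].  The per-slice statistic is
    restricted to *mask* when given (otherwise the whole slice); the median
    resists the bimodal foreground/background mixture.  Slices with no
    in-mask voxels or non-positive median are skipped; at least 3 usable
    slices are required.
    """
    img = np.asarray(getattr(image, "values", image), dtype=np.float64)
    sel = _mask_values(mask) if mask is not None else None
    zs, logs = [], []
    for z in range(img.shape[0]):
        vals = img[z][sel[z]] if sel is not None else img[z].ravel()
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        if med <= 0:
            continue
        zs.append(z)
        logs.append(np.log(med))
    if len(zs) < 3:
        raise ValueError(f"need >= 3 usable slices for gamma calibration, got {len(zs)}")
    slope = np.polyfit(np.asarray(zs, dtype=float), np.asarray(logs), 1)[0]
    return float(min(np.exp(slope), 1.0))


@dataclass
class SegmentationReport:
    """Bundle of evaluation quantities, serialisable to JSON."""

    dsc: float | None = None
    volume_total_mm3: float | None = None
    volume_per_mask_mm3: dict[str, float] | None = None
    voxel_counts: dict[str, int] | None = None
    gamma_fit: float | None = None

    def __post_init__(self) -> None:
        if self.dsc is not None and not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"dsc must be in [0, 1], got {self.dsc}")
        for name in ("volume_total_mm3",):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)
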