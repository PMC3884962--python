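"""Median pre-smoothing of the observed stack.

Confocal detection noise is Poisson-like; after median filtering the residual
noise in the smoothed image is well approximated as additive zero-mean
Gaussian, which is the noise model the segmentation energy assumes.  The
default window is an in-plane 3x3 (radius (0, 1, 1)): with interslice spacing
~7x the intraslice spacing, a window crossing slices would mix anatomy rather
than suppress noise.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import ndimage

from .grid import VoxelGrid


@dataclass(frozen=True)
class SmoothingSpec:
    """Per-axis median radii (rz, ry, rx); the window is (2r+1) per axis."""

    radius: tuple[int, int, int] = (0, 1, 1)

    def __post_init__(self) -> None:
        r = tuple(int(x) for x in self.radius)
        if len(r) != 3 or any(x < 0 for x in r):
            raise ValueError(f"radius must be 3 non-negative integers, got {self.radius!r}")
        object.__setattr__(self, "radius", r)

    @property
    def size(self) -> tuple[int, int, int]:
        return tuple(2 * r + 1 for r in self.radius)


def median_smooth(image: VoxelGrid, spec: SmoothingSpec = SmoothingSpec()) -> VoxelGrid:
    """Median-filter *image* with edge replication at the borders.

    Radius (0, 0, 0) is the identity.  The output range is a subset of the
    input range (a median never creates new extrema).
    """
    for ax, (w, n) in enumerate(zip(spec.size, image.shape)):
        if w > n:
            raise ValueError(
                f"median window {w} exceeds image extent {n} on axis {ax}"
            )
    if spec.size == (1, 1, 1):
        return VoxelGrid(image.values.copy(), image.spacing)
    smoothed = ndimage.median_filter(image.values, size=spec.size, mode="nearest")
    return VoxelGrid(smoothed, image.spacing)
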