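"""Reading and writing volumetric TIFF stacks and masks.

Multi-page grayscale TIFF is the interchange format: page order is z order,
page 0 the shallowest slice.  Sample values are never rescaled on read; masks
are written as 8-bit stacks with values {0, 255} and round-trip bit-exactly
through ``read_mask``.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .grid import DEFAULT_SPACING, BinaryMask, VoxelGrid


def read_volume(path: str | os.PathLike, spacing=DEFAULT_SPACING) -> VoxelGrid:
    """Read a single- or multi-page grayscale TIFF stack as a :class:`VoxelGrid`.

    The z index of the returned grid enumerates pages in file order.  Integer
    sample types are converted to float64 without rescaling.  Spacing always
    comes from the caller (TIFF spacing metadata is unreliable across
    dialects).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For non-image payloads, multi-channel pages, or pages of unequal
        shape (the message names the offending page index).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # tifffile raises various types for junk input
        raise ValueError(f"{path}: not a readable TIFF file ({exc})") from exc
    with tif:
        pages = tif.pages
        if len(pages) == 0:
            raise ValueError(f"{path}: TIFF contains no image pages")
        first_shape = pages[0].shape
        planes = []
        for i, page in enumerate(pages):
            if page.shape != first_shape:
                raise ValueError(
                    f"{path}: page {i} has shape {page.shape}, "
                    f"expected {first_shape} (page 0)"
                )
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"{path}: page {i} is not single-channel grayscale "
                    f"(shape {arr.shape}); split channels upstream"
                )
            planes.append(arr)
        volume = np.stack(planes, axis=0)
    return VoxelGrid(volume.astype(np.float64), spacing)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as an 8-bit TIFF stack with values {0, 255}, z = page order."""
    data = np.where(mask.values, np.uint8(255), np.uint8(0))
    tifffile.imwrite(path, data, photometric="minisblack")


def read_mask(path: str | os.PathLike, spacing=DEFAULT_SPACING) -> BinaryMask:
    """Read a mask stack: any sample value > 0 is foreground."""
    grid = read_volume(path, spacing=spacing)
    return BinaryMask(grid.values > 0, spacing=grid.spacing)
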