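"""Resolution reduction and binarization.

Scans are acquired at fine resolution (50 um in the reference protocol),
block-averaged to a working resolution (100 um), and then binarized with a
single global intensity threshold (200 CT units by default) that separates
CaCO3 from air and suppresses partial-volume voxels at the block-air
interface.  Thresholding is applied *after* downsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from coralct.volume_io import BinaryVolume, VolumeGrid

__all__ = [
    "PreprocessConfig",
    "downsample_mean",
    "apply_threshold",
    "largest_component",
    "preprocess",
]

log = logging.getLogger(__name__)

#: Global CT-number threshold separating CaCO3 from air.
DEFAULT_THRESHOLD = 200.0


@dataclass
class PreprocessConfig:
    downsample_factor: int = 2
    threshold: float = DEFAULT_THRESHOLD
    keep_largest_component: bool = False
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def downsample_mean(vol: VolumeGrid, factor: int) -> VolumeGrid:
    """Block-average by an integer factor along every axis.

    Each output voxel is the arithmetic mean of its ``factor**3`` input
    block and the voxel edge grows by ``factor``.  Trailing voxels of
    dimensions not divisible by ``factor`` are cropped (and logged).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return VolumeGrid(vol.data.copy(), vol.voxel_edge, vol.intensity_units)
    shape = vol.shape
    if any(s < factor for s in shape):
        raise ValueError(f"factor {factor} exceeds a volume dimension {shape}")
    new = tuple(s // factor for s in shape)
    crop = tuple(n * factor for n in new)
    if crop != shape:
        log.info("downsample_mean: cropping %s -> %s before averaging", shape, crop)
    d = vol.data[: crop[0], : crop[1], : crop[2]].astype(np.float64)
    d = d.reshape(new[0], factor, new[1], factor, new[2], factor).mean(axis=(1, 3, 5))
    return VolumeGrid(d, vol.voxel_edge * factor, vol.intensity_units)


def apply_threshold(vol: VolumeGrid, threshold: float = DEFAULT_THRESHOLD) -> BinaryVolume:
    """Binarize: solid where intensity >= threshold (boundary inclusive)."""
    return BinaryVolume(vol.data >= threshold, vol.voxel_edge)


def largest_component(mask: BinaryVolume, connectivity: int = 26) -> BinaryVolume:
    """Keep only the largest connected component of the mask.

    Ties are broken deterministically in favour of the component whose
    lowest-index (z, y, x) voxel comes first.
    """
    if mask.count() == 0:
        raise ValueError("cannot take largest component of an empty mask")
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    labels, n = ndimage.label(mask.mask, structure=structure)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    # np.argmax on ties returns the smallest label; scipy labels components
    # in raster (z, y, x) scan order, giving the documented tie-break.
    keep = int(np.argmax(counts == best))
    return BinaryVolume(labels == keep, mask.voxel_edge)


def preprocess(vol: VolumeGrid, cfg: PreprocessConfig | None = None) -> BinaryVolume:
    """Downsample then threshold (then optionally clean), per config."""
    cfg = cfg or PreprocessConfig()
    out = apply_threshold(downsample_mean(vol, cfg.downsample_factor), cfg.threshold)
    if cfg.keep_largest_component:
        out = largest_component(out, cfg.connectivity)
    return out
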