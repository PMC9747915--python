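"""Fixed-bin-number intensity discretization over the ROI."""

from __future__ import annotations

import numpy as np

from radiomit.types import VoxelImage

__all__ = ["discretize"]


def discretize(image: VoxelImage, n_bins: int = 32) -> np.ndarray:
    """Map ROI intensities to integer levels 1..n_bins (0 outside the ROI).

    Equal-width bins span [min, max] of the ROI intensities; the ROI maximum
    falls in the top bin. A constant ROI maps wholly to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    levels = np.zeros(image.intensities.shape, dtype=np.int32)
    roi = image.roi_values
    lo, hi = roi.min(), roi.max()
    if hi == lo:
        levels[image.mask] = 1
        return levels
    scaled = (image.intensities[image.mask] - lo) / (hi - lo) * n_bins
    binned = np.floor(scaled).astype(np.int32) + 1
    levels[image.mask] = np.clip(binned, 1, n_bins)
    return levels
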