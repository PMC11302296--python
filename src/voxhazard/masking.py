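"""Ternary reactivity masks from electronegativity grids, and the masked density.

Per molecule, voxels whose electronegativity exceeds the upper percentile
(default 90th) of that molecule's own distribution are class 2 (high
reactivity), voxels below the lower percentile (default 10th) are class 1
(low reactivity), and everything else is class 0 (medium/background).
Inequalities are strict — a voxel exactly equal to a threshold stays in
class 0 — and percentiles use linear interpolation between closest ranks.
Both choices shift only boundary voxels but are fixed here so masks are
reproducible.

The masked density multiplies the raw density by the indicator of the
reactive (class 1 or 2) regions, keeping real density values there and
zeroing the background.
"""

from __future__ import annotations

import numpy as np

from .cube import TernaryMask, VolumetricGrid

__all__ = ["ternary_mask", "masked_density", "one_hot"]


def ternary_mask(
    en_grid: VolumetricGrid,
    lower_percentile: float = 10.0,
    upper_percentile: float = 90.0,
) -> TernaryMask:
    """Percentile-threshold an electronegativity grid into {0, 1, 2} labels."""
    if not (0 <= lower_percentile < upper_percentile <= 100):
        raise ValueError("need 0 <= lower < upper <= 100")
    vals = en_grid.values
    if vals.size == 0:
        raise ValueError("empty grid")
    if not np.all(np.isfinite(vals)):
        raise ValueError("electronegativity grid contains non-finite values")
    p_lo, p_hi = np.percentile(vals, [lower_percentile, upper_percentile])
    labels = np.zeros(vals.shape, dtype=np.int8)
    labels[vals < p_lo] = 1
    labels[vals > p_hi] = 2
    return TernaryMask(labels)


def masked_density(density: VolumetricGrid, mask: TernaryMask) -> VolumetricGrid:
    """Density where the mask marks a reactive site (class 1 or 2), else 0."""
    if density.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: density {density.shape} vs mask {mask.shape}"
        )
    out = np.where(mask.labels > 0, density.values, 0.0)
    return density.with_values(out)


def one_hot(mask: TernaryMask) -> np.ndarray:
    """3-channel indicator array, shape (3, nx, ny, nz); channels sum to 1."""
    return np.stack([(mask.labels == c).astype(np.float64) for c in range(3)])
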