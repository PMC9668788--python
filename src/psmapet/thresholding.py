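"""Global-SUV threshold baseline segmenter with physiologic-region exclusion.

Mirrors the standard bootstrap for delineating tracer-avid disease on PSMA
PET: keep every voxel with SUV_bw strictly above a global threshold (3.0 by
default), then discard regions of known physiologic uptake supplied as an
explicit mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import (
    BinaryMask,
    ParameterError,
    VolumeGrid,
    _check_same_grid,
    connectivity_structure,
)


class InputError(ValueError):
    """Raised for PET volumes that cannot be thresholded (negative/non-finite)."""


@dataclass(frozen=True)
class ThresholdConfig:
    suv_threshold: float = 3.0  # strict '>' at the boundary
    connectivity: int = 26
    min_cluster_voxels: int = 1

    def __post_init__(self) -> None:
        if self.suv_threshold <= 0:
            raise ParameterError("SUV threshold must be positive")
        if self.min_cluster_voxels < 1:
            raise ParameterError("minimum cluster size must be >= 1")
        connectivity_structure(self.connectivity)  # validates


def global_threshold_segment(pet: VolumeGrid, cfg: ThresholdConfig = ThresholdConfig()) -> BinaryMask:
    """Voxels with SUV strictly greater than the threshold, small clusters removed."""
    values = np.asarray(pet.values)
    if not np.all(np.isfinite(values)):
        raise InputError("PET volume contains non-finite SUVs")
    if np.any(values < 0):
        raise InputError("PET volume contains negative SUVs")
    mask = values > cfg.suv_threshold
    if cfg.min_cluster_voxels > 1 and mask.any():
        structure = connectivity_structure(cfg.connectivity)
        labels, n = ndimage.label(mask, structure=structure)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < cfg.min_cluster_voxels) + 1
        if small.size:
            mask &= ~np.isin(labels, small)
    return BinaryMask(pet, mask)


def exclude_physiologic(mask: BinaryMask, physiologic: BinaryMask) -> BinaryMask:
    """Remove physiologic-uptake voxels: ``mask AND NOT physiologic``."""
    _check_same_grid(mask.grid, physiologic.grid)
    return BinaryMask(mask.grid, mask.membership & ~physiologic.membership)
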