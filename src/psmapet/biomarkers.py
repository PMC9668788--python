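"""Whole-body tumour-burden biomarkers from binary lesion masks.

TLV (total lesional volume, cm³) sums the volume of every positive voxel;
TLU (total lesional uptake, unitless) sums their SUV_bw values without volume
weighting.  The volume-weighted alternative Σ SUV × voxel-volume — total
lesion activity, analogous to total lesion glycolysis in FDG imaging — is
available under its own name but is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import BinaryMask, ParameterError, VolumeGrid, _check_same_grid
from . import survival as _survival


@dataclass(frozen=True)
class BiomarkerRecord:
    scan_id: str
    tlv_cm3: float
    tlu: float
    source: str = "auto"  # {auto, manual}

    def __post_init__(self) -> None:
        if self.tlv_cm3 < 0 or self.tlu < 0:
            raise ParameterError("TLV and TLU must be non-negative")


def compute_tlv(mask: BinaryMask) -> float:
    """Total lesional volume in cm³: positive-voxel count × voxel volume."""
    return mask.voxel_count * mask.grid.voxel_volume_cm3


def compute_tlu(mask: BinaryMask, pet: VolumeGrid) -> float:
    """Total lesional uptake: unweighted sum of SUV_bw over positive voxels."""
    _check_same_grid(mask.grid, pet)
    return float(np.asarray(pet.values)[mask.membership].sum())


def compute_total_lesion_activity(mask: BinaryMask, pet: VolumeGrid) -> float:
    """Volume-weighted uptake Σ SUV × voxel-volume (cm³·SUV); optional output."""
    return compute_tlu(mask, pet) * mask.grid.voxel_volume_cm3


def biomarker_record(
    scan_id: str, mask: BinaryMask, pet: VolumeGrid, source: str = "auto"
) -> BiomarkerRecord:
    return BiomarkerRecord(scan_id, compute_tlv(mask), compute_tlu(mask, pet), source)


def compare_biomarkers(
    auto: list[BiomarkerRecord],
    manual: list[BiomarkerRecord],
    log_transform: bool = False,
) -> pd.DataFrame:
    """Paired automated-vs-manual comparison per biomarker.

    Pairs records by ``scan_id`` and reports, for TLV and TLU separately:
    both medians, the two-sided Wilcoxon signed-rank p (degenerate all-zero
    differences flagged with p = 1), and Spearman ρ with its p-value.  With
    ``log_transform`` the scatter columns are log1p-transformed for plotting;
    rank statistics are unaffected.
    """
    auto_by_id = {r.scan_id: r for r in auto}
    manual_by_id = {r.scan_id: r for r in manual}
    if set(auto_by_id) != set(manual_by_id):
        raise ParameterError(
            f"unpaired scan ids: {sorted(set(auto_by_id) ^ set(manual_by_id))}"
        )
    ids = sorted(auto_by_id)
    if len(ids) < 5:
        raise ParameterError("need at least 5 paired scans")

    rows = []
    for name, getter in (("tlv_cm3", lambda r: r.tlv_cm3), ("tlu", lambda r: r.tlu)):
        a = np.array([getter(auto_by_id[i]) for i in ids], dtype=float)
        m = np.array([getter(manual_by_id[i]) for i in ids], dtype=float)
        diffs = a - m
        if np.all(diffs == 0):
            wilcoxon_p, degenerate = 1.0, True
        elif np.count_nonzero(diffs) < 5:
            # too few discordant pairs for the signed-rank test
            wilcoxon_p, degenerate = float("nan"), True
        else:
            _, wilcoxon_p = _survival.wilcoxon_signed_rank(diffs)
            degenerate = False
        rho, rho_p = _survival.spearman(a, m)
        rows.append(
            {
                "biomarker": name,
                "median_auto": float(np.median(a)),
                "median_manual": float(np.median(m)),
                "wilcoxon_p": wilcoxon_p,
                "wilcoxon_degenerate": degenerate,
                "spearman_rho": rho,
                "spearman_p": rho_p,
            }
        )
    return pd.DataFrame(rows)


def scatter_data(
    auto: list[BiomarkerRecord],
    manual: list[BiomarkerRecord],
    biomarker: str = "tlu",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Identity-line scatter points (auto vs manual), optionally log1p-scaled."""
    getter = {"tlv_cm3": lambda r: r.tlv_cm3, "tlu": lambda r: r.tlu}[biomarker]
    auto_by_id = {r.scan_id: r for r in auto}
    manual_by_id = {r.scan_id: r for r in manual}
    ids = sorted(set(auto_by_id) & set(manual_by_id))
    a = np.array([getter(auto_by_id[i]) for i in ids], dtype=float)
    m = np.array([getter(manual_by_id[i]) for i in ids], dtype=float)
    if log_transform:
        a, m = np.log1p(a), np.log1p(m)
    return pd.DataFrame({"scan_id": ids, "auto": a, "manual": m})
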