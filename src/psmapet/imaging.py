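"""Volume data model, NIfTI I/O, SUV conversion, resampling and connected components.

All in-package volumes live on axis-aligned grids: the world position of voxel
index ``(i, j, k)`` is ``origin + index * spacing`` (millimetres).  PET volumes
carry either activity concentration (Bq/mL) or body-weight-normalised
standardised uptake values (SUV_bw, unitless); CT volumes carry Hounsfield
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

GA68_HALF_LIFE_MIN = 67.71
"""Physical half-life of gallium-68 in minutes."""

SITE_CATEGORIES = (
    "local_prostate",
    "regional_nodal",
    "distant_nodal",
    "osseous",
    "visceral",
)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class FormatError(ValueError):
    """Raised for malformed or unsupported image files."""


class ParameterError(ValueError):
    """Raised for invalid physical/configuration parameters."""


class GridMismatchError(ValueError):
    """Raised when two volumes/masks that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar field on a regular axis-aligned grid.

    Parameters
    ----------
    values
        Scalar per voxel, shape ``(nx, ny, nz)``.
    spacing
        Voxel edge lengths in mm, strictly positive.
    origin
        World coordinates (mm) of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={values.ndim}")
        if any(n <= 0 for n in values.shape):
            raise FormatError(f"non-positive shape {values.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of a single voxel in cm³ (= product of spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.spacing, self.origin)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan acquisition metadata needed for SUV conversion."""

    patient_id: str
    timepoint: str = "baseline"  # {baseline, followup}
    body_weight_kg: float = 80.0
    injected_activity_mbq: float = 160.0
    injection_to_scan_delay_min: float = 60.0
    psma_status: str = "positive"  # {positive, negative}

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ParameterError("body weight must be positive")
        if self.injected_activity_mbq <= 0:
            raise ParameterError("injected activity must be positive")
        if self.injection_to_scan_delay_min < 0:
            raise ParameterError("injection-to-scan delay must be non-negative")
        if self.timepoint not in ("baseline", "followup"):
            raise ParameterError(f"unknown timepoint {self.timepoint!r}")
        if self.psma_status not in ("positive", "negative"):
            raise ParameterError(f"unknown psma_status {self.psma_status!r}")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean voxel membership on a reference grid."""

    grid: VolumeGrid
    membership: np.ndarray

    def __post_init__(self) -> None:
        membership = np.asarray(self.membership, dtype=bool)
        if membership.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {membership.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "membership", membership)

    @property
    def voxel_count(self) -> int:
        return int(self.membership.sum())

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership & other.membership)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership | other.membership)

    def difference(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership & ~other.membership)


@dataclass(frozen=True)
class LabelledMask:
    """Integer lesion labels (0 = background) with per-label anatomical sites."""

    grid: VolumeGrid
    labels: np.ndarray
    site_by_label: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise GridMismatchError(
                f"label shape {labels.shape} != grid shape {self.grid.shape}"
            )
        if labels.min(initial=0) < 0:
            raise FormatError("labels must be non-negative")
        labels = labels.astype(np.uint32, copy=False)
        present = set(int(v) for v in np.unique(labels)) - {0}
        sites = dict(self.site_by_label)
        missing = present - set(sites)
        if sites and missing:
            raise FormatError(f"labels {sorted(missing)} missing a site category")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "site_by_label", sites)

    @property
    def label_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    @property
    def n_lesions(self) -> int:
        return len(self.label_ids)

    def foreground(self) -> BinaryMask:
        return BinaryMask(self.grid, self.labels > 0)


def _check_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if not a.same_geometry(b):
        raise GridMismatchError("operands are not defined on the same grid")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI image into a :class:`VolumeGrid`.

    Spacing is taken from the header zooms and the origin from the affine
    translation; oblique orientations are not supported (all in-repo data is
    axis-aligned by construction).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeGrid(data, tuple(float(z) for z in zooms), origin)


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a volume as float64 NIfTI.  Non-finite voxel values are refused."""
    if not np.all(np.isfinite(grid.values)):
        raise FormatError("refusing to write non-finite voxel values")
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float64), grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, grid: VolumeGrid | None = None) -> LabelledMask:
    """Read an unsigned-integer NIfTI label map (sites unset)."""
    vol = read_volume(path)
    labels = np.rint(vol.values).astype(np.uint32)
    target = grid if grid is not None else vol.with_values(labels)
    if grid is not None and not vol.same_geometry(grid):
        raise GridMismatchError(f"{path}: mask geometry does not match reference grid")
    return LabelledMask(target if grid is not None else vol, labels)


def write_mask(mask: BinaryMask | LabelledMask, path: str | Path) -> Path:
    """Write a mask as uint16 NIfTI; labels are stored verbatim, never scaled."""
    if isinstance(mask, BinaryMask):
        labels = mask.membership.astype(np.uint16)
    else:
        labels = mask.labels.astype(np.uint16)
    path = Path(path)
    img = nib.Nifti1Image(labels, mask.grid.affine)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def decay_factor(delay_min: float, half_life_min: float = GA68_HALF_LIFE_MIN) -> float:
    """Fraction of injected activity remaining after ``delay_min`` minutes."""
    if half_life_min <= 0:
        raise ParameterError("half-life must be positive")
    return float(2.0 ** (-delay_min / half_life_min))


def to_suv_bw(
    activity: VolumeGrid,
    meta: ScanMeta,
    half_life_min: float = GA68_HALF_LIFE_MIN,
) -> VolumeGrid:
    """Convert activity concentration (Bq/mL) to body-weight SUV.

    SUV_bw(v) = C(v) [Bq/mL] × body weight [g] / injected activity decay-corrected
    to scan start [Bq].  The result is unitless (1 g of tissue ≈ 1 mL).
    """
    values = np.asarray(activity.values)
    if np.any(values < 0):
        raise ParameterError("activity concentration must be non-negative")
    injected_bq = meta.injected_activity_mbq * 1e6
    decayed = injected_bq * decay_factor(meta.injection_to_scan_delay_min, half_life_min)
    weight_g = meta.body_weight_kg * 1000.0
    return activity.with_values(values * (weight_g / decayed))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(
    source: VolumeGrid,
    target: VolumeGrid,
    mode: str = "spline",
    fill_value: float | None = None,
    spline_order: int = 3,
) -> VolumeGrid:
    """Resample ``source`` onto the geometry of ``target``.

    ``mode='spline'`` uses cubic B-spline interpolation (order configurable) for
    intensity images; ``mode='nearest'`` must be used for masks so labels are
    never blended.  Voxels falling outside the source extent are filled with
    ``fill_value`` (default: the source minimum, i.e. ≈ air for CT).
    """
    if mode not in ("spline", "nearest"):
        raise ParameterError(f"unknown resampling mode {mode!r}")
    if fill_value is None:
        fill_value = float(np.min(source.values))
    # target voxel centres expressed in source index coordinates
    idx = [
        (target.origin[a] + np.arange(target.shape[a]) * target.spacing[a] - source.origin[a])
        / source.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    order = 0 if mode == "nearest" else spline_order
    out = ndimage.map_coordinates(
        np.asarray(source.values, dtype=np.float64),
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="nearest",
        prefilter=order > 1,
    ).reshape(target.shape)
    # constant fill outside the source extent (voxel-centre convention)
    eps = 1e-9
    oob = np.zeros(target.shape, dtype=bool)
    for a in range(3):
        bad = (idx[a] < -eps) | (idx[a] > source.shape[a] - 1 + eps)
        shape = [1, 1, 1]
        shape[a] = -1
        oob |= bad.reshape(shape)
    out[oob] = fill_value
    return VolumeGrid(out, target.spacing, target.origin)


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3×3×3 structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except KeyError:
        raise ParameterError(f"connectivity must be one of 6/18/26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


def connected_components(mask: BinaryMask, connectivity: int = 26) -> LabelledMask:
    """Label maximal contiguous clusters of a binary mask.

    Labels 1..K are assigned in raster-scan order of each cluster's minimum
    flat index, making the labelling deterministic.  Site categories are left
    unset.
    """
    structure = connectivity_structure(connectivity)
    raw, n = ndimage.label(mask.membership, structure=structure)
    if n == 0:
        return LabelledMask(mask.grid, np.zeros(mask.grid.shape, dtype=np.uint32))
    # relabel by first raster occurrence (scipy already scans in C order, but
    # we do not rely on that implementation detail)
    flat = raw.ravel()
    labels_present, first_idx = np.unique(flat, return_index=True)
    order = first_idx[labels_present > 0].argsort()
    remap = np.zeros(n + 1, dtype=np.uint32)
    remap[labels_present[labels_present > 0][order]] = np.arange(1, n + 1)
    return LabelledMask(mask.grid, remap[raw])
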