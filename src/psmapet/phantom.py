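"""Synthetic whole-body PET/CT phantom cohorts with known ground truth.

The generator emulates the geometry of a whole-body gallium-68 PSMA PET scan:
a 96 × 96 × 256 grid at 4.07 × 4.07 × 2 mm voxels, low lognormal background
uptake, a handful of physiologic hot organs (bladder, kidneys, salivary
glands), and tracer-avid metastatic lesions with heterogeneous size, peak
uptake and anatomical site.  Each lesion is a cosine-tapered sphere; its
ground-truth mask is the set of voxels whose lesion uptake reaches the SUV
floor (3.0 by default), mirroring how avid disease is delineated on real
scans with a global SUV threshold.

Everything is bookkept: the returned scan carries per-lesion voxel counts,
sites and peak SUVs so downstream metrics can be checked exactly.  Paired
"predicted" masks with controlled error modes (lesion drops, boundary
erosion/dilation, partial overlap, false-positive clusters) and
proportional-hazards survival times tied to lesion burden complete the
test-bed.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging import (
    BinaryMask,
    LabelledMask,
    ParameterError,
    ScanMeta,
    SITE_CATEGORIES,
    VolumeGrid,
)


class GenerationError(RuntimeError):
    """Raised when lesion/false-positive placement fails after bounded retries."""


# Site mix of the metastatic-lesion population (fractions of all lesions):
# local prostate, regional nodal, distant nodal, osseous, visceral.
DEFAULT_SITE_PROBS: dict[str, float] = {
    "local_prostate": 141 / 880,
    "regional_nodal": 191 / 880,
    "distant_nodal": 356 / 880,
    "osseous": 167 / 880,
    "visceral": 25 / 880,
}

# axial bands (fractions of the z extent) used to place each lesion site;
# purely geometric stand-ins so per-site tables are meaningful
_SITE_Z_BANDS: dict[str, tuple[float, float]] = {
    "local_prostate": (0.04, 0.14),
    "regional_nodal": (0.14, 0.30),
    "distant_nodal": (0.30, 0.62),
    "osseous": (0.20, 0.88),
    "visceral": (0.62, 0.80),
}

HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_BONE = 700.0


@dataclass(frozen=True)
class Organ:
    """An ellipsoidal physiologic uptake region (centre/radii as fractions/mm)."""

    name: str
    center_frac: tuple[float, float, float]  # fractions of the grid extent
    radii_mm: tuple[float, float, float]
    suv: float


def default_organs() -> tuple[Organ, ...]:
    return (
        Organ("bladder", (0.50, 0.42, 0.08), (28.0, 28.0, 30.0), 22.0),
        Organ("kidney_left", (0.34, 0.55, 0.44), (22.0, 18.0, 40.0), 12.0),
        Organ("kidney_right", (0.66, 0.55, 0.44), (22.0, 18.0, 40.0), 12.0),
        Organ("salivary", (0.50, 0.45, 0.955), (30.0, 22.0, 16.0), 9.0),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the whole-body acquisition the package targets: full-
    resolution 96 × 96 × 256 grid at 4.07 × 4.07 × 2 mm, a mean of 880/209
    ≈ 4.21 lesions per PSMA-positive scan, the observed five-way site mix,
    and 53/128 ≈ 41.4 % PSMA-negative scans.
    """

    shape: tuple[int, int, int] = (96, 96, 256)
    spacing: tuple[float, float, float] = (4.07, 4.07, 2.0)
    background_median_suv: float = 0.5
    background_sigma: float = 0.3
    noise_sd: float = 0.1
    organs: tuple[Organ, ...] = field(default_factory=default_organs)
    lesions_per_positive_scan_mean: float = 880 / 209
    lesion_radius_mm: tuple[float, float] = (4.0, 20.0)
    lesion_peak_suv: tuple[float, float] = (3.5, 25.0)
    lesion_suv_floor: float = 3.0
    site_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_PROBS))
    negative_fraction: float = 53 / 128
    body_radii_frac: tuple[float, float] = (0.46, 0.38)
    spine_center_frac: tuple[float, float] = (0.50, 0.62)
    spine_radius_mm: float = 24.0
    max_placement_tries: int = 400

    def __post_init__(self) -> None:
        probs = np.array([self.site_probs[s] for s in SITE_CATEGORIES])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError("site probabilities must sum to 1")
        if not (0 < self.lesion_radius_mm[0] <= self.lesion_radius_mm[1]):
            raise ParameterError("lesion radius range must be positive and ordered")
        if not (0 < self.lesion_peak_suv[0] <= self.lesion_peak_suv[1]):
            raise ParameterError("lesion peak SUV range must be positive and ordered")
        if not 0 <= self.negative_fraction <= 1:
            raise ParameterError("negative fraction must lie in [0, 1]")


@dataclass(frozen=True)
class LesionInfo:
    """Generator bookkeeping for one ground-truth lesion."""

    label: int
    site: str
    center_index: tuple[int, int, int]
    radius_mm: float
    peak_suv: float
    voxel_count: int
    suv_sum: float


@dataclass(frozen=True)
class PhantomScan:
    """One generated scan: volumes, masks, metadata and lesion bookkeeping."""

    pet: VolumeGrid  # SUV_bw
    ct: VolumeGrid  # HU
    ground_truth: LabelledMask
    physiologic: BinaryMask
    meta: ScanMeta
    lesions: tuple[LesionInfo, ...]


@dataclass(frozen=True)
class CorruptionConfig:
    """Controlled error modes applied to a ground-truth mask.

    ``morph_radius``: >0 dilates the retained lesions by that many voxel
    shells, <0 erodes.  ``overlap_fraction``: if set, each retained lesion is
    shrunk to a contiguous interior region of ⌈f·V⌉ voxels (probes the
    volumetric detection rule).  ``fp_rate``: Poisson mean number of injected
    false-positive clusters per scan, placed disjoint from (and non-adjacent
    to) ground truth.
    """

    drop_probability: float = 0.0
    morph_radius: int = 0
    overlap_fraction: float | None = None
    fp_rate: float = 0.0
    fp_radius_voxels: tuple[int, int] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ParameterError("drop probability must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ParameterError("false-positive rate must be non-negative")
        if self.overlap_fraction is not None and not 0.0 < self.overlap_fraction <= 1.0:
            raise ParameterError("overlap fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Exponential proportional-hazards survival tied to lesion burden.

    Event times are exponential with rate ``baseline_hazard ×
    exp(beta_log_tlv · log1p(TLV))``; observation stops at an independent
    exponential censoring time (if ``censoring_rate`` > 0) or the
    administrative horizon, whichever comes first.
    """

    baseline_hazard_per_month: float = 0.01
    beta_log_tlv: float = 0.0
    horizon_months: float = 80.0
    censoring_rate_per_month: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard_per_month < 0 or self.censoring_rate_per_month < 0:
            raise ParameterError("hazard rates must be non-negative")
        if self.horizon_months <= 0:
            raise ParameterError("censoring horizon must be positive")


# ---------------------------------------------------------------------------
# scan generation
# ---------------------------------------------------------------------------

def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_index: tuple[float, float, float],
    radii_mm: tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = sum(
        ((g - c) * s / r) ** 2
        for g, c, s, r in zip(grids, center_index, spacing, radii_mm)
    )
    return r2 <= 1.0


def _body_mask(cfg: PhantomConfig) -> np.ndarray:
    nx, ny, nz = cfg.shape
    gx, gy = np.ogrid[:nx, :ny]
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    rx, ry = cfg.body_radii_frac[0] * nx, cfg.body_radii_frac[1] * ny
    ellipse = ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 <= 1.0
    return np.broadcast_to(ellipse[:, :, None], cfg.shape).copy()


def _spine_mask(cfg: PhantomConfig) -> np.ndarray:
    nx, ny, nz = cfg.shape
    gx, gy = np.ogrid[:nx, :ny]
    cx = cfg.spine_center_frac[0] * (nx - 1)
    cy = cfg.spine_center_frac[1] * (ny - 1)
    r2 = ((gx - cx) * cfg.spacing[0]) ** 2 + ((gy - cy) * cfg.spacing[1]) ** 2
    column = r2 <= cfg.spine_radius_mm**2
    zband = np.zeros(nz, dtype=bool)
    z0, z1 = int(0.10 * nz), int(0.95 * nz)
    zband[z0:z1] = True
    return column[:, :, None] & zband[None, None, :]


def _lesion_profile(
    cfg: PhantomConfig,
    center: tuple[int, int, int],
    radius_mm: float,
    peak: float,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Cosine-tapered spherical uptake profile on a local bounding box.

    Profile value is ``peak·(1+cos(π r/R))/2`` for r ≤ R (peak at the centre,
    0 at the boundary); returned as (bounding slices, dense array).
    """
    half = [int(math.ceil(radius_mm / s)) for s in cfg.spacing]
    sl = tuple(
        slice(max(0, c - h), min(n, c + h + 1))
        for c, h, n in zip(center, half, cfg.shape)
    )
    grids = np.ogrid[sl]
    r = np.sqrt(
        sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, cfg.spacing))
    )
    profile = np.where(r <= radius_mm, peak * 0.5 * (1.0 + np.cos(np.pi * r / radius_mm)), 0.0)
    return sl, profile


def _sample_lesion_count(rng: np.random.Generator, mean: float) -> int:
    """Poisson truncated to ≥ 1 by rejection."""
    for _ in range(10_000):
        n = int(rng.poisson(mean))
        if n >= 1:
            return n
    raise GenerationError("failed to sample a positive lesion count")


def generate_scan(
    config: PhantomConfig,
    positive: bool,
    seed: int,
    patient_id: str | None = None,
    timepoint: str = "baseline",
    n_lesions: int | None = None,
) -> PhantomScan:
    """Generate one phantom PET/CT scan with ground truth.

    Positive scans contain ≥ 1 lesion whose peak SUV exceeds the SUV floor;
    negative scans contain zero lesion voxels but retain the physiologic hot
    organs.  Identical ``(config, seed)`` gives bit-identical output.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = config.shape, config.spacing
    grid = VolumeGrid(np.zeros(shape), spacing)

    body = _body_mask(config)
    spine = _spine_mask(config)

    # CT: air / soft tissue / bone bands
    ct = np.full(shape, HU_AIR, dtype=np.float64)
    ct[body] = HU_SOFT_TISSUE
    ct[spine & body] = HU_BONE

    # PET background: lognormal inside the body, ~0 outside
    pet = np.zeros(shape, dtype=np.float64)
    nbody = int(body.sum())
    pet[body] = rng.lognormal(
        mean=math.log(config.background_median_suv),
        sigma=config.background_sigma,
        size=nbody,
    )

    # physiologic organs
    physio = np.zeros(shape, dtype=bool)
    for organ in config.organs:
        center = tuple((np.array(shape) - 1) * organ.center_frac)
        om = _ellipsoid_mask(shape, spacing, center, organ.radii_mm) & body
        physio |= om
        pet[om] = organ.suv

    labels = np.zeros(shape, dtype=np.uint32)
    site_by_label: dict[int, str] = {}
    lesions: list[LesionInfo] = []

    if positive:
        count = n_lesions if n_lesions is not None else _sample_lesion_count(
            rng, config.lesions_per_positive_scan_mean
        )
        site_names = list(SITE_CATEGORIES)
        site_p = np.array([config.site_probs[s] for s in site_names])
        # forbid lesion cores adjacent to physiologic regions or earlier lesions
        blocked = ndimage.binary_dilation(physio, iterations=1)
        for k in range(1, count + 1):
            site = site_names[int(rng.choice(len(site_names), p=site_p))]
            placed = False
            for _ in range(config.max_placement_tries):
                radius = float(rng.uniform(*config.lesion_radius_mm))
                peak = float(rng.uniform(*config.lesion_peak_suv))
                zlo, zhi = _SITE_Z_BANDS[site]
                cz = int(rng.integers(int(zlo * shape[2]), max(int(zhi * shape[2]), int(zlo * shape[2]) + 1)))
                if site == "osseous":
                    cand = np.argwhere(spine[:, :, cz])
                else:
                    cand = np.argwhere(body[:, :, cz] & ~spine[:, :, cz])
                if len(cand) == 0:
                    continue
                cx, cy = cand[int(rng.integers(len(cand)))]
                center = (int(cx), int(cy), cz)
                sl, profile = _lesion_profile(config, center, radius, peak)
                core = profile >= config.lesion_suv_floor
                if not core.any():
                    continue
                region_ok = body[sl] if site != "osseous" else np.ones_like(core)
                if np.any(core & ~region_ok):
                    continue
                if np.any(core & blocked[sl]) or np.any(core & (labels[sl] > 0)):
                    continue
                pet[sl] += profile
                labels[sl][core] = k
                site_by_label[k] = site
                blocked[sl] |= ndimage.binary_dilation(core, iterations=1)
                lesions.append(
                    LesionInfo(
                        label=k,
                        site=site,
                        center_index=center,
                        radius_mm=radius,
                        peak_suv=peak,
                        voxel_count=int(core.sum()),
                        suv_sum=0.0,  # filled after noise below
                    )
                )
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place lesion {k} (site={site}) after "
                    f"{config.max_placement_tries} tries; config too crowded"
                )

    if config.noise_sd > 0:
        pet += rng.normal(0.0, config.noise_sd, size=shape)
    np.clip(pet, 0.0, None, out=pet)

    lesions = [
        replace(info, suv_sum=float(pet[labels == info.label].sum())) for info in lesions
    ]

    weight = float(rng.uniform(60.0, 100.0))
    meta = ScanMeta(
        patient_id=patient_id or f"phantom-{seed}",
        timepoint=timepoint,
        body_weight_kg=weight,
        injected_activity_mbq=2.0 * weight,  # 2 MBq/kg administration
        injection_to_scan_delay_min=60.0,
        psma_status="positive" if positive else "negative",
    )
    pet_grid = grid.with_values(pet)
    return PhantomScan(
        pet=pet_grid,
        ct=grid.with_values(ct),
        ground_truth=LabelledMask(pet_grid, labels, site_by_label),
        physiologic=BinaryMask(pet_grid, physio),
        meta=meta,
        lesions=tuple(lesions),
    )


# ---------------------------------------------------------------------------
# prediction corruption
# ---------------------------------------------------------------------------

def _contiguous_subset(core: np.ndarray, n_keep: int) -> np.ndarray:
    """Grow a 6-connected region of ``n_keep`` voxels from the core's centroid."""
    coords = np.argwhere(core)
    centroid = coords.mean(axis=0)
    start = tuple(coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))])
    keep = np.zeros_like(core)
    seen = {start}
    queue = deque([start])
    kept = 0
    shape = core.shape
    while queue and kept < n_keep:
        v = queue.popleft()
        keep[v] = True
        kept += 1
        for axis in range(3):
            for step in (-1, 1):
                w = list(v)
                w[axis] += step
                w = tuple(w)
                if 0 <= w[axis] < shape[axis] and w not in seen and core[w]:
                    seen.add(w)
                    queue.append(w)
    if kept < n_keep:  # disconnected residue: fall back to arbitrary fill
        extra = [tuple(c) for c in coords if not keep[tuple(c)]]
        for w in extra[: n_keep - kept]:
            keep[w] = True
    return keep


def corrupt_prediction(gt: LabelledMask, cfg: CorruptionConfig) -> BinaryMask:
    """Derive a "predicted" binary mask from ground truth with controlled errors.

    Retained lesions are optionally eroded/dilated or shrunk to a contiguous
    interior fraction; dropped lesions contribute nothing; false-positive
    clusters are injected disjoint from (and non-adjacent to) the ground-truth
    foreground.  Fully deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = gt.labels
    pred = np.zeros(labels.shape, dtype=bool)
    struct6 = ndimage.generate_binary_structure(3, 1)

    for label in gt.label_ids:
        if rng.random() < cfg.drop_probability:
            continue
        lesion = labels == label
        if cfg.overlap_fraction is not None:
            n_keep = int(math.ceil(cfg.overlap_fraction * lesion.sum()))
            pred |= _contiguous_subset(lesion, n_keep)
        elif cfg.morph_radius > 0:
            pred |= ndimage.binary_dilation(lesion, struct6, iterations=cfg.morph_radius)
        elif cfg.morph_radius < 0:
            pred |= ndimage.binary_erosion(lesion, struct6, iterations=-cfg.morph_radius)
        else:
            pred |= lesion

    if cfg.fp_rate > 0:
        gt_fg = labels > 0
        n_fp = int(rng.poisson(cfg.fp_rate))
        shape = labels.shape
        for _ in range(n_fp):
            placed = False
            for _ in range(500):
                center = tuple(int(rng.integers(2, s - 2)) for s in shape)
                radius = int(rng.integers(cfg.fp_radius_voxels[0], cfg.fp_radius_voxels[1] + 1))
                sl = tuple(slice(c - radius, c + radius + 1) for c in center)
                grids = np.ogrid[tuple(slice(0, 2 * radius + 1) for _ in range(3))]
                sphere = sum((g - radius) ** 2 for g in grids) <= radius**2
                patch = np.zeros(shape, dtype=bool)
                patch[sl] = sphere
                grown = ndimage.binary_dilation(patch, struct6, iterations=1)
                if not np.any(grown & (gt_fg | pred)):
                    pred |= patch
                    placed = True
                    break
            if not placed:
                raise GenerationError("could not place a false-positive cluster")

    return BinaryMask(gt.grid, pred)


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------

def simulate_survival(
    tlv_values: Sequence[float],
    cfg: SurvivalSimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (time, event) pairs from baseline lesion burden.

    Event hazard is ``baseline × exp(β · log1p(TLV))``; independent exponential
    censoring (optional) and an administrative horizon truncate follow-up.
    Returns months of follow-up and boolean event indicators.
    """
    tlv = np.asarray(tlv_values, dtype=np.float64)
    if np.any(tlv < 0):
        raise ParameterError("TLV must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.baseline_hazard_per_month * np.exp(cfg.beta_log_tlv * np.log1p(tlv))
    with np.errstate(divide="ignore"):
        t_event = np.where(rate > 0, rng.exponential(1.0, size=tlv.size) / np.maximum(rate, 1e-300), np.inf)
    if cfg.censoring_rate_per_month > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate_per_month, size=tlv.size)
    else:
        t_cens = np.full(tlv.size, np.inf)
    t_cens = np.minimum(t_cens, cfg.horizon_months)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    # follow-up must be strictly positive for the survival machinery
    time = np.maximum(time, 1e-9)
    return time, event
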