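"""Three-level assessment of predicted lesion masks against ground truth.

* Patient level — was the scan's PSMA-positivity called correctly?  A positive
  scan is a true positive when at least one ground-truth lesion is detected;
  a negative scan is a true negative only when the prediction contains not a
  single positive voxel.
* Lesion level — a ground-truth lesion is *detected* when the predicted mask
  covers at least a fraction τ (default 10 %) of its volume.  Predicted
  clusters with no ground-truth overlap at all are false positives; clusters
  that touch ground truth without triggering a detection are neither.
* Voxel level — Dice similarity coefficient, sensitivity, PPV, specificity.

All percentages are kept at full precision internally; display rounding is
half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import (
    BinaryMask,
    GridMismatchError,
    LabelledMask,
    ParameterError,
    _check_same_grid,
    connected_components,
)
from . import survival as _survival

DEFAULT_TAU = 0.10


def round_display(value: float, ndigits: int = 1) -> float:
    """Half-up rounding for display (e.g. 94.55 → 94.6), matching print tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Percentages in [0, 100]; ``None`` marks an undefined metric."""

    accuracy: float | None = None
    sensitivity: float | None = None
    ppv: float | None = None
    specificity: float | None = None
    npv: float | None = None
    f1: float | None = None
    dsc: float | None = None

    def as_dict(self, display: bool = False) -> dict[str, float | None]:
        out = {}
        for name in ("accuracy", "sensitivity", "ppv", "specificity", "npv", "f1", "dsc"):
            v = getattr(self, name)
            out[name] = None if v is None else (round_display(v) if display else v)
        return out


@dataclass(frozen=True)
class LesionMatch:
    gt_label: int
    site: str | None
    volume_voxels: int
    overlap_voxels: int
    overlap_fraction: float
    detected: bool


@dataclass(frozen=True)
class DetectionReport:
    """Per-scan lesion matching: matches, FP clusters, derived detection metrics."""

    matches: tuple[LesionMatch, ...]
    fp_cluster_count: int
    tau: float

    @property
    def n_lesions(self) -> int:
        return len(self.matches)

    @property
    def n_detected(self) -> int:
        return sum(m.detected for m in self.matches)

    @property
    def sensitivity_pct(self) -> float | None:
        if not self.matches:
            return None
        return 100.0 * self.n_detected / self.n_lesions

    @property
    def ppv_pct(self) -> float | None:
        denom = self.n_detected + self.fp_cluster_count
        if denom == 0:
            return None
        return 100.0 * self.n_detected / denom


@dataclass(frozen=True)
class ScanClassification:
    gt_status: str  # {positive, negative}
    call: str  # {tp, fp, tn, fn}

    def as_counts(self) -> ConfusionCounts:
        return ConfusionCounts(**{self.call: 1})


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def match_lesions(
    gt: LabelledMask,
    pred: BinaryMask,
    tau: float = DEFAULT_TAU,
    connectivity: int = 26,
) -> DetectionReport:
    """Match ground-truth lesions against a predicted mask.

    The overlap fraction of each lesion is |pred ∩ lesion| / |lesion| against
    the *whole* predicted mask (one predicted cluster may detect several
    lesions); detection is inclusive at τ.  False-positive clusters are
    connected components of the prediction whose intersection with the
    ground-truth foreground is empty.
    """
    if not 0.0 < tau <= 1.0:
        raise ParameterError(f"tau must lie in (0, 1], got {tau}")
    _check_same_grid(gt.grid, pred.grid)
    labels = gt.labels
    predm = pred.membership

    matches = []
    for label in gt.label_ids:
        lesion = labels == label
        vol = int(lesion.sum())
        inter = int((lesion & predm).sum())
        frac = inter / vol
        matches.append(
            LesionMatch(
                gt_label=label,
                site=gt.site_by_label.get(label),
                volume_voxels=vol,
                overlap_voxels=inter,
                overlap_fraction=frac,
                detected=frac >= tau,
            )
        )

    fp_clusters = 0
    if predm.any():
        comp = connected_components(BinaryMask(pred.grid, predm), connectivity)
        gt_fg = labels > 0
        for cid in comp.label_ids:
            if not np.any((comp.labels == cid) & gt_fg):
                fp_clusters += 1

    return DetectionReport(tuple(matches), fp_clusters, tau)


def classify_scan(
    gt: LabelledMask,
    pred: BinaryMask,
    tau: float = DEFAULT_TAU,
    connectivity: int = 26,
) -> ScanClassification:
    """Patient-level call from the scan-classification criteria.

    Positive ground truth: true positive iff ≥ 1 lesion detected at τ, else a
    false negative.  Negative ground truth: true negative iff the prediction
    contains zero positive voxels, else a false positive.
    """
    _check_same_grid(gt.grid, pred.grid)
    if gt.n_lesions > 0:
        report = match_lesions(gt, pred, tau, connectivity)
        call = "tp" if report.n_detected >= 1 else "fn"
        return ScanClassification("positive", call)
    call = "tn" if not pred.membership.any() else "fp"
    return ScanClassification("negative", call)


def voxel_metrics(gt_fg: BinaryMask, pred: BinaryMask) -> MetricSet:
    """Voxel-level DSC, sensitivity, PPV and specificity (percentages).

    Undefined on empty ground truth (negative scans must be excluded by the
    caller); an empty prediction yields PPV 0 by convention.
    """
    _check_same_grid(gt_fg.grid, pred.grid)
    a = gt_fg.membership
    b = pred.membership
    na, nb = int(a.sum()), int(b.sum())
    if na == 0:
        raise ParameterError("voxel metrics undefined for empty ground truth")
    inter = int((a & b).sum())
    total = a.size
    tn = total - na - nb + inter
    return MetricSet(
        dsc=100.0 * 2 * inter / (na + nb),
        sensitivity=100.0 * inter / na,
        ppv=100.0 * inter / nb if nb > 0 else 0.0,
        specificity=100.0 * tn / (total - na),
    )


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Standard ratios from a 2×2 confusion table, as percentages.

    A metric whose denominator is zero is reported as undefined (``None``).
    """
    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    acc = ratio(c.tp + c.tn, c.total)
    sens = ratio(c.tp, c.tp + c.fn)
    ppv = ratio(c.tp, c.tp + c.fp)
    spec = ratio(c.tn, c.tn + c.fp)
    npv = ratio(c.tn, c.tn + c.fn)
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = f1_score(ppv, sens)
    return MetricSet(accuracy=acc, sensitivity=sens, ppv=ppv, specificity=spec, npv=npv, f1=f1)


def f1_score(ppv_pct: float, sensitivity_pct: float) -> float:
    """Harmonic mean of PPV and sensitivity (both as percentages)."""
    if not (0 <= ppv_pct <= 100 and 0 <= sensitivity_pct <= 100):
        raise ParameterError("PPV and sensitivity must lie in [0, 100]")
    if ppv_pct + sensitivity_pct == 0:
        raise ParameterError("F1 undefined when PPV and sensitivity are both zero")
    return 2.0 * ppv_pct * sensitivity_pct / (ppv_pct + sensitivity_pct)


def threshold_sweep(
    gt: LabelledMask,
    pred: BinaryMask,
    tau_grid: Sequence[float],
    connectivity: int = 26,
) -> pd.DataFrame:
    """Recompute patient- and lesion-level metrics across detection thresholds.

    Overlap fractions and FP clusters are computed once; only the detection
    rule varies with τ.  Returns a tidy frame with one row per (τ, level,
    metric).
    """
    taus = list(tau_grid)
    if not taus:
        raise ParameterError("tau grid must be non-empty")
    base = match_lesions(gt, pred, tau=min(min(taus), DEFAULT_TAU), connectivity=connectivity)
    rows = []
    for tau in taus:
        if not 0.0 < tau <= 1.0:
            raise ParameterError(f"tau must lie in (0, 1], got {tau}")
        detected = sum(m.overlap_fraction >= tau for m in base.matches)
        n = len(base.matches)
        sens = 100.0 * detected / n if n else None
        denom = detected + base.fp_cluster_count
        ppv = 100.0 * detected / denom if denom else None
        if gt.n_lesions > 0:
            patient_call = "tp" if detected >= 1 else "fn"
        else:
            patient_call = "tn" if not pred.membership.any() else "fp"
        rows.append({"tau": tau, "level": "lesion", "metric": "sensitivity", "value": sens})
        rows.append({"tau": tau, "level": "lesion", "metric": "ppv", "value": ppv})
        rows.append({"tau": tau, "level": "lesion", "metric": "fp_clusters", "value": base.fp_cluster_count})
        rows.append({"tau": tau, "level": "patient", "metric": "call", "value": patient_call})
    return pd.DataFrame(rows)


def subgroup_sensitivity(reports: Iterable[DetectionReport]) -> pd.DataFrame:
    """Per-site detection sensitivity pooled over scans.

    Sites absent from the cohort are omitted rather than reported as 0/0; an
    ``overall`` row aggregates everything.
    """
    detected: dict[str, int] = {}
    total: dict[str, int] = {}
    for report in reports:
        for m in report.matches:
            site = m.site or "unspecified"
            total[site] = total.get(site, 0) + 1
            detected[site] = detected.get(site, 0) + int(m.detected)
    rows = []
    for site in sorted(total):
        rows.append(
            {
                "site": site,
                "detected": detected[site],
                "total": total[site],
                "sensitivity_pct": 100.0 * detected[site] / total[site],
            }
        )
    if total:
        d, t = sum(detected.values()), sum(total.values())
        rows.append({"site": "overall", "detected": d, "total": t, "sensitivity_pct": 100.0 * d / t})
    return pd.DataFrame(rows, columns=["site", "detected", "total", "sensitivity_pct"])


def paired_observer_comparison(
    metrics_a: Mapping[str, Mapping[str, float]],
    metrics_b: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Compare two per-scan metric tables paired by scan id.

    ``metrics_a``/``metrics_b`` map scan id → {metric name → value}.  Reports
    per-metric medians for both sides and a two-sided Wilcoxon signed-rank
    p-value; pairs with all-zero differences are flagged degenerate (p = 1).
    """
    ids_a, ids_b = set(metrics_a), set(metrics_b)
    if ids_a != ids_b:
        raise ParameterError(f"unpaired scan ids: {sorted(ids_a ^ ids_b)}")
    ids = sorted(ids_a)
    if len(ids) < 5:
        raise ParameterError("need at least 5 paired scans")
    metric_names = sorted({k for sid in ids for k in metrics_a[sid]})
    rows = []
    for name in metric_names:
        a = np.array([metrics_a[sid][name] for sid in ids], dtype=float)
        b = np.array([metrics_b[sid][name] for sid in ids], dtype=float)
        diffs = a - b
        if np.all(diffs == 0):
            p, degenerate = 1.0, True
        elif np.count_nonzero(diffs) < 5:
            p, degenerate = float("nan"), True
        else:
            _, p = _survival.wilcoxon_signed_rank(diffs)
            degenerate = False
        rows.append(
            {
                "metric": name,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
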