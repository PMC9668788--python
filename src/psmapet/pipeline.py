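"""End-to-end cohort runs: simulate → predict → evaluate → biomarkers → survival.

A single master seed fans out deterministically to every stage via
``numpy.random.SeedSequence``; identical configs give byte-identical outputs.
The default run mirrors a held-out evaluation cohort: 128 scans of which
53 are PSMA-negative controls, predictions derived from ground truth with a
27 % per-lesion miss rate and 30/128 injected false-positive clusters per
scan on average, detection threshold τ = 0.10.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import BiomarkerRecord, biomarker_record, compare_biomarkers
from .evaluation import (
    ConfusionCounts,
    DetectionReport,
    classify_scan,
    confusion_metrics,
    match_lesions,
    round_display,
    subgroup_sensitivity,
    voxel_metrics,
)
from .phantom import (
    CorruptionConfig,
    PhantomConfig,
    SurvivalSimConfig,
    corrupt_prediction,
    generate_scan,
    simulate_survival,
)
from .survival import SurvivalRecord, StratifiedComparison, records_to_frame, stratify
from .thresholding import ThresholdConfig, exclude_physiologic, global_threshold_segment


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration for one reproducible pipeline run."""

    n_scans: int = 128
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    corruption: CorruptionConfig = field(
        default_factory=lambda: CorruptionConfig(drop_probability=0.27, fp_rate=30 / 128)
    )
    survival: SurvivalSimConfig = field(
        default_factory=lambda: SurvivalSimConfig(
            baseline_hazard_per_month=0.005, beta_log_tlv=1.0, horizon_months=80.0
        )
    )
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    predictor: str = "corruption"  # {corruption, threshold}
    tau: float = 0.10
    connectivity: int = 26
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CohortResult:
    """In-memory result of a cohort run; ``write`` materialises it as files."""

    config: RunConfig
    scans: pd.DataFrame
    patient_counts: ConfusionCounts
    detection_reports: list[DetectionReport]
    subgroup: pd.DataFrame
    biomarker_comparison: pd.DataFrame
    stratifications: dict[str, StratifiedComparison]
    sweep: pd.DataFrame
    auto_biomarkers: list[BiomarkerRecord] = field(default_factory=list)
    manual_biomarkers: list[BiomarkerRecord] = field(default_factory=list)

    # -- aggregate metrics ------------------------------------------------
    @property
    def lesion_totals(self) -> tuple[int, int, int]:
        """(detected, total ground-truth lesions, fp clusters) over the cohort."""
        detected = sum(r.n_detected for r in self.detection_reports)
        total = sum(r.n_lesions for r in self.detection_reports)
        fp = sum(r.fp_cluster_count for r in self.detection_reports)
        return detected, total, fp

    def summary(self) -> dict[str, Any]:
        detected, total, fp = self.lesion_totals
        patient = confusion_metrics(self.patient_counts)
        lesion = confusion_metrics(
            ConfusionCounts(tp=detected, fp=fp, fn=total - detected)
        )
        pos = self.scans[self.scans["gt_status"] == "positive"]
        neg = self.scans[self.scans["gt_status"] == "negative"]
        n_scans = len(self.scans)
        voxel = pos[["dsc", "voxel_sensitivity", "voxel_ppv"]].dropna()
        out: dict[str, Any] = {
            "n_scans": n_scans,
            "n_positive": int(len(pos)),
            "n_negative": int(len(neg)),
            "patient_level": {
                "counts": dataclasses.asdict(self.patient_counts),
                "metrics_pct": patient.as_dict(),
            },
            "lesion_level": {
                "detected": detected,
                "total": total,
                "fp_clusters": fp,
                "sensitivity_pct": lesion.sensitivity,
                "ppv_pct": lesion.ppv,
                "f1_pct": lesion.f1,
                "fp_per_scan": fp / n_scans if n_scans else None,
                "scans_per_fp": n_scans / fp if fp else None,
            },
            "voxel_level": {
                "dsc_mean": float(voxel["dsc"].mean()) if len(voxel) else None,
                "dsc_sd": float(voxel["dsc"].std(ddof=1)) if len(voxel) > 1 else None,
                "sensitivity_mean": float(voxel["voxel_sensitivity"].mean()) if len(voxel) else None,
                "ppv_mean": float(voxel["voxel_ppv"].mean()) if len(voxel) else None,
                "dsc_median": float(voxel["dsc"].median()) if len(voxel) else None,
            },
            "biomarkers": self.biomarker_comparison.to_dict(orient="records"),
            "survival": {
                name: {
                    "group_sizes": comp.group_sizes,
                    "statistic": comp.statistic,
                    "p_value": comp.p_value,
                    "p_display": comp.p_display,
                }
                for name, comp in self.stratifications.items()
            },
        }
        return out

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "package_version": __version__,
            "config_hash": self.config.content_hash(),
            "seed": self.config.seed,
            "config": self.config.to_dict(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        self.scans.to_csv(outdir / "scans.csv", index=False)
        self.subgroup.to_csv(outdir / "subgroup_sensitivity.csv", index=False)
        self.biomarker_comparison.to_csv(outdir / "biomarker_comparison.csv", index=False)
        self.sweep.to_csv(outdir / "threshold_sweep.csv", index=False)
        (outdir / "cohort_metrics.json").write_text(
            json.dumps(self.summary(), indent=2, default=str)
        )
        km_rows = []
        for name, comp in self.stratifications.items():
            for group, curve in comp.curves.items():
                for t, s in zip(curve.times, curve.survival):
                    km_rows.append(
                        {"comparison": name, "group": group, "time": t, "survival": s}
                    )
        pd.DataFrame(km_rows).to_csv(outdir / "km_curves.csv", index=False)
        return outdir


def _scan_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(3 * n + 8)][: 3 * n + 8]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> CohortResult:
    """Run the full synthetic-cohort pipeline; optionally write the run directory."""
    n = config.n_scans
    if n < 2:
        raise ValueError("need at least 2 scans")
    n_negative = int(round(config.phantom.negative_fraction * n))
    seeds = _scan_seeds(config.seed, n)

    rows = []
    patient_counts = ConfusionCounts()
    reports: list[DetectionReport] = []
    auto_bio: list[BiomarkerRecord] = []
    manual_bio: list[BiomarkerRecord] = []
    sweep_store = []  # per-scan (gt_positive, pred_nonempty, overlap fractions, fp count)

    for i in range(n):
        positive = i >= n_negative
        scan_id = f"P{i:04d}"
        scan = generate_scan(
            config.phantom, positive=positive, seed=seeds[i], patient_id=scan_id
        )
        gt = scan.ground_truth
        if config.predictor == "threshold":
            pred = exclude_physiologic(
                global_threshold_segment(scan.pet, config.threshold), scan.physiologic
            )
        else:
            pred = corrupt_prediction(
                gt,
                dataclasses.replace(config.corruption, seed=seeds[n + i]),
            )

        cls = classify_scan(gt, pred, config.tau, config.connectivity)
        patient_counts = patient_counts + cls.as_counts()
        report = match_lesions(gt, pred, config.tau, config.connectivity)
        reports.append(report)
        sweep_store.append(
            (
                positive,
                bool(pred.membership.any()),
                [m.overlap_fraction for m in report.matches],
                report.fp_cluster_count,
            )
        )

        if positive:
            vox = voxel_metrics(gt.foreground(), pred)
            dsc, vsens, vppv = vox.dsc, vox.sensitivity, vox.ppv
        else:
            dsc = vsens = vppv = None

        rec_auto = biomarker_record(scan_id, pred, scan.pet, source="auto")
        rec_manual = biomarker_record(scan_id, gt.foreground(), scan.pet, source="manual")
        auto_bio.append(rec_auto)
        manual_bio.append(rec_manual)

        rows.append(
            {
                "scan_id": scan_id,
                "gt_status": cls.gt_status,
                "call": cls.call,
                "n_lesions": report.n_lesions,
                "n_detected": report.n_detected,
                "fp_clusters": report.fp_cluster_count,
                "dsc": dsc,
                "voxel_sensitivity": vsens,
                "voxel_ppv": vppv,
                "tlv_auto_cm3": rec_auto.tlv_cm3,
                "tlu_auto": rec_auto.tlu,
                "tlv_manual_cm3": rec_manual.tlv_cm3,
                "tlu_manual": rec_manual.tlu,
                "psma_status": scan.meta.psma_status,
            }
        )

    scans = pd.DataFrame(rows)

    # survival: event process driven by the true (ground-truth) burden
    times, events = simulate_survival(
        scans["tlv_manual_cm3"].to_numpy(),
        dataclasses.replace(config.survival, seed=seeds[2 * n]),
    )
    scans["time_months"] = times
    scans["event"] = events

    survival_records = [
        SurvivalRecord(
            patient_id=r.scan_id,
            time_months=r.time_months,
            event=bool(r.event),
            tlv_cm3=r.tlv_auto_cm3,
            tlu=r.tlu_auto,
            psma_status=r.psma_status,
        )
        for r in scans.itertuples()
    ]
    frame = records_to_frame(survival_records)
    stratifications: dict[str, StratifiedComparison] = {}
    for biom in ("tlu", "tlv"):
        try:
            stratifications[f"{biom}_median_all"] = stratify(
                frame, biomarker=biom, rule="median_split", subset="all"
            )
            stratifications[f"{biom}_q1q4_psma_positive"] = stratify(
                frame, biomarker=biom, rule="q1_vs_q4", subset="psma_positive"
            )
        except ValueError:
            continue  # small/degenerate cohorts: skip that comparison

    result = CohortResult(
        config=config,
        scans=scans,
        patient_counts=patient_counts,
        detection_reports=reports,
        subgroup=subgroup_sensitivity(reports),
        biomarker_comparison=compare_biomarkers(auto_bio, manual_bio),
        stratifications=stratifications,
        sweep=_cohort_sweep(sweep_store, np.round(np.arange(0.05, 1.0001, 0.05), 2)),
        auto_biomarkers=auto_bio,
        manual_biomarkers=manual_bio,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def _cohort_sweep(store, tau_grid) -> pd.DataFrame:
    """Cohort-level metric curves as the detection threshold τ varies."""
    rows = []
    for tau in tau_grid:
        counts = ConfusionCounts()
        detected = total = fp = 0
        for positive, pred_nonempty, fracs, fp_count in store:
            det = sum(f >= tau for f in fracs)
            detected += det
            total += len(fracs)
            fp += fp_count
            if positive:
                counts = counts + ConfusionCounts(tp=1) if det else counts + ConfusionCounts(fn=1)
            else:
                counts = counts + (ConfusionCounts(tn=1) if not pred_nonempty else ConfusionCounts(fp=1))
        patient = confusion_metrics(counts)
        for metric, value in (
            ("patient_accuracy", patient.accuracy),
            ("patient_sensitivity", patient.sensitivity),
            ("patient_ppv", patient.ppv),
            ("lesion_sensitivity", 100.0 * detected / total if total else None),
            ("lesion_ppv", 100.0 * detected / (detected + fp) if detected + fp else None),
        ):
            rows.append({"tau": float(tau), "metric": metric, "value": value})
    return pd.DataFrame(rows)


def format_count_pct(numerator: int, denominator: int) -> str:
    """Display convention 'x.x (a/b)', e.g. '93.3 (70/75)'."""
    if denominator == 0:
        raise ValueError("empty denominator")
    pct = round_display(100.0 * numerator / denominator)
    # whole percentages print without a trailing .0 (e.g. '0 (0/1)' style avoided
    # for consistency: keep one decimal)
    return f"{pct} ({numerator}/{denominator})"


def report_tables(run_dir: str | Path) -> dict[str, Any]:
    """Human-readable summary tables from a completed run directory."""
    run_dir = Path(run_dir)
    metrics_path = run_dir / "cohort_metrics.json"
    if not metrics_path.exists():
        raise FileNotFoundError(f"incomplete run: missing {metrics_path}")
    summary = json.loads(metrics_path.read_text())
    if summary.get("n_scans", 0) == 0:
        raise ValueError("empty cohort")
    counts = summary["patient_level"]["counts"]
    tp, fp, tn, fn = counts["tp"], counts["fp"], counts["tn"], counts["fn"]
    n = tp + fp + tn + fn
    lesion = summary["lesion_level"]
    det, tot, fpc = lesion["detected"], lesion["total"], lesion["fp_clusters"]
    tables = {
        "patient_level": {
            "accuracy": format_count_pct(tp + tn, n),
            "sensitivity": format_count_pct(tp, tp + fn) if tp + fn else None,
            "ppv": format_count_pct(tp, tp + fp) if tp + fp else None,
            "specificity": format_count_pct(tn, tn + fp) if tn + fp else None,
            "npv": format_count_pct(tn, tn + fn) if tn + fn else None,
        },
        "lesion_level": {
            "sensitivity": format_count_pct(det, tot) if tot else None,
            "ppv": format_count_pct(det, det + fpc) if det + fpc else None,
            "f1": round_display(lesion["f1_pct"]) if lesion["f1_pct"] is not None else None,
        },
        "survival": {
            name: comp["p_display"] for name, comp in summary["survival"].items()
        },
    }
    subgroup_path = run_dir / "subgroup_sensitivity.csv"
    if subgroup_path.exists():
        sub = pd.read_csv(subgroup_path)
        tables["lesion_subgroups"] = {
            row.site: format_count_pct(int(row.detected), int(row.total))
            for row in sub.itertuples()
        }
    return tables
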