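"""Patient/lesion/voxel evaluation: matching rules, metric arithmetic, sweeps."""

import numpy as np
import pytest

from psmapet import (
    ConfusionCounts,
    classify_scan,
    confusion_metrics,
    f1_score,
    match_lesions,
    subgroup_sensitivity,
    threshold_sweep,
    voxel_metrics,
)
from psmapet.evaluation import paired_observer_comparison, round_display
from psmapet.imaging import BinaryMask, GridMismatchError, ParameterError

from conftest import make_binary, make_labelled
from oracles import (
    match_lesions_bruteforce,
    voxel_metrics_bruteforce,
    wilcoxon_exact_two_sided,
)


def _pred_on(gt, membership):
    return BinaryMask(gt.grid, np.asarray(membership, dtype=bool))


def two_lesion_toy():
    """27-voxel lesion A, 64-voxel lesion B on a 16³ grid."""
    labels = np.zeros((16, 16, 16), dtype=np.uint32)
    labels[1:4, 1:4, 1:4] = 1  # 27 voxels
    labels[8:12, 8:12, 8:12] = 2  # 64 voxels
    gt = make_labelled(labels, sites={1: "osseous", 2: "distant_nodal"})
    pred = np.zeros_like(labels, dtype=bool)
    pred[1, 1, 1:4] = True  # 3 of 27 in lesion A
    pred[8:12, 8:12, 8:10] = True  # 32 voxels
    pred[8:12, 8:10, 10] = True  # +8 -> 40 of 64 in lesion B
    pred[14, 14, 14] = True  # disjoint cluster, 5 voxels
    pred[14, 14, 13] = pred[14, 13, 14] = pred[13, 14, 14] = pred[15, 14, 14] = True
    return gt, _pred_on(gt, pred)


class TestMatchLesions:
    def test_perfect_prediction(self):
        gt, _ = two_lesion_toy()
        report = match_lesions(gt, _pred_on(gt, gt.labels > 0), tau=0.10)
        assert report.n_detected == 2
        assert report.fp_cluster_count == 0
        assert all(m.overlap_fraction == 1.0 for m in report.matches)

    def test_two_lesion_toy_counts(self):
        gt, pred = two_lesion_toy()
        report = match_lesions(gt, pred, tau=0.2)
        by_label = {m.gt_label: m for m in report.matches}
        assert by_label[1].overlap_fraction == pytest.approx(3 / 27)
        assert by_label[2].overlap_fraction == pytest.approx(40 / 64)
        assert not by_label[1].detected and by_label[2].detected
        assert report.sensitivity_pct == pytest.approx(50.0)
        assert report.fp_cluster_count == 1
        assert report.ppv_pct == pytest.approx(50.0)  # 1 / (1 + 1)

    def test_detection_boundary_inclusive(self):
        # 1000-voxel lesion with exactly 100 predicted interior voxels
        labels = np.zeros((12, 12, 12), dtype=np.uint32)
        labels[1:11, 1:11, 1:11] = 1
        gt = make_labelled(labels)
        pred = np.zeros_like(labels, dtype=bool)
        pred[1:5, 1:6, 1:6] = True  # 100 voxels inside the lesion
        assert pred.sum() == 100
        frac = match_lesions(gt, _pred_on(gt, pred), tau=0.10).matches[0]
        assert frac.overlap_fraction == pytest.approx(0.100)
        assert frac.detected
        assert not match_lesions(gt, _pred_on(gt, pred), tau=0.101).matches[0].detected

    def test_count_conservation(self):
        gt, pred = two_lesion_toy()
        report = match_lesions(gt, pred, tau=0.2)
        assert report.n_detected + sum(not m.detected for m in report.matches) == gt.n_lesions

    @pytest.mark.parametrize("tau", [0.0, -0.1, 1.5])
    def test_invalid_tau(self, tau):
        gt, pred = two_lesion_toy()
        with pytest.raises(ParameterError):
            match_lesions(gt, pred, tau=tau)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 14, size=3))
        from psmapet import connected_components

        gt_mask = rng.random(shape) > 0.85
        comp = connected_components(make_binary(gt_mask), connectivity)
        labels = comp.labels
        sites = {l: "osseous" for l in comp.label_ids}
        gt = make_labelled(labels, sites=sites)
        pred = rng.random(shape) > 0.8
        tau = float(rng.uniform(0.05, 0.9))
        report = match_lesions(gt, _pred_on(gt, pred), tau=tau, connectivity=connectivity)
        fracs, detected, fp = match_lesions_bruteforce(labels, pred, tau, connectivity)
        assert report.fp_cluster_count == fp
        for m in report.matches:
            assert m.overlap_fraction == pytest.approx(fracs[m.gt_label])
            assert m.detected == detected[m.gt_label]


class TestClassifyScan:
    def test_negative_scan_single_voxel_is_fp(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint32)
        gt = make_labelled(labels)
        pred = np.zeros_like(labels, dtype=bool)
        pred[0, 0, 0] = True
        assert classify_scan(gt, _pred_on(gt, pred)).call == "fp"

    def test_negative_scan_empty_prediction_is_tn(self):
        gt = make_labelled(np.zeros((8, 8, 8), dtype=np.uint32))
        assert classify_scan(gt, _pred_on(gt, np.zeros((8, 8, 8), bool))).call == "tn"

    def test_positive_scan_subthreshold_overlap_is_fn(self):
        labels = np.zeros((12, 12, 12), dtype=np.uint32)
        labels[1:11, 1:11, 1:11] = 1  # 1000 voxels
        gt = make_labelled(labels)
        pred = np.zeros_like(labels, dtype=bool)
        pred[1, 1, 1:6] = True  # 5/1000 overlap < 10%, prediction non-empty
        cls = classify_scan(gt, _pred_on(gt, pred), tau=0.10)
        assert cls.gt_status == "positive" and cls.call == "fn"

    def test_positive_scan_one_detection_is_tp(self):
        gt, pred = two_lesion_toy()
        assert classify_scan(gt, pred, tau=0.2).call == "tp"


class TestVoxelMetrics:
    def test_identical_masks_dsc_100(self):
        rng = np.random.default_rng(0)
        m = rng.random((6, 6, 6)) > 0.5
        a = make_binary(m)
        out = voxel_metrics(a, BinaryMask(a.grid, m.copy()))
        assert out.dsc == pytest.approx(100.0)

    def test_disjoint_masks_dsc_0(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0] = True
        n = np.zeros((4, 4, 4), dtype=bool)
        n[2] = True
        a = make_binary(m)
        out = voxel_metrics(a, BinaryMask(a.grid, n))
        assert out.dsc == 0.0

    def test_worked_example(self):
        # |A|=6, |B|=4, |A∩B|=3 -> DSC 60%, sensitivity 50%, PPV 75%
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :4] = a[1, 1, :2] = True
        b = np.zeros((4, 4, 4), dtype=bool)
        b[0, 0, 1:4] = b[3, 3, 3] = True
        ga = make_binary(a)
        out = voxel_metrics(ga, BinaryMask(ga.grid, b))
        assert out.dsc == pytest.approx(60.0)
        assert out.sensitivity == pytest.approx(50.0)
        assert out.ppv == pytest.approx(75.0)

    def test_empty_gt_rejected(self):
        a = make_binary(np.zeros((3, 3, 3), bool))
        with pytest.raises(ParameterError):
            voxel_metrics(a, BinaryMask(a.grid, np.ones((3, 3, 3), bool)))

    @pytest.mark.parametrize("seed", range(6))
    def test_dsc_symmetry_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8, 8)) > 0.6
        b = rng.random((8, 8, 8)) > 0.6
        if not (a.any() and b.any()):
            pytest.skip("degenerate draw")
        ga = make_binary(a)
        gb = BinaryMask(ga.grid, b)
        ab = voxel_metrics(ga, gb)
        ba = voxel_metrics(BinaryMask(ga.grid, b), BinaryMask(ga.grid, a))
        assert ab.dsc == pytest.approx(ba.dsc)
        dsc, sens, ppv, spec = voxel_metrics_bruteforce(a, b)
        assert ab.dsc == pytest.approx(dsc)
        assert ab.sensitivity == pytest.approx(sens)
        assert ab.ppv == pytest.approx(ppv)
        assert ab.specificity == pytest.approx(spec)


class TestConfusionMetrics:
    def test_patient_level_table(self):
        m = confusion_metrics(ConfusionCounts(tp=70, fn=5, tn=51, fp=2))
        assert round_display(m.accuracy) == 94.5
        assert round_display(m.sensitivity) == 93.3
        assert round_display(m.ppv) == 97.2
        assert round_display(m.specificity) == 96.2
        assert round_display(m.npv) == 91.1

    def test_lesion_level_ratios(self):
        # 224 detected of 307 lesions, 254 total predictions
        m = confusion_metrics(ConfusionCounts(tp=224, fn=307 - 224, fp=254 - 224))
        assert round_display(m.sensitivity) == 73.0
        assert round_display(m.ppv) == 88.2

    def test_all_correct_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=1, tn=1))
        for v in (m.accuracy, m.sensitivity, m.ppv, m.specificity, m.npv):
            assert v == pytest.approx(100.0)

    def test_undefined_metrics_are_none(self):
        m = confusion_metrics(ConfusionCounts(tp=5))
        assert m.specificity is None and m.npv is None
        assert m.sensitivity == pytest.approx(100.0)

    def test_all_zero_counts(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(tp=-1)
        m = confusion_metrics(ConfusionCounts())
        assert m.accuracy is None


class TestF1Score:
    def test_detection_f1(self):
        assert round_display(f1_score(100 * 224 / 254, 100 * 224 / 307)) == 79.9

    def test_observer_f1(self):
        assert round_display(f1_score(100 * 66 / 72, 100 * 66 / 92)) == 80.5

    @pytest.mark.parametrize("x", [10.0, 50.0, 99.9])
    def test_harmonic_mean_identity(self, x):
        assert f1_score(x, x) == pytest.approx(x)

    def test_both_zero_undefined(self):
        with pytest.raises(ParameterError):
            f1_score(0.0, 0.0)


class TestThresholdSweep:
    def test_single_tau_matches_single_call(self):
        gt, pred = two_lesion_toy()
        sweep = threshold_sweep(gt, pred, [0.10])
        report = match_lesions(gt, pred, tau=0.10)
        sens = sweep[(sweep.metric == "sensitivity")].value.iloc[0]
        assert sens == pytest.approx(report.sensitivity_pct)

    def test_toy_boundaries(self):
        gt, pred = two_lesion_toy()
        sweep = threshold_sweep(gt, pred, [0.05, 0.70])
        sens = sweep[sweep.metric == "sensitivity"].set_index("tau").value
        assert sens[0.05] == pytest.approx(100.0)  # 3/27≈0.111 and 40/64=0.625
        assert sens[0.70] == pytest.approx(0.0)

    def test_sensitivity_monotone_nonincreasing(self):
        gt, pred = two_lesion_toy()
        taus = list(np.linspace(0.01, 1.0, 100))
        sweep = threshold_sweep(gt, pred, taus)
        sens = sweep[sweep.metric == "sensitivity"].sort_values("tau").value.to_numpy()
        assert np.all(np.diff(sens) <= 1e-12)

    def test_fp_count_independent_of_tau(self):
        gt, pred = two_lesion_toy()
        sweep = threshold_sweep(gt, pred, [0.05, 0.5, 0.95])
        fp = sweep[sweep.metric == "fp_clusters"].value
        assert fp.nunique() == 1

    def test_empty_grid_rejected(self):
        gt, pred = two_lesion_toy()
        with pytest.raises(ParameterError):
            threshold_sweep(gt, pred, [])


class TestSubgroupSensitivity:
    def test_all_detected_every_site_100(self):
        gt, _ = two_lesion_toy()
        report = match_lesions(gt, _pred_on(gt, gt.labels > 0), tau=0.10)
        table = subgroup_sensitivity([report])
        assert (table[table.site != "overall"].sensitivity_pct == 100.0).all()

    def test_absent_site_omitted(self):
        gt, pred = two_lesion_toy()
        report = match_lesions(gt, pred, tau=0.2)
        table = subgroup_sensitivity([report])
        assert "local_prostate" not in set(table.site)
        assert {"osseous", "distant_nodal", "overall"} == set(table.site)

    def test_site_specific_drop_rates_recovered(self, small_phantom_config):
        # corruption with per-site drop emulated by dropping labels by site
        from psmapet import CorruptionConfig, corrupt_prediction, generate_scan
        from psmapet.imaging import BinaryMask as BM
        import numpy as np

        rng = np.random.default_rng(0)
        drop_by_site = {"local_prostate": 0.1, "osseous": 0.4}
        detected = {}
        total = {}
        for seed in range(40):
            scan = generate_scan(small_phantom_config, positive=True, seed=3000 + seed)
            gt = scan.ground_truth
            pred = np.zeros(gt.grid.shape, dtype=bool)
            for label in gt.label_ids:
                site = gt.site_by_label[label]
                if rng.random() >= drop_by_site.get(site, 0.0):
                    pred |= gt.labels == label
            report = match_lesions(gt, BM(gt.grid, pred), tau=0.10)
            for m in report.matches:
                total[m.site] = total.get(m.site, 0) + 1
                detected[m.site] = detected.get(m.site, 0) + int(m.detected)
        for site, drop in drop_by_site.items():
            p = 1 - drop
            n = total[site]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(detected[site] / n - p) < 3 * se, site


class TestPairedObserverComparison:
    def test_identical_inputs_degenerate(self):
        metrics = {f"s{i}": {"dsc": 50.0 + i} for i in range(6)}
        out = paired_observer_comparison(metrics, metrics)
        assert (out.p_value == 1.0).all()
        assert out.degenerate.all()

    def test_constant_shift_significant(self):
        rng = np.random.default_rng(1)
        base = {f"s{i}": {"dsc": float(rng.uniform(30, 60))} for i in range(20)}
        shifted = {k: {"dsc": v["dsc"] + 5.0} for k, v in base.items()}
        out = paired_observer_comparison(shifted, base)
        assert out.p_value.iloc[0] < 0.005
        # cross-check against exhaustive sign-flip enumeration
        diffs = [shifted[k]["dsc"] - base[k]["dsc"] for k in base]
        assert out.p_value.iloc[0] == pytest.approx(
            wilcoxon_exact_two_sided(diffs), abs=5e-4
        )

    def test_mismatched_ids_rejected(self):
        a = {f"s{i}": {"dsc": 1.0} for i in range(6)}
        b = {f"t{i}": {"dsc": 1.0} for i in range(6)}
        with pytest.raises(ParameterError):
            paired_observer_comparison(a, b)
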