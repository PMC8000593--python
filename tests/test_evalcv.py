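"""Evaluation: IoU geometry, greedy matching vs. brute force, fold logic,
aggregation arithmetic."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scintidet._util import render_2dp
from scintidet.detector import Detection
from scintidet.errors import SplitError, ValidationError
from scintidet.evalcv import (
    CVReport,
    LesionMetrics,
    PatientMetrics,
    aggregate,
    iou,
    make_folds,
    match_detections,
    merge_duplicate_truth,
    patient_call,
)
from scintidet.scan_io import Box, Category, DatasetManifest, ManifestEntry


def _box(x0, y0, x1, y1, category=Category.METASTASIS, conf=1.0):
    return Box(category=category, x_min=x0, y_min=y0, x_max=x1, y_max=y1, confidence=conf)


def _det(x0, y0, x1, y1, conf, category=Category.METASTASIS):
    return Detection(box=_box(x0, y0, x1, y1, category, conf), confidence=conf)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(_box(0, 0, 10, 10), _box(0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(_box(0, 0, 10, 10), _box(20, 20, 30, 30)) == 0.0

    def test_closed_form_overlap(self):
        assert iou(_box(0, 0, 10, 10), _box(5, 5, 15, 15)) == pytest.approx(25 / 175)

    def test_agrees_with_pixel_rasterization(self):
        """Formula IoU equals brute-force pixel counting on integer boxes."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            x0, y0 = rng.integers(0, 40, 2)
            a = _box(x0, y0, x0 + rng.integers(1, 30), y0 + rng.integers(1, 30))
            x0, y0 = rng.integers(0, 40, 2)
            b = _box(x0, y0, x0 + rng.integers(1, 30), y0 + rng.integers(1, 30))
            grid_a = np.zeros((80, 80), bool)
            grid_b = np.zeros((80, 80), bool)
            grid_a[int(a.y_min) : int(a.y_max), int(a.x_min) : int(a.x_max)] = True
            grid_b[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)] = True
            inter = np.logical_and(grid_a, grid_b).sum()
            union = np.logical_or(grid_a, grid_b).sum()
            assert iou(a, b) == pytest.approx(inter / union, abs=1e-9)


def brute_force_max_matching(dets, gts, threshold):
    """Oracle: assignment maximizing the number of IoU-qualified pairs."""
    n, m = len(dets), len(gts)
    qualified = {
        (i, j)
        for i in range(n)
        for j in range(m)
        if gts[j].category == dets[i].box.category and iou(dets[i].box, gts[j]) >= threshold
    }
    best = 0
    for r in range(min(n, m), 0, -1):
        for det_subset in itertools.permutations(range(n), r):
            for gt_subset in itertools.combinations(range(m), r):
                if all((i, j) in qualified for i, j in zip(det_subset, gt_subset)):
                    best = max(best, r)
            if best == r:
                break
        if best:
            break
    return best


class TestMatching:
    def test_boundary_iou_below_threshold_is_fp_and_fn(self):
        gt = _box(0, 0, 10, 10)
        d = _det(0, 0, 10, 10, 0.9)
        # shrink overlap to IoU 0.29 < 0.3
        d29 = _det(0, 5.5, 10, 15.5, 0.9)
        assert iou(d29.box, gt) < 0.3
        res = match_detections([d29], [gt])
        assert res.totals(Category.METASTASIS) == (0, 1, 1)
        res_exact = match_detections([d], [gt])
        assert res_exact.totals(Category.METASTASIS) == (1, 0, 0)

    def test_higher_confidence_detection_wins_single_gt(self):
        gt = _box(0, 0, 10, 10)
        d_hi = _det(0, 0, 10, 10, 0.9)
        d_lo = _det(1, 1, 11, 11, 0.6)
        res = match_detections([d_lo, d_hi], [gt])
        assert res.totals(Category.METASTASIS) == (1, 1, 0)
        (pair,) = res.pairs
        assert pair[2] == 1.0  # the exact-overlap, higher-confidence detection

    def test_equivocal_truth_absorbs_one_detection(self):
        eq = _box(0, 0, 10, 10, category=Category.EQUIVOCAL)
        d1 = _det(0, 0, 10, 10, 0.9)
        d2 = _det(1, 1, 11, 11, 0.8)
        res = match_detections([d1, d2], [eq])
        assert res.ignored == 1
        assert res.totals(Category.METASTASIS) == (0, 1, 0)  # second det is FP, no FN

    def test_category_mismatch_is_fp_not_tp(self):
        gt = _box(0, 0, 10, 10, category=Category.NORMAL_HOTSPOT)
        d = _det(0, 0, 10, 10, 0.9, category=Category.METASTASIS)
        res = match_detections([d], [gt])
        assert res.tp[Category.METASTASIS] == 0
        assert res.fp[Category.METASTASIS] == 1
        assert res.fn[Category.NORMAL_HOTSPOT] == 1

    def test_duplicate_fused_truth_is_premerged(self):
        a = _box(0, 0, 10, 10)
        b = _box(1, 0, 11, 10)  # IoU 9/11 >= 0.5 with a
        assert len(merge_duplicate_truth([a, b])) == 1
        d = _det(0, 0, 10, 10, 0.9)
        res = match_detections([d], [a, b])
        assert res.totals(Category.METASTASIS) == (1, 0, 0)

    def test_counting_identities(self, small_corpus):
        """TP+FN = merged non-equivocal truth; TP+FP+ignored = detections."""
        rng = np.random.default_rng(5)
        for img, _pos in small_corpus[:6]:
            dets = []
            for b in img.boxes[:4]:
                conf = float(rng.uniform(0.2, 1.0))
                dets.append(Detection(
                    box=Box(category=b.category, x_min=b.x_min, y_min=b.y_min,
                            x_max=b.x_max, y_max=b.y_max, confidence=conf),
                    confidence=conf))
            res = match_detections(dets, img.boxes)
            tp, fp, fn = res.totals()
            assert tp + fn == res.n_truth
            assert tp + fp + res.ignored == len(dets)

    def test_greedy_equals_brute_force_on_small_instances(self):
        """Exact agreement for <=2 detections; >=95% over 1,000 instances."""
        rng = np.random.default_rng(12)
        agree = total = 0
        for _ in range(1000):
            n_det = int(rng.integers(0, 4))
            n_gt = int(rng.integers(0, 4))
            dets = []
            for _i in range(n_det):
                x, y = rng.uniform(0, 70, 2)
                w, h = rng.uniform(8, 30, 2)
                dets.append(_det(x, y, x + w, y + h, float(rng.uniform(0.1, 1.0))))
            gts = []
            for _i in range(n_gt):
                x, y = rng.uniform(0, 70, 2)
                w, h = rng.uniform(8, 30, 2)
                gts.append(_box(x, y, x + w, y + h))
            res = match_detections(dets, gts, merge_duplicates=False)
            optimal = brute_force_max_matching(dets, gts, 0.3)
            total += 1
            same = res.totals()[0] == optimal
            agree += same
            if n_det <= 2:
                assert same, (dets, gts)
        assert agree / total >= 0.95

    def test_sensitivity_monotone_in_iou_threshold(self):
        rng = np.random.default_rng(3)
        dets, gts = [], []
        for _ in range(6):
            x, y = rng.uniform(0, 60, 2)
            gts.append(_box(x, y, x + 15, y + 15))
            dx, dy = rng.uniform(-6, 6, 2)
            dets.append(_det(x + dx, y + dy, x + 15 + dx, y + 15 + dy,
                             float(rng.uniform(0.3, 1.0))))
        last = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            res = match_detections(dets, gts, iou_threshold=thr, merge_duplicates=False)
            tp, _fp, fn = res.totals()
            sens = tp / (tp + fn)
            if last is not None:
                assert sens <= last
            last = sens

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            match_detections([], [], iou_threshold=0.0)


class TestPatientCall:
    def test_no_detections_is_negative(self):
        assert patient_call([]) is False

    def test_confident_metastasis_is_positive(self):
        assert patient_call([_det(0, 0, 10, 10, 0.9)], decision_conf=0.5) is True

    def test_normal_hotspots_never_trigger(self):
        dets = [_det(0, 0, 10, 10, 0.99, category=Category.NORMAL_HOTSPOT)]
        assert patient_call(dets) is False

    def test_threshold_is_strict(self):
        assert patient_call([_det(0, 0, 10, 10, 0.5)], decision_conf=0.5) is False


def _manifest(n_pos, n_neg):
    entries = [
        ManifestEntry(f"i{i}.png", f"l{i}.txt", f"p{i}", "synthetic", i < n_pos)
        for i in range(n_pos + n_neg)
    ]
    return DatasetManifest(entries=entries)


class TestFolds:
    def test_194_images_fold_sizes(self):
        m = _manifest(100, 94)
        folds = make_folds(m, k=10, seed=1)
        sizes = np.bincount(folds, minlength=10)
        assert all(s in (19, 20) for s in sizes)

    def test_stratified_counts_match_counting_oracle(self):
        m = _manifest(100, 94)
        folds = make_folds(m, k=10, seed=2)
        pos_flags = np.array([e.patient_positive for e in m.entries])
        for f in range(10):
            in_fold = np.asarray(folds) == f
            assert (in_fold & pos_flags).sum() == 10
            assert (in_fold & ~pos_flags).sum() in (9, 10)

    def test_same_seed_same_assignment(self):
        m = _manifest(30, 30)
        assert make_folds(m, k=5, seed=9) == make_folds(m, k=5, seed=9)

    def test_small_stratum_raises(self):
        m = _manifest(4, 40)
        with pytest.raises(SplitError):
            make_folds(m, k=10, seed=0)


class TestAggregate:
    def test_ten_copies_of_half(self):
        mean, sd = aggregate([0.5] * 10)
        assert (mean, sd) == (0.5, 0.0)

    def test_sample_standard_deviation(self):
        mean, sd = aggregate([0.4, 0.6])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.std([0.4, 0.6], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_mean_matches_numpy(self, values):
        mean, _sd = aggregate(values)
        assert mean == pytest.approx(float(np.mean(values)), abs=1e-12)

    def test_two_decimal_rendering_rounds_half_away(self):
        assert render_2dp(0.715) == 0.72
        assert render_2dp(0.7149) == 0.71
        assert render_2dp(-0.715) == -0.72


class TestMetricTypes:
    def test_undefined_ratios_are_none(self):
        assert LesionMetrics(0, 0, 0).sensitivity is None
        assert LesionMetrics(0, 0, 0).precision is None
        assert PatientMetrics(0, 0, 0, 0).specificity is None

    def test_defined_ratios(self):
        l = LesionMetrics(tp=6, fp=2, fn=2)
        assert l.sensitivity == 0.75 and l.precision == 0.75
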