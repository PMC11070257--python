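"""Coverage-rule matching and precision/recall characterization."""

import numpy as np
import pytest

from katydet.annotations import Annotation
from katydet.detect import Detection, ScoreTrack, group_detections
from katydet.evaluate import (
    classify_detections,
    classify_recall,
    pr_counts,
    pr_curve,
)


def det(begin, end, ci=0, score=0.9):
    return Detection(class_index=ci, begin_s=begin, end_s=end, score=score, group_size=1)


def ann(begin, end):
    return Annotation(begin_s=begin, end_s=end, low_hz=8e3, high_hz=1.2e4, tag="x")


class TestDetectionCoverage:
    def test_coverage_above_60_percent_is_tp(self):
        # overlap 0.25 of a 0.4 s detection = 62.5% > 60%
        flags = classify_detections([det(0.0, 0.4)], [(0, ann(0.1, 0.35))])
        assert flags == [True]

    def test_no_same_class_overlap_is_fp(self):
        flags = classify_detections([det(0.0, 0.4)], [(1, ann(0.1, 0.35))])
        assert flags == [False]

    def test_overlaps_sum_across_annotations(self):
        # two GT calls covering 0.3 + 0.4 of a 1.0 s detection = 70%
        gt = [(0, ann(0.0, 0.3)), (0, ann(0.5, 0.9))]
        assert classify_detections([det(0.0, 1.0)], gt) == [True]

    def test_exactly_60_percent_is_fp(self):
        # the rule is strictly "exceeds"
        flags = classify_detections([det(0.0, 1.0)], [(0, ann(0.0, 0.6))])
        assert flags == [False]
        flags = classify_detections([det(0.0, 1.0)], [(0, ann(0.0, 0.6000001))])
        assert flags == [True]


class TestRecallCoverage:
    def test_contained_annotation_recalled(self):
        assert classify_recall([(0, ann(0.1, 0.35))], [det(0.0, 0.4)]) == [True]

    def test_forty_percent_not_recalled(self):
        assert classify_recall([(0, ann(0.0, 1.0))], [det(0.6, 1.2)]) == [False]

    def test_summed_overlap_counts(self):
        dets = [det(0.0, 0.3), det(0.6, 1.2)]
        assert classify_recall([(0, ann(0.0, 1.0))], dets) == [True]  # 0.3 + 0.4 = 0.7

    def test_exactly_50_percent_is_recalled(self):
        # the recall rule is inclusive (>=)
        assert classify_recall([(0, ann(0.0, 1.0))], [det(0.5, 1.0)]) == [True]

    def test_wrong_class_does_not_recall(self):
        assert classify_recall([(0, ann(0.0, 1.0))], [det(0.0, 1.0, ci=1)]) == [False]


class TestPRCounts:
    def test_tp_plus_fp_equals_detections(self):
        dets = [det(0.0, 0.4), det(1.0, 1.4), det(2.0, 2.8, ci=1)]
        gt = [(0, ann(0.05, 0.35))]
        pts = pr_counts(dets, gt, n_classes=2, tau=0.5)
        pooled = pts[0]
        assert pooled.tp + pooled.fp == len(dets)

    def test_precision_missing_when_no_detections(self):
        pts = pr_counts([], [(0, ann(0.0, 1.0))], n_classes=1, tau=0.9)
        assert pts[0].precision is None
        assert pts[0].recall == 0.0

    def test_recall_missing_for_class_absent_from_gt(self):
        pts = pr_counts([det(0.0, 0.8, ci=1)], [(0, ann(0.0, 1.0))], n_classes=2, tau=0.1)
        per_class = pts[2]  # class index 1
        assert per_class.recall is None
        assert per_class.gt_total == 0

    def test_recall_from_recalled_count_not_tp_count(self):
        # one long detection covers two GT calls: 1 TP but 2 recalled
        dets = [det(0.0, 1.0)]
        gt = [(0, ann(0.0, 0.4)), (0, ann(0.5, 0.9))]
        pts = pr_counts(dets, gt, n_classes=1, tau=0.5)
        assert pts[0].tp == 1
        assert pts[0].recalled == 2
        assert pts[0].recall == 1.0


class TestPRCurve:
    def make_perfect_case(self):
        # track where class-0 windows 2..5 are positive; GT call right inside
        scores = np.zeros((10, 1))
        scores[2:6, 0] = 0.95
        track = ScoreTrack(scores=scores)
        # 4-window run -> extent [1.0, 1.2]; GT covering it
        gt = [(0, ann(0.95, 1.25))]
        return track, gt

    def test_perfect_detector_recall_one_at_low_tau(self):
        track, gt = self.make_perfect_case()
        curve = pr_curve(track, gt, n_classes=1, taus=[0.5])
        pooled = curve[0]
        assert pooled.recall == 1.0
        assert pooled.precision == 1.0

    def test_tau_above_all_scores(self):
        track, gt = self.make_perfect_case()
        pooled = pr_curve(track, gt, n_classes=1, taus=[0.99])[0]
        assert pooled.tp == 0 and pooled.fp == 0
        assert pooled.recall == 0.0 and pooled.precision is None

    def test_recall_non_increasing_for_confident_scores(self):
        # Strict monotonicity of recall in tau can fail for marginal score
        # profiles: shrinking a run changes the refined extent, which may
        # overlap a GT call *more* (a singleton's 0.8 s extent exceeds any
        # run intersection). For bimodal, confident score tracks — the
        # operating regime of a trained detector — recall is monotone.
        rng = np.random.default_rng(2)
        raw = rng.random((60, 2))
        scores = np.where(raw > 0.5, raw * 0.2 + 0.8, raw * 0.1)  # push to 0 / ~1
        track = ScoreTrack(scores=scores)
        gt = [(0, ann(1.0, 1.9)), (1, ann(4.0, 4.4)), (0, ann(8.0, 8.2))]
        curve = pr_curve(track, gt, n_classes=2)
        pooled = [p for p in curve if p.class_index is None]
        recalls = [p.recall for p in pooled]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(5)
        track = ScoreTrack(scores=rng.random((40, 2)))
        gt = [(0, ann(0.5, 1.3)), (1, ann(3.1, 3.3)), (1, ann(5.0, 5.9))]
        taus = [0.2, 0.5, 0.8]
        curve = pr_curve(track, gt, n_classes=2, taus=taus)
        for tau in taus:
            dets = group_detections(track, tau)
            tps = 0
            for d in dets:
                ov = sum(max(0.0, min(d.end_s, a.end_s) - max(d.begin_s, a.begin_s))
                         for ci, a in gt if ci == d.class_index)
                tps += ov > 0.6 * d.duration_s
            rec = 0
            for ci, a in gt:
                ov = sum(max(0.0, min(d.end_s, a.end_s) - max(d.begin_s, a.begin_s))
                         for d in dets if d.class_index == ci)
                rec += ov >= 0.5 * (a.end_s - a.begin_s)
            pooled = next(p for p in curve if p.class_index is None and p.tau == tau)
            assert (pooled.tp, pooled.recalled) == (tps, rec)
            assert pooled.tp + pooled.fp == len(dets)

    def test_multi_file_micro_aggregation(self):
        track, gt = self.make_perfect_case()
        empty_track = ScoreTrack(scores=np.zeros((10, 1)))
        curve = pr_curve([track, empty_track], [gt, [(0, ann(0.0, 0.5))]],
                         n_classes=1, taus=[0.5])
        pooled = curve[0]
        assert pooled.gt_total == 2
        assert pooled.recalled == 1
        assert pooled.recall == 0.5


class TestReportTiers:
    def test_confirmed_moves_fp_to_tp_and_grows_gt(self):
        from katydet.evaluate import report_tiers

        dets = [det(0.0, 0.4), det(2.0, 2.4)]  # second has no GT -> FP
        gt = [(0, ann(0.05, 0.35))]
        tiers = report_tiers(dets, gt, n_classes=1, tau=0.5, confirmed=[1])
        base, conf = tiers["base"][0], tiers["base+confirmed"][0]
        assert (base.tp, base.fp, base.gt_total) == (1, 1, 1)
        assert (conf.tp, conf.fp, conf.gt_total) == (2, 0, 2)
        assert conf.recall == 1.0

    def test_unable_counts_tp_without_growing_gt(self):
        from katydet.evaluate import report_tiers

        dets = [det(0.0, 0.4), det(2.0, 2.4)]
        gt = [(0, ann(0.05, 0.35))]
        tiers = report_tiers(dets, gt, n_classes=1, tau=0.5, unable_to_reject=[1])
        top = tiers["base+confirmed+unable"][0]
        assert (top.tp, top.fp, top.gt_total) == (2, 0, 1)

    def test_override_on_tp_detection_is_ignored(self):
        from katydet.evaluate import report_tiers

        dets = [det(0.0, 0.4)]
        gt = [(0, ann(0.05, 0.35))]
        tiers = report_tiers(dets, gt, n_classes=1, tau=0.5, confirmed=[0])
        assert tiers["base+confirmed"][0].tp == tiers["base"][0].tp == 1

    def test_bad_index_rejected(self):
        from katydet.evaluate import report_tiers

        with pytest.raises(IndexError):
            report_tiers([det(0.0, 0.4)], [], n_classes=1, tau=0.5, confirmed=[3])
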