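"""Coverage-constrained matching of detections to ground truth; precision/recall.

Because reported detection extents are quantized to multiples of 0.2 s while
ground-truth (GT) annotations are not, matching uses coverage rules rather
than one-to-one assignment:

* a detection is a **true positive** iff the summed overlap with same-class
  GT annotations *exceeds* 60% of the detection's duration (strict >);
* a GT call is **recalled** iff the summed overlap with same-class
  detections is *at least* 50% of the annotation's duration (>=).

One GT annotation may support several detections and vice versa, so
TP + false negatives need not equal the GT count; recall is therefore the
ratio of recalled GT calls to total GT calls, never derived from TP counts.
Counts are aggregated across files before taking ratios (micro-averaging),
both pooled and per class. Precision at TP+FP = 0 is reported as missing
(None), not zero. Frequency bounds play no part in matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from katydet.annotations import Annotation
from katydet.detect import Detection, ScoreTrack, default_thresholds, group_detections

__all__ = [
    "TP_COVERAGE",
    "RECALL_COVERAGE",
    "PRPoint",
    "classify_detections",
    "classify_recall",
    "pr_counts",
    "report_tiers",
    "pr_curve",
]

#: A detection is TP when same-class GT overlap exceeds this fraction of it.
TP_COVERAGE = 0.6
#: A GT call is recalled when same-class detection overlap reaches this fraction.
RECALL_COVERAGE = 0.5


@dataclass
class PRPoint:
    """Precision/recall record at one threshold (pooled or per class)."""

    tau: float
    tp: int
    fp: int
    gt_total: int
    recalled: int
    class_index: int | None = None  # None = pooled

    @property
    def precision(self) -> float | None:
        n = self.tp + self.fp
        return None if n == 0 else self.tp / n

    @property
    def recall(self) -> float | None:
        return None if self.gt_total == 0 else self.recalled / self.gt_total


def _overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def classify_detections(detections: list[Detection], ground_truth: list[tuple[int, Annotation]]) -> list[bool]:
    """TP/FP flag per detection (True = TP).

    ``ground_truth`` pairs each annotation with its class index. The summed
    same-class overlap must strictly exceed 60% of the detection duration.
    """
    flags = []
    for det in detections:
        total = sum(
            _overlap(det.begin_s, det.end_s, ann.begin_s, ann.end_s)
            for ci, ann in ground_truth
            if ci == det.class_index
        )
        flags.append(total > TP_COVERAGE * det.duration_s)
    return flags


def classify_recall(ground_truth: list[tuple[int, Annotation]], detections: list[Detection]) -> list[bool]:
    """Recalled flag per GT annotation (summed same-class overlap >= 50%)."""
    flags = []
    for ci, ann in ground_truth:
        total = sum(
            _overlap(det.begin_s, det.end_s, ann.begin_s, ann.end_s)
            for det in detections
            if det.class_index == ci
        )
        flags.append(total >= RECALL_COVERAGE * ann.duration_s)
    return flags


def pr_counts(detections: list[Detection], ground_truth: list[tuple[int, Annotation]],
              n_classes: int, tau: float) -> list[PRPoint]:
    """Pooled + per-class TP/FP/recall counts for one detection set.

    Returns ``n_classes + 1`` points: index 0 pooled, then one per class.
    """
    tp_flags = classify_detections(detections, ground_truth)
    rec_flags = classify_recall(ground_truth, detections)
    points = [
        PRPoint(tau=tau, tp=int(sum(tp_flags)), fp=int(len(tp_flags) - sum(tp_flags)),
                gt_total=len(ground_truth), recalled=int(sum(rec_flags)), class_index=None)
    ]
    for ci in range(n_classes):
        det_mask = [d.class_index == ci for d in detections]
        gt_mask = [gci == ci for gci, _ in ground_truth]
        tp = sum(f for f, m in zip(tp_flags, det_mask) if m)
        nd = sum(det_mask)
        rec = sum(f for f, m in zip(rec_flags, gt_mask) if m)
        points.append(PRPoint(tau=tau, tp=int(tp), fp=int(nd - tp),
                              gt_total=int(sum(gt_mask)), recalled=int(rec), class_index=ci))
    return points


def report_tiers(
    detections: list[Detection],
    ground_truth: list[tuple[int, Annotation]],
    n_classes: int,
    tau: float,
    confirmed: list[int] | None = None,
    unable_to_reject: list[int] | None = None,
) -> dict[str, list[PRPoint]]:
    """Three assessment tiers incorporating manual-review override lists.

    ``base`` uses automatic matching only. ``base+confirmed`` additionally
    treats the detections at the given indices as true positives backed by
    real (previously unannotated) calls — each adds one to the TP count and
    one to the ground-truth total of its class. ``base+confirmed+unable``
    further counts the ``unable_to_reject`` detections (those a reviewer
    could not confidently refute) as TPs. The review itself happens outside
    this package; only its outcome lists are consumed. True performance lies
    between the latter two tiers.
    """
    confirmed = sorted(set(confirmed or []))
    unable = sorted(set(unable_to_reject or []) - set(confirmed))
    for idx in confirmed + unable:
        if not 0 <= idx < len(detections):
            raise IndexError(f"override index {idx} outside the detection list")

    def adjust(points: list[PRPoint], indices: list[int], grow_gt: bool) -> list[PRPoint]:
        out = []
        for p in points:
            extra = sum(
                1 for i in indices
                if p.class_index is None or detections[i].class_index == p.class_index
            )
            out.append(PRPoint(
                tau=p.tau, tp=p.tp + extra, fp=p.fp - extra,
                gt_total=p.gt_total + (extra if grow_gt else 0),
                recalled=p.recalled + (extra if grow_gt else 0),
                class_index=p.class_index,
            ))
        return out

    base = pr_counts(detections, ground_truth, n_classes, tau)
    # only FP detections can be overridden; confirmed ones add their call to GT
    tp_flags = classify_detections(detections, ground_truth)
    confirmed = [i for i in confirmed if not tp_flags[i]]
    unable = [i for i in unable if not tp_flags[i]]
    with_confirmed = adjust(base, confirmed, grow_gt=True)
    with_unable = adjust(with_confirmed, unable, grow_gt=False)
    return {
        "base": base,
        "base+confirmed": with_confirmed,
        "base+confirmed+unable": with_unable,
    }


def pr_curve(tracks, ground_truths, n_classes: int, taus=None) -> list[PRPoint]:
    """Precision/recall characterization over a threshold sweep.

    ``tracks`` is a list of :class:`ScoreTrack` (one per test file) and
    ``ground_truths`` the matching per-file lists of (class_index,
    Annotation). For each tau, detections are grouped per file and counts
    summed across files before ratios (micro-averaging); pooled and
    per-class points are returned for every threshold.
    """
    if isinstance(tracks, ScoreTrack):
        tracks = [tracks]
        ground_truths = [ground_truths]
    if len(tracks) != len(ground_truths):
        raise ValueError("one ground-truth list per track is required")
    taus = default_thresholds() if taus is None else np.asarray(taus, dtype=float)
    curve: list[PRPoint] = []
    for tau in taus:
        agg: list[PRPoint] | None = None
        for track, gt in zip(tracks, ground_truths):
            pts = pr_counts(group_detections(track, float(tau)), gt, n_classes, float(tau))
            if agg is None:
                agg = pts
            else:
                agg = [
                    PRPoint(tau=a.tau, tp=a.tp + b.tp, fp=a.fp + b.fp,
                            gt_total=a.gt_total + b.gt_total,
                            recalled=a.recalled + b.recalled, class_index=a.class_index)
                    for a, b in zip(agg, pts)
                ]
        curve.extend(agg if agg is not None else [])
    return curve
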