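"""Raven Pro selection tables, class mapping and soft multi-label ground truth.

Call-level annotations are time-frequency bounding boxes tagged with a class
label, exchanged as Raven Pro selection tables (tab-separated, header row).
Tags map onto detection-target classes through a :class:`ClassMap` which also
handles species merges (indistinguishable call types sharing one class), a
"catch-all" reject class, and the special ``background`` tag: background
periods are not a class — segments drawn from them carry all-zero label
vectors and additionally feed the additive-background pool used by the
background-infusion augmentation.

Ground-truth label vectors are soft (values in [0, 1]): full temporal
containment of an annotation by a segment (or vice versa) scores 1.0; partial
overlap scores ``overlap / min(segment_length, annotation_duration)``, so
boundary-clipped calls are penalized less during training. Short calls
(< 0.4 s) sitting near a focal segment's edge are further down-weighted by a
"sound centralization" penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from katydet.signals import Recording, Segment, SEGMENT_LENGTH_S, segment_audio

__all__ = [
    "Annotation",
    "ClassMap",
    "LabelVector",
    "read_selection_table",
    "write_selection_table",
    "assign_labels",
    "centralization_penalty",
    "collect_background",
    "SelectionTableError",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("Begin Time (s)", "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)")
DEFAULT_TAG_COLUMN = "Tags"

#: Annotations shorter than this (s) are eligible for the centralization penalty.
PENALTY_MAX_DURATION_S = 0.4


class SelectionTableError(ValueError):
    """A selection table violated the expected Raven dialect."""


@dataclass
class Annotation:
    """A time-frequency bounding box with a free-text class tag."""

    begin_s: float
    end_s: float
    low_hz: float
    high_hz: float
    tag: str

    def __post_init__(self):
        if not (0 <= self.begin_s < self.end_s):
            raise ValueError(f"require 0 <= begin < end, got [{self.begin_s}, {self.end_s}]")
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(f"require 0 <= low < high freq, got [{self.low_hz}, {self.high_hz}]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


@dataclass
class ClassMap:
    """Mapping of annotation tags to detection-target class indices.

    ``class_names`` lists the target classes in index order (the deployed
    configuration has 32: 30 katydid classes covering 31 species after one
    merge, one bat class, one catch-all reject class). ``merges`` maps extra
    tags onto an existing class name. The ``background_tag`` maps to *no*
    class. ``penalty_classes`` names classes whose (short) calls receive the
    sound-centralization penalty; ``focal_advance`` gives the per-class
    segment advance used when preparing focal recordings (class-balance
    control).
    """

    class_names: list[str]
    merges: dict[str, str] = field(default_factory=dict)
    background_tag: str = "background"
    reject_class: str | None = None
    penalty_classes: frozenset[str] = frozenset()
    focal_advance: dict[str, float] = field(default_factory=dict)
    default_focal_advance: float = 0.2

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.background_tag in self.class_names:
            raise ValueError("background tag must not name a class")
        self._index = {name: i for i, name in enumerate(self.class_names)}
        for tag, target in self.merges.items():
            if target not in self._index:
                raise ValueError(f"merge target {target!r} is not a class")
            self._index.setdefault(tag, self._index[target])
        if self.reject_class is not None and self.reject_class not in self.class_names:
            raise ValueError(f"reject class {self.reject_class!r} is not a class")
        unknown = set(self.penalty_classes) - set(self.class_names)
        if unknown:
            raise ValueError(f"penalty classes not in class list: {sorted(unknown)}")

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def is_background(self, tag: str) -> bool:
        return tag == self.background_tag

    def index_of(self, tag: str) -> int:
        """Class index for a tag (after merges); background has no index."""
        try:
            return self._index[tag]
        except KeyError:
            raise KeyError(
                f"tag {tag!r} is neither a class, a merged tag, nor the background tag"
            ) from None

    def has_penalty(self, class_index: int) -> bool:
        return self.class_names[class_index] in self.penalty_classes

    def advance_for(self, class_name: str) -> float:
        return self.focal_advance.get(class_name, self.default_focal_advance)


#: A per-segment soft ground-truth vector (one score in [0,1] per class).
LabelVector = np.ndarray


def read_selection_table(path, tag_column: str = DEFAULT_TAG_COLUMN) -> list[Annotation]:
    """Read a Raven Pro selection table.

    Rows duplicated across Raven "views" (Spectrogram/Waveform) are
    de-duplicated by selection number when a ``Selection`` column exists.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_COLUMNS + (tag_column,):
        if col not in df.columns:
            raise SelectionTableError(f"{path}: missing required column {col!r}")
    if "Selection" in df.columns:
        df = df.drop_duplicates(subset="Selection", keep="first")
    out = []
    for row_no, row in df.iterrows():
        try:
            values = [float(row[c]) for c in REQUIRED_COLUMNS]
        except (TypeError, ValueError) as exc:
            raise SelectionTableError(
                f"{path}: unparsable numeric cell in data row {row_no + 1}: {exc}"
            ) from None
        try:
            out.append(Annotation(*values, tag=str(row[tag_column])))
        except ValueError as exc:
            raise SelectionTableError(f"{path}: data row {row_no + 1}: {exc}") from None
    return out


def write_selection_table(items, path, tag_column: str = DEFAULT_TAG_COLUMN) -> None:
    """Write annotations or detections as a Raven Pro selection table.

    Accepts :class:`Annotation` objects or any item with ``begin_s``/``end_s``
    and either a ``tag`` or a ``class_name`` plus optional ``score``
    attribute (detections). Times are printed with 9 decimals so a
    write-then-read round trip preserves coordinates.
    """
    rows = []
    for i, item in enumerate(items, start=1):
        tag = getattr(item, "tag", None)
        if tag is None:
            tag = getattr(item, "class_name", "")
        row = {
            "Selection": i,
            "View": "Spectrogram 1",
            "Channel": 1,
            "Begin Time (s)": f"{item.begin_s:.9f}",
            "End Time (s)": f"{item.end_s:.9f}",
            "Low Freq (Hz)": f"{getattr(item, 'low_hz', 0.0):.1f}",
            "High Freq (Hz)": f"{getattr(item, 'high_hz', 48000.0):.1f}",
            tag_column: tag,
        }
        score = getattr(item, "score", None)
        if score is not None:
            row["Score"] = f"{score:.6f}"
        rows.append(row)
    columns = ["Selection", "View", "Channel", *REQUIRED_COLUMNS, tag_column]
    if rows and "Score" in rows[0]:
        columns.append("Score")
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def centralization_penalty(segment: Segment, annotation: Annotation) -> float:
    """Sound-centralization penalty factor in [0, 1] for short calls.

    Annotations of at least 0.4 s, annotations lying (after clipping to the
    segment) wholly inside the central 25-75% band, and annotations spanning
    the segment's mid-epoch are not penalized (factor 1). Otherwise the
    factor is ``1 - delta/0.4`` where ``delta`` is the shortest temporal
    distance from the segment centre to the clipped annotation. Overlapping
    clipped annotations always give ``delta <= 0.4``, so the factor is
    non-negative.
    """
    if annotation.duration_s >= PENALTY_MAX_DURATION_S:
        return 1.0
    length = segment.duration_s
    # relative coordinates of the annotation clipped to the segment extent
    rel0 = max(annotation.begin_s, segment.start_s) - segment.start_s
    rel1 = min(annotation.end_s, segment.end_s) - segment.start_s
    if rel1 <= rel0:
        return 1.0  # no overlap: nothing to penalize
    centre = length / 2.0
    band_lo, band_hi = 0.25 * length, 0.75 * length
    if rel0 >= band_lo and rel1 <= band_hi:
        return 1.0
    if rel0 <= centre <= rel1:
        return 1.0
    delta = rel0 - centre if rel0 > centre else centre - rel1
    return 1.0 - delta / (length / 2.0)


def assign_labels(segment: Segment, annotations, class_map: ClassMap) -> LabelVector:
    """Soft ground-truth scores for one segment.

    Per class, the score is the maximum over that class's overlapping
    annotations of: 1.0 if one of segment/annotation temporally contains the
    other, else ``overlap / min(segment_length, annotation_duration)``. For
    penalty-flagged classes with calls shorter than 0.4 s, focal-provenance
    segments multiply in the centralization penalty. Background-tagged
    periods contribute nothing.
    """
    scores = np.zeros(class_map.num_classes, dtype=np.float64)
    s0, s1 = segment.start_s, segment.end_s
    length = segment.duration_s
    for ann in annotations:
        if class_map.is_background(ann.tag):
            continue
        try:
            ci = class_map.index_of(ann.tag)
        except KeyError as exc:
            raise KeyError(f"segment {segment.identifier!r}: {exc.args[0]}") from None
        ov = _overlap(s0, s1, ann.begin_s, ann.end_s)
        if ov <= 0:
            continue
        contained = (s0 <= ann.begin_s and ann.end_s <= s1) or (ann.begin_s <= s0 and s1 <= ann.end_s)
        score = 1.0 if contained else ov / min(length, ann.duration_s)
        if (
            class_map.has_penalty(ci)
            and segment.provenance == "focal"
            and ann.duration_s < PENALTY_MAX_DURATION_S
        ):
            score *= centralization_penalty(segment, ann)
        scores[ci] = max(scores[ci], score)
    return scores


def collect_background(recording: Recording, annotations, class_map: ClassMap,
                       training_advance_s: float = 0.2,
                       additive_advance_s: float = 0.1) -> tuple[list[Segment], list[Segment]]:
    """Background segment pools from an in-situ recording.

    Two passes over the recording: at 0.2 s advance for background *training*
    segments (all-zero label vectors) and at 0.1 s advance for *additive
    background* segments which feed the background-infusion augmentation and
    never enter the class-assigned training set. A segment qualifies only if
    it is fully contained in a background-tagged annotation and overlaps no
    class-tagged annotation.
    """
    if recording.provenance != "insitu":
        raise ValueError("background pools are collected from in-situ recordings only")
    bg = [a for a in annotations if class_map.is_background(a.tag)]
    fg = [a for a in annotations if not class_map.is_background(a.tag)]

    def qualifies(seg: Segment) -> bool:
        inside = any(a.begin_s <= seg.start_s and seg.end_s <= a.end_s for a in bg)
        clean = all(_overlap(seg.start_s, seg.end_s, a.begin_s, a.end_s) == 0 for a in fg)
        return inside and clean

    training = [s for s in segment_audio(recording, advance_s=training_advance_s) if qualifies(s)]
    additive = [s for s in segment_audio(recording, advance_s=additive_advance_s) if qualifies(s)]
    return training, additive
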