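"""Sliding-window inference and detection grouping.

Inference slides 0.8 s windows over a conditioned recording at a fixed 0.2 s
advance, producing one per-class score vector per window (no augmentation,
noise floor fixed at -100 dB). A threshold tau then marks positive windows,
and per class, maximal runs of consecutive positive windows are merged into
single detections whose time extents are refined by window algebra:

* a lone positive window reports its own boundaries, ``[t, t+0.8]``;
* runs of 2, 3 or 4 windows report the run's temporal intersection —
  0.6, 0.4 or 0.2 s respectively (4-window groups are the most overlapped);
* longer runs contain a contiguous sequence of 0.2 s most-overlapped
  (4-window) periods and report the span from the first to the last of
  them: ``[t_first + 0.6, t_first + (k-4)*0.2 + 0.8]`` for a k-window run.

All reported extents are therefore multiples of 0.2 s; the detection score
is the maximum window score in the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from katydet.signals import Recording, SEGMENT_LENGTH_S, segment_audio

__all__ = [
    "INFERENCE_ADVANCE_S",
    "ScoreTrack",
    "Detection",
    "score_recording",
    "group_detections",
    "sweep_thresholds",
    "default_thresholds",
]

INFERENCE_ADVANCE_S = 0.2


@dataclass
class ScoreTrack:
    """Per-window class scores for one recording.

    ``scores`` has shape (n_windows, n_classes); window i covers
    ``[i*advance, i*advance + length)`` seconds.
    """

    scores: np.ndarray
    advance_s: float = INFERENCE_ADVANCE_S
    length_s: float = SEGMENT_LENGTH_S
    class_names: list[str] | None = None
    identifier: str = ""

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class Detection:
    """A class-tagged detection with refined time extents."""

    class_index: int
    begin_s: float
    end_s: float
    score: float
    group_size: int
    class_name: str = ""
    identifier: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


def score_recording(model, recording: Recording, advance_s: float = INFERENCE_ADVANCE_S,
                    class_names: list[str] | None = None,
                    batch_size: int = 32) -> ScoreTrack:
    """Score a conditioned recording with sliding 0.8 s windows.

    ``model`` is anything with ``predict_scores(spectrogram_batch)`` (a
    :class:`~katydet.network.QuasiDenseNet`). Recordings shorter than one
    window yield an empty track.
    """
    from katydet.frontend import to_model_input
    from katydet.signals import normalize

    segments = segment_audio(recording, advance_s=advance_s)
    if not segments:
        n_classes = len(class_names) if class_names else 0
        return ScoreTrack(scores=np.zeros((0, max(n_classes, 1))), advance_s=advance_s,
                          class_names=class_names, identifier=recording.identifier)
    spect = np.asarray([to_model_input(normalize(s)) for s in segments], dtype=np.float32)
    scores = model.predict_scores(spect, batch_size=batch_size)
    return ScoreTrack(scores=scores, advance_s=advance_s,
                      class_names=class_names, identifier=recording.identifier)


def _run_extent(start_index: int, k: int, advance: float, length: float) -> tuple[float, float]:
    """Time extent reported for a k-window run starting at window ``start_index``."""
    t0 = start_index * advance
    if k == 1:
        return t0, t0 + length
    max_group = int(round(length / advance))  # windows sharing a common overlap (4)
    if k <= max_group:
        # intersection of all k windows
        return t0 + (k - 1) * advance, t0 + length
    # first through last 4-window most-overlapped period
    return (t0 + (max_group - 1) * advance,
            t0 + (k - max_group) * advance + length)


def group_detections(track: ScoreTrack, tau: float) -> list[Detection]:
    """Convert a score track into grouped detections at threshold tau.

    Windows with score >= tau are positive; per class, each maximal run of
    consecutive positive windows becomes exactly one detection (see module
    docstring for the extent rules). Detections are emitted in (class,
    begin time) order.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {tau}")
    out: list[Detection] = []
    n_windows, n_classes = track.scores.shape
    for ci in range(n_classes):
        positive = track.scores[:, ci] >= tau
        i = 0
        while i < n_windows:
            if not positive[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_windows and positive[j + 1]:
                j += 1
            k = j - i + 1
            begin, end = _run_extent(i, k, track.advance_s, track.length_s)
            out.append(
                Detection(
                    class_index=ci,
                    begin_s=begin,
                    end_s=end,
                    score=float(track.scores[i : j + 1, ci].max()),
                    group_size=k,
                    class_name=track.class_names[ci] if track.class_names else str(ci),
                    identifier=track.identifier,
                )
            )
            i = j + 1
    return out


def default_thresholds() -> np.ndarray:
    """The standard sweep: 0 to 1 in steps of 0.05 (21 points)."""
    return np.round(np.arange(0, 21) * 0.05, 2)


def sweep_thresholds(track: ScoreTrack, taus=None) -> dict[float, list[Detection]]:
    """Grouped detections for each threshold in an ascending sweep."""
    taus = default_thresholds() if taus is None else np.asarray(taus, dtype=float)
    if np.any((taus < 0) | (taus > 1)):
        raise ValueError("thresholds must lie in [0, 1]")
    if np.any(np.diff(taus) < 0):
        raise ValueError("thresholds must be sorted ascending")
    return {float(tau): group_detections(track, float(tau)) for tau in taus}
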