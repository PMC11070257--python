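"""End-to-end pipeline: corpus on disk -> prepared segments -> model -> detections.

Glue between the spec-level modules, used by the command-line interface and
by the scaled-down benchmark runs. A corpus directory follows the layout
written by :func:`katydet.synth.make_benchmark`: per-split subdirectories of
WAV files, each with a matching ``<name>.selections.txt`` Raven table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from katydet import annotations as anns
from katydet import signals
from katydet.annotations import ClassMap, read_selection_table
from katydet.detect import ScoreTrack, group_detections, score_recording
from katydet.evaluate import pr_curve
from katydet.network import (
    ArchitectureConfig,
    QuasiDenseNet,
    SpectrogramClassifier,
    TrainingSchedule,
)
from katydet.signals import Recording, Segment, read_wav

__all__ = [
    "PreparedDataset",
    "prepare_recording",
    "prepare_corpus",
    "reduced_architecture",
    "reduced_schedule",
    "train_on_corpus",
    "infer_recording",
    "evaluate_files",
]

logger = logging.getLogger(__name__)


@dataclass
class PreparedDataset:
    """Intermediate output of input preparation: segments + soft labels.

    ``background_pool`` holds additive-background waveforms (never part of
    the class-assigned training set); ``dataset`` pairs each retained,
    normalized segment with its label vector (all-zero for background
    training segments).
    """

    dataset: list[tuple[Segment, np.ndarray]] = field(default_factory=list)
    background_pool: list[np.ndarray] = field(default_factory=list)
    class_map: ClassMap | None = None

    def labels(self) -> np.ndarray:
        return np.asarray([lab for _, lab in self.dataset])


def _selection_table_path(wav_path: Path) -> Path:
    return wav_path.parent / (wav_path.stem + ".selections.txt")


def prepare_recording(recording: Recording, annotations, class_map: ClassMap,
                      advance_s: float | None = None) -> list[tuple[Segment, np.ndarray]]:
    """Condition, segment and label one recording; keep annotated segments.

    The advance defaults to the class map's per-class focal advance for
    focal recordings (single dominant class, determined from the
    annotations) and 0.2 s otherwise. Only segments with a non-zero label
    vector are retained here — background pools are collected separately.
    """
    conditioned = signals.condition(recording)
    if advance_s is None:
        advance_s = 0.2
        if recording.provenance == "focal":
            tags = [a.tag for a in annotations if not class_map.is_background(a.tag)]
            if tags:
                advance_s = class_map.advance_for(class_map.class_names[
                    class_map.index_of(tags[0])])
    out = []
    for seg in signals.segment_audio(conditioned, advance_s=advance_s):
        label = anns.assign_labels(seg, annotations, class_map)
        if label.any():
            out.append((signals.normalize(seg), label))
    return out


def prepare_corpus(corpus_dir, class_map: ClassMap) -> PreparedDataset:
    """Prepare a full corpus directory (focal + insitu splits).

    Focal files yield class-labelled segments at the per-class advance;
    in-situ files yield class-labelled segments (0.2 s advance), background
    training segments (0.2 s) and the additive-background pool (0.1 s).
    """
    corpus = Path(corpus_dir)
    prepared = PreparedDataset(class_map=class_map)
    for wav in sorted((corpus / "focal").glob("*.wav")):
        rec = read_wav(wav, provenance="focal")
        table = read_selection_table(_selection_table_path(wav))
        prepared.dataset.extend(prepare_recording(rec, table, class_map))
    insitu_dir = corpus / "insitu"
    if insitu_dir.is_dir():
        for wav in sorted(insitu_dir.glob("*.wav")):
            rec = read_wav(wav, provenance="insitu")
            table = read_selection_table(_selection_table_path(wav))
            conditioned = signals.condition(rec)
            prepared.dataset.extend(prepare_recording(rec, table, class_map, advance_s=0.2))
            bg_train, bg_add = anns.collect_background(conditioned, table, class_map)
            zero = np.zeros(class_map.num_classes)
            prepared.dataset.extend((signals.normalize(s), zero.copy()) for s in bg_train)
            prepared.background_pool.extend(
                signals.normalize(s).samples for s in bg_add
            )
    logger.info(
        "prepared %d segments (%d background waveforms in additive pool)",
        len(prepared.dataset), len(prepared.background_pool),
    )
    return prepared


def reduced_architecture(num_classes: int) -> ArchitectureConfig:
    """Desk-scale configuration: same block family, narrower and shallower.

    An initial frequency-only (6, 1) average pool shrinks the input to
    34x319 before the dense blocks — frequency resolution drops to 1.2 kHz
    but the 2.5 ms time base, which carries the inter-pulse-interval
    discrimination, is preserved. Three blocks with growth 8 keep CPU
    training in the minutes range while retaining every architectural
    ingredient.
    """
    return ArchitectureConfig(
        pre_conv_filters=12,
        num_blocks=3,
        growth_rate=12,
        bottleneck_factor=2,
        compression=0.4,
        head_width=48,
        num_classes=num_classes,
        pre_pool=(6, 1),
    )


def reduced_schedule(seed: int = 0, epochs: int = 10) -> TrainingSchedule:
    """Scaled-down schedule: 10 epochs, mini-batches of 16 (more updates per
    epoch on a small corpus), LR drops at 6 and 9, gradient clipping at
    global norm 1.0 (stabilizes the short high-rate phase)."""
    return TrainingSchedule(epochs=epochs, batch_size=16, lr_drop_epochs=(6, 9),
                            clip_norm=1.0, seed=seed)


def train_on_corpus(corpus_dir, class_map: ClassMap | None = None,
                    config: ArchitectureConfig | None = None,
                    schedule: TrainingSchedule | None = None,
                    augment: bool = True, seed: int = 0) -> SpectrogramClassifier:
    """Prepare a corpus and fit the classifier on it (full pipeline, train side)."""
    from katydet.synth import benchmark_class_map

    class_map = class_map or benchmark_class_map()
    prepared = prepare_corpus(corpus_dir, class_map)
    config = config or reduced_architecture(class_map.num_classes)
    schedule = schedule or reduced_schedule(seed)
    clf = SpectrogramClassifier(config=config, schedule=schedule, augment=augment, seed=seed)
    clf.fit(
        [seg for seg, _ in prepared.dataset],
        prepared.labels(),
        background_pool=prepared.background_pool or None,
    )
    return clf


def infer_recording(model: QuasiDenseNet, recording: Recording,
                    class_map: ClassMap, tau: float = 0.5):
    """Condition, score and group one recording into detections."""
    conditioned = signals.condition(recording)
    track = score_recording(model, conditioned, class_names=class_map.class_names)
    return track, group_detections(track, tau)


def evaluate_files(model: QuasiDenseNet, wav_paths, class_map: ClassMap, taus=None):
    """Score test files and compute the pooled/per-class PR characterization."""
    tracks, gts = [], []
    for wav in wav_paths:
        rec = read_wav(Path(wav), provenance="field")
        conditioned = signals.condition(rec)
        tracks.append(score_recording(model, conditioned, class_names=class_map.class_names))
        table = read_selection_table(_selection_table_path(Path(wav)))
        gts.append([
            (class_map.index_of(a.tag), a)
            for a in table
            if not class_map.is_background(a.tag)
        ])
    return pr_curve(tracks, gts, class_map.num_classes, taus=taus)
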