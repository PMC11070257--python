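"""Synthetic katydid-like calls, soundscapes and a reproducible benchmark corpus.

Katydid calls are modelled as trains of short windowed tonal (optionally
frequency-swept) pulses: pulse durations down to ~1 ms, species-specific
inter-pulse intervals, and centre frequencies in the 7-47 kHz band. The
discriminatory axes mirror the real problem — templates may share a centre
frequency and differ only in inter-pulse interval (the hardest case) or
differ spectrally.

Three recording styles are generated:

* **focal** — near-silent background, one class per file, high SNR (clean
  captive-individual recordings);
* **in-situ** — calls at moderate SNR over pink ambient noise, with
  explicitly annotated ``background`` periods (these feed the background
  training and additive-background pools);
* **test soundscapes** — calls of all classes planted at controlled in-band
  SNR over pink noise, with exact ground-truth selection tables.

Planted call extents equal the emitted annotation extents exactly, and a
fixed seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from katydet.annotations import Annotation, ClassMap, write_selection_table
from katydet.signals import Recording, TARGET_RATE, write_wav

__all__ = [
    "CallTemplate",
    "synth_call",
    "pink_noise",
    "synth_soundscape",
    "make_benchmark",
    "default_templates",
    "benchmark_class_map",
]

logger = logging.getLogger(__name__)

FREQ_BAND_HZ = (7_000.0, 47_000.0)
MIN_PULSE_MS = 0.8  # shortest pulses produced by Phaneropterinae


@dataclass(frozen=True)
class CallTemplate:
    """Parametric description of one species-like call type.

    ``inter_pulse_interval_ms`` is the silent gap between consecutive
    pulses, so call duration = n*pulse + (n-1)*interval. ``modulation``
    is ``"none"`` (constant carrier) or ``"sweep"`` (linear chirp across
    ``bandwidth_hz`` centred on ``centre_frequency_hz``).
    """

    class_name: str
    pulse_duration_ms: float
    inter_pulse_interval_ms: float
    pulses_per_call: int
    centre_frequency_hz: float
    bandwidth_hz: float = 2_000.0
    amplitude: float = 0.9
    modulation: str = "none"

    def __post_init__(self):
        if self.pulse_duration_ms < MIN_PULSE_MS:
            raise ValueError(
                f"pulse duration {self.pulse_duration_ms} ms below the {MIN_PULSE_MS} ms minimum"
            )
        if self.pulses_per_call < 1:
            raise ValueError("pulses_per_call must be >= 1")
        lo = self.centre_frequency_hz - self.bandwidth_hz / 2
        hi = self.centre_frequency_hz + self.bandwidth_hz / 2
        if lo < FREQ_BAND_HZ[0] or hi > FREQ_BAND_HZ[1]:
            raise ValueError(
                f"{self.class_name}: band [{lo}, {hi}] Hz outside {FREQ_BAND_HZ}"
            )
        if self.modulation not in ("none", "sweep"):
            raise ValueError(f"unknown modulation {self.modulation!r}")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")

    @property
    def duration_s(self) -> float:
        n = self.pulses_per_call
        return (n * self.pulse_duration_ms + (n - 1) * self.inter_pulse_interval_ms) / 1000.0

    @property
    def low_hz(self) -> float:
        return self.centre_frequency_hz - self.bandwidth_hz / 2

    @property
    def high_hz(self) -> float:
        return self.centre_frequency_hz + self.bandwidth_hz / 2


def synth_call(template: CallTemplate, rate: float = TARGET_RATE,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Waveform of one call: a train of Hann-windowed tonal/swept pulses.

    The per-pulse phase is randomized (seeded) so repeated calls are not
    bit-identical copies; the spectral peak sits at the template's centre
    frequency.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pulse = max(int(round(template.pulse_duration_ms * rate / 1000.0)), 2)
    n_gap = int(round(template.inter_pulse_interval_ms * rate / 1000.0))
    t = np.arange(n_pulse) / rate
    window = np.hanning(n_pulse)
    pulses = []
    for _ in range(template.pulses_per_call):
        phase = rng.uniform(0, 2 * math.pi)
        if template.modulation == "sweep":
            f0 = template.centre_frequency_hz - template.bandwidth_hz / 2
            f1 = template.centre_frequency_hz + template.bandwidth_hz / 2
            inst = f0 + (f1 - f0) * t / t[-1]
            arg = 2 * math.pi * np.cumsum(inst) / rate + phase
        else:
            arg = 2 * math.pi * template.centre_frequency_hz * t + phase
        pulses.append(template.amplitude * window * np.sin(arg))
    gap = np.zeros(n_gap)
    parts = []
    for i, p in enumerate(pulses):
        parts.append(p)
        if i < len(pulses) - 1:
            parts.append(gap)
    return np.concatenate(parts)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f power) noise via spectral shaping."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.arange(n // 2 + 1, dtype=np.float64)
    freqs[0] = 1.0
    spec /= np.sqrt(freqs)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _inband_rms(x: np.ndarray, low_hz: float, high_hz: float, rate: float) -> float:
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos")
    return float(np.sqrt(np.mean(sps.sosfiltfilt(sos, x) ** 2)))


def synth_soundscape(
    templates: list[CallTemplate],
    calls_per_class: int,
    duration_s: float,
    snr_db: float = 15.0,
    noise_rms: float = 0.01,
    rate: float = TARGET_RATE,
    seed: int | np.random.Generator = 0,
    provenance: str = "field",
    identifier: str = "soundscape",
    min_gap_s: float = 0.25,
) -> tuple[Recording, list[Annotation]]:
    """Plant calls at seeded random offsets over pink background noise.

    Each planted call is scaled so its realized in-band SNR (call RMS over
    noise RMS, both measured through a band-pass at the call's frequency
    bounds over the call extent) equals ``snr_db``. Call placements avoid
    temporal overlap across all classes by at least ``min_gap_s``. Emitted
    annotations match planted extents exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    audio = noise_rms * pink_noise(n, rng)

    # keep one analysis-window length clear of the file edges: a call closer
    # than 0.8 s to an edge cannot be covered by a full run of windows
    edge_margin = 0.8
    slots: list[tuple[float, float]] = []
    annotations: list[Annotation] = []
    # longest calls placed first so the schedule fills greedily
    order = sorted(
        [(tpl, k) for tpl in templates for k in range(calls_per_class)],
        key=lambda tk: -tk[0].duration_s,
    )
    for tpl, _ in order:
        call = synth_call(tpl, rate, rng)
        dur = len(call) / rate
        placed = False
        for _attempt in range(2000):
            start = rng.uniform(edge_margin, duration_s - dur - edge_margin)
            if not any(start < e + min_gap_s and start + dur + min_gap_s > b for b, e in slots):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {calls_per_class} calls/class in {duration_s} s; "
                "schedule over-full"
            )
        i0 = int(round(start * rate))
        noise_band_rms = _inband_rms(audio[i0 : i0 + len(call)], tpl.low_hz, tpl.high_hz, rate)
        call_rms = float(np.sqrt(np.mean(call**2)))
        scale = 10 ** (snr_db / 20.0) * noise_band_rms / call_rms
        audio[i0 : i0 + len(call)] += scale * call
        begin = i0 / rate
        slots.append((begin, begin + dur))
        annotations.append(
            Annotation(begin_s=begin, end_s=begin + dur,
                       low_hz=tpl.low_hz, high_hz=tpl.high_hz, tag=tpl.class_name)
        )
    annotations.sort(key=lambda a: a.begin_s)
    peak = np.max(np.abs(audio))
    if peak > 1.0:
        audio /= peak * 1.01
    rec = Recording(samples=audio, rate=rate, provenance=provenance, identifier=identifier)
    return rec, annotations


def default_templates() -> list[CallTemplate]:
    """The three benchmark call types.

    ``pulser_slow`` and ``pulser_fast`` share a 12 kHz centre frequency and
    differ only in inter-pulse interval (the hardest discrimination axis);
    ``sweeper_high`` is a frequency-modulated call at 30 kHz. All durations
    sit in 0.366-0.393 s: short enough that the sound-centralization
    penalty applies, long enough that a well-centred run's refined extent
    can satisfy both coverage rules (a 4-window intersection of 0.2 s
    covers >= 50% of the call, and the call covers > 60% of runs up to six
    windows; durations avoid exact multiples of 0.6 x 0.2 s, where the
    strict 60% rule is undecidable for a 2-window run).
    """
    return [
        CallTemplate("pulser_slow", pulse_duration_ms=2.0, inter_pulse_interval_ms=40.0,
                     pulses_per_call=10, centre_frequency_hz=12_000.0, bandwidth_hz=4_000.0),
        CallTemplate("pulser_fast", pulse_duration_ms=2.0, inter_pulse_interval_ms=15.0,
                     pulses_per_call=24, centre_frequency_hz=12_000.0, bandwidth_hz=4_000.0),
        CallTemplate("sweeper_high", pulse_duration_ms=30.0, inter_pulse_interval_ms=26.0,
                     pulses_per_call=7, centre_frequency_hz=30_000.0, bandwidth_hz=6_000.0,
                     modulation="sweep"),
    ]


def benchmark_class_map(templates: list[CallTemplate] | None = None) -> ClassMap:
    """Class map for the synthetic benchmark (one class per template).

    All benchmark call types are shorter than 0.4 s, so the sound-
    centralization penalty is enabled for every class — edge-sitting calls
    in focal training windows get down-weighted labels, which keeps
    detection runs (and hence reported extents) centred on the call.
    """
    templates = templates or default_templates()
    short = frozenset(t.class_name for t in templates if t.duration_s < 0.4)
    return ClassMap(class_names=[t.class_name for t in templates],
                    penalty_classes=short)


def _focal_recording(tpl: CallTemplate, duration_s: float, rate: float,
                     rng: np.random.Generator, identifier: str) -> tuple[Recording, list[Annotation]]:
    """One clean focal file: repeated calls of a single class over a faint floor."""
    n = int(round(duration_s * rate))
    audio = 1e-4 * pink_noise(n, rng)  # near-silent background
    annotations = []
    t = rng.uniform(0.05, 0.3)
    while True:
        call = synth_call(tpl, rate, rng)
        dur = len(call) / rate
        if t + dur > duration_s - 0.05:
            break
        i0 = int(round(t * rate))
        audio[i0 : i0 + len(call)] += call
        annotations.append(Annotation(begin_s=i0 / rate, end_s=i0 / rate + dur,
                                      low_hz=tpl.low_hz, high_hz=tpl.high_hz, tag=tpl.class_name))
        t += dur + rng.uniform(0.3, 0.6)
    return (
        Recording(samples=audio, rate=rate, provenance="focal", identifier=identifier),
        annotations,
    )


def make_benchmark(
    out_dir,
    templates: list[CallTemplate] | None = None,
    seed: int = 0,
    rate: float = TARGET_RATE,
    n_focal_files: int = 6,
    focal_duration_s: float = 6.0,
    n_insitu_files: int = 2,
    insitu_duration_s: float = 20.0,
    insitu_snr_db: float = 20.0,
    n_test_files: int = 2,
    test_duration_s: float = 45.0,
    test_calls_per_class: int = 8,
    test_snr_db: float = 15.0,
) -> dict:
    """Generate a train/test corpus on disk.

    Layout: ``focal/<class>_<i>.wav``, ``insitu/insitu_<i>.wav``,
    ``test/test_<i>.wav``, each with a matching ``*.selections.txt`` Raven
    table. In-situ tables include explicit ``background`` annotations
    covering the call-free periods. Returns a manifest dict (paths keyed by
    split). A fixed seed reproduces the corpus exactly.
    """
    templates = templates or default_templates()
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    manifest: dict = {"focal": [], "insitu": [], "test": [],
                      "classes": [t.class_name for t in templates]}

    focal_dir, insitu_dir, test_dir = out / "focal", out / "insitu", out / "test"
    for d in (focal_dir, insitu_dir, test_dir):
        d.mkdir(parents=True, exist_ok=True)

    for tpl in templates:
        for i in range(n_focal_files):
            name = f"{tpl.class_name}_{i}"
            rec, anns = _focal_recording(tpl, focal_duration_s, rate, rng, name + ".wav")
            wav = focal_dir / (name + ".wav")
            write_wav(wav, rec)
            write_selection_table(anns, focal_dir / (name + ".selections.txt"))
            manifest["focal"].append(str(wav))

    for i in range(n_insitu_files):
        name = f"insitu_{i}"
        rec, anns = synth_soundscape(
            templates, calls_per_class=2, duration_s=insitu_duration_s,
            snr_db=insitu_snr_db, seed=rng, provenance="insitu",
            identifier=name + ".wav", min_gap_s=1.0,
        )
        # annotate the call-free stretches as background
        events = sorted((a.begin_s, a.end_s) for a in anns)
        cursor = 0.0
        for b, e in events + [(insitu_duration_s, insitu_duration_s)]:
            if b - cursor >= 1.0:
                anns.append(Annotation(begin_s=cursor + 0.05, end_s=b - 0.05,
                                       low_hz=0.0, high_hz=rate / 2, tag="background"))
            cursor = max(cursor, e)
        anns.sort(key=lambda a: a.begin_s)
        wav = insitu_dir / (name + ".wav")
        write_wav(wav, rec)
        write_selection_table(anns, insitu_dir / (name + ".selections.txt"))
        manifest["insitu"].append(str(wav))

    for i in range(n_test_files):
        name = f"test_{i}"
        # gap of at least one window length: calls closer than 0.8 s merge
        # into one run whose extent cannot satisfy the 60% coverage rule even
        # for a perfect detector, which would make the benchmark unscorable
        rec, anns = synth_soundscape(
            templates, calls_per_class=test_calls_per_class, duration_s=test_duration_s,
            snr_db=test_snr_db, seed=rng, provenance="field",
            identifier=name + ".wav", min_gap_s=0.85,
        )
        wav = test_dir / (name + ".wav")
        write_wav(wav, rec)
        write_selection_table(anns, test_dir / (name + ".selections.txt"))
        manifest["test"].append(str(wav))

    logger.info("benchmark corpus written to %s", out)
    return manifest
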