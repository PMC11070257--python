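"""Audio conditioning: resampling, high-pass filtering, normalization, segmentation.

All katydid species of interest call dominantly above ~7 kHz, so recordings are
high-pass filtered at 6.9 kHz (12th-order Butterworth) and resampled to a
common 96 kHz rate (Nyquist 48 kHz stays above the highest call components).
Continuous audio is then cut into fixed 0.8 s windows — long enough to capture
>= 4 pulses of pulsed calls, short enough that millisecond-scale calls still
occupy a significant fraction of the input.

Conventions: intervals are half-open ``[begin, end)`` in seconds; sample
offsets are 0-based; a trailing partial window is dropped, never padded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "TARGET_RATE",
    "SEGMENT_LENGTH_S",
    "Recording",
    "Segment",
    "read_wav",
    "write_wav",
    "resample",
    "highpass",
    "normalize",
    "segment_audio",
    "condition",
]

logger = logging.getLogger(__name__)

#: Common sampling rate all audio is conditioned to (Hz).
TARGET_RATE = 96_000
#: Analysis window length (s).
SEGMENT_LENGTH_S = 0.8
#: Default high-pass cutoff (Hz) and Butterworth order.
HIGHPASS_CUTOFF_HZ = 6_900.0
HIGHPASS_ORDER = 12

PROVENANCES = ("focal", "insitu", "playback", "field")


@dataclass
class Recording:
    """A single-channel audio recording.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (dimensionless, float).
    rate : float
        Sampling frequency in Hz; must be positive.
    provenance : str
        One of ``focal``, ``insitu``, ``playback`` or ``field``. Focal
        recordings are clean captive-individual recordings; in-situ and
        playback are field-like; ``field`` marks deployment soundscapes.
    identifier : str
        Source-file name (used to key annotations and detections).
    """

    samples: np.ndarray
    rate: float
    provenance: str = "field"
    identifier: str = ""

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}, got {self.provenance!r}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (single channel)")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Segment:
    """A fixed-length analysis window cut from a :class:`Recording`."""

    samples: np.ndarray
    start_s: float
    rate: float = TARGET_RATE
    provenance: str = "field"
    identifier: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def read_wav(path, provenance: str = "field", identifier: str | None = None) -> Recording:
    """Read a WAV file (PCM 16/24/32-bit or float) into a :class:`Recording`.

    Multi-channel files use channel 0 with a warning. Integer PCM is scaled
    to [-1, 1) by the type's full-scale value.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        logger.warning("%s has %d channels; using channel 0", path, data.shape[1])
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / max(abs(info.min), info.max)
    else:
        data = data.astype(np.float64)
    name = identifier if identifier is not None else str(path).rsplit("/", 1)[-1]
    return Recording(samples=data, rate=float(rate), provenance=provenance, identifier=name)


def write_wav(path, recording: Recording) -> None:
    """Write a recording as 32-bit float WAV."""
    wavfile.write(str(path), int(recording.rate), recording.samples.astype(np.float32))


def resample(recording: Recording, target_rate: float = TARGET_RATE) -> Recording:
    """Resample to ``target_rate`` by polyphase filtering (anti-aliased).

    Rational-ratio resampling (e.g. the 250 kHz -> 96 kHz focal-recording
    case reduces to 48/125) with a built-in anti-alias low-pass. A recording
    already at the target rate is returned unchanged.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if recording.rate == target_rate:
        return recording
    ratio = Fraction(target_rate / recording.rate).limit_denominator(10_000)
    out = sps.resample_poly(recording.samples, ratio.numerator, ratio.denominator)
    return replace(recording, samples=out, rate=float(target_rate))


def highpass(
    recording: Recording,
    cutoff: float = HIGHPASS_CUTOFF_HZ,
    order: int = HIGHPASS_ORDER,
) -> Recording:
    """Butterworth high-pass as a causal second-order-section cascade.

    Default 12th order at 6.9 kHz suppresses low-frequency ambient energy
    below the katydid band. Causal (forward-only) filtering matches streaming
    deployment; ~-3 dB at the cutoff, >= 60 dB suppression an octave below.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if cutoff >= recording.rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz is not below the Nyquist rate {recording.rate / 2} Hz"
        )
    sos = sps.butter(order, cutoff, btype="highpass", fs=recording.rate, output="sos")
    out = sps.sosfilt(sos, recording.samples)
    return replace(recording, samples=out)


def normalize(segment: Segment) -> Segment:
    """Scale a segment to peak absolute amplitude 1.0 (all-zero passes through)."""
    peak = np.max(np.abs(segment.samples)) if len(segment.samples) else 0.0
    if peak == 0.0:
        return segment
    return replace(segment, samples=segment.samples / peak)


def segment_audio(
    recording: Recording,
    length_s: float = SEGMENT_LENGTH_S,
    advance_s: float = 0.2,
) -> list[Segment]:
    """Cut a recording into fixed-length windows with the given advance.

    Windows start at 0, ``advance_s``, ``2*advance_s``, ...; the count is
    ``floor((duration - length_s) / advance_s) + 1`` for recordings at least
    ``length_s`` long. The segment advance (window length minus overlap) is
    the class-balance control knob during training-input preparation and is
    fixed at 0.2 s for inference. Too-short recordings produce an empty list.
    """
    if advance_s <= 0 or advance_s > length_s:
        raise ValueError(f"require 0 < advance_s <= length_s, got advance={advance_s}, length={length_s}")
    n = len(recording.samples)
    win = round(length_s * recording.rate)
    hop_samples = advance_s * recording.rate
    if n < win:
        logger.info("recording %s shorter than %g s; no segments", recording.identifier, length_s)
        return []
    count = int(math.floor((n - win) / hop_samples)) + 1
    out = []
    for i in range(count):
        start = int(round(i * hop_samples))
        out.append(
            Segment(
                samples=recording.samples[start : start + win],
                start_s=start / recording.rate,
                rate=recording.rate,
                provenance=recording.provenance,
                identifier=recording.identifier,
            )
        )
    return out


def condition(recording: Recording, target_rate: float = TARGET_RATE,
              cutoff: float = HIGHPASS_CUTOFF_HZ, order: int = HIGHPASS_ORDER) -> Recording:
    """Full conditioning chain: high-pass filter then resample to 96 kHz."""
    return resample(highpass(recording, cutoff=cutoff, order=order), target_rate)
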