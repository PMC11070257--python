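"""PSD spectrogram front end producing fixed-shape model inputs.

A 0.8 s, 96 kHz segment is transformed with a 5 ms (480-sample) Hann window at
50% overlap — 2.5 ms time steps and exactly 200 Hz frequency bins (transform
length equals window length, no zero padding). Clipping the one-sided PSD to
the 6.8-47.4 kHz katydid band leaves 204 frequency rows x 319 time frames.
The log conversion adds a small constant ``eps`` setting the spectrogram's
noise floor in dB full scale (-100 dB at the default ``eps = 1e-10``); during
training the floor is randomized by the variable-noise-floor augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from katydet.signals import Segment, TARGET_RATE

__all__ = [
    "WINDOW_SAMPLES",
    "HOP_SAMPLES",
    "BAND_HZ",
    "MODEL_INPUT_SHAPE",
    "Spectrogram",
    "psd_spectrogram",
    "clip_band",
    "to_model_input",
]

#: 5 ms Hann window at 96 kHz, 50% overlap.
WINDOW_SAMPLES = 480
HOP_SAMPLES = 240
ROW_SPACING_HZ = TARGET_RATE / WINDOW_SAMPLES  # 200 Hz
COLUMN_SPACING_S = HOP_SAMPLES / TARGET_RATE  # 2.5 ms
#: Retained frequency band (Hz), inclusive of bin centres.
BAND_HZ = (6_800.0, 47_400.0)
MODEL_INPUT_SHAPE = (204, 319)
DEFAULT_FLOOR_DB = -100.0


@dataclass
class Spectrogram:
    """Log-PSD matrix in dB full scale; rows = frequency low->high, cols = time."""

    values: np.ndarray
    row_spacing_hz: float = ROW_SPACING_HZ
    column_spacing_s: float = COLUMN_SPACING_S
    band_hz: tuple[float, float] = BAND_HZ

    @property
    def shape(self):
        return self.values.shape


def psd_spectrogram(segment: Segment) -> np.ndarray:
    """One-sided linear power spectral density matrix of a conditioned segment.

    Returns a (241, 319) non-negative array for a 0.8 s, 96 kHz segment:
    241 bins at 200 Hz spacing spanning 0-48 kHz, 319 frames at 2.5 ms.
    """
    if segment.rate != TARGET_RATE:
        raise ValueError(f"segment must be at {TARGET_RATE} Hz, got {segment.rate}")
    if len(segment.samples) != int(0.8 * TARGET_RATE):
        raise ValueError(
            f"segment must be 0.8 s ({int(0.8 * TARGET_RATE)} samples), got {len(segment.samples)}"
        )
    _, _, psd = sps.spectrogram(
        segment.samples,
        fs=TARGET_RATE,
        window=sps.get_window("hann", WINDOW_SAMPLES),
        nperseg=WINDOW_SAMPLES,
        noverlap=WINDOW_SAMPLES - HOP_SAMPLES,
        nfft=WINDOW_SAMPLES,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return psd


def clip_band(psd: np.ndarray, row_spacing_hz: float = ROW_SPACING_HZ) -> np.ndarray:
    """Retain PSD rows whose bin centres fall in the 6.8-47.4 kHz band.

    With 200 Hz bins that is rows 34..237 inclusive -> exactly 204 rows,
    order preserved low->high. Pure row selection; values are untouched.
    """
    if row_spacing_hz != ROW_SPACING_HZ:
        raise ValueError(f"expected {ROW_SPACING_HZ} Hz row spacing, got {row_spacing_hz}")
    lo = int(round(BAND_HZ[0] / ROW_SPACING_HZ))
    hi = int(round(BAND_HZ[1] / ROW_SPACING_HZ))
    if psd.shape[0] <= hi:
        raise ValueError(f"PSD has {psd.shape[0]} rows; need at least {hi + 1}")
    return psd[lo : hi + 1]


def to_model_input(segment: Segment, floor_db: float = DEFAULT_FLOOR_DB) -> np.ndarray:
    """Full front end: PSD -> band clip -> log with the given noise floor.

    Returns the 204 x 319 log-PSD model input in dB full scale. Inference
    uses the fixed -100 dB floor; training draws the floor from the
    variable-noise-floor augmentation instead.
    """
    from katydet.augment import variable_noise_floor  # avoid import cycle

    return variable_noise_floor(clip_band(psd_spectrogram(segment)), floor_db)
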