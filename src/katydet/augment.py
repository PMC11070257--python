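"""Label-preserving, physics-based data augmentations and their chaining.

Six augmentations emulate naturally occurring variation without touching
timing metadata (labels are computed before augmentation and never revisited):

* **echo** — add a dampened (l dB), delayed (t ms) copy of the waveform;
* **volume ramping** — linear amplitude envelope, 1.0 at one end down to
  ``10^(-l/20)`` at the other (source moving toward/away from the receiver);
* **background infuse** — mix a real ambient-noise segment (ramped, then
  scaled l dB below the focal segment's absolute peak) into a focal segment;
* **Gaussian noise** — additive noise whose realized peak sits exactly l dB
  below the signal peak;
* **variable noise floor** — randomize the log-conversion constant eps so the
  spectrogram noise floor varies over [-105, -85] dB full scale;
* **alter distance** — linear spectral tilt of 0..l dB from the lowest to the
  highest retained frequency (distance-dependent high-frequency attenuation).

Application probabilities and parameter ranges differ between focal and
non-focal (in-situ/playback) inputs; echo and background infusion apply to
focal inputs only, and for focal inputs Gaussian noise is applied (p = 0.25)
only when background infusion was not. The ordering above is the order of
application; all random draws are uniform over the configured ranges from a
single seedable generator per chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from katydet.frontend import clip_band, psd_spectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "echo",
    "volume_ramp",
    "background_infuse",
    "gaussian_noise",
    "variable_noise_floor",
    "alter_distance",
    "AugmentSpec",
    "AugmentChain",
    "build_chain",
    "FOCAL_PARAMS",
    "NONFOCAL_PARAMS",
]


def _db_to_lin(db: float) -> float:
    return 10.0 ** (db / 20.0)


def echo(waveform: np.ndarray, l_db: float, t_ms: float, rate: float) -> np.ndarray:
    """Add a dampened, delayed copy of the waveform to itself.

    ``out[n] = x[n] + 10^(l/20) * x[n - round(t*rate/1000)]``; the delayed
    copy is truncated at the segment end, so the length is unchanged.
    """
    delay = int(round(t_ms * rate / 1000.0))
    if delay >= len(waveform):
        raise ValueError(f"echo delay ({delay} samples) must be shorter than the segment")
    out = waveform.copy()
    if delay > 0:
        out[delay:] += _db_to_lin(l_db) * waveform[: len(waveform) - delay]
    else:
        out += _db_to_lin(l_db) * waveform
    return out


def volume_ramp(waveform: np.ndarray, l_db: float, attenuated_end: str = "last") -> np.ndarray:
    """Multiply by a linear envelope from 1.0 down to ``10^(-l/20)`` at one end."""
    if l_db < 0:
        raise ValueError(f"ramp attenuation must be >= 0 dB, got {l_db}")
    if attenuated_end not in ("first", "last"):
        raise ValueError("attenuated_end must be 'first' or 'last'")
    lo = _db_to_lin(-l_db)
    n = len(waveform)
    env = np.linspace(1.0, lo, n) if attenuated_end == "last" else np.linspace(lo, 1.0, n)
    return waveform * env


def background_infuse(
    signal: np.ndarray,
    noise: np.ndarray,
    ramp_db: float,
    atten_db: float,
    attenuated_end: str = "last",
) -> np.ndarray:
    """Mix an additive-background segment into a focal segment.

    The noise is volume-ramped, then scaled so its absolute peak sits
    ``atten_db`` dB below the signal's absolute peak, then summed. With
    ``atten_db <= -12`` the focal signal stays dominant.
    """
    peak = np.max(np.abs(signal))
    if peak == 0.0:
        raise ValueError("background infusion needs a non-zero focal signal (peak-relative scaling)")
    if len(noise) != len(signal):
        raise ValueError("noise and signal segments must have equal length")
    ramped = volume_ramp(noise, ramp_db, attenuated_end)
    noise_peak = np.max(np.abs(ramped))
    if noise_peak == 0.0:
        return signal.copy()
    return signal + ramped * (_db_to_lin(atten_db) * peak / noise_peak)


def gaussian_noise(waveform: np.ndarray, l_db: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise whose realized peak is l dB below the signal peak.

    The noise draw is rescaled so its maximum absolute amplitude hits the
    target level exactly (the contract is on the peak, not the SD).
    """
    peak = np.max(np.abs(waveform))
    if peak == 0.0:
        raise ValueError("Gaussian-noise augmentation needs a non-zero input (peak-relative level)")
    rng = np.random.default_rng() if rng is None else rng
    noise = rng.standard_normal(len(waveform))
    noise *= _db_to_lin(l_db) * peak / np.max(np.abs(noise))
    return waveform + noise


def variable_noise_floor(linear_psd: np.ndarray, floor_db: float) -> np.ndarray:
    """Log-convert a linear PSD with the additive constant set by ``floor_db``.

    ``out = 10*log10(psd + eps)`` with ``eps = 10^(floor_db/10)``; an all-zero
    PSD maps to a constant matrix at ``floor_db`` (dB full scale). Training
    draws ``floor_db`` in [-105, -85]; inference fixes it at -100.
    """
    if floor_db >= 0:
        raise ValueError(f"noise floor must be negative dB full scale, got {floor_db}")
    eps = 10.0 ** (floor_db / 10.0)
    return 10.0 * np.log10(linear_psd + eps)


def alter_distance(log_spectrogram: np.ndarray, l_db: float) -> np.ndarray:
    """Linear spectral tilt: row i gains ``l * i/(R-1)`` dB (rows low->high).

    Negative l attenuates high frequencies (greater source-receiver
    distance); positive l amplifies them. Identical offset on every frame.
    """
    rows = log_spectrogram.shape[0]
    if rows < 2:
        return log_spectrogram + 0.0
    tilt = l_db * np.arange(rows) / (rows - 1)
    return log_spectrogram + tilt[:, None]


@dataclass
class AugmentSpec:
    """Probability and parameter ranges for one augmentation kind."""

    kind: str
    domain: str  # "time" | "spectral"
    probability: float
    ranges: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0,1], got {self.probability}")
        if self.domain not in ("time", "spectral"):
            raise ValueError(f"domain must be 'time' or 'spectral', got {self.domain!r}")
        for name, bounds in self.ranges.items():
            if name == "conditional":
                continue
            lo, hi = bounds
            if lo > hi:
                raise ValueError(f"{self.kind}.{name}: range [{lo}, {hi}] not ordered")


#: Per-provenance application probabilities and uniform parameter ranges.
FOCAL_PARAMS = dict(
    echo=dict(probability=0.20, l_db=(-24.0, -15.0), t_ms=(1.0, 6.0)),
    volume_ramp=dict(probability=0.33, l_db=(0.0, 6.0)),
    background_infuse=dict(probability=0.67, ramp_db=(0.0, 9.0), atten_db=(-18.0, -12.0)),
    gaussian_noise=dict(probability=0.25, l_db=(-24.0, -15.0), conditional=True),
    variable_noise_floor=dict(probability=1.00, floor_db=(-105.0, -85.0)),
    alter_distance=dict(probability=0.33, l_db=(-6.0, -3.0)),
)
NONFOCAL_PARAMS = dict(
    echo=None,
    volume_ramp=dict(probability=0.33, l_db=(0.0, 6.0)),
    background_infuse=None,
    gaussian_noise=dict(probability=0.75, l_db=(-45.0, -30.0), conditional=False),
    variable_noise_floor=dict(probability=1.00, floor_db=(-105.0, -85.0)),
    alter_distance=dict(probability=0.25, l_db=(-3.0, 3.0)),
)

_ORDER = ("echo", "volume_ramp", "background_infuse", "gaussian_noise",
          "variable_noise_floor", "alter_distance")
_DOMAIN = dict(echo="time", volume_ramp="time", background_infuse="time",
               gaussian_noise="time", variable_noise_floor="spectral",
               alter_distance="spectral")


@dataclass
class AugmentChain:
    """Ordered, probabilistic augmentation chain for one provenance group.

    Applied on the fly inside the training data stream, once per input per
    epoch: each augmentation fires independently with its configured
    probability, with parameters drawn uniformly from the provenance's
    ranges. For focal inputs Gaussian noise is only eligible when background
    infusion did not fire (then p = 0.25). A single seeded generator drives
    every draw, so a fixed seed reproduces augmented batches exactly.
    """

    provenance: str
    specs: list[AugmentSpec]
    rng: np.random.Generator

    def _spec(self, kind: str) -> AugmentSpec | None:
        for s in self.specs:
            if s.kind == kind:
                return s
        return None

    def draw_plan(self) -> dict:
        """Draw which augmentations fire and with which parameters.

        Exposed separately from :meth:`process` so application frequencies
        can be audited; all draws come from the chain's generator in chain
        order.
        """
        plan: dict = {}
        infused = False
        for kind in _ORDER:
            spec = self._spec(kind)
            if spec is None:
                continue
            if kind == "gaussian_noise" and spec.ranges.get("conditional") and infused:
                continue
            if self.rng.random() >= spec.probability:
                continue
            params = {
                name: self.rng.uniform(bounds[0], bounds[1])
                for name, bounds in spec.ranges.items()
                if name != "conditional"
            }
            if kind in ("volume_ramp", "background_infuse"):
                params["attenuated_end"] = "first" if self.rng.random() < 0.5 else "last"
            plan[kind] = params
            if kind == "background_infuse":
                infused = True
        if plan:
            logger.debug("augment plan (%s): %s", self.provenance, plan)
        return plan

    def process(
        self,
        waveform: np.ndarray,
        rate: float,
        background_pool: list[np.ndarray] | None = None,
        plan: dict | None = None,
    ) -> np.ndarray:
        """Augment one waveform and return the 204 x 319 log-PSD model input.

        Time-domain augmentations run on the waveform, then the PSD front end,
        then the spectral-domain augmentations. ``variable_noise_floor``
        always fires, so the log conversion happens here in every case.
        """
        from katydet.signals import Segment  # local to avoid cycle

        if plan is None:
            plan = self.draw_plan()
        x = np.asarray(waveform, dtype=np.float64)
        if "echo" in plan:
            x = echo(x, plan["echo"]["l_db"], plan["echo"]["t_ms"], rate)
        if "volume_ramp" in plan:
            p = plan["volume_ramp"]
            x = volume_ramp(x, p["l_db"], p["attenuated_end"])
        if "background_infuse" in plan and background_pool:
            p = plan["background_infuse"]
            noise = background_pool[self.rng.integers(len(background_pool))]
            if np.max(np.abs(x)) > 0:
                x = background_infuse(x, noise, p["ramp_db"], p["atten_db"], p["attenuated_end"])
        if "gaussian_noise" in plan and np.max(np.abs(x)) > 0:
            x = gaussian_noise(x, plan["gaussian_noise"]["l_db"], self.rng)
        seg = Segment(samples=x, start_s=0.0, rate=rate, provenance=self.provenance)
        spec = clip_band(psd_spectrogram(seg))
        floor = plan.get("variable_noise_floor", {}).get("floor_db", -100.0)
        out = variable_noise_floor(spec, floor)
        if "alter_distance" in plan:
            out = alter_distance(out, plan["alter_distance"]["l_db"])
        return out


def build_chain(provenance: str, seed: int | np.random.Generator = 0) -> AugmentChain:
    """Augmentation chain with the configured probabilities for a provenance group.

    ``provenance`` is ``"focal"`` or ``"non-focal"`` (in-situ and playback
    inputs share the non-focal settings).
    """
    if provenance == "focal":
        table = FOCAL_PARAMS
    elif provenance in ("non-focal", "nonfocal", "insitu", "playback"):
        table = NONFOCAL_PARAMS
        provenance = "non-focal"
    else:
        raise ValueError(f"unknown provenance {provenance!r}; use 'focal' or 'non-focal'")
    specs = []
    for kind in _ORDER:
        entry = table[kind]
        if entry is None:
            continue
        ranges = {k: v for k, v in entry.items() if k != "probability"}
        specs.append(AugmentSpec(kind=kind, domain=_DOMAIN[kind],
                                 probability=entry["probability"],
                                 ranges=ranges))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return AugmentChain(provenance=provenance, specs=specs, rng=rng)
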