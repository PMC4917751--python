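"""Synthetic annotated iEEG epochs: background, sharp trains, SSW runs.

Each epoch is 5 s at 1600 Hz by default and carries per-wave ground truth:

* **normal** -- 1/f colored background noise (default RMS 20 uV) plus a faint
  rhythmic component, no annotations;
* **sharp** -- background plus a train of narrow high-amplitude deflections
  (cusp-apex pulses with convex flanks, width 45-70 ms, 200-300 uV);
* **ssw** -- background plus a run of complexes, each a sharp followed after
  a short gap by a wider, lower raised-cosine slow wave (130-250 ms,
  110-200 uV).

Planted deflections are downward, matching the detector's upright
convention; ``invert=True`` flips the epoch to exercise the orientation
module and ``violate_thresholds=True`` scales amplitudes far below the
packaged thresholds so detection must reject the waves.  Morphology defaults
are chosen so the packaged thresholds geometrically accept the planted
waves.  All randomness is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import ConfigurationError
from .signal_io import Epoch, WaveAnnotation


@dataclass
class SynthConfig:
    """Generation parameters; ranges are (low, high) uniform draws."""

    fs: float = 1600.0
    epoch_seconds: float = 5.0
    background_alpha: float = 1.0     # 1/f^alpha spectral exponent
    background_rms: float = 20.0      # uV
    background_highpass_hz: float = 1.0  # emulates the 1-500 Hz acquisition band-pass
    rhythm_amp: float = 5.0           # uV, sinusoidal component (0 disables)
    rhythm_freq: float = 9.0          # Hz
    sharp_width_ms: tuple[float, float] = (45.0, 70.0)
    sharp_amp: tuple[float, float] = (200.0, 300.0)
    sharp_asymmetry: tuple[float, float] = (0.40, 0.50)  # ascend fraction of width
    sharp_shape_power: float = 2.0    # flank exponent; > 1 gives convex flanks
    sw_width_ms: tuple[float, float] = (130.0, 250.0)
    sw_amp: tuple[float, float] = (110.0, 200.0)
    sharps_per_epoch: tuple[int, int] = (4, 7)
    sharp_spacing_ms: tuple[float, float] = (250.0, 550.0)
    complexes_per_epoch: tuple[int, int] = (3, 5)
    ssw_gap_ms: tuple[float, float] = (10.0, 50.0)
    complex_spacing_ms: tuple[float, float] = (350.0, 600.0)
    edge_margin_ms: float = 300.0
    invert: bool = False
    violate_thresholds: bool = False

    def __post_init__(self) -> None:
        for name in ("sharp_width_ms", "sharp_amp", "sw_width_ms", "sw_amp",
                     "sharp_spacing_ms", "ssw_gap_ms", "complex_spacing_ms",
                     "sharp_asymmetry"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ConfigurationError(f"{name} range must be ordered and non-negative")
        if self.fs <= 0 or self.epoch_seconds <= 0:
            raise ConfigurationError("fs and epoch_seconds must be positive")
        if self.sharp_width_ms[0] * self.fs / 1000.0 < 4:
            raise ConfigurationError("sharp width is infeasible at this sampling rate")


def _background(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-cfg.background_alpha / 2.0)
    shaping[freqs < cfg.background_highpass_hz] = 0.0
    sig = np.fft.irfft(spectrum * shaping, n)
    std = sig.std()
    if std > 0 and cfg.background_rms > 0:
        sig *= cfg.background_rms / std
    else:
        sig = np.zeros(n)
    if cfg.rhythm_amp > 0:
        t = np.arange(n) / cfg.fs
        sig += cfg.rhythm_amp * np.sin(
            2 * np.pi * cfg.rhythm_freq * t + rng.uniform(0, 2 * np.pi)
        )
    return sig


def _sharp_pulse(width: int, amp: float, asym: float, power: float) -> np.ndarray:
    """Cusp-apex pulse with convex flanks: amp * (1 - |u|)**power per side."""
    left = max(2, int(round(asym * width)))
    right = max(2, width - left)
    k = np.arange(left + right + 1)
    u = np.where(k <= left, (left - k) / left, (k - left) / right)
    return amp * (1.0 - u) ** power


def _sw_pulse(width: int, amp: float) -> np.ndarray:
    """Raised-cosine dome of the given total width (samples)."""
    k = np.arange(width + 1)
    return 0.5 * amp * (1.0 + np.cos(2.0 * np.pi * (k - width / 2.0) / width))


def _plant(sig: np.ndarray, start: int, pulse: np.ndarray) -> tuple[int, int]:
    end = start + pulse.size - 1
    sig[start : end + 1] -= pulse  # downward deflection = upright convention
    return start, end


def generate_epoch(
    class_label: str,
    cfg: SynthConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    epoch_index: int = 0,
) -> tuple[Epoch, list[WaveAnnotation]]:
    """Generate one labeled epoch with ground-truth wave annotations."""
    if class_label not in ("normal", "sharp", "ssw"):
        raise ConfigurationError(f"unknown class label {class_label!r}")
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    n = int(round(cfg.fs * cfg.epoch_seconds))
    sig = _background(cfg, n, rng)
    margin = int(round(cfg.edge_margin_ms * cfg.fs / 1000.0))
    amp_scale = 0.3 if cfg.violate_thresholds else 1.0
    anns: list[WaveAnnotation] = []

    def samples(ms: float) -> int:
        return int(round(ms * cfg.fs / 1000.0))

    if class_label == "sharp":
        count = int(rng.integers(cfg.sharps_per_epoch[0], cfg.sharps_per_epoch[1] + 1))
        cursor = margin + samples(rng.uniform(0, 100))
        for _ in range(count):
            width = samples(rng.uniform(*cfg.sharp_width_ms))
            pulse = _sharp_pulse(
                width,
                amp_scale * rng.uniform(*cfg.sharp_amp),
                rng.uniform(*cfg.sharp_asymmetry),
                cfg.sharp_shape_power,
            )
            if cursor + pulse.size >= n - margin:
                break
            a, b = _plant(sig, cursor, pulse)
            anns.append(WaveAnnotation(epoch_index, "sharp", a, b))
            cursor = b + samples(rng.uniform(*cfg.sharp_spacing_ms))
    elif class_label == "ssw":
        count = int(rng.integers(cfg.complexes_per_epoch[0], cfg.complexes_per_epoch[1] + 1))
        cursor = margin + samples(rng.uniform(0, 100))
        for _ in range(count):
            s_width = samples(rng.uniform(*cfg.sharp_width_ms))
            s_pulse = _sharp_pulse(
                s_width,
                amp_scale * rng.uniform(*cfg.sharp_amp),
                rng.uniform(*cfg.sharp_asymmetry),
                cfg.sharp_shape_power,
            )
            gap = samples(rng.uniform(*cfg.ssw_gap_ms))
            w_width = samples(rng.uniform(*cfg.sw_width_ms))
            w_pulse = _sw_pulse(w_width, amp_scale * rng.uniform(*cfg.sw_amp))
            total = s_pulse.size + gap + w_pulse.size
            if cursor + total >= n - margin:
                break
            a, b = _plant(sig, cursor, s_pulse)
            anns.append(WaveAnnotation(epoch_index, "sharp", a, b))
            a2, b2 = _plant(sig, b + 1 + gap, w_pulse)
            anns.append(WaveAnnotation(epoch_index, "sw", a2, b2))
            cursor = b2 + samples(rng.uniform(*cfg.complex_spacing_ms))
    if cfg.invert:
        sig = -sig
    epoch = Epoch(samples=sig, fs=cfg.fs, label=class_label)
    return epoch, anns


def generate_dataset(
    n_per_class: int | Mapping[str, int],
    cfg: SynthConfig | None = None,
    seed: int = 0,
) -> tuple[list[Epoch], list[WaveAnnotation]]:
    """Generate a labeled dataset; reproducible and seed-disjoint.

    ``n_per_class`` is either a single count applied to all three classes or
    a mapping ``{label: count}`` (e.g. the clinical class ratio scaled down).
    """
    cfg = cfg or SynthConfig()
    if isinstance(n_per_class, int):
        if n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        plan = {"normal": n_per_class, "sharp": n_per_class, "ssw": n_per_class}
    else:
        plan = {k: int(v) for k, v in n_per_class.items()}
        if any(v < 0 for v in plan.values()):
            raise ConfigurationError("class counts must be non-negative")
    total = sum(plan.values())
    children = np.random.SeedSequence(seed).spawn(total)
    epochs: list[Epoch] = []
    annotations: list[WaveAnnotation] = []
    i = 0
    for label in ("normal", "sharp", "ssw"):
        for _ in range(plan.get(label, 0)):
            ep, anns = generate_epoch(label, cfg, seed=children[i], epoch_index=i)
            epochs.append(ep)
            annotations.extend(anns)
            i += 1
    return epochs, annotations


def annotation_peak(epoch: Epoch, annotation: WaveAnnotation, polarity: str = "down") -> int:
    """Sample index of the planted wave's apex (ground-truth peak)."""
    w = -epoch.samples if polarity == "down" else epoch.samples
    a, b = annotation.start_index, annotation.end_index
    return a + int(np.argmax(w[a : b + 1]))
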