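"""Automatic per-epoch polarity: decide whether a signal is upright.

The detector assumes wave deflections are downward ("upright" signal).
Rather than asking the user to invert channels, sharps are detected from both
the original and the negated epoch and the *dominance* of each result is
compared: the sum over detected sharps of the shorter of the ascending and
descending block durations (in samples).  The polarity with the larger
dominance wins; ties (including the zero-sharp case) keep the original
polarity.  Channel identity is never consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .detection import DetectedWave, WaveParams, detect_waves
from .signal_io import Epoch


@dataclass(frozen=True)
class OrientationResult:
    inverted: bool
    v_original: float
    v_inverted: float


def dominance(waves: Sequence[DetectedWave]) -> float:
    """Sum over sharps of min(ascending, descending block length), in samples."""
    total = 0.0
    for w in waves:
        if w.wave_type != "sharp":
            raise ValueError("dominance is defined over detected sharps only")
        total += min(w.peak_index - w.start_index, w.end_index - w.peak_index)
    return float(total)


def orient_epoch(
    epoch: Epoch,
    params_sharp: WaveParams,
    polarity: str = "down",
) -> tuple[Epoch, OrientationResult]:
    """Return the upright version of an epoch and the dominance evidence.

    Sharps are detected from the epoch and from its negation; the signal with
    the larger dominance is deemed upright.  On a tie the original polarity
    is kept.
    """
    flipped = replace(epoch, samples=-epoch.samples)
    sharps_orig = detect_waves(
        epoch, params_sharp, params_sharp, wave_types=("sharp",), polarity=polarity
    )
    sharps_inv = detect_waves(
        flipped, params_sharp, params_sharp, wave_types=("sharp",), polarity=polarity
    )
    v_orig = dominance(sharps_orig)
    v_inv = dominance(sharps_inv)
    inverted = v_inv > v_orig
    upright = flipped if inverted else epoch
    return upright, OrientationResult(inverted=inverted, v_original=v_orig, v_inverted=v_inv)
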