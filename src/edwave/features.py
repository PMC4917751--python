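"""Geometric/relational epoch features and the wavelet baseline features.

The 27 geometric features summarize an epoch (``S_ALL``) and its detected
waves.  Features 2-13 are computed over detected sharps, 14-25 are the paired
duplicates over detected slow-waves, and 26/27 describe the sharp/slow-wave
relation.  ``S_NS`` denotes the samples in the blocks not detected as a wave;
for the paired features it is taken per wave type (the complement of that
type's detections), so both halves of a pair stay informative.

Per-wave basic statistics (width, amplitude, kurtosis, amplitude/width ratio,
skewness) are computed per wave first, and their median/mean forms the epoch
feature.  Degenerate cases resolve to documented sentinels: wave statistics
are 0 when no wave of the type was detected, ratio features are 0 when their
denominator is 0, and the sharp-to-slow-wave distance is the epoch duration
when no slow-wave has a preceding sharp.

The baseline feature set is the continuous Morlet wavelet transform at
integer scales 1..10: per scale, the mean/max/min/std of the coefficient
magnitudes across positions (40 values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
import scipy.stats

from .detection import DetectedWave, WaveParams, detect_waves, merge_ranges
from .orientation import orient_epoch
from .signal_io import Epoch

#: Frozen order and naming of the 27 geometric/relational features.
FEATURE_NAMES: tuple[str, ...] = (
    "std_all",                    # f1
    "n_sharp",                    # f2
    "sharp_median_width_ms",      # f3
    "sharp_median_amp",           # f4
    "sharp_mean_kurtosis",        # f5
    "sharp_mean_amp_width_ratio", # f6
    "sharp_std_ns",               # f7
    "sharp_std_ratio",            # f8  = f1/f7
    "sharp_amp_ns_ratio",         # f9  = f4/f7
    "range_all",                  # f10
    "sharp_range_ns",             # f11
    "sharp_amp_range_ratio",      # f12 = f4/f11
    "sharp_mean_skewness",        # f13
    "n_sw",                       # f14
    "sw_median_width_ms",         # f15
    "sw_median_amp",              # f16
    "sw_mean_kurtosis",           # f17
    "sw_mean_amp_width_ratio",    # f18
    "sw_std_ns",                  # f19
    "sw_std_ratio",               # f20 = f1/f19
    "sw_amp_ns_ratio",            # f21 = f16/f19
    "range_all_dup",              # f22 (printed duplicate of f10)
    "sw_range_ns",                # f23
    "sw_amp_range_ratio",         # f24 = f16/f23
    "sw_mean_skewness",           # f25
    "sw_to_sharp_distance_ms",    # f26
    "sw_sharp_count_ratio",       # f27
)

#: Published feature-group pairing (0-based indices into FEATURE_NAMES).
FEATURE_GROUPS: dict[str, tuple[int, ...]] = {
    "1": (0,),
    "2-14": (1, 13),
    "3-15": (2, 14),
    "4-16": (3, 15),
    "5-17": (4, 16),
    "6-18": (5, 17),
    "7-19": (6, 18),
    "8-20": (7, 19),
    "9-21": (8, 20),
    "10-22": (9, 21),
    "11-23": (10, 22),
    "12-24": (11, 23),
    "13-25": (12, 24),
    "26": (25,),
    "27": (26,),
}


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError("feature vector length does not match its names")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class WaveletFeatureVector:
    values: np.ndarray
    names: tuple[str, ...]


def undetected_blocks(
    epoch: Epoch, waves: Sequence[DetectedWave]
) -> list[tuple[int, int]]:
    """Inclusive index intervals of the epoch not covered by any given wave."""
    n = epoch.n_samples
    for w in waves:
        if not 0 <= w.start_index <= w.end_index < n:
            raise ValueError("wave range outside the epoch")
    covered = merge_ranges((w.start_index, w.end_index) for w in waves)
    out = []
    cursor = 0
    for a, b in covered:
        if a > cursor:
            out.append((cursor, a - 1))
        cursor = b + 1
    if cursor <= n - 1:
        out.append((cursor, n - 1))
    return out


def _gather(samples: np.ndarray, blocks: list[tuple[int, int]]) -> np.ndarray:
    if not blocks:
        return np.empty(0)
    return np.concatenate([samples[a : b + 1] for a, b in blocks])


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def _wave_stats(epoch: Epoch, waves: list[DetectedWave]) -> tuple[float, float, float, float, float]:
    """(median width ms, median amp, mean kurtosis, mean amp/width, mean skewness)."""
    if not waves:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    widths = np.array([w.width_ms for w in waves])
    amps = np.array([w.amplitude for w in waves])
    kurts = []
    skews = []
    for w in waves:
        seg = epoch.samples[w.start_index : w.end_index + 1]
        # population moments; kurtosis non-excess
        kurts.append(scipy.stats.kurtosis(seg, fisher=False, bias=True))
        skews.append(scipy.stats.skew(seg, bias=True))
    ratio = float(np.mean([_safe_div(w.amplitude, w.width_ms) for w in waves]))
    return (
        float(np.median(widths)),
        float(np.median(amps)),
        float(np.mean(kurts)),
        ratio,
        float(np.mean(skews)),
    )


def extract_features(epoch: Epoch, waves: Sequence[DetectedWave]) -> FeatureVector:
    """Compute the 27 geometric/relational features of one (oriented) epoch."""
    s_all = epoch.samples
    sharps = [w for w in waves if w.wave_type == "sharp"]
    sws = [w for w in waves if w.wave_type == "sw"]

    f1 = float(s_all.std())
    f10 = float(s_all.max() - s_all.min()) if s_all.size else 0.0

    values = np.zeros(27)
    values[0] = f1
    values[9] = f10
    values[21] = f10  # printed duplicate

    for offset, type_waves in ((0, sharps), (12, sws)):
        med_w, med_a, kurt, ratio, skew = _wave_stats(epoch, type_waves)
        ns = _gather(s_all, undetected_blocks(epoch, type_waves))
        std_ns = float(ns.std()) if ns.size else 0.0
        range_ns = float(ns.max() - ns.min()) if ns.size else 0.0
        values[offset + 1] = len(type_waves)           # f2 / f14
        values[offset + 2] = med_w                     # f3 / f15
        values[offset + 3] = med_a                     # f4 / f16
        values[offset + 4] = kurt                      # f5 / f17
        values[offset + 5] = ratio                     # f6 / f18
        values[offset + 6] = std_ns                    # f7 / f19
        values[offset + 7] = _safe_div(f1, std_ns)     # f8 / f20
        values[offset + 8] = _safe_div(med_a, std_ns)  # f9 / f21
        values[offset + 10] = range_ns                 # f11 / f23
        values[offset + 11] = _safe_div(med_a, range_ns)  # f12 / f24
        values[offset + 12] = skew                     # f13 / f25

    values[25] = _sw_sharp_distance(epoch, sharps, sws)
    values[26] = _safe_div(len(sws), len(sharps)) if sharps else float(len(sws))
    return FeatureVector(values)


def _sw_sharp_distance(epoch: Epoch, sharps: list[DetectedWave], sws: list[DetectedWave]) -> float:
    """Mean peak-to-peak distance (ms) from each slow-wave to its closest
    preceding sharp; slow-waves with no preceding sharp are skipped, and the
    epoch duration is the sentinel when none has one."""
    duration_ms = epoch.n_samples / epoch.fs * 1000.0
    if not sws or not sharps:
        return duration_ms
    sharp_peaks = np.array(sorted(w.peak_index for w in sharps))
    dists = []
    for sw in sws:
        preceding = sharp_peaks[sharp_peaks < sw.peak_index]
        if preceding.size:
            dists.append((sw.peak_index - preceding[-1]) / epoch.fs * 1000.0)
    return float(np.mean(dists)) if dists else duration_ms


def wavelet_features(
    epoch: Epoch, n_scales: int = 10, wavelet: str = "cmor1.5-1.0"
) -> WaveletFeatureVector:
    """Morlet CWT baseline features: per integer scale 1..n_scales, the
    (mean, max, min, std) of coefficient magnitudes across positions."""
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    scales = np.arange(1, n_scales + 1)
    coeffs, _ = pywt.cwt(epoch.samples, scales, wavelet)
    mags = np.abs(coeffs)
    values = np.empty(4 * n_scales)
    names = []
    for j in range(n_scales):
        row = mags[j]
        values[4 * j : 4 * j + 4] = (row.mean(), row.max(), row.min(), row.std())
        names += [f"cwt_s{j+1}_{stat}" for stat in ("mean", "max", "min", "std")]
    return WaveletFeatureVector(values=values, names=tuple(names))


def feature_matrix(
    epochs: Sequence[Epoch],
    params_sharp: WaveParams,
    params_sw: WaveParams,
    feature_set: str = "geometric",
    orient: bool = True,
    n_scales: int = 10,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Detect waves in every epoch and assemble the feature matrix.

    ``feature_set`` is ``"geometric"`` (27 values), ``"wavelet"`` (40) or
    ``"both"`` (67).  Returns (X, labels, column names); labels come from
    ``epoch.label``.
    """
    if feature_set not in ("geometric", "wavelet", "both"):
        raise ValueError("feature_set must be 'geometric', 'wavelet' or 'both'")
    rows = []
    labels = []
    names: list[str] | None = None
    for ep in epochs:
        parts = []
        part_names: list[str] = []
        if feature_set in ("geometric", "both"):
            target = orient_epoch(ep, params_sharp)[0] if orient else ep
            waves = detect_waves(target, params_sharp, params_sw)
            fv = extract_features(target, waves)
            parts.append(fv.values)
            part_names += list(fv.names)
        if feature_set in ("wavelet", "both"):
            wv = wavelet_features(ep, n_scales=n_scales)
            parts.append(wv.values)
            part_names += list(wv.names)
        rows.append(np.concatenate(parts))
        labels.append(ep.label)
        names = part_names
    return np.vstack(rows), np.asarray(labels), names or []
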