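"""Chord-area wave detection: sharps and slow-waves from single-channel epochs.

The detector measures waveform sharpness with two normalized chord areas.
For a wave peak at sample ``x`` and a moving point (MP) at sample ``y``, a
straight chord is drawn from ``(x, s_x)`` to ``(y, s_y)`` and two areas are
accumulated over the samples between them:

* **AAL** -- area of the signal above the chord (signal bulging over the line),
* **AUL** -- area of the chord above the signal (signal sagging under the line),

each normalized by ``N = (s_x - s_y) + |y - x| + 1``.  The MP is scanned
outward from the peak between radii ``R_s`` and ``R_e`` (one sample per step);
a boundary candidate is recorded at ``MP_{i-1}`` whenever AUL first reaches
the threshold ``theta_aul`` (``AUL_{i-1} < theta_aul`` and
``AUL_i >= theta_aul``).  Each left/right candidate pair is then tested:

* **sharp** -- AAL of *both* boundaries below ``theta_aal`` (straight flanks)
  and both side amplitudes at least ``theta_amp``;
* **slow-wave (sw)** -- AAL of at least one boundary above ``theta_aal``
  (a flank bulging above the chord, i.e. a dome) and both side amplitudes at
  least ``theta_amp``;

and in either case the wave must have a duration inside the expected range
``[er_min, er_max]`` and pass the two symmetry ("balance") tests
``bal_amp >= theta_bal_amp`` and ``bal_time >= theta_bal_time``.  A pair
satisfying both wave types' conditions counts as a sharp (the narrower, more
specific morphology).  Overlapping accepted ranges are merged.

All quantities are differences of amplitudes, so detection is exactly
invariant under adding a constant to the signal.  The public functions assume
the *working polarity* in which wave peaks are local maxima;
:func:`detect_waves` applies the package's upright convention (deflections
downward) by negating the signal internally, so callers pass epochs as
recorded/oriented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.signal
from numpy.lib.stride_tricks import sliding_window_view

from ._exceptions import DegenerateNormalizationError
from .signal_io import Epoch

logger = logging.getLogger(__name__)

WAVE_TYPES = ("sharp", "sw")

#: JSON/YAML serialization keys for WaveParams, in canonical order.
PARAM_KEYS = (
    "theta_aul",
    "theta_aal",
    "theta_amp_uV",
    "theta_bal_amp",
    "theta_bal_time",
    "r_s_ms",
    "r_e_ms",
    "er_min_ms",
    "er_max_ms",
)


@dataclass
class WaveParams:
    """Per-wave-type detection thresholds and scan radii.

    Attributes
    ----------
    wave_type : {"sharp", "sw"}
    theta_aul : float
        AUL boundary-candidate threshold (dimensionless).
    theta_aal : float
        AAL sharpness threshold (dimensionless).
    theta_amp : float
        Minimum side amplitude in uV.
    theta_bal_amp, theta_bal_time : float
        Minimum amplitude/time symmetry ratios, each in [0, 0.5].
    r_s, r_e : float
        Inner and outer moving-point scan radii in ms.
    er_min, er_max : float
        Expected wave-duration range in ms.
    """

    wave_type: str
    theta_aul: float
    theta_aal: float
    theta_amp: float
    theta_bal_amp: float
    theta_bal_time: float
    r_s: float
    r_e: float
    er_min: float
    er_max: float

    def __post_init__(self) -> None:
        if self.wave_type not in WAVE_TYPES:
            raise ValueError(f"wave_type must be one of {WAVE_TYPES}")
        if not 0 < self.r_s < self.r_e:
            raise ValueError("scan radii must satisfy 0 < r_s < r_e")
        for name in ("theta_bal_amp", "theta_bal_time"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5]")
        if self.er_min > self.er_max:
            raise ValueError("er_min must not exceed er_max")
        for name in ("theta_aul", "theta_aal", "theta_amp", "er_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "theta_aul": self.theta_aul,
            "theta_aal": self.theta_aal,
            "theta_amp_uV": self.theta_amp,
            "theta_bal_amp": self.theta_bal_amp,
            "theta_bal_time": self.theta_bal_time,
            "r_s_ms": self.r_s,
            "r_e_ms": self.r_e,
            "er_min_ms": self.er_min,
            "er_max_ms": self.er_max,
        }

    @classmethod
    def from_dict(cls, wave_type: str, d: dict) -> "WaveParams":
        return cls(
            wave_type=wave_type,
            theta_aul=float(d["theta_aul"]),
            theta_aal=float(d["theta_aal"]),
            theta_amp=float(d["theta_amp_uV"]),
            theta_bal_amp=float(d["theta_bal_amp"]),
            theta_bal_time=float(d["theta_bal_time"]),
            r_s=float(d["r_s_ms"]),
            r_e=float(d["r_e_ms"]),
            er_min=float(d["er_min_ms"]),
            er_max=float(d["er_max_ms"]),
        )


@dataclass(frozen=True)
class BoundaryCandidate:
    """A candidate wave boundary found by the AUL threshold-crossing scan."""

    index: int
    side: str  # {"left", "right"}
    aal: float
    aul: float


@dataclass
class DetectedWave:
    """One detected sharp or slow-wave (indices inclusive, working polarity)."""

    wave_type: str
    peak_index: int
    start_index: int
    end_index: int
    amp_left: float
    amp_right: float
    width_ms: float
    bal_amp: float
    bal_time: float
    l_ascend_ms: float
    l_descend_ms: float

    @property
    def amplitude(self) -> float:
        """Per-wave amplitude: mean of the two side amplitudes (uV)."""
        return 0.5 * (self.amp_left + self.amp_right)


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert milliseconds to a sample count (round to nearest, minimum 1)."""
    return max(1, int(round(ms * fs / 1000.0)))


def compute_aal_aul(
    signal: Sequence[float] | np.ndarray,
    x: int,
    y: int,
    norm: str = "verbatim",
) -> tuple[float, float]:
    """Normalized chord areas between a peak at ``x`` and a moving point at ``y``.

    ``norm="verbatim"`` uses ``N = (s_x - s_y) + |y - x| + 1`` (amplitude plus
    length plus one); ``norm="length"`` uses the sample count ``|y - x| + 1``
    only.  Raises :class:`DegenerateNormalizationError` when ``N <= 0``.
    """
    s = np.asarray(signal, dtype=float)
    if x == y:
        raise ValueError("peak and moving point must differ")
    if not (0 <= x < s.size and 0 <= y < s.size):
        raise ValueError("indices out of range")
    lo, hi = (x, y) if x < y else (y, x)
    idx = np.arange(lo, hi + 1)
    chord = s[x] + (idx - x) * (s[y] - s[x]) / (y - x)
    dev = s[lo : hi + 1] - chord
    if norm == "verbatim":
        n_factor = (s[x] - s[y]) + abs(y - x) + 1
    elif norm == "length":
        n_factor = abs(y - x) + 1
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    if n_factor <= 0:
        raise DegenerateNormalizationError(
            f"normalization factor N={n_factor} <= 0 for pair (x={x}, y={y})"
        )
    aal = float(dev[dev > 0].sum() / n_factor)
    aul = float(-dev[dev < 0].sum() / n_factor)
    return aal, aul


def find_peaks(signal: Sequence[float] | np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat plateau reports its midpoint
    (rounded down).  Signal must be in working polarity (peaks are maxima)."""
    s = np.asarray(signal, dtype=float)
    if s.size < 3:
        raise ValueError("signal must contain at least 3 samples")
    idx, _ = scipy.signal.find_peaks(s)
    return idx


# ---------------------------------------------------------------------------
# AAL/AUL profiles over all moving-point distances.
#
# seg[k] = s[peak +/- k]; for each distance d in [d_min, d_max] the chord runs
# from seg[0] to seg[d].  Endpoint deviations are zero by construction, so the
# inner loop covers k in (0, d).  Distances with N <= 0 are flagged invalid.
# ---------------------------------------------------------------------------


def _profile_impl(seg, d_min, d_max):  # pragma: no cover - jitted
    nd = d_max - d_min + 1
    aal = np.zeros(nd)
    aul = np.zeros(nd)
    valid = np.zeros(nd, dtype=np.bool_)
    s0 = seg[0]
    for j in range(nd):
        d = d_min + j
        sd = seg[d]
        n_factor = (s0 - sd) + d + 1
        if n_factor <= 0:
            continue
        slope = (sd - s0) / d
        pos = 0.0
        neg = 0.0
        for k in range(1, d):
            dev = seg[k] - (s0 + slope * k)
            if dev > 0.0:
                pos += dev
            else:
                neg -= dev
        aal[j] = pos / n_factor
        aul[j] = neg / n_factor
        valid[j] = True
    return aal, aul, valid


try:
    from numba import njit

    _profile = njit(cache=True)(_profile_impl)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _profile = _profile_impl


def _side_profile(
    w: np.ndarray, peak: int, direction: str, d_min: int, d_max: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """AAL/AUL profiles for all MP distances on one side of a peak.

    Returns (distances, aal, aul, valid); empty arrays when the inner radius
    already lies beyond the epoch edge.
    """
    n = w.size
    avail = n - 1 - peak if direction == "right" else peak
    hi = min(d_max, avail)
    if hi < d_min:
        empty = np.empty(0)
        return empty.astype(int), empty, empty, empty.astype(bool)
    seg = w[peak : peak + hi + 1] if direction == "right" else w[peak::-1][: hi + 1]
    seg = np.ascontiguousarray(seg, dtype=float)
    aal, aul, valid = _profile(seg, d_min, hi)
    return np.arange(d_min, hi + 1), aal, aul, valid


def scan_boundary_candidates(
    signal: Sequence[float] | np.ndarray,
    peak: int,
    direction: str,
    params: WaveParams,
    fs: float,
) -> list[BoundaryCandidate]:
    """Scan the moving point outward and emit AUL threshold-crossing candidates.

    The MP starts ``r_s`` (converted to samples) from the peak and advances
    one sample per step until ``r_e`` or the epoch edge; ``MP_{i-1}`` becomes
    a candidate whenever ``AUL_{i-1} < theta_aul`` and ``AUL_i >= theta_aul``.
    Distances where N <= 0 cannot be scored and never form a crossing.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    w = np.asarray(signal, dtype=float)
    d_min = ms_to_samples(params.r_s, fs)
    d_max = ms_to_samples(params.r_e, fs)
    dists, aal, aul, valid = _side_profile(w, peak, direction, d_min, d_max)
    step = 1 if direction == "right" else -1
    out: list[BoundaryCandidate] = []
    for i in range(1, dists.size):
        if (
            valid[i - 1]
            and valid[i]
            and aul[i - 1] < params.theta_aul
            and aul[i] >= params.theta_aul
        ):
            d = int(dists[i - 1])
            out.append(
                BoundaryCandidate(
                    index=peak + step * d,
                    side=direction,
                    aal=float(aal[i - 1]),
                    aul=float(aul[i - 1]),
                )
            )
    return out


def _pair_passes(
    w: np.ndarray,
    peak: int,
    left_idx: int,
    right_idx: int,
    aal_left: float,
    aal_right: float,
    params: WaveParams,
    fs: float,
) -> bool:
    """Full acceptance test of one candidate pair under one wave type's params.

    Comparisons follow the printed conventions: strict ``<`` for the sharp AAL
    test, strict ``>`` for the slow-wave AAL test, ``>=`` for amplitudes, and
    discard on balance ``<`` threshold; ties on unstated sides reject.
    """
    width_ms = (right_idx - left_idx) / fs * 1000.0
    if not params.er_min <= width_ms <= params.er_max:
        return False
    amp_left = abs(w[peak] - w[left_idx])
    amp_right = abs(w[peak] - w[right_idx])
    if amp_left < params.theta_amp or amp_right < params.theta_amp:
        return False
    amp_sum = amp_left + amp_right
    if amp_sum <= 0 or min(amp_left, amp_right) / amp_sum < params.theta_bal_amp:
        return False
    l_asc = peak - left_idx
    l_desc = right_idx - peak
    if l_asc <= 0 or l_desc <= 0:
        return False
    if min(l_asc, l_desc) / (l_asc + l_desc) < params.theta_bal_time:
        return False
    if params.wave_type == "sharp":
        return aal_left < params.theta_aal and aal_right < params.theta_aal
    return aal_left > params.theta_aal or aal_right > params.theta_aal


def classify_pair(
    signal: Sequence[float] | np.ndarray,
    peak: int,
    left: BoundaryCandidate,
    right: BoundaryCandidate,
    params_sharp: WaveParams,
    params_sw: WaveParams,
    fs: float,
) -> str:
    """Label one candidate pair ``"sharp"``, ``"sw"`` or ``"none"``.

    A pair meeting both types' conditions is a sharp (precedence to the
    narrower morphology).
    """
    if not left.index < peak < right.index:
        raise ValueError("candidate pair must bracket the peak")
    w = np.asarray(signal, dtype=float)
    if _pair_passes(w, peak, left.index, right.index, left.aal, right.aal, params_sharp, fs):
        return "sharp"
    if _pair_passes(w, peak, left.index, right.index, left.aal, right.aal, params_sw, fs):
        return "sw"
    return "none"


def merge_ranges(ranges: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge inclusive integer index ranges into minimal disjoint intervals.

    Semantics match a boolean indicator array over samples: touching or
    adjacent ranges (``next.start <= current.end + 1``) merge.  Idempotent and
    invariant to input order.
    """
    rs = sorted((int(a), int(b)) for a, b in ranges)
    out: list[tuple[int, int]] = []
    for a, b in rs:
        if b < a:
            raise ValueError(f"invalid range ({a}, {b})")
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _window_extremes(
    w: np.ndarray, d_min: int, d_max: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(min, max) of w over [i+d_min, min(i+d_max, n-1)] (right windows) and
    over the mirrored left windows, for every i.  Positions with no valid
    window get +inf/-inf."""
    n = w.size

    def forward(v: np.ndarray, reduce, fill) -> np.ndarray:
        out = np.full(n, fill)
        width = d_max - d_min + 1
        if n >= width:
            sw_red = reduce(sliding_window_view(v, width), 1)  # len n-width+1
            m = n - width - d_min + 1
            if m > 0:
                out[:m] = sw_red[d_min : d_min + m]
            tail_start = max(0, m)
        else:
            tail_start = 0
        for i in range(tail_start, n):
            j = i + d_min
            if j < n:
                out[i] = reduce(v[j : min(i + d_max, n - 1) + 1], None)
        return out

    amin = lambda a, ax: a.min(axis=ax) if ax is not None else a.min()
    amax = lambda a, ax: a.max(axis=ax) if ax is not None else a.max()
    right_min = forward(w, amin, np.inf)
    right_max = forward(w, amax, -np.inf)
    left_min = forward(w[::-1], amin, np.inf)[::-1]
    left_max = forward(w[::-1], amax, -np.inf)[::-1]
    return left_min, left_max, right_min, right_max


def _make_wave(w: np.ndarray, wave_type: str, peak: int, start: int, end: int, fs: float) -> DetectedWave:
    return DetectedWave(
        wave_type=wave_type,
        peak_index=int(peak),
        start_index=int(start),
        end_index=int(end),
        amp_left=float(abs(w[peak] - w[start])),
        amp_right=float(abs(w[peak] - w[end])),
        width_ms=(end - start) / fs * 1000.0,
        bal_amp=_balance(abs(w[peak] - w[start]), abs(w[peak] - w[end])),
        bal_time=_balance(peak - start, end - peak),
        l_ascend_ms=(peak - start) / fs * 1000.0,
        l_descend_ms=(end - peak) / fs * 1000.0,
    )


def _balance(a: float, b: float) -> float:
    total = a + b
    if total <= 0:
        return 0.0
    return float(min(a, b) / total)


def detect_waves(
    epoch: Epoch,
    params_sharp: WaveParams,
    params_sw: WaveParams,
    wave_types: Sequence[str] = ("sharp", "sw"),
    polarity: str = "down",
    prune: bool = True,
) -> list[DetectedWave]:
    """Detect sharps and/or slow-waves in one epoch.

    The epoch is assumed upright (deflections downward when
    ``polarity="down"``); pass ``polarity="up"`` to skip the internal
    negation.  For each local peak, boundary candidates are scanned on both
    sides with the wave type's radii, every left x right pair is tested, and
    overlapping accepted ranges are merged (per peak, then across peaks for
    ranges of the same type).  Output is sorted by start index and is
    deterministic for fixed input.

    ``prune=True`` skips peaks that cannot satisfy the amplitude threshold
    for any boundary inside the scan window -- a necessary condition of the
    pair test, so pruning never changes the result.
    """
    if polarity not in ("down", "up"):
        raise ValueError("polarity must be 'down' or 'up'")
    w = -epoch.samples if polarity == "down" else epoch.samples.copy()
    n = w.size
    if n < 3:
        return []
    by_type = {"sharp": params_sharp, "sw": params_sw}
    peaks_all = find_peaks(w)
    detected: list[DetectedWave] = []
    for wave_type in wave_types:
        params = by_type[wave_type]
        if params is None:
            raise ValueError(f"missing parameters for wave type {wave_type!r}")
        d_min = ms_to_samples(params.r_s, epoch.fs)
        d_max = ms_to_samples(params.r_e, epoch.fs)
        if prune and peaks_all.size:
            # side amplitude is |w[peak] - w[boundary]|, so either a deep-enough
            # drop or a high-enough rise within the scan window qualifies
            l_min, l_max, r_min, r_max = _window_extremes(w, d_min, d_max)
            pv = w[peaks_all]
            left_ok = np.maximum(pv - l_min[peaks_all], l_max[peaks_all] - pv) >= params.theta_amp
            right_ok = np.maximum(pv - r_min[peaks_all], r_max[peaks_all] - pv) >= params.theta_amp
            peaks = peaks_all[left_ok & right_ok]
        else:
            peaks = peaks_all
        type_waves: list[DetectedWave] = []
        for peak in peaks:
            lefts = scan_boundary_candidates(w, int(peak), "left", params, epoch.fs)
            if not lefts:
                continue
            rights = scan_boundary_candidates(w, int(peak), "right", params, epoch.fs)
            if not rights:
                continue
            accepted: list[tuple[int, int]] = []
            for lc in lefts:
                for rc in rights:
                    label = classify_pair(w, int(peak), lc, rc, params_sharp, params_sw, epoch.fs)
                    if label == wave_type:
                        accepted.append((lc.index, rc.index))
            if accepted:
                for a, b in merge_ranges(accepted):
                    type_waves.append(_make_wave(w, wave_type, int(peak), a, b, epoch.fs))
        detected.extend(_merge_across_peaks(w, type_waves, epoch.fs))
    detected.sort(key=lambda dw: (dw.start_index, dw.wave_type, dw.end_index))
    return detected


def _merge_across_peaks(w: np.ndarray, waves: list[DetectedWave], fs: float) -> list[DetectedWave]:
    """Merge overlapping same-type detections originating from distinct peaks.

    Noise superimposed on a single physiological wave splinters its apex into
    several sample-level local maxima whose accepted ranges nearly coincide;
    the union is reported once, with the peak at the extremum of the merged
    range.
    """
    if not waves:
        return []
    wave_type = waves[0].wave_type
    merged = merge_ranges((dw.start_index, dw.end_index) for dw in waves)
    out = []
    for a, b in merged:
        if b - a < 2:
            continue
        peak = a + 1 + int(np.argmax(w[a + 1 : b]))
        out.append(_make_wave(w, wave_type, peak, a, b, fs))
    return out


def screen_epoch(
    waves: Sequence[DetectedWave],
    fs: float,
    min_train: int = 3,
    max_complex_gap_ms: float = 100.0,
) -> str:
    """Coarse discharge-vs-background screen from detected waves alone.

    The targeted discharge patterns are *repetitions* -- a train of repeated
    sharps or a run of sharp-and-slow-wave complexes, and both contain
    sharps -- so an epoch is flagged ``"ed"`` when at least ``min_train``
    sharps were detected or at least ``min_train`` sharps are each
    overlapped/followed (within ``max_complex_gap_ms``) by slow-wave
    activity extending past them, and ``"normal"`` otherwise.  Isolated
    slow-wave-shaped excursions with no accompanying sharp never flag an
    epoch, which is what makes this a usable screen on background activity;
    identifying the discharge *type* is the feature/SVM stage's job.
    """
    sharps = [w for w in waves if w.wave_type == "sharp"]
    sws = [w for w in waves if w.wave_type == "sw"]
    max_gap = max_complex_gap_ms * fs / 1000.0
    n_complexes = 0
    for sh in sharps:
        for sw in sws:
            # slow activity continuing past the sharp, starting at/near it
            if sw.end_index > sh.end_index and sw.start_index - sh.end_index <= max_gap:
                n_complexes += 1
                break
    if len(sharps) >= min_train or n_complexes >= min_train:
        return "ed"
    return "normal"


def waves_to_annotations(waves: Sequence[DetectedWave], epoch_index: int):
    """Export detected waves as the WaveAnnotation records of signal_io."""
    from .signal_io import WaveAnnotation

    return [
        WaveAnnotation(
            epoch_index=epoch_index,
            wave_type=dw.wave_type,
            start_index=dw.start_index,
            end_index=dw.end_index,
        )
        for dw in waves
    ]
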