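import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edwave._exceptions import DegenerateNormalizationError
from edwave.detection import (
    BoundaryCandidate,
    WaveParams,
    classify_pair,
    compute_aal_aul,
    detect_waves,
    find_peaks,
    merge_ranges,
    ms_to_samples,
    scan_boundary_candidates,
)
from edwave.signal_io import Epoch
from edwave.synth import annotation_peak

from conftest import make_epoch


def brute_force_aal_aul(s, x, y):
    """Element-wise chord-area computation: the independent oracle."""
    s = np.asarray(s, dtype=float)
    lo, hi = min(x, y), max(x, y)
    aal_sum = 0.0
    aul_sum = 0.0
    for i in range(lo, hi + 1):
        line = s[x] + (i - x) * (s[y] - s[x]) / (y - x)
        if s[i] - line > 0:
            aal_sum += s[i] - line
        elif s[i] - line < 0:
            aul_sum += line - s[i]
    n_factor = (s[x] - s[y]) + abs(y - x) + 1
    return aal_sum / n_factor, aul_sum / n_factor


class TestComputeAalAul:
    def test_collinear_signal_has_zero_areas(self):
        aal, aul = compute_aal_aul([0.0, 1.0, 2.0, 3.0], 0, 3)
        assert aal == 0.0 and aul == 0.0

    def test_hand_summed_triangle(self):
        # chord from (0,0) to (2,0) is flat; only s_1=2 lies above it; N = 0-0+2+1
        aal, aul = compute_aal_aul([0.0, 2.0, 0.0], 0, 2)
        assert aal == pytest.approx(2.0 / 3.0)
        assert aul == 0.0

    def test_matches_bruteforce_on_random_signals(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            s = rng.normal(scale=50, size=50)
            x, y = rng.choice(50, size=2, replace=False)
            try:
                got = compute_aal_aul(s, int(x), int(y))
            except DegenerateNormalizationError:
                assert (s[x] - s[y]) + abs(int(y) - int(x)) + 1 <= 0
                continue
            expected = brute_force_aal_aul(s, int(x), int(y))
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_degenerate_normalization_raises(self):
        # deep drop from x to y makes N = (s_x - s_y) + |y-x| + 1 <= 0
        s = np.array([0.0, 1.0, 100.0])
        with pytest.raises(DegenerateNormalizationError):
            compute_aal_aul(s, 0, 2)

    def test_same_index_rejected(self):
        with pytest.raises(ValueError):
            compute_aal_aul([0.0, 1.0, 0.0], 1, 1)

    def test_length_normalization_option(self):
        aal, aul = compute_aal_aul([0.0, 2.0, 0.0], 0, 2, norm="length")
        assert aal == pytest.approx(2.0 / 3.0)  # here N happens to equal len


class TestFindPeaks:
    def test_two_peaks(self):
        np.testing.assert_array_equal(find_peaks([0, 5, 0, 5, 0]), [1, 3])

    def test_monotone_ramp_has_none(self):
        assert find_peaks(np.arange(10.0)).size == 0

    def test_plateau_reports_left_midpoint(self):
        # enumeration over all indices: the only maximum is the plateau 4-5
        s = np.array([0, 1, 2, 3, 7, 7, 3, 2, 1, 0], dtype=float)
        np.testing.assert_array_equal(find_peaks(s), [4])

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            find_peaks([1.0, 2.0])


def exhaustive_scan(s, peak, direction, params, fs):
    """Evaluate AUL at every MP distance and apply the crossing rule: oracle."""
    d_min = ms_to_samples(params.r_s, fs)
    d_max = ms_to_samples(params.r_e, fs)
    step = 1 if direction == "right" else -1
    values = {}
    for d in range(d_min, d_max + 1):
        y = peak + step * d
        if not 0 <= y < len(s):
            break
        try:
            values[d] = compute_aal_aul(s, peak, y)
        except DegenerateNormalizationError:
            values[d] = None
    out = []
    dists = sorted(values)
    for prev, cur in zip(dists, dists[1:]):
        if values[prev] is None or values[cur] is None:
            continue
        if values[prev][1] < params.theta_aul and values[cur][1] >= params.theta_aul:
            out.append((peak + step * prev, values[prev][0], values[prev][1]))
    return out


class TestBoundaryScan:
    def test_flat_signal_yields_no_candidates(self, table_params):
        sharp, _ = table_params
        s = np.zeros(2000)
        s[1000] = 1.0  # a peak with flat surroundings: AUL stays ~0
        assert scan_boundary_candidates(s, 1000, "left", sharp, 1600) == []

    @pytest.mark.parametrize("direction", ["left", "right"])
    def test_matches_exhaustive_enumeration(self, direction, table_params):
        sharp, sw = table_params
        rng = np.random.default_rng(7)
        for params in (sharp, sw):
            for _ in range(20):
                s = rng.normal(scale=80, size=1200)
                peak = int(rng.integers(100, 1100))
                got = scan_boundary_candidates(s, peak, direction, params, 1600)
                expected = exhaustive_scan(s, peak, direction, params, 1600)
                assert [c.index for c in got] == [e[0] for e in expected]
                np.testing.assert_allclose(
                    [c.aal for c in got], [e[1] for e in expected], rtol=1e-9
                )
                np.testing.assert_allclose(
                    [c.aul for c in got], [e[2] for e in expected], rtol=1e-9
                )

    def test_inner_radius_beyond_edge_gives_empty(self, table_params):
        sharp, _ = table_params
        s = np.random.default_rng(0).normal(size=100)
        assert scan_boundary_candidates(s, 2, "left", sharp, 1600) == []


def _candidate(idx, side, aal):
    return BoundaryCandidate(index=idx, side=side, aal=aal, aul=0.0)


class TestClassifyPair:
    """Hand-checked threshold decisions against the packaged parameter set."""

    fs = 1600.0

    def _symmetric_wave(self, width_samples, amp):
        # working polarity: peak is a maximum at the center
        half = width_samples // 2
        s = np.zeros(4000)
        peak = 2000
        s[peak - half : peak + half + 1] = amp * (
            1 - np.abs(np.arange(-half, half + 1)) / half
        )
        return s, peak, peak - half, peak + half

    def test_narrow_high_symmetric_wave_is_sharp(self, table_params):
        sharp, sw = table_params
        s, peak, a, b = self._symmetric_wave(ms_to_samples(50, self.fs), 200.0)
        label = classify_pair(
            s, peak, _candidate(a, "left", 1.0), _candidate(b, "right", 1.0), sharp, sw, self.fs
        )
        assert label == "sharp"

    def test_wide_low_wave_with_big_aal_is_sw(self, table_params):
        sharp, sw = table_params
        s, peak, a, b = self._symmetric_wave(ms_to_samples(180, self.fs), 100.0)
        label = classify_pair(
            s, peak, _candidate(a, "left", 2.0), _candidate(b, "right", 0.1), sharp, sw, self.fs
        )
        assert label == "sw"

    def test_unbalanced_amplitudes_rejected(self, table_params):
        # bal_amp = 50/(50+200) = 0.2 < 0.34 -> discarded
        sharp, sw = table_params
        s = np.zeros(4000)
        peak, a, b = 2000, 2000 - 40, 2000 + 40
        s[peak] = 0.0
        s[a] = -200.0
        s[b] = -50.0
        s[a:peak] = np.linspace(-200, 0, peak - a, endpoint=False)
        s[peak + 1 : b + 1] = np.linspace(0, -50, b - peak)
        label = classify_pair(
            s, peak, _candidate(a, "left", 1.0), _candidate(b, "right", 1.0), sharp, sw, self.fs
        )
        assert label == "none"

    def test_subthreshold_amplitude_rejected(self, table_params):
        sharp, sw = table_params
        s, peak, a, b = self._symmetric_wave(ms_to_samples(50, self.fs), 100.0)  # < 148.21
        label = classify_pair(
            s, peak, _candidate(a, "left", 1.0), _candidate(b, "right", 1.0), sharp, sw, self.fs
        )
        assert label == "none"

    def test_width_outside_expected_range_rejected(self, table_params):
        sharp, sw = table_params
        s, peak, a, b = self._symmetric_wave(ms_to_samples(30, self.fs), 200.0)  # < 42.4 ms
        label = classify_pair(
            s, peak, _candidate(a, "left", 1.0), _candidate(b, "right", 1.0), sharp, sw, self.fs
        )
        assert label == "none"


class TestMergeRanges:
    def test_basic_overlap(self):
        assert merge_ranges([(0, 10), (5, 20)]) == [(0, 20)]

    def test_empty(self):
        assert merge_ranges([]) == []

    @given(
        st.lists(
            st.tuples(st.integers(0, 400), st.integers(0, 100)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=100,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_indicator_array_union(self, ranges):
        merged = merge_ranges(ranges)
        indicator = np.zeros(600, dtype=bool)
        for a, b in ranges:
            indicator[a : b + 1] = True
        runs = []
        i = 0
        while i < indicator.size:
            if indicator[i]:
                j = i
                while j + 1 < indicator.size and indicator[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        assert merged == runs

    @given(
        st.lists(
            st.tuples(st.integers(0, 400), st.integers(0, 100)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_idempotent_and_order_invariant(self, ranges):
        merged = merge_ranges(ranges)
        assert merge_ranges(merged) == merged
        assert merge_ranges(list(reversed(ranges))) == merged


class TestDetectWaves:
    def test_subthreshold_noise_epoch_has_no_waves(self, table_params):
        sharp, sw = table_params
        rng = np.random.default_rng(3)
        ep = make_epoch(rng.normal(scale=5, size=8000))
        assert detect_waves(ep, sharp, sw) == []

    def test_planted_sharps_each_found_once(self, table_params, synth_cfg):
        from edwave.synth import generate_epoch

        sharp, sw = table_params
        ep, anns = generate_epoch("sharp", synth_cfg, seed=42)
        waves = [w for w in detect_waves(ep, sharp, sw) if w.wave_type == "sharp"]
        assert len(waves) == len(anns)
        for ann in anns:
            pk = annotation_peak(ep, ann)
            assert any(w.start_index <= pk <= w.end_index for w in waves)

    def test_dc_offset_invariance(self, table_params, sharp_epoch):
        sharp, sw = table_params
        ep, _ = sharp_epoch
        shifted = Epoch(samples=ep.samples + 1000.0, fs=ep.fs, label=ep.label)
        w1 = detect_waves(ep, sharp, sw)
        w2 = detect_waves(shifted, sharp, sw)
        assert [(w.wave_type, w.start_index, w.end_index, w.peak_index) for w in w1] == [
            (w.wave_type, w.start_index, w.end_index, w.peak_index) for w in w2
        ]

    def test_pruning_does_not_change_the_result(self, table_params, ssw_epoch):
        sharp, sw = table_params
        ep, _ = ssw_epoch
        w1 = detect_waves(ep, sharp, sw, prune=True)
        w2 = detect_waves(ep, sharp, sw, prune=False)
        assert [(w.wave_type, w.start_index, w.end_index) for w in w1] == [
            (w.wave_type, w.start_index, w.end_index) for w in w2
        ]

    def test_infinite_amplitude_threshold_detects_nothing(self, table_params, sharp_epoch):
        sharp, sw = table_params
        ep, _ = sharp_epoch
        import dataclasses

        inf_sharp = dataclasses.replace(sharp, theta_amp=np.inf)
        inf_sw = dataclasses.replace(sw, theta_amp=np.inf)
        assert detect_waves(ep, inf_sharp, inf_sw) == []

    def test_raising_amplitude_threshold_is_monotone(self, table_params, ssw_epoch):
        import dataclasses

        sharp, sw = table_params
        ep, _ = ssw_epoch
        counts = []
        for factor in (1.0, 1.5, 2.5):
            p_s = dataclasses.replace(sharp, theta_amp=sharp.theta_amp * factor)
            p_w = dataclasses.replace(sw, theta_amp=sw.theta_amp * factor)
            counts.append(len(detect_waves(ep, p_s, p_w)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_detected_waves_are_self_consistent(self, table_params, ssw_epoch):
        """Geometry stored on each wave matches a recomputation from raw samples."""
        sharp, sw = table_params
        ep, _ = ssw_epoch
        w_sig = -ep.samples  # working polarity
        for w in detect_waves(ep, sharp, sw):
            assert w.start_index < w.peak_index < w.end_index
            amp_l = abs(w_sig[w.peak_index] - w_sig[w.start_index])
            amp_r = abs(w_sig[w.peak_index] - w_sig[w.end_index])
            assert w.amp_left == pytest.approx(amp_l)
            assert w.amp_right == pytest.approx(amp_r)
            assert w.width_ms == pytest.approx((w.end_index - w.start_index) / ep.fs * 1000)
            assert w.bal_amp == pytest.approx(min(amp_l, amp_r) / (amp_l + amp_r))
            assert 0 < w.bal_time <= 0.5

    def test_deterministic(self, table_params, ssw_epoch):
        sharp, sw = table_params
        ep, _ = ssw_epoch
        assert detect_waves(ep, sharp, sw) == detect_waves(ep, sharp, sw)


class TestWaveParams:
    def test_serialization_roundtrip(self, table_params, tmp_path):
        from edwave.calibration import load_params, save_params

        sharp, sw = table_params
        for suffix in ("json", "yaml"):
            path = tmp_path / f"params.{suffix}"
            save_params(path, sharp, sw)
            got_sharp, got_sw = load_params(path)
            assert got_sharp == sharp
            assert got_sw == sw

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            WaveParams(
                wave_type="sharp", theta_aul=1, theta_aal=1, theta_amp=1,
                theta_bal_amp=0.3, theta_bal_time=0.3, r_s=50, r_e=10,
                er_min=10, er_max=20,
            )
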