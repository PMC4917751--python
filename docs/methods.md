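# Methods

## Signal model and conventions

An **epoch** is a fixed-length, single-channel segment in microvolts with a
known sampling rate (defaults: 5 s at 1600 Hz, i.e. 8000 samples). Sample
indices are 0-based; annotated and detected wave ranges are inclusive on
both ends. Epochs are cut from continuous recordings without overlap and a
trailing remainder shorter than one epoch is dropped, so the epochs plus the
tail partition the signal.

The detector's **upright convention** is that wave deflections point
downward. All internal algebra runs on the negated signal (the *working
polarity*, in which wave peaks are local maxima); `detect_waves` performs
the negation itself, and a `polarity="up"` switch disables it. Every
detection quantity is a difference of amplitudes, so detection is exactly
invariant under adding a constant to the signal.

## Chord-area detection

For a peak at sample *x* and a moving point (MP) at *y*, the chord through
(x, s_x) and (y, s_y) splits the enclosed signal into the area above the
chord (AAL) and the area of the chord above the signal (AUL), each
normalized by `N = (s_x − s_y) + |y − x| + 1`. Notes on this normalization:

* The printed chord formula in the source material anchors the line at the
  wrong endpoint when its running index is read literally; evaluated as the
  chord through the two endpoints (which its own endpoints require) the
  formula is exact, and that is what is implemented.
* `N` adds microvolts to a sample count. It is implemented verbatim
  (`norm="verbatim"`); a pure sample-count normalization is available as
  `norm="length"` but is not the default anywhere. Pairs with `N ≤ 0`
  (possible when the MP lies far above the peak) cannot be scored and are
  skipped.
* Left and right MPs are handled symmetrically via `|y − x|`.

Detection of one wave type proceeds per local maximum of the working
signal (strict maxima; a flat plateau reports its midpoint, rounded down):

1. On each side, the MP starts `R_s` away from the peak (ms converted to
   samples by round-to-nearest, minimum 1) and advances one sample per step
   until `R_e` or the epoch edge. A **boundary candidate** is emitted at
   `MP_{i−1}` whenever `AUL_{i−1} < θ_AUL` and `AUL_i ≥ θ_AUL`.
2. Every left×right candidate pair is tested. Both wave types require: both
   side amplitudes `|s_peak − s_boundary| ≥ θ_amp`; duration within
   `[ER_min, ER_max]`; `bal_amp ≥ θ_bal_amp`; `bal_time ≥ θ_bal_time`.
   A **sharp** additionally needs both boundary AALs `< θ_AAL`; a
   **slow-wave** needs at least one AAL `> θ_AAL`. Comparisons are exactly
   as stated (strict where stated strict); ties on unstated sides reject.
   A pair satisfying both types counts as a sharp — the narrower, more
   specific morphology.
3. Accepted ranges of one peak are merged (they all contain the peak, so the
   union is a single interval). Duration filtering is applied per tested
   pair, before merging; merged ranges are not re-filtered.

The two wave types run independently, each with its own thresholds and scan
radii. As a final step, overlapping same-type ranges from *different* peaks
are also merged: background noise splinters a single physiological apex into
several sample-level maxima whose accepted ranges nearly coincide, and
without this merge one planted wave would be reported several times. The
merged wave's peak is the extremum of the merged range. Interval merging
follows boolean-indicator semantics (touching or adjacent integer ranges
merge); it is idempotent and input-order invariant.

A performance note: peaks that cannot reach `θ_amp` on both sides within the
scan window are pruned before scanning. The prune tests
`max(peak − window_min, window_max − peak) ≥ θ_amp` per side — a necessary
condition of the pair test (amplitudes are absolute differences) — so it
never changes the result; a property test verifies this. The per-distance
chord-area profiles are computed by a numba-jitted kernel with a pure-Python
fallback, and the kernel is property-tested against an element-wise
brute-force implementation.

## Orientation

Sharps are detected in both polarities of an epoch and the **dominance**
`V = Σ min(L_ascend, L_descend)` (in samples, over detected sharps) is
compared; the polarity with the larger V is upright. Ties — including
epochs with no sharps at all — keep the original polarity, making the
procedure deterministic and antisymmetric wherever the dominance values
differ. Channel identity is never consulted; orientation is per-epoch.

## Calibration

Thresholds derive from a small annotated sample (ten segments per discharge
type in the reference workflow). Per annotated wave the package measures
AUL, AAL, side amplitudes, both balance ratios and the width, then sets

* upper-bound thresholds (θ_AUL; θ_AAL for sharps) to mean + sd,
* lower-bound thresholds (θ_amp, θ_bal_amp, θ_bal_time, and θ_AAL for
  slow-waves, whose test keeps waves *above* the threshold) to mean − sd,
* `ER = [W̄ − sd_W, W̄ + sd_W]`, `R_s = θ_bal_time · ER_min`,
  `R_e = (1 − θ_bal_time) · ER_max`.

The sample standard deviation (n−1) is used, matching the small intended
sample. Two details are deliberate interpretations of an under-specified
procedure:

* **Slow-wave AAL direction.** The printed formula line puts θ_AAL_SW at
  mean + sd, but the stated construction principle (add the deviation for
  upper bounds, subtract it for lower bounds) requires mean − sd, and the
  published θ_AAL_SW = 0.85 is only consistent with the latter. The
  principle is the default (`aal_rule="principle"`); the printed variant is
  available as `aal_rule="printed"` and leaves slow-waves nearly
  undetectable by construction.
* **Boundary-consistent measurement.** Geometry is measured in two passes:
  θ_AUL comes from the chord areas at the annotation endpoints, then each
  wave is re-measured at its AUL-crossing boundaries — the same boundary
  estimator the detector uses. Measuring widths at raw annotation endpoints
  would systematically reject detections, whose boundaries overshoot the
  wave feet.

Per-wave scalars feed the thresholds from the side the detector actually
tests: AUL/AAL take the larger of the two sides, the amplitude the smaller.

**Transfer ceiling.** Because every threshold sits at mean ± sd of the
matched feature distribution, each binding test rejects its own ≈16% tail
(≈32% for the two-sided duration range), so the joint probability that a
fresh matched wave passes a given candidate pair is capped well below 1
(≈0.84^k · 0.68 when k one-sided tests bind). Multiple boundary candidates
per side soften this in noisy signals. On stereotyped synthetic morphology
(~8% dispersion, emulating within-focus discharges) the measured transfer is
roughly 60% for sharps and 85% for slow-waves; the end-to-end test asserts
majority transfer, not near-perfect recall. The packaged `default_params()`
carry the values derived on the reference recording; its duration range,
absent from the published table, is back-derived via
`ER_min = R_s / θ_bal_time`, `ER_max = R_e / (1 − θ_bal_time)`.

## Features

The 27 geometric/relational features follow the published list: the epoch's
amplitude standard deviation and range; per wave type the count, median
width, median amplitude, mean kurtosis, mean amplitude/width ratio, mean
skewness; the standard deviation and range of the *non-detected* blocks and
the derived ratios; the mean distance from each slow-wave to its closest
preceding sharp (peak-to-peak, ms); and the slow-wave/sharp count ratio.
Conventions where the source is silent:

* Non-detected blocks are taken per wave type (complement of that type's
  detections), keeping both halves of each paired feature informative; the
  epoch-range feature pair (10/22) is a printed duplicate and is reproduced
  as such.
* Per-wave statistics are computed per wave first, then the median/mean is
  taken. Kurtosis is non-excess and both moments are population moments on
  the raw (oriented) wave samples. A wave's amplitude is the mean of its two
  side amplitudes.
* Degenerate cases: wave statistics are 0 with no waves of the type; ratios
  with a zero denominator are 0; the count ratio clamps its denominator to 1
  when no sharp exists; the sharp→slow-wave distance falls back to the epoch
  duration when no slow-wave has a preceding sharp.

The wavelet baseline is the continuous Morlet transform at integer scales
1..10 (`cmor1.5-1.0`), with the mean, maximum, minimum and standard
deviation of the coefficient *magnitudes* per scale — 40 values. Both the
complex wavelet and the scale set are overridable.

`screen_epoch` offers a rule-based discharge-vs-background label from
detections alone (≥3 sharps, or ≥3 sharps each continued by slow activity):
the targeted patterns are repetitions, and isolated slow-wave-shaped
excursions without an accompanying sharp never flag an epoch. Distinguishing
sharp trains from SSW runs is deliberately left to the classifier — merged
slow-wave ranges legitimately cover their sharps, making the distinction
ambiguous at the range level.

## Classification

Stage 1 separates normal from ED epochs, stage 2 (trained on ED rows only)
separates sharps from SSWs. Both are RBF SVMs; the published configuration
states the kernel as a scaling factor σ, i.e.
`k(u,v) = exp(−‖u−v‖² / (2σ²))`, mapped to sklearn's `gamma = 1/(2σ²)` (a
unit test pins the mapping). The KKT tolerance L maps to `SVC(tol=...)`;
the KKT violation level K has no sklearn analogue and its published value 0
makes it a no-op. Features are z-scored with training-fold statistics
(switchable off). Defaults: stage 1 C=1, σ=3, L=0.01; stage 2 C=0.1, σ=3,
L=0.05.

Evaluation uses stratified 10-fold cross-validation; each training split
subsamples the normal class to at most 20 000 rows (test folds are never
capped). The score is the balanced accuracy
`Acc = Σ_i (Sens_i + Spec_i) / 2C`, chosen because the clinical class sizes
are severely unbalanced. The selectivity is implemented exactly as printed
in its source, `Sel = Σ_i TP_i / Σ_i (TN_i + FP_i)` — the right-hand side
sums over classes even though the original notation indexes the left by
class; this oddity is preserved deliberately. A per-feature-group ablation
(`feature_group_ablation` with the published group pairings) reports the
cross-validated accuracy of each group alone.

## Synthetic data

The generator emulates the reference recording's segment types: 5-s epochs
at 1600 Hz containing (a) background only, (b) a train of 4–7 sharps, or
(c) a run of 3–5 sharp-and-slow-wave complexes, each with exact ground-truth
ranges. Shapes and defaults, chosen once so the packaged thresholds
geometrically accept the planted waves:

* **Sharp**: cusp-apex pulse with convex flanks, `A·(1−|u|)²`, width
  45–70 ms, amplitude 200–300 µV, ascending fraction 0.40–0.50. Convex
  flanks keep the boundary AALs small and place the AUL crossing near the
  feet, like a real spike's concave-sided deflection.
* **Slow-wave**: raised cosine, width 130–250 ms, amplitude 110–200 µV —
  a dome whose bulge drives the AAL above the slow-wave threshold.
* **Background**: 1/f Gaussian noise at 20 µV RMS, high-passed at 1 Hz to
  match the reference recording's 1–500 Hz acquisition band-pass, plus a
  faint 9 Hz rhythm. At this RMS the background genuinely contains
  slow-wave-shaped excursions (≈85–105 µV symmetric domes) that the
  slow-wave rules accept several times per normal epoch — RMS below the
  amplitude threshold does *not* imply absence of detections, since the
  rules test peak-to-boundary differences. Sharps, with their 148 µV bar,
  have essentially no false positives; this asymmetry is why the epoch
  screen keys on sharps.

Planted deflections are downward (upright); `invert=True` exercises the
orientation module and `violate_thresholds=True` scales amplitudes to 30%
so detection must reject. All draws are uniform within the stated ranges and
every epoch derives deterministically from its seed (datasets spawn disjoint
child seeds). What the generator does **not** emulate: real spike field
spread across channels, morphology drift, artifacts, sleep architecture, or
non-Gaussian background — passing benchmarks bound algorithmic correctness,
not clinical performance.

## Benchmark problem sizes

The packaged benchmarks use 200 epochs per class for the detection
sensitivity/specificity measurements and 600 epochs (200 per class) for the
three-class cross-validation; the brute-force oracle suites run on ≥1000
random instances. With these sizes the full test suite and the acceptance
script each complete in a few minutes on a single core.

## Known limitations

* The headline clinical accuracies come from a single patient's unreleased
  recording; this package reproduces their metric arithmetic and the
  method, not the patient data.
* The verbatim chord-area normalization mixes units; results are therefore
  amplitude-scale dependent (though offset invariant), matching the printed
  method rather than a dimensionally clean variant.
* Mean-plus/minus-sd calibration cannot reach near-perfect transfer even on matched
  morphology (see the ceiling analysis above).
* Detection is offline and single-channel; no spatial aggregation or
  streaming.
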