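# Methods

This note records the models, parameter choices and numerical conventions
behind `lfaquant`, and what the synthetic phantom does and does not emulate.

## The measurement model

A developed LFA strip is imaged as an 8-bit grayscale frame. Within the
region of interest (RoI) the membrane appears as a bright background crossed
by two darker bands: the **test line**, whose darkness grows with analyte
concentration, and the **control line**, which must always develop on a valid
strip. Averaging the RoI across the transverse axis yields an intensity
profile `p(x)` along the flow axis; averaging over `h` transverse pixels
suppresses per-pixel noise by ≈ √h. Bands are the two dips of `p(x)`.

Line darkness is summarised by three ratios of the line minima to the mean
background between the lines:

```
ratio_tb = test_min / background_mean
ratio_cb = control_min / background_mean
ratio_tc = ratio_tb / ratio_cb          (= test_min / control_min)
```

All three are invariant under a multiplicative rescaling of the image —
the reason for normalising at all — and `ratio_tc` additionally cancels any
variation that scales both bands of one strip together (strip-to-strip
development variability). `ratio_tc` is computed as `ratio_tb / ratio_cb` so
the identity between the three ratios holds exactly in floating point.

## Synthetic phantom

The phantom renders

```
image(x, y) = B + s·(x − x_center)
              − j·D(c)·G(x; x_test, σ)
              − j·A_ctrl·G(x; x_ctrl, σ)
              + ε(x, y)
```

with `G` a unit-height Gaussian along the flow axis (constant transversely),
`j` a per-strip amplitude factor (truncated normal, mean 1, sd
`strip_jitter_sd`, ±3 sd), and `ε` i.i.d. Gaussian pixel noise. Values are
clipped to [0, 255] and quantised by round-half-up; optional rotation/offset
(bilinear, via `scipy.ndimage`) is applied last. The test-band depth follows
a Langmuir (single-site saturation) law

```
D(c) = amp_max · c / (c + k_half)
```

— the simplest form that is proportional to concentration at low `c`
(colour formation tracks captured analyte) and plateaus at high `c` as real
strips do.

Defaults (all configurable): 640×480 image; RoI 40 rows × 200 columns at
(220, 220); flow along the image width with the test line 60 px upstream
(left) of the control line at column 370; `B = 200` counts;
`σ = 6` px; `amp_max = 160`, `A_ctrl = 80`, `k_half = 300` ng/ml — chosen so
the test band exactly matches the control band at 300 ng/ml, putting the
test-control ratio at 1 there; `pixel_noise_sd = 2` counts;
`strip_jitter_sd = 0.07`; no illumination slope, rotation or offset. The
standard dilution ladder is 0, 50, 87, 131, 200, 296, 444, 600, 800,
1000 ng/ml with 5 replicate strips per level; of these, 0/87/131/296/444/1000
are the levels a visual grading of real strips distinguishes and the other
four are evenly interleaved to cover the working range.

**All phantom geometry is invented.** Real strip band widths, spacings and
depths are proprietary; the phantom is a testbed with plausible magnitudes,
not a physical model (no wicking kinetics, no nanoparticle optics, no sensor
byte-level emulation). Consequently, passing tests demonstrate correctness of
the *analysis chain* — detection, statistics, calibration algebra — under a
controlled image model, not performance on real strips. In particular the
phantom's strip-to-strip jitter is perfectly common-mode between the two
bands, which flatters control-normalised metrics relative to real data, where
control-line variability is only partly shared with the test line.

Determinism: every stochastic element derives from one root seed;
dilution-series strips get per-strip seeds via `numpy.random.SeedSequence`
hashing of (root, concentration index, replicate index), so single strips can
be re-rendered in isolation and identical configurations give bit-identical
images.

## Line detection

* **Control line**: leftmost minimum of the (smoothed) profile inside a
  search band, default fractions [0.55, 0.95) of the profile length. The
  search is restricted rather than global because above the concentration
  where the test band outgrows the control band, a global minimum would lock
  onto the wrong line; the strip sits in a mechanically fixed holder, so a
  fixed band is justified. A profile that is flat inside the band means no
  control line developed: the strip is invalid and the measurement aborts
  (`no_control_line`).
* **Test line**: leftmost minimum inside `control − 60 ± 15` px (clipped to
  the profile). On a blank strip the window is flat, the "minimum" is local
  background, and `ratio_tb ≈ 1` — the correct null reading.
* **Background**: mean and sample sd of positions strictly between the lines,
  excluding 18 px (3σ of the band width) around each; at least 5 positions
  must remain (`background_too_small` otherwise).
* The profile is smoothed before detection with a centred moving average
  (default window 5 px; edges use shrunken windows; window 1 disables). The
  line "value" is the single minimum sample, not a band average, so on noisy
  profiles windowed minima are biased slightly low; with default noise this
  bias is ≈ 0.3 counts and is bounded by test, not corrected.
* Ties on equal minima break to the smallest position, for determinism.

## Calibration, inversion, detection limit, risk

Replicate measurements at known concentrations reduce to per-concentration
mean and sample sd (n−1; sd 0 for singletons). An unweighted least-squares
quadratic is fitted to the mean ratio (a √n/sd-weighted variant is available
behind a flag). Numerical choices:

* **Only points inside the working range enter the fit** (default
  [0, 600] ng/ml, the roughly linear part of the response). Including the
  saturated tail drags the parabola and visibly biases inversion everywhere
  below it.
* **Vertex clipping.** A quadratic fitted through a saturating response
  typically reaches its minimum just below the upper range limit and turns
  upward. Rather than rejecting such fits, the working range is truncated to
  1 ng/ml below the parabola's vertex, preserving the strictly-decreasing
  invariant on the (slightly shortened) range. Fits that are not decreasing
  at the low end — genuinely non-monotone data — are rejected
  (`non_monotone_calibration`). At least 3 distinct in-range concentrations
  are required.
* **Inversion with censoring.** An unknown ratio maps to the unique root of
  the quadratic inside the working range. Ratios brighter than the blank end
  are censored `below_working_range` (clamped to the low end); ratios darker
  than the curve at the high end are censored `saturated` (clamped to the
  high end). Nothing is extrapolated.
* **Limit of detection**: smallest concentration on a grid (default 0, 25,
  50, 100, 200, 400, 800 ng/ml) whose noise-free pipeline ratio separates
  from the blank by more than `k·σᵣ` (defaults k = 2, σᵣ = 0.07) — a concrete
  operationalisation of "the error bars no longer overlap the blank". Under
  the default phantom the rule returns 100 ng/ml: the blank-to-signal gap is
  0.11 at 50 ng/ml (< 0.14) and 0.19 at 100 ng/ml.
* **Risk and bands**: `high_risk` iff the estimate is ≥ 250 ng/ml
  (inclusive; the clinical threshold is quoted as 250–300 and the lower bound
  is adopted). The coarser visual bands use boundaries 109 and 370 ng/ml —
  midpoints of the gaps between the visually distinguishable groups
  (≤87 / 131–296 / ≥444) — and are an explicit interpolation, not measured
  values.

### Which ratio to quantify with

`ratio_tb` is the default for calibration tables and the LOD rule (it is the
most sensitive metric at low concentrations, where the control line's own
variability would swamp a weak test band). For *quantifying unknowns* in a
regime dominated by strip-to-strip development variation, the
control-normalised `ratio_tc` is preferred and is what the round-trip
validation uses: the per-strip jitter cancels, leaving mostly the quadratic's
structural approximation error (≈ 5–10% at the range ends against the
Langmuir truth). With `ratio_tb` the same round-trip carries both that bias
and the full jitter, and its median error sits at the edge of 10%.

## Problem sizes and runtime

The validation suite works at desk scale: dilution series of 50 strips
(10 × 5), Monte-Carlo loops of 50–200 rendered strips, 1,000 random profiles
for the brute-force detection oracle, and a 20-strips-per-concentration
round-trip — a few seconds each on one core. The acceptance script renders a
handful of noise-free phantoms and finishes in seconds.

## Known limitations

* No rotation/perspective correction in the analysis path (phantom
  misalignment defaults to zero); the `rotation_deg`/`offset_px` knobs exist
  to study sensitivity, not to be corrected for.
* Single-strip, two-line assays only; no multiplex detection, though the
  windowed design extends naturally.
* The quadratic calibration is a deliberate approximation to a saturating
  response; 4PL/logistic alternatives are out of scope in this version, and
  the structural inversion bias near the range ends is the price.
* RGB input is reduced by fixed BT.601 luminance weights (0.299/0.587/0.114,
  round-half-up); native grayscale capture is assumed to be the norm.
* The minimum-sample line value is biased low on blank/noisy strips (bounded
  in tests, not corrected).
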