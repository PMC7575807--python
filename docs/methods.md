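# Methods

## Model and procedure

The package treats window-length selection for a centered moving-average
(MA) filter as a curve-analysis problem. For a uniformly sampled series
x(0..T−1) and each candidate window n = 1..N, the sum of absolute
differences

    SAD(n) = Σᵢ |x(i) − MA(x, n)(i)|

measures how much signal the window-n filter removes. SAD(1) = 0 exactly
and the curve is (empirically, not provably) increasing and concave for
heart-rate-like signals, saturating once the window exceeds the dominant
noise scale. Rather than eyeballing "where it flattens", the curve is
differentiated three times with the discrete gradient — central difference
½(g(i+1) − g(i−1)) inside, first-order one-sided differences at the two
ends — and the windows at which this third gradient (jerk) changes sign are
reported. Sign changes are detected at the later index of the changing
pair; values exactly 0 inherit the most recent nonzero sign, so a
touch-and-return at zero is not a crossing and a pass through zero counts
once. Crossings fewer than `merge_gap` (default 3) steps apart are merged,
left to right, to the ceiling of their arithmetic mean, with the merged
value re-entering the comparison with the next point — the minimal
deterministic extension of the pairwise rule.

The first zero-point P₁ sits at the measurement-noise scale (a few seconds
for 1 Hz heart rate), the second P₂ at the scale where physiological
responses become visible (tens of seconds). No automatic choice between
them is made; the analyst picks, or uses the combined estimate below.

### Uncertainty-adjusted estimates

Each downstream metric m has two candidate values m₁ (P₁-filtered trace)
and m₂ (P₂-filtered). They are combined with a weight from a right triangle
with legs a = 1 and b₂ = P₂ − P₁: c = √(b₂² + 1), UF = sin α = 1/c. The
construction is inspired by the footprint of uncertainty of interval type-2
fuzzy sets (the wider the gap between the two candidate windows, the less
the liberal result is trusted); no fuzzy inference machinery is
implemented. b₁ = P₁ is part of the stated geometry and is reported, but no
formula consumes it.

The adjusted longest period is the literal l_adj = l₂·UF + l₁ — *not* the
interpolation (l₂−l₁)·UF + l₁ that the area adjustment
A_adj = (A₂−A₁)·UF + A₁ uses. The asymmetry is kept deliberately: it is how
the length adjustment is defined in the source method, even though it can
exceed l₂ when l₁ is large and UF is not small. A_adj is always a convex
combination of A₁ and A₂.

Two precision modes exist because the method's published worked example is
internally inconsistent: its printed adjusted length (1028 s from l₁ = 950,
l₂ = 1298, P₁ = 5, P₂ = 22) requires UF pre-rounded to two decimals (0.06),
while its printed adjusted area (65 728 from A₁ = 66 253, A₂ = 57 314)
requires UF at full precision (0.05872…; the rounded factor gives 65 717).
The default mode `full` uses full floating precision everywhere;
`paper_compat` applies each convention where the example did — rounded UF
for the length, full precision for the area — and reports the
full-precision length alongside. Lengths are rounded half-away-from-zero to
whole seconds; areas are kept as floats with integer rounding only for
display.

## Threshold metrics

A period above threshold thr is a maximal run of consecutive samples with
HR ≥ thr (inclusive comparison by default; a strict mode exists as a
sensitivity check). Its length is i_stop − i_start sample intervals — the
fence-post convention, under which a k-sample run has length k−1. The
boundary samples of the series may open or close a period (otherwise a
trace entirely above threshold would have none), and single-sample
excursions are kept with length 0 so that the per-period sample counts
always reconcile with the direct count of supra-threshold samples — the
conservation law the test suite asserts. The area above threshold is
(Σ supra-threshold HR) − n·thr in bpm·samples, converted to heart beats by
·Δt/60; the total area under the trace is reported alongside for context.

## Input handling

All analysis runs on a uniform grid, 1 s by default, since windows,
periods and zero-points are expressed in seconds and the gradient assumes
unit steps; window indices are samples and equal seconds only at 1 Hz (the
reporting layer converts via the sample interval). Irregular input is
binned (bin mean, bins aligned to integer multiples of the interval,
left-edge timestamps) and empty bins are filled by linear interpolation —
but only across gaps up to `max_gap_s` (default 30 s); longer gaps raise an
error rather than fabricate data. Bin-mean plus linear interpolation was
chosen over nearest-neighbour because it preserves the mean level and
cannot invent spikes. The PAMAP2 protocol `.dat` reader takes column 1 as
time and column 3 as heart rate (`NaN` = missing) and applies the same
policy; how the original analyses reduced that sparse channel to 1 s is not
documented anywhere, so this reduction is this package's own choice.

## Moving-average conventions

The filter is centered with left half-width ⌊(w−1)/2⌋ and right half-width
⌈(w−1)/2⌉ (even windows take the extra sample on the right) and the window
is clipped to the available samples at the series edges, keeping output
length equal to input length as the SAD subtraction requires and avoiding
the boundary inflation zero-padding would cause. window = 1 is the identity
bit-for-bit, and single-sample and constant inputs avoid cumulative-sum
round-off, so SAD(1) = 0 holds exactly. These conventions are fixed so SAD
curves are reproducible bit-for-bit; a source using a different edge policy
will differ slightly near the boundaries.

## Numerical notes

* One-sided endpoint differences contaminate one additional index per
  gradient pass: the third gradient of a cubic-in-n curve equals six times
  the leading coefficient exactly on indices [3, N−4], not at the three
  indices nearest each end. Tests assert exactness on that interior.
* Zero-crossing detection, merging and selection are pure integer/sign
  logic — identical input bytes give identical zero-points.
* `classic_flattening_window` (smallest n whose relative SAD change over
  the next `span` windows is below `rel_tol`, defaults 10 and 1 %) is a
  clearly-labelled heuristic stand-in for the informal plateau-by-eye
  baseline; it is reported for comparison only and can legitimately return
  "did not flatten".
* N defaults to 250 and is validated against the series length; slowly
  flattening data may need a larger N (set `--max-window`).

## Synthetic generator

`sadjerk.synthetic` builds heart-rate-like traces as a pure function of
(spec, seed): piecewise-linear segments (level, duration, slope), Gaussian
noise of chosen SD, and rectangular artifacts — spikes (defaults sized like
the ~40 bpm excursions seen in real exercise traces), shallow dips (1–2 bpm
below a zone threshold, the phenomenon that splits supra-threshold
periods), and dropouts (replacement by a 60 bpm resting value). Gaussian
noise is a modelling choice, not a claim about sensor physics; the SD is a
parameter rather than a hard-coded "realistic" value. The generator does
not emulate heart-rate variability spectra, cardiac drift dynamics beyond
linear slopes, or beat-to-beat timing — so passing tests demonstrate the
*algorithmic* behaviour (window selection, dip healing, metric
conservation) on traces with the right coarse structure, not performance on
any real recording.

The canonical `dip_heal_scenario` fixture is noise-free by design: a 1200 s
trace (200 s at 95 bpm, 800 s at 115 bpm, 200 s at 95 bpm) with a 3 s dip
to 103 bpm — 2 bpm below the 105 bpm threshold — at mid-bout. Noise-free,
its guarantees are deterministic: the raw trace has two supra-threshold
periods (longest 398 s), and any MA window ≥ 7 samples lifts the dip back
above threshold ((4·115 + 3·103)/7 ≈ 109.9 ≥ 105), leaving a single period
longer than the raw maximum. The test sweep covers windows 7–99; windows
approaching the bout length itself would eventually smear the bout below
threshold, which is the over-smoothing failure the method guards against,
not a counter-example to the dip-healing claim.

## Problem sizes

The acceptance checks run at the sizes the method is used at: the
worked-example combination is closed-form; oracle-equivalence runs 100
random 600-sample series with N = 60; metric conservation runs 1000 random
series of 20–150 samples; the dip fixture is the full 1200 s trace. The
whole suite completes in well under a minute on one core.

## Known limitations

* The jerk zero-points of a short or very smooth series may number fewer
  than three (a constant series has none); the pipeline then skips the
  adjustment stage with a warning instead of failing.
* Only single-channel, uniformly-resampled series are supported — no ECG
  waveforms, RR intervals, or multi-channel files, and no multi-zone
  partitioning beyond a single threshold.
* The literal l_adj formula is not scale-free in l₁ (see above); users
  wanting a convex combination should read l_adj alongside the reported l₁
  and l₂.
* Published per-subject tables for the PAMAP2 / PhysioNet recordings
  depend on dataset downloads and on subject mappings and preprocessing
  that were never specified; `scripts/reproduce_tables.py` provides batch
  plumbing only and is excluded from the tested surface.
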