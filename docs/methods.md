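# Methods

## Input model and coordinate conventions

The pipeline consumes per-frame landmark predictions — x, y, likelihood for
each of (by default) forehead, nose, tongue tip and chin — as produced by a
markerless pose estimator. Coordinates are pixels in image convention
(origin top-left, y increasing downward); no physical calibration is
attempted, because the metrics of interest are relative magnitudes and
trends within and across sessions of one recording setup. Time is
`frame / fps`; the frame rate must be supplied (default 25 frames/s, a
standard bedside-camera rate) since landmark tables do not carry it. The
file's frame-index column orders the rows but is not used for timing.

Two dialects are read: the DeepLabCut CSV export (three header rows —
scorer, bodyparts, coords — with x/y/likelihood triplets) and a plain wide
CSV (`frame`, `<name>_x`, `<name>_y`, optional `<name>_likelihood`,
defaulting to 1.0). HDF5 exports are out of scope; CSV is the contract.

## Cleaning

Frames whose likelihood falls below a confidence threshold (default 0.9, a
conventional pose-estimation cutoff) have their coordinates replaced by
linear interpolation between the nearest confident neighbours;
leading/trailing low-confidence runs take the nearest confident value.
A low-confidence run longer than `max_gap` (default 0.5 s of frames) is a
data-quality error rather than something to paper over: half a second of
untracked tongue can hide an entire dyskinetic burst, so the user must
decide. Confident frames are never modified, and each cleaned track records
how many frames were imputed.

## Index frame

Displacement is measured from a fixed reference ("index") frame, by
convention the recording's first frame. Since the first frame may itself be
poorly tracked, the pipeline uses the earliest frame at which *every*
landmark meets the confidence threshold, falling back to frame 0 with a
warning if none qualifies. With clean data this is frame 0 exactly.

## Kinematic series

* Tongue displacement: dx(t), dy(t) relative to the index frame and the
  Euclidean magnitude √(dx²+dy²). The magnitude is the primary severity
  series; the per-axis series support axis-resolved views and the default
  between-session comparison.
* Inter-landmark distances: per-frame Euclidean distance between tongue tip
  and each other landmark.
* Whole-face vector series: the sum over the other landmarks of those
  distances, either raw (`Σ d_k(t)`) or, by default, as absolute deviation
  from the index frame (`Σ |d_k(t) − d_k(t₀)|`). The deviation form is the
  default because it isolates movement: its session means sit far below any
  plausible raw tongue–forehead distance sum, matching the magnitudes such
  summaries report in practice, and it reads 0 for a motionless face. The
  raw form is retained for completeness.

A deliberate asymmetry, exploited as a test property: a rigid translation of
the whole face (head repositioning) leaves every distance-based series
unchanged but shifts displacement series. Displacement metrics are therefore
biased by head motion; an optional nose-centred compensation helper exists
but is off by default, since the reference analysis applies none.

## Summary metrics

"Total displacement length" is the plain sum of the per-frame series, so
total = mean × n_frames exactly; it is not an arc length (a separate
`path_length` helper provides that). Totals are video-duration-dependent, so
each block also carries total per second. The standard deviation is the
population form (ddof 0) by default — this keeps the Poincaré identity
exact — with the sample form available by flag.

Poincaré descriptors are computed over the lag-1 pairs (s(t), s(t+lag)):
SD1 = std(diff)/√2, SD2 = std(sum)/√2. The identity SD1² + SD2² = 2·Var(s)
holds up to O(1/n) edge effects (the two marginal sub-series omit one end
point each); for n ≥ 1000 the relative gap is under 1 %. `implied_std`
inverts the identity, allowing an overall Std to be recovered from a
(SD1, SD2) pair — the package's desk-scale consistency check on published
summary tables.

Peak detection follows SciPy's find-peaks semantics: strict local maxima
(plateaus resolved to their midpoint), a minimum-separation constraint
resolved greedily in favour of higher peaks, then a topographic-prominence
filter. Defaults: prominence ≥ 10 % of the series range, separation ≥ 0.5 s.
These defaults are declared choices, not inferred ones — the reference
analysis does not record its parameters, which is why every report echoes
the full configuration.

**Choosing the prominence threshold.** The relative default adapts to each
series and suits single-session exploration, but for *counting* events
across sessions of different severity an absolute threshold is required:
on a burst-free series the range collapses to the noise floor and a relative
threshold promotes jitter to "peaks". The noise floor itself is larger than
naive intuition suggests: the displacement magnitude differences each frame
against the index frame, so with tracking jitter of sd σ the per-component
noise has sd σ√2, and over ~750 frames the largest noise prominences reach
≈ 6σ. The burst-recovery experiments therefore use an absolute prominence of
10 px — well above that floor at σ = 1 px and well below the smallest
simulated burst (20 px).

## Between-session inference

Per-frame values of a selected series (default: tongue x-displacement) are
grouped by session and compared with one-way fixed-effects ANOVA, followed
by all-pairs Tukey HSD. Both statistics are computed from the classical
formulas (sums of squares; q = |mean_i − mean_j| / √(MS_w/2·(1/n_i+1/n_j)),
which reduces to the balanced form and handles unbalanced designs as
Tukey–Kramer). F-statistic p-values come from the F distribution;
studentized-range tail probabilities are computed by direct numerical
integration — the range CDF of k standard normals, averaged over the
scaled-chi distribution of the pooled scale estimate — with absolute
accuracy around 1e-8 (cross-checked against an independent implementation
to 1e-6 in the tests; above 1e5 within-group df the infinite-df limit is
used).

Treating frames as independent observations mirrors the underlying clinical
analysis but ignores strong temporal autocorrelation; the resulting
p-values are anti-conservative and should be read descriptively. No
correction is applied, deliberately. A normality screen (skewness, excess
kurtosis, histogram) emits warnings only — it never gates the ANOVA, since
the reference procedure checked normality by inspection. The displacement
*magnitude* series is non-negative and typically right-skewed; the per-axis
series are closer to symmetric.

## Synthetic sessions

The simulator emulates a 30 s bedside recording at 25 fps of a four-landmark
face on a vertical midline (forehead (320,100), nose (320,220), tongue tip
(320,300), chin (320,360) px):

* independent Gaussian jitter per landmark (default sd 1 px) — the tracking
  noise floor;
* a slow shared sinusoidal head drift (default 3 px at 0.05 Hz, random
  phase) — inflates displacement, cancels in distances;
* tongue bursts: Gaussian pulses (default peak 40 px, FWHM 0.5 s) at
  Poisson event times (default 0.2 /s, i.e. ~6 bursts per recording) in
  uniformly random directions, or at an explicitly supplied schedule for
  controlled experiments;
* confidence dropouts: tongue frames demoted to likelihood U[0, 0.5] with
  probability 0.02 per frame.

The Gaussian pulse shape is chosen for its unambiguous single prominence.
All draws flow from one integer seed through NumPy's PCG64 generator, so
sessions are bit-reproducible. Defaults are fixed study conditions, not
fitting knobs.

The four-day severity schedule used in the qualitative-trend checks injects
(10 × 80 px, 5 × 40 px, 2 × 20 px, 0) bursts at evenly spaced times with
drift and dropouts off, emulating monotone clinical improvement down to a
burst-free day.

What the simulator does **not** model: pose-estimator failure modes other
than white jitter and dropouts (identity swaps, systematic bias near
occlusion), head *rotation* and scale change (only translation), lighting,
and any physiological structure in the tongue trajectory beyond isolated
bursts. Passing tests on synthetic data therefore demonstrate correctness
of the computation and the stated invariances, not clinical validity on
real video.

## Numerical choices and degenerate inputs

* Population (ddof 0) statistics throughout by default.
* A fully constant data set yields ANOVA F = 0, p = 1 (not an error); a
  zero within-group variance with distinct means yields F = ∞, p = 0.
* `clean_track` refuses tracks with zero confident frames.
* Peak detection requires ≥ 3 samples; Poincaré requires ≥ lag + 2.
* Translation invariance of distance series is exact in exact arithmetic;
  in floating point it holds bitwise only when the shift is exactly
  representable relative to the coordinates (integer shifts of binary-
  fraction coordinates), which is how the invariance test is constructed.
* CSV output uses `repr` (round-trip) floats for session files and a fixed
  `%.10g` format for reports, so repeated runs are byte-identical.

## Known limitations

Single-camera 2-D kinematics only; no affine head-pose normalisation or
lens-distortion correction. Pixel units make magnitudes
camera-geometry-dependent, so absolute values are not comparable across
setups. The frame-independence assumption in the ANOVA stage overstates
significance. Peak counts depend on declared detector parameters; there is
no attempt to map any metric onto clinical rating-scale scores.
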