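# Methods

`spinecm` reimplements, end to end, the server-side analysis chain of a
smartphone-based continuous trunk measurement: an inclinometer is slid
along the spine from C7 to S1, producing a timestamped angle trace whose
shape — not its timing — carries the clinical information. This note
records the model, the conventions chosen where more than one was
defensible, and what the synthetic data used for testing does and does
not establish.

## Speed-invariant normalization

A raw scan is a sequence of `(t, angle)` samples at a device rate near
10 Hz (transverse torsiometer mode) or 100 Hz (sagittal inclinometer
mode). Because operator hand speed varies, raw traces are not comparable
across acquisitions. The trace (after subtracting the operator's scalar
calibration offset) is partitioned into 400 consecutive index chunks —
chunk *i* holding raw indices `[floor(i·N/400), floor((i+1)·N/400))` —
and each chunk is replaced by its mean ("chunk averaging"). No other
filtering is applied; noise suppression is left entirely to the
polynomial fit.

Conventions that the data format does not itself fix:

* **Chunk partition on sample index, not elapsed time.** Deterministic,
  near-equal counts, and exact when N is a multiple of 400. Time-based
  chunking would differ for strongly non-uniform sampling.
* **Traces shorter than 400 samples** are linearly interpolated in index
  space up to exactly 400 points before chunking; interpolation
  preserves shape and the paper-level pipeline never states a minimum
  count.
* **Arc coordinate.** Profile value *i* sits at the chunk midpoint
  `s_i = (i + 0.5)/400` on `[0, 1]`, with 0 at C7 and 1 at S1; the
  midpoint convention avoids endpoint bias.
* Chunk means are accumulated with `np.add.reduceat`, so the N = 400
  case reproduces the input bit-exactly.

Chunk averaging removes timing information, so it is invariant to speed
fluctuations that average out within a chunk's time span. It is **not**
invariant to sustained speed drift: an operator who spends half the scan
time on the first third of the spine maps that third onto half of the
profile. Our sinusoidal speed profile (speed ∝ `1 + a·sin(2πft)`,
defaults a = 0.3, f = 2 Hz) oscillates around the mean pace and two
4000-sample noise-free scans agree to < 0.05° max-abs; the integrated
random-walk profile drifts (≈3.6° discrepancy at walk SD 0.02 per step)
and is provided precisely to exhibit this limitation. No position
sensing exists in the instrument, so this is a property of the method,
not of the implementation.

## Curve reconstruction

The 400-point profile is fitted by least squares with a degree-9
polynomial — flexible enough for multiple curvature inversions, stiff
enough to smooth sensor noise. The regression runs internally in a
Chebyshev basis on the data domain (a raw degree-9 Vandermonde on 400
points has condition ≈ 10^6, and its normal equations ≈ 10^13) and the
result is converted to monomial coefficients over `s ∈ [0, 1]`, which
are what the API reports. `fitted_values` is defined as the monomial
polynomial evaluated at the arc positions, so that identity holds
exactly. First and second derivatives are computed analytically from the
coefficients.

The unit-test oracle for the fit is an exact rational-arithmetic
normal-equations solve (`fractions.Fraction` Gaussian elimination) on a
dyadic-valued profile; a float64 normal-equations solve would be too
ill-conditioned to act as a 1e-6-relative referee.

## Landmarks and clinical outcomes

Landmark detection operates on a series with plateaus (runs of equal
values) compressed to a single candidate at their first index:

* `n2` — global minimum, first occurrence on ties;
* `n1` — nearest local peak strictly left of `n2` (interior compressed
  index with strictly larger value than both neighbours); if none, the
  maximum over the left segment ("previous maximum"); if `n2` is at the
  left edge, `n1 = n2`;
* `n3` — the mirror rule on the right.

A flat series therefore yields `n1 = n2 = n3` at index 0. Landmarks are
detected on both the fitted ("poli") and the raw normalized ("orig")
series; clinical outcomes always use the fitted series, the orig
landmarks are carried in the report for inspection.

**Transverse plane.** The right hump is the signed global maximum of the
reconstructed curve (reported when positive), the left hump the signed
global minimum (when negative); `var1`/`var2` are these signed extrema.
The ATR is the absolute magnitude of the more prominent hump, rounded
half-away-from-zero to a whole degree (scoliometer resolution; symmetric
between sides). Ties between equal-magnitude humps resolve to the right
side.

**Sagittal plane (standing).** `var1 = n1 − n2` is the thoracic kyphosis
amplitude and `var2 = n2 − n3` the lumbar lordosis amplitude — the pre-
and post-minimum excursions of the inclination curve. The sign
convention makes the kyphotic limb positive and the thoracolumbar
transition negative, so a typical adolescent profile reads kyphosis
≈ +30°, lordosis ≈ −43°. Apex positions are the first-derivative zeros
nearest `n1` and `n3`; the transition is placed at `n2`. A curve whose
valley lands on an edge has no interior minimum; the edge-fallback
landmarks are used and the outcome is flagged `degenerate`.

Scanning the same back in the opposite direction reverses the profile;
`n1` and `n3` swap roles and kyphosis/lordosis swap magnitudes with sign
flips — this reversal symmetry is enforced by test.

## Agreement statistics

* **ICC.** Two-way ANOVA mean squares (`MSR` rows/subjects, `MSC`
  columns/measurements, `MSE` residual); the primary form is absolute
  agreement over the average of k measurements,
  `ICC(A,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n)`, with the
  single-measure and consistency forms available. The 95% CI follows
  the McGraw–Wong F approximation (single-measure bounds stepped up by
  Spearman–Brown for the average form); the p-value is the one-sided F
  test of `MSR/MSE` on `(n−1, (n−1)(k−1))` df. A non-positive ICC
  denominator (no usable agreement signal, e.g. anti-correlated
  columns) leaves the estimator undefined — NaN, flagged — judged with
  a 1e-12 relative threshold so exact boundary tables classify
  deterministically; defined estimates are clipped at −1. The
  implementation agrees with `pingouin.intraclass_corr`'s ICC(A,k) to
  1e-12 on structured tables and with an exhaustively enumerated
  from-scratch ANOVA oracle (all 2-column tables, n ≤ 5, entries in
  {0,1,2}) to 1e-10.
* **SEM/MDC.** `SEM = SD·√(1 − ICC)`, `MDC = z·SD·√(2(1 − ICC))` with
  z = 1.96 (α = 0.05 two-sided); the identity `MDC = z·√2·SEM` holds to
  machine precision. The SD is the pooled sample SD of all observations
  across columns — a reliability table prints one mean (SD) per
  measure, and the pooled choice is the one documented here.
* **Spearman** via midranks with the t approximation (n − 2 df); a
  seeded permutation option exists for small n. Classification bands on
  |ρ|: insignificant < 0.3, low < 0.5, moderate < 0.7, high < 0.9,
  very high ≥ 0.9 (the 0.9 edge is assigned upward so the bands tile).
  ICC bands: poor < 0.4, moderate < 0.75, excellent ≥ 0.75.
* **Bland–Altman**: differences d = x − y, bias = mean(d), limits
  bias ± 1.96·SD(d) with the n−1 sample SD.
* **Sample size** for detecting ICC ρ1 against ρ0 with k measurements:
  Walter–Eliasziw–Donner,
  `n = 1 + 2k(z_{1−α} + z_{1−β})²/[(k−1)(ln C0)²]` with
  `C0 = (1 + kρ0/(1−ρ0))/(1 + kρ1/(1−ρ1))`, one-sided α by default,
  rounded up, with optional loss inflation `ceil(n/(1−loss))`. The
  standard design point (ρ1 = 0.5, k = 2, 80% power, α = 0.05
  one-sided) gives 22; at 90% power and ρ1 = 0.6 the formula gives 19.
  The analytic power of the resulting F test at n = 22, k = 2, true
  single-measure ICC 0.5 is 0.795 (`3·F(21,21)` against its 0.95
  quantile), consistent with the 80% design claim; seeded simulations
  land at 0.78–0.80.

## Synthetic data

Geometries are sums of Gaussian bumps over arc position — the minimal
smooth family producing single/double rib humps and
kyphotic-then-lordotic sagittal curves with multiple inversions. Scans
sample a geometry under a speed-profile time-warp with optional timing
jitter and Gaussian angle noise; every draw is governed by an explicit
integer seed and is bit-reproducible. Rating tables follow the two-way
additive model `y_ij = true_i + bias_j + e_ij`, whose implied
absolute-agreement average-measures ICC
`σ_s²/(σ_s² + (σ_bias² + σ_e²)/k)` is available analytically and can be
inverted for a target ICC (`error_sd_for_target_icc`).

Default magnitudes mirror the reliability tables of adolescent cohorts
measured with this class of instrument (e.g. right Adams hump mean 4.8°,
SD 4.1°, ICC 0.93; kyphosis 30.5°/12.9°; lordosis −43.2°/7.8°), shipped
as the `MEASURE_PRESETS` dictionary. Bump widths are fixed modelling
choices: 0.15 of the arc for the transverse hump and 0.16 for the three
sagittal bumps (centers 0.2/0.55/0.9) — a realistic multi-vertebral
extent at which the degree-9 fit tracks the family well inside the 0.5°
approximation budget used by the recovery tests. The sagittal preset
solves the bump amplitudes so the field's actual extrema equal the
prescribed n1/n2/n3 (a short fixed-point refinement handles bump
overlap, residual < 0.01°).

What the simulator does *not* emulate: torso surface biomechanics,
sensor-fusion artifacts, skin-contact loss, operator repositioning, or
heavy-tailed noise. Passing recovery tests therefore demonstrates that
the *pipeline arithmetic* is correct under the stated acquisition model,
not that the instrument is valid on real patients — that question is
empirical and belongs to clinical data.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen for statistical
resolution: 2000 replicates for type-I error, power and CI coverage
(binomial SE ≈ 0.5–1%), 1000 for ICC recovery (SE of the mean
≈ 0.001), 4000-sample scans for the speed-invariance bound, 400-point
profiles throughout, and exhaustive enumerations where the domain is
finite (3^8 landmark series; all small ICC tables). The full suite runs
in well under a minute of simulation time on one CPU.

## Known limitations

* Index-based chunking is only speed-invariant up to within-scan speed
  fluctuation that averages out; sustained drift biases the arc mapping
  (see above).
* Degree-9 fits underestimate very narrow features (width ≲ 0.08 arc);
  the defaults avoid this regime, real scans with extremely focal humps
  would not.
* The ICC CI is an F-based approximation; its simulated coverage at
  n = 32, k = 2, ICC 0.7 is ≈ 0.95 but degrades for very small n.
* Landmark detection assumes a single dominant valley; multi-valley
  sagittal profiles resolve to the global minimum and flag nothing.
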