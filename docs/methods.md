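# Methods

## Data model and preprocessing

A recording is a per-subject sequence of finite, non-negative activity
counts at fixed epochs of P minutes (default 1; P must divide 1440).
Epoch indexing is 0-based and half-open within the day: t ∈ {0, …, l−1}
maps to clock minutes [tP, (t+1)P). Recordings carry a
`start_offset_minutes` field; alignment discards every epoch before the
first midnight, and segmentation keeps ⌊length/l⌋ whole days, discarding
the trailing partial day. Both trims are logged with the counts they
removed, and nothing else ever modifies a count value, so total retained
count plus logged discards equals the input total. Missing epochs in an
input table are a hard error; an explicit `fill_gaps` option zero-fills
and logs them instead. All operations accept generic l, so toy grids
(l = 4, 8, 16) exercise the same code paths as the production l = 1440.

## Motion PDFs

Per day: P_{s,k}(t) = y_{s,k}(t) / Σ_t y_{s,k}(t). An all-zero day has no
defined density; it is flagged degenerate and excluded from averages with
a warning (reducing that subject's effective day count), never replaced by
a uniform density. Subject profiles are the plain mean of the subject's
day PDFs; group profiles are the plain mean of subject profiles. Subjects
are therefore weighted equally regardless of D_s (7 vs 14 observed days),
which is the deliberate averaging order: divide by D_s inside, by the
number of subjects outside. Every PDF at every level must sum to 1 within
1e−9 — double-precision headroom at l = 1440 — and the invariant is
enforced at construction.

The insomniac group mean is denoted P_I(t) throughout, symmetric in form
to the control P_C(t).

## Delayed Jaccard distance

J(P,Q) = 1 − Σ min(P,Q)/Σ max(P,Q) is a metric on densities over the
circular day. The delayed curve evaluates J(P, Q(·+τ)) at all l integer
shifts (no sub-epoch interpolation): τ_min is the amount by which Q must
be advanced to best overlap P, so with P = control and Q = insomnia,
τ_min > 0 reads "insomnia lags control by τ_min minutes". Worked example
at l = 8: Q(t) = P(t−3) gives J(3) = 0 and τ_min = 3.

Ties in the global minimum break toward the shift circularly closest to
0, then toward the smaller index — a flat curve (uniform PDFs) yields
τ_min = 0 deterministically. The plateau is the maximal circular run of
consecutive shifts with J ≤ J_min + tol containing τ_min; `plateau_tol`
defaults to 1e−3 absolute in J units (an interpretation-scale choice —
differences in J below 10⁻³ are far below count-noise effects at realistic
cohort sizes) and is exposed in configuration. Plateau width is reported
in minutes.

## Spectral decomposition

The forward DFT uses the negative-exponent, unnormalized convention,
ŷ(ω_k) = Σ_t x(t)e^(−i2πtk/l), implemented via `numpy.fft.fft` and tested
against a naive O(l²) double-sum oracle. No detrending or windowing is
applied. For real day vectors only k = 0 … l/2 are kept: k = 0 (DC) never
enters ensembles, and the Nyquist coefficient is real with phase in
{0, π}. Phases are quadrant-aware two-argument angles on the fixed branch
(−π, π] — a deliberate correction of the quadrant-blind arctan-of-a-ratio
shorthand, since observed phases span the full circle. A coefficient whose
amplitude is ≤ 1e−12 relative to the largest retained amplitude is treated
as numerically zero; its phase is undefined, recorded as NaN, and excluded
from ensembles with a logged count (never coerced to 0). Structurally
exact zeros do occur: a step profile awake exactly 2/3 of the day has
vanishing components at every k divisible by 3.

Ensembles pool one amplitude and one phase per component per day-segment
over all subjects of a group (subject-first averaging is available as an
option; pooling is the default and what the tests characterize).
Degenerate days are excluded consistently with the PDF pipeline. The
reporting cutoff K defaults to 30; full l/2 ensembles are available on
demand. Phase summaries use the circular mean (argument of the mean unit
phasor) with resultant length R ∈ [0, 1]; an arithmetic mean on the fixed
branch exists for comparison. A vanishing resultant (antipodal sample)
makes the mean angle undefined, returned as NaN.

Unit conversions: component k has period lP/k minutes; a phase difference
wraps to (−π, π] before converting via Δφ·lP/(2πk), so a nominal 350°
difference reads −40 min at k = 1, not +1400.

## Group testing

Per component, amplitudes (raw values) and phases (fixed branch) are
compared with the two-sided two-sample KS test. The p-value uses scipy's
exact small-sample null when n_a·n_b ≤ 10⁴ and the asymptotic Kolmogorov
distribution otherwise; asymptotic tail underflow is floored at the
smallest normal double so p stays in (0, 1]. Plain KS on a fixed branch is
the primary phase comparison; a rotation-invariant two-sample Kuiper
variant (V = D⁺ + D⁻ with the standard asymptotic series and small-sample
correction) is exposed as a non-default option for sensitivity analysis.
No multiple-testing correction is applied by default, matching
per-component reporting; Benjamini–Hochberg is available as an option.
Labels: significant p < 0.01, marginal 0.01 ≤ p < 0.1, both thresholds
configurable.

## Synthetic cohort generator

The generator emulates a two-group wrist-actigraphy study: by default 21
controls and 18 insomniacs, each observed a uniform-random 7–14 whole
days at 1-minute epochs, recordings starting at midnight. The per-epoch
mean intensity is a two-level day/night profile — awake on the circular
interval [wake, sleep) at `day_level` counts/epoch (default 300), asleep
at `night_level` (default 20) — with linear ramps of
`transition_width_minutes` at activity onset and offset: 10 min for
controls (abrupt transitions), 120 min for insomniacs (slow evening
decay). Default schedule: wake 07:00, sleep 23:00. Weak ultradian cosines
a·day_level·cos(2πkt/l + φ) are superposed, by default at k = 17, 19, 20
with relative amplitudes 0.03/0.02/0.01 (their sum stays below the night
level so the intensity is positive everywhere; configurations violating
this are rejected). The injected phase convention matches the DFT: on a
flat base profile, component k reads back exactly φ.

The insomnia intensity is circularly delayed by `offset_delay_minutes`
(default 90, the study-scale group offset) in both modes: `shift_only`
uses the delayed control intensity itself (making Δ the exact ground
truth for shift-recovery tests), otherwise the insomnia profile's own
shape is built first and then delayed.

Count noise families: `point` (no noise; counts equal the intensity),
`poisson`, and the default `nbinom` — a gamma-mixed Poisson with mean μ
and variance μ + μ²/r, r = 10 by default. No noise characterization of
real count devices is assumed anywhere in the analysis, so the family and
dispersion are free modelling choices, chosen once as a plausibly
overdispersed regime and documented here rather than tuned.

Seeding: one master seed; subject i of group g draws from
`SeedSequence(seed, spawn_key=(g, i))`, so cohorts are reproducible and
adding subjects never perturbs existing ones.

What the generator does **not** emulate: weekday/weekend structure, naps,
device non-wear gaps, infradian modulation, inter-day variability of the
underlying profile, or any empirically measured device noise. Tests
passing on synthetic cohorts therefore demonstrate correctness of the
estimators under the stated generative model — exact shift recovery,
calibrated type-I error, phase recoverability — not performance on real
recordings.

## Verification problem sizes

The test suite checks, among others: exact recovery of built-in delays
Δ ∈ {30, 60, 90, 120} min from noiseless shift-only cohorts at full
l = 1440; Δ = 90 min inside the reported plateau in ≥95% of 20
overdispersed-noise replicates at the default cohort size; type-I error
of the k = 1 amplitude KS test within the 99% binomial band around
α = 0.05 over 500 null replicates (10 v 10 subjects × 5 days on a
10-minute-epoch grid, exact KS at 50 v 50); ≥95% detection (p < 0.01)
of a 90-minute k = 1 phase offset over 100 replicates at 147 vs 126
day-segments with Poisson noise; and circular-mean phase recovery within
0.1 rad for an injected k = 17 component at relative amplitude 0.3 under
Poisson noise. The signal-to-noise floor for phase recovery at l = 1440
is roughly a·day_level·l/2 ≫ √(l·day_level) per segment; at the tested
a = 0.3, day_level = 200 the signal-to-noise ratio per segment is ≈80,
far above threshold, and recovery degrades gracefully as a shrinks.

## Known limitations

- τ_min is estimated between group-mean PDFs (the primary definition
  here); subject-level delayed-Jaccard curves are computable through the
  same API but are not aggregated into an alternative estimator.
- Phases are compared by plain KS on a fixed branch; samples straddling
  the ±π cut can inflate apparent differences. The Kuiper option guards
  against this but is not the default.
- No confidence interval is attached to τ_min; the plateau width is a
  resolution statement, not a sampling-uncertainty interval.
- Epoch-resolution shifts only; true offsets between epoch multiples
  round to the grid.
- The exact-vs-asymptotic KS switch at n_a·n_b = 10⁴ produces slightly
  discontinuous p-values across that boundary; both regimes are
  deterministic and documented.
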