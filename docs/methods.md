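# Methods

This note records the model, the numerical conventions, and the design
choices behind `fallwave`, at the level of detail a maintainer or reviewer
needs to re-derive the package's behavior.

## Signal model and units

All accelerations are in g (1 g = 9.81 m/s²); no unit conversion happens
inside the package.  A `Recording` is an (n, 3) array of axis accelerations
at a fixed sampling rate Fs (100 Hz default).  Every downstream quantity is
computed from the acceleration sum vector SV(t) = √(ax² + ay² + az²), which
is rotation-invariant and ≈ 1 g at rest.  SV is used raw — no filtering or
detrending is applied before analysis.

An *active period* is a one-minute recording whose SV range (max − min)
strictly exceeds 1.01 g; this is the inclusion criterion that defines the
ADL class.

## The adapted mother wavelet

**Fall pattern.** For each training fall, the 2-s window centered on the
first global SV maximum (the impact peak) is extracted; windows are
half-open `[peak − Fs·1, peak + Fs·1)` so the peak sits at offset Fs.  Falls
whose peak window would overrun the recording are excluded with a warning.
The pattern is the per-sample mean (with SD) of these aligned windows.

**Conversion to Ψ_fall.** The pattern is mean-subtracted and placed on N
equispaced abscissae of [0,1] with N equal to the pattern length (no
resampling; dx = 1/(N−1)).  Two conversion methods exist:

- `direct` (default): the mean-subtracted pattern itself.
- `polynomial`: a least-squares polynomial approximation under the linear
  constraint that the fit sums to zero, computed in a Chebyshev basis for
  conditioning (default degree 40; the basis is nested, so the residual is
  non-increasing in the degree).

Either way the ends are then tapered to zero with a cosine ramp over 2% of
the grid per side (continuity at the interval ends), the zero integral is
restored exactly by subtracting a taper-shaped multiple (this keeps the
endpoints pinned at zero), and the result is scaled to unit discrete L2 norm.
Construction enforces |Σψ·dx| ≤ 1e-6 and Σψ²·dx = 1 ± 1e-6.

`direct` is the default because the prototype concept is literally "the
average fall pattern as a wavelet": any polynomial smoothing of the ~0.1-s
impact spike discards exactly the structure the similarity score relies on
(the projection only reproduces the direct result around degree ~80).  The
polynomial route is kept for experiments with deliberately smoothed
prototypes.  Mean subtraction makes the conversion invariant to any
constant offset of the pattern, and the final normalization makes it
invariant to positive rescaling.

## The transform and its conventions

Coefficients are computed on an integer grid of scales
a ∈ [1.5·Fs, 2.5·Fs] and translations b ∈ [0.5·Fs, 1.5·Fs], step 1 sample
(configurable), as

    C(a, b) = w(a) · Σ_k SV(b + k) · ψ̃_a(k),      k ∈ [−a/2, a/2]

with the following conventions, each of which matters:

- **Translation marks the support center.**  ψ is evaluated at
  (k)/a + 1/2, i.e. the dilated wavelet occupies [b − a/2, b + a/2].  The
  prototype's impact peak sits at the midpoint of [0,1], and candidate
  windows are peak-centered, so the restricted translation band brackets
  the expected match at b = Fs.  (With a start-anchored support the band
  could never align the peaks at all.)
- **Discrete admissibility per scale.**  ψ̃_a is ψ linearly interpolated at
  the dilated lattice and then recentered to exact zero mean over its
  support; resampling alone leaves a small nonzero sum that would make the
  transform sensitive to constant offsets.
- **Edge extension, not zero-padding.**  Scales above 2·Fs always overhang
  the 2-s window; the window is extended by replicating its edge samples.
  A locally constant level then meets the full support and is annihilated
  exactly; zero-padding would instead inject a 1 g → 0 step at the window
  borders — the border effect the translation restriction is meant to
  avoid.
- **Normalization.**  w(a) = 1/a by default (L1), with w(a) = 1/√a (L2)
  as an option.  The two differ by a monotone per-scale factor.  Under the
  L2 weight a signal with exactly the prototype's shape maximizes at the
  matched scale a = 2·Fs (verified to ±2 samples); the L1 weight adds a
  1/√a tilt that favors compact, sharply peaked matches, and for a sharply
  peaked prototype moves the scale argmax to the lower grid edge while
  leaving the translation argmax at the window center.  Empirically (10
  seeded synthetic replicates) the L1 weight discriminates falls from ADLs
  better — broad smooth ADL transients match the prototype best at large
  scales, which 1/a suppresses — so it is the default; scale-localization
  statements are made, and tested, under the L2 option.
- Δt = 1 sample; coefficient magnitudes are therefore meaningful only
  within one convention, and thresholds are never compared across
  conventions.

## The three features

- **wavelet**: scan SV in order (stride 1 by default); each sample above
  the 1.5 g trigger whose centered 2-s window fits (windows overrunning an
  edge are skipped by default; reflection padding is available) is scored
  by the maximum C(a, b) over the grid; the feature is the overall maximum
  across candidates, clipped below at 0.  No trigger crossings → exactly 0.
  The trigger is deliberately below any plausible impact peak so falls are
  never skipped; raising it can only remove candidates (the feature is
  non-increasing in the threshold).
- **UPV**: global maximum of SV.
- **LPV**: minimum of SV within 1 s (configurable) up to and including the
  global maximum — the free-fall dip preceding the impact.  Low LPV
  indicates a fall, so evaluation orients it with `higher_is_fall=False`.

## Evaluation

Stratified k-fold (default 10) cross-validation, stratifying on the
fall/ADL label (delegated to scikit-learn's `StratifiedKFold` with
shuffling under the run seed).  For each fold the prototype is rebuilt from
the training falls only; the held-out recordings are scored once.  UPV/LPV
need no training.

**ROC and vertical averaging.**  Within a fold, a recording is called a
fall when its score strictly exceeds a threshold; sweeping the threshold
over the observed scores traces vertices from (specificity 0, sensitivity
1) to (1, 0).  Each fold's curve is sampled at fixed specificities on a
0..1 grid with step 0.001: linear interpolation between vertices of
distinct specificity, and the attainable upper point exactly at a vertex
specificity.  On tie-free scores this reproduces the empirical staircase —
the trapezoidal AUC of the sampled curve equals exhaustive threshold
enumeration and the Mann–Whitney statistic up to the grid resolution —
while fully tied scores degrade to the chance diagonal (AUC 0.5).  Fold
curves are averaged pointwise ("vertical averaging"); AUC is the trapezoid
over the averaged curve.

**Operating point.**  The maximum Youden index (sensitivity + specificity
− 1) over the averaged curve, ties resolved toward higher specificity; the
reported threshold is the median of per-fold thresholds realizing that grid
specificity.  95% CIs are mean ± 1.96·SD/√k over per-fold values; the CI
construction of the original tables is not documented, so ours is stated
rather than claimed identical.  Note the headline max YI comes from the
averaged curve while the CI comes from per-fold maxima; fold maxima are
upward-biased relative to the averaged-curve maximum (a max of means is
below the mean of maxima), so the point estimate can sit below its CI.

**Comparisons.**  Paired Wilcoxon signed-rank tests on per-fold AUC (and
per-fold max YI) of the wavelet feature vs each baseline, Bonferroni m = 2
per metric, α = 0.05, boundary inclusive.  The exact two-sided p-value is
computed from the null distribution of the signed-rank sum over doubled
mid-ranks (zeros dropped, ties mid-ranked), built by convolution — exactly
equivalent to enumerating all 2^m sign assignments — for up to 25 nonzero
pairs, with the tie-corrected normal approximation beyond.  Fewer than 5
folds → comparisons are reported as unavailable rather than computed.

**False alarms.**  A specificity s over n ADLs drawn from H hours of
monitoring projects to (1 − s)·n false alarms and (1 − s)·n/H per hour.

## The synthetic data generator

The generator emulates the recording conditions of real-world fall
datasets collected from lower-back sensors:

- one-minute recordings at 100 Hz; SV is the designed quantity and the
  tri-axial split assigns it a slowly wandering unit direction (features
  depend on SV only; the split exercises I/O and `compute_sv`).  With
  noise_sd = 0 the designed SV is reproduced exactly.
- **Falls**: rest at 1 g; cosine dip to LPV ~ U[0.2, 0.8] g over
  0.2–0.4 s; impact rise to UPV ~ U[2, 6] g over 0.05–0.15 s; damped
  ringing (4–8 Hz, time constant 0.3 s, amplitude 35% of the impact
  excess); impact near the midpoint ± up to 5 s.  A fraction 16/29 of
  falls is clipped per-axis at ±2 g (the rest, and all ADLs, at ±6 g),
  mirroring the mixed device ranges of real deployments — this saturation
  of most fall peaks is what makes the UPV baseline weaker than the
  wavelet feature on real data, and the ordering only emerges in
  simulation when it is modeled.
- **ADLs**: gait-band sinusoid (1.5–2.5 Hz, amplitude U[0.2, 0.6] g with
  slow waxing/waning) plus occasional smooth raised-cosine transients,
  upward (Poisson(0.7) per recording, peak height U[1.2, 3.0] g, width
  0.3–0.8 s, gait crossfaded out underneath so the drawn height is the
  realized maximum) and downward (Poisson(0.6), depth U[0.3, 0.7] g).
  Transients are symmetric bumps: no dip-then-sharp-peak fall signature.
  Recordings are redrawn until the active-period criterion holds.  The
  transient rates are calibrated so the *post-rejection* ADL population
  overlaps the fall features the way real active periods do: ≈13% exceed
  2.79 g at their maximum and ≈35% dip below 0.5 g — the overlap rates
  implied by the published specificities of UPV and LPV thresholds at
  those values.
- Gaussian SV noise, σ = 0.02 g.

What the simulator does **not** emulate: subject identity and within-
subject correlation (no leave-one-subject-out is possible), realistic gait
harmonics and posture transitions, sensor drift, or fall types with
atypical morphology (syncope-like slow collapses).  Passing the end-to-end
tests therefore shows the pipeline recovers the designed structure under
realistic amplitude overlap — not that the feature's clinical performance
on real falls is reproduced.

## Numerical details and degenerate inputs

- Peak ties: first global maximum wins everywhere.
- `max_coefficient` returns the first grid point on ties (scales-major).
- Constant patterns (zero wavelet) and polynomial degrees < 2 are rejected;
  empty recordings, out-of-bounds window centers, single-class folds,
  non-positive monitoring hours raise `InvalidInputError` with context.
- Sampling-rate inference from CSV time columns uses the median
  inter-sample interval and rejects > 1% jitter.
- Scan stride and scale/translation steps can be raised for speed; stride-1,
  step-1 results are the reference.

## Problem sizes

Default study conditions are 29 falls and 200 ADLs with 10-fold CV; the
test suite and the acceptance script use these sizes, with 10 seeded
replicates for the wavelet-vs-UPV ordering, and smaller sets (8–12 falls)
for unit-level checks.  A full replicate evaluates ~229 one-minute
recordings in a few seconds on one CPU.

## Known limitations

- Coefficient magnitudes (and hence score thresholds) are specific to this
  package's discretization; published threshold values from other
  implementations are not comparable.
- The vertical-averaging grid (0.001) limits AUC agreement with exhaustive
  enumeration to about that resolution.
- With very few falls per fold the per-fold ROC is coarse; CIs from 10
  folds on 29 falls are wide, and the Wilcoxon test at 10 pairs has limited
  power — mirroring the small-sample reality of real fall datasets.
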