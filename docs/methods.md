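# Methods

This note documents the processing chain, the synthetic-data model behind
the tests, the numerical choices, and what the package deliberately does
not do.

## Processing chain

1. **Gait events.** Hindlimb impacts are detected from hind-hoof vertical
   position: a downward crossing of a threshold set at 10% of the
   channel's per-trial range above its minimum, with negative velocity,
   refined to the first sample entering the stance plateau (within 2% of
   range of the minimum) and debounced at 60% of the running stride
   period. A crossing not followed by a stance dwell (≥ 10% of a stride
   below threshold) — e.g. a recording truncated at touch-down — is not
   emitted. Externally detected events can be supplied in the trial
   header and bypass detection. Whether "impact" is best defined at
   hoof-on or at peak deceleration is a modelling choice; the
   threshold-crossing definition is simple and exactly testable against
   the generator's ground truth, and nothing downstream depends on which
   valid detector is used.
2. **Stride segmentation.** Strides are half-open windows `[impact_k,
   impact_{k+1})` of one reference limb; a boundary sample belongs to the
   later stride. Side-specific sEMG parameters (sEMGabs) use each side's
   own hindlimb; all asymmetry parameters (kinematic and sEMGasym) use
   the left hindlimb so both sides share one temporal domain. Stride
   frequency is the reciprocal of the median stride duration.
3. **Kinematic filtering.** Upper-body displacement is high-pass filtered
   with a zero-phase (forward–backward) 4th-order Butterworth at
   `0.5 × stride frequency`. The factor 0.5 removes inter-stride body
   height drift while leaving both the double oscillation at `2f` and the
   asymmetry component at `f` essentially untouched (zero-phase gain at
   `f` with cut-off `f/2` is ≈ 0.996); it is configurable
   (`RunConfig.kin_cutoff_factor`).
4. **MinDiff / MaxDiff.** Per left-referenced stride, the window is split
   at its time midpoint and the index is the first-half extremum minus
   the second-half extremum. The midpoint split (rather than a split at
   the contralateral impact) keeps the computation well-defined when only
   left-limb events serve as reference. A stride whose halves do not each
   contain an interior local minimum and maximum is dropped (never
   imputed) and counted in the run log.
5. **Hip Hike.** Each limb's stance/swing windows are split at the
   contralateral impact (left stance = left impact → right impact, etc.);
   the index is the left minus right tuber coxae (max − min) amplitude
   per window. This amplitude-difference form is one of several Hip Hike
   formulations in use; it is documented here as this package's
   definition.
6. **Sign convention.** Positive MinDiff/MaxDiff/HipHike means the
   left-associated value is larger. All indices are odd under left-right
   mirroring of a trial. Data from right-side inductions are multiplied
   by −1 (signed parameters) and have their sEMGabs side labels swapped,
   after which sides are reported as LS (lame side, ipsilateral to
   induction) and NLS (non-lame side).
7. **sEMG conditioning.** DC-offset removal, zero-phase 4th-order
   Butterworth high-pass at 40 Hz, full-wave rectification. Because the
   filter runs forward–backward, the effective attenuation is the squared
   single-pass magnitude response — the quantity the filter tests check.
8. **ARV, outliers, normalization.** The ARV is the arithmetic mean of
   the rectified signal over the stride. Within each horse × muscle ×
   side × condition (and segmentation convention), ARVs outside
   mean ± 2 SD are removed in a single pass, with limits computed before
   any removal; the sample SD (n−1) is used — the choice of denominator
   is configurable in `remove_arv_outliers`. Survivors are normalized to
   the maximum surviving ARV of the **same measurement day's** baseline
   (baseline1 for iFL, baseline2 for iHL), so baseline values peak at
   exactly 100% and induced values may exceed it. Order is fixed:
   preprocess → segment → ARV → outlier removal → normalization.
9. **sEMGasym pairing.** Left and right ARVs are paired by left-referenced
   stride index; if either side was removed as an outlier the pair is
   dropped and logged.
10. **ROC / Youden.** Candidate cut-offs are the midpoints between
    consecutive distinct pooled values plus ∓∞ sentinels. The
    classification direction is fixed a priori per family — sEMGabs: lame
    above the cut-off; signed asymmetry parameters: lame below (the
    left-induction sign) — so AUC < 0.5 is possible and reported as-is
    rather than silently flipped. Youden ties are broken by higher
    specificity, then smaller |cut-off|. The trapezoidal AUC equals the
    all-pairs Mann–Whitney statistic with ties counted half. No
    confidence intervals or AUC-difference tests are computed. Strides,
    pooled across horses, are the classification unit.
11. **Induction sufficiency.** An induction is "sufficient" when the
    change in mean asymmetry between the paired baseline and induced
    condition reaches 13 mm for the head (MinDiff or MaxDiff poll,
    forelimb) or 5 mm for the pelvis (MinDiff and/or MaxDiff pelvis,
    hindlimb), and the induced condition's SD is smaller than its mean
    magnitude for the triggering parameter. The SD clause is evaluated on
    the induced condition only: baseline means are near zero by
    definition, so requiring SD < mean there would make the rule
    unsatisfiable. An insufficient induction is flagged prominently but
    does not abort the ROC stage.

## Synthetic cohort

The generator's defaults describe the study design the package targets:
8 horses × 4 conditions (baseline1, iFL, baseline2, iHL), 25 strides per
trial, stride frequency drawn per horse from 1.3–1.6 strides/s,
kinematics at 200 Hz and sEMG at 2000 Hz from one shared clock.

* **Midline displacement** = double oscillation `−A·cos(4πf t')` (A = 45 /
  25 / 35 mm for poll / withers / pelvis, minima at 12% and 62% of the
  stride) + an asymmetry component at `f` that offsets the two per-stride
  minima by exactly the injected value `a` and the maxima by `0.6a` +
  slow sinusoidal body-height drift (8 mm at 0.07 Hz) + white measurement
  noise (0.5 mm SD).
* **Per-stride variability.** The asymmetry takes a per-stride value
  `a + N(0, 1.5 mm)`, linearly interpolated between stride centres.
  Draws are mean-centred within each trial so that the trial mean equals
  the injected asymmetry exactly; without centring, each horse ×
  condition acquires a random trial-level offset that mis-centres the
  no-effect AUC distribution away from 0.5 (the generator's null
  calibration invariant).
* **Tubera coxae** oscillate at `2f` with amplitudes `30 ± a/4` mm so the
  stance/swing amplitude difference recovers the injected hip-hike value.
* **Hooves**: zero-height stance plateaus (duty factor 0.45) joined by
  80 mm half-sine swing arcs; the swing-to-stance transition is the
  ground-truth impact.
* **sEMG** = `dc_offset + scale · m_k · envelope(phase) · carrier`, with a
  20–450 Hz band-limited Gaussian carrier (SD 1.0), a Gaussian activation
  burst per stride at a muscle-specific phase (σ = 0.08 stride, tonic
  floor 0.25) locked to the ipsilateral hind cycle, and a lognormal
  per-stride amplitude multiplier `m_k` (σ = 0.15). The condition effect
  is the `scale` factor per (muscle, LS/NLS side, condition).
* **Injected effects** (defaults): iHL — NLS biceps ×1.5, LS gluteal and
  LS semitendinosus ×1.4, all other muscles ≤ ×1.15, pelvis asymmetry
  10 mm, hip hike 14 mm; iFL — triceps-led factors ≤ ×1.25 and a 25 mm
  head nod. With σ = 0.15 stride-to-stride variability the analytic
  two-lognormal AUC for a ×1.5 factor is ≈ 0.97 and for ×1.4 ≈ 0.94,
  placing the strongest synthetic parameters in the same band as the
  strongest parameters such experiments report; no public data constrain
  these distributions, so the values are plausible defaults, not a
  calibration.
* **Variance-reduction choice.** The per-stride multipliers `m_k` are
  drawn per (horse, muscle, side, stride index) *independent of
  condition*, i.e. baseline and induced trials share the same sequence.
  ROC analysis only sees the per-class marginal distributions, which are
  unchanged; but ratios of condition means become exact in expectation,
  which makes the generator's linearity contract (mean ARV scales with
  the injected factor) sharply testable at 25 strides.

What the generator does **not** emulate: stride-timing variability
(impacts are exactly periodic per trial), inter-muscle correlation of
bursts, movement artefact and power-line interference in sEMG, marker
occlusion/gap-filling, compensatory mechanics coupling the two limbs, and
day-to-day electrode repositioning. Passing tests therefore demonstrate
that the *pipeline* recovers known effects under clean, stationary
conditions — not that the parameters would reach the same AUCs on real
recordings.

## Numerical choices and degenerate inputs

* Zero-phase filtering uses `scipy.signal.sosfiltfilt`; series shorter
  than the filter warm-up raise an explicit error.
* Stride windows map to sample indices as `ceil(t·fs)` half-open ranges;
  an empty window is an error, not a NaN.
* Outlier limits on groups smaller than 3 are skipped with a warning.
* A baseline ARV group that is missing or all-zero raises an error naming
  the muscle/side rather than dividing by zero.
* Flat hoof channels (range < 5 mm) and trials with fewer than 3 impacts
  per limb raise insufficient-data errors.
* AUC edge behaviour: identical classes give 0.5; sentinel thresholds
  carry the (0,0) and (1,1) operating points.
* Filter edge transients of the low cut-off kinematic high-pass extend
  roughly one stride into each end of a trial; the generator therefore
  adds a lead-in/lead-out margin around the requested strides.

## Problem sizes

Default test and acceptance runs use 2–8 horses and 10–32 strides per
trial (the full default cohort is 8 × 4 trials × 25 strides). These sizes
give every ROC at least ~50 strides per class after outlier removal —
enough that Monte-Carlo checks (null AUC within 0.5 ± 0.1, effect
recovery within a few percent) are stable — while keeping a full run in
seconds.

## Known limitations

* The stride — not the horse — is the unit of analysis; pooled-stride
  AUCs overstate certainty relative to a per-horse analysis because
  strides within a horse are correlated. (The per-horse stratified
  variant is a natural extension; it is not implemented here.)
* Fixed classification directions mean a parameter whose true effect
  opposes its convention reports AUC < 0.5 rather than being flipped.
* No multivariate combination of parameters and no mixed-effects
  modelling; this package evaluates each parameter univariately.
* C3D ingestion is an extension point; the on-disk dialect is plain CSV.
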