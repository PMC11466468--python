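# Methods

## Problem and quantities

A tomotherapy unit modulates its fan beam with 64 pneumatic binary leaves.
The plan prescribes, per leaf and per projection, a *leaf open time* (LOT):
how long the leaf should stay out of the beam within that projection.  The
delivered dose tracks the executed LOTs, so verifying them — without a
phantom, for every fraction — is the basis of log-style patient-specific QA,
and the only practical option in adaptive workflows where the patient stays
on the couch while the plan is re-optimized.

`tomolot` reconstructs executed LOTs from two independent telemetry streams
and calibrates both against an ionization-chamber ground truth:

* **MV-detector method** — the 640-channel exit detector samples the exit
  fluence at 300 Hz.  After preprocessing, each leaf's per-projection pulse
  is measured as its width at a fractional height τ_MV.
* **Optical-sensor method** — photodiode pairs read a notch on each leaf at
  ~0.18 ms cycle time, giving a CLOSED / TRANSITION / OPEN state stream.
  Each open event contributes
  `LOT(τ) = [t3 + τ(t4 − t3)] − [t1 + τ(t2 − t1)]`,
  where t1…t4 are the four state-change times and τ_opt places the effective
  opening/closing instant inside the transition.
* **Chamber ground truth** — chamber charge is proportional to the
  time-integrated beamlet fluence, so for the reference plans
  `mean LOT = q_x / q_100% · t_proj` (only relative charge matters; no
  electrometer calibration or volume-averaging correction is needed).

Both thresholds are free parameters of their measurement definitions.  They
are fixed by a sweep: compute the mean discrepancy between method and
chamber over a calibration session at each τ on a grid (default 0.30–0.70,
step 0.01) and take the zero crossing by linear interpolation.

## Reference plans

Calibration uses 12 static-gantry plans: jaw openings {1, 2.5, 5} cm ×
LOT fractions {25, 50, 75, 100}% of a 348 ms projection, 400 projections,
leaves 27/39/47 active (the chamber positions), all other leaves closed.
The 100% plans serve as the charge-ratio denominators; the nine partial
plans provide the 27 calibration pairs (3 jaws × 3 fractions × 3 leaves).

## MV preprocessing chain

1. **Arc correction.** A sample is flagged as an arcing transient when its
   all-channel median jumps more than 5 robust SDs (1.4826·MAD of successive
   median differences) relative to *both* neighbours; flagged samples are
   replaced by per-channel linear interpolation in time.
2. **Leaf extraction.** The channel axis is interpolated linearly at each
   leaf's fractional channel coordinate (default: leaf ℓ at channel
   5 + 10(ℓ−1)).
3. **Offset subtraction.** The baseline (leakage + dark current) is the 5th
   percentile of the leaf's samples inside projections where the plan
   commands the leaf closed; result clipped at 0.  A low quantile, not the
   mean: a closed leaf's channel still sees cross-talk from open neighbours,
   and folding that pulse-shaped contamination into the baseline breaks the
   scale-equivariance of the deconvolution that follows (an early version
   using the mean produced a reproducible ~1 ms width bias).  Leaves open in
   every projection fall back to the 5th percentile of their whole trace.
4. **Richardson–Lucy deconvolution** across the leaf axis, per time sample,
   with a configurable cross-talk kernel (default [0.1, 0.8, 0.1], 10
   iterations).  RL is chosen for its positivity and flux conservation; with
   a normalized kernel the per-sample sum across leaves is preserved to
   better than 10⁻⁶ relative for interior-supported signals.
5. **Normalization.** Each leaf/projection segment is divided by its maximum
   over the central 50% of the projection window (excluding the edge
   transitions).  Projections whose central maximum is below 20% of the
   delivery-wide leaf-signal maximum are treated as closed and zeroed,
   so detector noise on a closed leaf is never normalized to unit height.
   A consequence shared with the real method: a commanded LOT too short to
   reach full opening is still normalized to 1 and its width overestimated.

Width at threshold: first upward and last downward crossing of τ inside the
projection window, located by linear interpolation between samples; a pulse
still above τ at a window boundary counts up to the boundary, so a leaf held
open across projections contributes full projection widths.  All outputs are
in ms; no resampling is performed.

## Optical segmentation

A leaf's state-change stream is segmented into events:

* **normal** — CLOSED→TRANSITION→OPEN→TRANSITION→CLOSED, giving t1…t4;
* **merged** — two OPENs separated only by a TRANSITION (commanded closed
  gap under ~50 ms: the leaf cannot close fully).  The shared transition is
  split at its midpoint, which stands in as t3 = t4 of the first event and
  t1 = t2 of the second.  This conserves total open time and is symmetric
  in τ; both halves are tagged `merged_open`;
* **no-open** — CLOSED→TRANSITION→CLOSED (commanded LOT too short to reach
  the open state): LOT is 0 by definition.

Events are assigned to the projection containing their temporal midpoint
(t1+t4)/2 and never split across projections, preserving the per-event LOT
identity; an event spanning more than two projections is assigned by
midpoint with a warning.  Adjacent-state violations (e.g. CLOSED→OPEN)
raise a malformed-log error naming the record.

## Synthetic delivery model

No public machine telemetry exists, so the package ships a simulator that
generates all three streams from one per-leaf transmission trajectory; its
defaults define the study conditions for every end-to-end test.

**Trajectory.** Commanded open intervals (centred in their projections,
coalesced when they touch) are executed with a command latency (20 ms), a
systematic fluence-LOT shift (+1.8 ms, emulating the executed-vs-planned
excess observed on real units), and Gaussian edge jitter (SD 1 ms).  Leaf
travel is linear in time over the opening (24 ms) and closing (16 ms)
transitions — asymmetric, as pneumatic open and close strokes differ; the
asymmetry is also what makes the optical threshold identifiable, since with
equal transition durations the event formula is exactly τ-independent.
Commanded closed gaps shorter than 50 ms produce a partial close: the leaf
dips toward closed and turns around, emitting the merged sensor sequence.
Commanded LOTs too short to complete the opening stroke produce a partial
peak and the no-open sequence.

**Transmission.** Beam transmission versus travel fraction follows a smooth
asymmetric penumbra curve, T(x) = x − 0.14 sin²(πx) + 0.03913 sin(2πx),
with mean exactly 0.43.  Consequently the fluence-equivalent boundary of a
transition sits at travel fraction 0.57, and T(0.57) = 0.42 — so the MV
width measurement matches the fluence LOT exactly at τ_MV = 0.42, and the
optical sensors (which switch into the new state at travel fractions 1.0
opening / 0.7544 closing, leaving the parked state at motion start) match
at τ_opt = 0.57 on both edges.  These defaults reproduce the threshold
asymmetry reported for real units; `linear` and `cosine` ramps (both
time-symmetric, true thresholds 0.5) are available for exactness tests.

**Ground truth** is the fluence-equivalent open time: the analytic integral
of T(x(t)) over each projection (piecewise-quadratic antiderivative, exact
to float precision).  The chamber charge is the same integral over the whole
delivery, scaled by the jaw opening, with 0.1% relative noise — so the
charge-ratio conversion is exact on noiseless runs by construction, which is
precisely the property that makes chamber charge a ground truth.

**MV trace**: transmission convolved across leaves with the cross-talk
kernel, mapped onto 640 channels by linear interpolation between leaf
centres, scaled by the jaw opening, plus a constant offset (0.06 of the open
amplitude), Gaussian noise (SD 0.01), and Poisson-timed single-sample
all-channel arcing spikes (0.05 s⁻¹).  **Optical log**: state-change records
quantized to the 0.18 ms polling cycle.

What the simulator does *not* emulate: detector saturation and pulse-level
linac output variation, dynamic-jaw shadowing, scatter between beamlets,
analog photodiode response, couch/gantry kinematics.  Passing tests
therefore demonstrate the correctness and internal consistency of the
reconstruction and calibration logic under a realistic error budget — not
the physics fidelity of any particular machine.

## Numerical choices

* Thresholds swept on 0.30–0.70 (step 0.01); τ* by linear interpolation at
  the first sign change; no sign change raises an error advising a wider
  grid.  Evaluating the mean discrepancy at τ* returns 0 within 0.05 ms
  (interpolation tolerance).
* The optical sweep is evaluated analytically: each event's LOT is affine
  in τ, so per-leaf mean curves are computed from two coefficients without
  re-segmentation.
* Replicate deliveries are averaged at the mean-LOT level before pairing
  (the charge ratio already yields one mean per delivery).
* Discrepancy summaries use the sample SD (n−1) and flag outliers beyond
  1.5×IQR from the quartiles; outliers are reported with labels, never
  silently removed.
* The paired two-tailed t-test (α = 0.05) compares calculated with measured
  mean LOTs; a zero-variance pairing is reported as degenerate rather than
  raising.  Pearson r and the OLS fit of calculated on measured come from
  `scipy.stats`.
* Mean LOT of a sinogram leaf is its row sum divided by the number of
  projections, matching the chamber's time-integrated quantity.
* 300 Hz samples are never resampled; sub-sample crossing times come from
  linear interpolation.  Remaining MV biases (finite sampling across curved
  ramps, normalization-maximum noise bias) shift the calibrated τ* by well
  under 0.01 — absorbed by calibration exactly as on a real unit.

## Problem sizes

End-to-end calibration/validation runs use the full 400-projection reference
plans: 12 deliveries for calibration (27 method-vs-chamber pairs) and 24
(two replicates of the nine partial plans plus references) for validation,
27 replicate-averaged pairs.  Unit tests use 2–10-projection plans, which
exercise every code path at negligible cost.

## Known limitations

* The optical method cannot observe how deep a partial close dips, so it
  overestimates the fluence LOT across merged events by up to one
  close+open transition span; the MV method shares a milder version of this
  through its normalization of never-fully-open pulses.  Reference plans
  avoid this regime by design.
* Sensor timing fractions and transition durations of real MLCs are not
  published; the defaults are plausible and configurable, and parameter
  recovery is verified against the simulator's own equivalents.
* Static jaws only; dynamic-jaw deliveries would shadow the MV detector and
  are out of scope.
* The fraction report summarises sinograms; it deliberately performs no
  dose reconstruction or gamma comparison.
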