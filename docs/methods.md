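# Methods

## Signals and conditioning

A trial is a 120 Hz record of three channels: grip force `gf` (N, the
normal force at the digits), stand load force `lf_stand` (N, the
vertical pull measured through the instrumented stand while the object
rests on it) and `az` (m/s², combined gravitational + kinematic
acceleration along the object's long axis).  All channels are low-pass
filtered with a 2nd-order Butterworth at 20 Hz applied forward and
backward (`scipy.signal.filtfilt`), i.e. an effective 4th-order
magnitude response with exactly zero phase — phase distortion would
bias every onset and peak time.  Force rates are finite differences of
the filtered signals (`numpy.gradient`: central in the interior,
second-order one-sided at the edges).  Non-finite samples are a hard
error; these records are too short for imputation to be anything but a
bias.

The load force on the digits is only observable through the stand
until lift-off; afterwards it is reconstructed as `mass · az`.  The two
sources are spliced at the stand-force maximum: the stand reading peaks
at the object's weight at the instant of lift-off and both sources
equal the weight there, so the merged trace is continuous to within
sensor noise.  (Splicing at the weight-crossing itself is circular —
the crossing is defined on the merged trace — and numerically fragile,
because the filtered stand channel tops out just *below* the weight:
its true peak falls between samples and zero-phase filtering shaves the
cliff at lift-off.)  The object's weight is estimated per trial as
`mass ·` median of the filtered `az` baseline before grip onset, so
per-trial deviations of the realized gravity are respected.

## Event detection

All landmarks use the sustained-threshold rules standard for grip-lift
data, with run lengths rounded conservatively (⌈0.125 s × 120 Hz⌉ = 15
samples; the 250 ms backoff is 30 samples):

* **onsets** (`tGFo`, `tLFo`): first sample of the first run with rate
  strictly above 0.4 N/s lasting ≥ 125 ms.  "First sample of the run"
  rather than the last keeps preload durations consistent with the
  convention that the onset marks where activity begins.  The LF onset
  search starts at `tGFo` (the digits touch the object before pulling).
* **lift-off** (`tLFw`): first crossing of the weight by the merged
  load force, linearly interpolated between bracketing samples — the
  only event defined by a level crossing rather than a sample test.
* **trial end** (`tEnd`): first run of load-force rate below −2 N/s
  lasting ≥ 125 ms (the set-down), minus 250 ms.  Searched from `tLFw`
  so loading-phase transients cannot fire it.
* **peaks**: global maxima of GF over `[tGFo, tEnd]` and LF over
  `[tLFo, tEnd]`; ties break to the earliest sample.
* **plateaus**: arithmetic means over the last 1.0 s before `tEnd`.

Detected events must satisfy `tGFo ≤ tLFo < tLFw ≤ tEnd`; violations
flag the trial rather than producing silent nonsense.

## Per-trial models

**Grip-force relaxation.**  Between the grip-force peak and the trial
end, `GF(t) = a + b·e^(−c·(t − tGFmax))` is fit by bounded nonlinear
least squares (`scipy.optimize.curve_fit`; a, b ≥ 0, c ∈ [10⁻³, 50]
1/s).  Initialization: `a₀` = mean of the segment's final second,
`b₀ = GF(tGFmax) − a₀`, `c₀ = 2` 1/s, with a deterministic ladder of
rescaled `c₀` values (×1, ×0.25, ×4, ×0.1, ×10) as restarts.  A flat
segment short-circuits to the degenerate fit (b = 0, c at its lower
bound, rmse 0) because c is unidentifiable there.  The offset `a` is
the robust plateau estimate; `1/c` is the relaxation time constant
reported as `tau`.

**Rate coupling.**  Over the loading phase `[tLFo, tLFw]` the
load-force rate is the reference; the grip-force rate is shifted
against it by every integer-sample lag within ±150 ms (37 lags at
120 Hz, no sub-sample interpolation) and the Pearson correlation
computed per lag.  The maximizing (r, lag) is reported; positive lag
means the grip-force rate led.  Exact ties break to the smaller |lag|,
then to the positive one.  Segments with variance below 10⁻¹² N²/s²
make the correlation undefined and are an error.

## Session aggregation

Switching indices are computed per participant per consecutive-phase
pair (`ΔGF = GF_max` of trial 1 in the next phase minus trial 4 in the
previous), then averaged across participants per transition;
participant-first aggregation matches the degrees of freedom of
per-participant inference.  The decomposition `ΔGF = α·m·Δg·g₀ + β`
(with g₀ = 9.81 m/s², Δg in multiples of g) is computed in two modes —
α pinned at 1.5 with β free, or β pinned at 1.44 N with α free — and in
both the identity `predictive_term + β = ΔGF` holds to 10⁻⁹ N by
construction.  The fixed-margin gain is undefined for Δg = 0.

Trial-1 peak regressions use per-phase participant means (one point per
stable phase) of trial-1 GF and LF peaks, fit by ordinary least squares
(`scipy.stats.linregress`).  "Ascending" covers phases up to and
including the single highest-g phase, "descending" from it on; the
highest-g phase contributes one point to pooled fits and is excluded
from ascending-vs-descending contrasts (it belongs to both limbs).
p-values use standard t approximations; no multiple-testing correction
is applied at this descriptive layer.

## The synthetic generator

`simulate_trial` builds each trial from closed-form primitives on a
uniform 120 Hz grid, then adds noise:

* **load force**: zero through baseline and preload; a cubic smoothstep
  ramp over the loading phase (default 300 ms) to a peak
  `(1 + overshoot)·m·g·g₀` (overshoot 0.12); linear relaxation of the
  overshoot at 1.2 N/s — a rate chosen between zero and the −2 N/s
  set-down criterion so settling can never satisfy the release rule,
  while the peak stays sharp enough to localize; a hold at exactly the
  weight (~2 s); a smoothstep release sized so the peak release rate
  matches `release_rate` (−8 N/s).
* **grip force**: a contact transient (Gaussian saturation, amplitude
  1 N, time scale preload/1.6 — brisk at contact, essentially complete
  by LF onset) plus a component proportional to load force, reaching
  `grip_gain·m·g·g₀ + margin` at the load-force peak; then exponential
  decay with time constant `decay_tau` (0.5 s) to the plateau
  `grip_gain·m·g·g₀`; release after the load force is down.  The
  additive margin is `base_margin` (1 N) on every trial plus
  `first_trial_margin` (1.44 N) on trial 1 after a transition —
  placed on grip force only, so trial-1 and trial-4 load forces
  overlap.  Summing a transient and a load-proportional component keeps
  the grip-force rate positive throughout the rise (real traces have no
  stationary point at the preload/loading junction) and makes the rise
  track the load-force rate over the loading phase.
* **stand channel / accelerometer**: the stand reads the load force
  until lift-off, then unloads over 100 ms; `az` reads `g·g₀` before
  lift-off and load/mass afterwards, so the reconstruction
  `mass · az` returns exactly the imposed load force.  After set-down
  `az` follows the (zero) finger load rather than returning to `g·g₀`
  — a deliberate simplification; the analysis window ends before it
  matters.
* **noise**: additive white Gaussian, SD 0.05 N per force channel
  (well inside a ±0.1 N sensor accuracy) and 0.1 m/s² on `az`.  The
  gravity level of each trial is jittered by SD 0.07 g around the
  programmed level, matching the spread of realized Gz in a long-arm
  centrifuge.
* **timing**: preload 70.9 ms on trial 1 and 66 % of that on trials
  2–4, reproducing the first-trial preload lengthening; 0.5 s baseline
  and tail.  Trial onset times within a phase are not modelled — trials
  are generated independently.

Because the grip-force peak scales on the *static weight* rather than
on the overshot load-force peak, the generator satisfies
`ΔGF = grip_gain·m·Δg·g₀ + first_trial_margin` exactly (before noise),
which is what makes the (α, β) recovery tests sharp.  A configured
grip–load lag is imposed as an integer sample shift of the whole
grip-force profile (positive = grip leads).

The gravity schedule defaults to 1, 1.5, 2, 2.5, 2, 1.5, 1 g with
18.4 s stable phases (27.4 s idle 1 g bookends), 1.6 s fast transitions
between hypergravity levels and 13.4 s slow transitions into and out of
1 g; all slopes stay below 0.32 g/s.  Every trial draws from an
independent `numpy` child stream keyed by (seed, participant, phase,
trial), so output is bit-reproducible and insensitive to generation
order.

**What the generator does not emulate** — and hence what passing
recovery tests do and do not show: no limb/muscle dynamics or
within-trial kinematic variability beyond the stereotyped profile, no
slips or friction, no inter-participant differences (all participants
share one parameter set; only noise realizations differ), no stress or
habituation dynamics beyond the fixed first-trial margin, and noise
that is white rather than the mixed drift/quantization of real strain
gauges.  Recovery on these traces validates the estimators'
correctness, not their robustness to every pathology of real
recordings.

## Numerical choices and degenerate inputs

* Run-length rounding is toward longer runs (ceil with a 10⁻⁹ guard
  against float fuzz in `min_duration · fs`).
* The onset threshold comparison is strict (`>`), so a rate pinned
  exactly at threshold never fires.
* Intervals are treated half-open in file conventions; plateau and
  peak windows include both endpoint samples.
* Under the default noise, the filtered force-rate noise has SD
  ≈ 1.6 N/s, an order of magnitude above the 0.4 N/s onset threshold
  at single-sample level; the 125 ms sustained requirement is what
  makes detection reliable.  The test suite quantifies the residual
  cost: each landmark is recovered within 5 samples in ≥ 95 % of 200
  seeded noisy trials, and within 2 samples on noiseless traces.
* Floats are written with 17 significant digits and read back with
  correctly-rounding parsing, so file round-trips are bit-identical.

## Known limitations

* The end rule requires a clean set-down; trials where the object is
  released more gently than −2 N/s sustained are flagged, not rescued.
* The fixed-margin gain diverges as Δg → 0; schedules with repeated
  equal levels should use the fixed-gain mode across those transitions.
* Cross-correlation lags are integer samples (8.3 ms resolution);
  sub-sample asynchrony is not estimated.
* The measured lag on synthetic trials can differ from an imposed lag
  by one sample, because the contact transient leaves a small
  non-proportional residue of grip-force rate at the start of the
  loading window.
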