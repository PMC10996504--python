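# Methods

## The task model

Two stimulus streams (tactile air puff, visual drifting grating; 2 s
each) are scheduled per session. In the *shaping* phase a balanced label
vector is randomly permuted (so counts are exactly equal, not
coin-flipped) and consecutive events are separated by Uniform(8, 12) s
gaps — a trial structure in which the unrewarded stimulus is informative.
In the *full* phase each stream independently draws the gap to its next
stimulus as Exponential(mean 10 s) + Uniform(8, 12) s, clipped at 55 s
and rounded to the nearest whole second. Beyond the 12-s offset support
the exponential's memorylessness makes the per-bin hazard analytically
constant at 1 − e^(−1/10) ≈ 0.0952 per 1-s bin, which is what the
flat-hazard checks assert. The rewarded (CS+) modality triggers a reward
exactly at stimulus offset.

Two open readings were fixed as follows: "binned by seconds" is
implemented as rounding the drawn interval to the nearest second (floor
would shift the mean by ~0.5 s away from the 20-s design value), and the
55-s cap clips rather than redraws (redrawing would distort the hazard in
the 13–45 s range that is asserted flat). Both choices are surfaced in
`RunConfig` (`isi_binning`, `isi_cap_mode`). The gap convention is
offset-to-next-onset; since the minimum draw is 8 s, streams never
overlap within a modality either way, and all interval statistics concern
the draws themselves.

## The synthetic session generator

The generator emulates the statistical structure the analyses assume,
not the biophysics:

* **Spiking** is an inhomogeneous Poisson process realized by
  discrete-time thinning on a 1-ms grid (one Bernoulli draw per bin with
  p = r(t)·dt; exact for the rates used, where r·dt ≤ ~0.05). The rate is
  r(t) = baseline × gain(t) + w · c(t), where gain(t) takes the modality
  gain from stimulus onset + latency for the response duration (maximum
  when windows overlap), an offset gain covers the 2 s after CS+ offset,
  and c(t) are mean-centered coupling signals: pupil lagged 1 s (the lag
  at which thalamic activity correlates with pupil most strongly),
  whisking amplitude, and 250-ms-smoothed lick rate. Negative rates are
  floored at zero and logged. Coupling weights are in Hz per unit of
  signal (degrees for whisking, trace units for pupil, licks/s for lick
  rate). `spike_rate_vector` exposes the exact rate function so tests can
  apply the time-rescaling theorem to the very rate that generated the
  spikes.
* **Licking** is inhomogeneous Poisson: baseline 0.5 Hz; anticipatory
  4 Hz during the CS+ once learned; a 7-Hz consumption burst for 2 s
  after each reward; in the *shaped* state (trial-structured task
  learned) the rate is suppressed ×0.1 during the CS−, producing the
  negative CS− lick index seen before animals learn the stimuli are
  decorrelated; in the *trained* state the CS− is ignored.
* **Pupil** (60 Hz) = baseline 20 + slow Gaussian drift (τ = 5 s,
  SD 0.4) − 2.0 × constriction kernel at grating onsets + 2.0 × dilation
  kernel at puff onsets (+1.5 × delayed dilation after the grating in
  visually conditioned, learned animals). Kernels are normalized alpha
  shapes.
* **Whisker angle** (125 Hz) oscillates at 8 ± 1 Hz around a 60°
  setpoint with half-amplitude 4° rising by up to 8° after puff onset
  (rise 0.15 s, decay 1.5 s), plus 0.3° white noise. The amplitude
  envelope used for generation is recorded as ground truth; the analysis
  side re-estimates amplitude from the angle trace, so envelope recovery
  is a genuine check.
* **Populations** place units uniformly in axis-aligned POm/LP/VPM boxes
  at mouse-brain-scale stereotaxic coordinates (a synthetic atlas; real atlas
  meshes are out of scope). Baseline rates are log-uniform, 3–20 Hz in
  POm and 2–12 Hz in LP (POm skewed higher); 60% of units are responsive
  with gains 2–4 (tactile cohort) or 1.5–3 per modality (visual cohort);
  latencies 20–150 ms; response durations 0.8–1.95 s; 50% of units carry
  an offset gain of 1.5–2.5. In the visual cohort the tactile-minus-
  visual gain difference increases along the medial-lateral axis at
  2 gain units/mm by default, emulating the laterally clustered
  touch-selective subregion the position model is meant to detect.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: bursting and refractoriness (an optional
dead-time exists only to exercise the QC filter), spike-sorting artifacts,
non-Poisson count dispersion, electrode drift, eye blinks beyond impulsive
dropouts, behavioral nonstationarity across a session, and any dependence
between units beyond their shared behavior coupling.

## Analysis conventions and numerical choices

* **Lick index**: baseline window [onset − 2 s, onset); stimulus window
  (onset, offset]; licks within ±50 ms of onset excluded from both. When
  the stimulus duration differs from 2 s the counts are converted to
  rates before the formula (an extension beyond the 2-s design, flagged
  in the record). Presentations with no licks in either window are
  undefined and excluded from session means rather than imputed as zero.
* **Pupil cleaning**: blink exclusion (deviation from a 3-s running
  median greater than 25% of the local median — the threshold is not
  specified by the protocol and is configurable) runs on the *raw* trace
  and is followed by the 5-frame moving average, so an artifact cannot
  leak into its neighbours through the smoother. Traces with > 50%
  excluded samples are rejected outright. The "5 frames" statement is
  taken at face value at 60 fps.
* **Whisking amplitude**: zero-phase 4th-order Butterworth band-pass
  4–30 Hz (the band is specified, the filter family is ours); Hilbert
  phase of the filtered angle; envelope anchors take the *unfiltered*
  angle at the phase-0 (protracted) and ±π (retracted) samples, are
  linearly interpolated between anchors, held constant beyond the first/
  last anchor, and the amplitude (protracted − retracted) is floored at
  zero.
* **Overlap exclusion**: presentations with an other-modality onset
  within ≤ 6 s (onset-to-onset) are dropped, symmetrically. The
  stimulus-window ambiguity band is excluded on the onset side only; the
  window rates use the 0.95-s effective durations.
* **Classification**: the ANOVA is one-way over three groups (all
  baseline rates pooled; puff-period rates; grating-period rates).
  "Paired ranked-sum" is read as the paired Wilcoxon signed-rank test.
  The Holm family is all units of one cohort × region group at α = 0.05;
  the per-modality signed-rank tests are uncorrected by design. Units
  with identical counts everywhere are untestable and never significant;
  all-zero rank differences yield p = 1.
* **Latency**: the 2.576 multiplier is used verbatim; the crossing is
  two-sided (increases and decreases); a zero baseline SD is floored at a
  configurable epsilon (10⁻⁶ Hz) and logged; the run must start within
  500 ms of onset.
* **Movement regression**: fit on whole-session 250-ms bins (not
  restricted to peri-stimulus segments — the trial-restricted reading is
  noted in `RunConfig.regression_scope`). Predictors are standardized
  internally for conditioning and coefficients reported on the original
  scale; constant predictors are dropped and logged; the intercept is the
  baseline term. Pupil enters unlagged — lagged relationships are probed
  by the cross-correlation analysis instead, at 100-ms bins and ±3 s lags
  (both configurable; neither is externally specified).
* **Quiet epochs** for spontaneous rate: stimuli occupy their whole
  [onset, offset] interval; licks and rewards are point events; an epoch
  must be event-free, preceded by ≥ 2 s without events, and last ≥ 6 s;
  overlapping qualifying windows are merged maximally. Reward-consumption
  licking is covered by the lick events themselves (conservative).

## Validation suite sizes

The recovery suite uses 3 × 10⁵ ISI draws for schedule statistics (the
at-risk count near 45 s is then large enough that binomial noise stays
well inside the 1.25 flatness bound); 50 units × 100 trials for latency
recovery; 200 null units × 100 trials for family-wise error control;
50 coupling/gain unit pairs for the movement-correction dissociation; and
100 runs × 300 units for position-model recovery. The zero-slope null
rejection rate is compared against the one-sided 99% binomial bound for a
true 5% rate, since at 100 runs the point estimate itself fluctuates.

## Known limitations

Single sessions carry one cohort, so the position model (which needs
both conditioning types) is exercised by the recovery suite rather than
`thalattn analyze`. The offset-period two-way ANOVA treats a unit's two
modality deltas as separate observations, mirroring the original design
rather than a mixed model. Region geometry is a box atlas; border
distances are distances to box faces. The simulator's behavior
magnitudes (lick rates, pupil kernel sizes) are plausible free
parameters, not measured values.
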