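# Methods

This note documents the model and procedure implemented in `cilialoss`, the
parameters that matter, what the synthetic generator does and does not
emulate, the numerical choices, and the known limits of the method.

## Input model

The atomic datum is one cilium's length time series: acquisition times in
seconds from movie start and lengths in micrometres, measured from a ciliary
membrane fluorescence marker (SSTR3::GFP) in 3-D confocal stacks acquired at
30–90 s intervals for 6–12 h.  Two features of this measurement process
drive every design choice below:

* **Measurement error is large.** Consecutive length measurements of a
  static cilium scatter with an SD of ~1.5 μm, comparable to half a cilium.
* **Background drift is small but real.** Non-disassembling control cilia
  decline at about −0.005 μm/min over 12 h (~0.4 μm per movie).

Missing or irregular frames are kept as-is (no resampling or interpolation);
all derivative computations use the actual Δt of each interval, so manually
sampled pre-event stretches at 15–30 min spacing are handled transparently.
Negative raw lengths are clipped to 0 on read, with a warning.

## Control baseline

From ≥1 control (non-disassembling) trajectories, on the *raw* series:

* `mean_slope` — per-cilium least-squares slope of length vs time, averaged
  (μm/min).  Its standard error over controls is retained and propagated
  into the changepoint test below.
* `diff_sd` — per-cilium SD of consecutive length differences, averaged
  (μm); for i.i.d. per-measurement noise σ this estimates σ√2 and proxies
  the length measurement error.  `max_diff_sd` (the maximum over cilia) is
  also reported because a conservative reading uses the worst control
  cilium.
* `instant_threshold` — defaults to `diff_sd`; an override is available, and
  with no controls at all the shipped constant 1.532 μm (the published
  calibration) must be supplied explicitly.

Baseline statistics are deliberately computed before smoothing: smoothing
would shrink exactly the frame-to-frame fluctuation that `diff_sd` is meant
to measure.

## Event detection and classification

1. **Completion** — the first index with raw length ≤ `zero_tol` (default
   0 μm) and all later points also at or below it; transient dips with
   recovery are ignored; trajectories that never complete are censored and
   excluded from class frequencies.  Completion is found on the raw series:
   a moving-average kernel smears the single-frame terminal drop across its
   half-width, which would both delay the detected completion into the zero
   tail and attenuate the penultimate length by ~1/3 at window 5.
2. **Smoothing for derivatives** — a Gaussian-weighted moving average
   (σ = window/4 frames, default window 5; a uniform kernel is selectable),
   with the truncated kernel renormalized at the edges and applied to the
   *pre-completion segment only*, so the zero tail never leaks into the
   kernel support.  Window 1 disables smoothing.
3. **Start detection** — scanning backwards from completion, the start is
   the first point whose interval derivative is no longer different in
   magnitude from the control slope (`|d| ≤ slope_tol_factor × |mean_slope|`,
   factor 1.0 by default).  This literal rule is exact on noiseless data but
   has essentially no specificity when the per-frame derivative noise
   (≈ 0.056 μm/min at σ = 0.3 μm after window-5 smoothing) exceeds the
   0.005 μm/min tolerance, so the default `robust` mode first asks whether
   any gradual phase exists at all: the raw lengths, detrended by the
   control slope, are regressed on a hinge max(0, t − t_s) for every
   candidate onset t_s, and a phase is accepted only if the most negative
   hinge-slope z-score (computed from the calibrated noise SD plus the
   propagated SE of the control slope) falls below −`robust_k` (default 3,
   chosen from an explicit false-positive/power scan: ~1% of flat
   trajectories acquire a spurious phase, and lowering k to 2.5 buys no net
   accuracy).  If no phase is detected the start is the penultimate point;
   otherwise the start is the earlier of the adaptive-tolerance backward
   scan and the best hinge kink.  With zero calibrated noise the robust mode
   reduces exactly to the literal rule.
4. **Classification** — Combined if the start precedes the penultimate point
   AND the penultimate length exceeds the Instant threshold; Instant if only
   the threshold criterion holds; Gradual if only the start criterion holds.
   The degenerate case (single-frame drop from at or below threshold) is
   indistinguishable from measurement error by the method's own logic and is
   assigned Gradual with a `degenerate` flag.  The penultimate length is
   read from the segment-smoothed series: the edge-truncated kernel averages
   only pre-drop frames, so an Instant drop is not attenuated while the
   upward bias of a noisy last-positive point is suppressed.
5. **Metrics** — the gradual rate is (start length − penultimate length) /
   elapsed time; the Instant rate is penultimate length / final frame
   interval, and is a *minimum* (lower bound) because the loss occurred
   somewhere within that frame.  On noisy data the reported bound uses the
   measured penultimate length and can exceed the true bound by the noise
   term; the bound is exact on noiseless data.  Phase fractions are of a
   noise-robust maximum length (95th percentile of the smoothed
   pre-completion series, floored at the start and penultimate lengths so
   fractions stay in [0, 1]); a plain per-frame maximum over hundreds of
   noisy frames is biased upward by ~2 extreme-value SDs, which would
   depress every fraction by ~5 points at σ = 0.3 μm.

## Cohort statistics

Class counts and relative frequencies are computed over classified
(non-censored) events, together with the instant-terminal fraction
(Instant + Combined).  Curves are normalized affinely in time (movie start →
0, completion → 1,000 arbitrary units) and by each cilium's maximum length,
then averaged pointwise after linear interpolation onto a common 1,001-point
grid; individual event start markers are carried through for plotting.
Event start/end timing histograms use 60-min bins by default.

Rate summaries report mean ± SD per class, with the Combined class split
into its gradual and instant phases, and three pairwise two-sided unpaired
t tests (Welch by default; Student's selectable): combined-gradual vs
gradual-only, combined-instant vs instant-only, gradual vs instant.  No
multiple-testing correction is applied (the tests are reported raw, and the
output says so).

Cross-condition comparisons of measurement distributions are
normality-gated: Lilliefors-corrected Kolmogorov–Smirnov, D'Agostino–Pearson
(n ≥ 8) and Shapiro–Wilk at α = 0.05 on each group; all pass → unpaired
t test, all fail → Mann–Whitney U, mixed → both tests run and reported.
Identical constant groups are degenerate and reported non-significant with a
flag.

## Synthetic generator

The generator emulates the measurement process, not the images: a grid of
frames (default 90 s over 720 min), additive i.i.d. Gaussian noise per
measurement while the cilium exists (default σ = 1.53/√2 ≈ 1.082 μm so that
control consecutive-difference SD recovers 1.53 μm), exact zeros after the
loss (a vanished cilium yields no length measurement), clipping at 0, and a
linear drift (−0.005 μm/min) on every trajectory.  Event end times are drawn
triangular over the movie with mode 2 h, so completion histograms peak at
1–3 h; a uniform option exists.

Per class (noiseless skeleton, noise superposed):

* **gradual** — min(plateau, decline) where the decline line reaches 0 at
  the drawn end time with a log-normal rate (moment-matched to mean 0.08,
  SD 0.11 μm/min, clipped below at 10⁻³ μm/min).
* **instant** — plateau whose value at the penultimate frame equals a drawn
  target (from the max-length distribution, floored at 1.6 μm), then a
  single-frame drop to 0.  Parameterizing by the penultimate length (rather
  than the t = 0 length) makes the generated minimum-rate distribution
  exact.
* **combined** — plateau, then a decline at a log-normal rate (mean 0.08,
  SD 0.26 μm/min, clipped below at 0.01 μm/min — a phase slower than the
  drift tolerance has no detectable onset even noiselessly) down to
  `combined_instant_fraction` (default 0.726) of the maximum length, then a
  single-frame drop.  Feasibility redraws enforce ≥1 plateau frame, ≥1
  declining frame, and that the observable phase drop retains at least half
  of the nominal (1 − fraction) share of the maximum: the Combined category
  is operationally defined by a visible gradual phase, and a phase whose
  length budget has been pre-consumed by drift is not an exemplar of it.

Control initial lengths are drawn conditioned on surviving the movie
(floor = |drift|·duration + 1 μm, the sub-micrometre scale below which a
cilium is a stub rather than a measurable organelle): the study's controls
are by definition cilia that persisted the full 12 h.  Without this,
clip-at-zero censoring of short controls biases the recovered slope by up to
~10%.

Everything is bit-reproducible: per-trajectory generators are spawned from
the master seed, so changing the master seed changes noise realizations but
not cohort structure.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: segmentation failures and tracking dropouts,
heteroscedastic noise (error growing with length or depth in the stack),
photobleaching, regrowth or multi-event trajectories, partial shedding,
z-motion artifacts of shed cilia, and any correlation between noise and
event phase.  Class-recovery rates measured here are upper bounds for real
movies.

## Accuracy and limits

* Noiseless cohorts of all three classes are classified with 100% accuracy
  for any smoothing window (verified for windows 1–7).
* At σ = 0.15 μm, three-class accuracy exceeds 95% (measured 99.1% mean over
  seeds).  At σ = 0.3 μm it saturates near 94% — a minority of combined
  events carry a gradual phase whose total length change is below one noise
  SD, which no detector can recover while keeping false gradual phases on
  flat trajectories rare; those events are classified Instant.  At the full
  measured noise (σ ≈ 1.08 μm) the gradual/combined split within the
  instant-terminal group is only partially recoverable, while the
  instant-terminal fraction itself (the main cohort statistic) remains
  accurate because it does not depend on start placement.
* Cohort-recovery statistics (instant-terminal fractions, combined-phase
  partition, baseline calibration, instant minimum rate) are recomputed by
  `scripts/acceptance.py` on cohorts of the published sizes (69 and 50
  events, 10 controls, 26 combined, 32 instant) with 10–20 seed replicates;
  these sizes keep the whole script within seconds on one CPU.

## Numerical choices

* Derivative comparisons in the backward scan carry a 10⁻¹² μm/min epsilon
  (an exact-drift interval computes as −0.005 ± 1 ulp).
* A calibrated `diff_sd` below 10⁻⁶ μm (1 nm) is treated as noiseless; the
  float residue of differencing an exactly linear control is ~10⁻¹⁶ μm.
* The hinge test is evaluated for all candidate kinks in O(n) via reversed
  cumulative sums.
* Log-normal rate distributions are moment-matched on the natural scale:
  σ²_ln = ln(1 + (SD/mean)²), μ_ln = ln(mean) − σ²_ln/2; clipping below is
  applied after drawing.
* Ties and degenerate inputs: windows are shrunk (staying odd) for
  trajectories shorter than the configured window; a trajectory that is zero
  from frame 0 is censored with a flag; constant groups in two-sample
  comparisons short-circuit to non-significant.
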