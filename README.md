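# cilialoss

Classification and kinetics of primary-cilium loss events from live-cell
length-vs-time trajectories.

## The problem

Mammalian cells disassemble their primary cilium before mitosis.  Long-term
live imaging of IMCD3 cells expressing the ciliary membrane marker
SSTR3::GFP shows that this loss is not a single process: some cilia shorten
continuously (**Gradual** resorption), most disappear whole within a single
imaging frame (**Instant** deciliation, i.e. shedding of membrane plus
axoneme), and some shorten for a while and then shed the remainder
(**Combined**).  Telling these apart from noisy length traces — 30–90 s frame
intervals, a frame-to-frame measurement scatter of ~1.5 μm from 3-D length
estimation — is a trajectory-classification problem, and the relative
frequencies of the classes are the biological readout (e.g. katanin p60
overexpression shifts cohorts toward Instant loss).

This package implements that analysis end to end for anyone who has
per-cilium length-vs-time tables: control-baseline calibration, event
detection, three-way classification, per-phase rate metrics, normalized
cumulative curves, cohort statistics, and a synthetic-trajectory generator
that emulates the measurement process so the whole pipeline is testable
without imaging data.

## The method

For each cilium with length series *L(t)*:

1. **Completion** *T*<sub>final</sub> is the first time point with
   *L* = 0 μm and no later recovery.
2. **Event start** *T*<sub>start</sub> is found by scanning backwards from
   *T*<sub>final</sub> until the derivative of the (Gaussian-weighted
   moving-average smoothed) series is no longer different in magnitude from
   the mean control slope (−0.005 μm/min, the background decline of
   non-disassembling control cilia over 12 h).  With calibrated measurement
   noise the scan is guarded by a changepoint test: the drift-detrended
   lengths are regressed on a hinge max(0, *t* − *t*<sub>s</sub>) over every
   candidate onset *t*<sub>s</sub>, and a gradual phase is accepted only when
   the hinge slope is negative at ≥ *k* calibrated noise SDs (*k* = 3).
3. **Classification** uses two criteria: did shortening begin before the
   penultimate frame (*T*<sub>start</sub> ≠ *T*<sub>final−1</sub>), and was
   the penultimate length *L*<sub>final−1</sub> above the measurement-error
   threshold (1.532 μm for the published calibration, or the mean per-cilium
   SD of consecutive control length differences)?
   Gradual = shortening only; Instant = single-frame loss from above
   threshold; Combined = both.
4. **Metrics**: the gradual rate is the length lost in the gradual phase over
   its duration; the Instant rate is *L*<sub>final−1</sub> divided by one
   frame interval — a *minimum* rate, since the loss happened somewhere
   within that frame; the fractions of maximum length lost per phase
   partition each event.

Cohorts are summarized by class counts and frequencies (including the
instant-terminal fraction, Instant + Combined), per-class rate mean ± SD with
pairwise unpaired *t* tests, hourly event start/end histograms, and curves
normalized to 1,000 time units and unit maximum length.  Cross-condition
comparisons are normality-gated: Kolmogorov–Smirnov (Lilliefors),
D'Agostino–Pearson and Shapiro–Wilk at α = 0.05 decide between the unpaired
*t* test and the Mann–Whitney U test (both are reported when the tests
disagree).

## Worked example

Generate a synthetic cohort with the study's structure (10 control cilia and
11/32/26 gradual/instant/combined events, 12-h movies at 90-s intervals,
per-measurement noise 1.082 μm) and analyze it:

```bash
cilialoss simulate --out demo/data --seed 7
cilialoss analyze --data demo/data --out demo/results
```

which prints (log lines abridged):

```
wrote 79 trajectories (69 events) to demo/data
baseline: mean_slope=-0.00507 um/min diff_sd=1.5128 um instant_threshold=1.5128 um (n=10 controls)
classified 69 events (instant-terminal 85.5%); outputs in demo/results
```

The calibration recovers the generator's settings: the mean control slope
−0.00507 μm/min is the background drift, and `diff_sd` = 1.51 μm is the SD of
consecutive control length differences (σ√2 for per-measurement noise σ =
1.082 μm), which becomes the Instant threshold.  The instant-terminal
fraction, 85.5%, is the share of events ending in a single-frame loss — the
cohort was generated with 58/69 ≈ 84%, and at this noise level a minority of
gradual events whose last measurable length sits above the threshold are
counted as Combined.  `demo/results/` contains the per-event table
(`events.csv`: class, start/end times, per-phase rates and fractions), a JSON
summary (counts, frequencies, rate statistics with pairwise tests, timing
histograms), normalized-curve and rate plots, and a `run_record.json` with
the exact configuration.  Note that at the full measured noise the slow
gradual phase of many Combined events carries less length change than the
measurement error, so the gradual/combined split within the instant-terminal
group is only partially recoverable; at noise ≤ 0.3 μm three-class accuracy
exceeds 94% (see `docs/methods.md`).

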