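# Methods

## Problem and model

Overnight polysomnography scores sleep apnea–hypopnea syndrome (SAHS) by
counting apnea–hypopnea (AH) events: apneas (>90% drop in airflow amplitude,
≥10 s) and hypopneas (30–90% drop, ≥10 s, with ≥3% oxygen desaturation or an
arousal).  The apnea–hypopnea index (AHI, events per hour) grades severity at
the standard 5/15/30 events/h cutoffs.  This package detects AH events from
only two channels — nasal flow (NF, thermistor) and SpO2 (finger pulse
oximetry), both on an 8 Hz grid — with a cascade of two random forests:

1. a **60-s screen**: 10 CARTs over a reduced six-feature set
   (`Fha`, `Fhap`, `Spstd`, `Spran`, `Spdum`, `Spdua`), sliding with a 1-s
   step, intended to discard the large majority of event-free minutes cheaply;
2. a **10-s detector**: 20 CARTs over all 19 features, applied only to 10-s
   windows screened in by stage 1.

The 10-s label sequence is then cleaned by two run-length rules (an AH run
must span ≥10 consecutive start seconds; N gaps of ≤5 between valid runs are
refilled) before maximal AH runs become event intervals, an AHI estimate, and
a severity grade.

AH and N segments are heavily imbalanced over a night, so both forests weight
the classes by the inverse ratio of their training counts.  Tree
hyperparameters beyond the tree counts are scikit-learn defaults and are
recorded on the persisted model artifact.

## Preprocessing

* SpO2 below 50% is physiologically impossible for a usable oximeter trace
  and is masked invalid.  Masking (rather than deleting samples) keeps the
  two channels time-aligned; windows with more than 10% invalid content are
  excluded from training and scoring.
* NF is smoothed with a 4-point moving average (causal by default; a
  centered, delay-free variant is config-switchable) and high-passed with a
  third-order 0.05 Hz Butterworth filter applied forward–backward, so
  baseline drift is removed without delaying event timing.  The causal
  average carries a 1.5-sample (0.19 s) group delay, negligible against the
  1-s label grid.
* SpO2 is advanced by τ = 23 s, the nominal lung-to-periphery circulation
  delay, so a desaturation co-occurs with the flow signature that caused it.
  The trailing τ seconds become invalid.  τ is config-exposed but not
  re-optimized here.
* Both window sizes slide with a 1-s step; a segment is labeled AH when its
  overlap with the **union** of annotated events strictly exceeds 5 s (union
  semantics make the rule invariant to splitting an event into abutting
  parts; the strict boundary sends an exact 5-s overlap to N).  One rule
  serves both window sizes.

## Features

Breaths are detected as prominence-filtered alternating NF extrema, paired
disjointly (1st–2nd, 3rd–4th, …); the tidal-volume proxy `Ft` is the
amplitude difference within a pair.  The default prominence threshold is 5%
of the signal range; for whole-recording extraction breaths are detected once
on the full filtered channel so overlapping windows agree on breath
boundaries.  The rolling baseline `Fb` is the maximum `Ft` over the 30 s
preceding the segment (equivalently, over the 30 preceding 1-s-step
segments); `Spbm`/`Spba` are the maximum/mean SpO2 over the same lookback.
At recording start the within-segment values substitute; a zero-breath
segment emits an all-zero NF sub-vector so classifiers never see missing
values.

`Fkur` is computed as the fourth standardized moment (Pearson kurtosis) of
the magnitude-spectrum values in the 0.2–0.4 Hz breathing band, after
removing the segment mean, from an unwindowed discrete Fourier transform.
The phrasing "fourth moment of the spectrum" admits alternatives (power
spectrum, band-limited time-domain kurtosis); both are implemented behind the
`fkur_mode` switch, magnitude being the default.  As a standardized moment it
is invariant to amplitude scaling.  Duration-type SpO2 features (`Sp92`,
`Sp91`, `Spdum`, `Spdua`) are reported in seconds.

## Event detection boundaries

The run-validity threshold is ≥10 consecutive AH start seconds (an event of
the minimum 10-s duration under the 1-s step cannot produce much more), and
gaps of exactly 5 are merged; both boundaries are arguable off-by-one choices
and are config-switchable (`min_run`, `max_gap`).  Rules apply in order —
invalidate short runs, then fill short gaps — and merged runs are not
re-tested.  A corrected run over starts `[a, b]` becomes the interval
`[a, b+10)`, which systematically overestimates duration by up to ~8 s per
event boundary pair; counts, and therefore AHI, are unaffected.  The AHI
denominator is the analyzed (valid-masked) duration: no sleep staging is
performed, so total analyzed time stands in for total sleep time, biasing
AHI slightly low relative to a sleep-time denominator.

## Cross-validation and gating

Twofold cross-validation splits segments in half at random (seeded); each
segment is predicted once, by the fold model that did not train on it.
Because 1-s-step windows overlap heavily, segment-level splitting leaks
nearly identical windows across folds and flatters segment metrics; a
subject-level split mode is provided for leakage-free estimates.  The gating
rule screens a 10-s window in when some AH-flagged 60-s window fully contains
it (strictest reading); an any-overlap alternative is config-switchable.
Gating can only remove positives, so the cascade's AH set is a subset of the
raw 10-s detector's — a tested invariant.

## Synthetic data

The generator emulates the structure the detector relies on, not respiratory
physiology: NF is a frequency-jittered sinusoid (0.25 Hz nominal — one breath
per 3–5 s) with a ±10% slowly varying envelope, 0.005 Hz baseline drift
(inside the high-pass stopband, amplitude 0.3 of the unit breath amplitude)
and Gaussian sensor noise (SD 0.03).  Events are scheduled by a renewal
process (exponential gaps, 15-s minimum separation so the gap-merge rule is
not exercised by accident) targeting the configured AHI; each event scales
the envelope to its residual fraction with 2-s cosine ramps — apneas to
≤0.08·(0.5–1) of baseline (a >90% drop), hypopneas to a residual drawn from
the full 0.1–0.7 scoring band.  SpO2 sits at a 97% baseline with slow wander,
desaturates by 3–10% starting exactly 23 s after each event onset (half-
cosine fall over 8 s, hold tracking event duration, 15-s exponential
recovery), is quantized to integer percent like a pulse oximeter, and is
corrupted by ~2-s dropout bursts below 50% at a 1% sample rate.  Cohorts draw
per-subject target AHIs uniformly within severity bands (NON 1–4.5, MILD
6–14, MODERATE 16–29, SEVERE 31–55) with deterministic per-subject seeds.

What passing on this data does **not** show: robustness to real thermistor
nonlinearity, movement artifacts in flow, arousal-terminated hypopneas
without desaturation, variable circulation delays across subjects, central
vs. obstructive morphology, or wake periods (the generator breathes all
night).  It does validate the machinery end to end: feature geometry, class
imbalance handling, gating, run-length correction, and AHI/severity
aggregation.

## Problem sizes and numerics

Tests and the acceptance script use 1-h recordings for the 24-subject cohort
run and 10–15-min recordings for unit-level checks; these sizes give stable
statistics while keeping a full suite run to minutes.  Filtering requires
≥32 samples (forward–backward pad length).  Degenerate inputs are defined,
not exceptional: flat NF yields zero breaths and an all-zero NF sub-vector;
an all-invalid SpO2 window yields an all-zero SpO2 sub-vector and an
unusable segment; empty lookbacks fall back to within-segment baselines.
Reported percentages are rounded half-up to one decimal (kappa to two), the
convention of published tables, and cross-cutoff means average the displayed
one-decimal values; full precision is kept internally.  When a small cohort
lacks a reference severity class entirely, the undefined cells of the
severity report are `None` and are excluded from the means.

## Known limitations

* No apnea/hypopnea sub-typing, no central/obstructive discrimination, no
  sleep staging — out of scope by design.
* The segment-level CV default inherits the window-overlap leakage discussed
  above; use `split="subject"` for honest generalization estimates.
* The UCDDB respiratory-event text dialect parser covers the common layout
  (clock time, type, duration) but not every historical variant.
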