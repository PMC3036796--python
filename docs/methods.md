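# Methods

This note documents the models, conventions and design choices behind
`neoseize`, in the order the pipeline runs.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and the epoch grid

All times are 0-based seconds from record start; intervals are half-open
`[start, end)`.  The analysis grid places epoch `i` at
`[i·hop, i·hop + L)` with defaults `L = 8 s`, `hop = 4 s` (50 % overlap);
a record of duration `D` holds `floor((D − L)/hop) + 1` epochs, zero when
`D < L`.  Every stage — labelling, scoring, smoothing, sweeping — shares
this grid, which is what makes epoch-based and event-based results
commensurable.

**Rasterizing reference events.** Expert annotations arrive as time
intervals; an epoch is labelled seizure when the union of reference events
covers at least half of it (`min_overlap_frac = 0.5`, configurable).  With
50 % epoch overlap, a rule based on *any* overlap would label two extra
epochs per seizure boundary from 2–4 s slivers and inflate the seizure
class; the majority rule avoids that.  Overlapping input events are merged
silently — they describe the same seizure state, not separate seizures.

**Rasterizing predicted events.** Going back from events to epoch
decisions (needed to score epoch metrics after the collar) uses the
*strict* majority rule applied per event, OR-combined.  On the 50 %-overlap
grid an epoch adjacent to a decision run overlaps that run's event by
exactly half an epoch, as does the gap epoch between two runs separated by
a single negative epoch; the strict per-event rule leaves both at 0 and is
the exact inverse of run-joining.  Using the reference (`≥`, union) rule
here measurably inflated epoch sensitivity on random traces, which is why
the two directions deliberately differ.

## Detector front end

The raw EEG (nominally 256 Hz, 8 bipolar channels) is low-passed at
12.8 Hz with a 257-tap linear-phase FIR applied forward–backward
(zero-phase, so decision timing is not skewed by group delay) and
decimated to 32 Hz; integer rate ratios decimate by slicing, rational
ratios fall back to polyphase resampling after the same filter.  The
measured response of this filter keeps a 5 Hz tone within 5 % of unit
amplitude and attenuates 15 Hz by far more than 20 dB (checked in the test
suite).

Per-epoch features are computed from the 256-sample epochs via a pluggable
registry.  The default set (11 features) covers time-domain amplitude and
complexity (RMS, line length, zero crossings, the three Hjorth
parameters), spectral content (band powers 0.5–4, 4–8, 8–12.8 Hz, 95 %
spectral edge frequency) and an information measure (Shannon entropy of
the 16-bin amplitude histogram).  It is a representative neonatal-EEG
front end, *not* a reproduction of any specific published feature list;
users can register additional features.  Degenerate inputs are pinned
explicitly: a flat epoch has zero Hjorth mobility/complexity and zero
histogram entropy rather than 0/0.

Features are z-scored anisotropically with a template (per-feature mean
and sample, n−1, standard deviation) fitted on training rows only and then
applied unchanged to test data; zero-variance features are centered but
left unscaled, with a warning.  The classifier is an RBF-kernel SVM
(defaults C = 1, gamma = 1/n_features, inverse-prevalence class weights —
non-seizure dominates real recordings) whose decision values are mapped to
posteriors by Platt sigmoid calibration fitted on internal training folds.
Because kernel-SVM training is super-linear in n while the evaluation
harness pools epochs across channels and patients, training subsamples to
at most 4 000 rows (stratified, seeded, configurable); this is a scaling
choice of the package, applied identically everywhere.  Channel-wise
epochs are pooled with their record-level labels — a focal seizure thus
contributes some seizure-labelled epochs whose channel carries no
discharge.  That label noise is inherent to multi-channel training with
record-level annotations and is accepted rather than hidden.

## Post-processing chain

Stage order: per-channel moving-average filter → per-channel threshold
(`≥`, so a threshold of 1.0 can still fire on saturated posteriors) →
epoch-wise OR fusion across channels → run-joining into events → collar.

The MAF is centered with an odd length (default 15 epochs); at record
edges the window shrinks to the available epochs, which preserves the
trace length and the [0, 1] range without inventing padding values.  Its
temporal half-span is `((L−1)/2)·hop` — 28 s at the defaults — so a 40 s
collar adds only 12 s beyond data the smoothed decision already saw.

The collar extends each event by `collar_s` (default 40 s) on both sides,
clips to the record, and merges events whose extended intervals overlap or
abut.  A zero collar is the exact identity: pre-existing abutting events
(runs separated by one negative epoch) stay separate.  The collar operates
on fused events in seconds; an epoch-domain collar is deliberately not
offered.

## Metrics

Undefined ratios (0/0) are carried as `None`/NaN with a warning where they
are skipped, never silently coerced.

Event matching is any-overlap: a reference seizure is detected if a
predicted event touches it for any positive duration anywhere in its span;
a predicted event is a false detection only if it overlaps no reference
event, and one predicted event overlapping k references detects all k
while counting as neither a false detection nor multiple detections.
FD/h divides the false-detection count by the *total* record duration,
seizure time included.  FD/h(30 s) merges false detections whose gap is
strictly below 30 s before counting; MFDD averages the durations of the
raw, un-joined false detections, keeping the joined rate a separate
variant.  ROC/PR curve computation is delegated to scikit-learn behind the
package's interface; the test suite verifies the ROC area against a
brute-force pairwise (Mann–Whitney) oracle with tie handling, and the PR
area against exhaustive threshold enumeration.

**Threshold sweeps** re-run the full post-processing chain (including the
collar) at every threshold — default grid 1 001 points in [0, 1], reduced
in the heavier tests — and tabulate both metric families per threshold.
The ROC area of a sweep is the trapezoid area of its
(1−specificity, sensitivity) points anchored at (0,0) and (1,1); the PR
area integrates the *upper envelope* of the observed
(recall, precision) points step-wise, because many thresholds can share a
recall value and the curve point at that recall is the best precision
achieved there.

One documented deviation: the count of false detections is **not**
monotone in the threshold.  At low thresholds false detections merge with
each other and with true detections into fewer events, so FD/h can rise
before it falls; the guaranteed monotonicities (tested) are the nesting of
firing-epoch sets and the non-increase of GDR, sensitivity and total
predicted duration.

## Evaluation protocol

Leave-one-out over patients, folds in sorted-id order, so the procedure is
deterministic and invariant to input ordering.  Nothing from the test
patient — neither its epochs nor its labels — touches training or the
normalization template of its fold (asserted by corrupting the test
patient's annotations and checking the fold's probability trace is
bit-identical).  Missing data for any patient aborts before any training
starts.

Operating points are one cohort-level threshold per FD/h target: the
threshold maximizing cohort-mean sensitivity subject to cohort-mean
FD/h ≤ target, ties broken toward the larger (more conservative)
threshold; when no sensitivity column is supplied the smallest feasible
threshold is used, since sensitivity never increases with the threshold.
An unreachable target raises, reporting the achievable minimum.

Macro averaging weighs patients equally (mean and sample sd of per-patient
values); duration-weighted pooling is available but never the default.
A static-split mode exists only for comparison: estimates from repeated
random 75/25 hold-out partitions scatter more than the LOO macro-mean
standard error on the same per-patient values (tested), which is the core
argument for patient-wise cross-validation on small clinical cohorts.

The bundled 17-patient benchmark table (267.9 h, 705 seizures) fixes the
report schema and the consistency arithmetic: its macro means, the mean
record length 267.9/17 ≈ 15.76 h, and the detected-burden estimates
`n_events · mean_duration · sensitivity/100` for the low-burden patients
(≈12 and ≈4 min) are all recomputed from the rows by the tests and the
acceptance script, never hard-coded as results.

## Synthetic cohorts

The generators emulate the *statistics* of a term-HIE NICU monitoring
cohort, not neonatal EEG morphology.

**Schedules.** Seizure onsets alternate with exponential gaps (floored at
30 s, mean set so the rate is 2.6 seizures/hour); durations are lognormal
with mean 3.89 min and log-sd 0.9, clipped to [10 s, 35 min] — a
right-skewed law consistent with a cohort spanning sub-minute to
half-hour seizures.  Only mean/min/max duration and the overall rate are
matched; no inter-seizure-interval distribution is imitated because none
is available.  `min_events = 1` by default: the emulated cohort consists
exclusively of seizure patients, so a draw with no seizures is redrawn
deterministically from the next seed substream.

**Score traces** bypass the classifier to test the metric layer with known
discriminability: the latent value is `mu1` on seizure epochs of the
seizure-active channels (default 2 of 8, focal emphasis) and `mu0`
elsewhere, plus stationary AR(1) Gaussian noise and optional iid
measurement noise, through a logistic link.  With no autocorrelation the
pooled-epoch ROC area has the closed form Φ((mu1−mu0)/(σ√2)), which the
tests recover within Monte-Carlo tolerance across seeds; with slow AR(1)
signal noise plus iid sensor noise, 15-epoch MAF smoothing strictly raises
the ROC area.

**Toy EEG** is 1/f background noise (30 µV RMS per channel) to which each
seizure adds an amplitude-enveloped 1–3 Hz oscillation with a 50 % first
harmonic on a random channel subset; `snr` scales the oscillation
amplitude relative to the background RMS, and background and seizure
randomness use separate seed substreams so `snr = 0` is bit-identical to
background-only generation.  Artifacts, inter-patient background
variability and real discharge morphology are *not* modelled: a passing
end-to-end test shows the pipeline's plumbing and ranking behaviour are
correct under a detectable signature, not that the bundled feature set
would reach clinical performance on real NICU data.

**Problem sizes.** The end-to-end checks use 4 patients × 0.5 h at SNR 5
(and at SNR 0 for the chance-level control) with a 101-point threshold
grid; the metric-layer simulations use single-channel traces of 30 h
(≈27 000 epochs).  These sizes give stable estimates for the tested
tolerances while keeping the default suite fast.

## Known limitations

- EDF writing supports the 16-bit single-record-duration subset this
  package itself produces; reading goes through mne and accepts general
  EDF.
- The default feature set is a reasonable front end, not an optimized or
  published one; reported synthetic performance says nothing quantitative
  about clinical recordings.
- Per-patient operating thresholds (as opposed to cohort-level ones) exist
  behind the reporting API but are not the default, mirroring the single
  cohort threshold convention of the report schema.
- Inter-annotator adjudication is out of scope: one annotation set is the
  reference.
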