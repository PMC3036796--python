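# neoseize

Performance assessment for EEG-based neonatal seizure detectors.

Seizures are the most common neurological emergency in the neonatal
intensive care unit, and most are detectable only in continuous EEG.
Automated detectors exist, but their published scores are hard to compare:
some report epoch-based metrics, some event-based ones, and both families
can be made to look arbitrarily good by post-processing choices.  This
package implements a complete assessment framework for such detectors — for
algorithm developers who need honest, comparable numbers, and for anyone
reproducing or stress-testing published evaluation pipelines — together
with a reference SVM detector and synthetic cohorts so everything is
testable without clinical recordings.

## What it computes

**Epoch-based metrics.** The record is segmented into 8-s epochs with 50 %
overlap.  With the usual confusion counts, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP); ROC curves (area by
trapezoid rule, equal to the normalized Mann–Whitney statistic) and
precision–recall curves (area by step interpolation; the random baseline is
the seizure prevalence, which makes PR the stricter score under class
imbalance).  Epoch sensitivity equals the fraction of *seizure burden*
(total time in seizure) that the detector recovers.

**Event-based metrics.** Consecutive positive epochs are joined into
events.  GDR (good detection rate) is the percentage of reference seizures
overlapped anywhere within their span by a predicted event; FD/h is the
number of predicted events with zero reference overlap per hour, with a
variant FD/h(30 s) that first merges false detections closer than 30 s.
Because both can be driven to perfect values by widening decisions, the
framework also reports MFDD — the mean duration of a false detection at an
operating point.  A monitor producing `FD/h` false alarms of mean length
`MFDD` minutes occupies `100 · FD/h · MFDD / 60` percent of the review time
in vain; 1 FD/h lasting 20 min wastes ~33 % of the clinician's attention, 2
FD/h of 1 min only ~3 %.

**Post-processing chain.** Per-channel seizure posteriors are smoothed with
a centered moving-average filter (default 15 epochs), thresholded, fused
across channels by epoch-wise OR, and the resulting events are extended by
a collar (default 40 s) on both sides.  A 15-epoch MAF on the 4-s hop grid
reaches (15−1)/2 × 4 = 28 s of context either side, so of the 40 s collar
only 12 s is genuine extrapolation beyond the smoothed window.

**Evaluation protocol.** Leave-one-out cross-validation over patients: each
patient in turn is scored by a model trained (including its feature
normalization template) exclusively on the others.  Per-patient reports
(record length, seizure statistics, ROC/PR areas, GDR and sensitivity at
target FD/h operating points) are macro-averaged with equal patient weight.
A bundled benchmark table of 17 patients (267.9 h, 705 seizures) documents
the report schema; its macro means (ROC 96.3 %, PR 80.8 %, GDR 81.7 % at
0.5 FD/h, 89.2 % at 1 FD/h) are recomputed by the test suite from the
per-patient rows.

## Worked example

Simulate a 4-patient cohort of half-hour records with strong (SNR 5)
rhythmic 1–3 Hz seizure discharges on 2 of 8 channels, run the full
leave-one-out pipeline, and report at the 0.5 and 1 FD/h operating points:

```python
import numpy as np
from neoseize import generate_cohort, run_loo_evaluation, evaluate_cohort_reports

cohort = generate_cohort(4, record_hours=0.5, snr=5.0, seed=1)
folds = run_loo_evaluation(cohort, thresholds=np.linspace(0, 1, 101), seed=1)
reports, summary = evaluate_cohort_reports(
    folds, {pid: p.annotations for pid, p in cohort.items()}, (0.5, 1.0)
)
```

which prints, via `PatientReport.to_row()`:

```
p01: 1 seizures, ROC 99.3 %, PR 80.7 %, GDR@1FD/h 100.0 %, Sens@1FD/h 100.0 %
p02: 2 seizures, ROC 99.7 %, PR 98.9 %, GDR@1FD/h 100.0 %, Sens@1FD/h 100.0 %
p03: 1 seizures, ROC 98.2 %, PR 36.0 %, GDR@1FD/h 100.0 %, Sens@1FD/h 100.0 %
p04: 2 seizures, ROC 98.4 %, PR 85.8 %, GDR@1FD/h 100.0 %, Sens@1FD/h 100.0 %
macro ROC area: 98.9 % (sd 0.7)
macro PR area:  75.3 % (sd 27.3)
```

Every reference seizure is found (GDR 100 %) with no false detections at
the chosen threshold, and the ROC areas are uniformly high.  The PR areas
scatter widely: patient p03 carries a single short seizure, so seizure
epochs are rare and the precision of the collar-widened decisions is low —
exactly the class-imbalance sensitivity that makes PR worth reporting next
to ROC.

The same round trip is available from the shell:

```bash
neoseize simulate --out cohort/ --patients 4 --hours 0.5 --snr 5 --seed 1
neoseize evaluate --data cohort/ --out results/
neoseize report --results results/
```

## Layout

- `src/neoseize/io_formats.py` — EDF and annotation/trace CSV I/O, epoch
  grid, event↔epoch conversions
- `src/neoseize/detector.py` — 32 Hz front end, feature registry, SVM with
  Platt calibration
- `src/neoseize/postprocess.py` — MAF, thresholding, channel fusion, collar
- `src/neoseize/metrics.py` — epoch/event metrics, ROC/PR, threshold sweeps
- `src/neoseize/protocol.py` — LOO harness, macro averaging, reports
- `src/neoseize/synthetic.py` — schedule, score-trace and EEG generators
- `src/neoseize/cli.py` — the `neoseize` command (simulate / train / score /
  evaluate / report)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
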