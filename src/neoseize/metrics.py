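"""Epoch-based and event-based performance metrics for seizure detectors.

Epoch-based scores (sensitivity, specificity, precision, ROC and PR curves)
treat every analysis epoch as an independent test example.  Event-based
scores operate on maximal seizure intervals: the good detection rate (GDR)
counts a reference seizure as detected if any predicted event overlaps it
anywhere within its span, and the false-detection rate (FD/h) counts
predicted events with zero reference overlap per hour of recording.  Because
both event scores can be made arbitrarily good by post-processing that
widens decisions, they are accompanied by the mean false-detection duration
(MFDD): the average length of a false detection at one operating point.
A clinician reviewing a monitor in vain spends roughly
``fd_per_h * mfdd_min / 60`` of the monitoring time on false alarms, which
is the fraction :func:`time_in_fd_fraction` reports.

Undefined ratios (0/0) are carried as ``None`` (scalars) or NaN (tables),
never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .io_formats import (
    AnnotationSet,
    EpochGrid,
    SeizureEvent,
    decisions_to_events,
    events_to_epoch_labels,
)
from .postprocess import PostprocessConfig, apply_collar, smooth_maf

__all__ = [
    "ConfusionCounts",
    "EpochMetrics",
    "EventMatchResult",
    "EventMetrics",
    "MetricCurve",
    "confusion_counts",
    "epoch_metrics",
    "roc_curve",
    "pr_curve",
    "match_events",
    "join_close_events",
    "event_metrics",
    "time_in_fd_fraction",
    "sweep_operating_points",
    "roc_area_from_sweep",
    "pr_area_from_sweep",
    "SWEEP_COLUMNS",
]


# ---------------------------------------------------------------------------
# Epoch-based metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EpochMetrics:
    """Sensitivity/specificity/precision; ``None`` marks a 0/0 ratio."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None


def confusion_counts(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Confusion-matrix counts of binary epoch decisions against reference."""
    pred = np.asarray(pred).astype(bool).ravel()
    ref = np.asarray(ref).astype(bool).ravel()
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: pred {pred.size} vs ref {ref.size}")
    return ConfusionCounts(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        tn=int(np.sum(~pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def epoch_metrics(c: ConfusionCounts) -> EpochMetrics:
    """sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); precision = TP/(TP+FP)."""
    return EpochMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
    )


@dataclass
class MetricCurve:
    """A threshold-swept curve with its area.

    ``x``/``y`` are the curve coordinates (FPR/TPR for ROC, recall/precision
    for PR); ``thresholds`` the score cutoffs that generated them, descending
    in score so the curve is traversed left to right.
    """

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    area: float
    kind: str = "roc"


def roc_curve(scores: np.ndarray, ref: np.ndarray) -> MetricCurve:
    """ROC curve over all distinct score thresholds, area by trapezoid rule.

    Ties are grouped: equal scores form one step, so constant scores give the
    chance diagonal (area 0.5).  Requires both classes in ``ref``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    ref = np.asarray(ref).astype(int).ravel()
    if scores.shape != ref.shape:
        raise ValueError("scores and ref must have equal length")
    if len(np.unique(ref)) < 2:
        raise ValueError("ROC requires both classes in the reference")
    fpr, tpr, thr = skm.roc_curve(ref, scores, drop_intermediate=False)
    return MetricCurve(fpr, tpr, thr, area=float(skm.auc(fpr, tpr)), kind="roc")


def pr_curve(scores: np.ndarray, ref: np.ndarray) -> MetricCurve:
    """Precision-recall curve; area by step interpolation over recall.

    The area (average precision) of a random scorer approaches the positive
    prevalence.  Requires at least one positive in ``ref``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    ref = np.asarray(ref).astype(int).ravel()
    if scores.shape != ref.shape:
        raise ValueError("scores and ref must have equal length")
    if ref.sum() == 0:
        raise ValueError("PR curve requires at least one positive example")
    precision, recall, thr = skm.precision_recall_curve(ref, scores)
    area = float(skm.average_precision_score(ref, scores))
    # sklearn returns recall descending; flip to ascend like the ROC x-axis
    return MetricCurve(recall[::-1], precision[::-1], thr[::-1], area=area, kind="pr")


# ---------------------------------------------------------------------------
# Event-based metrics
# ---------------------------------------------------------------------------

@dataclass
class EventMatchResult:
    n_ref_events: int
    n_detected_ref_events: int
    fd_events: list[SeizureEvent] = field(default_factory=list)
    overlapping_pred_events: list[SeizureEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_detected_ref_events > self.n_ref_events:
            raise ValueError("cannot detect more reference events than exist")


@dataclass(frozen=True)
class EventMetrics:
    """GDR (%), FD/h, joined FD/h and MFDD (min); ``None`` where undefined."""

    gdr: float | None
    fd_per_h: float
    fd_per_h_joined: float
    mfdd_min: float | None


def _assert_disjoint(events: Sequence[SeizureEvent], what: str) -> list[SeizureEvent]:
    evs = sorted(events)
    for a, b in zip(evs, evs[1:]):
        if b.start_s < a.end_s:
            raise ValueError(f"{what} events must be non-overlapping: {a} vs {b}")
    return evs


def match_events(
    pred: Sequence[SeizureEvent], ref: Sequence[SeizureEvent]
) -> EventMatchResult:
    """Any-overlap event matching.

    A reference seizure is detected iff some predicted event overlaps it by
    more than 0 s — anywhere within its span.  A predicted event is a false
    detection iff it overlaps no reference event; a predicted event touching
    one or more reference events is neither a false detection nor counted as
    multiple detections.
    """
    pred = _assert_disjoint(pred, "predicted")
    ref = _assert_disjoint(ref, "reference")
    detected = sum(1 for rv in ref if any(rv.overlap_s(pv) > 0 for pv in pred))
    fd = [pv for pv in pred if all(pv.overlap_s(rv) == 0 for rv in ref)]
    hit = [pv for pv in pred if any(pv.overlap_s(rv) > 0 for rv in ref)]
    return EventMatchResult(
        n_ref_events=len(ref),
        n_detected_ref_events=detected,
        fd_events=fd,
        overlapping_pred_events=hit,
    )


def join_close_events(events: Sequence[SeizureEvent], gap_s: float) -> list[SeizureEvent]:
    """Merge events whose separating gap is strictly below ``gap_s`` seconds.

    Used on false detections to report the joined false-detection rate, which
    discounts spiky bursts of short false alarms.
    """
    if gap_s < 0:
        raise ValueError("gap_s must be >= 0")
    evs = _assert_disjoint(events, "input")
    out: list[SeizureEvent] = []
    for ev in evs:
        if out and ev.start_s - out[-1].end_s < gap_s:
            out[-1] = SeizureEvent(out[-1].start_s, max(out[-1].end_s, ev.end_s))
        else:
            out.append(ev)
    return out


def event_metrics(
    match: EventMatchResult,
    record_duration_h: float,
    join_gap_s: float = 30.0,
) -> EventMetrics:
    """GDR, FD/h, joined FD/h and MFDD at one operating point.

    MFDD averages the durations of the raw (un-joined) false detections; the
    joined rate is a separate reported variant.  The FD/h denominator is the
    total record duration including seizure time.
    """
    if record_duration_h <= 0:
        raise ValueError("record_duration_h must be > 0")
    gdr = (
        100.0 * match.n_detected_ref_events / match.n_ref_events
        if match.n_ref_events > 0
        else None
    )
    n_fd = len(match.fd_events)
    fd_per_h = n_fd / record_duration_h
    fd_joined = len(join_close_events(match.fd_events, join_gap_s)) / record_duration_h
    mfdd = (
        float(np.mean([ev.duration_s for ev in match.fd_events]) / 60.0)
        if n_fd
        else None
    )
    return EventMetrics(gdr=gdr, fd_per_h=fd_per_h, fd_per_h_joined=fd_joined, mfdd_min=mfdd)


def time_in_fd_fraction(fd_per_h: float, mfdd_min: float) -> float:
    """Percent of monitoring time spent reviewing false detections.

    A system producing ``fd_per_h`` false alarms per hour, each lasting
    ``mfdd_min`` minutes on average, occupies
    ``100 * fd_per_h * mfdd_min / 60`` percent of the monitored time.
    """
    if fd_per_h < 0 or mfdd_min < 0:
        raise ValueError("inputs must be >= 0")
    return 100.0 * fd_per_h * mfdd_min / 60.0


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

SWEEP_COLUMNS = (
    "threshold",
    "sensitivity",
    "specificity",
    "precision",
    "gdr",
    "fd_per_h",
    "fd_per_h_joined",
    "mfdd_min",
)


def default_thresholds(n: int = 1001) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def predicted_events_to_epoch_labels(
    events: Sequence[SeizureEvent], grid: EpochGrid
) -> np.ndarray:
    """Rasterize predicted events back to epoch decisions (strict majority).

    Each event is rasterized independently — an epoch fires iff a single
    event covers strictly more than half of it — and the per-event label
    vectors are OR-combined.  On the 50 %-overlap grid this is the exact
    inverse of run-joining: epochs adjacent to a decision run, and the gap
    epoch between two abutting events, overlap any one event by exactly half
    an epoch and stay 0.
    """
    n = grid.n_epochs
    starts = np.arange(n) * grid.hop_s
    ends = starts + grid.epoch_len_s
    labels = np.zeros(n, dtype=np.int8)
    half = grid.epoch_len_s / 2.0
    for ev in events:
        overlap = np.clip(
            np.minimum(ends, ev.end_s) - np.maximum(starts, ev.start_s), 0.0, None
        )
        labels[overlap > half + 1e-12] = 1
    return labels


def sweep_operating_points(
    trace,
    ref: AnnotationSet,
    config: PostprocessConfig,
    grid: EpochGrid | None = None,
    thresholds: np.ndarray | None = None,
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Run the full post-processing chain at every threshold and score it.

    For each threshold the chain (MAF -> threshold -> OR fusion -> events ->
    collar) is re-run in full, then both metric families are computed: epoch
    metrics against the rasterized reference labels, event metrics against
    the reference events.  Undefined cells carry NaN.  The returned table
    backs GDR-vs-FD/h, sens/spec/precision-vs-FD/h, ROC and PR renderings.
    """
    from .detector import ProbabilityTrace  # noqa: PLC0415 - import cycle

    if isinstance(trace, ProbabilityTrace):
        grid = trace.grid
        channels = trace.probabilities
    else:
        if grid is None:
            raise ValueError("grid required when trace is a bare array")
        channels = np.atleast_2d(np.asarray(trace, dtype=float))
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and (thresholds.min() < 0 or thresholds.max() > 1):
        raise ValueError("thresholds must lie in [0, 1]")

    smoothed = np.vstack([smooth_maf(ch, config.maf_len_epochs) for ch in channels])
    ref_labels = events_to_epoch_labels(ref, grid, min_overlap_frac)
    duration_h = grid.record_duration_s / 3600.0

    rows = []
    for th in thresholds:
        fused = (smoothed >= th).any(axis=0).astype(np.int8)
        events = apply_collar(
            decisions_to_events(fused, grid), config.collar_s, grid.record_duration_s
        )
        pred_labels = predicted_events_to_epoch_labels(events, grid)
        em = epoch_metrics(confusion_counts(pred_labels, ref_labels))
        ev = event_metrics(
            match_events(events, ref.events), duration_h, config.fd_join_gap_s
        )
        rows.append(
            (
                th,
                np.nan if em.sensitivity is None else em.sensitivity,
                np.nan if em.specificity is None else em.specificity,
                np.nan if em.precision is None else em.precision,
                np.nan if ev.gdr is None else ev.gdr,
                ev.fd_per_h,
                ev.fd_per_h_joined,
                np.nan if ev.mfdd_min is None else ev.mfdd_min,
            )
        )
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))


def plot_performance_curves(sweep: pd.DataFrame, path) -> None:
    """Render the four standard performance views of one sweep table to a file.

    Panels: ROC, PR, GDR against FD/h, and the epoch/event summary with all
    metrics mapped onto the common FD/h x-axis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = sweep.dropna(subset=["sensitivity", "specificity"])
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    ax = axes[0, 0]
    ax.plot(1 - sub["specificity"], sub["sensitivity"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", c="gray")
    ax.set(xlabel="1 - specificity", ylabel="sensitivity",
           title=f"ROC (area {roc_area_from_sweep(sweep):.3f})")

    ax = axes[0, 1]
    pr = sweep.dropna(subset=["sensitivity", "precision"])
    ax.plot(pr["sensitivity"], pr["precision"], drawstyle="steps-post")
    ax.set(xlabel="recall", ylabel="precision", ylim=(0, 1.02),
           title=f"PR (area {pr_area_from_sweep(sweep):.3f})")

    ax = axes[1, 0]
    ev = sweep.dropna(subset=["gdr"])
    ax.plot(ev["fd_per_h"], ev["gdr"], marker=".", ls="")
    ax.set(xlabel="FD/h", ylabel="GDR (%)", title="GDR vs FD/h")

    ax = axes[1, 1]
    for col, scale in (("gdr", 1.0), ("sensitivity", 100.0),
                       ("specificity", 100.0), ("precision", 100.0)):
        d = sweep.dropna(subset=[col])
        ax.plot(d["fd_per_h"], d[col] * scale, marker=".", ls="", label=col, ms=3)
    ax.set(xlabel="FD/h", ylabel="%", title="metrics on common FD/h axis")
    ax.legend(fontsize=8)

    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def roc_area_from_sweep(sweep: pd.DataFrame) -> float:
    """Trapezoid ROC area from a sweep table's (1-specificity, sensitivity).

    The curve is anchored at (0,0) and (1,1); rows with undefined epoch
    metrics are dropped.
    """
    sub = sweep.dropna(subset=["sensitivity", "specificity"])
    fpr = np.concatenate([[0.0], 1.0 - sub["specificity"].to_numpy(), [1.0]])
    tpr = np.concatenate([[0.0], sub["sensitivity"].to_numpy(), [1.0]])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def pr_area_from_sweep(sweep: pd.DataFrame) -> float:
    """Step-interpolated PR area from a sweep table (precision over recall).

    Several thresholds can share one recall value; the curve point at that
    recall is the best (maximum) precision achieved there, so the area
    integrates the upper envelope of the observed operating points.
    """
    sub = sweep.dropna(subset=["sensitivity", "precision"])
    if sub.empty:
        raise ValueError("no defined precision/recall points in sweep")
    env = sub.groupby("sensitivity")["precision"].max().sort_index()
    prev_r = 0.0
    area = 0.0
    for r, p in env.items():
        area += (r - prev_r) * p
        prev_r = r
    return float(area)
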