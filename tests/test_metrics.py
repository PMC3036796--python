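"""Epoch and event metric definitions, curve areas and the threshold sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from neoseize import (
    AnnotationSet,
    ConfusionCounts,
    EpochGrid,
    PostprocessConfig,
    SeizureEvent,
    confusion_counts,
    epoch_metrics,
    event_metrics,
    events_to_epoch_labels,
    join_close_events,
    match_events,
    pr_curve,
    roc_curve,
    sweep_operating_points,
    time_in_fd_fraction,
)
from neoseize.metrics import roc_area_from_sweep


# ---------------------------------------------------------------------------
# Confusion counts and epoch metrics
# ---------------------------------------------------------------------------

class TestConfusion:
    def test_all_negative_agreement(self):
        c = confusion_counts(np.zeros(10), np.zeros(10))
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 10, 0)

    def test_complement_prediction_has_no_correct_epochs(self):
        ref = np.array([1, 0, 1, 0])
        c = confusion_counts(1 - ref, ref)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_mixed_example_counts(self):
        ref = np.array([1, 1, 0, 0, 1])
        pred = np.array([1, 0, 0, 1, 1])
        c = confusion_counts(pred, ref)
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 1, 1, 1)
        assert c.total == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros(3), np.zeros(4))

    @pytest.mark.parametrize(
        "c,sens,spec,prec",
        [
            (ConfusionCounts(9, 0, 0, 1), 0.9, None, 1.0),
            (ConfusionCounts(2, 2, 5, 0), 1.0, 5 / 7, 0.5),
            (ConfusionCounts(0, 0, 10, 0), None, 1.0, None),
        ],
    )
    def test_ratios_with_explicit_undefined_flags(self, c, sens, spec, prec):
        m = epoch_metrics(c)
        assert m.sensitivity == sens and m.specificity == spec and m.precision == prec


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _auc_pairwise(scores, ref):
    """Brute-force Mann-Whitney AUC: fraction of correctly ordered pairs."""
    pos = scores[ref == 1]
    neg = scores[ref == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation_has_unit_area(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        ref = np.array([0, 0, 1, 1])
        assert roc_curve(scores, ref).area == pytest.approx(1.0)

    def test_constant_scores_give_chance_diagonal(self):
        scores = np.full(50, 0.3)
        ref = np.r_[np.ones(10), np.zeros(40)]
        assert roc_curve(scores, ref).area == pytest.approx(0.5)

    def test_binormal_closed_form(self, rng):
        n = 20000
        scores = np.r_[rng.normal(0, 1, n), rng.normal(1.5, 1, n)]
        ref = np.r_[np.zeros(n), np.ones(n)]
        expected = norm.cdf(1.5 / np.sqrt(2))  # = 0.8556 for d' = 1.5
        assert roc_curve(scores, ref).area == pytest.approx(expected, abs=0.01)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))

    @given(st.integers(0, 10_000), st.integers(5, 60), st.integers(1, 3))
    @settings(max_examples=30)
    def test_area_equals_pairwise_mann_whitney(self, seed, n, score_levels):
        """Trapezoid ROC area equals the normalized U statistic, ties included."""
        r = np.random.default_rng(seed)
        ref = r.integers(0, 2, size=n)
        if ref.min() == ref.max():
            ref[0] = 1 - ref[0]
        # few distinct score levels force heavy ties
        scores = r.integers(0, 2 * score_levels + 1, size=n) / (2 * score_levels)
        assert roc_curve(scores, ref).area == pytest.approx(
            _auc_pairwise(scores, ref), abs=1e-12
        )


# ---------------------------------------------------------------------------
# PR
# ---------------------------------------------------------------------------

def _ap_by_enumeration(scores, ref):
    """Step-interpolated PR area by exhaustive threshold enumeration."""
    order = np.argsort(-scores, kind="stable")
    ref = ref[order]
    tp = fp = 0
    n_pos = ref.sum()
    area = 0.0
    prev_recall = 0.0
    # group tied scores into one step
    i = 0
    s = scores[order]
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += ref[i:j].sum()
        fp += (j - i) - ref[i:j].sum()
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestPrCurve:
    def test_perfect_separation_has_unit_area(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        ref = np.array([0, 0, 1, 1])
        assert pr_curve(scores, ref).area == pytest.approx(1.0)

    def test_random_scores_baseline_near_prevalence(self, rng):
        n = 50_000
        ref = (rng.uniform(size=n) < 0.1).astype(int)
        scores = rng.uniform(size=n)
        assert pr_curve(scores, ref).area == pytest.approx(0.10, abs=0.02)

    def test_four_point_hand_example_matches_enumeration(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        ref = np.array([1, 0, 1, 0])
        expected = _ap_by_enumeration(scores, ref)  # 1*0.5 + (2/3)*0.5
        assert expected == pytest.approx(1 / 2 + 1 / 3)
        assert pr_curve(scores, ref).area == pytest.approx(expected, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([0.1, 0.9]), np.array([0, 0]))

    @given(st.integers(0, 10_000), st.integers(5, 40))
    @settings(max_examples=30)
    def test_area_matches_enumeration_oracle(self, seed, n):
        r = np.random.default_rng(seed)
        ref = r.integers(0, 2, size=n)
        if ref.sum() == 0:
            ref[0] = 1
        scores = np.round(r.uniform(size=n), 1)  # ties likely
        assert pr_curve(scores, ref).area == pytest.approx(
            _ap_by_enumeration(scores, ref), abs=1e-12
        )


# ---------------------------------------------------------------------------
# Event matching and event metrics
# ---------------------------------------------------------------------------

class TestMatchEvents:
    def test_identical_events_all_detected(self):
        ev = [SeizureEvent(10, 70)]
        m = match_events(ev, ev)
        assert m.n_detected_ref_events == 1 and not m.fd_events

    def test_overlap_anywhere_within_span_counts(self):
        """Touching even the last second of a seizure is a good detection."""
        ref = [SeizureEvent(0, 60)]
        pred = [SeizureEvent(59, 65)]
        m = match_events(pred, ref)
        assert m.n_detected_ref_events == 1
        assert m.fd_events == []

    def test_disjoint_prediction_is_false_detection(self):
        m = match_events([SeizureEvent(200, 260)], [SeizureEvent(0, 60)])
        assert m.n_detected_ref_events == 0
        assert m.fd_events == [SeizureEvent(200, 260)]

    def test_one_prediction_detects_all_spanned_references(self):
        ref = [SeizureEvent(0, 60), SeizureEvent(100, 160)]
        pred = [SeizureEvent(50, 110)]
        m = match_events(pred, ref)
        assert m.n_detected_ref_events == 2
        assert m.fd_events == [] and len(m.overlapping_pred_events) == 1

    def test_abutting_events_do_not_count_as_overlap(self):
        m = match_events([SeizureEvent(60, 70)], [SeizureEvent(0, 60)])
        assert m.n_detected_ref_events == 0 and len(m.fd_events) == 1

    def test_overlapping_list_rejected(self):
        with pytest.raises(ValueError):
            match_events([SeizureEvent(0, 10), SeizureEvent(5, 15)], [])


class TestJoinCloseEvents:
    def test_zero_gap_is_identity(self):
        evs = [SeizureEvent(0, 10), SeizureEvent(35, 45)]
        assert join_close_events(evs, 0.0) == evs

    def test_gap_below_threshold_merges(self):
        evs = [SeizureEvent(0, 10), SeizureEvent(35, 45)]  # gap 25 s
        assert join_close_events(evs, 30.0) == [SeizureEvent(0, 45)]

    def test_gap_at_threshold_does_not_merge(self):
        evs = [SeizureEvent(0, 10), SeizureEvent(45, 55)]  # gap 35 s
        assert join_close_events(evs, 30.0) == evs

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            join_close_events([], -1.0)


class TestEventMetrics:
    def test_single_long_false_detection(self):
        """One 20-minute FD in a one-hour record: 1 FD/h with MFDD 20 min."""
        m = match_events([SeizureEvent(0, 1200)], [SeizureEvent(3000, 3060)])
        em = event_metrics(m, record_duration_h=1.0)
        assert em.fd_per_h == 1.0
        assert em.mfdd_min == pytest.approx(20.0)
        assert time_in_fd_fraction(em.fd_per_h, em.mfdd_min) == pytest.approx(
            33.3, abs=0.05
        )

    def test_no_false_detections_leaves_mfdd_undefined(self):
        m = match_events([SeizureEvent(0, 10)], [SeizureEvent(5, 15)])
        em = event_metrics(m, 1.0)
        assert em.fd_per_h == 0.0 and em.mfdd_min is None

    def test_mean_duration_and_rate_arithmetic(self):
        fds = [SeizureEvent(0, 60), SeizureEvent(300, 420), SeizureEvent(900, 1080)]
        em = event_metrics(match_events(fds, []), 2.0)
        assert em.fd_per_h == pytest.approx(1.5)
        assert em.mfdd_min == pytest.approx(2.0)
        assert em.gdr is None  # no reference events

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            event_metrics(match_events([], []), 0.0)

    @given(
        st.lists(st.tuples(st.floats(0, 7000), st.floats(1, 120)), max_size=10),
        st.floats(0, 60),
    )
    def test_joined_rate_never_exceeds_raw_rate(self, raw, gap):
        from neoseize import merge_events

        fds = merge_events([SeizureEvent(s, s + d) for s, d in raw])
        em = event_metrics(match_events(fds, []), 2.0, join_gap_s=gap)
        assert em.fd_per_h_joined <= em.fd_per_h + 1e-12


class TestTimeInFdFraction:
    @pytest.mark.parametrize(
        "fd,mfdd,expected", [(1, 20, 33.3), (2, 1, 3.3), (0, 50, 0.0)]
    )
    def test_worked_examples(self, fd, mfdd, expected):
        assert time_in_fd_fraction(fd, mfdd) == pytest.approx(expected, abs=0.05)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            time_in_fd_fraction(-1, 5)


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

class TestSweep:
    def test_oracle_trace_is_perfect_at_all_positive_thresholds(self):
        grid = EpochGrid(1200.0)
        ref = AnnotationSet("p", [SeizureEvent(96, 200), SeizureEvent(600, 700)])
        trace = events_to_epoch_labels(ref, grid).astype(float)[None, :]
        cfg = PostprocessConfig(maf_len_epochs=1, collar_s=0.0)
        sweep = sweep_operating_points(
            trace, ref, cfg, grid, thresholds=np.linspace(0.1, 1.0, 10)
        )
        assert (sweep["gdr"] == 100.0).all()
        assert (sweep["fd_per_h"] == 0.0).all()

    def test_threshold_zero_predicts_whole_record(self):
        grid = EpochGrid(1200.0)
        ref = AnnotationSet("p", [SeizureEvent(96, 200)])
        trace = np.zeros((2, grid.n_epochs))
        cfg = PostprocessConfig(maf_len_epochs=1, collar_s=0.0)
        sweep = sweep_operating_points(trace, ref, cfg, grid, thresholds=np.array([0.0]))
        row = sweep.iloc[0]
        assert row["gdr"] == 100.0 and row["fd_per_h"] == 0.0
        assert row["sensitivity"] == 1.0 and row["specificity"] == 0.0

    def test_sweep_roc_matches_pooled_curve_without_postprocessing(self, rng):
        """Sweeping the raw chain on one channel retraces the epoch ROC."""
        grid = EpochGrid(4 * 3600.0)
        n = grid.n_epochs
        labels = np.zeros(n, dtype=int)
        for start in range(100, n - 100, 400):
            labels[start : start + 60] = 1
        z = np.where(labels == 1, 1.5, 0.0) + rng.normal(0, 1, n)
        probs = 1 / (1 + np.exp(-z))
        # reference events exactly matching the labelled epochs
        from neoseize import decisions_to_events

        ref = AnnotationSet("p", decisions_to_events(labels, grid))
        cfg = PostprocessConfig(maf_len_epochs=1, collar_s=0.0)
        sweep = sweep_operating_points(
            probs[None, :], ref, cfg, grid, thresholds=np.linspace(0, 1, 1001)
        )
        pooled = roc_curve(probs, events_to_epoch_labels(ref, grid))
        assert roc_area_from_sweep(sweep) == pytest.approx(pooled.area, abs=0.02)

    def test_detection_scores_monotone_in_threshold(self, rng):
        """GDR, sensitivity and detected burden never increase with threshold.

        The firing-epoch sets are nested across thresholds, so every
        predicted event at a higher threshold is contained in one at a lower
        threshold.  The false-detection *count* carries no such guarantee:
        at low thresholds false detections merge into fewer events.
        """
        grid = EpochGrid(3600.0)
        ref = AnnotationSet("p", [SeizureEvent(500, 700), SeizureEvent(2000, 2400)])
        probs = rng.uniform(size=(3, grid.n_epochs))
        sweep = sweep_operating_points(
            probs, ref, PostprocessConfig(), grid, thresholds=np.linspace(0, 1, 51)
        )
        assert np.all(np.diff(sweep["gdr"].to_numpy()) <= 1e-9)
        assert np.all(np.diff(sweep["sensitivity"].to_numpy()) <= 1e-9)

    def test_sensitivity_equals_detected_burden_fraction(self):
        """Epoch sensitivity measures the fraction of seizure burden found.

        On a non-overlapping grid with grid-aligned events, tp * hop equals
        the overlap time between predicted and reference events exactly.
        """
        grid = EpochGrid(2000.0, epoch_len_s=8.0, hop_s=8.0)
        ref = AnnotationSet("p", [SeizureEvent(80, 400), SeizureEvent(800, 1200)])
        pred_events = [SeizureEvent(240, 400), SeizureEvent(800, 1000)]
        ref_lab = events_to_epoch_labels(ref, grid, 1e-9)
        pred_lab = events_to_epoch_labels(AnnotationSet("q", pred_events), grid, 1e-9)
        c = confusion_counts(pred_lab, ref_lab)
        overlap = sum(
            rv.overlap_s(pv) for rv in ref.events for pv in pred_events
        )
        assert c.tp * grid.hop_s == pytest.approx(overlap)
        m = epoch_metrics(c)
        assert m.sensitivity == pytest.approx(overlap / ref.total_seizure_s)


def test_plot_performance_curves_writes_figure(tmp_path, rng):
    from neoseize.metrics import plot_performance_curves

    grid = EpochGrid(1800.0)
    ref = AnnotationSet("p", [SeizureEvent(100, 300)])
    probs = rng.uniform(size=(1, grid.n_epochs))
    sweep = sweep_operating_points(
        probs, ref, PostprocessConfig(), grid, thresholds=np.linspace(0, 1, 21)
    )
    out = tmp_path / "curves.png"
    plot_performance_curves(sweep, out)
    assert out.exists() and out.stat().st_size > 0
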