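"""Decision post-processing: MAF smoothing, thresholding, fusion, collar.

Stage order matches the detection system it serves: each channel's posterior
trace is smoothed with a centered moving-average filter (MAF), compared to a
threshold, the per-channel binary decisions are fused across channels by
epoch-wise OR, fused runs are joined into events, and finally every event is
extended by the collar on both sides (merging events that come to touch).

A centered L-epoch MAF spans (L-1)/2 hops of context on each side; on the
default 4-s hop grid the 15-epoch MAF therefore reaches 28 s either way, so
of a 40 s collar only 12 s extends beyond the data the smoothed decision
already saw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import EpochGrid, SeizureEvent, decisions_to_events, merge_events

__all__ = [
    "PostprocessConfig",
    "BinaryDecisionSeries",
    "smooth_maf",
    "threshold_decisions",
    "fuse_channels",
    "apply_collar",
    "maf_half_span_seconds",
    "run_postprocessing",
]


@dataclass(frozen=True)
class PostprocessConfig:
    """Post-processing parameters.

    maf_len_epochs : odd window length of the moving-average filter (epochs).
    threshold      : decision threshold on the smoothed posterior, in [0, 1].
    collar_s       : seconds added to both sides of every predicted event.
    fd_join_gap_s  : gap below which false detections are merged when the
                     joined false-detection rate is reported (metrics side
                     only; not part of the decision chain).
    """

    maf_len_epochs: int = 15
    threshold: float = 0.5
    collar_s: float = 40.0
    fd_join_gap_s: float = 30.0

    def __post_init__(self) -> None:
        if self.maf_len_epochs < 1 or self.maf_len_epochs % 2 == 0:
            raise ValueError("maf_len_epochs must be an odd positive integer")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if self.collar_s < 0:
            raise ValueError("collar_s must be >= 0")
        if self.fd_join_gap_s < 0:
            raise ValueError("fd_join_gap_s must be >= 0")

    @classmethod
    def from_file(cls, path) -> "PostprocessConfig":
        """Load a config block from a YAML or JSON file.

        Recognized keys: maf_len_epochs, threshold, collar_s, fd_join_gap_s;
        unknown keys raise.
        """
        import json
        from pathlib import Path

        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {"maf_len_epochs", "threshold", "collar_s", "fd_join_gap_s"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class BinaryDecisionSeries:
    """Per-epoch binary decisions on a grid, per channel or fused."""

    decisions: np.ndarray
    grid: EpochGrid
    provenance: str = "per-channel"

    def __post_init__(self) -> None:
        self.decisions = np.asarray(self.decisions).astype(np.int8).ravel()
        if not np.isin(self.decisions, (0, 1)).all():
            raise ValueError("decisions must be binary")
        if len(self.decisions) != self.grid.n_epochs:
            raise ValueError("decision length must equal grid.n_epochs")


def smooth_maf(trace: np.ndarray, maf_len_epochs: int) -> np.ndarray:
    """Centered moving average over ``maf_len_epochs`` epochs.

    At the record edges the window shrinks to the available epochs, so the
    output keeps the trace length and stays inside [0, 1] without invented
    padding values.
    """
    if maf_len_epochs < 1 or maf_len_epochs % 2 == 0:
        raise ValueError("MAF length must be an odd positive integer")
    x = np.asarray(trace, dtype=float).ravel()
    if maf_len_epochs == 1 or x.size == 0:
        return x.copy()
    half = maf_len_epochs // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, x.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def threshold_decisions(
    smoothed: np.ndarray, threshold: float, grid: EpochGrid, provenance: str = "per-channel"
) -> BinaryDecisionSeries:
    """Binary decision per epoch: 1 iff smoothed posterior >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    smoothed = np.asarray(smoothed, dtype=float).ravel()
    return BinaryDecisionSeries((smoothed >= threshold).astype(np.int8), grid, provenance)


def fuse_channels(per_channel: list[BinaryDecisionSeries]) -> BinaryDecisionSeries:
    """Epoch-wise OR across channels: any channel firing marks the epoch."""
    if not per_channel:
        raise ValueError("fuse_channels needs at least one series")
    grid = per_channel[0].grid
    n = len(per_channel[0].decisions)
    for s in per_channel:
        if len(s.decisions) != n or s.grid != grid:
            raise ValueError("all series must share one grid")
    fused = np.zeros(n, dtype=np.int8)
    for s in per_channel:
        fused |= s.decisions
    return BinaryDecisionSeries(fused, grid, provenance="fused")


def apply_collar(
    events: list[SeizureEvent], collar_s: float, record_duration_s: float
) -> list[SeizureEvent]:
    """Extend each event by ``collar_s`` on both sides, clip, and merge.

    Events whose extended intervals overlap or abut exactly are merged
    (closure of the union); the result is sorted and non-overlapping.  A
    zero collar is the identity: pre-existing abutting events (runs
    separated by a single non-seizure epoch) stay separate.
    """
    if collar_s < 0:
        raise ValueError("collar_s must be >= 0")
    _check_disjoint(events, "events")
    if collar_s == 0:
        return sorted(events)
    extended = [
        SeizureEvent(max(0.0, ev.start_s - collar_s), min(record_duration_s, ev.end_s + collar_s))
        for ev in events
    ]
    return merge_events(extended)


def maf_half_span_seconds(maf_len_epochs: int, hop_s: float = 4.0) -> float:
    """Temporal half-span of a centered MAF: ``((L-1)/2) * hop_s`` seconds."""
    if maf_len_epochs < 1 or maf_len_epochs % 2 == 0:
        raise ValueError("MAF length must be an odd positive integer")
    return (maf_len_epochs - 1) / 2 * hop_s


def run_postprocessing(
    trace, config: PostprocessConfig, grid: EpochGrid | None = None
) -> list[SeizureEvent]:
    """Full chain: per-channel MAF -> threshold -> OR fusion -> events -> collar."""
    from .detector import ProbabilityTrace  # noqa: PLC0415 - avoid import cycle

    if isinstance(trace, ProbabilityTrace):
        grid = trace.grid
        channels = trace.probabilities
    else:
        if grid is None:
            raise ValueError("grid required when trace is a bare array")
        channels = np.atleast_2d(np.asarray(trace, dtype=float))
    series = [
        threshold_decisions(smooth_maf(ch, config.maf_len_epochs), config.threshold, grid)
        for ch in channels
    ]
    fused = fuse_channels(series)
    events = decisions_to_events(fused.decisions, grid)
    return apply_collar(events, config.collar_s, grid.record_duration_s)


def _check_disjoint(events: list[SeizureEvent], what: str) -> None:
    for a, b in zip(sorted(events), sorted(events)[1:]):
        if b.start_s < a.end_s:
            raise ValueError(f"{what} must be non-overlapping; {a} overlaps {b}")
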