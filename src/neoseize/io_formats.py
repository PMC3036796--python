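"""I/O and domain types for seizure annotations, epoch grids and EEG signals.

All times are 0-based seconds from record start; intervals are half-open
``[start, end)``.  The epoch grid is the 8-s / 50 %-overlap segmentation
shared by every downstream stage: epoch ``i`` occupies
``[i*hop_s, i*hop_s + epoch_len_s)``.

Signals travel as ``(channels, samples)`` float arrays in microvolts.  EDF
is the only signal format: reading goes through :mod:`mne`; writing uses a
minimal EDF writer (16-bit, one-second data records) sufficient for the
simulated cohorts this package produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecordingMeta",
    "SeizureEvent",
    "AnnotationSet",
    "EpochGrid",
    "merge_events",
    "read_annotation_csv",
    "write_annotation_csv",
    "load_recording",
    "write_edf",
    "events_to_epoch_labels",
    "decisions_to_events",
    "read_trace_csv",
    "write_trace_csv",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingMeta:
    """Metadata of one EEG recording."""

    patient_id: str
    duration_s: float
    sampling_rate_hz: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        object.__setattr__(self, "channel_names", tuple(self.channel_names))


@dataclass(frozen=True, order=True)
class SeizureEvent:
    """One seizure interval ``[start_s, end_s)`` in record-time seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"end_s must exceed start_s, got ({self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, other: "SeizureEvent") -> float:
        """Length of temporal intersection with *other* (0 if disjoint)."""
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))


def merge_events(events: Sequence[SeizureEvent]) -> list[SeizureEvent]:
    """Sort events and merge any that overlap or abut into maximal intervals."""
    if not events:
        return []
    out: list[SeizureEvent] = []
    for ev in sorted(events):
        if out and ev.start_s <= out[-1].end_s:
            if ev.end_s > out[-1].end_s:
                out[-1] = SeizureEvent(out[-1].start_s, ev.end_s)
        else:
            out.append(ev)
    return out


@dataclass
class AnnotationSet:
    """Seizure events of one patient, sorted and pairwise non-overlapping.

    Overlapping input events are merged on construction: they denote the same
    underlying seizure state, not distinct seizures.
    """

    patient_id: str
    events: list[SeizureEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = merge_events(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def total_seizure_s(self) -> float:
        """Total seizure burden in seconds."""
        return sum(ev.duration_s for ev in self.events)

    def validate_bounds(self, duration_s: float) -> None:
        for ev in self.events:
            if ev.end_s > duration_s + 1e-9:
                raise ValueError(
                    f"event ({ev.start_s}, {ev.end_s}) exceeds record "
                    f"duration {duration_s} s"
                )


@dataclass(frozen=True)
class EpochGrid:
    """Fixed epoch segmentation of a record.

    Epoch ``i`` is ``[i*hop_s, i*hop_s + epoch_len_s)``; with the defaults
    (8-s epochs, 4-s hop) consecutive epochs overlap by 50 %.
    """

    record_duration_s: float
    epoch_len_s: float = 8.0
    hop_s: float = 4.0

    def __post_init__(self) -> None:
        if self.epoch_len_s <= 0 or self.hop_s <= 0:
            raise ValueError("epoch_len_s and hop_s must be positive")
        if self.hop_s > self.epoch_len_s:
            raise ValueError("hop_s must not exceed epoch_len_s")
        if self.record_duration_s < 0:
            raise ValueError("record_duration_s must be >= 0")

    @property
    def n_epochs(self) -> int:
        if self.record_duration_s < self.epoch_len_s:
            return 0
        return int(math.floor((self.record_duration_s - self.epoch_len_s) / self.hop_s)) + 1

    def epoch_start_s(self, i: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(i) * self.hop_s if isinstance(i, np.ndarray) else i * self.hop_s

    def epoch_interval(self, i: int) -> tuple[float, float]:
        start = i * self.hop_s
        return start, start + self.epoch_len_s


# ---------------------------------------------------------------------------
# Annotation CSV  (schema: patient_id,start_s,end_s)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("patient_id", "start_s", "end_s")


def read_annotation_csv(path: str | Path) -> AnnotationSet:
    """Read one patient's annotation CSV into an :class:`AnnotationSet`.

    The file must carry the header ``patient_id,start_s,end_s``.  Events are
    sorted and overlap-merged on load.  Rows with ``end_s <= start_s`` and
    rows that fail to parse raise, naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse annotation CSV {path}: {exc}") from exc
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing annotation columns {sorted(missing)}; "
            f"expected header {','.join(ANNOTATION_COLUMNS)}"
        )
    if df.empty:
        return AnnotationSet(patient_id=path.stem, events=[])
    pids = df["patient_id"].unique()
    if len(pids) > 1:
        raise ValueError(f"{path}: multiple patient ids {list(pids)} in one file")
    events = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            start, end = float(row["start_s"]), float(row["end_s"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}") from exc
        if not (np.isfinite(start) and np.isfinite(end)):
            raise ValueError(f"{path}: non-finite times at line {line_no}")
        if end <= start or start < 0:
            raise ValueError(
                f"{path}: invalid event ({start}, {end}) at line {line_no}: "
                "need 0 <= start < end"
            )
        events.append(SeizureEvent(start, end))
    return AnnotationSet(patient_id=str(pids[0]), events=events)


def write_annotation_csv(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` in the 3-column annotation schema."""
    df = pd.DataFrame(
        {
            "patient_id": [annotations.patient_id] * len(annotations.events),
            "start_s": [ev.start_s for ev in annotations.events],
            "end_s": [ev.end_s for ev in annotations.events],
        },
        columns=list(ANNOTATION_COLUMNS),
    )
    # %.17g round-trips float64 exactly, so load(write(x)) == x
    df.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


# ---------------------------------------------------------------------------
# EDF signals
# ---------------------------------------------------------------------------

def load_recording(
    path: str | Path,
    channels: Sequence[str] | None = None,
) -> tuple[np.ndarray, RecordingMeta]:
    """Load an EDF recording as a ``(channels, samples)`` array in microvolts.

    Parameters
    ----------
    path
        EDF file path.
    channels
        Optional channel subset, in the order requested.  A channel absent
        from the file raises a ``ValueError`` listing the available labels.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    if channels is not None:
        missing = [ch for ch in channels if ch not in available]
        if missing:
            raise ValueError(
                f"channel(s) {missing} not in {path.name}; available: {available}"
            )
        raw = raw.pick(list(channels))
    data_uv = raw.get_data() * 1e6  # mne returns volts for EEG channels
    meta = RecordingMeta(
        patient_id=path.stem,
        duration_s=raw.n_times / raw.info["sfreq"],
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
    )
    return data_uv, meta


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    sampling_rate_hz: int,
    channel_names: Sequence[str],
    patient_id: str = "anonymous",
) -> None:
    """Write a ``(channels, samples)`` microvolt array to a 16-bit EDF file.

    Uses one-second data records; the signal is zero-padded to a whole number
    of seconds if needed.  Per-channel physical min/max are taken from the
    data, so quantization error is bounded by the per-channel dynamic range
    divided by 2**16.
    """
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data_uv.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match number of rows")
    fs = int(sampling_rate_hz)
    if fs != sampling_rate_hz or fs <= 0:
        raise ValueError("sampling_rate_hz must be a positive integer for EDF export")
    n_rec = int(math.ceil(n_samp / fs))
    if n_rec * fs != n_samp:
        pad = np.zeros((n_ch, n_rec * fs - n_samp))
        data_uv = np.hstack([data_uv, pad])

    pmin = data_uv.min(axis=1).copy()
    pmax = data_uv.max(axis=1).copy()
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    def _field(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b.ljust(width)

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(patient_id, 80))
        f.write(_field("startdate X X X", 80))
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(str(256 * (n_ch + 1)), 8))
        f.write(_field("", 44))
        f.write(_field(str(n_rec), 8))
        f.write(_field("1", 8))
        f.write(_field(str(n_ch), 4))
        for nm in channel_names:
            f.write(_field(nm, 16))
        for _ in channel_names:
            f.write(_field("", 80))       # transducer
        for _ in channel_names:
            f.write(_field("uV", 8))      # physical dimension
        for v in pmin:
            f.write(_field(f"{v:.8g}"[:8], 8))
        for v in pmax:
            f.write(_field(f"{v:.8g}"[:8], 8))
        for _ in channel_names:
            f.write(_field(str(dmin), 8))
        for _ in channel_names:
            f.write(_field(str(dmax), 8))
        for _ in channel_names:
            f.write(_field("", 80))       # prefiltering
        for _ in channel_names:
            f.write(_field(str(fs), 8))   # samples per record
        for _ in channel_names:
            f.write(_field("", 32))

        # reparse the truncated 8-char physical bounds so writer and header agree
        pmin_h = np.array([float(f"{v:.8g}"[:8]) for v in pmin])
        pmax_h = np.array([float(f"{v:.8g}"[:8]) for v in pmax])
        scale = (dmax - dmin) / (pmax_h - pmin_h)
        for r in range(n_rec):
            for i in range(n_ch):
                seg = data_uv[i, r * fs : (r + 1) * fs]
                dig = np.clip(
                    np.round((seg - pmin_h[i]) * scale[i] + dmin), dmin, dmax
                ).astype("<i2")
                f.write(dig.tobytes())


# ---------------------------------------------------------------------------
# Event <-> epoch conversion
# ---------------------------------------------------------------------------

def events_to_epoch_labels(
    annotations: AnnotationSet,
    grid: EpochGrid,
    min_overlap_frac: float = 0.5,
    strict: bool = False,
) -> np.ndarray:
    """Rasterize seizure events onto the epoch grid as a binary label vector.

    Epoch ``i`` is labelled 1 iff its temporal overlap with the union of the
    events is at least (``strict``: strictly exceeds)
    ``min_overlap_frac * epoch_len_s``.  The default of 0.5 labels an epoch
    seizure only when the majority of it lies inside a seizure, avoiding
    inflation of the seizure class by boundary slivers under 50 % epoch
    overlap.  The strict variant at 0.5 is the exact inverse of run-joining
    on the 50 %-overlap grid (an epoch adjacent to a run overlaps its event
    by exactly half an epoch) and is used to rasterize *predicted* events.
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must lie in (0, 1]")
    annotations.validate_bounds(grid.record_duration_s)
    n = grid.n_epochs
    labels = np.zeros(n, dtype=np.int8)
    if n == 0 or not annotations.events:
        return labels
    starts = np.arange(n) * grid.hop_s
    ends = starts + grid.epoch_len_s
    overlap = np.zeros(n)
    for ev in annotations.events:  # events are disjoint, so overlaps add
        overlap += np.clip(
            np.minimum(ends, ev.end_s) - np.maximum(starts, ev.start_s), 0.0, None
        )
    need = min_overlap_frac * grid.epoch_len_s
    hit = overlap > need + 1e-12 if strict else overlap >= need - 1e-12
    labels[hit] = 1
    return labels


def decisions_to_events(decisions: np.ndarray, grid: EpochGrid) -> list[SeizureEvent]:
    """Join maximal runs of positive epoch decisions into seizure events.

    Each run of consecutive 1s becomes one event spanning from the first
    epoch's start to the last epoch's end, clipped to the record duration.
    Runs separated by at least one zero epoch stay separate events (their
    spans may still overlap in time because epochs overlap).
    """
    decisions = np.asarray(decisions)
    if decisions.ndim != 1:
        raise ValueError("decisions must be a 1-D vector")
    if len(decisions) != grid.n_epochs:
        raise ValueError(
            f"decisions length {len(decisions)} != grid n_epochs {grid.n_epochs}"
        )
    events: list[SeizureEvent] = []
    d = decisions.astype(bool)
    if not d.any():
        return events
    padded = np.diff(np.concatenate([[0], d.view(np.int8), [0]]))
    run_starts = np.flatnonzero(padded == 1)
    run_ends = np.flatnonzero(padded == -1) - 1  # inclusive epoch index
    for a, b in zip(run_starts, run_ends):
        start = a * grid.hop_s
        end = min(b * grid.hop_s + grid.epoch_len_s, grid.record_duration_s)
        events.append(SeizureEvent(start, end))
    return events


# ---------------------------------------------------------------------------
# Per-epoch trace CSV  (schema: epoch_index,channel,value)
# ---------------------------------------------------------------------------

def write_trace_csv(values: np.ndarray, channel_names: Sequence[str], path: str | Path) -> None:
    """Write a ``(channels, epochs)`` value array as long-form CSV."""
    values = np.atleast_2d(values)
    n_ch, n_ep = values.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match number of rows")
    df = pd.DataFrame(
        {
            "epoch_index": np.tile(np.arange(n_ep), n_ch),
            "channel": np.repeat(list(channel_names), n_ep),
            "value": values.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a long-form epoch/channel/value CSV back to ``(channels, epochs)``."""
    df = pd.read_csv(path)
    required = {"epoch_index", "channel", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    channels = list(dict.fromkeys(df["channel"]))
    n_ep = int(df["epoch_index"].max()) + 1 if len(df) else 0
    out = np.full((len(channels), n_ep), np.nan)
    for k, ch in enumerate(channels):
        sub = df[df["channel"] == ch].sort_values("epoch_index")
        if len(sub) != n_ep or not np.array_equal(sub["epoch_index"].values, np.arange(n_ep)):
            raise ValueError(f"{path}: channel {ch!r} has an incomplete epoch index")
        out[k] = sub["value"].values
    return out, channels
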