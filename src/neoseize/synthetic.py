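"""Synthetic cohorts emulating a neonatal seizure-monitoring dataset.

Three generators at increasing realism:

* :func:`generate_schedule` draws seizure-event schedules whose rate
  (2.6 seizures/hour) and mean duration (3.89 min) match the statistics of a
  term-HIE NICU cohort, with a right-skewed (lognormal) duration law spanning
  roughly ten seconds to tens of minutes.
* :func:`generate_score_traces` emits per-epoch posterior-probability traces
  with a *known* discriminability: latent class means plus AR(1) Gaussian
  noise through a logistic link, so with no autocorrelation the pooled-epoch
  ROC area has the closed form Phi((mu1-mu0)/(sigma*sqrt(2))).  This tests
  the metric layer without any classifier.
* :func:`generate_eeg` synthesizes toy multichannel EEG: 1/f background
  noise, with each seizure adding an amplitude-enveloped 1-3 Hz oscillation
  plus first harmonic to a small random channel subset (focal emphasis).
  It exercises the full detector front end, not neonatal EEG morphology.

All randomness flows from a per-config integer seed; generators are
deterministic given their config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_formats import (
    AnnotationSet,
    EpochGrid,
    RecordingMeta,
    SeizureEvent,
    events_to_epoch_labels,
)

__all__ = [
    "DEFAULT_CHANNELS",
    "ScheduleConfig",
    "ScoreTraceConfig",
    "EEGSynthConfig",
    "generate_schedule",
    "generate_score_traces",
    "generate_eeg",
    "generate_cohort",
]

DEFAULT_CHANNELS = ("F4-C4", "C4-O2", "F3-C3", "C3-O1", "T4-C4", "C4-Cz", "Cz-C3", "C3-T3")


# ---------------------------------------------------------------------------
# Seizure schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    """Seizure schedule statistics.

    Defaults match the emulated cohort: ~2.6 seizures/hour, mean duration
    3.89 min, durations lognormal (log-sd 0.9) clipped to [10 s, 35 min],
    exponential inter-seizure gaps floored at 30 s.  ``min_events`` >= 1
    mirrors a cohort composed exclusively of seizure patients: a draw with
    fewer events is deterministically redrawn from the next seed substream.
    """

    record_hours: float = 1.0
    seizures_per_hour: float = 2.6
    mean_seizure_min: float = 3.89
    duration_log_sd: float = 0.9
    min_duration_s: float = 10.0
    max_duration_s: float = 35.0 * 60.0
    min_gap_s: float = 30.0
    min_events: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.record_hours <= 0:
            raise ValueError("record_hours must be > 0")
        if self.seizures_per_hour < 0 or self.mean_seizure_min <= 0:
            raise ValueError("rate must be >= 0 and mean duration > 0")


def _draw_schedule(config: ScheduleConfig, rng: np.random.Generator) -> list[SeizureEvent]:
    duration_s = config.record_hours * 3600.0
    mean_dur_s = config.mean_seizure_min * 60.0
    cycle_s = 3600.0 / config.seizures_per_hour
    mean_gap_s = max(cycle_s - mean_dur_s, config.min_gap_s)
    # exponential part sized so the floored gap keeps the configured mean
    exp_mean = max(mean_gap_s - config.min_gap_s, 1.0)
    mu_log = math.log(mean_dur_s) - config.duration_log_sd**2 / 2.0

    events: list[SeizureEvent] = []
    # first seizure onset ~ uniform within one cycle, so records of any
    # length see the configured rate on average
    t = rng.uniform(0.0, cycle_s)
    while t < duration_s:
        dur = float(
            np.clip(
                rng.lognormal(mu_log, config.duration_log_sd),
                config.min_duration_s,
                config.max_duration_s,
            )
        )
        end = min(t + dur, duration_s)
        if end - t >= config.min_duration_s:
            events.append(SeizureEvent(t, end))
        t = end + config.min_gap_s + rng.exponential(exp_mean)
    return events


def generate_schedule(config: ScheduleConfig) -> AnnotationSet:
    """Draw one patient's seizure schedule as an :class:`AnnotationSet`.

    Alternates gap and duration draws until the record ends; events are
    non-overlapping by construction and clipped to the record.  With
    ``seizures_per_hour == 0`` the schedule is empty regardless of
    ``min_events``.
    """
    if config.seizures_per_hour == 0:
        return AnnotationSet(patient_id=f"synth{config.seed}", events=[])
    for attempt in range(64):
        rng = np.random.default_rng([config.seed, attempt])
        events = _draw_schedule(config, rng)
        if len(events) >= config.min_events:
            return AnnotationSet(patient_id=f"synth{config.seed}", events=events)
    raise RuntimeError(
        "could not draw the requested minimum number of seizures; "
        "record too short for the configured rate"
    )


# ---------------------------------------------------------------------------
# Posterior score traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTraceConfig:
    """Latent-Gaussian score-trace model.

    Latent value is ``mu1`` on seizure-labelled epochs of seizure-active
    channels and ``mu0`` elsewhere, plus stationary AR(1) Gaussian noise of
    marginal sd ``sigma`` (per channel), plus optional iid measurement noise;
    posteriors are the logistic transform of the latent value.
    """

    mu0: float = -2.0
    mu1: float = 2.0
    sigma: float = 1.0
    ar_coeff: float = 0.0
    iid_noise_sd: float = 0.0
    n_channels: int = 8
    active_channels_per_event: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


def _ar1_noise(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    w = rng.standard_normal(n)
    if phi == 0:
        return sigma * w
    x = np.empty(n)
    x[0] = w[0]  # stationary start: marginal sd already sigma after scaling
    innov = math.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov * w[t]
    return sigma * x


def generate_score_traces(schedule: AnnotationSet, grid: EpochGrid, config: ScoreTraceConfig):
    """Per-channel posterior traces with analytically known separability.

    Returns a :class:`~neoseize.detector.ProbabilityTrace`.  Each seizure
    activates ``active_channels_per_event`` randomly chosen channels (all of
    them if the count reaches ``n_channels``); the epoch labels used for the
    latent mean assignment are exactly ``events_to_epoch_labels`` of the
    schedule, keeping generator and scorer on one grid.
    """
    from .detector import ProbabilityTrace  # noqa: PLC0415 - import cycle

    rng = np.random.default_rng([config.seed, 17])
    n_ep = grid.n_epochs
    n_ch = config.n_channels
    z = np.full((n_ch, n_ep), config.mu0, dtype=float)
    n_active = min(config.active_channels_per_event, n_ch)
    for ev in schedule.events:
        ev_labels = events_to_epoch_labels(
            AnnotationSet("ev", [ev]), grid, min_overlap_frac=0.5
        ).astype(bool)
        chans = rng.choice(n_ch, size=n_active, replace=False)
        for c in chans:
            z[c, ev_labels] = config.mu1
    for c in range(n_ch):
        z[c] += _ar1_noise(rng, n_ep, config.sigma, config.ar_coeff)
    if config.iid_noise_sd > 0:
        z += config.iid_noise_sd * rng.standard_normal(z.shape)
    probs = expit(z)
    return ProbabilityTrace(probs, grid, tuple(f"ch{i}" for i in range(n_ch)))


# ---------------------------------------------------------------------------
# Toy multichannel EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGSynthConfig:
    """Toy EEG synthesis parameters.

    Background is 1/f^exponent noise at ``background_rms_uv`` microvolts RMS
    per channel.  Each seizure adds a rhythmic 1-3 Hz oscillation with a 50 %
    first harmonic, shaped by a smooth onset/offset amplitude envelope, to
    ``active_channels_per_event`` random channels.  ``snr`` is the amplitude
    of the seizure oscillation relative to the background RMS; snr 0 yields
    the background alone.
    """

    fs: float = 256.0
    n_channels: int = 8
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    background_exponent: float = 1.0
    background_rms_uv: float = 30.0
    seizure_freq_lo: float = 1.0
    seizure_freq_hi: float = 3.0
    harmonic_ratio: float = 0.5
    active_channels_per_event: int = 2
    snr: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 64:
            raise ValueError("fs must be >= 64 Hz")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if len(self.channel_names) != self.n_channels:
            object.__setattr__(
                self, "channel_names",
                tuple(f"ch{i}" for i in range(self.n_channels)),
            )


def _colored_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        shape = freqs ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _envelope(n: int) -> np.ndarray:
    """Smooth onset/offset amplitude envelope (raised-cosine ramps, 10 % each)."""
    ramp = max(2, int(0.1 * n))
    env = np.ones(n)
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[:ramp] = up
    env[-ramp:] = up[::-1]
    return env


def generate_eeg(
    schedule: AnnotationSet, config: EEGSynthConfig
) -> tuple[np.ndarray, RecordingMeta]:
    """Synthesize a multichannel record realizing the given seizure schedule.

    Background and seizure randomness come from separate seed substreams, so
    the background is bit-identical across ``snr`` settings with the same
    seed (snr 0 returns exactly the background).
    """
    duration_s = max((ev.end_s for ev in schedule.events), default=0.0)
    duration_s = max(duration_s, getattr(schedule, "duration_s", 0.0))
    return generate_eeg_for_duration(schedule, duration_s, config)


def generate_eeg_for_duration(
    schedule: AnnotationSet, duration_s: float, config: EEGSynthConfig
) -> tuple[np.ndarray, RecordingMeta]:
    """Like :func:`generate_eeg` with an explicit record duration in seconds."""
    if duration_s <= 0:
        raise ValueError("record duration must be > 0")
    schedule.validate_bounds(duration_s)
    fs = config.fs
    n_samp = int(round(duration_s * fs))
    rng_bg = np.random.default_rng([config.seed, 0])
    rng_sz = np.random.default_rng([config.seed, 1])

    data = np.empty((config.n_channels, n_samp))
    for c in range(config.n_channels):
        data[c] = config.background_rms_uv * _colored_noise(
            rng_bg, n_samp, config.background_exponent
        )

    amp = config.snr * config.background_rms_uv
    n_active = min(config.active_channels_per_event, config.n_channels)
    for ev in schedule.events:
        f0 = rng_sz.uniform(config.seizure_freq_lo, config.seizure_freq_hi)
        phase = rng_sz.uniform(0, 2 * np.pi)
        chans = rng_sz.choice(config.n_channels, size=n_active, replace=False)
        i0, i1 = int(round(ev.start_s * fs)), min(int(round(ev.end_s * fs)), n_samp)
        t = np.arange(i0, i1) / fs
        wave = np.sin(2 * np.pi * f0 * t + phase)
        wave += config.harmonic_ratio * np.sin(2 * np.pi * 2 * f0 * t + 2 * phase)
        wave *= _envelope(i1 - i0)
        if amp > 0:
            for c in chans:
                data[c, i0:i1] += amp * wave

    meta = RecordingMeta(
        patient_id=schedule.patient_id,
        duration_s=n_samp / fs,
        sampling_rate_hz=fs,
        channel_names=config.channel_names,
    )
    return data, meta


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    """One simulated patient: raw EEG plus its reference annotation."""

    signal_uv: np.ndarray
    meta: RecordingMeta
    annotations: AnnotationSet
    schedule_config: ScheduleConfig = field(repr=False, default=None)


def generate_cohort(
    n_patients: int,
    record_hours: float = 1.0,
    snr: float = 5.0,
    seed: int = 0,
    schedule_kwargs: dict | None = None,
    eeg_kwargs: dict | None = None,
) -> dict[str, SyntheticPatient]:
    """Simulate a cohort of patients with EEG and reference annotations.

    Patient ``k`` uses seed substream ``seed*1000 + k`` for both its schedule
    and its EEG, so cohorts are reproducible and patients independent.
    """
    cohort: dict[str, SyntheticPatient] = {}
    for k in range(n_patients):
        pid = f"p{k + 1:02d}"
        sub = seed * 1000 + k
        sc = ScheduleConfig(record_hours=record_hours, seed=sub, **(schedule_kwargs or {}))
        schedule = generate_schedule(sc)
        schedule.patient_id = pid
        ec = EEGSynthConfig(snr=snr, seed=sub, **(eeg_kwargs or {}))
        sig, meta = generate_eeg_for_duration(schedule, record_hours * 3600.0, ec)
        meta = RecordingMeta(pid, meta.duration_s, meta.sampling_rate_hz, meta.channel_names)
        cohort[pid] = SyntheticPatient(sig, meta, schedule, sc)
    return cohort
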