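"""Reference SVM seizure-detector front end.

Pipeline per channel: down-sample the raw EEG to the 32 Hz analysis rate
through a zero-phase 12.8 Hz low-pass FIR, cut it into 8-s epochs with 50 %
overlap, extract per-epoch features, z-score them against a template fitted
on training data only, and score each epoch with an RBF-kernel SVM whose
decision values are mapped to seizure posterior probabilities by Platt
sigmoid calibration.

The feature set is pluggable.  The bundled default covers time-domain
amplitude and complexity measures, band powers and spectral shape, and an
amplitude-histogram entropy; it is a representative front end, not a
reproduction of any particular published feature list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
from scipy import signal as sps
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .io_formats import EpochGrid

__all__ = [
    "ANALYSIS_RATE_HZ",
    "ANTIALIAS_CUTOFF_HZ",
    "FeatureMatrix",
    "NormalizationTemplate",
    "DetectorModel",
    "ProbabilityTrace",
    "FEATURE_REGISTRY",
    "DEFAULT_FEATURES",
    "register_feature",
    "resample_to_analysis_rate",
    "segment_epochs",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
    "train_detector",
    "predict_probability_trace",
    "save_model",
    "load_model",
]

ANALYSIS_RATE_HZ = 32
ANTIALIAS_CUTOFF_HZ = 12.8
_FIR_TAPS = 257  # zero-phase via filtfilt => effective attenuation doubles


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-epoch feature rows for one channel."""

    values: np.ndarray  # (n_epochs, n_features)
    feature_names: tuple[str, ...]
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("values width must match feature_names")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/Inf")


@dataclass
class NormalizationTemplate:
    """Per-feature mean/sd fitted on training data (anisotropic z-scoring)."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.mean) == len(self.sd) == len(self.feature_names)):
            raise ValueError("template vectors must match feature_names length")


@dataclass
class DetectorModel:
    """Trained classifier plus everything needed to score new channels."""

    classifier: CalibratedClassifierCV
    template: NormalizationTemplate
    feature_names: tuple[str, ...]
    hyperparams: dict = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class ProbabilityTrace:
    """Per-channel, per-epoch seizure posteriors on a shared epoch grid."""

    probabilities: np.ndarray  # (n_channels, n_epochs), values in [0, 1]
    grid: EpochGrid
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.probabilities = np.atleast_2d(np.asarray(self.probabilities, dtype=float))
        if self.probabilities.shape[1] != self.grid.n_epochs:
            raise ValueError(
                f"trace length {self.probabilities.shape[1]} != grid "
                f"n_epochs {self.grid.n_epochs}"
            )
        if self.probabilities.size and (
            self.probabilities.min() < -1e-12 or self.probabilities.max() > 1 + 1e-12
        ):
            raise ValueError("posteriors must lie in [0, 1]")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i}" for i in range(self.probabilities.shape[0])
            )

    @property
    def n_channels(self) -> int:
        return self.probabilities.shape[0]


# ---------------------------------------------------------------------------
# Down-sampling
# ---------------------------------------------------------------------------

def resample_to_analysis_rate(x: np.ndarray, fs_in: float) -> np.ndarray:
    """Down-sample a signal (last axis) to 32 Hz with a 12.8 Hz anti-alias FIR.

    The low-pass is a linear-phase FIR applied forward-backward (zero phase),
    so epoch timing is not skewed by group delay.  Integer input/output rate
    ratios decimate by slicing; rational ratios fall back to polyphase
    resampling after the same filter.
    """
    if fs_in < 2 * ANALYSIS_RATE_HZ:
        raise ValueError(f"fs_in must be >= {2 * ANALYSIS_RATE_HZ} Hz, got {fs_in}")
    x = np.asarray(x, dtype=float)
    taps = sps.firwin(_FIR_TAPS, ANTIALIAS_CUTOFF_HZ, fs=fs_in)
    padlen = min(3 * _FIR_TAPS, x.shape[-1] - 1)
    y = sps.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)
    ratio = fs_in / ANALYSIS_RATE_HZ
    if abs(ratio - round(ratio)) < 1e-9:
        return y[..., :: int(round(ratio))]
    frac = Fraction(fs_in / ANALYSIS_RATE_HZ).limit_denominator(1000)
    if abs(float(frac) - ratio) > 1e-9:
        raise ValueError(f"cannot resample irrational rate ratio {ratio}")
    return sps.resample_poly(y, frac.denominator, frac.numerator, axis=-1)


def segment_epochs(signal32: np.ndarray, grid: EpochGrid) -> np.ndarray:
    """Slice a 32 Hz signal into the grid's epochs: ``(n_epochs, samples)``.

    With the default grid this yields 256-sample rows hopped by 128 samples.
    """
    signal32 = np.asarray(signal32, dtype=float)
    if signal32.ndim != 1:
        raise ValueError("segment_epochs expects a single-channel 1-D signal")
    hop = int(round(grid.hop_s * ANALYSIS_RATE_HZ))
    win = int(round(grid.epoch_len_s * ANALYSIS_RATE_HZ))
    n = grid.n_epochs
    if n == 0:
        return np.empty((0, win))
    if (n - 1) * hop + win > signal32.size:
        raise ValueError("signal shorter than the grid it was built from")
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return signal32[idx]


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

FeatureFunc = Callable[[np.ndarray, float], np.ndarray]
FEATURE_REGISTRY: dict[str, FeatureFunc] = {}


def register_feature(name: str) -> Callable[[FeatureFunc], FeatureFunc]:
    """Register a per-epoch feature ``f(epochs, fs) -> (n_epochs,) vector``."""

    def deco(func: FeatureFunc) -> FeatureFunc:
        FEATURE_REGISTRY[name] = func
        return func

    return deco


@register_feature("rms_amplitude")
def _rms(ep: np.ndarray, fs: float) -> np.ndarray:
    return np.sqrt(np.mean(ep**2, axis=1))


@register_feature("line_length")
def _line_length(ep: np.ndarray, fs: float) -> np.ndarray:
    return np.sum(np.abs(np.diff(ep, axis=1)), axis=1)


@register_feature("zero_crossings")
def _zero_crossings(ep: np.ndarray, fs: float) -> np.ndarray:
    centered = ep - ep.mean(axis=1, keepdims=True)
    return np.sum(np.abs(np.diff(np.signbit(centered).astype(int), axis=1)), axis=1).astype(float)


def _variance(ep: np.ndarray) -> np.ndarray:
    return np.var(ep, axis=1)


@register_feature("hjorth_activity")
def _hjorth_activity(ep: np.ndarray, fs: float) -> np.ndarray:
    return _variance(ep)


@register_feature("hjorth_mobility")
def _hjorth_mobility(ep: np.ndarray, fs: float) -> np.ndarray:
    v0 = _variance(ep)
    v1 = np.var(np.diff(ep, axis=1), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.sqrt(v1 / v0)
    return np.where(v0 > 0, m, 0.0)  # flat epoch: zero derivative power


@register_feature("hjorth_complexity")
def _hjorth_complexity(ep: np.ndarray, fs: float) -> np.ndarray:
    d1 = np.diff(ep, axis=1)
    m1 = _hjorth_mobility(ep, fs)
    m2 = _hjorth_mobility(d1, fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = m2 / m1
    return np.where(m1 > 0, c, 0.0)


def _psd(ep: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    freqs, pxx = sps.periodogram(ep, fs=fs, axis=1, detrend="constant")
    return freqs, pxx


def _band_power(ep: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    freqs, pxx = _psd(ep, fs)
    sel = (freqs >= lo) & (freqs < hi)
    return pxx[:, sel].sum(axis=1)


@register_feature("bandpower_0p5_4")
def _bp_delta(ep: np.ndarray, fs: float) -> np.ndarray:
    return _band_power(ep, fs, 0.5, 4.0)


@register_feature("bandpower_4_8")
def _bp_theta(ep: np.ndarray, fs: float) -> np.ndarray:
    return _band_power(ep, fs, 4.0, 8.0)


@register_feature("bandpower_8_12p8")
def _bp_alpha(ep: np.ndarray, fs: float) -> np.ndarray:
    return _band_power(ep, fs, 8.0, 12.8)


@register_feature("spectral_edge_95")
def _sef95(ep: np.ndarray, fs: float) -> np.ndarray:
    """Frequency below which 95 % of the 0.5-12.8 Hz power lies."""
    freqs, pxx = _psd(ep, fs)
    sel = (freqs >= 0.5) & (freqs <= 12.8)
    f = freqs[sel]
    p = pxx[:, sel]
    tot = p.sum(axis=1, keepdims=True)
    out = np.zeros(ep.shape[0])
    nz = tot[:, 0] > 0
    if nz.any():
        csum = np.cumsum(p[nz], axis=1) / tot[nz]
        idx = np.argmax(csum >= 0.95, axis=1)
        out[nz] = f[idx]
    return out


@register_feature("amplitude_entropy")
def _amp_entropy(ep: np.ndarray, fs: float) -> np.ndarray:
    """Shannon entropy (nats) of the 16-bin normalized amplitude histogram."""
    out = np.zeros(ep.shape[0])
    for i, row in enumerate(ep):
        lo, hi = row.min(), row.max()
        if hi - lo < 1e-12:
            continue  # delta distribution: zero entropy
        counts, _ = np.histogram(row, bins=16, range=(lo, hi))
        p = counts / counts.sum()
        p = p[p > 0]
        out[i] = -(p * np.log(p)).sum()
    return out


DEFAULT_FEATURES: tuple[str, ...] = tuple(FEATURE_REGISTRY)


def extract_features(
    epochs: np.ndarray,
    feature_set: Sequence[str] = DEFAULT_FEATURES,
    fs: float = float(ANALYSIS_RATE_HZ),
    channel: str = "",
) -> FeatureMatrix:
    """Compute the named features for every epoch row."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] == 0:
        raise ValueError("extract_features requires at least one epoch")
    unknown = [f for f in feature_set if f not in FEATURE_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown feature(s) {unknown}; registered: {sorted(FEATURE_REGISTRY)}"
        )
    cols = [FEATURE_REGISTRY[name](epochs, fs) for name in feature_set]
    return FeatureMatrix(np.column_stack(cols), tuple(feature_set), channel=channel)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def fit_normalizer(train: FeatureMatrix) -> NormalizationTemplate:
    """Fit the per-feature mean/sd template on training rows only.

    Uses the sample (n-1) standard deviation.  Zero-variance features are
    centered but left unscaled (sd fixed at 1) with a warning.
    """
    X = train.values
    if X.shape[0] < 2:
        raise ValueError("fit_normalizer needs at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd < 1e-12
    if zero.any():
        names = [train.feature_names[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"zero-variance feature(s) {names}: centered but not scaled",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    return NormalizationTemplate(mean, sd, train.feature_names)


def apply_normalizer(template: NormalizationTemplate, features: FeatureMatrix) -> FeatureMatrix:
    """Z-score a feature matrix with a previously fitted template."""
    if features.feature_names != template.feature_names:
        raise ValueError("feature names/order do not match the template")
    return FeatureMatrix(
        (features.values - template.mean) / template.sd,
        features.feature_names,
        channel=features.channel,
    )


def stack_features(mats: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Vertically stack per-channel feature matrices (shared feature set)."""
    if not mats:
        raise ValueError("nothing to stack")
    names = mats[0].feature_names
    if any(m.feature_names != names for m in mats):
        raise ValueError("feature sets differ across matrices")
    return FeatureMatrix(np.vstack([m.values for m in mats]), names)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

def train_detector(
    features: FeatureMatrix,
    labels: np.ndarray,
    C: float = 1.0,
    gamma: float | str = "auto",
    class_weight: str | Mapping | None = "balanced",
    max_train_epochs: int | None = 4000,
    seed: int = 0,
) -> DetectorModel:
    """Train the RBF-SVM epoch classifier with Platt posterior calibration.

    ``gamma="auto"`` is 1/n_features.  Class weighting defaults to inverse
    prevalence because non-seizure epochs dominate real recordings.  When the
    pooled training set exceeds ``max_train_epochs`` rows, a seeded
    stratified subsample caps it (kernel-SVM training is super-linear in n).
    """
    labels = np.asarray(labels).astype(int).ravel()
    X = features.values
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must match feature rows")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(seed)
    if max_train_epochs is not None and X.shape[0] > max_train_epochs:
        keep: list[np.ndarray] = []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            n_cls = max(2, int(round(max_train_epochs * len(idx) / len(labels))))
            keep.append(rng.choice(idx, size=min(n_cls, len(idx)), replace=False))
        sel = np.sort(np.concatenate(keep))
        X, labels = X[sel], labels[sel]

    degenerate = bool(np.allclose(X, X[0]))
    if degenerate:
        warnings.warn(
            "all training feature rows identical; posteriors will track the "
            "class prior",
            RuntimeWarning,
            stacklevel=2,
        )

    template = fit_normalizer(FeatureMatrix(X, features.feature_names))
    Xn = (X - template.mean) / template.sd
    svc = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight)
    min_class = int(np.bincount(labels).min())
    clf = CalibratedClassifierCV(
        svc,
        method="sigmoid",          # Platt calibration on training folds
        cv=min(5, max(2, min_class)),
        ensemble=False,
    )
    clf.fit(Xn, labels)
    return DetectorModel(
        classifier=clf,
        template=template,
        feature_names=features.feature_names,
        hyperparams={
            "C": C,
            "gamma": gamma,
            "class_weight": class_weight,
            "max_train_epochs": max_train_epochs,
            "seed": seed,
        },
        degenerate=degenerate,
    )


def predict_probability_trace(
    model: DetectorModel,
    per_channel_features: Sequence[FeatureMatrix],
    grid: EpochGrid,
    channel_names: Sequence[str] | None = None,
) -> ProbabilityTrace:
    """Score each channel's epochs, returning per-epoch seizure posteriors.

    The model's normalization template (fitted on training data) is applied
    before prediction; test data never updates it.
    """
    rows = []
    for fm in per_channel_features:
        if fm.feature_names != model.feature_names:
            missing = set(model.feature_names) - set(fm.feature_names)
            raise ValueError(
                f"feature mismatch; missing from input: {sorted(missing)}"
                if missing
                else "feature order differs from the model configuration"
            )
        Xn = (fm.values - model.template.mean) / model.template.sd
        pos = list(model.classifier.classes_).index(1)
        rows.append(model.classifier.predict_proba(Xn)[:, pos])
    probs = np.vstack(rows)
    names = tuple(channel_names) if channel_names else tuple(
        fm.channel or f"ch{i}" for i, fm in enumerate(per_channel_features)
    )
    return ProbabilityTrace(probs, grid, names)


def write_features_csv(per_channel: Sequence[FeatureMatrix], path) -> None:
    """Export per-channel feature matrices as long-form CSV.

    Columns: ``epoch_index,channel,feature,value``.
    """
    import pandas as pd

    frames = []
    for k, fm in enumerate(per_channel):
        n_ep, n_ft = fm.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "epoch_index": np.repeat(np.arange(n_ep), n_ft),
                    "channel": fm.channel or f"ch{k}",
                    "feature": np.tile(list(fm.feature_names), n_ep),
                    "value": fm.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_model(model: DetectorModel, path) -> None:
    """Persist classifier + template + feature config to one archive file."""
    joblib.dump(
        {
            "classifier": model.classifier,
            "template": model.template,
            "feature_names": model.feature_names,
            "hyperparams": model.hyperparams,
            "degenerate": model.degenerate,
        },
        path,
    )


def load_model(path) -> DetectorModel:
    blob = joblib.load(path)
    return DetectorModel(
        classifier=blob["classifier"],
        template=blob["template"],
        feature_names=tuple(blob["feature_names"]),
        hyperparams=blob["hyperparams"],
        degenerate=blob.get("degenerate", False),
    )
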