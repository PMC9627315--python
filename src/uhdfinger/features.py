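"""Band-power features: causal band-pass, segment power, centred moving
average, log transform, trailing power-shift compensation, epoching.

Band power is estimated in non-overlapping 0.25 s segments (feature rate
4 Hz), smoothed with a centred 0.75 s moving average (shrinking windows at
the stream edges), and log10-transformed.  The power-shift compensation
subtracts the trailing 25 s mean of the log band power per channel, which
removes slow drifts that would otherwise bias the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .preprocess import _butter_sos
from .synthetic import BASELINE, REST, Recording
from scipy.signal import sosfilt

logger = logging.getLogger(__name__)

__all__ = [
    "BandPowerFeatures",
    "EpochedFeatures",
    "band_power",
    "power_shift_compensation",
    "epoch",
    "centered_moving_average",
    "trailing_mean",
    "concat_bands",
    "concat_epochs",
]

MU_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 25.0)
HIGH_GAMMA_BAND = (70.0, 170.0)  # supported pre-downsampling; off by default


@dataclass
class BandPowerFeatures:
    """Per-channel log10 band power at the feature rate (1 / segment_s)."""

    values: np.ndarray  # (n_channels, n_features)
    feature_fs: float  # Hz
    band: tuple[float, float]
    segment_s: float
    smooth_s: float
    labels: list[str]
    compensation_window_s: float | None = None
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.feature_fs * self.segment_s - 1.0) > 1e-9:
            raise InvalidParameterError("feature_fs must equal 1 / segment_s")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("log band power must be finite")

    @property
    def times(self) -> np.ndarray:
        """Start time (s) of each feature segment."""
        return np.arange(self.values.shape[1]) * self.segment_s


@dataclass
class EpochedFeatures:
    """Cue-aligned feature epochs: trials x channels x epoch samples."""

    tensor: np.ndarray  # (n_trials, n_channels, n_epoch_samples)
    labels: np.ndarray  # (n_trials,) trial_type per trial
    times: np.ndarray  # (n_epoch_samples,) seconds relative to the cue
    feature_fs: float
    channel_labels: list[str]
    band: tuple[tuple[float, float], ...]  # one entry per stacked band

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.tensor.ndim != 3 or self.tensor.shape[0] != len(self.labels):
            raise InvalidParameterError("tensor must be (n_trials, n_channels, n_samples)")
        if self.tensor.shape[2] != len(self.times):
            raise InvalidParameterError("epoch sample count must match the time vector")

    @property
    def n_trials(self) -> int:
        return self.tensor.shape[0]

    def select_classes(self, classes) -> "EpochedFeatures":
        keep = np.isin(self.labels, list(classes))
        return replace(self, tensor=self.tensor[keep], labels=self.labels[keep])

    def select_channels(self, mask: np.ndarray) -> "EpochedFeatures":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            tensor=self.tensor[:, mask, :],
            channel_labels=[l for l, m in zip(self.channel_labels, mask) if m],
        )

    def to_tidy(self) -> pd.DataFrame:
        """Long-format export (trial, channel, time, value, label)."""
        n_t, n_c, n_s = self.tensor.shape
        idx = pd.MultiIndex.from_product(
            [range(n_t), self.channel_labels, self.times], names=["trial", "channel", "time"]
        )
        df = pd.DataFrame({"value": self.tensor.reshape(-1)}, index=idx).reset_index()
        df["label"] = np.repeat(self.labels, n_c * n_s)
        return df


# ---------------------------------------------------------------------------


def centered_moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average along the last axis with shrinking edge windows."""
    if width < 1 or width % 2 == 0:
        raise InvalidParameterError("moving-average width must be a positive odd integer")
    n = x.shape[-1]
    half = width // 2
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    lo = np.clip(np.arange(n) - half, 0, None)
    hi = np.clip(np.arange(n) + half + 1, None, n)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def trailing_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Trailing-inclusive mean along the last axis (shorter at the start)."""
    n = x.shape[-1]
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    idx = np.arange(n)
    lo = np.clip(idx - width + 1, 0, None)
    return (c[..., idx + 1] - c[..., lo]) / (idx - lo + 1)


def band_power(
    recording: Recording,
    band: tuple[float, float],
    segment_s: float = 0.25,
    smooth_s: float = 0.75,
) -> BandPowerFeatures:
    """Log10 band power in non-overlapping segments with centred smoothing."""
    low, high = band
    nyq = recording.fs / 2.0
    if not (0 < low < high < nyq):
        raise InvalidParameterError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    width = smooth_s / segment_s
    if abs(width - round(width)) > 1e-9 or int(round(width)) % 2 == 0:
        raise InvalidParameterError("smooth_s must be an odd multiple of segment_s")

    sos = _butter_sos(4, band, "bandpass", recording.fs)
    p = sosfilt(sos, recording.data, axis=-1) ** 2
    seg = int(round(segment_s * recording.fs))
    n_seg = p.shape[-1] // seg
    p = p[:, : n_seg * seg].reshape(p.shape[0], n_seg, seg).mean(axis=-1)
    p = centered_moving_average(p, int(round(width)))
    return BandPowerFeatures(
        values=np.log10(p),
        feature_fs=1.0 / segment_s,
        band=(float(low), float(high)),
        segment_s=segment_s,
        smooth_s=smooth_s,
        labels=list(recording.labels),
        processing=("bandpass", "square", "segment-mean", "moving-average", "log10"),
    )


def power_shift_compensation(
    features: BandPowerFeatures, window_s: float = 25.0
) -> BandPowerFeatures:
    """Subtract the trailing ``window_s`` mean of log band power, per channel."""
    if window_s < features.segment_s:
        raise InvalidParameterError("compensation window must cover at least one segment")
    width = int(round(window_s * features.feature_fs))
    values = features.values - trailing_mean(features.values, width)
    return replace(
        features,
        values=values,
        compensation_window_s=window_s,
        processing=features.processing + ("power-shift-compensation",),
    )


def epoch(
    features: BandPowerFeatures,
    events: pd.DataFrame,
    pre_s: float = 0.5,
    post_s: float = 7.0,
    task_types=None,
) -> EpochedFeatures:
    """Cut cue-aligned epochs from the feature stream.

    The cue is mapped to the last feature-segment boundary at or before its
    onset, keeping the pre-cue reference strictly pre-cue.  Trials too close
    to the stream boundary are dropped with a logged warning.
    """
    ffs = features.feature_fs
    n_pre = int(round(pre_s * ffs))
    n_post = int(round(post_s * ffs))
    if task_types is None:
        task = events[~events["trial_type"].isin([REST, BASELINE])]
    else:
        task = events[events["trial_type"].isin(task_types)]

    n_feat = features.values.shape[1]
    epochs, labels, dropped = [], [], 0
    for _, ev in task.iterrows():
        cue = int(np.floor(float(ev["onset"]) * ffs))
        lo, hi = cue - n_pre, cue + n_post
        if lo < 0 or hi > n_feat:
            dropped += 1
            continue
        epochs.append(features.values[:, lo:hi])
        labels.append(str(ev["trial_type"]))
    if dropped:
        logger.warning("dropped %d trial(s) too close to the stream boundary", dropped)
    tensor = (
        np.stack(epochs)
        if epochs
        else np.empty((0, features.values.shape[0], n_pre + n_post))
    )
    times = (np.arange(n_pre + n_post) - n_pre) / ffs
    return EpochedFeatures(
        tensor=tensor,
        labels=np.asarray(labels, dtype=object),
        times=times,
        feature_fs=ffs,
        channel_labels=list(features.labels),
        band=(features.band,),
    )


def concat_bands(parts: list[EpochedFeatures]) -> EpochedFeatures:
    """Stack per-band epochs along the channel axis (features per channel x band)."""
    first = parts[0]
    for p in parts[1:]:
        if p.n_trials != first.n_trials or not np.array_equal(p.labels, first.labels):
            raise InvalidParameterError("band epochs must share the same trials")
        if not np.array_equal(p.times, first.times):
            raise InvalidParameterError("band epochs must share the same time grid")
    tensor = np.concatenate([p.tensor for p in parts], axis=1)
    chans = [
        f"{lab}@{p.band[0][0]:g}-{p.band[0][1]:g}Hz" for p in parts for lab in p.channel_labels
    ]
    return EpochedFeatures(
        tensor=tensor,
        labels=first.labels.copy(),
        times=first.times.copy(),
        feature_fs=first.feature_fs,
        channel_labels=chans,
        band=tuple(b for p in parts for b in p.band),
    )


def concat_epochs(parts: list[EpochedFeatures]) -> EpochedFeatures:
    """Concatenate epochs across runs (same channels and time grid)."""
    first = parts[0]
    for p in parts[1:]:
        if p.channel_labels != first.channel_labels or not np.array_equal(p.times, first.times):
            raise InvalidParameterError("run epochs must share channels and time grid")
    return replace(
        first,
        tensor=np.concatenate([p.tensor for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
    )
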