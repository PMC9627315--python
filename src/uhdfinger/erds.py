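"""Event-related desynchronization/synchronization analysis.

ERD/S of the average trial is the log band power minus its mean over a
pre-cue reference window, reported in dB (10 x log10 units).  The module
also provides the scalp heatmap interpolation with a linear-decay kernel,
the focal-electrode selection rule (greatest desynchronization beyond the
2.5th percentile), and short-time-Fourier-transform time-frequency maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as _ndzoom
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hamming
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import InvalidParameterError
from .features import EpochedFeatures
from .montage import Montage
from .synthetic import BASELINE, REST, Recording

__all__ = [
    "ERDSMap",
    "SurfaceHeatmap",
    "TimeFrequencyERDS",
    "compute_erds",
    "erds_by_class",
    "focal_selection",
    "nearest_rank_threshold",
    "heatmap",
    "hemisphere_vertices",
    "time_frequency_erds",
]


@dataclass
class ERDSMap:
    """Average-trial ERD/S (dB) per channel and epoch sample."""

    values: np.ndarray  # (n_channels, n_epoch_samples) dB
    times: np.ndarray  # seconds relative to cue
    reference_window_s: tuple[float, float]
    band: tuple[float, float] | tuple
    channel_labels: list[str]
    n_trials: int = 0

    def mean_in_window(self, window_s: tuple[float, float]) -> np.ndarray:
        """Per-channel mean ERD/S over a time window [start, end)."""
        lo, hi = window_s
        sel = (self.times >= lo) & (self.times < hi)
        if not sel.any():
            raise InvalidParameterError(f"window {window_s} contains no epoch samples")
        return self.values[:, sel].mean(axis=1)


@dataclass
class SurfaceHeatmap:
    """Scalp-surface activation interpolated from electrode values."""

    vertices: np.ndarray  # (m, 3)
    activation: np.ndarray  # (m,)
    kernel_radii: np.ndarray  # per included electrode (mm)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            np.column_stack([self.vertices, self.activation]),
            columns=["x", "y", "z", "value"],
        ).to_csv(path, index=False)


def compute_erds(
    epochs: EpochedFeatures, reference_window_s: tuple[float, float] = (-0.5, 0.0)
) -> ERDSMap:
    """ERD/S of the average trial relative to a pre-cue reference window.

    The log band power is averaged over trials, the per-channel mean over
    the reference samples is subtracted, and the result is scaled to dB
    (factor 10 on log10 features).
    """
    if epochs.n_trials < 1:
        raise InvalidParameterError("need at least one trial")
    lo, hi = reference_window_s
    ref = (epochs.times >= lo) & (epochs.times < hi)
    if not ref.any():
        raise InvalidParameterError("reference window contains no epoch samples")
    mean_log = epochs.tensor.mean(axis=0)  # channels x time
    values = 10.0 * (mean_log - mean_log[:, ref].mean(axis=1, keepdims=True))
    return ERDSMap(
        values=values,
        times=epochs.times.copy(),
        reference_window_s=reference_window_s,
        band=epochs.band[0] if len(epochs.band) == 1 else epochs.band,
        channel_labels=list(epochs.channel_labels),
        n_trials=epochs.n_trials,
    )


def erds_by_class(
    epochs: EpochedFeatures, reference_window_s: tuple[float, float] = (-0.5, 0.0)
) -> dict[str, ERDSMap]:
    """One average-trial ERD/S map per trial class (finger)."""
    return {
        str(c): compute_erds(epochs.select_classes([c]), reference_window_s)
        for c in np.unique(epochs.labels)
    }


def nearest_rank_threshold(values: np.ndarray, percentile: float) -> tuple[float, int]:
    """Nearest-rank lower-percentile threshold.

    Returns ``(threshold, k)`` where ``k = floor(percentile/100 * n)`` and
    the threshold is the (k+1)-th smallest value; selecting strictly below
    it keeps exactly k electrodes on tie-free inputs.
    """
    n = len(values)
    k = int(np.floor(percentile / 100.0 * n))
    srt = np.sort(values)
    thr = srt[min(k, n - 1)]
    return float(thr), k


def focal_selection(
    erds: "ERDSMap | dict[str, ERDSMap]",
    window_s: tuple[float, float] = (1.0, 2.0),
    percentile: float = 2.5,
):
    """Electrodes with greater desynchronization than (100 - percentile)% of all.

    The mean ERD/S over ``window_s`` is thresholded at the ``percentile``-th
    nearest-rank quantile; electrodes strictly below it are selected (~6 of
    256 at 2.5%).  Accepts one map or a per-finger dict of maps.
    """
    if isinstance(erds, dict):
        return {f: focal_selection(m, window_s, percentile) for f, m in erds.items()}
    if not (0.0 < percentile < 100.0):
        raise InvalidParameterError("percentile must lie strictly between 0 and 100")
    means = erds.mean_in_window(window_s)
    thr, _ = nearest_rank_threshold(means, percentile)
    return np.flatnonzero(means < thr)


# ---------------------------------------------------------------------------
# scalp heatmaps


def heatmap(
    activation: np.ndarray,
    montage: Montage,
    vertices: np.ndarray,
    bad: np.ndarray | None = None,
    bad_mode: str = "exclude",
) -> SurfaceHeatmap:
    """Interpolate electrode activation onto surface vertices.

    Each electrode spreads its value with a linear-decay kernel that is 1 at
    the electrode and reaches 0 at the Euclidean distance to its closest
    (included) electrode; vertex values are the sum over electrodes.  Bad
    channels are excluded by default; ``bad_mode="zero"`` instead keeps them
    with activation forced to 0 (figure-compatibility behaviour).
    """
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    if len(vertices) == 0:
        raise InvalidParameterError("vertex set must not be empty")
    activation = np.asarray(activation, dtype=float)
    if bad is None:
        bad = np.zeros(montage.n_channels, dtype=bool)
    bad = np.asarray(bad, dtype=bool)

    if bad_mode == "exclude":
        include = ~bad
    elif bad_mode == "zero":
        include = np.ones(montage.n_channels, dtype=bool)
        activation = np.where(bad, 0.0, activation)
    else:
        raise InvalidParameterError(f"unknown bad_mode {bad_mode!r}")

    pos = montage.positions[include]
    act = activation[include]
    if len(pos) == 0:
        return SurfaceHeatmap(vertices, np.zeros(len(vertices)), np.empty(0))
    if len(pos) == 1:
        # no closest electrode to define the kernel radius; fall back to pitch
        radii = np.array([montage.pitch])
    else:
        d_ee = squareform(pdist(pos))
        np.fill_diagonal(d_ee, np.inf)
        radii = d_ee.min(axis=1)
    d = cdist(vertices, pos)
    w = np.clip(1.0 - d / radii[None, :], 0.0, None)
    out = w @ act
    return SurfaceHeatmap(vertices, out, radii)


def hemisphere_vertices(radius_mm: float = 90.0, n: int = 2000) -> np.ndarray:
    """Quasi-uniform vertex set on the upper hemisphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere only
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z * z)
    return radius_mm * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ---------------------------------------------------------------------------
# time-frequency maps


@dataclass
class TimeFrequencyERDS:
    """Average-trial ERD/S image over frequency x epoch time."""

    values: np.ndarray  # (n_freqs, n_times) dB
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s relative to cue
    frame_rate: float  # Hz
    n_trials: int

    def interpolated(self, factor: int = 10) -> "TimeFrequencyERDS":
        """Bicubic up-sampling in both axes (display refinement)."""
        values = _ndzoom(self.values, factor, order=3)
        freqs = np.linspace(self.freqs[0], self.freqs[-1], values.shape[0])
        times = np.linspace(self.times[0], self.times[-1], values.shape[1])
        return TimeFrequencyERDS(values, freqs, times, self.frame_rate * factor, self.n_trials)


def time_frequency_erds(
    recording: Recording,
    channel: int,
    f_range: tuple[float, float] = (8.0, 30.0),
    window_s: float = 1.0,
    overlap_s: float = 0.95,
    pre_s: float = 1.0,
    post_s: float = 7.0,
    reference_window_s: tuple[float, float] = (-1.0, 0.0),
    task_types=None,
) -> TimeFrequencyERDS:
    """STFT time-frequency ERD/S for one channel.

    Power is estimated with a Hamming window (1 s, 0.95 s overlap: 20 Hz
    frame rate, 1 Hz bins), log10-transformed, epoched around the cues,
    averaged over trials and referenced to the pre-cue window, in dB.
    """
    fs = recording.fs
    nperseg = int(round(window_s * fs))
    if nperseg > recording.n_samples:
        raise InvalidParameterError("STFT window is longer than the recording")
    hop = nperseg - int(round(overlap_s * fs))
    if hop < 1:
        raise InvalidParameterError("overlap must be smaller than the window")
    frame_rate = fs / hop

    stft = ShortTimeFFT(hamming(nperseg, sym=False), hop=hop, fs=fs, scale_to="psd")
    spec = stft.spectrogram(recording.data[channel])
    t = stft.t(recording.n_samples)
    fsel = (stft.f >= f_range[0]) & (stft.f <= f_range[1])
    logp = np.log10(np.clip(spec[fsel], 1e-300, None))

    if task_types is None:
        task = recording.events[~recording.events["trial_type"].isin([REST, BASELINE])]
    else:
        task = recording.events[recording.events["trial_type"].isin(task_types)]
    n_pre = int(round(pre_s * frame_rate))
    n_post = int(round(post_s * frame_rate))
    epochs = []
    for _, ev in task.iterrows():
        cue = int(np.searchsorted(t, float(ev["onset"]), side="right")) - 1
        lo, hi = cue - n_pre, cue + n_post
        if lo < 0 or hi > logp.shape[1]:
            continue
        epochs.append(logp[:, lo:hi])
    if not epochs:
        raise InvalidParameterError("no complete trials for the time-frequency map")
    mean_log = np.mean(epochs, axis=0)
    times = (np.arange(n_pre + n_post) - n_pre) / frame_rate
    ref = (times >= reference_window_s[0]) & (times < reference_window_s[1])
    values = 10.0 * (mean_log - mean_log[:, ref].mean(axis=1, keepdims=True))
    return TimeFrequencyERDS(
        values=values,
        freqs=stft.f[fsel],
        times=times,
        frame_rate=frame_rate,
        n_trials=len(epochs),
    )
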