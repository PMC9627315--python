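"""Preprocessing: resampling, line-noise notch cascade, statistical
bad-channel/bad-run identification, and common-average referencing.

All filters are 4th-order Butterworth applied causally (forward only), so
that — apart from the offline bad-channel statistics and the centred moving
average downstream — the pipeline remains usable in a real-time setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfilt

from .errors import DegenerateDataError, InvalidParameterError
from .synthetic import BASELINE, REST, Recording

__all__ = [
    "BadChannelReport",
    "resample",
    "notch_cascade",
    "identify_bad",
    "apply_car",
    "bandpass",
]


@dataclass
class BadChannelReport:
    """Per-run log-band-power z-scores and the resulting bad channel/run flags."""

    z_scores: np.ndarray  # (n_runs, n_channels)
    bad_channels: np.ndarray  # (n_channels,) bool, disjunction over retained runs
    bad_runs: np.ndarray  # (n_runs,) bool
    threshold_z: float
    run_fraction_threshold: float
    labels: list[str]

    @property
    def n_bad_channels(self) -> int:
        return int(self.bad_channels.sum())

    def to_dict(self) -> dict:
        return {
            "threshold_z": self.threshold_z,
            "run_fraction_threshold": self.run_fraction_threshold,
            "bad_channels": [self.labels[i] for i in np.flatnonzero(self.bad_channels)],
            "bad_runs": np.flatnonzero(self.bad_runs).tolist(),
            "z_scores": self.z_scores.round(4).tolist(),
        }


def _butter_sos(order: int, band, btype: str, fs: float):
    # design order follows the MATLAB butter convention the reference
    # pipeline uses: an order-4 band filter has 4 poles per band edge
    return butter(order, band, btype=btype, fs=fs, output="sos")


def bandpass(recording: Recording, band: tuple[float, float], order: int = 4) -> Recording:
    """Causal Butterworth band-pass of the given order."""
    low, high = band
    nyq = recording.fs / 2.0
    if not (0 < low < high < nyq):
        raise InvalidParameterError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    sos = _butter_sos(order, band, "bandpass", recording.fs)
    return Recording(sosfilt(sos, recording.data, axis=-1), recording.fs, list(recording.labels), recording.events.copy())


def resample(recording: Recording, fs_out: float) -> Recording:
    """Anti-aliased polyphase down-sampling; event onsets stay in seconds."""
    if fs_out >= recording.fs:
        raise InvalidParameterError("fs_out must be smaller than the input rate")
    frac = Fraction(fs_out / recording.fs).limit_denominator(1000)
    data = resample_poly(recording.data, frac.numerator, frac.denominator, axis=-1)
    expected = int(round(recording.n_samples * fs_out / recording.fs))
    data = data[:, :expected] if data.shape[1] >= expected else data
    return Recording(data, fs_out, list(recording.labels), recording.events.copy())


def notch_cascade(recording: Recording, base_hz: float = 60.0, width_hz: float = 4.0) -> Recording:
    """Cascade of 4th-order Butterworth band-stops at ``base_hz`` and every
    harmonic strictly below Nyquist."""
    nyq = recording.fs / 2.0
    if base_hz >= nyq:
        raise InvalidParameterError("notch base frequency must be below Nyquist")
    data = recording.data
    for f0 in notch_frequencies(recording.fs, base_hz):
        sos = _butter_sos(4, (f0 - width_hz / 2, f0 + width_hz / 2), "bandstop", recording.fs)
        data = sosfilt(sos, data, axis=-1)
    return Recording(data, recording.fs, list(recording.labels), recording.events.copy())


def notch_frequencies(fs: float, base_hz: float) -> list[float]:
    """Line-noise harmonics strictly below Nyquist."""
    nyq = fs / 2.0
    return [k * base_hz for k in range(1, int(np.ceil(nyq / base_hz)) + 1) if k * base_hz < nyq]


def _task_mask(recording: Recording, task_types=None) -> np.ndarray:
    """Boolean sample mask covering the task periods of the event table."""
    if task_types is None:
        task = recording.events[~recording.events["trial_type"].isin([REST, BASELINE])]
    else:
        task = recording.events[recording.events["trial_type"].isin(task_types)]
    mask = np.zeros(recording.n_samples, dtype=bool)
    for _, ev in task.iterrows():
        i0 = int(np.floor(ev["onset"] * recording.fs))
        i1 = int(np.ceil((ev["onset"] + ev["duration"]) * recording.fs))
        mask[i0 : min(i1, recording.n_samples)] = True
    return mask


def identify_bad(
    recordings_by_run: list[Recording],
    band: tuple[float, float] = (8.0, 25.0),
    threshold_z: float = 6.0,
    run_fraction: float = 0.1,
    task_types=None,
) -> BadChannelReport:
    """Statistical bad-channel and bad-run identification (report only).

    Per run: common-average reference, 8-25 Hz band-pass, restriction to the
    task periods, per-channel mean power, log10 transform, z-transform across
    channels.  Channels with z above ``threshold_z`` are bad; runs where the
    bad fraction exceeds ``run_fraction`` are bad; a channel bad in any
    retained run is bad in all runs.  Input recordings are not modified.
    """
    if not recordings_by_run:
        raise InvalidParameterError("need at least one run")
    n_ch = recordings_by_run[0].n_channels
    if n_ch < 2:
        raise InvalidParameterError("need at least two channels")

    z_rows = []
    for rec in recordings_by_run:
        mask = _task_mask(rec, task_types)
        if not mask.any():
            raise InvalidParameterError("task windows are empty for one run")
        x = rec.data - rec.data.mean(axis=0, keepdims=True)  # CAR
        sos = _butter_sos(4, band, "bandpass", rec.fs)
        x = sosfilt(sos, x, axis=-1)[:, mask]
        x = x - x.mean(axis=-1, keepdims=True)
        logp = np.log10(np.mean(x * x, axis=-1))
        z_rows.append((logp - logp.mean()) / logp.std())
    z = np.vstack(z_rows)

    flagged = z > threshold_z
    bad_runs = flagged.mean(axis=1) > run_fraction
    retained = ~bad_runs
    if retained.any():
        bad_channels = flagged[retained].any(axis=0)
    else:
        bad_channels = flagged.any(axis=0)
    if bad_channels.all():
        raise DegenerateDataError("all channels flagged bad")
    return BadChannelReport(
        z_scores=z,
        bad_channels=bad_channels,
        bad_runs=bad_runs,
        threshold_z=threshold_z,
        run_fraction_threshold=run_fraction,
        labels=list(recordings_by_run[0].labels),
    )


def apply_car(recording: Recording, exclude: np.ndarray | None = None) -> Recording:
    """Common-average reference; excluded (bad) channels are dropped.

    At each sample the mean over the included channels is subtracted from
    the included channels, which form the output recording.
    """
    if exclude is None:
        exclude = np.zeros(recording.n_channels, dtype=bool)
    exclude = np.asarray(exclude, dtype=bool)
    include = ~exclude
    if include.sum() < 2:
        raise InvalidParameterError("common average reference needs at least two channels")
    data = recording.data[include]
    data = data - data.mean(axis=0, keepdims=True)
    labels = [l for l, m in zip(recording.labels, include) if m]
    return Recording(data, recording.fs, labels, recording.events.copy())
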