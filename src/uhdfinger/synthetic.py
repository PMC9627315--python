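"""Synthetic ultra-high-density EEG with cued single-finger extensions.

The generator emulates the statistical structure the downstream analysis
relies on, not a biophysical forward model: amplitude-modulated band-limited
mu (8-12 Hz) and beta (13-25 Hz) oscillators at finger-specific cortical
sites, mixed into the channels with a linear distance-decay profile, on top
of per-channel pink noise, spatially mixed pink background sources (a
surrogate for volume conduction, giving neighbouring electrodes their
distance-dependent correlation), a shared power-line sinusoid, a slow
multiplicative band-power drift, and optional injected bad channels.

Event-related desynchronization is realized as a multiplicative amplitude
scale ``a = 10**(ERD_dB / 20)`` on the oscillator inside the task window
(0.25 s raised-cosine ramps), so band power changes by exactly the stated
dB in expectation; the beta rebound and the late mu synchronization are the
same mechanism with positive dB.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, sosfilt

from .errors import InvalidEventError, InvalidParameterError
from .montage import Montage, _Projection, edge_channels

__all__ = [
    "FINGERS",
    "Paradigm",
    "FingerEffect",
    "NoiseSpec",
    "EffectSpec",
    "Recording",
    "generate_paradigm",
    "synthesize_recording",
    "simulate_dataset",
    "default_finger_effects",
    "preset",
    "write_events",
    "read_events",
]

FINGERS = ("thumb", "index", "middle", "ring", "little")

BASELINE = "baseline"
REST = "rest"


@dataclass
class Paradigm:
    """Cued finger-extension protocol: 10 runs of 5 x 5 pseudo-random trials."""

    runs: int = 10
    trials_per_finger_per_run: int = 5
    rest_range_s: tuple[float, float] = (3.0, 4.0)
    task_s: float = 5.0
    baseline_s: float = 30.0
    fingers: tuple[str, ...] = FINGERS

    def __post_init__(self) -> None:
        lo, hi = self.rest_range_s
        if not (0 < lo <= hi):
            raise InvalidParameterError("rest_range_s must satisfy 0 < min <= max")
        if self.task_s <= 0 or self.baseline_s < 0:
            raise InvalidParameterError("task_s must be positive and baseline_s non-negative")
        if self.runs < 1 or self.trials_per_finger_per_run < 0:
            raise InvalidParameterError("runs must be >= 1 and trial count non-negative")

    @property
    def trials_per_run(self) -> int:
        return len(self.fingers) * self.trials_per_finger_per_run


@dataclass
class FingerEffect:
    """Source geometry and ERD/ERS dynamics for one finger.

    Windows are in seconds relative to the cue; depths are dB changes of
    band power (ERD negative, ERS/rebound positive).
    """

    center_channel: int
    radius_mm: float = 15.0
    mu_amp_uv: float = 10.0
    beta_amp_uv: float = 8.0
    mu_erd_db: float = -3.0
    mu_erd_window_s: tuple[float, float] = (0.5, 2.5)
    mu_ers_db: float = 1.5
    mu_ers_window_s: tuple[float, float] = (3.5, 5.0)
    beta_erd_db: float = -3.0
    beta_erd_window_s: tuple[float, float] = (0.5, 5.0)
    beta_ers_db: float = 2.0
    beta_ers_window_s: tuple[float, float] = (6.0, 7.0)
    ramp_s: float = 0.25

    def __post_init__(self) -> None:
        if self.mu_erd_db > 0 or self.beta_erd_db > 0:
            raise InvalidParameterError("ERD depths must be <= 0 dB")
        if self.mu_ers_db < 0 or self.beta_ers_db < 0:
            raise InvalidParameterError("ERS magnitudes must be >= 0 dB")
        if self.radius_mm <= 0:
            raise InvalidParameterError("spatial decay radius must be positive")


@dataclass
class NoiseSpec:
    """Background model: pink noise, spatial background sources, line, drift."""

    pink_amp_uv: float = 5.0
    line_amp_uv: float = 5.0
    line_freq_hz: float = 60.0
    drift_sigma_db: float = 0.5
    drift_tau_s: float = 60.0
    n_background_sources: int = 40
    background_amp_uv: float = 8.0
    background_radius_range_mm: tuple[float, float] = (40.0, 150.0)


@dataclass
class EffectSpec:
    """Full signal model: per-finger effects, noise, injected bad channels."""

    fingers: dict[str, FingerEffect]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    bad_channels: dict[int, float] = field(default_factory=dict)  # index -> gain

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fingers = {k: FingerEffect(**v) for k, v in raw["fingers"].items()}
        noise = NoiseSpec(**raw.get("noise", {}))
        bad = {int(k): float(v) for k, v in raw.get("bad_channels", {}).items()}
        return cls(fingers=fingers, noise=noise, bad_channels=bad)


@dataclass
class Recording:
    """Channels x samples EEG (microvolts) with its event table."""

    data: np.ndarray  # (n_channels, n_samples) uV
    fs: float  # Hz
    labels: list[str]
    events: pd.DataFrame  # columns onset, duration, trial_type

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise InvalidParameterError("data must be (n_channels, n_samples) matching labels")
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if len(self.events) and self.events["onset"].max() > self.duration_s:
            raise InvalidParameterError("event onsets must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.labels), self.events.copy())

    # -- container io -------------------------------------------------------

    def save_npz(self, path: str | Path) -> None:
        """Native uncompressed container: signal, rate, labels and events."""
        np.savez(
            path,
            data=self.data,
            fs=np.array([self.fs]),
            labels=np.array(self.labels),
            events=np.array([self.events.to_json(orient="split")]),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "Recording":
        with np.load(path, allow_pickle=False) as z:
            events = pd.read_json(__import__("io").StringIO(str(z["events"][0])), orient="split")
            return cls(
                data=z["data"],
                fs=float(z["fs"][0]),
                labels=[str(l) for l in z["labels"]],
                events=events,
            )

    def to_mne(self):
        """Convert to an :class:`mne.io.RawArray` (data in volts, annotated events)."""
        import mne

        info = mne.create_info(list(self.labels), self.fs, ch_types="eeg")
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="error")
        if len(self.events):
            raw.set_annotations(
                mne.Annotations(
                    onset=self.events["onset"].to_numpy(float),
                    duration=self.events["duration"].to_numpy(float),
                    description=self.events["trial_type"].tolist(),
                )
            )
        return raw

    @classmethod
    def from_edf(cls, path: str | Path, events: pd.DataFrame | None = None) -> "Recording":
        """Read a European Data Format recording (microvolt scaling applied)."""
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if events is None:
            ann = raw.annotations
            events = pd.DataFrame(
                {"onset": ann.onset, "duration": ann.duration, "trial_type": ann.description}
            )
        return cls(raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names), events)


# ---------------------------------------------------------------------------
# paradigm


def generate_paradigm(paradigm: Paradigm, seed: int) -> pd.DataFrame:
    """Event tables for every run of the protocol.

    Each run starts with a baseline event, then alternates rest (uniform in
    ``rest_range_s``) and task (``task_s``) events; the cue order is a seeded
    permutation containing each finger exactly ``trials_per_finger_per_run``
    times.  Returns a frame with columns run, onset, duration, trial_type
    (onsets relative to the run start).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(paradigm.runs):
        cues = np.repeat(paradigm.fingers, paradigm.trials_per_finger_per_run)
        cues = rng.permutation(cues)
        t = 0.0
        rows.append((run, t, paradigm.baseline_s, BASELINE))
        t += paradigm.baseline_s
        for cue in cues:
            rest = rng.uniform(*paradigm.rest_range_s)
            rows.append((run, t, rest, REST))
            t += rest
            rows.append((run, t, paradigm.task_s, str(cue)))
            t += paradigm.task_s
    return pd.DataFrame(rows, columns=["run", "onset", "duration", "trial_type"])


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write a BIDS-style events.tsv (onset, duration, trial_type)."""
    events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# signal synthesis


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float) -> np.ndarray:
    """Unit-variance pink (1/f amplitude-spectrum) noise, channel-wise."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n=n_samp, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_oscillator(
    rng: np.random.Generator, n_samp: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance band-limited noise oscillator."""
    sos = butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n_samp))
    return x / x.std()


def _apply_window_gain(
    env: np.ndarray, fs: float, t0: float, t1: float, gain: float, ramp_s: float
) -> None:
    """Multiply ``env`` by a plateau of ``gain`` over [t0, t1] with cosine ramps."""
    n = env.shape[-1]
    t = np.arange(n) / fs
    s = np.zeros(n)
    ramp = max(ramp_s, 1.0 / fs)
    up = (t >= t0) & (t < t0 + ramp)
    s[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / ramp))
    s[(t >= t0 + ramp) & (t <= t1 - ramp)] = 1.0
    down = (t > t1 - ramp) & (t <= t1)
    s[down] = 0.5 * (1 - np.cos(np.pi * (t1 - t[down]) / ramp))
    env *= 1.0 + (gain - 1.0) * s


def _ou_process(
    rng: np.random.Generator, n: int, dt: float, tau: float, sigma: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples (autocorrelation time ``tau``)."""
    x = np.empty(n)
    a = np.exp(-dt / tau)
    x[0] = sigma * rng.standard_normal()
    innov = sigma * np.sqrt(1 - a * a) * rng.standard_normal(n - 1) if n > 1 else []
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i - 1]
    return x


def synthesize_recording(
    montage: Montage,
    events: pd.DataFrame,
    effects: EffectSpec,
    fs: float = 600.0,
    seed: int = 0,
    tail_s: float = 3.0,
) -> Recording:
    """Synthesize one continuous run for the given event table.

    Deterministic given (montage, events, effects, fs, seed).  Events must
    use trial types from the finger labels of ``effects`` plus rest and
    baseline.
    """
    if fs < 200:
        raise InvalidParameterError("sampling rate must be at least 200 Hz")
    if len(events) == 0:
        raise InvalidParameterError("event table must not be empty")
    known = set(effects.fingers) | {REST, BASELINE}
    unknown = set(events["trial_type"].astype(str)) - known
    if unknown:
        raise InvalidEventError(f"unknown trial types {sorted(unknown)}")

    duration = float((events["onset"] + events["duration"]).max()) + tail_s
    n_samp = int(round(duration * fs))
    n_ch = montage.n_channels
    rng = np.random.default_rng(seed)
    noise = effects.noise

    data = noise.pink_amp_uv * _pink_noise(rng, n_ch, n_samp, fs)

    # spatially mixed pink background sources: volume-conduction surrogate.
    # A mixture of decay radii gives neighbouring electrodes the broad,
    # distance-dependent correlation profile real scalp EEG shows.
    if noise.n_background_sources > 0 and noise.background_amp_uv > 0:
        n_src = noise.n_background_sources
        centers = montage.positions[rng.integers(0, n_ch, size=n_src)] + rng.normal(
            scale=2.0, size=(n_src, 3)
        )
        radii = rng.uniform(*noise.background_radius_range_mm, size=n_src)
        from scipy.spatial.distance import cdist

        w = np.clip(1.0 - cdist(montage.positions, centers) / radii, 0.0, None)
        bg = _pink_noise(rng, n_src, n_samp, fs)
        data += noise.background_amp_uv * (w @ bg)

    # finger-specific oscillatory sources with task modulation
    task = events[~events["trial_type"].isin([REST, BASELINE])]
    for finger, eff in effects.fingers.items():
        d = np.linalg.norm(montage.positions - montage.positions[eff.center_channel], axis=1)
        w = np.clip(1.0 - d / eff.radius_mm, 0.0, None)
        mu = eff.mu_amp_uv * _band_oscillator(rng, n_samp, fs, (8.0, 12.0))
        beta = eff.beta_amp_uv * _band_oscillator(rng, n_samp, fs, (13.0, 25.0))
        env_mu = np.ones(n_samp)
        env_beta = np.ones(n_samp)
        for _, ev in task[task["trial_type"] == finger].iterrows():
            o = float(ev["onset"])
            for (w0, w1), db in (
                (eff.mu_erd_window_s, eff.mu_erd_db),
                (eff.mu_ers_window_s, eff.mu_ers_db),
            ):
                if db != 0.0:
                    _apply_window_gain(env_mu, fs, o + w0, o + w1, 10 ** (db / 20), eff.ramp_s)
            for (w0, w1), db in (
                (eff.beta_erd_window_s, eff.beta_erd_db),
                (eff.beta_ers_window_s, eff.beta_ers_db),
            ):
                if db != 0.0:
                    _apply_window_gain(env_beta, fs, o + w0, o + w1, 10 ** (db / 20), eff.ramp_s)
        data += np.outer(w, mu * env_mu + beta * env_beta)

    # slow multiplicative band-power drift (log-power OU, per channel)
    if noise.drift_sigma_db > 0:
        n_ctrl = max(int(np.ceil(duration)) + 2, 4)
        t_ctrl = np.arange(n_ctrl, dtype=float)
        t_samp = np.arange(n_samp) / fs
        for i in range(n_ch):
            db = _ou_process(rng, n_ctrl, 1.0, noise.drift_tau_s, noise.drift_sigma_db)
            data[i] *= 10 ** (np.interp(t_samp, t_ctrl, db) / 20.0)

    if noise.line_amp_uv > 0:
        t = np.arange(n_samp) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += noise.line_amp_uv * np.sin(2 * np.pi * noise.line_freq_hz * t + phase)

    for idx, gain in effects.bad_channels.items():
        data[idx] = gain * noise.pink_amp_uv * rng.standard_normal(n_samp)

    return Recording(
        data=data,
        fs=fs,
        labels=list(montage.labels),
        events=events[["onset", "duration", "trial_type"]].reset_index(drop=True),
    )


def simulate_dataset(
    montage: Montage,
    paradigm: Paradigm,
    effects: EffectSpec,
    fs: float = 600.0,
    seed: int = 0,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate the full multi-run dataset: one Recording per run.

    Run-level seeds are spawned from ``seed``, so recordings are mutually
    independent but jointly reproducible.
    """
    events = generate_paradigm(paradigm, seed)
    child = np.random.SeedSequence(seed).spawn(paradigm.runs)
    recordings = []
    for run in range(paradigm.runs):
        ev = events[events["run"] == run].drop(columns="run").reset_index(drop=True)
        run_seed = int(child[run].generate_state(1)[0] % (2**31))
        recordings.append(synthesize_recording(montage, ev, effects, fs=fs, seed=run_seed))
    return recordings, events


# ---------------------------------------------------------------------------
# default effects and presets


def default_finger_effects(
    montage: Montage,
    erd_db: float = -3.0,
    radius_mm: float = 15.0,
    spacing_factor: float = 2.0,
    fingers: tuple[str, ...] = FINGERS,
    **finger_kwargs,
) -> dict[str, FingerEffect]:
    """Place one source per finger on interior electrodes along a line.

    Centres are the interior electrodes closest to equally spaced points
    (``spacing_factor`` x pitch apart) through the patch centre, mimicking
    the somatotopic strip of the hand area.
    """
    proj = _Projection(montage.positions)
    uv = proj.forward(montage.positions)
    interior = np.flatnonzero(~edge_channels(montage))
    if len(interior) < len(fingers):  # tiny montages: fall back to all electrodes
        interior = np.arange(montage.n_channels)
    n_f = len(fingers)
    offsets = (np.arange(n_f) - (n_f - 1) / 2) * spacing_factor * montage.pitch
    out = {}
    used: set[int] = set()
    for finger, off in zip(fingers, offsets):
        target = np.array([off, 0.0])
        order = interior[np.argsort(np.linalg.norm(uv[interior] - target, axis=1))]
        center = next(int(c) for c in order if int(c) not in used)
        used.add(center)
        out[finger] = FingerEffect(
            center_channel=center,
            radius_mm=radius_mm,
            mu_erd_db=erd_db,
            beta_erd_db=erd_db,
            **finger_kwargs,
        )
    return out


def preset(name: str):
    """Named desk-scale study conditions.

    ``demo``   4 grids (64 ch), 3 runs, -3 dB ERD: the default worked example.
    ``strong`` 4 grids, 3 runs, -4 dB ERD: clearly separable finger sources.
    ``null``   like demo but with all ERD/ERS depths at 0 dB.
    Returns (montage, paradigm, effects).
    """
    from .montage import build_uhd_montage

    if name == "demo":
        m = build_uhd_montage(n_grids=4)
        return m, Paradigm(runs=3), EffectSpec(fingers=default_finger_effects(m))
    if name == "strong":
        m = build_uhd_montage(n_grids=4)
        return m, Paradigm(runs=3), EffectSpec(fingers=default_finger_effects(m, erd_db=-4.0))
    if name == "null":
        m = build_uhd_montage(n_grids=4)
        fingers = default_finger_effects(m, erd_db=0.0)
        for eff in fingers.values():
            eff.mu_ers_db = 0.0
            eff.beta_ers_db = 0.0
        return m, Paradigm(runs=3), EffectSpec(fingers=fingers)
    raise InvalidParameterError(f"unknown preset {name!r}")
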