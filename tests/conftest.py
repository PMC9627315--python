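"""Shared fixtures: montages and desk-scale synthetic analyses.

Expensive synthetic datasets are session-scoped so several test modules can
reuse one simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uhdfinger import (
    EffectSpec,
    Montage,
    Paradigm,
    Recording,
    apply_car,
    build_uhd_montage,
    identify_bad,
    notch_cascade,
    resample,
    simulate_dataset,
)
from uhdfinger.features import (
    BETA_BAND,
    MU_BAND,
    band_power,
    concat_epochs,
    epoch,
    power_shift_compensation,
)
from uhdfinger.synthetic import default_finger_effects, preset


def preprocess_runs(recordings):
    """Reference preprocessing chain: resample, notch, bad detection, CAR."""
    prepped = [notch_cascade(resample(r, 200.0), 60.0) for r in recordings]
    report = identify_bad(prepped)
    retained = [r for r, bad in zip(prepped, report.bad_runs) if not bad]
    return [apply_car(r, exclude=report.bad_channels) for r in retained], report


def band_epochs(referenced, bands=(MU_BAND, BETA_BAND)):
    """Per-band epoched features, concatenated over runs."""
    out = []
    for band in bands:
        per_run = [
            epoch(power_shift_compensation(band_power(r, band)), r.events)
            for r in referenced
        ]
        out.append(concat_epochs(per_run))
    return out


@pytest.fixture(scope="session")
def montage_small():
    return build_uhd_montage(n_grids=4)


@pytest.fixture(scope="session")
def montage_full():
    return build_uhd_montage()


@pytest.fixture(scope="session")
def grid3x3():
    """Regular 3x3 planar grid with 10 mm spacing."""
    pos = np.array([[i, j, 0.0] for i in range(3) for j in range(3)], dtype=float) * 10.0
    return Montage(
        labels=[f"c{i}" for i in range(9)],
        positions=pos,
        grid_id=np.zeros(9, dtype=int),
        roi_mask=np.ones(9, dtype=bool),
        pitch=10.0,
    )


@pytest.fixture(scope="session")
def demo_dataset():
    """Desk-scale cued-finger dataset: 64 channels, 3 runs, -3 dB ERD."""
    montage, paradigm, effects = preset("demo")
    recordings, events = simulate_dataset(montage, paradigm, effects, seed=11)
    return montage, effects, recordings, events


@pytest.fixture(scope="session")
def demo_analysis(demo_dataset):
    """Preprocessed demo dataset with mu/beta epochs."""
    montage, effects, recordings, _ = demo_dataset
    referenced, report = preprocess_runs(recordings)
    epochs_mu, epochs_beta = band_epochs(referenced)
    roi = montage.roi_mask[~report.bad_channels]
    return {
        "montage": montage,
        "effects": effects,
        "referenced": referenced,
        "report": report,
        "mu": epochs_mu,
        "beta": epochs_beta,
        "roi": roi,
    }


@pytest.fixture(scope="session")
def strong_analysis():
    """Strong-effect preset (-4 dB ERD) ready for decoding."""
    montage, paradigm, effects = preset("strong")
    recordings, _ = simulate_dataset(montage, paradigm, effects, seed=1)
    referenced, report = preprocess_runs(recordings)
    epochs_mu, epochs_beta = band_epochs(referenced)
    roi = montage.roi_mask[~report.bad_channels]
    return {
        "montage": montage,
        "effects": effects,
        "epochs": [epochs_mu, epochs_beta],
        "roi": roi,
    }


@pytest.fixture()
def single_finger_recording():
    """One clean 25-trial single-finger run on a 16-channel grid.

    Low-noise conditions for sign-pattern and recovery smoke checks.
    """
    montage = build_uhd_montage(n_grids=1)
    fingers = default_finger_effects(
        montage, erd_db=-4.0, fingers=("index",), mu_ers_db=3.0, beta_ers_db=3.0
    )
    effects = EffectSpec(fingers=fingers)
    effects.noise.pink_amp_uv = 1.0
    effects.noise.line_amp_uv = 0.0
    effects.noise.drift_sigma_db = 0.0
    effects.noise.n_background_sources = 0
    paradigm = Paradigm(runs=1, trials_per_finger_per_run=25, fingers=("index",))
    recordings, _ = simulate_dataset(montage, paradigm, effects, seed=5)
    return montage, effects, recordings[0]


def white_recording(n_channels=4, duration_s=60.0, fs=200.0, seed=0, events=None):
    """Plain white-noise recording for filter and correlation tests."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    if events is None:
        events = pd.DataFrame(
            {"onset": [0.0], "duration": [duration_s], "trial_type": ["baseline"]}
        )
    return Recording(
        data=rng.standard_normal((n_channels, n)),
        fs=fs,
        labels=[f"ch{i}" for i in range(n_channels)],
        events=events,
    )
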