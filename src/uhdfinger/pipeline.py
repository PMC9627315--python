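"""End-to-end pipeline: simulate/ingest -> preprocess -> features -> ERD/S
-> classification -> neighbour redundancy, with a machine-readable manifest.

Defaults reproduce the reference analysis settings exactly: 200 Hz output
rate, 60 Hz notch cascade, bad-channel z threshold 6 with a 10% bad-run
fraction, mu 8-12 / beta 13-25 Hz bands, 0.25 s segments with a 0.75 s
centred moving average, 25 s power-shift compensation, -0.5..7 s epochs,
-0.5..0 s ERD/S reference, 2.5th-percentile focal selection, 0-5 s task
window, 10x10-fold CV and 100 permutations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import PairwiseDecoder, bh_correct, class_pairs
from .errors import InvalidParameterError, UhdFingerError
from .features import (
    BETA_BAND,
    HIGH_GAMMA_BAND,
    MU_BAND,
    EpochedFeatures,
    band_power,
    concat_epochs,
    epoch,
    power_shift_compensation,
)
from .erds import erds_by_class, focal_selection
from .montage import (
    Montage,
    builtin_density_targets,
    four_nearest_neighbors,
    select_density_subset,
    write_montage,
)
from .neighbors import density_summary, neighbor_correlations
from .preprocess import apply_car, identify_bad, notch_cascade, resample
from .synthetic import Recording, preset, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineStageError", "run_pipeline",
           "save_epochs", "load_epochs", "BAND_PRESETS"]

BAND_PRESETS = {"mu": MU_BAND, "beta": BETA_BAND, "high_gamma": HIGH_GAMMA_BAND}


class PipelineStageError(UhdFingerError):
    """Error raised inside a pipeline stage, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline (defaults = reference settings)."""

    preset: str = "demo"
    seed: int = 0
    fs_out: float = 200.0
    notch_hz: float = 60.0
    bad_z: float = 6.0
    bad_run_fraction: float = 0.1
    bands: tuple[str, ...] = ("mu", "beta")
    segment_s: float = 0.25
    smooth_s: float = 0.75
    compensation_s: float = 25.0
    epoch_pre_s: float = 0.5
    epoch_post_s: float = 7.0
    reference_window_s: tuple[float, float] = (-0.5, 0.0)
    focal_window_s: tuple[float, float] = (1.0, 2.0)
    focal_percentile: float = 2.5
    task_window_s: tuple[float, float] = (0.0, 5.0)
    n_iterations: int = 10
    k_folds: int = 10
    n_permutations: int = 100
    compare_densities: bool = True

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("reference_window_s", "focal_window_s", "task_window_s"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.bands = tuple(cfg.bands)
        return cfg


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the run manifest."""

    config: PipelineConfig
    montage: Montage
    retained_montage: Montage
    bad_report: object
    classification: pd.DataFrame  # pair, peak_time_s, acc_mean, acc_sd, p_raw, p_fdr
    erds: dict  # band -> finger -> ERDSMap
    focal: dict  # band -> finger -> selected channel indices
    neighbors: pd.DataFrame | None
    epochs_by_band: dict
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.classification.to_csv(out / "classification.csv", index=False)
        if self.neighbors is not None:
            self.neighbors.to_csv(out / "neighbors.csv", index=False)
        write_montage(self.montage, out / "montage.tsv")
        focal_json = {
            band: {f: np.asarray(ix).tolist() for f, ix in by_f.items()}
            for band, by_f in self.focal.items()
        }
        (out / "focal_selection.json").write_text(json.dumps(focal_json, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _resolve_band(name: str) -> tuple[float, float]:
    if name not in BAND_PRESETS:
        raise InvalidParameterError(
            f"unknown band name {name!r}; choose from {sorted(BAND_PRESETS)}"
        )
    return BAND_PRESETS[name]


def run_pipeline(
    config: PipelineConfig,
    recordings: list[Recording] | None = None,
    montage: Montage | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis, deterministically for a given config.

    Without explicit ``recordings``/``montage`` the synthetic preset named
    by the config is simulated with the config seed.
    """
    # -- simulate / ingest --------------------------------------------------
    try:
        if recordings is None:
            montage_, paradigm, effects = preset(config.preset)
            montage = montage if montage is not None else montage_
            recordings, _ = simulate_dataset(
                montage, paradigm, effects, seed=config.seed
            )
        elif montage is None:
            raise InvalidParameterError("a montage is required with explicit recordings")
    except UhdFingerError as err:
        raise PipelineStageError("simulate", err) from err

    # -- preprocess ---------------------------------------------------------
    try:
        prepped = [
            notch_cascade(resample(r, config.fs_out), config.notch_hz) for r in recordings
        ]
        report = identify_bad(
            prepped, threshold_z=config.bad_z, run_fraction=config.bad_run_fraction
        )
        retained_runs = [r for r, bad in zip(prepped, report.bad_runs) if not bad]
        referenced = [apply_car(r, exclude=report.bad_channels) for r in retained_runs]
        retained_montage = montage.subset(~report.bad_channels)
    except UhdFingerError as err:
        raise PipelineStageError("preprocess", err) from err

    # -- features -----------------------------------------------------------
    try:
        band_defs = {name: _resolve_band(name) for name in config.bands}
        epochs_by_band: dict[str, EpochedFeatures] = {}
        for name, band in band_defs.items():
            per_run = []
            for rec in referenced:
                feats = band_power(rec, band, config.segment_s, config.smooth_s)
                feats = power_shift_compensation(feats, config.compensation_s)
                per_run.append(
                    epoch(feats, rec.events, config.epoch_pre_s, config.epoch_post_s)
                )
            epochs_by_band[name] = concat_epochs(per_run)
    except UhdFingerError as err:
        raise PipelineStageError("features", err) from err

    # -- erds ---------------------------------------------------------------
    try:
        erds_maps = {
            name: erds_by_class(ep, config.reference_window_s)
            for name, ep in epochs_by_band.items()
        }
        focal = {
            name: focal_selection(maps, config.focal_window_s, config.focal_percentile)
            for name, maps in erds_maps.items()
        }
    except UhdFingerError as err:
        raise PipelineStageError("erds", err) from err

    # -- classify -----------------------------------------------------------
    try:
        roi = retained_montage.roi_mask
        fingers = sorted(set(np.unique(next(iter(epochs_by_band.values())).labels)))
        rows = []
        epoch_list = [epochs_by_band[name] for name in config.bands]
        for a, b in class_pairs(fingers):
            res = PairwiseDecoder(epoch_list, classes=(a, b), roi=roi,
                                  task_window_s=config.task_window_s).fit(
                n_iterations=config.n_iterations,
                k_folds=config.k_folds,
                seed_base=config.seed,
            )
            p_raw = np.nan
            if config.n_permutations > 0:
                p_raw = res.permutation_test(config.n_permutations, seed=config.seed).p_value
            rows.append(
                (f"{a} vs {b}", res.peak_time_s, res.peak_accuracy_mean,
                 res.peak_accuracy_sd, p_raw)
            )
        classification = pd.DataFrame(
            rows, columns=["pair", "peak_time_s", "acc_mean", "acc_sd", "p_raw"]
        )
        if config.n_permutations > 0:
            classification["p_fdr"] = bh_correct(classification["p_raw"].to_numpy())
        else:
            classification["p_fdr"] = np.nan
    except UhdFingerError as err:
        raise PipelineStageError("classify", err) from err

    # -- neighbors ----------------------------------------------------------
    neighbors_df = None
    try:
        if config.compare_densities and referenced:
            concat = Recording(
                np.concatenate([r.data for r in referenced], axis=-1),
                referenced[0].fs,
                list(referenced[0].labels),
                referenced[0].events.copy(),
            )
            stats = {"uhd": neighbor_correlations(concat, four_nearest_neighbors(retained_montage))}
            for name in ("dense", "sparse"):
                targets = builtin_density_targets(retained_montage, name)
                mask = select_density_subset(retained_montage, targets)
                sub = retained_montage.subset(mask)
                graph = four_nearest_neighbors(sub)
                if graph.n_pairs:
                    idx = np.flatnonzero(mask)
                    sub_rec = Recording(
                        concat.data[idx], concat.fs,
                        [concat.labels[i] for i in idx], concat.events.copy(),
                    )
                    stats[name] = neighbor_correlations(sub_rec, graph)
            neighbors_df = density_summary(stats)
    except UhdFingerError as err:
        raise PipelineStageError("neighbors", err) from err

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_runs_input": len(recordings),
        "n_runs_retained": len(referenced),
        "bad_channels": report.to_dict()["bad_channels"],
        "bad_runs": report.to_dict()["bad_runs"],
        "n_channels_retained": retained_montage.n_channels,
        "n_trials": int(next(iter(epochs_by_band.values())).n_trials),
    }

    result = PipelineResult(
        config=config,
        montage=montage,
        retained_montage=retained_montage,
        bad_report=report,
        classification=classification,
        erds=erds_maps,
        focal=focal,
        neighbors=neighbors_df,
        epochs_by_band=epochs_by_band,
        manifest=manifest,
    )
    if out_dir is not None:
        result.save(out_dir)
    return result


# ---------------------------------------------------------------------------
# epoch container io (used by the command-line stages)


def save_epochs(epochs: EpochedFeatures, path: str | Path) -> None:
    np.savez(
        path,
        tensor=epochs.tensor,
        labels=np.asarray(epochs.labels, dtype=str),
        times=epochs.times,
        feature_fs=np.array([epochs.feature_fs]),
        channel_labels=np.asarray(epochs.channel_labels, dtype=str),
        band=np.asarray(epochs.band, dtype=float),
    )


def load_epochs(path: str | Path) -> EpochedFeatures:
    with np.load(path, allow_pickle=False) as z:
        return EpochedFeatures(
            tensor=z["tensor"],
            labels=z["labels"].astype(object),
            times=z["times"],
            feature_fs=float(z["feature_fs"][0]),
            channel_labels=[str(c) for c in z["channel_labels"]],
            band=tuple(tuple(b) for b in z["band"]),
        )
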