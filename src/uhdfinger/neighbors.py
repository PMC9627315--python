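"""Redundancy between neighbouring electrodes.

For every unique four-nearest-neighbour electrode pair of a montage the
centre-to-centre Euclidean distance, Pearson's correlation of the 1-30 Hz
band-passed signals and the coefficient of determination (R^2 = r^2) are
computed; montage-level summaries are reported as median [IQR].  Comparing
these across electrode densities quantifies how much information adjacent
ultra-high-density electrodes share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .montage import NeighborGraph
from .preprocess import bandpass
from .synthetic import Recording

logger = logging.getLogger(__name__)

__all__ = ["NeighborPairStats", "neighbor_correlations", "density_summary"]


@dataclass
class NeighborPairStats:
    """Per-pair distance/correlation table with median [IQR] summaries."""

    table: pd.DataFrame  # columns pair_i, pair_j, distance_mm, r, r2
    band: tuple[float, float]

    def summary(self) -> pd.DataFrame:
        """Median and nearest-rank [25th; 75th] percentiles per metric."""
        rows = []
        for metric in ("distance_mm", "r", "r2"):
            x = self.table[metric].to_numpy()
            q25, q75 = np.quantile(x, [0.25, 0.75], method="inverted_cdf")
            rows.append((metric, float(np.median(x)), float(q25), float(q75)))
        return pd.DataFrame(rows, columns=["metric", "median", "q25", "q75"])

    @property
    def n_pairs(self) -> int:
        return len(self.table)


def neighbor_correlations(
    recording: Recording,
    graph: NeighborGraph,
    band: tuple[float, float] = (1.0, 30.0),
) -> NeighborPairStats:
    """Distance, Pearson r and R^2 for every unique neighbouring pair.

    The (already preprocessed, post-CAR) recording is band-pass filtered to
    the stated band; correlations use all samples.  Pairs containing a
    constant channel are dropped with a warning.
    """
    if graph.n_pairs == 0:
        raise InvalidParameterError("neighbour graph has no pairs")
    if graph.pairs.max() >= recording.n_channels:
        raise InvalidParameterError("graph refers to channels missing from the recording")
    filtered = bandpass(recording, band).data
    sd = filtered.std(axis=-1)
    rows, dropped = [], 0
    centered = filtered - filtered.mean(axis=-1, keepdims=True)
    for (i, j), dist in zip(graph.pairs, graph.distances):
        if sd[i] == 0 or sd[j] == 0:
            dropped += 1
            continue
        r = float(np.dot(centered[i], centered[j]) / (len(centered[i]) * sd[i] * sd[j]))
        rows.append((int(i), int(j), float(dist), r, r * r))
    if dropped:
        logger.warning("dropped %d pair(s) containing a constant channel", dropped)
    table = pd.DataFrame(rows, columns=["pair_i", "pair_j", "distance_mm", "r", "r2"])
    return NeighborPairStats(table=table, band=(float(band[0]), float(band[1])))


def density_summary(stats_by_montage: dict[str, NeighborPairStats]) -> pd.DataFrame:
    """Stacked median [IQR] summaries for several montage densities."""
    frames = []
    for name, stats in stats_by_montage.items():
        s = stats.summary()
        s.insert(0, "montage_name", name)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)
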