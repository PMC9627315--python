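"""Time-resolved pairwise finger decoding with permutation inference.

The model is a linear support-vector machine (box constraint 1, features
standardized, no hyperparameter search) applied independently at every
feature time step inside the task window.  Performance is estimated with an
n-times-of-k-fold stratified cross-validation (n = k = 10 by default; fold
assignment seeded by the iteration index), summarized at the time point of
highest mean accuracy, and tested against a label-permutation null whose
peak-time accuracies are modelled with a fitted Gaussian (so empirical
p-values below 1/#permutations are attainable).

The surface follows the statsmodels convention: :class:`PairwiseDecoder`
is built from epoched features, ``fit()`` returns :class:`DecodingResults`,
and the permutation test hangs off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InvalidDataError, InvalidParameterError
from .features import EpochedFeatures, concat_bands

__all__ = [
    "PairwiseDecoder",
    "DecodingResults",
    "PermutationNull",
    "SubsetComparison",
    "pairwise_cv",
    "permutation_pvalue",
    "bh_correct",
    "subset_comparison",
    "class_pairs",
]


def class_pairs(classes) -> list[tuple[str, str]]:
    """All unordered class pairs (5 fingers -> 10 two-class problems)."""
    return list(combinations(list(classes), 2))


class PairwiseDecoder:
    """Two-class time-resolved decoder over ROI band-power features.

    Parameters
    ----------
    epochs
        Epoched log band-power features; a list is treated as one entry per
        frequency band and stacked along the channel axis.
    classes
        The two trial classes to discriminate; inferred when the epochs
        contain exactly two.
    roi
        Boolean channel mask (per underlying channel, broadcast over bands)
        restricting the feature set to the region of interest.
    task_window_s
        Time window (relative to the cue) whose feature steps are decoded.
    """

    def __init__(
        self,
        epochs: EpochedFeatures | list[EpochedFeatures],
        classes: tuple[str, str] | None = None,
        roi: np.ndarray | None = None,
        task_window_s: tuple[float, float] = (0.0, 5.0),
    ):
        if isinstance(epochs, (list, tuple)):
            n_bands = len(epochs)
            epochs = concat_bands(list(epochs))
        else:
            n_bands = len(epochs.band) if isinstance(epochs.band[0], tuple) else 1
        if classes is None:
            present = np.unique(epochs.labels)
            if len(present) != 2:
                raise InvalidDataError("classes must be given unless exactly two are present")
            classes = (str(present[0]), str(present[1]))
        self.classes = tuple(classes)
        epochs = epochs.select_classes(self.classes)
        if roi is not None:
            roi = np.asarray(roi, dtype=bool)
            n_ch = epochs.tensor.shape[1]
            if len(roi) != n_ch:
                if n_ch % len(roi) == 0:  # per-band stacking of the same montage
                    roi = np.tile(roi, n_ch // len(roi))
                else:
                    raise InvalidParameterError("roi mask does not match the channel axis")
            epochs = epochs.select_channels(roi)
        self.epochs = epochs
        sel = (epochs.times >= task_window_s[0]) & (epochs.times <= task_window_s[1])
        if not sel.any():
            raise InvalidParameterError("task window contains no feature steps")
        self.task_window_s = task_window_s
        self.step_times = epochs.times[sel]
        self._X = epochs.tensor[:, :, sel]  # trials x features x steps
        self._y = np.asarray([self.classes.index(str(l)) for l in epochs.labels])
        self.n_bands = n_bands

    # -- fitting ------------------------------------------------------------

    def _cv_accuracy(self, y: np.ndarray, k_folds: int, seed: int, per_class: bool = False):
        """One k-fold CV over all time steps.

        Fold assignment (stratified, shuffled with ``seed``) is shared by
        all time steps, mirroring a per-iteration random seed.  Features are
        standardized on each training fold (linear kernel, scale 1 after
        standardization).  Returns (n_steps,) mean accuracies, and per-class
        accuracies when requested.
        """
        n_steps = self._X.shape[2]
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(len(y)), y))
        acc = np.zeros(n_steps)
        cls = np.zeros((n_steps, 2)) if per_class else None
        cls_n = np.zeros((n_steps, 2)) if per_class else None
        for train, test in splits:
            y_tr, y_te = y[train], y[test]
            for s in range(n_steps):
                X_tr = self._X[train, :, s]
                mu = X_tr.mean(axis=0)
                sd = X_tr.std(axis=0)
                sd[sd == 0] = 1.0
                svm = SVC(kernel="linear", C=1.0).fit((X_tr - mu) / sd, y_tr)
                pred = svm.predict((self._X[test, :, s] - mu) / sd)
                acc[s] += np.mean(pred == y_te)
                if per_class:
                    for c in (0, 1):
                        sel = y_te == c
                        if sel.any():
                            cls[s, c] += np.mean(pred[sel] == c)
                            cls_n[s, c] += 1
        acc /= len(splits)
        if per_class:
            with np.errstate(invalid="ignore"):
                cls = np.where(cls_n > 0, cls / np.maximum(cls_n, 1), np.nan)
            return acc, cls
        return acc

    def fit(
        self, n_iterations: int = 10, k_folds: int = 10, seed_base: int = 0
    ) -> "DecodingResults":
        """Run the n-times-of-k-fold CV over every task-window time step."""
        counts = np.bincount(self._y, minlength=2)
        if counts.min() < k_folds:
            raise InvalidDataError(
                f"each class needs at least k_folds={k_folds} trials, got {counts.tolist()}"
            )
        n_steps = len(self.step_times)
        accuracy = np.empty((n_iterations, n_steps))
        class_accuracy = np.empty((n_iterations, n_steps, 2))
        seeds = [seed_base + i for i in range(1, n_iterations + 1)]
        for i, seed in enumerate(seeds):
            accuracy[i], class_accuracy[i] = self._cv_accuracy(
                self._y, k_folds, seed, per_class=True
            )
        return DecodingResults(
            model=self,
            accuracy=100.0 * accuracy,
            class_accuracy=100.0 * class_accuracy,
            times=self.step_times.copy(),
            seeds=seeds,
            k_folds=k_folds,
        )


@dataclass
class DecodingResults:
    """Cross-validated accuracies with the peak-time summary."""

    model: PairwiseDecoder
    accuracy: np.ndarray  # (n_iterations, n_steps), percent
    class_accuracy: np.ndarray  # (n_iterations, n_steps, 2), percent
    times: np.ndarray
    seeds: list[int]
    k_folds: int

    def __post_init__(self) -> None:
        mean = self.accuracy.mean(axis=0)
        self.peak_step = int(np.argmax(mean))  # earliest step at the maximum
        self.peak_time_s = float(self.times[self.peak_step])
        self.peak_accuracy_mean = float(mean[self.peak_step])
        peak_col = self.accuracy[:, self.peak_step]
        self.peak_accuracy_sd = float(peak_col.std(ddof=1)) if len(peak_col) > 1 else 0.0

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    def permutation_test(self, n_permutations: int = 100, seed: int = 0) -> "PermutationNull":
        """Label-permutation null of the peak-time model performance.

        Each permutation reruns the full n-times-of-k-fold CV on shuffled
        labels (fresh fold seeds derived from ``seed`` and the permutation
        index) and is summarized exactly like the observed model: by its
        mean accuracy at its own best time step.  Keeping the max-over-time
        selection inside the null is what makes the test calibrated.  A
        Gaussian is fitted to the null performances and the upper tail at
        the observed peak accuracy is the empirical p-value.
        """
        if n_permutations < 20:
            warnings.warn("fewer than 20 permutations give an unstable Gaussian null fit")
        dec = self.model
        n_steps = len(self.times)
        null = np.empty(n_permutations)
        for j in range(n_permutations):
            ss = np.random.SeedSequence([seed, j])
            rng = np.random.default_rng(ss)
            y = rng.permutation(dec._y)
            fold_seeds = rng.integers(0, 2**31 - 1, size=len(self.seeds))
            acc = np.stack(
                [dec._cv_accuracy(y, self.k_folds, int(s)) for s in fold_seeds]
            )
            null[j] = 100.0 * acc.mean(axis=0).max()
        mean, sd = float(null.mean()), float(null.std(ddof=1))
        p = float(stats.norm.sf(self.peak_accuracy_mean, loc=mean, scale=sd))
        return PermutationNull(
            null_performances=null,
            null_mean=mean,
            null_sd=sd,
            observed=self.peak_accuracy_mean,
            p_value=p,
            n_permutations=n_permutations,
        )

    def summary(self) -> str:
        """Human-readable summary table (statsmodels style)."""
        from statsmodels.iolib.table import SimpleTable

        a, b = self.model.classes
        rows = [
            ["classes", f"{a} vs {b}"],
            ["trials", str(len(self.model._y))],
            ["features", str(self.model._X.shape[1])],
            ["CV", f"{len(self.seeds)} x {self.k_folds}-fold (stratified)"],
            ["task window [s]", f"{self.model.task_window_s[0]:g} .. {self.model.task_window_s[1]:g}"],
            ["peak time [s]", f"{self.peak_time_s:.2f}"],
            ["peak accuracy [%]", f"{self.peak_accuracy_mean:.1f} ({self.peak_accuracy_sd:.1f})"],
        ]
        return str(SimpleTable(rows, headers=["", ""], title="Pairwise finger decoding"))


@dataclass
class PermutationNull:
    """Permutation-null accuracies with the fitted Gaussian and p-value."""

    null_performances: np.ndarray
    null_mean: float
    null_sd: float
    observed: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# functional surface


def pairwise_cv(
    epochs,
    roi: np.ndarray | None = None,
    n_iterations: int = 10,
    k_folds: int = 10,
    seed_base: int = 0,
    classes: tuple[str, str] | None = None,
    task_window_s: tuple[float, float] = (0.0, 5.0),
) -> DecodingResults:
    """Fit the time-resolved pairwise decoder (thin wrapper over the model)."""
    return PairwiseDecoder(epochs, classes=classes, roi=roi, task_window_s=task_window_s).fit(
        n_iterations=n_iterations, k_folds=k_folds, seed_base=seed_base
    )


def permutation_pvalue(
    epochs,
    roi: np.ndarray | None,
    observed: DecodingResults,
    n_permutations: int = 100,
    seed: int = 0,
) -> PermutationNull:
    """Permutation p-value for an observed decoding result."""
    del epochs, roi  # the observed results object carries its own data
    return observed.permutation_test(n_permutations=n_permutations, seed=seed)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg (FDR) step-up adjustment with monotonicity."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InvalidParameterError("p-value list must not be empty")
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SubsetComparison:
    """Paired two-tailed Wilcoxon signed-rank comparison of performances."""

    statistic: float
    p_value: float
    median_difference: float
    iqr_difference: tuple[float, float]
    n: int


def subset_comparison(performances_full, performances_subset) -> SubsetComparison:
    """Compare paired model performances between montage densities.

    Returns the two-tailed Wilcoxon signed-rank test together with the
    median [IQR] of the paired differences (full minus subset).
    """
    full = np.asarray(performances_full, dtype=float)
    sub = np.asarray(performances_subset, dtype=float)
    if full.shape != sub.shape or full.ndim != 1:
        raise InvalidParameterError("performances must be paired 1-D arrays of equal length")
    diff = full - sub
    if np.all(diff == 0):
        raise DegenerateDataError("all paired differences are zero")
    res = stats.wilcoxon(full, sub, alternative="two-sided")
    q25, q75 = np.quantile(diff, [0.25, 0.75], method="inverted_cdf")
    return SubsetComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_difference=float(np.median(diff)),
        iqr_difference=(float(q25), float(q75)),
        n=len(diff),
    )
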