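"""Pairwise decoding model, permutation inference and comparison statistics."""

import numpy as np
import pytest
from scipy import stats

from uhdfinger import (
    DegenerateDataError,
    InvalidDataError,
    InvalidParameterError,
    PairwiseDecoder,
    bh_correct,
    class_pairs,
    pairwise_cv,
    subset_comparison,
)
from uhdfinger.features import EpochedFeatures


def gaussian_epochs(n_per_class=20, n_channels=6, n_steps=30, seed=0, effect=0.0):
    """Synthetic log band-power epochs; ``effect`` shifts class 'b' channels."""
    rng = np.random.default_rng(seed)
    tensor = rng.standard_normal((2 * n_per_class, n_channels, n_steps))
    labels = np.array(["a"] * n_per_class + ["b"] * n_per_class, dtype=object)
    tensor[n_per_class:, : n_channels // 2, :] += effect
    return EpochedFeatures(
        tensor=tensor,
        labels=labels,
        times=(np.arange(n_steps) - 2) / 4.0,
        feature_fs=4.0,
        channel_labels=[f"ch{i}" for i in range(n_channels)],
        band=((8.0, 12.0),),
    )


class TestPairwiseDecoder:
    def test_separable_classes_reach_high_accuracy(self):
        res = PairwiseDecoder(gaussian_epochs(effect=3.0)).fit(2, 5, 0)
        assert res.peak_accuracy_mean > 90.0

    def test_null_labels_stay_inside_the_chance_band(self):
        res = PairwiseDecoder(gaussian_epochs(n_per_class=100, seed=3)).fit(3, 5, 0)
        assert res.peak_accuracy_mean < 62.0
        assert np.all(res.accuracy >= 0.0) and np.all(res.accuracy <= 100.0)

    def test_same_seed_base_reproduces_results(self):
        ep = gaussian_epochs(effect=1.0)
        a = PairwiseDecoder(ep).fit(2, 5, 7)
        b = PairwiseDecoder(ep).fit(2, 5, 7)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)
        assert a.peak_time_s == b.peak_time_s

    def test_label_swap_leaves_accuracy_unchanged(self):
        ep = gaussian_epochs(effect=1.5, seed=5)
        a = PairwiseDecoder(ep, classes=("a", "b")).fit(2, 4, 0)
        b = PairwiseDecoder(ep, classes=("b", "a")).fit(2, 4, 0)
        np.testing.assert_allclose(a.accuracy, b.accuracy, atol=1e-9)

    def test_peak_is_earliest_maximum_within_task_window(self):
        ep = gaussian_epochs(seed=8)
        res = PairwiseDecoder(ep).fit(2, 4, 0)
        mean = res.mean_accuracy
        assert res.peak_accuracy_mean == mean.max()
        assert res.peak_step == np.argmax(mean)
        assert 0.0 <= res.peak_time_s <= 5.0

    def test_roi_mask_restricts_features(self):
        ep = gaussian_epochs(effect=2.0)
        roi = np.zeros(6, dtype=bool)
        roi[3:] = True  # keep only unshifted channels -> chance level
        informative = PairwiseDecoder(ep).fit(2, 5, 0)
        uninformative = PairwiseDecoder(ep, roi=roi).fit(2, 5, 0)
        assert uninformative.peak_accuracy_mean < informative.peak_accuracy_mean - 15.0

    def test_too_few_trials_for_folds_rejected(self):
        with pytest.raises(InvalidDataError):
            PairwiseDecoder(gaussian_epochs(n_per_class=4)).fit(2, 5, 0)

    def test_summary_mentions_classes_and_peak(self):
        res = PairwiseDecoder(gaussian_epochs(effect=2.0)).fit(2, 5, 0)
        text = res.summary()
        assert "a vs b" in text and "peak" in text

    def test_functional_wrapper_equals_model(self):
        ep = gaussian_epochs(effect=1.0, seed=9)
        a = pairwise_cv(ep, n_iterations=2, k_folds=4, seed_base=1)
        b = PairwiseDecoder(ep).fit(2, 4, 1)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)


class TestPermutationTest:
    def test_pvalue_follows_fitted_gaussian_tail(self):
        res = PairwiseDecoder(gaussian_epochs(n_per_class=10, seed=2, effect=2.0)).fit(2, 5, 0)
        with pytest.warns(UserWarning):
            null = res.permutation_test(n_permutations=10, seed=0)
        expected = stats.norm.sf(res.peak_accuracy_mean, null.null_mean, null.null_sd)
        assert null.p_value == pytest.approx(expected)
        assert 0.0 < null.p_value < 1.0

    def test_null_centres_on_chance_per_step_and_matches_observed_peak(self):
        res = PairwiseDecoder(gaussian_epochs(n_per_class=10, seed=4)).fit(2, 5, 0)
        # per-time-step accuracy on label-free data is chance level ...
        assert abs(res.accuracy.mean() - 50.0) < 5.0
        null = res.permutation_test(n_permutations=24, seed=1)
        # ... while the null statistic keeps the max-over-time selection and
        # is exchangeable with the observed peak on null data
        assert abs(null.null_mean - res.peak_accuracy_mean) < 3 * null.null_sd
        assert null.null_sd > 0

    def test_permutation_null_is_seeded(self):
        res = PairwiseDecoder(gaussian_epochs(n_per_class=8, seed=6)).fit(2, 4, 0)
        a = res.permutation_test(n_permutations=20, seed=3)
        b = res.permutation_test(n_permutations=20, seed=3)
        np.testing.assert_array_equal(a.null_performances, b.null_performances)


class TestBenjaminiHochberg:
    def test_hand_computed_stepup_example(self):
        np.testing.assert_allclose(
            bh_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_correct([0.2]), [0.2])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_correct([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_stepup(self, seed):
        p = np.random.default_rng(seed).uniform(size=10)
        # brute-force step-up with monotonicity enforcement
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        np.testing.assert_allclose(bh_correct(p), adj, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_correct([])


class TestSubsetComparison:
    def test_identical_vectors_are_degenerate(self):
        x = np.linspace(50, 90, 50)
        with pytest.raises(DegenerateDataError):
            subset_comparison(x, x)

    def test_constant_shift_detected_with_tiny_pvalue(self):
        rng = np.random.default_rng(0)
        full = rng.uniform(60, 90, 50)
        res = subset_comparison(full, full - 5.0)
        assert res.p_value < 1e-3
        assert res.median_difference == pytest.approx(5.0)
        assert res.iqr_difference == (5.0, 5.0)

    def test_matches_exact_signed_rank_enumeration(self):
        rng = np.random.default_rng(1)
        full = rng.normal(70, 5, 9)
        sub = full - rng.normal(1.0, 2.0, 9)
        res = subset_comparison(full, sub)
        # exact two-sided null: enumerate all sign assignments of |d| ranks
        d = full - sub
        ranks = stats.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        n = len(d)
        for bits in range(2**n):
            signs = np.array([(bits >> k) & 1 for k in range(n)])
            w = min(ranks[signs == 1].sum(), ranks[signs == 0].sum())
            count += w <= w_obs
        assert res.p_value == pytest.approx(count / 2**n)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidParameterError):
            subset_comparison([1.0, 2.0], [1.0])


def test_five_classes_make_ten_pairs():
    pairs = class_pairs(["thumb", "index", "middle", "ring", "little"])
    assert len(pairs) == 10
    assert len(set(map(frozenset, pairs))) == 10
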