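"""ERD/S maps, focal selection, heatmap interpolation and time-frequency maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uhdfinger import (
    InvalidParameterError,
    Montage,
    Recording,
    compute_erds,
    focal_selection,
    heatmap,
    time_frequency_erds,
)
from uhdfinger.erds import ERDSMap, erds_by_class
from uhdfinger.features import EpochedFeatures, band_power, epoch


def make_epochs(tensor, labels=None, feature_fs=4.0, pre=2):
    tensor = np.asarray(tensor, dtype=float)
    n_t, n_c, n_s = tensor.shape
    return EpochedFeatures(
        tensor=tensor,
        labels=np.asarray(labels if labels is not None else ["index"] * n_t, dtype=object),
        times=(np.arange(n_s) - pre) / feature_fs,
        feature_fs=feature_fs,
        channel_labels=[f"ch{i}" for i in range(n_c)],
        band=((8.0, 12.0),),
    )


def make_map(values, feature_fs=4.0, pre=2):
    values = np.atleast_2d(values)
    return ERDSMap(
        values=values,
        times=(np.arange(values.shape[1]) - pre) / feature_fs,
        reference_window_s=(-0.5, 0.0),
        band=(8.0, 12.0),
        channel_labels=[f"ch{i}" for i in range(values.shape[0])],
    )


class TestComputeErds:
    def test_constant_features_give_zero_erds(self):
        ep = make_epochs(np.full((5, 3, 30), 1.7))
        np.testing.assert_allclose(compute_erds(ep).values, 0.0, atol=1e-12)

    def test_reference_window_mean_is_zero(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((8, 4, 30)))
        m = compute_erds(ep)
        ref = (m.times >= -0.5) & (m.times < 0.0)
        np.testing.assert_allclose(m.values[:, ref].mean(axis=1), 0.0, atol=1e-9)

    def test_scaling_is_10x_log10(self):
        ep = make_epochs(np.zeros((1, 1, 30)))
        ep.tensor[0, 0, 10:] = 0.5  # +0.5 log10 units -> +5 dB
        m = compute_erds(ep)
        assert m.values[0, -1] == pytest.approx(5.0)

    def test_empty_reference_window_rejected(self):
        ep = make_epochs(np.zeros((2, 1, 30)))
        with pytest.raises(InvalidParameterError):
            compute_erds(ep, reference_window_s=(-0.2, -0.1))

    def test_mu_dynamics_sign_pattern(self, single_finger_recording):
        # clean single-source run: ERD in 0.5-2.5 s, ERS in 3.5-5 s post-cue
        _, effects, rec = single_finger_recording
        from uhdfinger import apply_car, notch_cascade, resample
        from uhdfinger.features import power_shift_compensation

        prep = apply_car(notch_cascade(resample(rec, 200.0), 60.0))
        feats = power_shift_compensation(band_power(prep, (8.0, 12.0)))
        maps = erds_by_class(epoch(feats, prep.events))
        center = effects.fingers["index"].center_channel
        m = maps["index"]
        assert m.mean_in_window((1.0, 2.0))[center] < -1.0
        assert m.mean_in_window((4.0, 5.0))[center] > 0.5


class TestFocalSelection:
    def test_256_electrodes_at_2p5_percent_select_6(self):
        rng = np.random.default_rng(1)
        m = make_map(rng.standard_normal((256, 30)))
        assert len(focal_selection(m, percentile=2.5)) == 6

    def test_all_equal_values_select_nothing(self):
        m = make_map(np.ones((64, 30)))
        assert len(focal_selection(m)) == 0

    def test_values_1_to_100_percentile_5_select_the_five_smallest(self):
        values = np.tile(np.arange(1.0, 101.0)[:, None], (1, 30))
        m = make_map(values)
        assert set(focal_selection(m, percentile=5.0)) == {0, 1, 2, 3, 4}

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(5, 300), pct=st.floats(0.5, 50.0), seed=st.integers(0, 2**16))
    def test_count_is_floor_of_fraction_on_tie_free_inputs(self, n, pct, seed):
        values = np.random.default_rng(seed).permutation(np.arange(n, dtype=float))
        m = make_map(np.tile(values[:, None], (1, 8)))
        selected = focal_selection(m, window_s=(0.0, 1.0), percentile=pct)
        assert len(selected) == int(np.floor(pct / 100.0 * n))

    def test_invalid_percentile_rejected(self):
        m = make_map(np.zeros((10, 30)))
        with pytest.raises(InvalidParameterError):
            focal_selection(m, percentile=0.0)

    def test_per_finger_dict_interface(self):
        rng = np.random.default_rng(2)
        maps = {f: make_map(rng.standard_normal((40, 30))) for f in ("thumb", "index")}
        out = focal_selection(maps)
        assert set(out) == {"thumb", "index"}
        assert all(len(ix) == 1 for ix in out.values())  # floor(0.025 * 40)


def line_montage(n, spacing=10.0):
    pos = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    return Montage(
        labels=[f"e{i}" for i in range(n)],
        positions=pos,
        grid_id=np.zeros(n, dtype=int),
        roi_mask=np.ones(n, dtype=bool),
        pitch=spacing,
    )


class TestHeatmap:
    def test_linear_decay_kernel_shape(self):
        m = line_montage(2, spacing=10.0)  # nearest-electrode distance 10
        vertices = np.array([[0, 0, 0], [5, 50, 0], [0, 50, 0], [15, 50, 0]], dtype=float)
        vertices[0] = m.positions[0]
        vertices[1] = m.positions[0] + [0, 5, 0]
        vertices[2] = m.positions[0] + [0, 11, 0]
        hm = heatmap(np.array([1.0, 0.0]), m, vertices)
        assert hm.activation[0] == pytest.approx(1.0)
        assert hm.activation[1] == pytest.approx(0.5)
        assert hm.activation[2] == 0.0

    def test_overlapping_kernels_sum(self):
        m = line_montage(2, spacing=10.0)
        midpoint = m.positions.mean(axis=0)
        hm = heatmap(np.array([3.0, 3.0]), m, midpoint[None, :])
        assert hm.activation[0] == pytest.approx(3.0)  # 2 * a * (1 - 0.5)

    def test_all_bad_channels_give_zero_map(self):
        m = line_montage(4)
        hm = heatmap(np.ones(4), m, np.random.default_rng(0).normal(size=(50, 3)),
                     bad=np.ones(4, dtype=bool))
        np.testing.assert_array_equal(hm.activation, 0.0)

    def test_bad_mode_zero_keeps_channel_with_zero_activation(self):
        m = line_montage(3)
        bad = np.array([False, True, False])
        vertices = m.positions.copy()
        excl = heatmap(np.ones(3), m, vertices, bad=bad, bad_mode="exclude")
        zero = heatmap(np.ones(3), m, vertices, bad=bad, bad_mode="zero")
        # in zero mode the bad electrode still shapes its neighbours' radii
        assert excl.kernel_radii.shape == (2,)
        assert zero.kernel_radii.shape == (3,)

    @pytest.mark.parametrize("seed", range(3))
    def test_superposition_and_linearity_vs_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 20)
        pos = np.column_stack([rng.uniform(0, 80, (n, 2)), np.zeros(n)])
        m = Montage([f"e{i}" for i in range(n)], pos, np.zeros(n, int), np.ones(n, bool), 1.0)
        vertices = np.column_stack([rng.uniform(0, 80, (300, 2)), np.zeros(300)])
        act = rng.standard_normal(n)
        hm = heatmap(act, m, vertices)
        # brute force: per-vertex, per-electrode loop
        expected = np.zeros(len(vertices))
        for v_idx, v in enumerate(vertices):
            for e in range(n):
                d_e = min(np.linalg.norm(pos[e] - pos[j]) for j in range(n) if j != e)
                d = np.linalg.norm(v - pos[e])
                if d < d_e:
                    expected[v_idx] += act[e] * (1 - d / d_e)
        np.testing.assert_allclose(hm.activation, expected, atol=1e-10)
        doubled = heatmap(2.0 * act, m, vertices)
        np.testing.assert_allclose(doubled.activation, 2.0 * hm.activation, atol=1e-10)


class TestTimeFrequency:
    def test_frame_rate_is_20_hz(self):
        rng = np.random.default_rng(3)
        ev = pd.DataFrame({"onset": [10.0], "duration": [5.0], "trial_type": ["index"]})
        rec = Recording(rng.standard_normal((1, 4000)), 200.0, ["ch0"], ev)
        tf = time_frequency_erds(rec, channel=0)
        assert tf.frame_rate == pytest.approx(20.0)
        assert tf.freqs[0] == 8.0 and tf.freqs[-1] == 30.0
        assert np.all(np.diff(tf.freqs) == 1.0)

    def test_stationary_noise_has_near_zero_erds(self):
        rng = np.random.default_rng(4)
        onsets = 10.0 + 9.0 * np.arange(50)
        ev = pd.DataFrame(
            {"onset": onsets, "duration": [5.0] * 50, "trial_type": ["index"] * 50}
        )
        n = int((onsets[-1] + 9) * 200)
        rec = Recording(rng.standard_normal((1, n)), 200.0, ["ch0"], ev)
        tf = time_frequency_erds(rec, channel=0)
        assert abs(tf.values.mean()) < 0.2

    def test_beta_erd_and_rebound_sign_pattern(self, single_finger_recording):
        _, effects, rec = single_finger_recording
        from uhdfinger import apply_car, notch_cascade, resample

        prep = apply_car(notch_cascade(resample(rec, 200.0), 60.0))
        center = effects.fingers["index"].center_channel
        tf = time_frequency_erds(prep, channel=center)
        beta = (tf.freqs >= 13) & (tf.freqs <= 25)
        during = (tf.times >= 1.0) & (tf.times <= 4.0)
        after = (tf.times >= 6.0) & (tf.times <= 7.0)
        assert tf.values[np.ix_(beta, during)].mean() < -1.0
        assert tf.values[np.ix_(beta, after)].mean() > 0.5

    def test_window_longer_than_recording_rejected(self):
        ev = pd.DataFrame({"onset": [0.1], "duration": [0.2], "trial_type": ["index"]})
        rec = Recording(np.zeros((1, 100)), 200.0, ["ch0"], ev)
        with pytest.raises(InvalidParameterError):
            time_frequency_erds(rec, channel=0)

    def test_interpolation_refines_grid_10x(self):
        rng = np.random.default_rng(5)
        ev = pd.DataFrame({"onset": [10.0], "duration": [5.0], "trial_type": ["index"]})
        rec = Recording(rng.standard_normal((1, 4000)), 200.0, ["ch0"], ev)
        tf = time_frequency_erds(rec, channel=0)
        fine = tf.interpolated(10)
        assert fine.values.shape == (tf.values.shape[0] * 10, tf.values.shape[1] * 10)
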