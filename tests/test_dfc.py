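"""Windowed connectivity estimation: dipole strength, filtering, windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfcstates import dfc, synth
from dfcstates.dfc import (
    ParcelTimeSeries,
    WindowSpec,
    build_participant_dfc,
    combine_dipole_moments,
    concat_group,
    devectorize_upper,
    downsample_strength,
    lowpass,
    parcel_average,
    sliding_window_corr,
    vectorize_upper,
)


class TestDipoleStrength:
    def test_pythagorean_triple(self):
        assert combine_dipole_moments([3.0], [4.0], [0.0])[0] == pytest.approx(5.0)

    def test_zero(self):
        assert combine_dipole_moments([0.0], [0.0], [0.0])[0] == 0.0

    def test_matches_norm_oracle(self, rng):
        j = rng.standard_normal((3, 500))
        expected = np.linalg.norm(j, axis=0)  # independent norm routine
        np.testing.assert_allclose(combine_dipole_moments(*j), expected, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_dipole_moments([1.0, 2.0], [1.0], [1.0])


class TestDownsample:
    def test_constant_preserved(self):
        out = downsample_strength(np.full(500, 3.3), rate_hz=250, target_hz=1.0)
        np.testing.assert_allclose(out, 3.3)

    def test_250hz_10s_gives_10_samples(self):
        out = downsample_strength(np.arange(2500.0), rate_hz=250, target_hz=1.0)
        assert out.shape[0] == 10

    def test_alternating_cancels(self):
        p = np.tile([1.0, -1.0], 100)
        np.testing.assert_allclose(downsample_strength(p, 4, 1.0), 0.0)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            downsample_strength(np.zeros(100), rate_hz=2.5, target_hz=1.0)


class TestParcelAverage:
    def test_single_voxel_parcels_identity(self, rng):
        vox = rng.standard_normal((3, 1, 1, 20))
        labels = np.array([1, 2, 3]).reshape(3, 1, 1)
        out = parcel_average(vox, labels)
        np.testing.assert_allclose(out, vox[:, 0, 0, :].T)

    def test_two_voxel_mean(self):
        vox = np.zeros((2, 1, 1, 3))
        vox[0, 0, 0] = [1.0, 2.0, 3.0]
        vox[1, 0, 0] = [3.0, 4.0, 5.0]
        out = parcel_average(vox, np.ones((2, 1, 1), dtype=int))
        np.testing.assert_allclose(out[:, 0], [2.0, 3.0, 4.0])

    def test_matches_loop_oracle(self, rng):
        vox = rng.standard_normal((4, 5, 3, 11))
        labels = rng.integers(1, 4, size=(4, 5, 3))
        out = parcel_average(vox, labels)
        for r in range(1, 4):
            expected = vox[labels == r].mean(axis=0)
            np.testing.assert_allclose(out[:, r - 1], expected, atol=1e-12)

    def test_empty_parcel_named_in_error(self, rng):
        vox = rng.standard_normal((2, 2, 2, 5))
        labels = np.ones((2, 2, 2), dtype=int)
        labels[0, 0, 0] = 3  # label 2 missing
        with pytest.raises(ValueError, match="2"):
            parcel_average(vox, labels)


def _sinusoid_amplitude(series, freq_hz, dt):
    """Oracle: amplitude via least-squares sinusoid regression."""
    t = np.arange(series.shape[0]) * dt
    X = np.column_stack([np.sin(2 * np.pi * freq_hz * t), np.cos(2 * np.pi * freq_hz * t)])
    coef, *_ = np.linalg.lstsq(X, series, rcond=None)
    return float(np.hypot(*coef))


class TestLowpass:
    def test_dc_preserved(self):
        ts = ParcelTimeSeries(np.full((200, 2), 5.0), sample_interval=2.0)
        out = lowpass(ts, cutoff_hz=0.1)
        np.testing.assert_allclose(out.values, 5.0, atol=1e-6)

    def test_slow_sinusoid_passes(self):
        t = np.arange(500) * 2.0
        x = np.sin(2 * np.pi * 0.02 * t)
        ts = ParcelTimeSeries(np.column_stack([x, x]), sample_interval=2.0)
        amp = _sinusoid_amplitude(lowpass(ts).values[:, 0], 0.02, 2.0)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_fast_sinusoid_attenuated(self):
        t = np.arange(500) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        ts = ParcelTimeSeries(np.column_stack([x, x]), sample_interval=2.0)
        amp = _sinusoid_amplitude(lowpass(ts).values[:, 0], 0.2, 2.0)
        assert amp < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        ts = ParcelTimeSeries(np.zeros((100, 2)) + np.arange(100)[:, None], sample_interval=2.0)
        with pytest.raises(ValueError):
            lowpass(ts, cutoff_hz=0.3)

    def test_short_series_rejected(self):
        ts = ParcelTimeSeries(np.random.default_rng(0).standard_normal((10, 2)), 2.0)
        with pytest.raises(ValueError):
            lowpass(ts)


class TestSlidingWindows:
    def test_window_sample_arithmetic(self):
        assert WindowSpec.from_seconds(42, 6, 2.0) == WindowSpec(21, 3)
        assert WindowSpec.from_seconds(40, 5, 1.0) == WindowSpec(40, 5)

    def test_window_count_formula(self):
        w = WindowSpec(21, 3)
        for n in (21, 24, 99, 300):
            if (n - 21) % 3 == 0:
                assert w.n_windows(n) == (n - 21) // 3 + 1

    def test_uncovered_tail_rejected_then_trimmed(self, rng):
        w = WindowSpec(40, 5)
        ts = ParcelTimeSeries(rng.standard_normal((101, 3)), 1.0)
        with pytest.raises(ValueError):
            sliding_window_corr(ts, w)  # (101 - 40) % 5 == 1 uncovered sample
        out = sliding_window_corr(ts, w, trim=True)
        assert out.shape[0] == (100 - 40) // 5 + 1

    def test_identical_parcels_perfect_correlation(self, rng):
        x = rng.standard_normal(80)
        ts = ParcelTimeSeries(np.column_stack([x, x]), 1.0)
        out = sliding_window_corr(ts, WindowSpec(40, 5))
        np.testing.assert_allclose(out[:, 0, 1], 1.0)

    def test_zero_variance_window_rejected(self):
        vals = np.random.default_rng(0).standard_normal((40, 3))
        vals[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            sliding_window_corr(ParcelTimeSeries(vals, 1.0), WindowSpec(40, 5))

    def test_window_alignment_left_half_open(self):
        # first window must cover samples [0, L): plant a spike correlation there
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((60, 2))
        vals[:20, 1] = vals[:20, 0]  # perfectly coupled only in first window
        out = sliding_window_corr(ParcelTimeSeries(vals, 1.0), WindowSpec(20, 20))
        assert out[0, 0, 1] == pytest.approx(1.0)
        assert abs(out[1, 0, 1]) < 0.5


class TestVectorize:
    def test_r3_order(self):
        m = np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.3], [0.2, 0.3, 1.0]])
        np.testing.assert_allclose(vectorize_upper(m), [0.1, 0.2, 0.3])

    def test_r90_length(self):
        assert vectorize_upper(np.eye(90)).shape[0] == 4005

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(R=st.integers(2, 10), seed=st.integers(0, 1000))
    def test_round_trip(self, R, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((R, R))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        np.testing.assert_allclose(devectorize_upper(vectorize_upper(m), R), m)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            devectorize_upper(np.zeros(4), 3)


class TestParticipantDFC:
    def test_single_window_gives_zeros(self, rng):
        ts = ParcelTimeSeries(rng.standard_normal((40, 4)), 1.0)
        C_p, static = build_participant_dfc(ts, WindowSpec(40, 5))
        assert C_p.shape == (6, 1)
        np.testing.assert_allclose(C_p, 0.0, atol=1e-14)

    def test_zero_row_means_and_idempotence(self, rng):
        ts = ParcelTimeSeries(rng.standard_normal((140, 5)), 1.0)
        C_p, _ = build_participant_dfc(ts, WindowSpec(40, 5))
        assert np.abs(C_p.mean(axis=1)).max() < 1e-12
        # re-subtracting the (now zero) mean changes nothing
        np.testing.assert_allclose(C_p - C_p.mean(axis=1, keepdims=True), C_p)

    def test_group_concatenation_slices(self, rng):
        w = WindowSpec(40, 5)
        parts = []
        for _ in range(2):
            ts = ParcelTimeSeries(rng.standard_normal((85, 4)), 1.0)
            parts.append(build_participant_dfc(ts, w))
        ds = concat_group(parts, 4, w)
        assert ds.T == 20 and ds.M == 6
        assert ds.participant_slices == [slice(0, 10), slice(10, 20)]
        for sl in ds.participant_slices:
            assert np.abs(ds.C[:, sl].mean(axis=1)).max() < 1e-12

    def test_parcel_count_mismatch_rejected(self, rng):
        w = WindowSpec(40, 5)
        ts = ParcelTimeSeries(rng.standard_normal((40, 3)), 1.0)
        with pytest.raises(ValueError):
            concat_group([build_participant_dfc(ts, w)], 4, w)


class TestPlantedStateRecoveryByWindows:
    def test_noiseless_single_state_window_matches_planted(self):
        """Window correlation of a single-state segment converges on the
        planted matrix (long window, small R, so the estimator noise floor
        1/sqrt(n) sits below the tolerance)."""
        S = synth.community_matrix(4, [[0, 1]], 0.8)
        S = 0.9 * S + 0.1 * np.eye(4)
        truth = synth.GroundTruth(
            state_matrices=[S], weight_course=np.ones((1, 2000)), seed=0
        )
        latent = synth.gen_latent_series(truth)
        corr = sliding_window_corr(latent, WindowSpec(1000, 1000))
        assert np.abs(corr - S).max() < 0.15
        assert np.linalg.norm(corr[0] - S) < 0.3


class TestIO:
    def test_tsv_round_trip(self, rng, tmp_path):
        ts = ParcelTimeSeries(rng.standard_normal((30, 4)), 2.0, participant_id="sub-09")
        ts.to_tsv(tmp_path / "ts.tsv")
        back = ParcelTimeSeries.from_tsv(tmp_path / "ts.tsv")
        np.testing.assert_allclose(back.values, ts.values)
        assert back.sample_interval == 2.0 and back.participant_id == "sub-09"

    def test_dataset_hdf5_round_trip(self, rng, tmp_path):
        w = WindowSpec(40, 5)
        ts = ParcelTimeSeries(rng.standard_normal((85, 4)), 1.0)
        ds = concat_group([build_participant_dfc(ts, w)], 4, w)
        ds.to_hdf5(tmp_path / "dfc.h5")
        back = dfc.DFCDataset.from_hdf5(tmp_path / "dfc.h5")
        np.testing.assert_allclose(back.C, ds.C)
        assert back.window_spec == w and back.participant_slices == ds.participant_slices
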