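import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emophys import features as feat
from emophys.wavedet import FiducialSeries

finite_series = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2,
    max_size=40)


class TestStats6:
    def test_hand_arithmetic(self):
        out = feat.stats6([1, 2, 3])
        assert out == {"mean": 2.0, "median": 2.0, "std": 1.0, "min": 1.0,
                       "max": 3.0, "range": 2.0}

    def test_singleton_has_zero_spread(self):
        out = feat.stats6([2.0])
        assert out["std"] == 0.0 and out["range"] == 0.0 and out["mean"] == 2.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(finite_series)
    def test_matches_brute_force(self, xs):
        """stats6 agrees with a direct elementwise recomputation."""
        out = feat.stats6(xs)
        n = len(xs)
        mean = sum(xs) / n
        var = sum((v - mean) ** 2 for v in xs) / (n - 1)
        assert out["mean"] == pytest.approx(mean, rel=1e-9, abs=1e-9)
        assert out["std"] == pytest.approx(var**0.5, rel=1e-6, abs=1e-6)
        assert out["range"] == pytest.approx(max(xs) - min(xs))
        assert out["range"] >= 0 and out["std"] >= 0


class TestStats7:
    def test_constant_series_ratios_are_one(self):
        out = feat.stats7([4.0, 4.0, 4.0])
        assert out["minRatio"] == 1.0 and out["maxRatio"] == 1.0

    def test_hand_count(self):
        out = feat.stats7([0.0, 0.0, 0.0, 10.0])
        assert out["minRatio"] == 0.75 and out["maxRatio"] == 0.25

    def test_linear_ramp_band_occupancy(self):
        # range 9, closed band of width 0.9 above min holds only the minimum
        out = feat.stats7(list(range(10)))
        assert out["minRatio"] == 0.1 and out["maxRatio"] == 0.1

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(finite_series)
    def test_matches_brute_force_band_count(self, xs):
        out = feat.stats7(xs)
        lo, hi = min(xs), max(xs)
        band = 0.1 * (hi - lo)
        assert out["minRatio"] == pytest.approx(
            sum(v <= lo + band for v in xs) / len(xs))
        assert out["maxRatio"] == pytest.approx(
            sum(v >= hi - band for v in xs) / len(xs))


class TestIntervals:
    def _fiducials(self):
        # two beats: R at 200 and 400 samples; P/Q/S/T at template offsets
        idx = {"R": np.array([200, 400]), "P": np.array([160, 360]),
               "Q": np.array([192, 392]), "S": np.array([208, 408]),
               "T": np.array([250, 450])}
        amps = {w: np.ones(2) for w in idx}
        return FiducialSeries(kind="ecg", indices=idx, amplitudes=amps, fs=200.0)

    def test_same_wave_and_within_beat_intervals(self):
        out = feat.intervals_from_fiducials(self._fiducials(), 200.0)
        np.testing.assert_allclose(out["RR"], [1000.0])
        np.testing.assert_allclose(out["PQ"], [160.0, 160.0])
        np.testing.assert_allclose(out["QS"], [80.0, 80.0])
        np.testing.assert_allclose(out["ST"], [210.0, 210.0])

    def test_single_beat_rejected(self):
        fid = self._fiducials()
        single = FiducialSeries(kind="ecg",
                                indices={w: v[:1] for w, v in fid.indices.items()},
                                amplitudes={w: v[:1] for w, v in fid.amplitudes.items()},
                                fs=200.0)
        with pytest.raises(ValueError):
            feat.intervals_from_fiducials(single, 200.0)


class TestPNN50:
    def test_hand_enumeration(self):
        assert feat.pnn50([800, 860, 865, 800]) == pytest.approx(2 / 3)

    def test_constant_is_zero(self):
        assert feat.pnn50([800, 800, 800]) == 0.0

    def test_strict_inequality_at_exactly_50ms(self):
        assert feat.pnn50([800, 850]) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=300, max_value=2000), min_size=2,
                    max_size=30))
    def test_bounded_in_unit_interval(self, rr):
        assert 0.0 <= feat.pnn50(rr) <= 1.0


class TestTriangularIndex:
    def test_identical_intervals(self):
        assert feat.triangular_index([800.0] * 10) == 1.0

    def test_hand_histogram(self):
        assert feat.triangular_index([800.0] * 6 + [900.0] * 3) == 1.5

    def test_single_interval(self):
        assert feat.triangular_index([750.0]) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=300, max_value=2000), min_size=1,
                    max_size=30))
    def test_at_least_one(self, rr):
        assert feat.triangular_index(rr) >= 1.0


class TestHRVFeatures:
    def test_constant_tachogram_has_zero_spectral_mean(self):
        out = feat.hrv_features([800.0] * 20)
        assert out["freqmean"] == pytest.approx(0.0, abs=1e-9)
        assert out["pNN50"] == 0.0

    def test_composes_stats6(self):
        rr = [700.0, 800.0, 900.0, 750.0]
        out = feat.hrv_features(rr)
        for key, val in feat.stats6(rr).items():
            assert out[key] == val

    def test_distribution_stats_over_nonzero_bins(self):
        out = feat.hrv_distribution_features([800.0] * 10)
        assert out["mean"] == 10.0 and out["std"] == 0.0 and out["Triind"] == 1.0
        two_bins = feat.hrv_distribution_features([800.0] * 5 + [900.0] * 5)
        assert two_bins["mean"] == 5.0 and two_bins["range"] == 0.0
        assert two_bins["Triind"] == 2.0


class TestCatalog:
    def test_column_counts_per_signal(self):
        cols = feat.feature_columns()
        assert len(cols) == 136
        assert sum(c.startswith("ECG_") for c in cols) == 81
        assert sum(c.startswith("GSR_") for c in cols) == 21
        assert sum(c.startswith("EMG_") for c in cols) == 21
        assert sum(c.startswith("PPG_") for c in cols) == 13

    def test_diff_stack_on_linear_ramp(self):
        out = feat.diff_stack_features(np.arange(50, dtype=float), "GSR")
        assert len(out) == 21
        assert out["GSR_1Diff_std"] == 0.0
        assert out["GSR_2Diff_minRatio"] == 1.0  # constant zero second diff

    def test_fuse_requires_all_channels(self):
        partial = {c: 0.0 for c in feat.feature_columns()
                   if not c.startswith("PPG_")}
        with pytest.raises(ValueError):
            feat.fuse({"seg0": partial}, {"seg0": "fear"})

    def test_fused_table_shape_and_order(self, small_feature_table):
        assert small_feature_table.shape[1] == 137  # 136 features + label
        assert list(small_feature_table.columns[:-1]) == feat.feature_columns()
        assert small_feature_table.columns[-1] == "emotion"

    def test_zero_jitter_segment_recovers_generator_interval(self):
        """On noise-free data the RR mean equals the programmed beat spacing."""
        from emophys.synthgen import EmotionRegime, generate_ecg
        from emophys.wavedet import detect_ecg_fiducials, remove_baseline
        reg = EmotionRegime("sadness", hr_mean=60, hr_sd=0, scr_rate=0,
                            gsr_tonic=5, emg_burst_rate=0, emg_gain=1)
        x, _ = generate_ecg(30, 200.0, reg, drift_amp=0.0, noise_sd=0.0, seed=1)
        fid = detect_ecg_fiducials(remove_baseline(x), 200.0)
        out = feat.ecg_features(fid, 200.0)
        assert out["ECG_RR_mean"] == pytest.approx(1000.0, abs=5.0)
        assert out["ECG_RR_std"] == pytest.approx(0.0, abs=5.0)


class TestVarianceFilter:
    def _table(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "const": np.ones(40),
            "bernoulli": np.tile([0.0, 1.0], 20),
            "wide": rng.normal(0, 10, 40),
        })
        df["emotion"] = "fear"
        return df

    def test_constant_dropped_bernoulli_kept(self):
        kept, mask = feat.variance_filter(self._table())
        assert "const" not in kept.columns
        assert "bernoulli" in kept.columns  # variance 0.25 >= 0.16
        assert mask.tolist() == [False, True, True]

    def test_zero_threshold_keeps_everything(self):
        kept, _ = feat.variance_filter(self._table(), threshold=0.0)
        assert kept.shape[1] == 4

    def test_mask_reapplies_to_new_table(self):
        table = self._table()
        _, mask = feat.variance_filter(table)
        out = feat.apply_mask(table, mask)
        assert list(out.columns) == ["bernoulli", "wide", "emotion"]
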