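import numpy as np
import pandas as pd
import pytest

from actisurv import features as feat
from actisurv.simulate import FEATURE_NAMES

from conftest import constructed_trace


def rle_oracle(labels):
    """Brute-force run-length encoding, epoch by epoch."""
    runs = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] += 1
        else:
            runs.append([lab, i, 1])
    return [r for r in runs if r[0] >= 0]


class TestClassifyEpochs:
    @pytest.mark.parametrize("a,expected", [
        (39.99, 0), (40.0, 1), (99.99, 1), (100.0, 2), (0.0, 0)])
    def test_boundary_semantics(self, a, expected):
        assert feat.classify_epochs(np.array([a]))[0] == expected

    def test_all_zero_trace_is_all_sb(self):
        assert (feat.classify_epochs(np.zeros(100)) == 0).all()

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            feat.classify_epochs(np.zeros(5), sb_threshold=40,
                                 mvpa_threshold=40)

    def test_negative_acceleration_names_epoch(self):
        with pytest.raises(ValueError, match="epoch 3"):
            feat.classify_epochs(np.array([1.0, 2.0, 3.0, -0.5]))

    def test_non_waking_epochs_masked(self):
        labels = feat.classify_epochs(np.array([10.0, 50.0, 120.0]),
                                      waking=np.array([1, 0, 1]))
        assert list(labels) == [0, -1, 2]


class TestDetectBouts:
    def test_simple_runs(self):
        labels = np.array([0] * 10 + [1] * 5 + [0] * 3)
        b = feat.detect_bouts(labels)
        assert list(b["length"]) == [10, 5, 3]
        assert list(b["state"]) == [0, 1, 0]
        assert list(b["start"]) == [0, 10, 15]

    def test_single_epoch_alternation(self):
        b = feat.detect_bouts(np.array([0, 1, 0]))
        assert list(b["length"]) == [1, 1, 1]

    def test_matches_rle_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            labels = rng.integers(-1, 3, size=rng.integers(1, 300))
            got = feat.detect_bouts(labels)
            exp = rle_oracle(labels)
            assert [list(r) for r in
                    got[["state", "start", "length"]].to_numpy()] == exp

    def test_non_waking_gap_splits_bouts(self):
        b = feat.detect_bouts(np.array([0, 0, -1, 0, 0]))
        assert list(b["length"]) == [2, 2]


class TestExtractFeatures:
    def test_constructed_trace_arithmetic(self):
        fv = feat.extract_features(constructed_trace())
        assert fv["dur_SB"] == 600 and fv["dur_LIPA"] == 300
        assert fv["dur_MVPA"] == 60
        assert fv["mean_bout_SB"] == 600
        assert fv["sb_ge30"] == 600 and fv["sb_lt10"] == 0
        assert fv["mvpa_ge10"] == 60 and fv["mvpa_lt10"] == 0
        assert fv["n_bouts_SB"] == fv["n_bouts_LIPA"] == fv["n_bouts_MVPA"] == 1
        assert fv["days_mvpa30"] == 1
        assert fv["mean_acceleration"] == pytest.approx(40.625, abs=1e-12)

    def test_sb_category_boundaries(self):
        def trace(sb_len):
            enmo = np.concatenate([np.full(sb_len, 10.0), np.full(400, 60.0)])
            return pd.DataFrame({"participant_id": 0, "day_index": 0,
                                 "epoch_index": np.arange(enmo.size),
                                 "enmo_mg": enmo, "waking": 1})
        fv29 = feat.extract_features(trace(29))
        assert fv29["sb_10_30"] == 29 and fv29["sb_ge30"] == 0
        fv30 = feat.extract_features(trace(30))
        assert fv30["sb_ge30"] == 30 and fv30["sb_10_30"] == 0

    def test_invariants_on_random_traces(self, rng):
        """Tiling, category additivity and mean*count identities."""
        for _ in range(50):
            n_days = int(rng.integers(1, 4))
            frames = []
            for d in range(n_days):
                waking = int(rng.integers(400, 900))
                labels = rng.integers(0, 3, waking)
                enmo = np.where(labels == 0, rng.uniform(0, 40, waking),
                                np.where(labels == 1,
                                         rng.uniform(40, 100, waking),
                                         rng.uniform(100, 400, waking)))
                frames.append(pd.DataFrame({
                    "participant_id": 0, "day_index": d,
                    "epoch_index": np.arange(waking), "enmo_mg": enmo,
                    "waking": 1}))
            fv = feat.extract_features(pd.concat(frames))
            total = fv["dur_SB"] + fv["dur_LIPA"] + fv["dur_MVPA"]
            assert total == pytest.approx(fv["waking_minutes"], abs=1e-9)
            assert fv["sb_lt10"] + fv["sb_10_30"] + fv["sb_ge30"] == \
                pytest.approx(fv["dur_SB"], abs=1e-9)
            assert fv["lipa_lt10"] + fv["lipa_ge10"] == \
                pytest.approx(fv["dur_LIPA"], abs=1e-9)
            assert fv["mvpa_lt10"] + fv["mvpa_ge10"] == \
                pytest.approx(fv["dur_MVPA"], abs=1e-9)
            for s in ("SB", "LIPA", "MVPA"):
                # ratio-of-sums mean bout duration: mean*count = duration
                assert fv[f"mean_bout_{s}"] * fv[f"n_bouts_{s}"] == \
                    pytest.approx(fv[f"dur_{s}"], rel=1e-9)

    def test_invariant_to_day_order(self):
        base = constructed_trace()
        day2 = base.copy()
        day2["day_index"] = 1
        a = feat.extract_features(pd.concat([base, day2]))
        b = feat.extract_features(pd.concat([day2, base]))
        pd.testing.assert_series_equal(a, b)

    def test_no_waking_days_rejected(self):
        df = constructed_trace()
        df["waking"] = 0
        with pytest.raises(ValueError):
            feat.extract_features(df)


class TestIntensityDistribution:
    def test_power_law_trace_recovers_gradient(self):
        # minutes per bin proportional to midpoint^-2 over bins 0-500 mg
        mids = np.arange(12.5, 500, 25.0)
        minutes = np.round(2e5 * mids ** -2.0).astype(int)
        enmo = np.concatenate([np.full(m, mid) for mid, m in
                               zip(mids, minutes)])
        intercept, gradient = feat.intensity_distribution([enmo])
        assert gradient == pytest.approx(-2.0, abs=0.05)

    def test_two_bin_slope_is_two_point_formula(self):
        enmo = np.concatenate([np.full(100, 10.0), np.full(25, 60.0)])
        intercept, gradient = feat.intensity_distribution([enmo])
        expected = (np.log(25) - np.log(100)) / (np.log(62.5) - np.log(12.5))
        assert gradient == pytest.approx(expected, abs=1e-12)
        assert intercept == pytest.approx(
            np.log(100) - expected * np.log(12.5), abs=1e-9)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            feat.intensity_distribution([np.full(100, 10.0)])


class TestTimingM5:
    def test_constructed_trace_window(self):
        # most active 300-epoch window starts at epoch 660 (0-based)
        fv = feat.extract_features(constructed_trace())
        assert fv["timing_pa"] == pytest.approx(660 / 60.0)

    def test_constant_day_ties_break_earliest(self):
        assert feat.timing_m5([np.full(400, 50.0)], [420]) == \
            pytest.approx(420 / 60.0)

    def test_high_block_found(self):
        enmo = np.full(600, 5.0)
        enmo[200:500] = 200.0
        assert feat.timing_m5([enmo], [0]) == pytest.approx(200 / 60.0)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(100):
            n = int(rng.integers(300, 700))
            enmo = rng.uniform(0, 300, n)
            got = feat.timing_m5([enmo], [0])
            sums = [enmo[i:i + 300].sum() for i in range(n - 300 + 1)]
            assert got == pytest.approx(int(np.argmax(sums)) / 60.0)

    def test_short_days_rejected(self):
        with pytest.raises(ValueError):
            feat.timing_m5([np.ones(100)], [0])


class TestStandardizeByWaking:
    def test_identity_at_reference(self):
        fv = feat.extract_features(constructed_trace())
        out = feat.standardize_by_waking(fv, reference_minutes=960.0)
        pd.testing.assert_series_equal(out, fv)

    def test_double_waking_halves_durations(self):
        fv = feat.extract_features(constructed_trace())
        out = feat.standardize_by_waking(fv, reference_minutes=480.0)
        assert out["dur_SB"] == fv["dur_SB"] / 2
        assert out["n_bouts_MVPA"] == fv["n_bouts_MVPA"] / 2
        assert out["dur_SB"] + out["dur_LIPA"] + out["dur_MVPA"] == \
            pytest.approx(480.0)
        assert out["mean_acceleration"] == fv["mean_acceleration"]
        assert out["timing_pa"] == fv["timing_pa"]

    def test_invariants_preserved(self, rng):
        fv = feat.extract_features(constructed_trace())
        for _ in range(20):
            ref = float(rng.uniform(300, 1200))
            out = feat.standardize_by_waking(fv, reference_minutes=ref)
            assert out["sb_lt10"] + out["sb_10_30"] + out["sb_ge30"] == \
                pytest.approx(out["dur_SB"], rel=1e-12)

    def test_nonpositive_waking_rejected(self):
        fv = feat.extract_features(constructed_trace())
        fv["waking_minutes"] = 0.0
        with pytest.raises(ValueError):
            feat.standardize_by_waking(fv)
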