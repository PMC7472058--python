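import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actichild import (
    BASE_FEATURES,
    TEMPORAL_FEATURES,
    UsageError,
    base_features,
    build_feature_table,
    dominant_frequency,
    temporal_features,
    vector_magnitude,
)
from actichild.windowing import LabeledWindow

import _oracles
from conftest import make_log, make_recording


def random_window(rng, n=None):
    n = n or int(rng.integers(20, 300))
    kind = rng.integers(3)
    if kind == 0:  # noise around gravity
        s = rng.normal(0, rng.uniform(0.01, 0.5), size=(n, 3))
        s[:, 2] += 1
    elif kind == 1:  # periodic + noise
        t = np.arange(n) / 100.0
        f = rng.uniform(0.5, 4.5)
        s = rng.normal(0, 0.1, size=(n, 3))
        s[:, 2] += 1 + rng.uniform(0.1, 1.0) * np.sin(2 * np.pi * f * t)
    else:  # near-constant
        s = np.full((n, 3), rng.uniform(-1, 1, size=3))
        s += rng.normal(0, 1e-6, size=(n, 3))
    return s


def as_window(samples, idx=0):
    return LabeledWindow("s", "hip", idx, len(samples) / 100.0, samples, "SED", False, 1.0)


class TestVectorMagnitude:
    @pytest.mark.parametrize(
        "xyz,expected", [((3, 4, 0), 5.0), ((0, 0, 1), 1.0), ((0, 0, 0), 0.0)]
    )
    def test_pythagoras(self, xyz, expected):
        assert vector_magnitude(np.array([xyz], float))[0] == pytest.approx(expected)


class TestBaseFeatures:
    def test_constant_signal(self):
        s = np.zeros((400, 3))
        s[:, 2] = 1.0
        f = base_features(s, 100)
        assert f["vm_mean"] == 1.0
        assert f["vm_sd"] == 0.0
        assert f["vm_iqr"] == 0.0
        assert f["vm_p2p"] == 0.0
        assert f["vm_median_crossings"] == 0.0
        assert f["vm_cv"] == 0.0
        assert f["corr_xy"] == 0.0  # zero-variance axes
        assert f["dom_freq_mag"] == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_dominant_frequency(self):
        t = np.arange(1000) / 100.0
        s = np.zeros((1000, 3))
        s[:, 2] = 1.2 + np.sin(2 * np.pi * 2.0 * t)
        f = base_features(s, 100)
        assert f["dom_freq_hz"] == pytest.approx(2.0, abs=100 / 1024)
        # peak magnitude ~ the sinusoid amplitude up to scalloping loss
        # (worst case 2/pi for a rectangular window between bins)
        assert 0.6 <= f["dom_freq_mag"] <= 1.05

    def test_agrees_with_bruteforce(self, rng):
        for _ in range(50):
            s = random_window(rng)
            ours = base_features(s, 100)
            ref = _oracles.base_features_bruteforce(s, 100)
            for name in BASE_FEATURES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-9), name

    def test_percentile_ordering_and_identities(self, rng):
        for _ in range(50):
            f = base_features(random_window(rng), 100)
            assert (
                f["vm_min"] <= f["vm_p10"] <= f["vm_p25"] <= f["vm_p50"]
                <= f["vm_p75"] <= f["vm_p95"] <= f["vm_max"]
            )
            assert f["vm_iqr"] == pytest.approx(f["vm_p75"] - f["vm_p25"])
            assert f["vm_p2p"] == pytest.approx(f["vm_max"] - f["vm_min"])
            assert -1 <= f["corr_xy"] <= 1
            assert 0.25 <= f["dom_freq_hz"] <= 5.0

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scale_equivariance(self, scale, seed):
        s = random_window(np.random.default_rng(seed), n=128)
        f1 = base_features(s, 100)
        f2 = base_features(scale * s, 100)
        for name in ("vm_mean", "vm_sd", "vm_sum", "vm_p2p"):
            assert f2[name] == pytest.approx(scale * f1[name], rel=1e-9)
        assert f2["vm_power"] == pytest.approx(scale**2 * f1["vm_power"], rel=1e-9)
        for name in ("vm_cv", "vm_median_crossings", "dom_freq_hz"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-9)
        for name in ("corr_xy", "corr_xz", "corr_yz"):
            # correlations are bounded in [-1, 1]; near-constant axes lose
            # relative precision to cancellation, so compare absolutely
            assert f2[name] == pytest.approx(f1[name], abs=1e-6)


class TestDominantFrequency:
    def test_three_hz_sinusoid(self):
        t = np.arange(1000) / 100.0
        vm = 1.0 + 0.5 * np.sin(2 * np.pi * 3.0 * t)
        hz, mag = dominant_frequency(vm, 100)
        assert hz == pytest.approx(3.0, abs=100 / 1024)

    def test_white_noise_stays_in_band(self, rng):
        for _ in range(20):
            hz, _ = dominant_frequency(rng.normal(size=200), 100)
            assert 0.25 <= hz <= 5.0

    def test_constant_signal_low_frequency_tiebreak(self):
        hz, mag = dominant_frequency(np.ones(100), 100)
        assert mag == 0.0
        # lowest representable in-band frequency at nfft=1024
        assert hz == pytest.approx(np.ceil(0.25 * 1024 / 100) * 100 / 1024)

    def test_low_rate_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="actichild.features"):
            dominant_frequency(np.random.default_rng(0).normal(size=50), 8.0)
        assert any("band" in r.message for r in caplog.records)


class TestTemporalFeatures:
    def test_constant_everywhere_gives_zeros(self):
        s = np.zeros((100, 3))
        s[:, 2] = 1.0
        seq = [as_window(s, i) for i in range(5)]
        f = temporal_features(seq, 2)
        assert all(f[name] == 0.0 for name in TEMPORAL_FEATURES)

    def test_sd_5win_population_formula(self):
        # per-window VM means 1..5 -> population SD sqrt(2)
        seq = []
        for i, level in enumerate([1, 2, 3, 4, 5]):
            s = np.zeros((100, 3))
            s[:, 2] = level
            seq.append(as_window(s, i))
        f = temporal_features(seq, 2)
        assert f["sd_5win"] == pytest.approx(np.sqrt(2.0))

    def test_edge_replication(self, rng):
        seq = [as_window(random_window(rng, n=100), i) for i in range(4)]
        f = temporal_features(seq, 0)
        own_sd = vector_magnitude(seq[0].samples).std()
        assert f["sd_lag1"] == pytest.approx(own_sd)
        assert f["sd_lag2"] == pytest.approx(own_sd)

    def test_time_reversal_swaps_lag_and_lead(self, rng):
        seq = [as_window(random_window(rng, n=80), i) for i in range(7)]
        fwd = temporal_features(seq, 3)
        rev = temporal_features(list(reversed(seq)), 3)
        assert fwd["sd_lag1"] == pytest.approx(rev["sd_lead1"])
        assert fwd["sd_lag2"] == pytest.approx(rev["sd_lead2"])
        assert fwd["sd_5win"] == pytest.approx(rev["sd_5win"])

    def test_agrees_with_bruteforce(self, rng):
        seq = [as_window(random_window(rng, n=60), i) for i in range(6)]
        vms = [list(vector_magnitude(w.samples)) for w in seq]
        for i in range(6):
            ours = temporal_features(seq, i)
            ref = _oracles.temporal_features_bruteforce(vms, i)
            for name in TEMPORAL_FEATURES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-9), name

    def test_pooled_samples_variant(self, rng):
        seq = [as_window(random_window(rng, n=60), i) for i in range(5)]
        f = temporal_features(seq, 2, five_window_sd="pooled_samples")
        pooled = np.concatenate([vector_magnitude(w.samples) for w in seq])
        assert f["sd_5win"] == pytest.approx(pooled.std())

    def test_empty_sequence_rejected(self):
        with pytest.raises(UsageError):
            temporal_features([], 0)


class TestBuildFeatureTable:
    def test_row_and_column_counts(self):
        rec = make_recording(duration_s=60)
        log = make_log([(60, "WALK")])
        base = build_feature_table([rec], [log], window_s=10, include_temporal=False,
                                   placement="hip")
        assert len(base) == 6
        assert len(base.columns) == 5 + 20
        lag = build_feature_table([rec], [log], window_s=10, include_temporal=True,
                                  placement="hip")
        assert len(lag.columns) == 5 + 25

    def test_combined_placement_has_50_feature_columns(self):
        hip = make_recording(duration_s=60, placement="hip")
        wrist = make_recording(duration_s=60, placement="wrist", seed=9)
        log = make_log([(60, "RUN")])
        tbl = build_feature_table([hip, wrist], [log], window_s=10,
                                  include_temporal=True, placement="hip_wrist")
        feats = [c for c in tbl.columns if c.startswith(("hip_", "wrist_"))]
        assert len(feats) == 50
        assert len(tbl) == 6

    def test_excluded_windows_dropped_but_feed_neighbors(self):
        rec = make_recording(duration_s=30)
        log = make_log([(10, "WALK"), (10, "OUT_OF_VIEW"), (10, "RUN")])
        tbl = build_feature_table([rec], [log], window_s=10, include_temporal=True,
                                  placement="hip")
        assert list(tbl["window_index"]) == [0, 2]
        # lead-1 of window 0 is the excluded middle window's signal SD
        from actichild.windowing import segment
        from actichild import annotate_samples
        wins = segment(rec, annotate_samples(rec, log), 10)
        mid_sd = vector_magnitude(wins[1].samples).std()
        assert tbl.iloc[0]["sd_lead1"] == pytest.approx(mid_sd)
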