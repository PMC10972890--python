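import numpy as np
import pandas as pd
import pytest

from microstatekit import (
    LabelSequence,
    Recording,
    SmoothingParams,
    SynthConfig,
    ValidationError,
    band_power,
    class_parameters,
    feature_column_names,
    make_templates,
    segmentize,
    simulate_recording,
    transition_matrix,
    windowed_feature_table,
)

from oracles import class_parameters_direct, transition_counts


def _seq(labels, fs=200.0, corr=None, gfp=None):
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    corr = np.ones(n) if corr is None else np.asarray(corr, float)
    gfp = np.ones(n) if gfp is None else np.asarray(gfp, float)
    return LabelSequence(labels, corr, gfp, fs)


class TestClassParameters:
    def test_single_segment_window(self):
        seq = _seq(np.ones(2000, dtype=int), fs=200.0)
        p = class_parameters(seq, segmentize(seq), K=3)
        np.testing.assert_allclose(p.coverage, [1.0, 0.0, 0.0])
        assert p.duration_ms[0] == pytest.approx(10000.0)
        assert p.occurrence[0] == pytest.approx(0.1)
        assert not p.present[1] and not p.present[2]

    def test_perfect_fit_spatial_parameters(self, rng):
        labels = rng.integers(1, 4, 400)
        seq = _seq(labels, corr=np.ones(400), gfp=rng.uniform(0.5, 2, 400))
        p = class_parameters(seq, segmentize(seq), K=3)
        np.testing.assert_allclose(p.mspatcorr[p.present], 1.0)
        assert p.gev.sum() == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        labels = rng.integers(1, 5, 600)
        corr = rng.uniform(-1, 1, 600)
        gfp = rng.uniform(0.1, 3, 600)
        seq = _seq(labels, fs=250.0, corr=corr, gfp=gfp)
        p = class_parameters(seq, segmentize(seq), K=4)
        expected = class_parameters_direct(labels, corr, gfp, 250.0, 4)
        for k in range(1, 5):
            e = expected[k]
            assert p.occurrence[k - 1] == pytest.approx(e["occurrence"], abs=1e-9)
            assert p.duration_ms[k - 1] == pytest.approx(e["duration"], abs=1e-9)
            assert p.coverage[k - 1] == pytest.approx(e["coverage"], abs=1e-9)
            assert p.gev[k - 1] == pytest.approx(e["gev"], abs=1e-9)
            assert p.gfp[k - 1] == pytest.approx(e["gfp"], abs=1e-9)
            assert p.mspatcorr[k - 1] == pytest.approx(e["mspatcorr"], abs=1e-9)

    def test_coverage_occurrence_duration_identity(self, rng):
        labels = rng.integers(1, 4, 1000)
        seq = _seq(labels, fs=200.0)
        p = class_parameters(seq, segmentize(seq), K=3)
        assert p.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        window_s = 1000 / 200.0
        for k in range(3):
            identity = p.occurrence[k] * p.duration_ms[k] / 1000.0
            assert identity == pytest.approx(p.coverage[k], rel=1e-6)


class TestTransitionMatrix:
    def test_two_state_alternation(self):
        seq = _seq([1, 1, 2, 2, 1, 1, 2, 2], fs=100.0)
        t = transition_matrix(segmentize(seq), K=2)
        np.testing.assert_allclose(t, [[0, 1], [1, 0]])

    def test_three_state_cycle_hand_count(self):
        seq = _seq([1, 2, 3, 1, 2, 3], fs=100.0)
        t = transition_matrix(segmentize(seq), K=3)
        expected = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        np.testing.assert_allclose(t, expected)

    def test_matches_counting_oracle(self, rng):
        seg_labels = [int(rng.integers(1, 5))]
        while len(seg_labels) < 50:
            nxt = int(rng.integers(1, 5))
            if nxt != seg_labels[-1]:
                seg_labels.append(nxt)
        labels = np.repeat(seg_labels, rng.integers(1, 4, size=50))
        seq = _seq(labels, fs=100.0)
        t = transition_matrix(segmentize(seq), K=4)
        np.testing.assert_allclose(t, transition_counts(seg_labels, 4), atol=1e-12)

    def test_rows_stochastic_with_zero_diagonal(self, rng):
        labels = rng.integers(1, 6, 500)
        t = transition_matrix(segmentize(_seq(labels)), K=5)
        np.testing.assert_allclose(np.diag(t), 0.0)
        sums = t.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))

    def test_single_segment_all_zero(self):
        t = transition_matrix(segmentize(_seq(np.ones(10, dtype=int))), K=3)
        np.testing.assert_allclose(t, 0.0)


@pytest.fixture(scope="module")
def sim_62():
    cfg = SynthConfig(K_true=10, C=62, fs=100.0, duration_s=178.0, seed=5)
    rec, _, _, tpl = simulate_recording(cfg)
    return rec, tpl


class TestWindowedFeatureTable:

    def test_trial_window_counts(self, sim_62):
        rec, tpl = sim_62
        params = SmoothingParams(mode="min_duration", min_duration_ms=30.0)
        table = windowed_feature_table(rec, tpl, 15.0, params)
        assert len(table) == 11  # 178 s // 15 s

        short = Recording(rec.data[:, : int(60 * rec.fs)], rec.fs,
                          rec.channel_names)
        table4 = windowed_feature_table(short, tpl, 15.0, params)
        assert len(table4) == 4  # 60 s // 15 s

    def test_feature_count_k10(self, sim_62):
        rec, tpl = sim_62
        params = SmoothingParams(mode="min_duration", min_duration_ms=30.0)
        table = windowed_feature_table(rec, tpl, 15.0, params)
        n_features = table.shape[1] - 1  # minus t_start_s annotation
        assert n_features == 160  # 4K + K^2 temporal (140) + 2K spatial (20)
        temporal = [c for c in table.columns
                    if not c.startswith(("gfp_", "mspatcorr_", "t_start"))]
        assert len(temporal) == 140

    def test_feature_count_k9_c32(self):
        cfg = SynthConfig(K_true=9, C=32, fs=100.0, duration_s=45.0, seed=6)
        rec, _, _, tpl = simulate_recording(cfg)
        params = SmoothingParams(mode="min_duration", min_duration_ms=30.0)
        table = windowed_feature_table(rec, tpl, 15.0, params)
        assert table.shape[1] - 1 == 135  # 117 temporal + 18 spatial
        no_spatial = windowed_feature_table(rec, tpl, 15.0, params,
                                            include_spatial=False)
        assert no_spatial.shape[1] - 1 == 117

    def test_column_formula_across_configs(self):
        for K in (2, 5, 9, 10):
            assert len(feature_column_names(K, True)) == 4 * K + K**2 + 2 * K
            assert len(feature_column_names(K, False)) == 4 * K + K**2

    def test_no_complete_window_rejected(self, sim_62):
        rec, tpl = sim_62
        short = Recording(rec.data[:, :300], rec.fs, rec.channel_names)
        with pytest.raises(ValidationError):
            windowed_feature_table(short, tpl, 15.0)


class TestBandPower:
    def test_pure_alpha_tone(self):
        fs = 200.0
        t = np.arange(int(20 * fs)) / fs
        tone = 30 * np.sin(2 * np.pi * 10 * t)
        rec = Recording(np.vstack([tone, -tone]), fs, ["a", "b"])
        table = band_power(rec)
        total = sum(table[f"{b}_a"].iloc[0]
                    for b in ("delta", "theta", "alpha", "beta", "gamma"))
        assert table["alpha_a"].iloc[0] / total > 0.90

    def test_62_channels_gives_310_columns(self, rng):
        rec = Recording(rng.normal(size=(62, 1000)), 200.0,
                        [f"E{i}" for i in range(62)])
        assert band_power(rec).shape[1] == 310

    def test_white_noise_parseval(self, rng):
        fs = 200.0
        rec = Recording(rng.normal(0, 10, size=(2, int(60 * fs))), fs, ["a", "b"])
        from scipy import signal as sps

        sos = sps.butter(4, (1, 45), btype="bandpass", fs=fs, output="sos")
        filtered = sps.sosfiltfilt(sos, rec.data[0])
        table = band_power(rec)
        total = sum(table[f"{b}_a"].iloc[0]
                    for b in ("delta", "theta", "alpha", "beta", "gamma"))
        assert total == pytest.approx(np.var(filtered), rel=0.10)

    def test_short_window_rejected(self, rng):
        rec = Recording(rng.normal(size=(2, 100)), 200.0, ["a", "b"])
        with pytest.raises(ValidationError):
            band_power(rec)
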