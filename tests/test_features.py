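import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from wristhr.features import (
    NormStats,
    STAT_NAMES,
    WindowTable,
    accumulated_energy,
    apply_norm,
    feature_battery,
    feature_catalogue,
    featurize,
    fit_norm,
    fundamental_frequency,
    stat_battery,
)
from wristhr.preprocess import Window


def oracle_stats(x):
    """Direct-formula reference for the 14-statistic battery (scipy-based)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = np.std(x, ddof=1)
    if np.all(x == x[0]):
        skew = kurt = 0.0
    else:
        skew = ss.skew(x, bias=True)
        kurt = ss.kurtosis(x, fisher=False, bias=True)
    counts, edges = np.histogram(x, bins=10)
    b = np.argmax(counts)
    ax = np.abs(x) + 1e-9
    return np.array([
        np.mean(x), np.median(x), sd, np.mean(np.abs(x - np.mean(x))),
        np.percentile(x, 25), np.percentile(x, 75),
        np.percentile(x, 75) - np.percentile(x, 25), skew, kurt,
        (edges[b] + edges[b + 1]) / 2, ss.trim_mean(x, 0.10),
        ss.gmean(ax), ss.hmean(ax), np.var(x, ddof=1),
    ])


class TestCatalogue:
    def test_63_unique_columns(self):
        cat = feature_catalogue()
        assert len(cat) == 63
        assert len(set(cat)) == 63

    def test_signal_allocation(self):
        cat = feature_catalogue()
        assert sum(c.startswith("ppg_") for c in cat) == 18
        for sig in ("accel", "gyro", "temp"):
            assert sum(c.startswith(sig + "_") for c in cat) == 15


class TestStatBattery:
    def test_constant_window_conventions(self):
        out = stat_battery(np.full(50, 4.2))
        named = dict(zip(STAT_NAMES, out))
        for key in ("mean", "median", "trimmed_mean"):
            assert named[key] == pytest.approx(4.2)
        assert named["mode"] == pytest.approx(4.2, abs=0.5)
        for key in ("sd", "variance", "mad", "iqr", "skewness", "kurtosis"):
            assert named[key] == 0.0

    @given(st.integers(0, 2**31 - 1), st.sampled_from([20, 60, 120]))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_oracle(self, seed, n):
        x = np.random.default_rng(seed).normal(2.0, 3.0, size=n)
        got = stat_battery(x)
        want = oracle_stats(x)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_mean_scales_linearly(self, rng):
        x = rng.normal(size=120) + 1.0
        a = stat_battery(x)[0]
        b = stat_battery(3.0 * x)[0]
        assert b == pytest.approx(3.0 * a, rel=1e-12)


class TestSpectralFeatures:
    def test_energy_unit_impulse(self):
        # FFT of [1,0,0,0] is an all-ones spectrum; energy = 4
        assert accumulated_energy(np.array([1.0, 0.0, 0.0, 0.0])) == pytest.approx(4.0)

    def test_energy_matches_parseval(self, rng):
        x = rng.normal(size=120)
        assert accumulated_energy(x) == pytest.approx(len(x) * np.sum(x**2), rel=1e-9)

    def test_energy_scales_quadratically(self, rng):
        x = rng.normal(size=120)
        assert accumulated_energy(2.0 * x) == pytest.approx(
            4.0 * accumulated_energy(x), rel=1e-9)

    def test_fundamental_of_pure_sine(self):
        t = np.arange(120) / 20.0
        x = np.sin(2 * np.pi * 1.5 * t)
        f = fundamental_frequency(x, 20.0)
        assert f == pytest.approx(1.5, abs=20.0 / 2048)


class TestFeatureBattery:
    def _window(self, rng, ppg=None):
        return Window(
            t_start=0.0,
            ppg=ppg if ppg is not None else rng.normal(size=120),
            accel_norm=np.abs(rng.normal(size=60)),
            gyro_norm=np.abs(rng.normal(size=60)),
            temperature=34.0 + 0.01 * rng.normal(size=6),
            label_task=1,
            label_hr=70.0,
        )

    def test_vector_length_and_finiteness(self, rng):
        vec = feature_battery(self._window(rng))
        assert vec.shape == (63,)
        assert np.all(np.isfinite(vec))

    def test_start_time_does_not_matter(self, rng):
        w = self._window(rng)
        w2 = Window(**{**w.__dict__, "t_start": 123.0})
        assert np.array_equal(feature_battery(w), feature_battery(w2))

    def test_derivative_features(self):
        rng = np.random.default_rng(1)
        w = self._window(rng, ppg=np.arange(120, dtype=float))
        vec = feature_battery(w)
        cat = feature_catalogue()
        named = dict(zip(cat, vec))
        # linear ramp: first derivative = slope * fs, second = 0
        assert named["ppg_d1_mean"] == pytest.approx(20.0)
        assert named["ppg_d2_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_too_small_window_rejected(self, rng):
        w = self._window(rng)
        w.temperature = np.array([34.0])
        with pytest.raises(ValueError, match="too few"):
            feature_battery(w)

    def test_featurize_table_shape(self, short_windows):
        table = featurize(short_windows[:10])
        assert len(table) == 10
        assert table.features.shape == (10, 63)
        assert set(table.label_task) <= {1, 2, 3}


class TestNormalization:
    def _table(self, rng, n=40):
        df_windows = [
            Window(0.0, rng.normal(size=120), np.abs(rng.normal(size=60)),
                   np.abs(rng.normal(size=60)), 34 + 0.1 * rng.normal(size=6), 1, 70.0)
            for _ in range(n)
        ]
        return featurize(df_windows)

    def test_train_table_mean0_sd1(self, rng):
        table = self._table(rng)
        stats = fit_norm(table)
        normed = apply_norm(table, stats)
        feats = normed.features
        assert np.all(np.abs(feats.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(feats.std(axis=0, ddof=1) - 1.0) < 1e-10)

    def test_simple_column(self):
        import pandas as pd

        cat = ["f0"]
        df = pd.DataFrame({"f0": [1.0, 2.0, 3.0], "label_hr": [60.0] * 3,
                           "label_task": [1, 1, 1]})
        t = WindowTable(df, catalogue=cat)
        normed = apply_norm(t, fit_norm(t))
        col = normed.features[:, 0]
        assert np.mean(col) == pytest.approx(0.0, abs=1e-12)
        assert np.std(col, ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_constant_column_dropped_with_warning(self, caplog):
        import pandas as pd

        df = pd.DataFrame({"f0": [1.0, 2.0, 3.0], "f1": [5.0, 5.0, 5.0],
                           "label_hr": [60.0] * 3, "label_task": [1, 1, 1]})
        t = WindowTable(df, catalogue=["f0", "f1"])
        with caplog.at_level("WARNING"):
            stats = fit_norm(t)
        assert stats.names == ("f0",)
        assert "zero-variance" in caplog.text
        normed = apply_norm(t, stats)
        assert list(normed.catalogue) == ["f0"]

    def test_idempotent(self, rng):
        table = self._table(rng, n=30)
        once = apply_norm(table, fit_norm(table))
        twice = apply_norm(once, fit_norm(once))
        np.testing.assert_allclose(once.features, twice.features, atol=1e-10)

    def test_mismatched_catalogue_rejected(self, rng):
        table = self._table(rng, n=10)
        stats = NormStats(names=("nonexistent",), mean=np.zeros(1), sd=np.ones(1))
        with pytest.raises(ValueError, match="unknown columns"):
            apply_norm(table, stats)

    def test_test_table_uses_train_stats(self, rng):
        train, test = self._table(rng, 30), self._table(rng, 30)
        stats = fit_norm(train)
        normed_test = apply_norm(test, stats)
        # test-table columns are NOT exactly standardized (different sample)
        assert np.any(np.abs(normed_test.features.mean(axis=0)) > 1e-6)


class TestWindowTableValidation:
    def test_bad_task_label_rejected(self):
        import pandas as pd

        cat = feature_catalogue()
        df = pd.DataFrame(np.zeros((2, 63)), columns=cat)
        df["label_hr"] = 60.0
        df["label_task"] = [1, 7]
        with pytest.raises(ValueError, match="label_task"):
            WindowTable(df)

    def test_missing_column_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"label_hr": [60.0], "label_task": [1]})
        with pytest.raises(ValueError, match="missing columns"):
            WindowTable(df)
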