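import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affectsense.io_formats import FeatureTable, SignalRecord
from affectsense.preprocessing import (
    FilterSpec, SplitSpec, WindowSpec, apply_filter, drop_nonfeature_columns,
    inherit_labels, normalize_vad, denormalize_vad, segment_signal,
    stratified_split, zscore_apply, zscore_fit, zscore_signal,
)


def _table(n_rows, n_cols, labels=None, rng=None):
    rng = rng or np.random.default_rng(0)
    labels = labels if labels is not None else rng.integers(0, 3, n_rows)
    return FeatureTable([f"c{i}" for i in range(n_cols)],
                        rng.standard_normal((n_rows, n_cols)), labels)


class TestDropColumns:
    def test_drop_meta_columns_leaves_62(self):
        table = _table(10, 64)
        table.column_names[0] = "subject id"
        table.column_names[1] = "condition"
        out = drop_nonfeature_columns(table, ["subject id", "condition"])
        assert out.n_features == 62
        assert out.column_names == [f"c{i}" for i in range(2, 64)]

    def test_absent_name_warns_and_skips(self):
        table = _table(5, 3)
        with pytest.warns(UserWarning, match="not present"):
            out = drop_nonfeature_columns(table, ["ghost"])
        assert out.column_names == table.column_names

    def test_dropping_everything_errors(self):
        table = _table(5, 2)
        with pytest.raises(ValueError, match="zero feature columns"):
            drop_nonfeature_columns(table, ["c0", "c1"])


class TestZScore:
    def test_fit_apply_gives_zero_mean_unit_sd(self, rng):
        x = rng.standard_normal((100, 5)) * 3 + 2
        p = zscore_fit(x)
        z = zscore_apply(x, p)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0) - 1).max() < 1e-9

    def test_population_sd_convention(self):
        p = zscore_fit(np.array([[1.0], [2.0], [3.0]]))
        assert p.mu[0] == 2.0
        assert p.sigma[0] == pytest.approx(0.8165, abs=1e-4)
        z = zscore_apply(np.array([[1.0], [2.0], [3.0]]), p).ravel()
        np.testing.assert_allclose(z, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_feature_rejected(self):
        x = np.ones((10, 2))
        x[:, 1] = np.arange(10)
        with pytest.raises(ValueError, match="constant feature"):
            zscore_fit(x)

    def test_dimension_mismatch(self, rng):
        p = zscore_fit(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            zscore_apply(rng.standard_normal((4, 2)), p)

    def test_per_signal_mode(self, rng):
        x = rng.standard_normal(500) * 4 + 7
        z = zscore_signal(x)
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9


class TestStratifiedSplit:
    def test_study_scale_sizes(self):
        # 70/15/15 of 135,650 rows with floor conventions
        table = _table(135_650, 1)
        tr, va, te = stratified_split(table, SplitSpec(stratified=False, seed=0))
        assert (tr.n_rows, va.n_rows, te.n_rows) == (94_955, 20_347, 20_348)

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        table = _table(101, 2, rng=rng)
        table.values[:, 0] = np.arange(101)  # unique key per row
        tr, va, te = stratified_split(table, SplitSpec(seed=3))
        keys = np.concatenate([tr.values[:, 0], va.values[:, 0], te.values[:, 0]])
        assert len(keys) == 101
        assert len(np.unique(keys)) == 101

    def test_stratified_proportions_within_one_row(self):
        labels = np.repeat([0, 1], 10)
        table = _table(20, 2, labels=labels)
        tr, va, te = stratified_split(table, SplitSpec(seed=1))
        for part in (tr, va, te):
            counts = np.bincount(part.labels, minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_class_too_small_to_stratify(self):
        labels = np.array([0, 0, 0, 0, 1, 1])
        table = _table(6, 2, labels=labels)
        with pytest.raises(ValueError, match="too small"):
            stratified_split(table, SplitSpec(seed=0))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(train_frac=0.8, val_frac=0.15, test_frac=0.15)


class TestSegmentation:
    def test_study_window_counts(self):
        # 60 s at 128 Hz, 5 s windows, 50% overlap
        windows = segment_signal(np.arange(7680.0), WindowSpec(640, 320))
        assert windows.shape == (23, 640)
        np.testing.assert_array_equal(windows[1], np.arange(320.0, 960.0))

    def test_single_window_when_exact(self):
        x = np.arange(64.0)
        windows = segment_signal(x, WindowSpec(64, 32))
        np.testing.assert_array_equal(windows, x[None, :])

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter than window"):
            segment_signal(np.arange(63.0), WindowSpec(64, 32))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 400), st.integers(1, 100), st.integers(0, 300))
    def test_count_formula_property(self, w, s_raw, extra):
        s = min(s_raw, w)
        n = w + extra
        windows = segment_signal(np.zeros(n), WindowSpec(w, s))
        assert windows.shape == ((n - w) // s + 1, w)


class TestInheritLabels:
    def test_replication_with_provenance(self):
        out = inherit_labels((3.0, 4.0, 2.0), 23, subject_id="S01", trial_id=7)
        assert out["labels"].shape == (23, 3)
        assert np.all(out["labels"] == [3.0, 4.0, 2.0])
        assert np.all(out["trial_id"] == 7)
        assert np.all(out["subject_id"] == "S01")

    def test_zero_windows_empty(self):
        assert inherit_labels((1.0, 1.0, 1.0), 0)["labels"].shape == (0, 3)


class TestFilters:
    def test_notch_attenuates_mains(self, rng):
        t = np.arange(1280) / 128.0
        sine = np.sin(2 * np.pi * 50.0 * t)
        rec = SignalRecord(["x"], sine[None, :], 128.0)
        out = apply_filter(rec, FilterSpec(kind="notch", center_hz=50.0, q=30.0))
        rms_in = np.sqrt((sine ** 2).mean())
        rms_out = np.sqrt((out.data[0] ** 2).mean())
        assert rms_out < 0.05 * rms_in

    def test_bandpass_passes_in_band_signal(self):
        t = np.arange(2560) / 128.0
        sig = np.sin(2 * np.pi * 8.0 * t) + 0.5 * np.sin(2 * np.pi * 15.0 * t)
        rec = SignalRecord(["x"], sig[None, :], 128.0)
        out = apply_filter(rec, FilterSpec(kind="butterworth_bandpass",
                                           band_hz=(1.0, 40.0)))
        assert out.data.shape == rec.data.shape
        r = np.corrcoef(out.data[0], sig)[0, 1]
        assert r > 0.99

    def test_band_above_nyquist_rejected(self, two_channel_record):
        with pytest.raises(ValueError, match="invalid"):
            apply_filter(two_channel_record,
                         FilterSpec(kind="butterworth_bandpass", band_hz=(1.0, 70.0)))
        with pytest.raises(ValueError, match="invalid"):
            apply_filter(two_channel_record,
                         FilterSpec(kind="notch", center_hz=64.0))


class TestVadNormalization:
    @pytest.mark.parametrize("raw, expected", [
        ((1, 3, 5), (0.0, 0.5, 1.0)),
        ((5, 5, 5), (1.0, 1.0, 1.0)),
        ((1, 1, 1), (0.0, 0.0, 0.0)),
    ])
    def test_endpoints_and_midpoint(self, raw, expected):
        np.testing.assert_allclose(normalize_vad(raw), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_vad((0.5, 3.0, 3.0))

    @given(st.lists(st.floats(1.0, 5.0), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_denormalize_inverts(self, raw):
        np.testing.assert_allclose(denormalize_vad(normalize_vad(raw)), raw,
                                   atol=1e-12)
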