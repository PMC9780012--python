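"""Record ingestion, epoch slicing, the reconstructed feature table and its
index bookkeeping."""

import itertools
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physiostate.entropy import EntropyParams
from physiostate.exceptions import ConfigError, DataFormatError
from physiostate.features import (
    FeatureTable,
    MultichannelRecord,
    build_feature_table,
    count_feature_subsets,
    feature_channel_scale,
    feature_index,
    read_edf,
    read_feature_table,
    read_record,
    slice_epochs,
    write_feature_table,
    write_record,
)
from physiostate.synthetic import SignalGenConfig, gen_record


def small_record(n_epochs=4, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(["C1", "C2"] * (n_epochs // 2), dtype=object)[:n_epochs]
    return MultichannelRecord(
        channel_names=["a", "b"],
        samples={
            "a": rng.standard_normal(n_epochs * 20),
            "b": rng.standard_normal(n_epochs * 60),
        },
        rates={"a": 2.0, "b": 6.0},
        epoch_len_s=10.0,
        labels=labels,
    )


class TestRecordValidation:
    def test_bad_label_rejected(self):
        with pytest.raises(DataFormatError, match="labels"):
            MultichannelRecord(["a"], {"a": np.zeros(20)}, {"a": 2.0}, 10.0,
                               np.array(["C1", "C3"], dtype=object))

    def test_duration_mismatch_rejected(self):
        with pytest.raises(DataFormatError, match="spans"):
            MultichannelRecord(
                ["a", "b"],
                {"a": np.zeros(20), "b": np.zeros(90)},
                {"a": 2.0, "b": 6.0},
                10.0,
                np.array(["C1"], dtype=object),
            )

    def test_label_count_must_match_epochs(self):
        with pytest.raises(DataFormatError, match="labels"):
            MultichannelRecord(["a"], {"a": np.zeros(40)}, {"a": 2.0}, 10.0,
                               np.array(["C1"], dtype=object))


class TestSliceEpochs:
    def test_trailing_partial_dropped(self):
        rec = MultichannelRecord(["a"], {"a": np.arange(125.0)}, {"a": 1.0}, 60.0,
                                 np.array(["C1", "C2"], dtype=object))
        epochs = slice_epochs(rec)
        assert len(epochs) == 2
        np.testing.assert_allclose(epochs[0]["a"], np.arange(60.0))
        np.testing.assert_allclose(epochs[1]["a"], np.arange(60.0, 120.0))

    def test_mixed_rates_stay_aligned(self):
        rec = small_record()
        epochs = slice_epochs(rec)
        assert len(epochs) == 4
        for ep in epochs:
            assert ep["a"].size == 20 and ep["b"].size == 60

    def test_non_integral_epoch_rejected(self):
        rec = small_record()
        rec.epoch_len_s = 10.3  # bypasses init validation on purpose
        with pytest.raises(ConfigError, match="whole number"):
            slice_epochs(rec)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(1, 12), st.integers(1, 8))
    def test_epoch_count_equals_label_count(self, n_epochs, rate):
        labels = np.array(["C1", "C2"] * n_epochs, dtype=object)[:n_epochs]
        rec = MultichannelRecord(
            ["a"], {"a": np.zeros(n_epochs * rate * 5)}, {"a": float(rate)}, 5.0, labels
        )
        assert len(slice_epochs(rec)) == len(labels)


class TestFeatureIndex:
    @pytest.mark.parametrize(
        "c, s, ms, expected",
        [(1, 1, 4, 1), (3, 4, 4, 12), (2, 1, 4, 5), (2, 3, 4, 7)],
    )
    def test_forward(self, c, s, ms, expected):
        assert feature_index(c, s, ms) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 6), st.integers(1, 8), st.integers(1, 8))
    def test_bijection(self, c, ms, s):
        s = min(s, ms)
        f = feature_index(c, s, ms)
        assert feature_channel_scale(f, ms) == (c, s)

    def test_out_of_range(self):
        with pytest.raises(ConfigError):
            feature_index(1, 5, 4)
        with pytest.raises(ConfigError):
            feature_index(0, 1, 4)


class TestBuildFeatureTable:
    def test_shape_and_columns(self):
        rec = gen_record(SignalGenConfig(n_epochs_per_class=5, epoch_len_s=15.0, seed=1))
        table = build_feature_table(rec, EntropyParams(tau_list=(1, 2, 3, 5)))
        assert table.n_features == 12
        assert table.feature_names == [f"f{i}" for i in range(1, 13)]
        assert table.n_cases == 10
        assert table.column_of("EEG", 1) == "f9"
        assert table.channel_of("f12") == "EEG"

    def test_constant_channel_features_zero(self):
        n = 6
        rng = np.random.default_rng(0)
        rec = MultichannelRecord(
            ["flat", "noisy"],
            {"flat": np.ones(n * 40), "noisy": rng.standard_normal(n * 40)},
            {"flat": 4.0, "noisy": 4.0},
            10.0,
            np.array(["C1", "C2"] * 3, dtype=object),
        )
        table = build_feature_table(rec, EntropyParams(tau_list=(1, 2)))
        flat_cols = [table.column_of("flat", 1), table.column_of("flat", 2)]
        assert (table.features[flat_cols].to_numpy() == 0.0).all()

    def test_classes_differ_in_eeg_features(self):
        """Irregularity-separated classes show up in the EEG entropy
        features' class-wise means."""
        rec = gen_record(SignalGenConfig(n_epochs_per_class=15, epoch_len_s=15.0, seed=5))
        table = build_feature_table(rec)
        c1 = table.labels == "C1"
        eeg1 = table.features.loc[c1, "f9"]
        eeg2 = table.features.loc[~c1.to_numpy(), "f9"]
        assert eeg1.mean() > eeg2.mean()


class TestSubsetCount:
    @pytest.mark.parametrize("n, expected", [(12, 4095), (1, 1), (4, 15)])
    def test_values(self, n, expected):
        assert count_feature_subsets(n) == expected

    @pytest.mark.parametrize("n", range(1, 17))
    def test_matches_explicit_enumeration(self, n):
        items = list(range(n))
        explicit = sum(
            1 for k in range(1, n + 1) for _ in itertools.combinations(items, k)
        )
        assert count_feature_subsets(n) == explicit

    def test_nonpositive_rejected(self):
        with pytest.raises(ConfigError):
            count_feature_subsets(0)


class TestTableIO:
    def test_reference_layout_row_parses(self, tmp_path):
        """A published-style table row (case id, twelve entropy features in
        bits, label) reads back with full precision."""
        text = (
            "case,f1,f2,f3,f4,f5,f6,f7,f8,f9,f10,f11,f12,label\n"
            "X1,0.00093,0.00187,0.00280,0.00467,0.00435,0.00871,0.0131,"
            "0.0219,0.8533,1.2302,1.5895,1.8297,C1\n"
            "X2,0.00102,0.00205,0.00308,0.00513,0.00515,0.01034,0.0115,"
            "0.0261,1.1602,1.2659,1.7055,1.9507,C1\n"
        )
        path = tmp_path / "t.csv"
        path.write_text(text)
        table = read_feature_table(path)
        assert table.features.loc["X1", "f1"] == 0.00093
        assert table.features.loc["X1", "f12"] == 1.8297
        assert table.labels.loc["X1"] == "C1"

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("case,f1,label\n")
        with pytest.raises(DataFormatError):
            read_feature_table(path)

    def test_duplicate_case_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("case,f1,label\nX1,0.1,C1\nX1,0.2,C2\n")
        with pytest.raises(DataFormatError, match="duplicate"):
            read_feature_table(path)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_write_read_roundtrip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(2, 12)), int(rng.integers(1, 6))
        index = pd.Index([f"X{i + 1}" for i in range(n)], name="case")
        df = pd.DataFrame(
            rng.standard_normal((n, k)), index=index,
            columns=[f"f{i + 1}" for i in range(k)],
        )
        labels = pd.Series(rng.choice(["C1", "C2"], n), index=index, name="label")
        table = FeatureTable(df, labels)
        path = tmp_path_factory.mktemp("io") / "t.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        # writer keeps 12 significant digits
        pd.testing.assert_frame_equal(back.features, table.features, rtol=1e-11, atol=1e-13)
        pd.testing.assert_series_equal(back.labels, table.labels)


class TestRecordIO:
    def test_record_roundtrip(self, tmp_path):
        rec = small_record(seed=9)
        path = tmp_path / "rec.csv"
        write_record(rec, path)
        back = read_record(path)
        assert back.channel_names == rec.channel_names
        for name in rec.channel_names:
            np.testing.assert_allclose(back.samples[name], rec.samples[name], atol=1e-10)
        assert list(back.labels) == list(rec.labels)
        assert back.epoch_len_s == rec.epoch_len_s

    def test_synthetic_record_roundtrip(self, tmp_path):
        rec = gen_record(SignalGenConfig(n_epochs_per_class=3, epoch_len_s=10.0, seed=2))
        path = tmp_path / "rec.tsv"
        write_record(rec, path)
        back = read_record(path)
        for name in rec.channel_names:
            np.testing.assert_allclose(back.samples[name], rec.samples[name], atol=1e-10)

    def test_interior_blank_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,label\n1.0,C1\n,\n3.0,\n4.0,\n")
        (tmp_path / "bad.csv.schema").write_text("epoch_len_s=2\nrate.a=2\n")
        with pytest.raises(DataFormatError, match="blank cell"):
            read_record(path)

    def test_edf_stub(self):
        with pytest.raises(NotImplementedError, match="unsupported"):
            read_edf("whatever.edf")
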