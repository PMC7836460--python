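"""Schema, CSV loading, encoding, scaling and splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hypredict.data import (
    DEFAULT_SCHEMA,
    FeatureScaler,
    PREDICTOR_NAMES,
    SampleTable,
    SchemaError,
    Split,
    encode_features,
    fit_scaler,
    load_samples,
    save_samples,
    split_dataset,
)


class TestLoadSamples:
    def test_round_trip_row_count_and_order(self, sample_csv):
        table = load_samples(sample_csv)
        assert table.n == 3
        assert list(table.data["altitude"]) == [1500, 2500, 3500]

    def test_text_labels_become_codes(self, sample_csv):
        table = load_samples(sample_csv)
        assert list(table.data["aspect"]) == [1, 2, 4]  # north, 2, west
        assert list(table.data["phenology"]) == [1, 2, 3]

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        cols = [c for c in PREDICTOR_NAMES if c != "ph"]
        path.write_text(",".join(cols) + "\n" + ",".join(["1"] * len(cols)) + "\n")
        with pytest.raises(SchemaError, match="ph"):
            load_samples(path)

    def test_unknown_label_lists_valid_labels(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = ",".join(PREDICTOR_NAMES)
        row = "1500,10,northeast,1,0.5,0.2,2,150,40,38,22,0.05,7.0"
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(SchemaError, match="north"):
            load_samples(path)

    def test_unparseable_value_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = ",".join(PREDICTOR_NAMES)
        good = "1500,10,1,1,0.5,0.2,2,150,40,38,22,0.05,7.0"
        bad = "oops,10,1,1,0.5,0.2,2,150,40,38,22,0.05,7.0"
        path.write_text(header + "\n" + good + "\n" + bad + "\n")
        with pytest.raises(SchemaError, match="row 1"):
            load_samples(path)

    def test_column_order_in_csv_is_irrelevant(self, sample_csv, tmp_path):
        table = load_samples(sample_csv)
        df = pd.read_csv(sample_csv)
        shuffled = tmp_path / "shuffled.csv"
        df[df.columns[::-1]].to_csv(shuffled, index=False)
        X1, _ = encode_features(table)
        X2, _ = encode_features(load_samples(shuffled))
        np.testing.assert_array_equal(X1, X2)


class TestEncodeFeatures:
    def test_thirteen_predictors(self, sample_csv):
        X, y = encode_features(load_samples(sample_csv))
        assert X.shape == (3, 13)
        assert y is not None and y.shape == (3,)

    def test_prediction_mode_without_target(self, sample_csv):
        df = pd.read_csv(sample_csv).drop(columns=["Hypericin content"])
        path = sample_csv.parent / "notarget.csv"
        df.to_csv(path, index=False)
        table = load_samples(path)
        X, y = encode_features(table)
        assert X.shape == (3, 13) and y is None

    def test_ordinals_pass_through_as_codes(self, sample_csv):
        X, _ = encode_features(load_samples(sample_csv))
        j = PREDICTOR_NAMES.index("phenology")
        np.testing.assert_array_equal(X[:, j], [1, 2, 3])


class TestScaler:
    def test_midpoint_maps_to_zero(self):
        sc = fit_scaler(np.array([[0.0], [10.0]]))
        assert sc.transform(np.array([[5.0]]))[0, 0] == pytest.approx(0.0)

    def test_constant_column_maps_to_zero_and_inverts(self):
        X = np.full((4, 2), 3.0)
        X[:, 1] = [1, 2, 3, 4]
        sc = fit_scaler(X)
        Xs = sc.transform(X)
        np.testing.assert_allclose(Xs[:, 0], 0.0)
        np.testing.assert_allclose(sc.inverse_transform(Xs), X, atol=1e-12)

    def test_training_data_lands_in_unit_interval(self, rng):
        X = rng.normal(size=(30, 5)) * rng.uniform(0.1, 100, size=5)
        sc = fit_scaler(X)
        Xs = sc.transform(X)
        assert Xs.min() >= -1 - 1e-12 and Xs.max() <= 1 + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_scale_invert_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 4)) * 10
        y = rng.normal(size=8)
        sc = fit_scaler(X, y)
        np.testing.assert_allclose(sc.inverse_transform(sc.transform(X)), X, atol=1e-12)
        np.testing.assert_allclose(
            sc.inverse_transform_target(sc.transform_target(y)), y, atol=1e-12
        )

    def test_unfitted_scaler_raises(self):
        with pytest.raises(RuntimeError):
            FeatureScaler().transform(np.zeros((1, 2)))

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(5, 3))
        sc = fit_scaler(X, rng.normal(size=5))
        sc2 = FeatureScaler.from_dict(sc.to_dict())
        np.testing.assert_array_equal(sc.transform(X), sc2.transform(X))


class TestSplit:
    def test_field_study_sizes(self):
        sp = split_dataset(100, (0.6, 0.2, 0.2), seed=0)
        assert (len(sp.train_idx), len(sp.val_idx), len(sp.test_idx)) == (60, 20, 20)

    def test_exact_fraction_sizes(self):
        sp = split_dataset(10, (0.6, 0.2, 0.2), seed=0)
        assert (len(sp.train_idx), len(sp.val_idx), len(sp.test_idx)) == (6, 2, 2)

    def test_remainders_assigned_train_val_test(self):
        sp = split_dataset(11, (0.6, 0.2, 0.2), seed=0)
        # floor gives (6, 2, 2); the 1 leftover row goes to train
        assert (len(sp.train_idx), len(sp.val_idx), len(sp.test_idx)) == (7, 2, 2)

    def test_determinism(self):
        a = split_dataset(50, (0.6, 0.2, 0.2), seed=3)
        b = split_dataset(50, (0.6, 0.2, 0.2), seed=3)
        assert a == b

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_dataset(2, (0.6, 0.2, 0.2), seed=0)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            split_dataset(10, (0.5, 0.2, 0.2), seed=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(3, 500),
        st.sampled_from([(0.6, 0.2, 0.2), (0.5, 0.25, 0.25), (0.7, 0.15, 0.15)]),
        st.integers(0, 2**31 - 1),
    )
    def test_partitions_disjoint_and_exhaustive(self, n, fractions, seed):
        sp = split_dataset(n, fractions, seed)
        all_idx = sp.train_idx + sp.val_idx + sp.test_idx
        assert sorted(all_idx) == list(range(n))

    def test_json_round_trip(self, tmp_path):
        sp = split_dataset(20, seed=5)
        p = tmp_path / "split.json"
        sp.save(p)
        assert Split.load(p) == sp


def test_save_samples_round_trip(sample_csv, tmp_path):
    table = load_samples(sample_csv)
    out = tmp_path / "out.csv"
    save_samples(table, out)
    again = load_samples(out)
    pd.testing.assert_frame_equal(table.data, again.data, check_dtype=False)


def test_negative_hypericin_rejected(sample_csv):
    table = load_samples(sample_csv)
    df = table.data.copy()
    df.loc[0, "hypericin"] = -0.1
    with pytest.raises(SchemaError):
        SampleTable(df)
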