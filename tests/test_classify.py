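"""Splitting, scaling, oversampling, model training and evaluation mechanics."""

import numpy as np
import pandas as pd
import pytest

from qcrvisc.classify import (
    ConfusionMatrix,
    MlpSpec,
    SplitSpec,
    accuracy_from_matrix,
    apply_scaler,
    evaluate,
    fit_robust_scaler,
    oversample_minority,
    reported_accuracy,
    run_experiment,
    split_dataset,
    train_mlp,
    train_rf,
    train_svm,
)


class TestSplit:
    def test_point_split_sizes_match_study_geometry(self, edta_cohort, heparin_cohort):
        # ceil-based test/validation sizes reproduce the published totals
        train, val, test = split_dataset(edta_cohort, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (3480, 746, 746)
        train, val, test = split_dataset(heparin_cohort, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (3672, 788, 788)

    def test_partition_is_exhaustive_and_disjoint(self, small_cohort):
        parts = split_dataset(small_cohort, SplitSpec(seed=3))
        together = pd.concat(parts).sort_values(
            ["sample_id", "repeat", "point"]
        ).reset_index(drop=True)
        original = small_cohort.sort_values(
            ["sample_id", "repeat", "point"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(together, original)

    def test_grouped_split_keeps_samples_whole(self, small_cohort):
        parts = split_dataset(small_cohort, SplitSpec(mode="grouped", seed=1))
        seen = {}
        for name, part in zip("tvx", parts):
            for sid in part["sample_id"].unique():
                assert sid not in seen, f"sample {sid} spans partitions"
                seen[sid] = name
        assert len(seen) == small_cohort["sample_id"].nunique()

    def test_grouped_split_needs_enough_samples(self):
        rows = pd.DataFrame(
            {
                "sample_id": ["a", "a", "b", "b"],
                "label": ["inflammatory"] * 2 + ["infectious"] * 2,
                "x": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="samples"):
            split_dataset(rows, SplitSpec(mode="grouped", seed=0))

    def test_split_is_seeded(self, small_cohort):
        a = split_dataset(small_cohort, SplitSpec(seed=7))
        b = split_dataset(small_cohort, SplitSpec(seed=7))
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa, pb)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.7, 0.2, 0.2))


class TestOversampling:
    def _rows(self, n_maj, n_min):
        return pd.DataFrame(
            {
                "label": ["inflammatory"] * n_maj + ["infectious"] * n_min,
                "x": np.arange(n_maj + n_min, dtype=float),
            }
        )

    def test_balances_to_twice_majority(self):
        out = oversample_minority(self._rows(100, 20), seed=0)
        counts = out["label"].value_counts()
        assert counts["inflammatory"] == counts["infectious"] == 100
        assert len(out) == 200
        # every majority row survives untouched
        assert set(out[out["label"] == "inflammatory"]["x"]) == set(range(100))

    def test_synthetic_rows_exist_in_input(self):
        rows = self._rows(50, 10)
        out = oversample_minority(rows, seed=1)
        original = set(rows[rows["label"] == "infectious"]["x"])
        assert set(out[out["label"] == "infectious"]["x"]) <= original

    def test_already_balanced_unchanged_up_to_order(self):
        rows = self._rows(30, 30)
        out = oversample_minority(rows, seed=2)
        assert sorted(out["x"]) == sorted(rows["x"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            oversample_minority(self._rows(10, 0).iloc[:10], seed=0)


class TestRobustScaler:
    def test_hand_computed_example(self):
        frame = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0]})
        params = fit_robust_scaler(frame, ["f"])
        assert params.center[0] == 3.0
        assert params.scale[0] == 2.0
        out = apply_scaler(params, frame)
        np.testing.assert_allclose(out["f"], [-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_constant_feature_named_in_error(self):
        frame = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            fit_robust_scaler(frame, ["good", "flat"])

    def test_transformed_training_data_is_standardised(self, small_cohort):
        params = fit_robust_scaler(small_cohort)
        out = apply_scaler(params, small_cohort)
        for col in params.columns:
            assert out[col].median() == pytest.approx(0.0, abs=1e-9)
            q1, q3 = np.percentile(out[col], [25, 75])
            assert q3 - q1 == pytest.approx(1.0, rel=1e-9)


def _blobs(n=1000, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.concatenate([rng.normal(0, 1, (half, 3)), rng.normal(sep, 1, (half, 3))])
    frame = pd.DataFrame(x, columns=["delta_f_hz", "delta_gamma_hz", "eta_mpas"])
    frame["label"] = ["inflammatory"] * half + ["infectious"] * half
    return frame.sample(frac=1, random_state=seed).reset_index(drop=True)


class TestModels:
    def test_mlp_separates_well_separated_blobs(self):
        blobs = _blobs()
        train, test = blobs.iloc[:800], blobs.iloc[800:]
        model, history = train_mlp(train, test, MlpSpec(epochs=100, seed=0))
        _, acc = evaluate(model, test)
        assert acc >= 0.99
        assert len(history) == 100
        frame = history.to_frame()
        assert set(frame.columns) == {
            "epoch", "train_accuracy", "train_loss", "val_accuracy", "val_loss"
        }
        assert frame["train_accuracy"].between(0, 1).all()

    def test_mlp_spec_validation(self):
        with pytest.raises(ValueError):
            MlpSpec(epochs=0)
        with pytest.raises(ValueError):
            MlpSpec(hidden_layers=3)

    def test_mlp_input_dim_mismatch(self):
        blobs = _blobs(n=100)
        with pytest.raises(ValueError, match="input_dim"):
            train_mlp(blobs, blobs, MlpSpec(input_dim=5, epochs=1, seed=0))

    def test_svm_separable_toy(self):
        blobs = _blobs(n=200, sep=10.0)
        model = train_svm(blobs)
        _, acc = evaluate(model, blobs)
        assert acc == 1.0

    def test_svm_single_class_rejected(self):
        blobs = _blobs(n=100)
        with pytest.raises(ValueError):
            train_svm(blobs[blobs["label"] == "inflammatory"])

    def test_rf_has_configured_forest_size_and_is_seeded(self):
        blobs = _blobs(n=60, sep=3.0)
        model = train_rf(blobs, seed=4)
        assert len(model.estimators_) == 2171
        again = train_rf(blobs, seed=4)
        x = blobs[["delta_f_hz", "delta_gamma_hz", "eta_mpas"]].to_numpy()
        np.testing.assert_array_equal(model.predict(x), again.predict(x))


class TestEvaluation:
    class _Stub:
        def __init__(self, preds):
            self.preds = np.asarray(preds)

        def predict(self, X):
            return self.preds

    def test_confusion_orientation_inflammatory_positive(self):
        frame = _blobs(n=8, sep=0.0)
        frame["label"] = ["inflammatory"] * 5 + ["infectious"] * 3
        preds = ["inflammatory"] * 4 + ["infectious"] + ["infectious"] * 2 + ["inflammatory"]
        cm, acc = evaluate(self._Stub(preds), frame)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (4, 1, 2, 1)
        assert acc == pytest.approx(6 / 8)
        # row sums recover the class counts
        assert cm.tp + cm.fn == 5
        assert cm.tn + cm.fp == 3

    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((627, 4, 10, 147), 774 / 788),
            ((562, 12, 53, 119), 681 / 746),
            ((488, 86, 20, 152), 640 / 746),
            ((1, 0, 0, 1), 1.0),
            ((0, 1, 1, 0), 0.0),
        ],
    )
    def test_accuracy_from_matrix(self, cells, expected):
        tp, fp, fn, tn = cells
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        assert accuracy_from_matrix(cm) == pytest.approx(expected)

    def test_reported_accuracy_truncates(self):
        assert reported_accuracy(640 / 746) == 0.85   # 0.8579
        assert reported_accuracy(678 / 746) == 0.90   # 0.9088
        assert reported_accuracy(0.92) == 0.92

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, fp=0, fn=0, tn=0)


class TestRunExperiment:
    def test_pipeline_is_reproducible(self, small_cohort):
        kwargs = dict(
            mlp_spec=MlpSpec(epochs=5, seed=3),
            split=SplitSpec(seed=3),
            balance="none",
            seed=3,
        )
        a = run_experiment(small_cohort, "mlp", **kwargs)
        b = run_experiment(small_cohort, "mlp", **kwargs)
        assert a["confusion"] == b["confusion"]
        assert a["accuracy"] == b["accuracy"]

    def test_balanced_run_uses_doubled_majority(self, small_cohort):
        maj = small_cohort["label"].value_counts().max()
        res = run_experiment(
            small_cohort,
            "mlp",
            mlp_spec=MlpSpec(epochs=2, seed=0),
            balance="before_split",
            seed=0,
        )
        assert res["n_train"] + res["n_val"] + res["n_test"] == 2 * maj

    def test_unknown_model_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            run_experiment(small_cohort, "gbm")
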