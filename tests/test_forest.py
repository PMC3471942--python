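import numpy as np
import pandas as pd
import pytest

from thermoforest import StabilityForest, StabilityForestResults
from thermoforest.forest import (
    augment_with_reverse,
    base_protein_map,
    evaluate,
    feature_importance,
    train_rf,
)
from thermoforest.records import (
    MutationDataset, MutationRecord, ProteinRecord, Substitution, ValidationError,
)


@pytest.fixture
def tiny_forward_dataset():
    p = ProteinRecord(id="p", sequence="MVKAYLLW" * 4)
    records = [
        MutationRecord("p", (Substitution("V", 2, "A"),), ddg=-1.2),
        MutationRecord("p", (Substitution("K", 3, "R"), Substitution("A", 4, "G")),
                       ddg=0.4),
    ]
    return MutationDataset(records=records, proteins={"p": p})


class TestAugment:
    def test_reverse_record_swaps_and_negates(self, tiny_forward_dataset):
        ds = augment_with_reverse(tiny_forward_dataset)
        assert len(ds) == 4
        rev = [r for r in ds.records if r.direction == "reverse"][0]
        assert str(rev.subs[0]) == "A2V"
        assert rev.ddg == 1.2
        assert rev.pair_id == tiny_forward_dataset.records[0].pair_id

    def test_mutant_protein_created_with_inherited_layers(self):
        p = ProteinRecord(id="p", sequence="MVKAY",
                          rsa=np.array([0.1, 0.2, 0.3, 0.4, 0.5]),
                          ss=["H"] * 5)
        ds = MutationDataset(
            records=[MutationRecord("p", (Substitution("V", 2, "A"),), ddg=-1.0)],
            proteins={"p": p})
        out = augment_with_reverse(ds)
        mutant = out.proteins["p|V2A"]
        assert mutant.sequence == "MAKAY"
        assert mutant.ss == p.ss and np.all(mutant.rsa == p.rsa)
        assert base_protein_map(out) == {"p|V2A": "p"}

    def test_double_augmentation_rejected(self, tiny_forward_dataset):
        ds = augment_with_reverse(tiny_forward_dataset)
        with pytest.raises(ValidationError):
            augment_with_reverse(ds)

    def test_perfect_balance_without_zeros(self, small_bench):
        n = len(small_bench.dataset)
        assert all(r.ddg != 0 for r in small_bench.dataset.records)
        ds = augment_with_reverse(small_bench.dataset)
        stabilizing = sum(1 for r in ds.records if r.ddg > 0)
        destabilizing = sum(1 for r in ds.records if r.ddg < 0)
        assert stabilizing == destabilizing == n


class TestTrainRf:
    def test_constant_labels_predict_constant(self, rng):
        X = rng.normal(size=(30, 4))
        model = train_rf(X, np.full(30, 2.5), n_trees=20, seed=0)
        np.testing.assert_allclose(model.predict(rng.normal(size=(5, 4))), 2.5)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(40, 4))
        y = X[:, 0] + rng.normal(scale=0.1, size=40)
        p1 = train_rf(X, y, n_trees=30, seed=7).predict(X)
        p2 = train_rf(X, y, n_trees=30, seed=7).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_tree_count(self):
        with pytest.raises(ValidationError):
            train_rf(np.zeros((3, 1)), np.zeros(3), n_trees=0)


class TestImportance:
    def test_signal_outranks_noise(self, rng):
        X = rng.normal(size=(120, 5))
        y = 3.0 * X[:, 2] + rng.normal(scale=0.5, size=120)
        model = train_rf(X, y, n_trees=100, seed=1)
        df = feature_importance([model], [f"f{i}" for i in range(5)])
        assert df.index[0] == "f2"
        assert np.isnan(df["se"]).all()  # single model: no spread estimate

    def test_constant_feature_importance_zero(self, rng):
        X = rng.normal(size=(60, 3))
        X[:, 1] = 1.0
        y = X[:, 0]
        model = train_rf(X, y, n_trees=50, seed=2)
        df = feature_importance([model], ["a", "const", "c"])
        assert df.loc["const", "mean"] == 0

    def test_multi_model_standard_error(self, rng):
        X = rng.normal(size=(60, 3))
        y = X[:, 0]
        models = [train_rf(X, y, n_trees=20, seed=s) for s in range(3)]
        df = feature_importance(models, ["a", "b", "c"])
        assert np.isfinite(df["se"]).all()


class TestEvaluate:
    def test_per_direction_metrics(self):
        meta = pd.DataFrame({
            "direction": ["forward"] * 4 + ["reverse"] * 4,
            "ddg": [1.0, 2.0, -1.0, -2.0, -1.0, -2.0, 1.0, 2.0],
        })
        y_pred = np.array([0.9, 1.8, -1.1, -1.9, -0.9, -1.8, 1.1, 1.9])
        report = evaluate(meta, y_pred)
        assert report.loc["forward", "AUC"] == 1.0
        assert report.loc["forward", "ACC"] == 1.0
        assert report.loc["reverse", "R"] > 0.99

    def test_single_class_direction_auc_nan(self):
        meta = pd.DataFrame({"direction": ["forward"] * 3, "ddg": [1.0, 2.0, 3.0]})
        report = evaluate(meta, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(report.loc["forward", "AUC"])


class TestModelObjects:
    def test_fit_and_summary(self, small_bench):
        model = StabilityForest(dataset=small_bench.dataset,
                                pipeline=small_bench.pipeline, n_trees=50)
        results = model.fit(seed=0)
        text = results.summary()
        assert "sequence" in text and "trees: 50" in text
        assert results.feature_importances["mean"].sum() == pytest.approx(1.0)

    def test_save_load_roundtrip(self, small_bench, tmp_path):
        model = StabilityForest(dataset=small_bench.dataset,
                                pipeline=small_bench.pipeline, n_trees=30)
        results = model.fit(seed=3)
        path = tmp_path / "model.joblib"
        results.save(path)
        loaded = StabilityForestResults.load(path, small_bench.pipeline)
        a = results.predict_dataset(model.dataset)["y_pred"]
        b = loaded.predict_dataset(model.dataset)["y_pred"]
        np.testing.assert_array_equal(a, b)

    def test_cross_validate_report_shape(self, small_bench):
        model = StabilityForest(dataset=small_bench.dataset,
                                pipeline=small_bench.pipeline,
                                n_trees=50, n_folds=5)
        res = model.cross_validate(seed=0)
        assert set(res.metrics.index) == {"forward", "reverse"}
        assert set(res.metrics.columns) == {"AUC", "ACC", "R"}
        assert ((res.metrics[["AUC", "ACC"]] >= 0) &
                (res.metrics[["AUC", "ACC"]] <= 1)).all().all()
        assert res.metrics["R"].between(-1, 1).all()
        assert len(res.importance) == 34
        assert res.per_fold["fold"].nunique() == 5
        assert np.isfinite(res.predictions["y_pred"]).all()

    def test_cv_files_are_deterministic(self, small_bench, tmp_path):
        model = StabilityForest(dataset=small_bench.dataset,
                                pipeline=small_bench.pipeline, n_trees=30)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        model.cross_validate(seed=5).to_files(out1)
        model2 = StabilityForest(dataset=small_bench.dataset,
                                 pipeline=small_bench.pipeline, n_trees=30)
        model2.cross_validate(seed=5).to_files(out2)
        for name in ("report.tsv", "per_fold.tsv", "importance.tsv",
                     "predictions.tsv", "report.txt"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
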