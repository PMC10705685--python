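"""Splits, fusion and classifiers: arithmetic, leakage guards, protocol grids."""

import numpy as np
import pandas as pd
import pytest

from pupaevision.modeling import (
    ClassifierSpec,
    FeatureFusion,
    FusionSpec,
    SplitSpec,
    fuse,
    grid_search_train,
    make_labels,
    predict,
    split_dataset,
)


def synthetic_manifest(pupae_per_class=120, seed=0):
    """Label/weight table shaped like generator output (no images needed)."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in ("a", "b", "c", "d", "e"):
        for sex in ("female", "male"):
            for i in range(pupae_per_class):
                pid = f"{sp}_{sex}_{i:04d}"
                w = float(np.exp(rng.normal(0.2, 0.1)))
                for posture in ("back", "abdomen", "side"):
                    rows.append(dict(pupa_id=pid, species=sp, sex=sex,
                                     posture=posture, weight=w))
    return pd.DataFrame(rows)


class TestSplit:
    def test_8_2_counts_per_class(self):
        m = split_dataset(synthetic_manifest(120), SplitSpec("8:2"))
        per = m.groupby(["species", "sex", "split"])["pupa_id"].nunique().unstack()
        assert (per["train"] == 96).all()
        assert (per["test"] == 24).all()
        images = m.groupby(["species", "sex", "split"]).size().unstack()
        assert (images["train"] == 288).all() and (images["test"] == 72).all()

    def test_8_1_1_counts_per_class(self):
        m = split_dataset(synthetic_manifest(120), SplitSpec("8:1:1"))
        per = m.groupby(["species", "sex", "split"])["pupa_id"].nunique().unstack()
        assert (per["train"] == 96).all()
        assert (per["calibration"] == 12).all()
        assert (per["test"] == 12).all()

    def test_weight_distributions_match_across_splits(self):
        m = split_dataset(synthetic_manifest(120, seed=3), SplitSpec("8:2"))
        for (_, _), grp in m.groupby(["species", "sex"]):
            overall = grp.drop_duplicates("pupa_id")["weight"].mean()
            for split in ("train", "test"):
                mean = grp[grp["split"] == split].drop_duplicates("pupa_id")[
                    "weight"
                ].mean()
                assert abs(mean - overall) / overall < 0.05

    def test_postures_grouped_by_pupa(self):
        m = split_dataset(synthetic_manifest(20), SplitSpec("8:2"))
        assert (m.groupby("pupa_id")["split"].nunique() == 1).all()

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_dataset(synthetic_manifest(4), SplitSpec("8:2"))

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec("7:3")

    def test_task_relabeling(self):
        m = synthetic_manifest(5)
        for task, n in (("species", 5), ("sex", 2), ("species_sex", 10)):
            y, classes = make_labels(m, task)
            assert len(classes) == n
            assert set(y) == set(range(n))


class TestFusion:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.train = {
            "hog": rng.normal(size=(600, 1296)),
            "sdpsf": rng.normal(size=(600, 37)),
        }
        self.test = {
            "hog": rng.normal(size=(40, 1296)),
            "sdpsf": rng.normal(size=(40, 37)),
        }

    def test_large_member_compressed_to_exactly_500(self):
        fusion = FeatureFusion(FusionSpec(("hog",))).fit(self.train)
        assert fusion.transform(self.test).shape == (40, 500)
        assert fusion.projection_matrix("hog").shape == (1296, 500)

    def test_small_member_passes_through(self):
        fusion = FeatureFusion(FusionSpec(("sdpsf",))).fit(self.train)
        assert fusion.transform(self.test).shape == (40, 37)
        assert fusion.projection_matrix("sdpsf") is None

    def test_concatenation_order_and_dim(self):
        fusion = FeatureFusion(FusionSpec(("hog", "sdpsf"))).fit(self.train)
        out = fusion.transform(self.test)
        assert out.shape == (40, 537)
        # trailing block is the pass-through member (z-scored)
        z = (self.test["sdpsf"] - self.train["sdpsf"].mean(0)) / self.train[
            "sdpsf"
        ].std(0)
        assert np.allclose(out[:, 500:], z, atol=1e-6)

    def test_rank_deficient_training_padded_with_zero_variance_axes(self):
        small = {"hog": self.train["hog"][:60]}
        fusion = FeatureFusion(FusionSpec(("hog",))).fit(small)
        out = fusion.transform({"hog": self.test["hog"]})
        assert out.shape == (40, 500)
        assert not out[:, :59].std(axis=0).min() == 0
        assert np.allclose(out[:, 60:], 0)

    def test_test_transform_reuses_train_projection(self):
        fusion = FeatureFusion(FusionSpec(("hog",))).fit(self.train)
        before = fusion.projection_matrix("hog").copy()
        fusion.transform(self.test)
        fusion.transform(self.train)
        assert np.array_equal(before, fusion.projection_matrix("hog"))
        via_helper = fuse(self.test, fusion.spec, fusion)
        assert np.array_equal(via_helper, fusion.transform(self.test))

    def test_missing_member_named_in_error(self):
        fusion = FeatureFusion(FusionSpec(("hog", "glcm")))
        with pytest.raises(KeyError, match="glcm"):
            fusion.fit(self.train)
        bad = dict(self.train)
        bad["hog"] = bad["hog"].copy()
        bad["hog"][7, 0] = np.nan
        with pytest.raises(ValueError, match="sample 7.*hog"):
            FeatureFusion(FusionSpec(("hog",))).fit(bad)


def separable_blobs(n_per_class=30, n_classes=4, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=25.0, size=(n_classes, 8))
    x = np.vstack(
        [centers[k] + rng.normal(scale=0.5, size=(n_per_class, 8))
         for k in range(n_classes)]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    return x, y


class TestClassifiers:
    def test_protocol_grid_sizes(self):
        assert len(ClassifierSpec("RF").param_grid()["n_estimators"]) == 61
        mlp = ClassifierSpec("MLP").param_grid()
        assert len(mlp["hidden_layer_sizes"]) == 10 and len(mlp["alpha"]) == 6
        svm = ClassifierSpec("SVM").param_grid()
        assert len(svm["C"]) == 11 and len(svm["gamma"]) == 11
        assert ClassifierSpec("SVM", mode="fixed").param_grid() == {}

    def test_fixed_settings_follow_protocol(self):
        svm = ClassifierSpec("SVM", mode="fixed").build_estimator()
        assert svm.kernel == "linear" and svm.C == 1.0 and svm.random_state == 9
        mlp = ClassifierSpec("MLP", mode="fixed").build_estimator()
        assert mlp.hidden_layer_sizes == 120 and mlp.alpha == 1e-5
        rf = ClassifierSpec("RF", mode="fixed").build_estimator()
        assert rf.n_estimators == 500 and rf.criterion == "gini"

    def test_single_point_grid_equals_direct_fit(self):
        x, y = separable_blobs()
        spec = ClassifierSpec("SVM")
        grid_model = grid_search_train(x, y, spec, param_grid={"C": [1.0], "gamma": [0.1]})
        direct = spec.build_estimator().set_params(C=1.0, gamma=0.1).fit(x, y)
        assert np.array_equal(grid_model.estimator.predict(x), direct.predict(x))

    def test_svm_grid_perfect_on_separable_data(self):
        x, y = separable_blobs()
        model = grid_search_train(x, y, ClassifierSpec("SVM"))
        assert model.best_cv_accuracy == 1.0
        assert len(model.cv_table) == 121
        labels, _ = predict(model, x)
        assert np.array_equal(labels, y)

    def test_too_few_samples_per_class_rejected(self):
        x, y = separable_blobs(n_per_class=3)
        with pytest.raises(ValueError, match="5 samples"):
            grid_search_train(x, y, ClassifierSpec("RF"))

    def test_predict_contract(self):
        x, y = separable_blobs()
        model = grid_search_train(
            x, y, ClassifierSpec("RF"), param_grid={"n_estimators": [50]}
        )
        labels, scores = predict(model, x)
        assert scores.shape == (len(x), 4)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(labels, model.classes_[scores.argmax(axis=1)])
        with pytest.raises(ValueError, match="dim"):
            predict(model, x[:, :5])

    def test_svm_scores_argmax_consistent(self):
        x, y = separable_blobs()
        model = grid_search_train(
            x, y, ClassifierSpec("SVM"), param_grid={"C": [1.0], "gamma": [0.05]}
        )
        labels, scores = predict(model, x)
        assert np.array_equal(labels, model.classes_[scores.argmax(axis=1)])
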