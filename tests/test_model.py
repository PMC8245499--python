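import numpy as np
import pytest
from sklearn.base import clone
from sklearn.datasets import make_blobs

from acpstep import (
    ACPClassifier,
    SubtypeGroup,
    grid_search_train,
    load_model,
    make_dataset,
    save_model,
)
from acpstep.model import BUNDLE_SCHEMA_VERSION

from conftest import FAST_C_GRID, FAST_GAMMA_GRID


@pytest.fixture(scope="module")
def fitted(small_synthetic):
    clf = ACPClassifier(
        features="aac+pcp+taac+tpcp",
        C_grid=FAST_C_GRID,
        gamma_grid=FAST_GAMMA_GRID,
        cv=3,
        random_state=1,
    )
    ds = small_synthetic
    return clf.fit(ds["sequence"].tolist(), ds["label"].to_numpy())


class TestGridSearch:
    def test_separable_blobs_high_cv_accuracy(self):
        X, y = make_blobs(n_samples=100, centers=2, cluster_std=0.5, random_state=0)
        svm, C, gamma, score = grid_search_train(
            X, y, C_grid=FAST_C_GRID, gamma_grid=FAST_GAMMA_GRID, seed=0
        )
        assert score >= 0.95
        assert C in FAST_C_GRID and gamma in FAST_GAMMA_GRID

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="both classes"):
            grid_search_train(X, np.zeros(20))

    def test_deterministic_choice(self):
        X, y = make_blobs(n_samples=80, centers=2, cluster_std=2.0, random_state=3)
        runs = {
            grid_search_train(X, y, C_grid=FAST_C_GRID, gamma_grid=FAST_GAMMA_GRID, seed=5)[1:3]
            for _ in range(2)
        }
        assert len(runs) == 1


class TestFit:
    def test_three_group_models_with_own_parameters(self, fitted):
        assert set(fitted.models_) == set(SubtypeGroup)
        for m in fitted.models_.values():
            assert m["C"] in FAST_C_GRID and m["gamma"] in FAST_GAMMA_GRID
            assert m["n_pos"] > 0 and m["n_neg"] > 0

    def test_feature_dimension_seen_by_svms(self, small_synthetic):
        clf = ACPClassifier(
            features="aac+dpc+pcp",
            C_grid=(8.0,),
            gamma_grid=(0.125,),
            cv=3,
            random_state=0,
        ).fit(small_synthetic["sequence"].tolist(), small_synthetic["label"].to_numpy())
        for m in clf.models_.values():
            assert m["svm"].n_features_in_ == 428

    def test_scaler_maps_training_rows_to_unit_interval(self, fitted, small_synthetic):
        feats = fitted._encode(small_synthetic["sequence"].tolist())
        keys = fitted._group_keys(small_synthetic["sequence"].tolist())
        for g, m in fitted.models_.items():
            Z = m["scaler"].transform(feats[keys == g])
            assert Z.min() >= -1e-12 and Z.max() <= 1 + 1e-12

    def test_missing_class_in_group_raises(self):
        seqs = ["GGGGGGKKKKK"] * 6 + ["KKKKKGGGGGG"] * 6  # C+ all ACP, N+ all nonACP
        y = ["ACP"] * 6 + ["nonACP"] * 6
        with pytest.raises(ValueError, match="missing"):
            ACPClassifier(features="aac", C_grid=(1.0,), gamma_grid=(0.1,), cv=2).fit(seqs, y)

    def test_short_sequence_error_propagates(self, small_synthetic):
        clf = ACPClassifier(window=60)
        with pytest.raises(ValueError):
            clf.fit(
                small_synthetic["sequence"].tolist(),
                small_synthetic["label"].to_numpy(),
            )


class TestPredict:
    def test_interpolates_separable_training_data(self, fitted, small_synthetic):
        from acpstep import confusion, metrics

        pred = fitted.predict(small_synthetic["sequence"].tolist())
        m = metrics(confusion(small_synthetic["label"].to_numpy(), pred))
        assert m.balanced_accuracy >= 0.90

    def test_deterministic_end_to_end(self, small_synthetic):
        ds = small_synthetic
        def run():
            clf = ACPClassifier(
                features="aac+pcp", C_grid=FAST_C_GRID, gamma_grid=FAST_GAMMA_GRID,
                cv=3, random_state=9,
            ).fit(ds["sequence"].tolist(), ds["label"].to_numpy())
            return clf.meta_, clf.predict_table(ds)
        meta1, t1 = run()
        meta2, t2 = run()
        assert meta1 == meta2
        assert t1.equals(t2)

    def test_reversal_can_change_submodel(self, fitted):
        seq = "FLWCPCLKKCF"  # charge near the C-terminus
        table = fitted.predict_table(
            make_dataset([("fwd", seq, "UNLABELED"), ("rev", seq[::-1], "UNLABELED")])
        )
        assert set(table["group"]) == {"C+", "N+"}

    def test_empty_input(self, fitted):
        assert len(fitted.predict([])) == 0

    def test_probability_requires_flag(self, fitted):
        with pytest.raises(AttributeError):
            fitted.predict_proba(["GLFDIIKKIAESF"])

    def test_platt_probabilities_track_labels(self, small_synthetic):
        ds = small_synthetic
        clf = ACPClassifier(
            features="aac+pcp", C_grid=(8.0,), gamma_grid=(0.125,), cv=3,
            probability=True, random_state=2,
        ).fit(ds["sequence"].tolist(), ds["label"].to_numpy())
        proba = clf.predict_proba(ds["sequence"].tolist())[:, 1]
        assert proba.shape == (len(ds),)
        assert ((proba >= 0) & (proba <= 1)).all()
        pos = proba[(ds["label"] == "ACP").to_numpy()].mean()
        neg = proba[(ds["label"] == "nonACP").to_numpy()].mean()
        assert pos > neg


class TestSklearnCompat:
    def test_get_set_params_and_clone(self):
        clf = ACPClassifier(features="aac", cv=3, random_state=7)
        params = clf.get_params()
        assert params["features"] == "aac" and params["random_state"] == 7
        cloned = clone(clf)
        assert cloned.get_params() == params
        cloned.set_params(two_step=False)
        assert cloned.two_step is False


class TestPersistence:
    def test_round_trip(self, tmp_path, fitted, small_synthetic):
        path = tmp_path / "model.joblib"
        save_model(fitted, path)
        reloaded = load_model(path)
        seqs = small_synthetic["sequence"].tolist()
        assert (reloaded.predict(seqs) == fitted.predict(seqs)).all()
        assert reloaded.meta_ == fitted.meta_

    def test_rejects_unknown_schema(self, tmp_path, fitted):
        import joblib

        path = tmp_path / "model.joblib"
        joblib.dump({"schema_version": BUNDLE_SCHEMA_VERSION + 1, "model": None}, path)
        with pytest.raises(ValueError, match="schema"):
            load_model(path)

    def test_unfitted_cannot_be_saved(self, tmp_path):
        with pytest.raises(RuntimeError):
            save_model(ACPClassifier(), tmp_path / "m.joblib")
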