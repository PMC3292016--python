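import numpy as np
import pytest

from afpkit.classifier import (
    GridSpec,
    ModelFileError,
    fit_grid,
    load_model,
    predict,
    save_model,
)
from afpkit.compositions import aac
from afpkit.features import FeatureVector


@pytest.fixture(scope="module")
def toy_2d():
    """Two well-separated 2-D Gaussian blobs."""
    rng = np.random.default_rng(0)
    n = 40
    X = np.vstack(
        [
            rng.normal([0.0, 0.0], 0.3, size=(n, 2)),
            rng.normal([4.0, 4.0], 0.3, size=(n, 2)),
        ]
    )
    y = np.array([0] * n + [1] * n)
    return X, y


@pytest.fixture(scope="module")
def trained(separable_dataset):
    seqs, y = separable_dataset
    feats = [aac(s) for s in seqs]
    model, report = fit_grid(feats, y, grid=GridSpec.coarse(seed=11))
    return feats, y, model, report


class TestFitGrid:
    def test_separable_reaches_full_cv_accuracy(self, trained):
        _, _, _, report = trained
        assert report["cv_accuracy"].max() == 1.0

    def test_report_covers_whole_grid(self, trained):
        _, _, _, report = trained
        grid = GridSpec.coarse()
        assert len(report) == len(grid.c_values) * len(grid.gamma_values)

    def test_deterministic_given_seed(self, toy_2d):
        X, y = toy_2d
        g = GridSpec.coarse(seed=5)
        m1, r1 = fit_grid(X, y, grid=g)
        m2, r2 = fit_grid(X, y, grid=g)
        assert (m1.c, m1.gamma) == (m2.c, m2.gamma)
        assert r1.equals(r2)
        p1, _ = predict(m1, X)
        p2, _ = predict(m2, X)
        np.testing.assert_array_equal(p1, p2)

    def test_label_inversion_symmetry(self, toy_2d):
        """Binary accuracy is symmetric under consistent relabeling, so
        the best grid accuracy must match."""
        X, y = toy_2d
        g = GridSpec.coarse(seed=5)
        _, r1 = fit_grid(X, y, grid=g)
        _, r2 = fit_grid(X, 1 - y, grid=g)
        assert r1["cv_accuracy"].max() == r2["cv_accuracy"].max()

    def test_tie_break_prefers_small_c_then_gamma(self, toy_2d):
        # fully separable: many pairs tie at accuracy 1, so the winner
        # must be the first in (C, gamma) grid order among the maxima
        X, y = toy_2d
        g = GridSpec.coarse(seed=5)
        model, report = fit_grid(X, y, grid=g)
        best = report["cv_accuracy"].max()
        winners = report[report["cv_accuracy"] == best]
        first = winners.sort_values(["C", "gamma"]).iloc[0]
        assert (model.c, model.gamma) == (first["C"], first["gamma"])

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_grid(X, np.ones(10, int), grid=GridSpec.coarse())

    def test_mixed_dimension_rejected(self):
        feats = [
            FeatureVector(scheme="pseaac", values=np.ones(30) / 30),
            FeatureVector(scheme="pseaac", values=np.ones(25) / 25),
        ]
        with pytest.raises(ValueError, match="dimension"):
            fit_grid(feats, [0, 1], grid=GridSpec.coarse())

    def test_scaling_maps_training_data_into_unit_box(self, toy_2d):
        X, y = toy_2d
        model, _ = fit_grid(X, y, grid=GridSpec.coarse(seed=1))
        scaled = model.scale(X)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0

    def test_matches_nearest_centroid_on_wide_margin(self, toy_2d):
        X, y = toy_2d
        model, _ = fit_grid(X, y, grid=GridSpec.coarse(seed=1))
        _, calls = predict(model, X)
        centroids = np.array([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
        nearest = np.argmin(
            ((X[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1
        )
        np.testing.assert_array_equal(calls, nearest)


class TestPredict:
    def test_threshold_zero_calls_all_positive(self, trained):
        feats, _, model, _ = trained
        _, calls = predict(model, feats, threshold=0.0)
        assert calls.all()

    def test_threshold_monotonicity(self, trained):
        feats, _, model, _ = trained
        prev = None
        for t in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            _, calls = predict(model, feats, threshold=t)
            if prev is not None:
                # raising the threshold never flips negative -> positive
                assert not np.any((prev == 0) & (calls == 1))
            prev = calls

    def test_separable_holdout_all_correct(self, separable_dataset):
        seqs, y = separable_dataset
        feats = [aac(s) for s in seqs]
        train_idx = np.r_[0:40, 50:90]
        test_idx = np.r_[40:50, 90:100]
        model, _ = fit_grid(
            [feats[i] for i in train_idx], y[train_idx], grid=GridSpec.coarse(seed=11)
        )
        _, calls = predict(model, [feats[i] for i in test_idx])
        np.testing.assert_array_equal(calls, y[test_idx])

    def test_probabilities_in_unit_interval(self, trained):
        feats, _, model, _ = trained
        probs, _ = predict(model, feats)
        assert np.all(probs >= 0.0) and np.all(probs <= 1.0)

    def test_scheme_mismatch_rejected(self, trained):
        _, _, model, _ = trained
        bad = [FeatureVector(scheme="dipeptide", values=np.zeros(400))]
        with pytest.raises(ValueError, match="scheme"):
            predict(model, bad)

    def test_dimension_mismatch_rejected(self, trained):
        _, _, model, _ = trained
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((2, 7)))


class TestPersistence:
    def test_round_trip_identical_probabilities(self, trained, tmp_path):
        feats, _, model, _ = trained
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        p1, _ = predict(model, feats[:10])
        p2, _ = predict(back, feats[:10])
        np.testing.assert_array_equal(p1, p2)
        assert back.metadata == model.metadata
        assert (back.c, back.gamma, back.scheme) == (model.c, model.gamma, model.scheme)

    def test_alphabet_mismatch_rejected(self, trained, tmp_path):
        feats, _, model, _ = trained
        import joblib

        path = tmp_path / "model.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["metadata"]["alphabet"] = "YWVTSRQPNMLKIHGFEDCA"
        joblib.dump(payload, path)
        with pytest.raises(ModelFileError, match="alphabet"):
            load_model(path)

    def test_truncated_file_is_error_not_crash(self, trained, tmp_path):
        _, _, model, _ = trained
        path = tmp_path / "model.joblib"
        save_model(model, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ModelFileError):
            load_model(path)

    def test_version_mismatch_rejected(self, trained, tmp_path):
        _, _, model, _ = trained
        import joblib

        path = tmp_path / "model.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["format_version"] = 999
        joblib.dump(payload, path)
        with pytest.raises(ModelFileError, match="format_version"):
            load_model(path)


class TestGridSpec:
    def test_default_lattice_shape(self):
        g = GridSpec.default()
        assert g.c_values[0] == 2.0**-5 and g.c_values[-1] == 2.0**15
        assert g.gamma_values[0] == 2.0**-15 and g.gamma_values[-1] == 2.0**3
        assert g.folds == 5

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(c_values=(), gamma_values=(1.0,))
        with pytest.raises(ValueError):
            GridSpec(c_values=(1.0,), gamma_values=(-1.0,))
        with pytest.raises(ValueError):
            GridSpec(folds=1)
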