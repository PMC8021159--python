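import numpy as np
import pytest

from dropseg.classic_models import (
    BankMismatchError,
    ClassicHyperparams,
    PixelClassifier,
    UnsupportedModelOperation,
    load_model,
    save_model,
)
from dropseg.filters import FeatureStack


def separable_matrix(rng, n=2000, k=6):
    """Features with an 'identity' column; label = identity > 128."""
    X = rng.uniform(0, 255, size=(n, k)).astype(np.float32)
    y = (X[:, 0] > 128).astype(np.uint8)
    return X, y


def xor_matrix(rng, n=2000):
    """Two informative binary features whose XOR is the label, plus noise."""
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    X = np.column_stack(
        [a + rng.normal(0, 0.05, n), b + rng.normal(0, 0.05, n),
         rng.normal(size=n)]
    ).astype(np.float32)
    return X, (a ^ b).astype(np.uint8)


def stack_from(X, h, w, bank_id="bank-a"):
    return FeatureStack(values=X.reshape(h, w, -1), bank_id=bank_id)


class TestTraining:
    @pytest.mark.parametrize("method", ["rf", "xgb", "mlp", "lda"])
    def test_separable_data_learned_almost_perfectly(self, method, rng):
        X, y = separable_matrix(rng)
        model = PixelClassifier(method=method, seed=0).fit(X, y)
        acc = (model.predict(X) == y).mean()
        assert acc >= 0.99

    def test_xor_separates_tree_from_linear_models(self, rng):
        X, y = xor_matrix(rng)
        rf = PixelClassifier(method="rf", seed=0).fit(X, y)
        lda = PixelClassifier(method="lda", seed=0).fit(X, y)
        assert (rf.predict(X) == y).mean() >= 0.95
        assert (lda.predict(X) == y).mean() <= 0.60

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(50, 4))
        with pytest.raises(ValueError, match="single class"):
            PixelClassifier(method="rf").fit(X, np.zeros(50))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            PixelClassifier(method="rf").fit(np.empty((0, 4)), np.empty(0))

    def test_nonconvergence_recorded_not_fatal(self, rng):
        X, y = xor_matrix(rng, n=200)
        hp = ClassicHyperparams(method="mlp", mlp_max_iter=3)
        model = PixelClassifier(method="mlp", hyperparams=hp).fit(X, y)
        assert model.training_summary_["convergence_warnings"]

    def test_training_summary_reports_balance(self, rng):
        X, y = separable_matrix(rng, n=500)
        model = PixelClassifier(method="lda").fit(X, y)
        assert model.training_summary_["n_rows"] == 500
        assert model.training_summary_["positive_fraction"] == pytest.approx(
            y.mean()
        )


class TestClassification:
    def test_mask_shape_matches_stack(self, rng):
        X, y = separable_matrix(rng, n=15 * 7)
        model = PixelClassifier(method="rf", seed=0).fit(X, y, bank_id="bank-a")
        scores, mask = model.segment_stack(stack_from(X, 15, 7))
        assert scores.shape == (15, 7)
        assert mask.pixels.shape == (15, 7)

    def test_heldout_agreement_with_generating_rule(self, rng):
        X, y = separable_matrix(rng, n=4000)
        model = PixelClassifier(method="rf", seed=0).fit(X, y)
        Xh, yh = separable_matrix(rng, n=40 * 25)
        _, mask = model.segment_stack(stack_from(Xh, 40, 25, bank_id=None))
        assert (mask.pixels.ravel() == yh).mean() >= 0.99

    def test_scores_lie_in_unit_interval(self, rng):
        X, y = separable_matrix(rng, n=600)
        for method in ("rf", "xgb", "svm", "lda"):
            model = PixelClassifier(method=method, seed=0).fit(X, y)
            scores, _ = model.segment_stack(stack_from(X[:100], 10, 10, None))
            assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_bank_mismatch_rejected(self, rng):
        X, y = separable_matrix(rng, n=100)
        model = PixelClassifier(method="lda").fit(X, y, bank_id="bank-a")
        with pytest.raises(BankMismatchError):
            model.segment_stack(stack_from(X, 10, 10, bank_id="bank-b"))

    def test_deterministic_given_seed(self, rng):
        X, y = separable_matrix(rng, n=1000)
        Xp = X[:200]
        masks = []
        for _ in range(2):
            model = PixelClassifier(method="rf", seed=3).fit(X, y)
            _, mask = model.segment_stack(stack_from(Xp, 20, 10, None))
            masks.append(mask.pixels)
        np.testing.assert_array_equal(masks[0], masks[1])


class TestFeatureImportance:
    def test_importances_normalized_and_sorted(self, rng):
        X, y = separable_matrix(rng)
        model = PixelClassifier(method="rf", seed=0).fit(X, y)
        ranked = model.feature_importances()
        vals = [v for _, v in ranked]
        assert sum(vals) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in vals)
        assert vals == sorted(vals, reverse=True)

    def test_constant_feature_has_no_importance(self, rng):
        X, y = separable_matrix(rng)
        X[:, 3] = 42.0
        model = PixelClassifier(method="rf", seed=0).fit(X, y)
        imp = dict(model.feature_importances())
        assert imp["feature_3"] <= 1e-6

    def test_linear_model_unsupported(self, rng):
        X, y = separable_matrix(rng, n=200)
        model = PixelClassifier(method="lda").fit(X, y)
        with pytest.raises(UnsupportedModelOperation):
            model.feature_importances()


class TestPersistence:
    def test_save_load_preserves_classification(self, tmp_path, rng):
        X, y = separable_matrix(rng, n=800)
        model = PixelClassifier(method="xgb", seed=0).fit(X, y, bank_id="bank-a")
        probe = stack_from(X[:100], 10, 10, "bank-a")
        _, before = model.segment_stack(probe)
        path = tmp_path / "model.bin"
        save_model(model, path)
        loaded = load_model(path)
        _, after = loaded.segment_stack(probe)
        np.testing.assert_array_equal(before.pixels, after.pixels)
        assert loaded.bank_id_ == "bank-a"

    def test_load_missing_path(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "absent.bin")

    def test_load_corrupted_file(self, tmp_path):
        path = tmp_path / "garbage.bin"
        path.write_bytes(b"not a model")
        with pytest.raises(ValueError):
            load_model(path)

    def test_loaded_model_still_enforces_bank(self, tmp_path, rng):
        X, y = separable_matrix(rng, n=300)
        model = PixelClassifier(method="lda").fit(X, y, bank_id="bank-a")
        path = tmp_path / "model.bin"
        model.save(path)
        loaded = PixelClassifier.load(path)
        with pytest.raises(BankMismatchError):
            loaded.segment_stack(stack_from(X[:100], 10, 10, "bank-z"))


class TestHyperparams:
    def test_reference_defaults(self):
        hp = ClassicHyperparams(method="svm")
        assert hp.rf_n_estimators == 100
        assert hp.xgb_max_depth == 4 and hp.xgb_subsample == 0.5
        assert hp.svm_kernel == "poly" and hp.svm_degree == 3
        assert hp.svm_max_iter == 1000 and hp.svm_cache_mb == 5000
        assert hp.mlp_hidden_layers == (50, 25)
        assert hp.mlp_n_iter_no_change == 50
        assert hp.lda_solver == "svd"

    def test_thread_cap_is_advisory(self):
        hp = ClassicHyperparams(method="rf", n_threads=999)
        assert hp.effective_threads() <= 25

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ClassicHyperparams(method="boost")
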