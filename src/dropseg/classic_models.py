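"""The five non-convolutional per-pixel classifiers.

Each classifier consumes the flattened (n_pixels, k) feature matrix from
the filter bank and predicts lipid / non-lipid per pixel.  Backends are
scikit-learn (random forest, polynomial-kernel SVM, multilayer
perceptron, linear discriminant analysis) and XGBoost (gradient
boosting), configured with fixed reference hyperparameters:

    RF   100 estimators
    XGB  100 estimators, max depth 4, subsample 0.5
    SVM  polynomial kernel, degree 3, gamma "scale", max 1000 iterations
    MLP  hidden layers (50, 25), ReLU, Adam, max 1000 iterations,
         50 iterations without improvement
    LDA  SVD solver

Thread counts are advisory caps (the reference setting of 25 threads is
hardware-specific); all stochastic learners take an explicit seed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .filters import FeatureStack, FilterSpec, PixelMatrix
from .io import BinaryMask

METHODS = ("rf", "xgb", "svm", "mlp", "lda")

MODEL_FORMAT_VERSION = 1

_ADVISORY_THREAD_CAP = 25


class BankMismatchError(ValueError):
    """Features were extracted with a different bank than the model was trained on."""


class UnsupportedModelOperation(TypeError):
    """The requested introspection is not defined for this model family."""


@dataclass
class ClassicHyperparams:
    """Reference hyperparameters for one method; defaults are fixed above."""

    method: str = "rf"
    rf_n_estimators: int = 100
    xgb_n_estimators: int = 100
    xgb_max_depth: int = 4
    xgb_subsample: float = 0.5
    svm_kernel: str = "poly"
    svm_degree: int = 3
    svm_gamma: str = "scale"
    svm_max_iter: int = 1000
    svm_cache_mb: int = 5000
    mlp_hidden_layers: tuple[int, int] = (50, 25)
    mlp_activation: str = "relu"
    mlp_solver: str = "adam"
    mlp_max_iter: int = 1000
    mlp_n_iter_no_change: int = 50
    lda_solver: str = "svd"
    n_threads: int | None = None  # advisory; capped at 25

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        for name in ("rf_n_estimators", "xgb_n_estimators", "xgb_max_depth",
                     "svm_max_iter", "mlp_max_iter", "mlp_n_iter_no_change"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def effective_threads(self) -> int:
        cap = min(_ADVISORY_THREAD_CAP, os.cpu_count() or 1)
        return min(self.n_threads, cap) if self.n_threads else cap


def _build_backend(hp: ClassicHyperparams, seed: int):
    jobs = hp.effective_threads()
    if hp.method == "rf":
        return RandomForestClassifier(
            n_estimators=hp.rf_n_estimators, n_jobs=jobs, random_state=seed
        )
    if hp.method == "xgb":
        return XGBClassifier(
            n_estimators=hp.xgb_n_estimators,
            max_depth=hp.xgb_max_depth,
            subsample=hp.xgb_subsample,
            n_jobs=jobs,
            random_state=seed,
            tree_method="hist",
        )
    if hp.method == "svm":
        return SVC(
            kernel=hp.svm_kernel,
            degree=hp.svm_degree,
            gamma=hp.svm_gamma,
            max_iter=hp.svm_max_iter,
            cache_size=hp.svm_cache_mb,
            random_state=seed,
        )
    if hp.method == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=hp.mlp_hidden_layers,
            activation=hp.mlp_activation,
            solver=hp.mlp_solver,
            max_iter=hp.mlp_max_iter,
            n_iter_no_change=hp.mlp_n_iter_no_change,
            random_state=seed,
        )
    if hp.method == "lda":
        return LinearDiscriminantAnalysis(solver=hp.lda_solver)
    raise ValueError(hp.method)  # pragma: no cover


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class PixelClassifier(ClassifierMixin, BaseEstimator):
    """Per-pixel lipid / non-lipid classifier over filter-bank features.

    Parameters
    ----------
    method : one of ``"rf"``, ``"xgb"``, ``"svm"``, ``"mlp"``, ``"lda"``.
    seed : seed for every stochastic backend (default 0).
    hyperparams : optional :class:`ClassicHyperparams` override; when None
        the reference defaults for ``method`` are used.

    Score maps are posterior probabilities where the backend provides
    them; SVM and LDA decision values pass through a logistic squashing so
    every method exposes a uniform [0, 1] score for ROC analysis.  The
    binary decision uses each method's native rule (probability >= 0.5,
    equivalently a non-negative decision value).
    """

    def __init__(self, method: str = "rf", seed: int = 0,
                 hyperparams: ClassicHyperparams | None = None):
        self.method = method
        self.seed = seed
        self.hyperparams = hyperparams

    def _resolved_hp(self) -> ClassicHyperparams:
        if self.hyperparams is not None:
            if self.hyperparams.method != self.method.lower():
                raise ValueError("hyperparams.method disagrees with method")
            return self.hyperparams
        return ClassicHyperparams(method=self.method)

    def fit(self, X, y, bank_id: str | None = None):
        if isinstance(X, PixelMatrix):
            bank_id = X.bank_id if bank_id is None else bank_id
            X, y = X.data, X.labels
        X = np.asarray(X)
        y = np.asarray(y).ravel()
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training matrix must be 2D and non-empty")
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature rows and labels differ in length")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                f"training labels contain a single class ({classes.tolist()}); "
                "both lipid and non-lipid pixels are required"
            )
        hp = self._resolved_hp()
        model = _build_backend(hp, self.seed)
        caught: list[str] = []
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
        for w in rec:
            if issubclass(w.category, ConvergenceWarning):
                caught.append(str(w.message))
        self.model_ = model
        self.hyperparams_ = hp
        self.bank_id_ = bank_id
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.training_summary_ = {
            "n_rows": int(X.shape[0]),
            "positive_fraction": float(np.mean(y == 1)),
            "convergence_warnings": caught,
        }
        return self

    def _check_bank(self, bank_id: str | None) -> None:
        if self.bank_id_ is not None and bank_id is not None and bank_id != self.bank_id_:
            raise BankMismatchError(
                f"feature bank {bank_id!r} does not match the training bank "
                f"{self.bank_id_!r}"
            )

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        """[0, 1] score per row (probability or squashed decision value)."""
        check_is_fitted(self, "model_")
        if hasattr(self.model_, "predict_proba"):
            return self.model_.predict_proba(X)[:, 1]
        return _logistic(self.model_.decision_function(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if isinstance(X, PixelMatrix):
            self._check_bank(X.bank_id)
            X = X.data
        return np.asarray(self.model_.predict(X)).astype(np.uint8)

    def segment_stack(self, stack: FeatureStack) -> tuple[np.ndarray, BinaryMask]:
        """Classify every pixel of one feature stack.

        Returns the (h, w) score map in [0, 1] and the binary mask from
        the method's native decision rule.
        """
        check_is_fitted(self, "model_")
        self._check_bank(stack.bank_id)
        if stack.k != self.n_features_in_:
            raise ValueError(
                f"stack depth {stack.k} != trained feature count {self.n_features_in_}"
            )
        rows = stack.values.reshape(-1, stack.k)
        scores = self.predict_proba_rows(rows).reshape(stack.height, stack.width)
        labels = self.model_.predict(rows).reshape(stack.height, stack.width)
        return scores, BinaryMask(pixels=labels.astype(np.uint8))

    def feature_importances(
        self, specs: tuple[FilterSpec, ...] | None = None
    ) -> list[tuple[str, float]]:
        """Ranked (filter id, importance) pairs for tree-ensemble models.

        Importances are non-negative and normalized to sum to 1; only
        random forest and XGBoost expose interpretable per-feature
        importance.
        """
        check_is_fitted(self, "model_")
        if self.method.lower() not in ("rf", "xgb"):
            raise UnsupportedModelOperation(
                f"feature importance is only defined for tree ensembles, not "
                f"{self.method!r}"
            )
        imp = np.asarray(self.model_.feature_importances_, dtype=np.float64)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        names = (
            [s.id for s in specs]
            if specs is not None
            else [f"feature_{i}" for i in range(imp.size)]
        )
        ranked = sorted(zip(names, imp.tolist()), key=lambda t: -t[1])
        return ranked

    def save(self, path: str) -> None:
        """Persist as a single version-tagged blob (header + fitted backend)."""
        check_is_fitted(self, "model_")
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "method": self.method,
                "seed": self.seed,
                "bank_id": self.bank_id_,
                "hyperparams": asdict(self.hyperparams_),
                "n_features_in": self.n_features_in_,
                "training_summary": self.training_summary_,
                "model": self.model_,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "PixelClassifier":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        try:
            blob = joblib.load(path)
            version = blob["format_version"]
            method = blob["method"]
        except Exception as exc:  # corrupted or foreign file
            raise ValueError(f"{path}: not a readable model file ({exc})") from exc
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported model format version {version}"
            )
        hp_dict = dict(blob["hyperparams"])
        hp_dict["mlp_hidden_layers"] = tuple(hp_dict["mlp_hidden_layers"])
        est = cls(method=method, seed=blob["seed"],
                  hyperparams=ClassicHyperparams(**hp_dict))
        est.model_ = blob["model"]
        est.hyperparams_ = est.hyperparams
        est.bank_id_ = blob["bank_id"]
        est.n_features_in_ = blob["n_features_in"]
        est.training_summary_ = blob["training_summary"]
        est.classes_ = np.array([0, 1], dtype=np.uint8)
        return est


def train_pixel_classifier(
    matrix: PixelMatrix, hp: ClassicHyperparams | None = None,
    method: str = "rf", seed: int = 0,
) -> PixelClassifier:
    """Fit one classifier on a flattened pixel matrix (thin wrapper)."""
    if hp is not None:
        method = hp.method
    return PixelClassifier(method=method, seed=seed, hyperparams=hp).fit(matrix, None)


def classify_pixels(
    model: PixelClassifier, stack: FeatureStack
) -> tuple[np.ndarray, BinaryMask]:
    """Apply a trained classifier to a feature stack (thin wrapper)."""
    return model.segment_stack(stack)


def feature_importances(model: PixelClassifier, specs=None):
    return model.feature_importances(specs)


def save_model(model: PixelClassifier, path: str) -> None:
    model.save(path)


def load_model(path: str) -> PixelClassifier:
    return PixelClassifier.load(path)
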