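"""Final-model evaluation: ELM / RF / SVM with grid search and metric tables.

The ELM is a single-hidden-layer network with random fixed input weights and
pseudoinverse-fitted output weights.  RF and SVM come from scikit-learn.
Hyperparameters for all three are chosen by stratified 5-fold CV accuracy on
the training partition; the test partition never influences preprocessing
statistics, band selection, or the grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import SpectraSet, make_preprocessor

__all__ = [
    "EvalProtocol",
    "ELMClassifier",
    "grid_search_classifier",
    "compute_metrics",
    "run_experiment_grid",
]


@dataclass
class EvalProtocol:
    """Split, grids and metrics for the classifier comparison."""

    test_fraction: float = 0.2
    seed: int = 0
    elm_hidden_grid: tuple = tuple(range(30, 101, 10))
    rf_n_trees: int = 300
    rf_depth_grid: tuple = tuple(range(1, 21))
    svm_c_grid: tuple = tuple(2.0**e for e in range(-5, 16, 2))
    svm_gamma_grid: tuple = tuple(2.0**e for e in range(-15, 4, 2))
    cv_folds: int = 5

    def to_dict(self) -> dict:
        return {
            "test_fraction": self.test_fraction,
            "seed": self.seed,
            "elm_hidden_grid": list(self.elm_hidden_grid),
            "rf_n_trees": self.rf_n_trees,
            "rf_depth_grid": list(self.rf_depth_grid),
            "svm_c_grid": list(self.svm_c_grid),
            "svm_gamma_grid": list(self.svm_gamma_grid),
            "cv_folds": self.cv_folds,
        }


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine with sigmoid hidden units.

    Input weights and biases are drawn once from U(-1, 1); output weights are
    the Moore-Penrose least-squares solution onto one-hot targets.
    """

    def __init__(self, n_hidden: int = 50, seed: int = 0) -> None:
        self.n_hidden = n_hidden
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("ELM needs at least two training samples")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self.classes_, y_idx = np.unique(np.asarray(y), return_inverse=True)
        rng = np.random.default_rng(self.seed)
        self.W_ = rng.uniform(-1.0, 1.0, size=(X.shape[1], self.n_hidden))
        self.b_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._hidden(X)
        T = np.eye(len(self.classes_))[y_idx]
        self.beta_ = np.linalg.pinv(H) @ T
        return self

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(X @ self.W_ + self.b_)))

    def predict(self, X):
        scores = self._hidden(np.asarray(X, dtype=float)) @ self.beta_
        return self.classes_[np.argmax(scores, axis=1)]


def _cv_accuracy(make_model, X, y, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = make_model().fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def grid_search_classifier(kind: str, X, y, protocol: EvalProtocol | None = None):
    """Pick the best grid point by stratified CV accuracy and refit on all of X.

    Returns ``(fitted_model, chosen_params)``.
    """
    protocol = protocol or EvalProtocol()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < protocol.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{protocol.cv_folds} CV folds"
        )

    kind = kind.lower()
    if kind == "elm":
        grid = [{"n_hidden": h} for h in protocol.elm_hidden_grid]
        factory = lambda p: ELMClassifier(n_hidden=p["n_hidden"], seed=protocol.seed)
    elif kind == "rf":
        grid = [{"max_depth": d} for d in protocol.rf_depth_grid]
        factory = lambda p: RandomForestClassifier(
            n_estimators=protocol.rf_n_trees,
            max_depth=p["max_depth"],
            random_state=protocol.seed,
            n_jobs=1,
        )
    elif kind == "svm":
        grid = [
            {"C": c, "gamma": g}
            for c in protocol.svm_c_grid
            for g in protocol.svm_gamma_grid
        ]
        factory = lambda p: SVC(
            kernel="rbf", C=p["C"], gamma=p["gamma"], random_state=protocol.seed
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")

    best_params, best_acc = None, -1.0
    for params in grid:
        acc = _cv_accuracy(
            lambda: factory(params), X, y, protocol.cv_folds, protocol.seed
        )
        if acc > best_acc:
            best_params, best_acc = params, acc
    model = factory(best_params).fit(X, y)
    return model, dict(best_params)


def compute_metrics(y_true, y_pred) -> dict:
    """Accuracy plus macro precision/recall/F1 (0/0 counted as 0)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0, labels=np.unique(y_true)
    )
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "macro_precision": float(prec),
        "macro_recall": float(rec),
        "macro_f1": float(f1),
    }


def run_experiment_grid(
    spectra: SpectraSet,
    protocol: EvalProtocol | None = None,
    preprocessors: tuple = ("raw",),
    selectors: dict | None = None,
    classifiers: tuple = ("elm", "rf", "svm"),
) -> pd.DataFrame:
    """One evaluation row per (preprocessor, selector, classifier) combination.

    ``selectors`` maps a name to a callable ``(X_train, y_train) -> mask`` or
    to ``None`` for the full-band baseline.  Selection and all fitted
    statistics use the training partition only; the mask is then applied to
    both partitions.
    """
    protocol = protocol or EvalProtocol()
    selectors = selectors or {"full": None}

    idx = np.arange(spectra.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=protocol.test_fraction,
        stratify=spectra.labels,
        random_state=protocol.seed,
    )
    train_set = spectra.subset_samples(train_idx)
    test_set = spectra.subset_samples(test_idx)

    rows = []
    for prep_name in preprocessors:
        prep = make_preprocessor(prep_name)
        prep.fit(train_set)
        ptr = prep.transform(train_set)
        pte = prep.transform(test_set)
        for sel_name, selector in selectors.items():
            try:
                if selector is None:
                    mask = np.ones(spectra.n_bands, dtype=bool)
                else:
                    mask = np.asarray(
                        selector(ptr.reflectance, ptr.labels), dtype=bool
                    )
                Xtr = ptr.reflectance[:, mask]
                Xte = pte.reflectance[:, mask]
                scaler = StandardScaler().fit(Xtr)
                Ztr, Zte = scaler.transform(Xtr), scaler.transform(Xte)
                for clf_name in classifiers:
                    model, params = grid_search_classifier(
                        clf_name, Ztr, ptr.labels, protocol
                    )
                    train_metrics = compute_metrics(ptr.labels, model.predict(Ztr))
                    test_metrics = compute_metrics(pte.labels, model.predict(Zte))
                    rows.append(
                        {
                            "preprocess": prep_name,
                            "selector": sel_name,
                            "classifier": clf_name,
                            "n_bands": int(mask.sum()),
                            "params": str(params),
                            "train_accuracy": train_metrics["accuracy"],
                            "test_accuracy": test_metrics["accuracy"],
                            "macro_precision": test_metrics["macro_precision"],
                            "macro_recall": test_metrics["macro_recall"],
                            "macro_f1": test_metrics["macro_f1"],
                        }
                    )
            except Exception as exc:
                raise RuntimeError(
                    f"evaluation failed for combination "
                    f"({prep_name}, {sel_name})"
                ) from exc
    return pd.DataFrame(rows)
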