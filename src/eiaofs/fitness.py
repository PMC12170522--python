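"""Wrapper objective for subset selection: KNN error plus a size penalty.

The objective of a candidate band subset is

    fitness = alpha * knn_error + (1 - alpha) * n_selected / n_total

with lower values better.  The KNN error is measured on a fixed, seeded
evaluation split (stratified holdout by default, k-fold optionally) so that
every fitness call inside one optimizer run sees the same partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

__all__ = ["FitnessConfig", "SubsetEvaluator", "knn_error", "subset_fitness"]


@dataclass
class FitnessConfig:
    """Parameters of the wrapper objective.

    ``alpha`` weights the error term; the size penalty gets ``1 - alpha``.
    """

    alpha: float = 0.99
    knn_k: int = 3
    scheme: str = "holdout"  # "holdout" or "kfold"
    test_fraction: float = 0.3
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.knn_k < 1:
            raise ValueError(f"knn_k must be >= 1, got {self.knn_k}")
        if self.scheme not in ("holdout", "kfold"):
            raise ValueError(f"unknown evaluation scheme {self.scheme!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def subset_fitness(error: float, n_selected: int, n_total: int, alpha: float) -> float:
    """Combine a classification error and a subset size into one objective."""
    if n_selected == 0:
        raise ValueError("fitness of an empty subset is undefined")
    if not 0.0 <= error <= 1.0:
        raise ValueError(f"error rate must lie in [0, 1], got {error}")
    return alpha * error + (1.0 - alpha) * n_selected / n_total


def _knn_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, k: int) -> np.ndarray:
    """Euclidean KNN; voting ties broken by the single nearest neighbour."""
    d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, kind="stable", axis=1)[:, :k]
    neigh = ytr[order]  # (n_test, k), nearest first
    n_classes = int(ytr.max()) + 1
    pred = np.empty(len(Xte), dtype=ytr.dtype)
    for i in range(len(Xte)):
        counts = np.bincount(neigh[i], minlength=n_classes)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            pred[i] = winners[0]
        else:
            # first neighbour whose class is among the tied winners
            for lab in neigh[i]:
                if lab in winners:
                    pred[i] = lab
                    break
    return pred


class SubsetEvaluator:
    """Callable objective mapping a band mask to its wrapper fitness.

    The evaluation split is drawn once at construction and reused for every
    call; results are cached per mask, so re-evaluating a mask is free.
    Features are z-scored with training-partition statistics before the
    distance computation.
    """

    def __init__(self, X: np.ndarray, y, config: FitnessConfig | None = None) -> None:
        self.config = config or FitnessConfig()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        labels, self.y = np.unique(np.asarray(y), return_inverse=True)
        self.classes_ = labels
        if self.y.size != self.X.shape[0]:
            raise ValueError("label count does not match the number of rows")
        self.n_total = self.X.shape[1]
        self._splits = self._make_splits()
        self._check_class_sizes()
        self._cache: dict[bytes, tuple[float, float]] = {}

    def _make_splits(self) -> list[tuple[np.ndarray, np.ndarray]]:
        cfg = self.config
        if cfg.scheme == "holdout":
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=cfg.test_fraction, random_state=cfg.seed
            )
        else:
            splitter = StratifiedKFold(
                n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
            )
        return [(tr, te) for tr, te in splitter.split(self.X, self.y)]

    def _check_class_sizes(self) -> None:
        k = self.config.knn_k
        for tr, _ in self._splits:
            counts = np.bincount(self.y[tr], minlength=len(self.classes_))
            short = np.flatnonzero(counts < k)
            if short.size:
                raise ValueError(
                    f"class {self.classes_[short[0]]!r} has only "
                    f"{counts[short[0]]} training samples, fewer than k={k}"
                )

    def _mask_indices(self, mask) -> np.ndarray:
        m = np.asarray(mask)
        if m.dtype == bool or (m.size == self.n_total and np.all((m == 0) | (m == 1))):
            idx = np.flatnonzero(m)
        else:
            idx = np.unique(m.astype(int))
        if idx.size == 0:
            raise ValueError("cannot evaluate an empty band subset")
        if idx.min() < 0 or idx.max() >= self.n_total:
            raise ValueError("band index out of range")
        return idx

    def error(self, mask) -> float:
        """Misclassification rate of KNN restricted to the masked columns."""
        return self._evaluate(mask)[0]

    def accuracy(self, mask) -> float:
        return 1.0 - self._evaluate(mask)[0]

    def __call__(self, mask) -> float:
        return self._evaluate(mask)[1]

    def _evaluate(self, mask) -> tuple[float, float]:
        idx = self._mask_indices(mask)
        key = idx.astype(np.int32).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Xs = self.X[:, idx]
        errors = []
        for tr, te in self._splits:
            mu = Xs[tr].mean(axis=0)
            sd = Xs[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Ztr = (Xs[tr] - mu) / sd
            Zte = (Xs[te] - mu) / sd
            pred = _knn_predict(Ztr, self.y[tr], Zte, self.config.knn_k)
            errors.append(float(np.mean(pred != self.y[te])))
        err = float(np.mean(errors))
        fit = subset_fitness(err, idx.size, self.n_total, self.config.alpha)
        self._cache[key] = (err, fit)
        return err, fit


def knn_error(X: np.ndarray, y, mask, cfg: FitnessConfig | None = None) -> float:
    """One-off KNN error of a band subset under the configured split."""
    return SubsetEvaluator(X, y, cfg).error(mask)
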