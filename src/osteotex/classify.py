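"""RBF-SVM training with a deterministic cross-validated log-grid search."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from osteotex.errors import DataError, LabelError, SchemaError

#: 13-point log grid spanning 1e-3 .. 1e3 for both C and the kernel scale.
DEFAULT_GRID = tuple(np.logspace(-3, 3, 13))


@dataclass
class TrainedClassifier:
    """Standardization stats + fitted RBF SVM + training metadata.

    The kernel is K(x, z) = exp(-||x - z||^2 / kernel_scale^2); the
    decision function is evaluated in numpy from the stored support
    vectors so serialized models reproduce scores exactly.
    """

    feature_names: tuple[str, ...]
    mu: np.ndarray
    sd: np.ndarray
    box_constraint: float
    kernel_scale: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    classes: tuple
    cv_error: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def gamma(self) -> float:
        return 1.0 / (self.kernel_scale**2)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mu) / self.sd

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed score, positive for the second (disease) class."""
        Z = self._standardize(X)
        sq = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        kernel = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return kernel @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray):
        scores = self.decision_function(X)
        out = np.where(scores >= 0, 1, 0)
        return np.asarray(self.classes)[out]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "mu": self.mu.tolist(),
            "sd": self.sd.tolist(),
            "box_constraint": self.box_constraint,
            "kernel_scale": self.kernel_scale,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "classes": [int(c) if isinstance(c, (int, np.integer)) else c for c in self.classes],
            "cv_error": self.cv_error,
            "seed": self.seed,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedClassifier":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(payload["feature_names"]),
            mu=np.asarray(payload["mu"]),
            sd=np.asarray(payload["sd"]),
            box_constraint=payload["box_constraint"],
            kernel_scale=payload["kernel_scale"],
            support_vectors=np.asarray(payload["support_vectors"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            intercept=payload["intercept"],
            classes=tuple(payload["classes"]),
            cv_error=payload["cv_error"],
            seed=payload["seed"],
            meta=payload.get("meta", {}),
        )


def _fit_svc(Z: np.ndarray, y01: np.ndarray, c: float, gamma: float) -> SVC:
    svc = SVC(C=c, kernel="rbf", gamma=gamma)
    svc.fit(Z, y01)
    return svc


def train_svm(
    X,
    y,
    seed: int = 0,
    c_grid=DEFAULT_GRID,
    scale_grid=DEFAULT_GRID,
    n_folds: int = 10,
    feature_names: tuple[str, ...] | None = None,
) -> TrainedClassifier:
    """Grid-search C and kernel scale by stratified K-fold CV error.

    Ties resolve to the smaller C, then the larger kernel scale; the winner
    is refit on all data.  Standardization statistics come from the
    training data only.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] < 20:
        raise DataError("need at least 20 samples")
    classes = np.unique(y)
    if classes.size != 2:
        raise LabelError("need exactly 2 classes")
    y01 = (y == classes[1]).astype(int)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    folds = list(skf.split(Z, y01))

    best = None  # (error, C, kernel_scale)
    for c in c_grid:  # ascending C
        for ks in sorted(scale_grid, reverse=True):  # descending scale
            gamma = 1.0 / (ks * ks)
            wrong = 0
            total = 0
            for tr, te in folds:
                svc = _fit_svc(Z[tr], y01[tr], c, gamma)
                wrong += int(np.sum(svc.predict(Z[te]) != y01[te]))
                total += len(te)
            err = wrong / total
            if best is None or err < best[0] - 1e-15:
                best = (err, float(c), float(ks))
    cv_error, c_star, ks_star = best

    final = _fit_svc(Z, y01, c_star, 1.0 / ks_star**2)
    return TrainedClassifier(
        feature_names=tuple(feature_names) if feature_names else tuple(f"f{j}" for j in range(X.shape[1])),
        mu=mu,
        sd=sd,
        box_constraint=c_star,
        kernel_scale=ks_star,
        support_vectors=final.support_vectors_.copy(),
        dual_coef=final.dual_coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        classes=tuple(classes.tolist()),
        cv_error=float(cv_error),
        seed=int(seed),
    )


def decision_scores(clf: TrainedClassifier, X, feature_names=None) -> np.ndarray:
    """Signed decision value per row; positive predicts the disease class."""
    if feature_names is not None and tuple(feature_names) != tuple(clf.feature_names):
        raise SchemaError(
            f"feature mismatch: model expects {clf.feature_names}, got {tuple(feature_names)}"
        )
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(clf.feature_names):
        raise SchemaError("feature matrix width does not match the trained model")
    return clf.decision_function(X)
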