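"""Supervised classification of genomic signatures under a fold plan.

Backends: an RBF-kernel SVM (features z-scored on the training folds), a
Random Forest with the Gini criterion, a 1-nearest-neighbour classifier over
a user-supplied pairwise distance (the contract through which digital
signal processing style pipelines plug in), and an optional two-hidden-layer
neural network (512 and 64 units, ReLU, dropout 0.5) that requires torch.

Hyperparameters not dictated by the method are fixed, seeded defaults
(recorded in ``DEFAULT_HYPERPARAMETERS``) — reproducibility is preferred
over per-dataset tuning because the claims of interest are qualitative
accuracy orderings, not backend optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .folds import FoldPlan

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "DEFAULT_HYPERPARAMETERS",
    "fit_predict",
    "run_cv",
    "pearson_distance",
    "BACKENDS",
]

DEFAULT_HYPERPARAMETERS = {
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "random_forest_gini": {"n_estimators": 100, "criterion": "gini"},
    "ann": {"hidden": (512, 64), "dropout": 0.5, "epochs": 50,
            "lr": 1e-3, "batch_size": 32},
    "distance_based": {"metric": "pearson"},
}

BACKENDS = tuple(DEFAULT_HYPERPARAMETERS)


@dataclass
class ClassifierSpec:
    """Backend id + hyperparameter overrides + seed."""

    backend: str = "random_forest_gini"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def params(self) -> dict:
        if self.backend not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(f"unknown backend {self.backend!r}")
        p = dict(DEFAULT_HYPERPARAMETERS[self.backend])
        p.update(self.hyperparameters)
        return p


@dataclass
class CVResult:
    """Per-fold and mean cross-validation accuracy, in percent."""

    fold_accuracies: list[float]
    fold_plan_mode: str
    label_scheme: str
    k: int | None = None
    backend: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def pearson_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(1 - Pearson r) / 2 between rows of a and rows of b, in [0, 1]."""
    return cdist(a, b, metric="correlation") / 2.0


def _ann_fit_predict(spec: ClassifierSpec, train_X, train_y, test_X):
    try:
        import torch
        from torch import nn
    except ImportError as exc:  # pragma: no cover - torch is an optional extra
        raise ImportError(
            "the 'ann' backend requires torch (install the [ann] extra)"
        ) from exc
    p = spec.params()
    torch.manual_seed(spec.seed)
    classes, y_idx = np.unique(train_y, return_inverse=True)
    model = nn.Sequential(
        nn.Linear(train_X.shape[1], p["hidden"][0]), nn.ReLU(), nn.Dropout(p["dropout"]),
        nn.Linear(p["hidden"][0], p["hidden"][1]), nn.ReLU(), nn.Dropout(p["dropout"]),
        nn.Linear(p["hidden"][1], len(classes)),
    )
    opt = torch.optim.Adam(model.parameters(), lr=p["lr"])
    loss_fn = nn.CrossEntropyLoss()
    X = torch.as_tensor(np.asarray(train_X), dtype=torch.float32)
    y = torch.as_tensor(y_idx, dtype=torch.long)
    model.train()
    for _ in range(p["epochs"]):
        perm = torch.randperm(len(X))
        for start in range(0, len(X), p["batch_size"]):
            sl = perm[start:start + p["batch_size"]]
            opt.zero_grad()
            loss = loss_fn(model(X[sl]), y[sl])
            loss.backward()
            opt.step()
    model.eval()
    with torch.no_grad():
        pred = model(torch.as_tensor(np.asarray(test_X),
                                     dtype=torch.float32)).argmax(1).numpy()
    return classes[pred]


def fit_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: Sequence,
    test_X: np.ndarray,
    distance_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Train the backend on (train_X, train_y) and predict labels for test_X."""
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train/test dimensionality mismatch")
    classes = np.unique(train_y)
    if len(classes) == 1:
        return np.full(len(test_X), classes[0])
    p = spec.params()
    if spec.backend == "svm_rbf":
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=p["C"], gamma=p["gamma"], random_state=spec.seed))
        model.fit(train_X, train_y)
        return model.predict(test_X)
    if spec.backend == "random_forest_gini":
        model = RandomForestClassifier(
            n_estimators=p["n_estimators"], criterion=p["criterion"],
            random_state=spec.seed, n_jobs=1)
        model.fit(train_X, train_y)
        return model.predict(test_X)
    if spec.backend == "distance_based":
        fn = distance_fn or pearson_distance
        d = np.asarray(fn(test_X, train_X))
        return train_y[np.argmin(d, axis=1)]
    if spec.backend == "ann":
        return _ann_fit_predict(spec, train_X, train_y, test_X)
    raise ValueError(f"unknown backend {spec.backend!r}")


def run_cv(
    signatures: np.ndarray,
    labels: Sequence,
    plan: FoldPlan,
    spec: ClassifierSpec,
    k: int | None = None,
    label_scheme: str = "",
    distance_fn: Callable | None = None,
) -> CVResult:
    """Cross-validate: for each fold, fit on the complement and score on the fold.

    Accuracy is reported in percent; the mean is the average of per-fold
    accuracies, mirroring standard stratified cross-validation reporting.
    """
    X = np.asarray(signatures, dtype=float)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("signatures and labels must align")
    plan.validate(len(y))
    accs = []
    for test_idx in plan.folds:
        if len(test_idx) == 0:
            raise ValueError("empty fold in plan")
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        if len(np.unique(y[mask])) == 1:
            import logging
            logging.getLogger(__name__).warning("single-class training fold")
        pred = fit_predict(spec, X[mask], y[mask], X[test_idx],
                           distance_fn=distance_fn)
        accs.append(100.0 * float(np.mean(pred == y[test_idx])))
    return CVResult(fold_accuracies=accs, fold_plan_mode=plan.mode,
                    label_scheme=label_scheme, k=k, backend=spec.backend)
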