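"""Two-layer classification: one-class authentication and multi-class identification.

The first layer is a one-class SVM with an RBF kernel trained only on
non-intruder (enrolled) feature vectors; any vector the decision function
rejects is treated as an intruder.  ``nu`` upper-bounds the fraction of
training errors (and lower-bounds the support-vector fraction); ``gamma``
sets the RBF width.  The second layer is a multi-class linear SVM
identifying which enrolled subject produced an accepted vector, scored by
stratified k-fold cross-validated accuracy.

Biometric rates are counted per instance (epoch):
TAR = accepted genuine / genuine, TRR = rejected intruders / intruders,
FAR = 1 - TRR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, OneClassSVM

__all__ = [
    "AuthModel",
    "AuthMetrics",
    "train_one_class",
    "evaluate_authentication",
    "crossval_identification",
    "authenticate_then_identify",
]


@dataclass
class AuthModel:
    """Fitted one-class decision function plus its training metadata."""

    svm: OneClassSVM
    nu: float
    gamma: float
    n_features: int
    metadata: dict = field(default_factory=dict)

    def accepts(self, vectors: np.ndarray) -> np.ndarray:
        """Boolean acceptance per row, from the natural zero decision boundary."""
        vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
        if vectors.shape[1] != self.n_features:
            raise ValueError(
                f"vectors have {vectors.shape[1]} features, model expects {self.n_features}"
            )
        return self.svm.predict(vectors) == 1


@dataclass(frozen=True)
class AuthMetrics:
    """Instance-level authentication rates; FAR = 1 - TRR by construction."""

    tar: float
    trr: float
    n_genuine: int
    n_genuine_accepted: int
    n_intruder: int
    n_intruder_accepted: int

    @property
    def far(self) -> float:
        return 1.0 - self.trr


def train_one_class(features: np.ndarray, nu: float, gamma: float,
                    metadata: dict | None = None) -> AuthModel:
    """Train the RBF one-class SVM on enrolled-subject feature vectors.

    The nu-SVM dual degenerates at the ends of the admissible range: below
    ``1/n`` the box constraints cannot sum to one, and at exactly 1 every
    point must be an outlier, which the solver cannot represent with finite
    coefficients.  The value passed to the solver is therefore clipped to
    ``[1/n_instances, 0.999]``; the requested nu is kept as the model's
    reported parameter.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 instances")
    if not (0 < nu <= 1):
        raise ValueError(f"nu must lie in (0, 1], got {nu}")
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    effective_nu = min(max(nu, 1.0 / features.shape[0]), 0.999)
    svm = OneClassSVM(kernel="rbf", nu=effective_nu, gamma=gamma)
    svm.fit(features)
    return AuthModel(svm=svm, nu=nu, gamma=gamma, n_features=features.shape[1],
                     metadata=dict(metadata or {}))


def evaluate_authentication(model: AuthModel, genuine: np.ndarray,
                            intruder: np.ndarray) -> AuthMetrics:
    """Count instance-level acceptances on genuine and intruder vectors."""
    genuine = np.atleast_2d(np.asarray(genuine, dtype=np.float64))
    intruder = np.atleast_2d(np.asarray(intruder, dtype=np.float64))
    if genuine.size == 0:
        raise ValueError("genuine set is empty")
    if intruder.size == 0:
        raise ValueError("intruder set is empty")
    acc_gen = model.accepts(genuine)
    acc_int = model.accepts(intruder)
    return AuthMetrics(
        tar=float(np.mean(acc_gen)),
        trr=float(np.mean(~acc_int)),
        n_genuine=len(acc_gen),
        n_genuine_accepted=int(np.sum(acc_gen)),
        n_intruder=len(acc_int),
        n_intruder_accepted=int(np.sum(acc_int)),
    )


def crossval_identification(features: np.ndarray, labels, k: int = 10,
                            seed: int = 0, C: float = 1.0) -> tuple[float, float]:
    """Mean and std of stratified k-fold accuracies of a linear multi-class SVM.

    Fold assignment uses a fixed shuffle seed, so results are deterministic
    for a given (features, labels, k, seed).
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has only {counts.min()} instances, fewer than "
            f"k={k} folds; use a smaller k"
        )
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies = []
    for train_idx, test_idx in folds.split(features, labels):
        clf = SVC(kernel="linear", C=C)
        clf.fit(features[train_idx], labels[train_idx])
        accuracies.append(float(clf.score(features[test_idx], labels[test_idx])))
    return float(np.mean(accuracies)), float(np.std(accuracies))


def authenticate_then_identify(model: AuthModel, identifier, vectors: np.ndarray):
    """Two-stage flow: identify an instance only if the first layer accepts it.

    ``identifier`` is any fitted classifier with a ``predict`` method.
    Returns a list with one entry per row: the predicted subject label for
    accepted instances, None for rejected ones.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    accepted = model.accepts(vectors)
    out: list = [None] * len(accepted)
    if accepted.any():
        preds = identifier.predict(vectors[accepted])
        for slot, p in zip(np.flatnonzero(accepted), preds):
            out[slot] = p
    return out
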