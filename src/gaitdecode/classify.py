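"""Dimensionality reduction (PCA at 90 % variance) and the sparse logistic
regression classifier.

PCA is fitted on training trials only; the test set is centred with the
training mean and projected with the training loadings.  The classifier is
L1-regularised logistic regression with the regularisation strength chosen
by internal stratified 5-fold CV on the training set; features are
standardised with training statistics so the sparsity pattern is meaningful
across heterogeneous time–frequency magnitudes.  The decision rule is
change-speed iff P(change) > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegressionCV

from .featselect import _encode_labels

PCA_VARIANCE = 0.90


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray          # (n_retained, n_features), orthonormal rows
    explained_ratio: np.ndarray
    n_retained: int

    def __post_init__(self) -> None:
        if self.loadings.shape[0] != self.n_retained:
            raise ValueError("loadings row count must equal retained dimension")


@dataclass
class SLRModel:
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    coef: np.ndarray
    intercept: float
    C: float
    seed: int

    @property
    def nonzero_indices(self) -> np.ndarray:
        return np.nonzero(self.coef)[0]

    @property
    def sparsity(self) -> float:
        """Fraction of exactly-zero weights."""
        return float(np.mean(self.coef == 0.0))


def fit_pca(train_features: np.ndarray, variance: float = PCA_VARIANCE) -> PCAModel:
    """Centred PCA keeping the smallest dimension reaching ``variance``."""
    X = np.asarray(train_features, float)
    if X.shape[0] < 2:
        raise ValueError("need at least two training trials for PCA")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("training features have zero variance")
    max_dim = min(X.shape[0] - 1, X.shape[1])
    if variance >= 1.0:
        pca = PCA(n_components=max_dim, svd_solver="full")
    else:
        pca = PCA(n_components=variance, svd_solver="full")
    pca.fit(X)
    return PCAModel(mean=pca.mean_, loadings=pca.components_,
                    explained_ratio=pca.explained_variance_ratio_,
                    n_retained=pca.components_.shape[0])


def project(features: np.ndarray, model: PCAModel) -> np.ndarray:
    X = np.asarray(features, float)
    if X.shape[-1] != model.mean.shape[0]:
        raise ValueError("feature dimensionality does not match the PCA model")
    return (X - model.mean) @ model.loadings.T


def fit_slr(X: np.ndarray, y, seed: int = 0,
            Cs: np.ndarray | None = None, cv: int = 5) -> SLRModel:
    """Sparse logistic regression with internally cross-validated strength."""
    X = np.asarray(X, float)
    yb = _encode_labels(y)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    n_min = int(np.bincount(yb).min())
    folds = max(2, min(cv, n_min))
    clf = LogisticRegressionCV(
        Cs=Cs if Cs is not None else np.logspace(-2, 2, 9),
        cv=folds, l1_ratios=[1.0], scoring="accuracy", solver="liblinear",
        random_state=seed, max_iter=2000, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(Xs, yb)
    return SLRModel(scaler_mean=mean, scaler_std=std,
                    coef=clf.coef_.ravel(), intercept=float(clf.intercept_[0]),
                    C=float(np.atleast_1d(clf.C_)[0]), seed=seed)


def predict_proba(model: SLRModel, X: np.ndarray) -> np.ndarray:
    """P(change-speed) per trial."""
    Xs = (np.asarray(X, float) - model.scaler_mean) / model.scaler_std
    z = Xs @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


def predict(model: SLRModel, X: np.ndarray) -> np.ndarray:
    """1 = change-speed (P > 0.5), 0 = constant-speed (P ≤ 0.5)."""
    return (predict_proba(model, X) > 0.5).astype(int)
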