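"""From-scratch linear, quadratic and penalized discriminant analysis.

All three impose a Gaussian mixture on the training data.  LDA assumes a
covariance Sigma shared by all classes and scores a new spectrum with the
linear discriminant functions

    delta_c(x) = x' Sigma^-1 mu_c - 1/2 mu_c' Sigma^-1 mu_c + log pi_c,

QDA allows per-class covariances,

    delta_c(x) = -1/2 log|Sigma_c| - 1/2 (x-mu_c)' Sigma_c^-1 (x-mu_c) + log pi_c,

and PDA is LDA with Sigma replaced by the ridge-penalized Sigma + lambda*I,
which stays invertible for the many highly correlated wavelengths of a raw
spectrum (hence LDA/QDA are used on PC scores only, PDA on spectra only).
The predicted class is the argmax of delta_c; ties break in class-label
order.  Pooled covariance uses divisor N - C, per-class covariances n_c - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

logger = logging.getLogger(__name__)

#: Relative jitter added to a QDA class covariance only when its Cholesky
#: factorization fails; the event is logged.
_QDA_JITTER = 1e-10


def _class_stats(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([(y == c).sum() for c in classes])
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 rows: {list(bad)}")
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    return X, y, classes, counts, means


def _cho_spd(matrix: np.ndarray):
    """Cholesky factor, rejecting numerically singular matrices.

    potrf can succeed on an exactly singular matrix when rounding leaves a
    tiny positive pivot, so the smallest pivot is checked explicitly.
    """
    cho = cho_factor(matrix, lower=True)
    pivots = np.diag(cho[0])
    if pivots.min() ** 2 < 1e-10 * pivots.max() ** 2:
        raise LinAlgError("matrix numerically singular")
    return cho


def _pooled_covariance(X, y, classes, counts, means) -> np.ndarray:
    n, p = X.shape
    scatter = np.zeros((p, p))
    for c, mu in zip(classes, means):
        centered = X[y == c] - mu
        scatter += centered.T @ centered
    return scatter / (n - classes.size)


@dataclass
class LDAModel:
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray
    covariance: np.ndarray
    _cho: tuple

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """delta_c(x) for every row of X; columns follow self.classes."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        solved = cho_solve(self._cho, self.means.T)  # Sigma^-1 mu_c, p x C
        return X @ solved - 0.5 * np.sum(self.means.T * solved, axis=0) + np.log(
            self.priors
        )

    @classmethod
    def from_parameters(cls, classes, priors, means, covariance) -> "LDAModel":
        """Build an LDA rule from known (population) parameters."""
        covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
        return cls(
            classes=np.asarray(classes),
            priors=np.asarray(priors, dtype=float),
            means=np.atleast_2d(np.asarray(means, dtype=float)),
            covariance=covariance,
            _cho=cho_factor(covariance, lower=True),
        )


def fit_lda(X: np.ndarray, y: np.ndarray, priors: np.ndarray | None = None) -> LDAModel:
    """Fit LDA: class means, pooled covariance (divisor N - C), frequency priors.

    Raises on a singular pooled covariance with guidance to reduce dimension
    (e.g. classify PC scores instead of raw spectra).
    """
    X, y, classes, counts, means = _class_stats(X, y)
    pooled = _pooled_covariance(X, y, classes, counts, means)
    try:
        cho = _cho_spd(pooled)
    except LinAlgError as err:
        raise ValueError(
            "pooled covariance is singular; reduce the dimension (use PC "
            "scores) or use penalized discriminant analysis"
        ) from err
    priors = counts / counts.sum() if priors is None else np.asarray(priors, float)
    return LDAModel(classes=classes, priors=priors, means=means, covariance=pooled, _cho=cho)


def classify_lda(model: LDAModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(model.discriminants(X), axis=1)]


@dataclass
class QDAModel:
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray
    covariances: list
    _chos: list
    logdets: np.ndarray

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.classes.size))
        for k in range(self.classes.size):
            centered = X - self.means[k]
            maha = np.sum(centered * cho_solve(self._chos[k], centered.T).T, axis=1)
            out[:, k] = -0.5 * self.logdets[k] - 0.5 * maha + np.log(self.priors[k])
        return out


def fit_qda(X: np.ndarray, y: np.ndarray, priors: np.ndarray | None = None) -> QDAModel:
    """Fit QDA: per-class means and covariances (divisor n_c - 1).

    Every class must have more rows than the feature dimension so its
    covariance can be full rank.  If a factorization still fails numerically,
    a single relative jitter is applied and the event logged.
    """
    X, y, classes, counts, means = _class_stats(X, y)
    p = X.shape[1]
    if np.any(counts <= p):
        bad = classes[counts <= p]
        raise ValueError(
            f"classes {list(bad)} have n_c <= dimension {p}; QDA needs n_c > p "
            "(use PC scores)"
        )
    covs, chos, logdets = [], [], []
    for c, mu in zip(classes, means):
        centered = X[y == c] - mu
        cov = centered.T @ centered / (centered.shape[0] - 1)
        try:
            cho = cho_factor(cov, lower=True)
        except LinAlgError:
            jitter = _QDA_JITTER * np.mean(np.diag(cov))
            logger.info("QDA: jitter %.3g added to class %r covariance", jitter, c)
            cov = cov + jitter * np.eye(p)
            try:
                cho = cho_factor(cov, lower=True)
            except LinAlgError as err:
                raise ValueError(f"class {c!r}: covariance not positive-definite") from err
        covs.append(cov)
        chos.append(cho)
        logdets.append(2.0 * np.sum(np.log(np.diag(cho[0]))))
    priors = counts / counts.sum() if priors is None else np.asarray(priors, float)
    return QDAModel(
        classes=classes,
        priors=priors,
        means=means,
        covariances=covs,
        _chos=chos,
        logdets=np.asarray(logdets),
    )


def classify_qda(model: QDAModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(model.discriminants(X), axis=1)]


@dataclass
class PDAModel:
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray
    lam: float
    _cho: tuple

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        solved = cho_solve(self._cho, self.means.T)
        return X @ solved - 0.5 * np.sum(self.means.T * solved, axis=0) + np.log(
            self.priors
        )


def fit_pda(
    X: np.ndarray, y: np.ndarray, lam: float, priors: np.ndarray | None = None
) -> PDAModel:
    """Fit PDA: LDA with the pooled covariance replaced by Sigma + lambda*I.

    The identity penalty matrix gives a ridge-type regularization that keeps
    the solve well-posed even when Sigma is singular (p >> N), which is the
    regime of raw spectra.  lambda = 0 reduces exactly to LDA and then
    requires an invertible Sigma.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    X, y, classes, counts, means = _class_stats(X, y)
    pooled = _pooled_covariance(X, y, classes, counts, means)
    penalized = pooled + lam * np.eye(pooled.shape[0])
    try:
        cho = _cho_spd(penalized) if lam == 0 else cho_factor(penalized, lower=True)
    except LinAlgError as err:
        raise ValueError(
            "penalized covariance is singular; lambda = 0 requires an "
            "invertible pooled covariance"
        ) from err
    priors = counts / counts.sum() if priors is None else np.asarray(priors, float)
    return PDAModel(classes=classes, priors=priors, means=means, lam=lam, _cho=cho)


def classify_pda(model: PDAModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(model.discriminants(X), axis=1)]
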