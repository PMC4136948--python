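"""Covariance-based PCA with the average-eigenvalue dimension criterion.

The k-th principal component score of a spectrum x is z_k = alpha_k' x,
where alpha_k is the eigenvector of the sample covariance belonging to the
k-th largest eigenvalue lambda_k.  Variables are left unscaled (all share
reflectance units).  The score dimension q is the number of eigenvalues
strictly greater than the mean of all p eigenvalues — an objective,
cheap criterion; q is recomputed for every dataset rather than fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class PCAModel:
    """Center, orthonormal eigenvectors, descending eigenvalues, chosen q.

    ``eigenvalues`` always has length p (zeros padded beyond the data rank);
    ``eigenvectors`` holds the computable min(n, p) columns.
    """

    center: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    q: int

    @property
    def p(self) -> int:
        return self.center.shape[0]

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def select_n_components(eigenvalues: np.ndarray) -> int:
    """Average-eigenvalue criterion: count eigenvalues strictly above the mean.

    Falls back to q = 1 when no eigenvalue strictly exceeds the mean (all
    equal), guaranteeing a non-degenerate score space.  The criterion is
    scale-equivariant: rescaling all eigenvalues leaves q unchanged.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    tol = 1e-10 * max(ev.max(), np.finfo(float).tiny)
    if ev.min() < -tol:
        raise ValueError(f"negative eigenvalue {ev.min():.3g} beyond tolerance")
    q = int(np.sum(ev > ev.mean()))
    return max(q, 1)


def fit_pca(X: np.ndarray) -> PCAModel:
    """Eigendecompose the sample covariance of X (rows = observations).

    Computed through the SVD of the centered data, which is exact and avoids
    forming the p x p covariance when p >> n.  Eigenvector signs are fixed so
    each column's largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    n, p = X.shape
    center = X.mean(axis=0)
    u, s, vt = np.linalg.svd(X - center, full_matrices=False)
    eigvals = s**2 / (n - 1)
    vectors = vt.T
    # Sign convention: largest-|entry| coordinate of each eigenvector positive.
    flip = np.sign(vectors[np.argmax(np.abs(vectors), axis=0), np.arange(vectors.shape[1])])
    flip[flip == 0] = 1.0
    vectors = vectors * flip
    full = np.zeros(p)
    full[: eigvals.shape[0]] = eigvals
    return PCAModel(
        center=center,
        eigenvectors=vectors,
        eigenvalues=full,
        q=select_n_components(full),
    )


def project(model: PCAModel, X: np.ndarray, q: int | None = None) -> np.ndarray:
    """Scores of X on the first q eigenvectors (default: the model's q)."""
    X = np.asarray(X, dtype=float)
    if q is None:
        q = model.q
    if not 1 <= q <= model.n_components:
        raise ValueError(f"q = {q} outside [1, {model.n_components}]")
    if X.shape[-1] != model.p:
        raise ValueError(f"X has {X.shape[-1]} variables, model expects {model.p}")
    return (X - model.center) @ model.eigenvectors[:, :q]


def save_pca(model: PCAModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "pca.npz",
        center=model.center,
        eigenvectors=model.eigenvectors,
        eigenvalues=model.eigenvalues,
    )
    (directory / "manifest.json").write_text(json.dumps({"q": model.q}))


def load_pca(directory: str | Path) -> PCAModel:
    directory = Path(directory)
    data = np.load(directory / "pca.npz")
    q = json.loads((directory / "manifest.json").read_text())["q"]
    return PCAModel(
        center=data["center"],
        eigenvectors=data["eigenvectors"],
        eigenvalues=data["eigenvalues"],
        q=int(q),
    )
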