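"""Per-class multivariate-Gaussian estimation and spectra simulation.

Each tissue class c is modelled as N_p(mu_c, Sigma_c).  With only n_c = 12
preprocessed spectra per class and p = 1150 wavelengths, the sample
covariance has rank at most n_c - 1, so sampling goes through a symmetric
square-root factor obtained from the centered data (or, for an explicit
covariance, an eigendecomposition with small negative eigenvalues clipped
to zero).  Simulated "estimation datasets" of m_c draws per class, split
50/50 into train and test, are what the classifier benchmark consumes; the
original spectra themselves are not reused downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .synthetic import spectra_matrix

#: Relative eigenvalue threshold: anything below this times the largest
#: eigenvalue is treated as zero rank; anything below minus it is rejected.
_EIG_REL_TOL = 1e-10


@dataclass
class ClassGaussianEstimate:
    """Estimated mean, covariance factor and sample size of one tissue class.

    ``factor`` is a p x r matrix with factor @ factor.T equal to the sample
    covariance (mean-centered, divisor n_c - 1); r is the covariance rank.
    """

    label: str
    mean: np.ndarray
    factor: np.ndarray
    n_c: int

    @property
    def p(self) -> int:
        return self.mean.shape[0]

    @property
    def rank(self) -> int:
        return self.factor.shape[1]

    @property
    def covariance(self) -> np.ndarray:
        return self.factor @ self.factor.T

    @classmethod
    def from_data(cls, label: str, X: np.ndarray) -> "ClassGaussianEstimate":
        X = np.asarray(X, dtype=float)
        n_c = X.shape[0]
        if n_c < 2:
            raise ValueError(f"class {label!r} has n_c = {n_c} < 2 observations")
        mean = X.mean(axis=0)
        centered = X - mean
        # SVD of the centered data gives the covariance square root directly
        # and is O(n^2 p) instead of O(p^3) when n << p.
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        sig = s / np.sqrt(n_c - 1)
        keep = sig**2 > _EIG_REL_TOL * max(sig[0] ** 2, np.finfo(float).tiny)
        return cls(label=label, mean=mean, factor=vt[keep].T * sig[keep], n_c=n_c)

    @classmethod
    def from_moments(
        cls, label: str, mean: np.ndarray, covariance: np.ndarray, n_c: int
    ) -> "ClassGaussianEstimate":
        """Build from an explicit covariance via eigendecomposition.

        Eigenvalues below a small negative tolerance are rejected as non-PSD;
        those in [-tol, tol] are clipped to zero (rank-deficient classes).
        """
        mean = np.asarray(mean, dtype=float)
        covariance = np.asarray(covariance, dtype=float)
        if not np.allclose(covariance, covariance.T, atol=1e-8):
            raise ValueError(f"class {label!r}: covariance is not symmetric")
        eigvals, eigvecs = np.linalg.eigh((covariance + covariance.T) / 2.0)
        tol = _EIG_REL_TOL * max(eigvals[-1], 0.0, np.finfo(float).tiny)
        if eigvals[0] < -max(tol, 1e-8 * abs(eigvals[-1]) + 1e-12):
            raise ValueError(
                f"class {label!r}: covariance has negative eigenvalue {eigvals[0]:.3g}"
            )
        keep = eigvals > tol
        factor = eigvecs[:, keep] * np.sqrt(eigvals[keep])
        return cls(label=label, mean=mean, factor=factor, n_c=int(n_c))


def estimate_class_params(table: pd.DataFrame) -> list[ClassGaussianEstimate]:
    """Estimate (mu_c, Sigma_c, n_c) for every tissue class in a table.

    The mean is the per-column average; the covariance is the mean-centered
    sample covariance with divisor n_c - 1.  Classes are returned in sorted
    label order.  A class with fewer than two rows is rejected by name.
    """
    if "Tissue" not in table.columns:
        raise ValueError("table lacks a Tissue column")
    X = spectra_matrix(table)
    labels = np.asarray(table["Tissue"].astype(str))
    estimates = []
    for label in sorted(np.unique(labels)):
        rows = X[labels == label]
        estimates.append(ClassGaussianEstimate.from_data(label, rows))
    return estimates


def sample_class_spectra(
    est: ClassGaussianEstimate, m: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw m spectra from N_p(mu_c, Sigma_c) via the square-root factor.

    Valid for rank-deficient covariances: draws lie in mu_c + the column
    space of the factor.  Deterministic given an integer seed.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((m, est.rank))
    return est.mean[None, :] + z @ est.factor.T


@dataclass(frozen=True)
class SimulationPlan:
    """How many datasets to simulate, how large, and how to split them."""

    n_datasets: int = 1000
    m_c: int = 100
    seed: int = 0
    train_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be positive")
        if self.m_c < 2:
            raise ValueError("m_c must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass
class EstimationDataset:
    """One simulated labeled dataset with its stratified train/test split."""

    X: np.ndarray
    y: np.ndarray
    is_train: np.ndarray
    index: int = 0

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.X[self.is_train], self.y[self.is_train]

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        return self.X[~self.is_train], self.y[~self.is_train]

    def to_frame(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(columns) if columns is not None else [
            str(i) for i in range(self.X.shape[1])
        ]
        frame = pd.DataFrame(self.X, columns=cols)
        frame.insert(0, "Tissue", self.y)
        frame["split"] = np.where(self.is_train, "train", "test")
        return frame


def generate_estimation_datasets(
    estimates: Sequence[ClassGaussianEstimate],
    plan: SimulationPlan,
) -> Iterator[EstimationDataset]:
    """Lazily yield ``plan.n_datasets`` simulated datasets.

    Each dataset holds exactly m_c rows per class and a class-stratified
    split with round(train_fraction * m_c) training rows per class.  Every
    dataset uses an independent substream spawned from plan.seed, so the
    sequence is reproducible and any prefix is stable.
    """
    if not estimates:
        raise ValueError("no class estimates given")
    n_train = int(round(plan.train_fraction * plan.m_c))
    if n_train < 1 or n_train >= plan.m_c:
        raise ValueError("train_fraction leaves an empty train or test set")
    children = np.random.SeedSequence([int(plan.seed), 0xE57]).spawn(plan.n_datasets)
    for i in range(plan.n_datasets):
        rng = np.random.default_rng(children[i])
        blocks, labels, flags = [], [], []
        for est in estimates:
            blocks.append(sample_class_spectra(est, plan.m_c, rng))
            labels.extend([est.label] * plan.m_c)
            mask = np.zeros(plan.m_c, dtype=bool)
            mask[rng.permutation(plan.m_c)[:n_train]] = True
            flags.append(mask)
        yield EstimationDataset(
            X=np.vstack(blocks),
            y=np.asarray(labels),
            is_train=np.concatenate(flags),
            index=i,
        )


def save_estimates(
    estimates: Sequence[ClassGaussianEstimate], directory: str | Path
) -> None:
    """Write estimates as one .npz per class plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, est in enumerate(estimates):
        fname = f"class_{k}.npz"
        np.savez(directory / fname, mean=est.mean, factor=est.factor)
        manifest.append({"label": est.label, "n_c": est.n_c, "file": fname})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_estimates(directory: str | Path) -> list[ClassGaussianEstimate]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    estimates = []
    for entry in manifest:
        data = np.load(directory / entry["file"])
        estimates.append(
            ClassGaussianEstimate(
                label=entry["label"],
                mean=data["mean"],
                factor=data["factor"],
                n_c=int(entry["n_c"]),
            )
        )
    return estimates
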