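"""Adapters to standard tree, random-forest and neural-network learners.

These are off-the-shelf reference methods around the bespoke discriminant /
KNN / PCA code: a binary-split Gini CART tree with cost-complexity pruning,
a bootstrap forest with mtry random split candidates and majority vote, and
a single-hidden-layer network of M sigmoid units with softmax outputs.  All
delegate to scikit-learn; the adapters pin the configuration the benchmark
uses and make every call deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

#: Effectively-unpruned complexity used to grow the large initial tree.
FULL_TREE_ALPHA = 1e-6


@dataclass(frozen=True)
class TreeConfig:
    """CART: binary Gini splits, cost-complexity pruned at alpha in [0, 1]."""

    alpha: float = FULL_TREE_ALPHA
    min_samples_split: int = 2
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class ForestConfig:
    """Random forest: B bootstrap Gini trees, mtry split candidates each."""

    n_trees: int = 500
    mtry: int | None = None  # default: floor(sqrt(p))

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass(frozen=True)
class NNetConfig:
    """Single hidden layer of M sigmoid units, softmax output.

    The optimizer settings (L-BFGS, 200 iterations, tiny L2 stabilizer) are
    adapter defaults — documented, not derived from any reference run.
    """

    hidden_units: int = 1
    max_iter: int = 200
    alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


BaselineConfig = TreeConfig | ForestConfig | NNetConfig


def make_tree(config: TreeConfig, seed: int) -> DecisionTreeClassifier:
    return DecisionTreeClassifier(
        criterion="gini",
        ccp_alpha=config.alpha,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        random_state=seed,
    )


def make_forest(config: ForestConfig, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.mtry if config.mtry is not None else "sqrt",
        bootstrap=True,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def make_nnet(config: NNetConfig, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="logistic",
        solver="lbfgs",
        alpha=config.alpha,
        max_iter=config.max_iter,
        random_state=seed,
    )


def baseline_fit_predict(
    method: str,
    config: BaselineConfig | None,
    train: tuple[np.ndarray, np.ndarray],
    test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit one baseline learner on (X, y) and predict labels for test rows."""
    X, y = train
    X = np.asarray(X, dtype=float)
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if method == "tree":
        model = make_tree(config or TreeConfig(), seed)
    elif method == "forest":
        model = make_forest(config or ForestConfig(), seed)
    elif method == "nnet":
        model = make_nnet(config or NNetConfig(), seed)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.predict(test)


def default_mtry(p: int) -> int:
    return max(1, int(np.floor(np.sqrt(p))))


__all__ = [
    "TreeConfig",
    "ForestConfig",
    "NNetConfig",
    "BaselineConfig",
    "baseline_fit_predict",
    "make_tree",
    "make_forest",
    "make_nnet",
    "default_mtry",
    "FULL_TREE_ALPHA",
]
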