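"""Hyperparameter selection for the benchmark's tunable classifiers.

k (KNN), lambda (PDA) and M (neural net) are chosen by evaluating every
candidate on a held-out split and taking the one with the lowest
misclassification rate; mtry (random forest) by a factor-2 out-of-bag
search around floor(sqrt(p)); the tree complexity alpha by growing a large
tree and reading the best value off an internal cross-validated pruning
table.  Ties always resolve to the earliest candidate in the stated grid
order, which favors the simpler model for ascending grids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .baselines import ForestConfig, NNetConfig, baseline_fit_predict, default_mtry, make_forest, make_tree, TreeConfig, FULL_TREE_ALPHA
from .discriminant import classify_pda, fit_pda
from .knn import knn_classify

logger = logging.getLogger(__name__)

#: Candidate grids as used in the benchmark.
KNN_K_GRID = tuple(range(1, 11))
PDA_LAMBDA_GRID = tuple(float(10.0**i) for i in range(-6, 4))
NNET_M_GRID_SPECTRA = tuple(range(1, 5))
NNET_M_GRID_SCORES = tuple(range(1, 11))

#: Relative OOB improvement required to keep stepping the mtry search.
MTRY_IMPROVE = 0.01


@dataclass
class TuningResult:
    """Grid, per-candidate error profile, and the selected value."""

    method: str
    candidates: list
    errors: list
    selected: object
    failed: dict = field(default_factory=dict)
    predictions: np.ndarray | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        ok = [e for e in self.errors if np.isfinite(e)]
        if ok and np.isfinite(self.errors[self.candidates.index(self.selected)]):
            assert self.errors[self.candidates.index(self.selected)] == min(ok)


def _evaluate(method, candidate, train, holdout_X, seed):
    X, y = train
    if callable(method):
        return method(candidate, train, holdout_X, seed)
    if method == "knn":
        return knn_classify(X, y, holdout_X, int(candidate))
    if method == "pda":
        return classify_pda(fit_pda(X, y, float(candidate)), holdout_X)
    if method == "nnet":
        return baseline_fit_predict(
            "nnet", NNetConfig(hidden_units=int(candidate)), train, holdout_X, seed
        )
    raise ValueError(f"unknown tunable method {method!r}")


def grid_tune(method, grid, train, holdout, seed: int = 0) -> TuningResult:
    """Fit every candidate on ``train`` and score it on ``holdout``.

    ``method`` is "knn", "pda", "nnet", or a callable
    (candidate, (X, y), holdout_X, seed) -> predicted labels.  Candidates
    whose fit raises are recorded as failed and excluded from the argmin.
    Returns the full error profile, the selected candidate and its holdout
    predictions.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty candidate grid")
    holdout_X, holdout_y = holdout
    holdout_y = np.asarray(holdout_y)
    errors, failed = [], {}
    best = None  # (error, candidate, predictions); strict improvement only
    for candidate in grid:
        try:
            pred = np.asarray(_evaluate(method, candidate, train, holdout_X, seed))
        except (ValueError, np.linalg.LinAlgError) as err:
            errors.append(np.nan)
            failed[candidate] = str(err)
            continue
        err_rate = float(np.mean(pred != holdout_y))
        errors.append(err_rate)
        if best is None or err_rate < best[0]:
            best = (err_rate, candidate, pred)
    if best is None:
        raise ValueError(f"all candidates failed: {failed}")
    name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    result = TuningResult(
        method=name,
        candidates=grid,
        errors=errors,
        selected=best[1],
        failed=failed,
        predictions=best[2],
    )
    logger.info("grid_tune %s: selected %r, profile %s", name, best[1], errors)
    return result


def tune_mtry(
    train: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    n_trees: int = 100,
    improve: float = MTRY_IMPROVE,
) -> TuningResult:
    """Factor-2 out-of-bag search for the forest's split-candidate count.

    Starts at floor(sqrt(p)); repeatedly doubles (and, from the start value,
    halves) mtry while the OOB error improves by at least ``improve``
    relative.  Returns the visited values, their OOB errors, and the argmin.
    """
    X, y = train
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if np.unique(np.asarray(y)).size < 2:
        raise ValueError("need at least 2 classes")
    if p == 1:
        return TuningResult(
            "mtry", [1], [np.nan], 1, note="p = 1: only one candidate"
        )

    def oob_error(mtry: int) -> float:
        forest = make_forest(ForestConfig(n_trees=n_trees, mtry=mtry), seed, oob=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(X, y)
        return 1.0 - forest.oob_score_

    start = default_mtry(p)
    visited: dict[int, float] = {start: oob_error(start)}
    for step in (lambda m: m * 2, lambda m: max(1, m // 2)):
        current, current_err = start, visited[start]
        while True:
            nxt = min(step(current), p)
            if nxt == current or nxt in visited:
                break
            err = oob_error(nxt)
            visited[nxt] = err
            if current_err - err < improve * max(current_err, 1e-12):
                break
            current, current_err = nxt, err
    candidates = sorted(visited)
    errors = [visited[m] for m in candidates]
    selected = candidates[int(np.argmin(errors))]
    logger.info("tune_mtry: selected %d, profile %s", selected, dict(visited))
    return TuningResult("mtry", candidates, errors, selected)


def tune_tree_alpha(
    train: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    cv_folds: int = 5,
) -> TuningResult:
    """Pick the tree pruning complexity from a cross-validated pruning table.

    Grows a large tree at complexity 1e-6, extracts the cost-complexity
    pruning path, estimates each path value's error by internal k-fold
    cross-validation on the training data, and selects the minimizer (ties:
    the smallest complexity).
    """
    X, y = train
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        return TuningResult(
            "tree_alpha", [0.0], [0.0], 0.0, note="single-class data: root tree"
        )
    big = make_tree(TreeConfig(alpha=FULL_TREE_ALPHA), seed)
    path = big.cost_complexity_pruning_path(X, y)
    candidates = [float(a) for a in np.unique(np.clip(path.ccp_alphas, 0.0, 1.0))]
    folds = min(cv_folds, int(np.min(np.bincount(np.unique(y, return_inverse=True)[1]))))
    if folds < 2:
        cv_errors = [float(np.mean(make_tree(TreeConfig(alpha=a), seed).fit(X, y).predict(X) != y)) for a in candidates]
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
        cv_errors = []
        for a in candidates:
            errs = []
            for tr, te in splits:
                tree = make_tree(TreeConfig(alpha=a), seed).fit(X[tr], y[tr])
                errs.append(np.mean(tree.predict(X[te]) != y[te]))
            cv_errors.append(float(np.mean(errs)))
    selected = candidates[int(np.argmin(cv_errors))]
    logger.info("tune_tree_alpha: selected %.3g over %d candidates", selected, len(candidates))
    return TuningResult("tree_alpha", candidates, cv_errors, selected)
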