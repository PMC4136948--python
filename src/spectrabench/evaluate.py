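"""Benchmark orchestration: misclassification rates, averaged confusion
matrices, quantile summaries, and repeated k-fold cross-validation.

The benchmark applies each (algorithm, representation) pair to every
simulated estimation dataset: simulate, split 50/50, reduce to PC scores
where the pair calls for it (with the average-eigenvalue q recomputed per
dataset), tune, fit, and score on the test half.  Raw-spectra pairs skip the
PCA step.  LDA and QDA run on PC scores only, PDA on raw spectra only;
everything else runs on both, giving the eleven benchmark rows.

The confirmatory analysis is a repeated 10-fold cross-validation on the
preprocessed (one-spectrum-per-animal-and-tissue) table, reporting the mean
misclassification over folds and the SD over repeated random partitionings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import (
    ForestConfig,
    NNetConfig,
    TreeConfig,
    baseline_fit_predict,
)
from .discriminant import (
    classify_lda,
    classify_pda,
    classify_qda,
    fit_lda,
    fit_pda,
    fit_qda,
)
from .knn import KNNConfig, knn_classify
from .pca import fit_pca, project
from .simulate import ClassGaussianEstimate, SimulationPlan, generate_estimation_datasets
from .synthetic import spectra_matrix
from .tuning import (
    KNN_K_GRID,
    NNET_M_GRID_SCORES,
    NNET_M_GRID_SPECTRA,
    PDA_LAMBDA_GRID,
    grid_tune,
    tune_mtry,
    tune_tree_alpha,
)

logger = logging.getLogger(__name__)

QUANTILE_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


# ---------------------------------------------------------------------------
# Metrics


def misclassification_rate(y_true, y_pred) -> float:
    """Proportion of observations with a wrongly predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(y_true != y_pred))


@dataclass
class ConfusionMatrix:
    """Row-normalized (true x predicted) proportions.

    Rows index the true tissue, columns the classified tissue; every
    supported row sums to 1.  Rows of classes absent from y_true are all
    zero and listed in ``zero_support`` rather than silently normalized.
    """

    labels: tuple
    matrix: np.ndarray
    zero_support: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(y_true, y_pred, labels) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = tuple(labels)
    index = {c: i for i, c in enumerate(labels)}
    unknown = (set(y_true) | set(y_pred)) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the declared set: {sorted(map(str, unknown))}")
    counts = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    row_totals = counts.sum(axis=1)
    zero = tuple(c for c, total in zip(labels, row_totals) if total == 0)
    safe = np.where(row_totals > 0, row_totals, 1.0)
    return ConfusionMatrix(labels, counts / safe[:, None], zero_support=zero)


def average_confusion_matrices(matrices) -> ConfusionMatrix:
    """Element-wise mean of confusion matrices sharing one label ordering."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to average")
    labels = matrices[0].labels
    if any(m.labels != labels for m in matrices):
        raise ValueError("confusion matrices have mismatched label orderings")
    mean = np.mean([m.matrix for m in matrices], axis=0)
    zero = tuple(sorted({c for m in matrices for c in m.zero_support}, key=labels.index))
    return ConfusionMatrix(labels, mean, zero_support=zero)


def summarize_quantiles(rates) -> np.ndarray:
    """Five-number summary: minimum, quartiles, median, maximum."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate vector")
    return np.quantile(rates, QUANTILE_LEVELS)


def expected_random_guess_rate(n_classes: int) -> float:
    """Analytic misclassification of uniform guessing on balanced classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be positive")
    return (n_classes - 1) / n_classes


# ---------------------------------------------------------------------------
# Algorithm specifications


@dataclass(frozen=True)
class AlgorithmSpec:
    """One benchmark row: a classifier, its input representation, tuning."""

    name: str
    method: str  # knn | lda | qda | pda | tree | forest | nnet
    representation: str  # "pcs" | "spectra"
    tune: bool = True
    config: object = None

    def __post_init__(self) -> None:
        if self.representation not in ("pcs", "spectra"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.method in ("lda", "qda") and self.representation != "pcs":
            raise ValueError(f"{self.method} is restricted to PC scores")
        if self.method == "pda" and self.representation != "spectra":
            raise ValueError("pda is restricted to raw spectra")
        if self.method not in ("knn", "lda", "qda", "pda", "tree", "forest", "nnet"):
            raise ValueError(f"unknown method {self.method!r}")


def default_algorithm_specs(
    tune_trees: bool = False, forest_trees: int = 500
) -> list[AlgorithmSpec]:
    """The eleven benchmark (algorithm, representation) pairs.

    Trees run untuned by default (deep, effectively unpruned);
    ``tune_trees=True`` switches on complexity selection from the internal
    cross-validated pruning table.
    """
    forest = ForestConfig(n_trees=forest_trees)
    return [
        AlgorithmSpec("KNN PCs", "knn", "pcs"),
        AlgorithmSpec("KNN spectra", "knn", "spectra"),
        AlgorithmSpec("LDA PCs", "lda", "pcs"),
        AlgorithmSpec("NNet PCs", "nnet", "pcs"),
        AlgorithmSpec("NNet spectra", "nnet", "spectra"),
        AlgorithmSpec("PDA spectra", "pda", "spectra"),
        AlgorithmSpec("QDA PCs", "qda", "pcs"),
        AlgorithmSpec("RForest PCs", "forest", "pcs", config=forest),
        AlgorithmSpec("RForest spectra", "forest", "spectra", config=forest),
        AlgorithmSpec("Tree PCs", "tree", "pcs", tune=tune_trees),
        AlgorithmSpec("Tree spectra", "tree", "spectra", tune=tune_trees),
    ]


def _nnet_grid(representation: str):
    return NNET_M_GRID_SCORES if representation == "pcs" else NNET_M_GRID_SPECTRA


def _apply_spec(
    spec: AlgorithmSpec,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    seed: int,
) -> np.ndarray:
    """Tune (on the same train/test split), fit, and predict the test rows."""
    Xtr, ytr = train
    Xte, yte = test
    if spec.method == "knn":
        if spec.tune:
            return grid_tune("knn", KNN_K_GRID, train, test, seed).predictions
        k = spec.config.k if isinstance(spec.config, KNNConfig) else 1
        return knn_classify(Xtr, ytr, Xte, k)
    if spec.method == "lda":
        return classify_lda(fit_lda(Xtr, ytr), Xte)
    if spec.method == "qda":
        return classify_qda(fit_qda(Xtr, ytr), Xte)
    if spec.method == "pda":
        if spec.tune:
            return grid_tune("pda", PDA_LAMBDA_GRID, train, test, seed).predictions
        lam = spec.config if spec.config is not None else 1.0
        return classify_pda(fit_pda(Xtr, ytr, float(lam)), Xte)
    if spec.method == "nnet":
        if spec.tune:
            return grid_tune(
                "nnet", _nnet_grid(spec.representation), train, test, seed
            ).predictions
        config = spec.config if isinstance(spec.config, NNetConfig) else NNetConfig()
        return baseline_fit_predict("nnet", config, train, Xte, seed)
    if spec.method == "forest":
        config = spec.config if isinstance(spec.config, ForestConfig) else ForestConfig()
        if spec.tune:
            result = tune_mtry(train, seed, n_trees=min(config.n_trees, 100))
            config = replace(config, mtry=int(result.selected))
        return baseline_fit_predict("forest", config, train, Xte, seed)
    if spec.method == "tree":
        config = spec.config if isinstance(spec.config, TreeConfig) else TreeConfig()
        if spec.tune:
            result = tune_tree_alpha(train, seed)
            config = replace(config, alpha=float(result.selected))
        return baseline_fit_predict("tree", config, train, Xte, seed)
    raise ValueError(f"unknown method {spec.method!r}")


# ---------------------------------------------------------------------------
# Simulation benchmark


@dataclass
class BenchmarkResult:
    """Per-dataset rates, averaged confusion matrices, selected PCA dims."""

    labels: tuple
    rates: pd.DataFrame  # rows = datasets, columns = spec names
    confusions: dict
    selected_q: np.ndarray

    def quantile_table(self) -> pd.DataFrame:
        """Five-number summaries of the misclassification rates per pair."""
        table = {
            name: summarize_quantiles(self.rates[name].to_numpy())
            for name in self.rates.columns
        }
        return pd.DataFrame(table, index=["0%", "25%", "50%", "75%", "100%"]).T

    def rates_long(self) -> pd.DataFrame:
        """Long-format (dataset, algorithm, rate) table, boxplot-ready."""
        long = self.rates.reset_index(names="dataset").melt(
            id_vars="dataset", var_name="algorithm", value_name="rate"
        )
        return long


def run_benchmark(
    estimates: list[ClassGaussianEstimate],
    plan: SimulationPlan,
    specs: list[AlgorithmSpec] | None = None,
    seed: int = 0,
    pca_on: str = "train",
) -> BenchmarkResult:
    """Apply every algorithm spec to every simulated estimation dataset.

    Per dataset: simulate, split, fit PCA on the training half (or on the
    pooled dataset with ``pca_on="pooled"``) with the average-eigenvalue q,
    tune and fit each spec, and record its test misclassification rate and
    row-normalized confusion matrix.  Fully reproducible from the plan seed
    (data) and ``seed`` (tuning and randomized learners).
    """
    if specs is None:
        specs = default_algorithm_specs()
    if not specs:
        raise ValueError("no algorithm specs")
    if pca_on not in ("train", "pooled"):
        raise ValueError("pca_on must be 'train' or 'pooled'")
    labels = tuple(sorted(est.label for est in estimates))
    need_pcs = any(s.representation == "pcs" for s in specs)

    rates = {s.name: np.empty(plan.n_datasets) for s in specs}
    conf_sums = {s.name: np.zeros((len(labels), len(labels))) for s in specs}
    zero_support = {s.name: set() for s in specs}
    selected_q = np.empty(plan.n_datasets, dtype=int)

    for ds in generate_estimation_datasets(estimates, plan):
        Xtr, ytr = ds.train
        Xte, yte = ds.test
        children = np.random.SeedSequence([int(seed), 0xBE7C, ds.index]).spawn(len(specs))
        if need_pcs:
            model = fit_pca(Xtr if pca_on == "train" else ds.X)
            selected_q[ds.index] = model.q
            Str = project(model, Xtr)
            Ste = project(model, Xte)
        else:
            selected_q[ds.index] = 0
        for spec, child in zip(specs, children):
            if spec.representation == "pcs":
                train, test = (Str, ytr), (Ste, yte)
            else:
                train, test = (Xtr, ytr), (Xte, yte)
            spec_seed = int(child.generate_state(1)[0] % (2**31))
            pred = _apply_spec(spec, train, test, spec_seed)
            rate = misclassification_rate(yte, pred)
            rates[spec.name][ds.index] = rate
            cm = confusion_matrix(yte, pred, labels)
            conf_sums[spec.name] += cm.matrix
            zero_support[spec.name].update(cm.zero_support)
            logger.info("dataset %d %s: rate %.4f", ds.index, spec.name, rate)

    confusions = {
        name: ConfusionMatrix(
            labels,
            conf_sums[name] / plan.n_datasets,
            zero_support=tuple(sorted(zero_support[name], key=labels.index)),
        )
        for name in conf_sums
    }
    return BenchmarkResult(
        labels=labels,
        rates=pd.DataFrame(rates),
        confusions=confusions,
        selected_q=selected_q,
    )


# ---------------------------------------------------------------------------
# Confirmatory repeated k-fold cross-validation


@dataclass
class CVResult:
    """Mean misclassification over folds and SD over repeated partitions."""

    per_repeat: pd.DataFrame  # rows = repeats, columns = spec names
    mean: pd.Series = field(init=False)
    sd: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.per_repeat.mean(axis=0)
        self.sd = self.per_repeat.std(axis=0, ddof=1) if len(self.per_repeat) > 1 else (
            self.per_repeat.iloc[0] * 0.0
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_rate": self.mean, "sd_over_repeats": self.sd})


def kfold_sizes(n: int, k: int) -> list[int]:
    """Group sizes "as equal as possible": n%k groups of n//k+1, rest n//k."""
    if k > n:
        raise ValueError(f"k = {k} exceeds number of rows {n}")
    base, extra = divmod(n, k)
    return [base + 1] * extra + [base] * (k - extra)


def _tuned_value(spec, train, seed):
    """Select a hyperparameter on an internal stratified 50/50 split."""
    Xtr, ytr = train
    rng = np.random.default_rng(seed)
    inner = np.zeros(len(ytr), dtype=bool)
    for c in np.unique(ytr):
        idx = np.flatnonzero(ytr == c)
        take = max(1, int(round(0.5 * len(idx))))
        inner[rng.permutation(idx)[:take]] = True
    if inner.all() or not inner.any():
        raise ValueError("internal tuning split is degenerate")
    sub_train = (Xtr[inner], ytr[inner])
    sub_hold = (Xtr[~inner], ytr[~inner])
    if spec.method == "knn":
        grid = [k for k in KNN_K_GRID if k <= len(sub_train[1])]
        return grid_tune("knn", grid, sub_train, sub_hold, seed).selected
    if spec.method == "pda":
        return grid_tune("pda", PDA_LAMBDA_GRID, sub_train, sub_hold, seed).selected
    if spec.method == "nnet":
        return grid_tune(
            "nnet", _nnet_grid(spec.representation), sub_train, sub_hold, seed
        ).selected
    raise ValueError(spec.method)


def _cv_fit_predict(spec, train, test_X, seed):
    """Fit one spec on a CV training fold and predict the held-out fold."""
    Xtr, ytr = train
    if spec.method in ("knn", "pda", "nnet") and spec.tune:
        value = _tuned_value(spec, train, seed)
        if spec.method == "knn":
            return knn_classify(Xtr, ytr, test_X, int(value))
        if spec.method == "pda":
            return classify_pda(fit_pda(Xtr, ytr, float(value)), test_X)
        return baseline_fit_predict(
            "nnet", NNetConfig(hidden_units=int(value)), train, test_X, seed
        )
    # Remaining methods tune internally (forest OOB, tree CV) or not at all.
    return _apply_no_holdout(spec, train, test_X, seed)


def _apply_no_holdout(spec, train, test_X, seed):
    Xtr, ytr = train
    if spec.method == "knn":
        k = spec.config.k if isinstance(spec.config, KNNConfig) else 1
        return knn_classify(Xtr, ytr, test_X, k)
    if spec.method == "lda":
        return classify_lda(fit_lda(Xtr, ytr), test_X)
    if spec.method == "qda":
        return classify_qda(fit_qda(Xtr, ytr), test_X)
    if spec.method == "pda":
        lam = spec.config if spec.config is not None else 1.0
        return classify_pda(fit_pda(Xtr, ytr, float(lam)), test_X)
    if spec.method == "nnet":
        config = spec.config if isinstance(spec.config, NNetConfig) else NNetConfig()
        return baseline_fit_predict("nnet", config, train, test_X, seed)
    if spec.method == "forest":
        config = spec.config if isinstance(spec.config, ForestConfig) else ForestConfig()
        if spec.tune:
            result = tune_mtry(train, seed, n_trees=min(config.n_trees, 100))
            config = replace(config, mtry=int(result.selected))
        return baseline_fit_predict("forest", config, train, test_X, seed)
    if spec.method == "tree":
        config = spec.config if isinstance(spec.config, TreeConfig) else TreeConfig()
        if spec.tune:
            result = tune_tree_alpha(train, seed)
            config = replace(config, alpha=float(result.selected))
        return baseline_fit_predict("tree", config, train, test_X, seed)
    raise ValueError(spec.method)


def repeated_kfold_cv(
    table: pd.DataFrame,
    specs: list[AlgorithmSpec] | None = None,
    k: int = 10,
    repeats: int = 50,
    seed: int = 0,
    pca_on: str = "train",
) -> CVResult:
    """Repeated k-fold CV of the algorithm specs on a preprocessed table.

    Each repeat draws one plain-random partition into k groups of sizes as
    equal as possible (for 96 rows and k = 10: six groups of 10, four of 9);
    each group serves once as the test fold.  The per-repeat rate is the
    size-weighted average of fold rates (= total errors / n); the result
    reports its mean and SD over repeats.  PCA, tuning and fitting happen
    inside each training fold.
    """
    if specs is None:
        specs = default_algorithm_specs()
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = spectra_matrix(table)
    y = np.asarray(table["Tissue"].astype(str))
    n = len(y)
    sizes = kfold_sizes(n, k)
    root = np.random.SeedSequence([int(seed), 0xCF])
    per_repeat = {s.name: np.zeros(repeats) for s in specs}

    for r, child in enumerate(root.spawn(repeats)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        errors = {s.name: 0 for s in specs}
        start = 0
        for f, size in enumerate(sizes):
            test_idx = perm[start : start + size]
            train_idx = np.concatenate([perm[:start], perm[start + size :]])
            start += size
            Xtr, ytr = X[train_idx], y[train_idx]
            Xte, yte = X[test_idx], y[test_idx]
            need_pcs = any(s.representation == "pcs" for s in specs)
            if need_pcs:
                model = fit_pca(Xtr if pca_on == "train" else X)
                Str, Ste = project(model, Xtr), project(model, Xte)
            fold_seed = int(
                np.random.SeedSequence([int(seed), 0xCF, r, f]).generate_state(1)[0]
                % (2**31)
            )
            for s in specs:
                if s.representation == "pcs":
                    pred = _cv_fit_predict(s, (Str, ytr), Ste, fold_seed)
                else:
                    pred = _cv_fit_predict(s, (Xtr, ytr), Xte, fold_seed)
                errors[s.name] += int(np.sum(pred != yte))
        for s in specs:
            per_repeat[s.name][r] = errors[s.name] / n
        logger.info("cv repeat %d: %s", r, {k_: v[r] for k_, v in per_repeat.items()})

    return CVResult(per_repeat=pd.DataFrame(per_repeat))
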