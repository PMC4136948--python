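"""k-nearest-neighbor classification with deterministic tie handling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class KNNConfig:
    """Neighbor count k; the metric is the Euclidean distance."""

    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


def knn_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    config: KNNConfig | int = 1,
) -> np.ndarray:
    """Majority vote of the k Euclidean-nearest training rows per query.

    Deterministic conventions: distance ties in neighbor selection break by
    training-row order (stable sort); vote ties break by the smallest summed
    neighbor distance among the tied classes, then by class-label order.
    """
    if isinstance(config, int):
        config = KNNConfig(k=config)
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if config.k > train_X.shape[0]:
        raise ValueError(f"k = {config.k} exceeds training size {train_X.shape[0]}")

    classes = np.unique(train_y)
    dists = cdist(test_X, train_X)
    order = np.argsort(dists, axis=1, kind="stable")[:, : config.k]

    out = np.empty(test_X.shape[0], dtype=train_y.dtype)
    for i in range(test_X.shape[0]):
        nbr_labels = train_y[order[i]]
        nbr_dists = dists[i, order[i]]
        votes = np.array([(nbr_labels == c).sum() for c in classes])
        top = votes == votes.max()
        if top.sum() == 1:
            out[i] = classes[np.argmax(votes)]
        else:
            sums = np.array(
                [
                    nbr_dists[nbr_labels == c].sum() if keep else np.inf
                    for c, keep in zip(classes, top)
                ]
            )
            out[i] = classes[np.argmin(sums)]  # argmin is first-of-ties: label order
    return out
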