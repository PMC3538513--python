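"""k-nearest-neighbour classifier on Euclidean descriptor distance.

The k training vectors nearest to the query vote for their class; the
predicted label is the majority vote (argmax_v sum_i delta(v, f(x_i))).
Distance ties break by training index, vote ties resolve to non-inhibitor.
Default k = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .base import NON_INHIBITOR, Prediction, sign_label

DEFAULT_K = 1


@dataclass
class KNNModel:
    x: np.ndarray
    y: np.ndarray
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.x.shape[0]:
            raise ValueError(f"k must be in [1, {self.x.shape[0]}], got {self.k}")
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("feature/label length mismatch")


def train_knn(x: np.ndarray, y: np.ndarray, k: int = DEFAULT_K) -> KNNModel:
    return KNNModel(x=np.asarray(x, dtype=float), y=np.asarray(y, dtype=int), k=k)


def knn_predict(model: KNNModel, x: np.ndarray) -> Prediction:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.x.shape[1]:
        raise ValueError("dimension mismatch with training matrix")
    d = cdist(x, model.x)[0]
    # stable sort: equal distances keep training order, i.e. lowest index wins
    nn = np.argsort(d, kind="stable")[: model.k]
    vote = int(np.sum(model.y[nn]))
    # vote margin; exact ties (vote == 0) resolve to -1
    return Prediction(label=sign_label(vote), score=float(vote))


def knn_predict_batch(model: KNNModel, x: np.ndarray) -> np.ndarray:
    """Vote margins for many query rows; label = sign with ties to -1."""
    d = cdist(np.atleast_2d(x), model.x)
    nn = np.argsort(d, axis=1, kind="stable")[:, : model.k]
    return model.y[nn].sum(axis=1).astype(float)
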