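"""Probabilistic neural network (Gaussian Parzen-window Bayes classifier).

Class-conditional densities are Parzen estimates over the training vectors
of each class,

    f_i(x) = (1/n_i) sum_{x_k in class i} exp( -sum_j ((x_j - x_kj)/sigma_j)^2 ),

and the query is assigned to the class maximizing h_i c_i f_i(x) (priors and
misclassification costs default to equal).  Per-class 1/n_i normalization is
the default — with strongly imbalanced classes the unnormalized sum
degenerates to the majority class — but the raw summation-layer variant is
available.  All accumulation is in the log domain: at the default
sigma = 0.02 the individual kernel terms underflow double precision long
before the class comparison becomes meaningless, and the log-sum-exp form
keeps the comparison exact.  Exact ties resolve to non-inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .base import NON_INHIBITOR, Prediction, sign_label

DEFAULT_SIGMA = 0.02


@dataclass
class PNNModel:
    x_pos: np.ndarray  # class +1 training vectors
    x_neg: np.ndarray  # class -1 training vectors
    sigma: np.ndarray  # shared scalar broadcast or per-descriptor widths
    prior_pos: float = 0.5
    prior_neg: float = 0.5
    cost_pos: float = 1.0
    cost_neg: float = 1.0
    normalize: bool = True  # divide each class sum by its class size

    def __post_init__(self) -> None:
        if self.x_pos.shape[0] == 0 or self.x_neg.shape[0] == 0:
            raise ValueError("both classes must be non-empty")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


def train_pnn(
    x: np.ndarray,
    y: np.ndarray,
    sigma: float | np.ndarray = DEFAULT_SIGMA,
    normalize: bool = True,
) -> PNNModel:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))
    return PNNModel(
        x_pos=x[y == 1].copy(),
        x_neg=x[y == -1].copy(),
        sigma=sig,
        normalize=normalize,
    )


def _log_density(x: np.ndarray, train: np.ndarray, sigma: np.ndarray, normalize: bool) -> np.ndarray:
    scaled_q = np.atleast_2d(x) / sigma
    scaled_t = train / sigma
    neg_d2 = -cdist(scaled_q, scaled_t, "sqeuclidean")
    out = logsumexp(neg_d2, axis=1)
    if normalize:
        out = out - np.log(train.shape[0])
    return out


def pnn_log_ratio(model: PNNModel, x: np.ndarray) -> np.ndarray:
    """log(h+ c+ f+(x)) - log(h- c- f-(x)) for each query row."""
    lp = _log_density(x, model.x_pos, model.sigma, model.normalize)
    ln = _log_density(x, model.x_neg, model.sigma, model.normalize)
    return (
        lp + np.log(model.prior_pos * model.cost_pos)
        - ln - np.log(model.prior_neg * model.cost_neg)
    )


def pnn_predict(model: PNNModel, x: np.ndarray) -> Prediction:
    score = float(pnn_log_ratio(model, x)[0])
    return Prediction(label=sign_label(score), score=score)


def pnn_predict_batch(model: PNNModel, x: np.ndarray) -> np.ndarray:
    """Log density ratios for many query rows; label = sign, ties to -1."""
    return pnn_log_ratio(model, x)
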