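"""Hard-margin RBF support vector machine.

The decision function is

    f(x) = sign( sum_i alpha_i^0 y_i K(x, x_i) + b ),
    K(x_i, x_j) = exp(-||x_j - x_i||^2 / (2 sigma^2)),

with the dual coefficients obtained by maximizing
sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j) subject to
0 <= alpha_i <= c and sum_i alpha_i y_i = 0.  scikit-learn's SMO solver is
used as the QP engine; the trained state is extracted into a plain container
and the decision value is always re-evaluated from the support vectors and
coefficients above.  Defaults c = 100,000 (an essentially hard margin) and
sigma = 1.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .base import NON_INHIBITOR, Prediction, sign_label

DEFAULT_C = 100_000.0
DEFAULT_SIGMA = 1.2


@dataclass
class SVMModel:
    support_vectors: np.ndarray  # (m, d) scaled descriptor rows
    dual_coef: np.ndarray        # alpha_i^0 * y_i per support vector
    bias: float
    sigma: float
    c: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.c <= 0:
            raise ValueError("sigma and c must be positive")
        # dual feasibility: |alpha_i y_i| <= c and sum alpha_i y_i ~ 0
        if np.any(np.abs(self.dual_coef) > self.c * (1 + 1e-8)):
            raise ValueError("dual coefficients exceed the margin parameter")

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]


def rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(np.atleast_2d(a), np.atleast_2d(b), "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def train_svm(
    x: np.ndarray,
    y: np.ndarray,
    c: float = DEFAULT_C,
    sigma: float = DEFAULT_SIGMA,
) -> SVMModel:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("training data must contain both classes labelled +1/-1")
    if c <= 0 or sigma <= 0:
        raise ValueError("c and sigma must be positive")
    clf = SVC(C=c, kernel="rbf", gamma=1.0 / (2.0 * sigma**2))
    clf.fit(x, y)
    # sklearn orders classes_ as [-1, +1]; dual_coef_ is alpha_i * y_i for
    # the positive class orientation, which matches f(x) > 0 => +1.
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        sigma=sigma,
        c=c,
    )


def svm_decision(model: SVMModel, x: np.ndarray) -> Prediction:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.support_vectors.shape[1]:
        raise ValueError("dimension mismatch with support vectors")
    k = rbf_kernel(x, model.support_vectors, model.sigma)
    score = float((k @ model.dual_coef).ravel()[0] + model.bias)
    return Prediction(label=sign_label(score), score=score)


def svm_decision_batch(model: SVMModel, x: np.ndarray) -> np.ndarray:
    """Decision values for many query rows at once."""
    k = rbf_kernel(np.atleast_2d(x), model.support_vectors, model.sigma)
    return k @ model.dual_coef + model.bias
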