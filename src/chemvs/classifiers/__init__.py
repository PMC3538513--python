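"""Screening engines: hard-margin RBF-SVM, Tanimoto similarity search,
k-nearest-neighbour and probabilistic neural network.

All engines consume min-max-scaled descriptor vectors; the :class:`Engine`
wrapper fits the scaling on the training set and applies it uniformly so the
four methods are compared on equal footing (RBF kernels and Euclidean
distances are scale-sensitive, and the Tanimoto coefficient is defined on
scaled vectors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from ..chemspace import ScalingModel, fit_scaling
from .base import INHIBITOR, NON_INHIBITOR, Prediction, sign_label
from .knn import DEFAULT_K, KNNModel, knn_predict, knn_predict_batch, train_knn
from .pnn import DEFAULT_SIGMA as PNN_DEFAULT_SIGMA
from .pnn import PNNModel, pnn_predict, pnn_predict_batch, train_pnn
from .similarity import DEFAULT_CUTOFF, SimilarityScreenResult, similarity_screen
from .svm import DEFAULT_C, DEFAULT_SIGMA, SVMModel, svm_decision, svm_decision_batch, train_svm

__all__ = [
    "Prediction", "INHIBITOR", "NON_INHIBITOR",
    "SVMModel", "train_svm", "svm_decision", "svm_decision_batch",
    "KNNModel", "train_knn", "knn_predict", "knn_predict_batch",
    "PNNModel", "train_pnn", "pnn_predict", "pnn_predict_batch",
    "SimilarityScreenResult", "similarity_screen",
    "Engine", "make_engine", "save_engine", "load_engine",
    "ENGINE_DEFAULTS",
]

ENGINE_DEFAULTS: dict[str, dict[str, Any]] = {
    "svm": {"c": DEFAULT_C, "sigma": DEFAULT_SIGMA},
    "knn": {"k": DEFAULT_K},
    "pnn": {"sigma": PNN_DEFAULT_SIGMA},
    "tanimoto": {"cutoff": DEFAULT_CUTOFF},
}


@dataclass
class Engine:
    """A trained screening engine plus the scaling fitted on its training set."""

    name: str
    params: dict[str, Any]
    scaling: ScalingModel | None = None
    model: Any = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "Engine":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        self.scaling = fit_scaling(x, reference="training set")
        xs = self.scaling.apply(x)
        if self.name == "svm":
            self.model = train_svm(xs, y, c=self.params["c"], sigma=self.params["sigma"])
        elif self.name == "knn":
            self.model = train_knn(xs, y, k=self.params["k"])
        elif self.name == "pnn":
            self.model = train_pnn(xs, y, sigma=self.params["sigma"])
        elif self.name == "tanimoto":
            actives = xs[y == INHIBITOR]
            if actives.shape[0] == 0:
                raise ValueError("tanimoto engine needs at least one active")
            self.model = actives
        else:
            raise ValueError(f"unknown engine {self.name!r}")
        return self

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("engine is not fitted")
        xs = self.scaling.apply(np.atleast_2d(np.asarray(x, dtype=float)))
        if self.name == "svm":
            return svm_decision_batch(self.model, xs)
        if self.name == "knn":
            return knn_predict_batch(self.model, xs)
        if self.name == "pnn":
            return pnn_predict_batch(self.model, xs)
        res = similarity_screen(self.model, xs, cutoff=self.params["cutoff"])
        return res.best_sim - self.params["cutoff"]

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(x)
        return np.where(scores > 0, INHIBITOR, NON_INHIBITOR)


def make_engine(name: str, **params: Any) -> Engine:
    if name not in ENGINE_DEFAULTS:
        raise ValueError(f"unknown engine {name!r}; choose from {sorted(ENGINE_DEFAULTS)}")
    merged = {**ENGINE_DEFAULTS[name], **params}
    return Engine(name=name, params=merged)


def save_engine(engine: Engine, path: str | Path) -> None:
    """Serialize a fitted engine to a portable JSON container."""
    if engine.model is None:
        raise RuntimeError("engine is not fitted")
    doc: dict[str, Any] = {
        "engine": engine.name,
        "params": engine.params,
        "scaling": engine.scaling.to_json(),
    }
    m = engine.model
    if engine.name == "svm":
        doc["model"] = {
            "support_vectors": m.support_vectors.tolist(),
            "dual_coef": m.dual_coef.tolist(),
            "bias": m.bias,
            "sigma": m.sigma,
            "c": m.c,
        }
    elif engine.name == "knn":
        doc["model"] = {"x": m.x.tolist(), "y": m.y.tolist(), "k": m.k}
    elif engine.name == "pnn":
        doc["model"] = {
            "x_pos": m.x_pos.tolist(),
            "x_neg": m.x_neg.tolist(),
            "sigma": m.sigma.tolist(),
            "normalize": m.normalize,
        }
    else:
        doc["model"] = {"actives": m.tolist()}
    Path(path).write_text(json.dumps(doc))


def load_engine(path: str | Path) -> Engine:
    doc = json.loads(Path(path).read_text())
    eng = Engine(name=doc["engine"], params=doc["params"])
    eng.scaling = ScalingModel.from_json(doc["scaling"])
    m = doc["model"]
    if eng.name == "svm":
        eng.model = SVMModel(
            support_vectors=np.asarray(m["support_vectors"], dtype=float),
            dual_coef=np.asarray(m["dual_coef"], dtype=float),
            bias=float(m["bias"]),
            sigma=float(m["sigma"]),
            c=float(m["c"]),
        )
    elif eng.name == "knn":
        eng.model = KNNModel(
            x=np.asarray(m["x"], dtype=float),
            y=np.asarray(m["y"], dtype=int),
            k=int(m["k"]),
        )
    elif eng.name == "pnn":
        eng.model = PNNModel(
            x_pos=np.asarray(m["x_pos"], dtype=float),
            x_neg=np.asarray(m["x_neg"], dtype=float),
            sigma=np.asarray(m["sigma"], dtype=float),
            normalize=bool(m["normalize"]),
        )
    else:
        eng.model = np.asarray(m["actives"], dtype=float)
    return eng
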