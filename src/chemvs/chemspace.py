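"""Chemical-space operations: descriptor scaling, Tanimoto similarity,
compound-family clustering and putative-negative generation.

The screening pipeline scales every descriptor to [0,1] against a named
reference library, measures similarity with the Tanimoto coefficient on the
scaled continuous vectors,

    sim(i, j) = x_i . x_j / (|x_i|^2 + |x_j|^2 - x_i . x_j),

partitions a library into compound families by k-means in the scaled space,
and builds a putative non-inhibitor training set by taking a few
representative compounds (nearest to the centroid) from every family that
contains no known active.  The assumption behind the negatives is that
undiscovered actives occupy only a small fraction of the active-free
families, so the label noise introduced is low.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingModel",
    "FamilyAssignment",
    "fit_scaling",
    "tanimoto",
    "tanimoto_matrix",
    "cluster_families",
    "assign_to_families",
    "select_putative_negatives",
]


@dataclass
class ScalingModel:
    """Per-descriptor min/max over a named reference library.

    ``apply`` maps each column to [0,1] via (x - min)/(max - min); constant
    columns map to 0 and out-of-reference values are clipped.
    """

    minimum: np.ndarray
    maximum: np.ndarray
    reference: str = ""

    def __post_init__(self) -> None:
        if np.any(self.maximum < self.minimum):
            raise ValueError("max < min in scaling model")

    @property
    def constant(self) -> np.ndarray:
        return self.maximum == self.minimum

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(matrix, dtype=float))
        span = np.where(self.constant, 1.0, self.maximum - self.minimum)
        scaled = (x - self.minimum) / span
        scaled[:, self.constant] = 0.0
        out = np.clip(scaled, 0.0, 1.0)
        return out if np.asarray(matrix).ndim == 2 else out[0]

    def to_json(self) -> dict:
        return {
            "reference": self.reference,
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
        }

    @classmethod
    def from_json(cls, doc: dict) -> "ScalingModel":
        return cls(
            minimum=np.asarray(doc["minimum"], dtype=float),
            maximum=np.asarray(doc["maximum"], dtype=float),
            reference=doc.get("reference", ""),
        )


def fit_scaling(matrix: np.ndarray, reference: str = "") -> ScalingModel:
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("scaling requires a non-empty 2-D matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in reference matrix")
    model = ScalingModel(minimum=x.min(axis=0), maximum=x.max(axis=0), reference=reference)
    n_const = int(model.constant.sum())
    if n_const:
        logger.info("%d constant descriptor(s) in reference %r", n_const, reference)
    return model


def tanimoto(x: np.ndarray, y: np.ndarray) -> float:
    """Tanimoto coefficient between two scaled descriptor vectors.

    Undefined (raises) when both vectors are all-zero; callers must handle
    that case rather than receive a silent 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dimension mismatch")
    dot = float(x @ y)
    denom = float(x @ x) + float(y @ y) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined: both vectors are all-zero")
    return dot / denom


def tanimoto_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarities between rows of two scaled matrices.

    Rows that are all-zero on both sides yield NaN (undefined), matching the
    scalar contract.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    dot = a @ b.T
    na = np.einsum("ij,ij->i", a, a)[:, None]
    nb = np.einsum("ij,ij->i", b, b)[None, :]
    denom = na + nb - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, dot / denom, np.nan)


@dataclass
class FamilyAssignment:
    """k-means partition of a compound library into chemical-space families."""

    compound_to_family: dict[str, int]
    centroids: np.ndarray
    seed: int
    requested_k: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroids")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def members(self, family: int) -> list[str]:
        return [c for c, f in self.compound_to_family.items() if f == family]

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "requested_k": self.requested_k,
            "centroids": self.centroids.tolist(),
            "compound_to_family": self.compound_to_family,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "FamilyAssignment":
        return cls(
            compound_to_family={k: int(v) for k, v in doc["compound_to_family"].items()},
            centroids=np.asarray(doc["centroids"], dtype=float),
            seed=int(doc["seed"]),
            requested_k=int(doc.get("requested_k", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "FamilyAssignment":
        return cls.from_json(json.loads(Path(path).read_text()))


def cluster_families(
    matrix: np.ndarray,
    k: int,
    seed: int,
    ids: list[str] | None = None,
) -> FamilyAssignment:
    """Partition a scaled descriptor matrix into k compound families.

    Seeded k-means++ so the same (matrix, k, seed) always yields the same
    assignment; empty clusters are dropped with a warning and family ids
    renumbered contiguously.
    """
    x = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in descriptor matrix")
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(x)
    occupied = np.unique(labels)
    if len(occupied) < k:
        logger.warning("dropping %d empty families", k - len(occupied))
    remap = {old: new for new, old in enumerate(occupied)}
    return FamilyAssignment(
        compound_to_family={c: remap[l] for c, l in zip(ids, labels)},
        centroids=km.cluster_centers_[occupied],
        seed=seed,
        requested_k=k,
    )


def assign_to_families(assignment: FamilyAssignment, matrix: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) family id per row; ties break low."""
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if x.shape[1] != assignment.centroids.shape[1]:
        raise ValueError("dimension mismatch with family centroids")
    d = cdist(x, assignment.centroids)
    return np.argmin(d, axis=1)  # argmin returns the lowest index on ties


def select_putative_negatives(
    assignment: FamilyAssignment,
    matrix: np.ndarray,
    ids: list[str],
    active_ids: set[str],
    per_family: int = 2,
    seed: int = 0,
) -> list[str]:
    """Representative compounds from every family containing no active.

    From each active-free family, up to ``per_family`` members nearest to the
    family centroid (ties by id) are selected as putative negatives.  The
    result is guaranteed disjoint from the active set.  ``seed`` is recorded
    for provenance; selection itself is deterministic.
    """
    if per_family < 1:
        raise ValueError("per_family must be >= 1")
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    fam_of = assignment.compound_to_family
    active_families = {fam_of[c] for c in active_ids if c in fam_of}
    selected: list[str] = []
    for fam in range(assignment.k):
        if fam in active_families:
            continue
        member_idx = [i for i, c in enumerate(ids) if fam_of.get(c) == fam]
        if not member_idx:
            continue
        d = np.linalg.norm(x[member_idx] - assignment.centroids[fam], axis=1)
        order = sorted(range(len(member_idx)), key=lambda t: (d[t], ids[member_idx[t]]))
        selected.extend(ids[member_idx[t]] for t in order[:per_family])
    if not selected:
        logger.warning("every family contains actives; no putative negatives selected")
    assert not set(selected) & active_ids
    return selected
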