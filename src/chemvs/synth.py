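"""Synthetic descriptor-space libraries and packaged molecule fixtures.

The classifier and clustering machinery is exercised on generated data that
emulates the structure the screening method assumes: compound families are
spherical Gaussian clusters in descriptor space, actives occupy a few
families, putative inactives many more.  Working in descriptor space gives
exact control of class separability and ground-truth family labels;
molecule-space fixtures (a packaged SMILES set with hand-computed golden
descriptor values) cover the chemistry path separately.

Default study conditions: 50 actives in 2 families, 2,000 inactives in 8
families, 98 dimensions, per-coordinate within-family spread 0.05 and
inter-centroid separation 3.0 — roughly ten times the within-family point
scale, i.e. a near-separable library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "SyntheticSpec",
    "SyntheticLibrary",
    "generate_synthetic_library",
    "generate_decoy_screen",
    "fixture_molecules",
    "fixture_golden_values",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_active: int = 50
    n_inactive: int = 2000
    n_dim: int = 98
    n_active_families: int = 2
    n_inactive_families: int = 8
    separation: float = 3.0
    spread: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_inactive, self.n_active_families, self.n_inactive_families) < 1:
            raise ValueError("counts must be >= 1")
        if self.separation <= 0 or self.spread <= 0:
            raise ValueError("separation and spread must be positive")


@dataclass
class SyntheticLibrary:
    x: np.ndarray
    y: np.ndarray            # +1 active / -1 inactive
    family: np.ndarray       # ground-truth family id per row
    ids: list[str]
    centroids: np.ndarray    # (n_families, n_dim), active families first
    spec: SyntheticSpec


def _draw_centroids(
    rng: np.random.Generator,
    k: int,
    n_dim: int,
    separation: float,
    existing: np.ndarray | None = None,
    max_tries: int = 500,
) -> np.ndarray:
    """Uniform centroids on [0,1]^d with pairwise distance >= separation."""
    placed = [] if existing is None else [c for c in existing]
    new: list[np.ndarray] = []
    for _ in range(k):
        for attempt in range(max_tries):
            cand = rng.uniform(0.0, 1.0, size=n_dim)
            if all(np.linalg.norm(cand - c) >= separation for c in placed):
                placed.append(cand)
                new.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {k} centroids at separation {separation} "
                f"in {n_dim} dimensions after {max_tries} tries"
            )
    return np.vstack(new)


def _split_counts(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def generate_synthetic_library(spec: SyntheticSpec) -> SyntheticLibrary:
    """Spherical-Gaussian compound families with known labels.

    Active and inactive families are disjoint; family centroids respect the
    requested minimum separation.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_active_families + spec.n_inactive_families
    centroids = _draw_centroids(rng, k, spec.n_dim, spec.separation)
    counts = _split_counts(spec.n_active, spec.n_active_families) + _split_counts(
        spec.n_inactive, spec.n_inactive_families
    )
    rows, labels, fams = [], [], []
    for fam, n in enumerate(counts):
        pts = centroids[fam] + rng.normal(0.0, spec.spread, size=(n, spec.n_dim))
        rows.append(pts)
        labels.extend([1 if fam < spec.n_active_families else -1] * n)
        fams.extend([fam] * n)
    x = np.vstack(rows)
    ids = [f"syn{i:05d}" for i in range(x.shape[0])]
    return SyntheticLibrary(
        x=x,
        y=np.asarray(labels, dtype=int),
        family=np.asarray(fams, dtype=int),
        ids=ids,
        centroids=centroids,
        spec=spec,
    )


def generate_decoy_screen(
    library: SyntheticLibrary,
    n_test_active: int = 20,
    n_decoys: int = 10_000,
    n_novel_families: int = 10,
    similar_fraction: float = 0.3,
    similar_radii: tuple[float, ...] = (0.4, 0.7, 1.0),
    seed: int = 1,
) -> tuple[np.ndarray, list[str], set[str]]:
    """A screening library: held-out actives plus unseen decoy families.

    Emulates a large-library screen: most decoys come from novel families far
    from everything in the training chemical space, while a
    ``similar_fraction`` share comes from families placed at intermediate
    distances (``similar_radii`` x separation) from the active families — the
    analogue of a similar-compound subset, the harder screening condition.
    Decoy families are kept closer to their seeding active centroid than to
    any training family so "similar" really means similar to actives.

    Returns ``(matrix, ids, known_active_ids)``; test actives are fresh draws
    from the training active families.
    """
    spec = library.spec
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    actives: set[str] = set()

    # held-out actives from the training active families
    for i in range(n_test_active):
        fam = i % spec.n_active_families
        rows.append(library.centroids[fam] + rng.normal(0.0, spec.spread, spec.n_dim))
        name = f"testact{i:04d}"
        ids.append(name)
        actives.add(name)

    n_similar = int(round(n_decoys * similar_fraction))
    n_far = n_decoys - n_similar

    # similar decoy families: shells around active centroids, nearer to their
    # seeding active than to any inactive training family
    shell_centroids = []
    inactive_centroids = library.centroids[spec.n_active_families :]
    for r in similar_radii:
        for fam in range(spec.n_active_families):
            base = library.centroids[fam]
            for _ in range(500):
                u = rng.normal(size=spec.n_dim)
                u /= np.linalg.norm(u)
                cand = base + r * spec.separation * u
                d_self = r * spec.separation
                if np.all(np.linalg.norm(inactive_centroids - cand, axis=1) > d_self):
                    shell_centroids.append(cand)
                    break
            else:
                raise RuntimeError("could not place a similar decoy family")
    for i, n in enumerate(_split_counts(n_similar, len(shell_centroids))):
        pts = shell_centroids[i] + rng.normal(0.0, spec.spread, size=(n, spec.n_dim))
        rows.append(pts)
        ids.extend(f"decsim{i}_{j:05d}" for j in range(n))

    # far decoy families: fresh centroids respecting the global separation
    novel = _draw_centroids(
        rng, n_novel_families, spec.n_dim, spec.separation, existing=library.centroids
    )
    for i, n in enumerate(_split_counts(n_far, n_novel_families)):
        pts = novel[i] + rng.normal(0.0, spec.spread, size=(n, spec.n_dim))
        rows.append(pts)
        ids.extend(f"decfar{i}_{j:05d}" for j in range(n))

    return np.vstack(rows), ids, actives


def fixture_molecules() -> list[tuple[str, str]]:
    """Packaged drug-like SMILES fixtures as (smiles, name) pairs.

    Spans alkanes, aromatics, N/O/S heterocycles, fused systems, an
    anilino-quinazoline kinase-inhibitor scaffold and charged species.
    """
    text = resources.files("chemvs.data").joinpath("fixtures.smi").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name = line.split(None, 1)
        out.append((smiles, name.strip()))
    return out


def fixture_golden_values() -> list[tuple[str, str, float]]:
    """Hand-computed golden descriptor values as (name, descriptor, value)."""
    text = resources.files("chemvs.data").joinpath("fixture_golden.tsv").read_text()
    out = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, desc, value = line.split("\t")
        out.append((name, desc, float(value)))
    return out
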