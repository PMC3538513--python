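"""The 98-descriptor featurization: 18 simple + 3 chemical + 35 connectivity/
shape + 42 electrotopological-state values in a fixed registry order."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..chem_io import MolecularGraph
from .chemical import CHEMICAL_NAMES, chemical_properties
from .estate import ESTATE_NAMES, estate_sums, estate_values, intrinsic_states
from .simple import SIMPLE_NAMES, simple_properties
from .topology import TOPOLOGY_NAMES, connectivity_shape

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorRegistry",
    "DescriptorVector",
    "REGISTRY",
    "simple_properties",
    "chemical_properties",
    "connectivity_shape",
    "estate_sums",
    "estate_values",
    "intrinsic_states",
    "compute_descriptor_vector",
    "featurize_library",
    "write_descriptor_table",
    "read_descriptor_table",
]


@dataclass(frozen=True)
class DescriptorRegistry:
    """Fixed-order catalogue of the 98 descriptors and their classes."""

    names: tuple[str, ...]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != 98 or len(set(self.names)) != 98:
            raise ValueError("registry must hold exactly 98 unique descriptor names")

    def __len__(self) -> int:
        return 98

    def index(self, name: str) -> int:
        return self.names.index(name)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.classes:
            out[c] = out.get(c, 0) + 1
        return out


REGISTRY = DescriptorRegistry(
    names=tuple(SIMPLE_NAMES + CHEMICAL_NAMES + TOPOLOGY_NAMES + ESTATE_NAMES),
    classes=tuple(
        ["simple"] * len(SIMPLE_NAMES)
        + ["chemical"] * len(CHEMICAL_NAMES)
        + ["connectivity_shape"] * len(TOPOLOGY_NAMES)
        + ["estate"] * len(ESTATE_NAMES)
    ),
)


@dataclass(frozen=True)
class DescriptorVector:
    values: np.ndarray
    molecule_id: str

    def __post_init__(self) -> None:
        if self.values.shape != (98,):
            raise ValueError(f"descriptor vector must have 98 values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            bad = [REGISTRY.names[i] for i in np.flatnonzero(~np.isfinite(self.values))]
            raise ValueError(f"non-finite descriptors for {self.molecule_id}: {bad}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[REGISTRY.index(name)])


def compute_descriptor_vector(mol: MolecularGraph) -> DescriptorVector:
    values = np.array(
        simple_properties(mol)
        + chemical_properties(mol)
        + connectivity_shape(mol)
        + estate_sums(mol),
        dtype=float,
    )
    return DescriptorVector(values=values, molecule_id=mol.name)


def featurize_library(
    mols: list[MolecularGraph],
) -> tuple[np.ndarray, list[str], int]:
    """Descriptor matrix (n x 98) for a molecule list, in input order.

    Molecules whose featurization fails are dropped with a logged warning;
    returns ``(matrix, ids, n_failed)``.
    """
    if not mols:
        raise ValueError("empty molecule list")
    rows, ids, failed = [], [], 0
    for mol in mols:
        try:
            vec = compute_descriptor_vector(mol)
        except Exception as exc:  # noqa: BLE001 - any per-molecule failure is skipped
            failed += 1
            logger.warning("featurization failed for %s: %s", mol.name, exc)
            continue
        rows.append(vec.values)
        ids.append(mol.name)
    if not rows:
        raise ValueError(f"all {failed} molecules failed featurization")
    return np.vstack(rows), ids, failed


def write_descriptor_table(
    path: str | Path, matrix: np.ndarray, ids: list[str], sep: str = "\t"
) -> None:
    df = pd.DataFrame(matrix, columns=list(REGISTRY.names))
    df.insert(0, "molecule_id", ids)
    df.to_csv(path, sep=sep, index=False)


def read_descriptor_table(path: str | Path, sep: str = "\t") -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=sep)
    ids = df.iloc[:, 0].astype(str).tolist()
    return df.iloc[:, 1:].to_numpy(dtype=float), ids
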