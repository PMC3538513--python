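"""Molecule input: SMILES/SDF parsing into hydrogen-suppressed molecular graphs.

RDKit does the heavy lifting (parsing, aromaticity perception, implicit-H
bookkeeping); the rest of the package consumes only the plain
:class:`MolecularGraph` container defined here, so every descriptor is a pure
function of the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "MoleculeParseError",
    "parse_smiles",
    "read_molecules",
    "to_rdkit",
]


class MoleculeParseError(ValueError):
    """Raised when a molecule record cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    n_h: int = 0  # attached (suppressed) hydrogens
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int  # 1, 2 or 3; aromatic bonds carry order 1 plus the flag
    aromatic: bool = False


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed chemical graph.

    Explicit hydrogens from the input are folded into per-atom attached-H
    counts.  Bond endpoints are validated on construction.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"invalid bond endpoints ({b.i},{b.j}) for {n} atoms")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        for a in self.atoms:
            if a.n_h < 0:
                raise ValueError("negative attached-H count")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 1,
}


def _from_rdkit(mol: Chem.Mol, name: str = "") -> MolecularGraph:
    mol = Chem.RemoveHs(mol)
    atoms = [
        Atom(
            element=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _BOND_ORDER.get(b.GetBondType())
        if order is None:
            raise MoleculeParseError(
                f"unsupported bond type {b.GetBondType()} in {name or Chem.MolToSmiles(mol)}"
            )
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, b.GetIsAromatic())
        )
    return MolecularGraph(atoms=atoms, bonds=bonds, name=name)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    logger.warning("multi-fragment input; keeping largest of %d fragments", len(frags))
    return max(frags, key=lambda m: m.GetNumAtoms())


def parse_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Multi-fragment (dot-separated) inputs keep only the fragment with the most
    heavy atoms; salts and counterions are irrelevant downstream.

    Raises
    ------
    MoleculeParseError
        If the string is empty or RDKit cannot parse it.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    return _from_rdkit(_largest_fragment(mol), name=name or smiles.strip())


def _iter_smi(path: Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            yield smiles, name


def read_molecules(
    path: str | Path, fmt: str | None = None
) -> tuple[list[MolecularGraph], int]:
    """Read a .smi or .sdf file into molecular graphs.

    Returns ``(graphs, n_failed)``; records that fail to parse are skipped
    with a logged warning.  ``fmt`` defaults to the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("smi", "sdf"):
        raise ValueError(f"unsupported format {fmt!r}; expected 'smi' or 'sdf'")

    graphs: list[MolecularGraph] = []
    failed = 0
    if fmt == "smi":
        for smiles, name in _iter_smi(path):
            try:
                graphs.append(parse_smiles(smiles, name=name))
            except MoleculeParseError as exc:
                failed += 1
                logger.warning("skipping record %s: %s", name, exc)
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                failed += 1
                logger.warning("skipping unparseable SDF record %d", idx)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{idx}"
            graphs.append(_from_rdkit(_largest_fragment(mol), name=name or f"record{idx}"))
    if not graphs:
        logger.warning("no molecules read from %s (%d failures)", path, failed)
    return graphs, failed


def to_rdkit(graph: MolecularGraph) -> Chem.Mol:
    """Rebuild an RDKit molecule from a molecular graph.

    Used where a descriptor delegates to an RDKit contribution model (ALogP);
    attached-H counts become explicit-H annotations so the rebuilt molecule is
    chemically identical to the parsed one.
    """
    rw = Chem.RWMol()
    for a in graph.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.charge)
        at.SetNumExplicitHs(a.n_h)
        at.SetNoImplicit(True)
        at.SetIsAromatic(a.aromatic)
        rw.AddAtom(at)
    for b in graph.bonds:
        if b.aromatic:
            bt = Chem.BondType.AROMATIC
        else:
            bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}[b.order]
        rw.AddBond(b.i, b.j, bt)
        rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(b.aromatic)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol
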