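"""Simple molecular property descriptors (18 values).

Counts of the common elements, atoms, bonds, rings, rotatable bonds,
hydrogen-bond donors/acceptors, aromatic and heteroaromatic ring counts, and
the average molecular weight.  "Number of bonds" includes bonds to suppressed
hydrogens; "Number of non-H bonds" is the heavy-atom bond count.
"""

from __future__ import annotations

from rdkit import Chem

from ..chem_io import MolecularGraph
from ._graph import ring_bond_set, sssr_rings

_PT = Chem.GetPeriodicTable()

SIMPLE_NAMES = [
    "nC", "nN", "nO", "nP", "nS",
    "nHeavy", "nRings", "nBonds", "nBondsHeavy", "MW",
    "nRotatable", "nHBDonors", "nHBAcceptors",
    "nAromRing5", "nAromRing6", "nRingN", "nRingO", "nRingS",
]


def is_donor(mol: MolecularGraph, i: int) -> bool:
    a = mol.atoms[i]
    return a.element in ("N", "O") and a.n_h >= 1


def is_acceptor(mol: MolecularGraph, i: int) -> bool:
    """N or O that is not positively charged (configurable convention)."""
    a = mol.atoms[i]
    return a.element in ("N", "O") and a.charge <= 0


def _rotatable_bonds(mol: MolecularGraph) -> int:
    ring = ring_bond_set(mol)
    deg = [mol.degree(i) for i in range(mol.n_atoms)]
    # atom indices of carbonyl carbons (C with a double bond to O), for the
    # amide C-N exclusion
    carbonyl_c = set()
    for b in mol.bonds:
        if b.order == 2 and not b.aromatic:
            ei, ej = mol.atoms[b.i].element, mol.atoms[b.j].element
            if ei == "C" and ej == "O":
                carbonyl_c.add(b.i)
            elif ej == "C" and ei == "O":
                carbonyl_c.add(b.j)
    n = 0
    for b in mol.bonds:
        if b.order != 1 or b.aromatic:
            continue
        if (min(b.i, b.j), max(b.i, b.j)) in ring:
            continue
        if deg[b.i] < 2 or deg[b.j] < 2:
            continue
        pair = {mol.atoms[b.i].element, mol.atoms[b.j].element}
        if pair == {"C", "N"}:
            c = b.i if mol.atoms[b.i].element == "C" else b.j
            if c in carbonyl_c:
                continue  # amide
        n += 1
    return n


def molecular_weight(mol: MolecularGraph) -> float:
    """Sum of average atomic masses over heavy atoms plus attached hydrogens."""
    mw = 0.0
    h_mass = _PT.GetAtomicWeight("H")
    for a in mol.atoms:
        mw += _PT.GetAtomicWeight(a.element) + a.n_h * h_mass
    return mw


def simple_properties(mol: MolecularGraph) -> list[float]:
    elems = [a.element for a in mol.atoms]
    rings = sssr_rings(mol)
    aromatic_atoms = {i for i, a in enumerate(mol.atoms) if a.aromatic}

    def aromatic_ring(ring: list[int]) -> bool:
        return all(i in aromatic_atoms for i in ring)

    def het_ring(ring: list[int], symbol: str) -> bool:
        return any(elems[i] == symbol for i in ring)

    n_h_total = sum(a.n_h for a in mol.atoms)
    return [
        float(elems.count("C")),
        float(elems.count("N")),
        float(elems.count("O")),
        float(elems.count("P")),
        float(elems.count("S")),
        float(mol.n_atoms),
        float(len(rings)),
        float(mol.n_bonds + n_h_total),
        float(mol.n_bonds),
        molecular_weight(mol),
        float(_rotatable_bonds(mol)),
        float(sum(is_donor(mol, i) for i in range(mol.n_atoms))),
        float(sum(is_acceptor(mol, i) for i in range(mol.n_atoms))),
        float(sum(1 for r in rings if len(r) == 5 and aromatic_ring(r))),
        float(sum(1 for r in rings if len(r) == 6 and aromatic_ring(r))),
        float(sum(1 for r in rings if het_ring(r, "N"))),
        float(sum(1 for r in rings if het_ring(r, "O"))),
        float(sum(1 for r in rings if het_ring(r, "S"))),
    ]
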