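"""Chemical property descriptors (3 values).

* total Sanderson electronegativity: sum over all atoms (including attached
  hydrogens) of the carbon-relative Sanderson electronegativity ratio;
* total atomic polarizability: sum of static atomic polarizabilities
  including attached hydrogens;
* ALogP: the Crippen atom-contribution octanol/water logP, delegated to
  RDKit's implementation of the contribution model.
"""

from __future__ import annotations

import logging

from rdkit.Chem import Crippen

from ..chem_io import MolecularGraph, to_rdkit
from .tables import POLARIZABILITY, SANDERSON_EN

logger = logging.getLogger(__name__)

CHEMICAL_NAMES = ["SandersonEN", "Polarizability", "ALogP"]


def _sum_with_h(mol: MolecularGraph, table: dict[str, float], what: str) -> float:
    total = 0.0
    h = table["H"]
    for a in mol.atoms:
        contrib = table.get(a.element)
        if contrib is None:
            logger.warning("no %s parameter for element %s; contributing 0", what, a.element)
            contrib = 0.0
        total += contrib + a.n_h * h
    return total


def sanderson_electronegativity(mol: MolecularGraph) -> float:
    en_c = SANDERSON_EN["C"]
    scaled = {k: v / en_c for k, v in SANDERSON_EN.items()}
    return _sum_with_h(mol, scaled, "Sanderson electronegativity")


def total_polarizability(mol: MolecularGraph) -> float:
    return _sum_with_h(mol, POLARIZABILITY, "polarizability")


def alogp(mol: MolecularGraph) -> float:
    return float(Crippen.MolLogP(to_rdkit(mol)))


def chemical_properties(mol: MolecularGraph) -> list[float]:
    return [sanderson_electronegativity(mol), total_polarizability(mol), alogp(mol)]
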