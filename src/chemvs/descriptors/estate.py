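"""Electrotopological-state descriptors (42 values).

Kier-Hall E-state machinery on the hydrogen-suppressed graph:

* intrinsic state  I_i = ((2/N_i)^2 delta_v,i + 1) / delta_i  with N the
  principal quantum number, delta the heavy-atom degree and
  delta_v = Z_v - h;
* pairwise perturbation  dI_ij = (I_i - I_j) / (d_ij + 1)^2  over all heavy
  atom pairs, d_ij the bond-count graph distance;
* E-state  S_i = I_i + sum_j dI_ij.

The first 24 outputs are sums of S_i over the named heavy-atom types (0 when
a type is absent), followed by sums over all heavy atoms, all carbons, all
heteroatoms and all H-bond acceptors.  The 13 hydrogen E-state sums and the
donor-H sum are computed on the hydrogen-augmented graph: every attached
hydrogen receives the intrinsic state I_H = ((2/1)^2 * 1 + 1)/1 = 5 from the
same formula at N = 1 and is perturbed by all heavy atoms (H-H perturbations
cancel since all I_H are equal); the hydrogen type follows its parent heavy
atom's type.

Atom types are canonical Kier-Hall bond-pattern strings (single/double/
triple/aromatic bond counts plus attached-H count).  Two registry labels map
to canonical patterns: ``SsssC`` denotes the quaternary carbon (ssssC) and
``SaOH`` the aromatic-ring oxygen (aaO).  Charge-separated nitro nitrogens
(pattern dssN with two oxygen neighbours) are typed ddsN.
"""

from __future__ import annotations

from ..chem_io import MolecularGraph
from ._graph import distance_matrix, hybridization
from .simple import is_acceptor, is_donor
from .tables import PRINCIPAL_QUANTUM, VALENCE_ELECTRONS

ESTATE_TYPE_LABELS = [
    "SsCH3", "SdCH2", "SssCH2", "SdsCH", "SaaCH", "SsssCH", "SdssC", "SaasC",
    "SaaaC", "SsssC", "SsNH3", "SsNH2", "SssNH2", "SdNH", "SssNH", "SaaNH",
    "SdsN", "SaaN", "SsssN", "SddsN", "SaOH", "SsOH", "SssO", "SsSH",
]

# registry label -> canonical bond-pattern type
_LABEL_TO_TYPE = {lab: lab[1:] for lab in ESTATE_TYPE_LABELS}
_LABEL_TO_TYPE["SsssC"] = "ssssC"
_LABEL_TO_TYPE["SaOH"] = "aaO"

_H_TYPE_LABELS = [
    "HsOH", "HdNH", "HsSH", "HsNH2", "HssNH", "HaaNH", "HtCH", "HdCH2",
    "HdsCH", "HaaCH", "HCsats", "HCsatu", "Havin",
]
_PARENT_TO_H = {
    "sOH": "HsOH", "dNH": "HdNH", "sSH": "HsSH", "sNH2": "HsNH2",
    "ssNH": "HssNH", "aaNH": "HaaNH", "tCH": "HtCH", "dCH2": "HdCH2",
    "dsCH": "HdsCH", "aaCH": "HaaCH",
}

ESTATE_NAMES = (
    ESTATE_TYPE_LABELS
    + ["Sall", "SallC", "Shetero", "Sacceptor"]
    + _H_TYPE_LABELS
    + ["Hdonor"]
)


def atom_type(mol: MolecularGraph, i: int) -> str:
    """Canonical Kier-Hall bond-pattern type string for heavy atom i."""
    ns = nd = nt = na = 0
    for b in mol.bonds:
        if i not in (b.i, b.j):
            continue
        if b.aromatic:
            na += 1
        elif b.order == 2:
            nd += 1
        elif b.order == 3:
            nt += 1
        else:
            ns += 1
    a = mol.atoms[i]
    pattern = "d" * nd + "t" * nt + "a" * na + "s" * ns
    if a.n_h == 0:
        suffix = a.element
    elif a.n_h == 1:
        suffix = a.element + "H"
    else:
        suffix = f"{a.element}H{a.n_h}"
    t = pattern + suffix
    # charge-separated nitro: N(+)(=O)(-O-) carries pattern dssN
    if t == "dssN":
        n_o = sum(1 for j in mol.neighbors(i) if mol.atoms[j].element == "O")
        if n_o >= 2:
            t = "ddsN"
    return t


def intrinsic_states(mol: MolecularGraph) -> list[float]:
    out = []
    for i, a in enumerate(mol.atoms):
        delta = mol.degree(i)
        if delta == 0:
            out.append(0.0)  # isolated heavy atom: degenerate convention
            continue
        zv = VALENCE_ELECTRONS.get(a.element, 4)
        nq = PRINCIPAL_QUANTUM.get(a.element, 2)
        dv = zv - a.n_h
        out.append(((2.0 / nq) ** 2 * dv + 1.0) / delta)
    return out


def estate_values(mol: MolecularGraph) -> list[float]:
    """Per-heavy-atom E-state values S_i."""
    n = mol.n_atoms
    intr = intrinsic_states(mol)
    if n == 1:
        return list(intr)
    dmat = distance_matrix(mol)
    out = []
    for i in range(n):
        s = intr[i]
        for j in range(n):
            if j == i or dmat[i, j] < 0:
                continue
            s += (intr[i] - intr[j]) / (dmat[i, j] + 1.0) ** 2
        out.append(s)
    return out


def hydrogen_estate_values(mol: MolecularGraph) -> list[tuple[int, float]]:
    """E-state values of attached hydrogens as (parent atom index, S_H) pairs.

    On the H-augmented graph the distance from an H on parent p to heavy atom
    j is d(p, j) + 1, so the perturbation denominator is (d(p, j) + 2)^2.
    """
    intr = intrinsic_states(mol)
    i_h = 5.0  # ((2/1)^2 * 1 + 1) / 1
    dmat = distance_matrix(mol) if mol.n_atoms > 1 else None
    out: list[tuple[int, float]] = []
    for p, a in enumerate(mol.atoms):
        if a.n_h == 0:
            continue
        s = i_h
        for j in range(mol.n_atoms):
            d = 0.0 if j == p else (dmat[p, j] if dmat is not None else -1.0)
            if d < 0 and j != p:
                continue
            s += (i_h - intr[j]) / (d + 2.0) ** 2
        for _ in range(a.n_h):
            out.append((p, s))
    return out


def estate_sums(mol: MolecularGraph) -> list[float]:
    svals = estate_values(mol)
    types = [atom_type(mol, i) for i in range(mol.n_atoms)]

    by_label = []
    for label in ESTATE_TYPE_LABELS:
        target = _LABEL_TO_TYPE[label]
        by_label.append(sum(s for t, s in zip(types, svals) if t == target))

    s_all = sum(svals)
    s_c = sum(s for a, s in zip(mol.atoms, svals) if a.element == "C")
    s_het = sum(s for a, s in zip(mol.atoms, svals) if a.element != "C")
    s_acc = sum(s for i, s in enumerate(svals) if is_acceptor(mol, i))

    hyb = hybridization(mol)
    adj = mol.adjacency()
    h_sums = {label: 0.0 for label in _H_TYPE_LABELS}
    h_donor = 0.0
    for p, s_h in hydrogen_estate_values(mol):
        t = types[p]
        label = _PARENT_TO_H.get(t)
        if label is None:
            if mol.atoms[p].element == "C" and hyb[p] == 3:
                unsat = any(hyb[q] != 3 for q in adj[p])
                label = "HCsatu" if unsat else "HCsats"
            else:
                label = "Havin"  # catch-all for remaining H environments
        h_sums[label] += s_h
        if is_donor(mol, p):
            h_donor += s_h

    return (
        by_label
        + [s_all, s_c, s_het, s_acc]
        + [h_sums[label] for label in _H_TYPE_LABELS]
        + [h_donor]
    )
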