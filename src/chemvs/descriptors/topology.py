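"""Molecular connectivity and shape descriptors (35 values).

Topological indices computed on the hydrogen-suppressed graph with unit bond
lengths.  Formulas follow the standard handbook definitions:

* Schultz MTI = sum_i [v (A + D)]_i with v the vertex-degree vector,
  A the adjacency and D the topological distance matrix.
* Gutman MTI = sum_{i<j} deg_i deg_j d_ij.
* Wiener W = sum_{i<j} d_ij;  Harary H = sum_{i<j} 1/d_ij.
* Gravitational index (topological analogue of the 3D mass-distance index):
  sum_{i<j} m_i m_j / d_ij^2 with m the heavy-atom average atomic mass.
* Molecular path counts p_1..p_6 and total path count
  (atoms + all simple paths, each counted once).
* Balaban J = M/(mu+1) sum_bonds (s_i s_j)^(-1/2), s = distance-row sums,
  mu = cyclomatic number.
* Valence connectivity chi^v of order 0-2 with the Kier-Hall valence delta
  (delta_v = Z_v - h for second-row atoms, (Z_v - h)/(Z - Z_v - 1) below);
  delta-chi_m = chi_m(simple) - chi_m(valence).
* Pogliani index = sum_i Z_v,i / N_i (valence electrons over period).
* Solvation connectivity chi^s of order m:
  (1/2^(m+1)) sum_paths prod(L) / sqrt(prod(delta)), L = period.
* Kier kappa shape indices of order 1-3 and their alpha-modified forms
  (alpha from Kier covalent-radius ratios), Kier flexibility
  phi = (1-kappa-alpha)(2-kappa-alpha)/A.
* Topological radius (min eccentricity), Petitjean graph-theoretical shape
  coefficient (diameter - radius)/radius, eccentricity (sum of atom
  eccentricities), centralization 2W - n*(min distance-row sum).
* LogP from connectivity: the classic single-variable linear calibration on
  the first-order valence connectivity index, 0.950 * chi1v - 1.480.

Degenerate inputs (single atoms, vanishing path counts) emit 0 rather than
NaN so downstream linear algebra stays total.
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem

from ..chem_io import MolecularGraph
from ._graph import distance_matrix, enumerate_paths, hybridization, path_atom_tuples
from .tables import (
    ATOMIC_NUMBER,
    KIER_RADII,
    PRINCIPAL_QUANTUM,
    R_C_SP3,
    VALENCE_ELECTRONS,
)

_PT = Chem.GetPeriodicTable()

TOPOLOGY_NAMES = [
    "SchultzMTI", "GutmanMTI", "Wiener", "Harary", "Gravitational",
    "PathCount1", "PathCount2", "PathCount3", "PathCount4", "PathCount5",
    "PathCount6", "TotalPathCount", "BalabanJ",
    "Chi0v", "Chi1v", "Chi2v", "DeltaChi0", "DeltaChi1", "DeltaChi2",
    "Pogliani", "SolvChi0", "SolvChi1", "SolvChi2",
    "Kappa1", "Kappa2", "Kappa3",
    "KappaAlpha1", "KappaAlpha2", "KappaAlpha3", "KierFlexibility",
    "TopoRadius", "ShapeCoefficient", "Eccentricity", "Centralization",
    "LogPConn",
]


def simple_delta(mol: MolecularGraph) -> list[float]:
    return [float(mol.degree(i)) for i in range(mol.n_atoms)]


def valence_delta(mol: MolecularGraph) -> list[float]:
    """Kier-Hall valence connectivity delta per heavy atom."""
    out = []
    for a in mol.atoms:
        zv = VALENCE_ELECTRONS.get(a.element, 4)
        z = ATOMIC_NUMBER.get(a.element, zv)
        if z <= 10:  # second row (and H/B..F)
            dv = zv - a.n_h
        else:
            dv = (zv - a.n_h) / (z - zv - 1)
        out.append(float(dv))
    return out


def _chi(mol: MolecularGraph, delta: list[float], order: int) -> float:
    total = 0.0
    for path in path_atom_tuples(mol, order):
        prod = 1.0
        for i in path:
            prod *= delta[i]
        if prod > 0:
            total += prod ** -0.5
    return total


def _kappa(a: float, p1: float, p2: float, p3: float, n_int: int) -> tuple[float, float, float]:
    k1 = a * (a - 1.0) ** 2 / p1**2 if p1 > 0 else 0.0
    k2 = (a - 1.0) * (a - 2.0) ** 2 / p2**2 if p2 > 0 else 0.0
    if p3 > 0:
        if n_int % 2 == 1:
            k3 = (a - 1.0) * (a - 3.0) ** 2 / p3**2
        else:
            k3 = (a - 3.0) * (a - 2.0) ** 2 / p3**2
    else:
        k3 = 0.0
    return k1, k2, k3


def kier_alpha(mol: MolecularGraph) -> float:
    hyb = hybridization(mol)
    alpha = 0.0
    for a, h in zip(mol.atoms, hyb):
        r = KIER_RADII.get((a.element, h)) or KIER_RADII.get((a.element, 3))
        if r is None:
            continue  # unparameterized element: no shape correction
        alpha += r / R_C_SP3 - 1.0
    return alpha


def connectivity_shape(mol: MolecularGraph) -> list[float]:
    n = mol.n_atoms
    if n == 0:
        return [0.0] * len(TOPOLOGY_NAMES)

    dmat = distance_matrix(mol)
    deg = np.array([mol.degree(i) for i in range(n)], dtype=float)
    adj = np.zeros((n, n))
    for b in mol.bonds:
        adj[b.i, b.j] = adj[b.j, b.i] = 1.0

    iu = np.triu_indices(n, k=1)
    dvals = dmat[iu]
    wiener = float(dvals.sum()) if n > 1 else 0.0
    harary = float((1.0 / dvals[dvals > 0]).sum()) if n > 1 else 0.0
    schultz = float(deg @ (adj + dmat) @ np.ones(n)) if n > 1 else 0.0
    gutman = float(sum(deg[i] * deg[j] * dmat[i, j] for i, j in zip(*iu))) if n > 1 else 0.0

    masses = np.array([_PT.GetAtomicWeight(a.element) for a in mol.atoms])
    grav = 0.0
    for i, j in zip(*iu):
        if dmat[i, j] > 0:
            grav += masses[i] * masses[j] / dmat[i, j] ** 2

    paths = enumerate_paths(mol)
    p = [float(paths.get(m, 0)) for m in range(1, 7)]
    total_paths = float(n + sum(paths.values()))

    # Balaban J
    mu = mol.n_bonds - n + 1  # cyclomatic number (connected graph)
    s = dmat.sum(axis=1)
    bal = 0.0
    for b in mol.bonds:
        if s[b.i] > 0 and s[b.j] > 0:
            bal += (s[b.i] * s[b.j]) ** -0.5
    balaban = mol.n_bonds / (mu + 1.0) * bal if mol.n_bonds else 0.0

    sdelta = simple_delta(mol)
    vdelta = valence_delta(mol)
    chi_s = [_chi(mol, sdelta, m) for m in range(3)]
    chi_v = [_chi(mol, vdelta, m) for m in range(3)]
    dchi = [cs - cv for cs, cv in zip(chi_s, chi_v)]

    pogliani = sum(
        VALENCE_ELECTRONS.get(a.element, 4) / PRINCIPAL_QUANTUM.get(a.element, 2)
        for a in mol.atoms
    )

    period = [float(PRINCIPAL_QUANTUM.get(a.element, 2)) for a in mol.atoms]
    solv = []
    for m in range(3):
        tot = 0.0
        for path in path_atom_tuples(mol, m):
            prod_l = 1.0
            prod_d = 1.0
            for i in path:
                prod_l *= period[i]
                prod_d *= sdelta[i]
            if prod_d > 0:
                tot += prod_l / math.sqrt(prod_d)
        solv.append(tot / 2 ** (m + 1))

    k1, k2, k3 = _kappa(float(n), p[0], p[1], p[2], n)
    alpha = kier_alpha(mol)
    ka1, ka2, ka3 = _kappa(n + alpha, p[0] + alpha, p[1] + alpha, p[2] + alpha, n)
    flexibility = ka1 * ka2 / n if n else 0.0

    if n > 1:
        ecc = dmat.max(axis=1)
        radius = float(ecc.min())
        diameter = float(ecc.max())
        shape_coeff = (diameter - radius) / radius if radius > 0 else 0.0
        ecc_total = float(ecc.sum())
        centralization = 2.0 * wiener - n * float(s.min())
    else:
        radius = shape_coeff = ecc_total = centralization = 0.0

    logp_conn = 0.950 * chi_v[1] - 1.480

    return [
        schultz, gutman, wiener, harary, grav,
        *p, total_paths, balaban,
        chi_v[0], chi_v[1], chi_v[2], dchi[0], dchi[1], dchi[2],
        pogliani, solv[0], solv[1], solv[2],
        k1, k2, k3, ka1, ka2, ka3, flexibility,
        radius, shape_coeff, ecc_total, centralization,
        logp_conn,
    ]
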