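"""Element parameter tables used by the descriptor modules.

Values are the standard handbook parameterizations (Sanderson electronegativity
scale; CRC static atomic polarizabilities in 1e-24 cm^3; Kier's covalent radii
for the kappa-alpha shape correction).  An element absent from a table
contributes 0 to the affected descriptor and triggers a logged warning — the
descriptor stays finite.
"""

from __future__ import annotations

# Sanderson electronegativities; descriptors use the carbon-relative ratio.
SANDERSON_EN: dict[str, float] = {
    "H": 2.592,
    "B": 2.275,
    "C": 2.746,
    "N": 3.194,
    "O": 3.654,
    "F": 4.000,
    "Si": 2.138,
    "P": 2.515,
    "S": 2.957,
    "Cl": 3.475,
    "Br": 3.219,
    "I": 2.778,
}

# Static average atomic polarizabilities (CRC Handbook), 1e-24 cm^3.
POLARIZABILITY: dict[str, float] = {
    "H": 0.666793,
    "B": 3.03,
    "C": 1.76,
    "N": 1.10,
    "O": 0.802,
    "F": 0.557,
    "Si": 5.38,
    "P": 3.63,
    "S": 2.90,
    "Cl": 2.18,
    "Br": 3.05,
    "I": 5.35,
}

# Valence electron counts Z_v for the organic subset.
VALENCE_ELECTRONS: dict[str, int] = {
    "H": 1,
    "B": 3,
    "C": 4,
    "N": 5,
    "O": 6,
    "F": 7,
    "Si": 4,
    "P": 5,
    "S": 6,
    "Cl": 7,
    "Br": 7,
    "I": 7,
}

# Total electron counts Z (atomic numbers) for the valence-delta correction
# of higher-row elements: delta_v = (Z_v - h) / (Z - Z_v - 1).
ATOMIC_NUMBER: dict[str, int] = {
    "H": 1,
    "B": 5,
    "C": 6,
    "N": 7,
    "O": 8,
    "F": 9,
    "Si": 14,
    "P": 15,
    "S": 16,
    "Cl": 17,
    "Br": 35,
    "I": 53,
}

# Principal quantum number (period) for the E-state (2/N)^2 scaling and the
# solvation-connectivity / Pogliani indices.
PRINCIPAL_QUANTUM: dict[str, int] = {
    "H": 1,
    "B": 2,
    "C": 2,
    "N": 2,
    "O": 2,
    "F": 2,
    "Si": 3,
    "P": 3,
    "S": 3,
    "Cl": 3,
    "Br": 4,
    "I": 5,
}

# Kier covalent radii (Angstrom) by (element, hybridization) for the alpha
# modification of the kappa shape indices; alpha_i = r_i / r(C sp3) - 1.
# Hybridization keys: 3 = sp3, 2 = sp2/aromatic, 1 = sp.
KIER_RADII: dict[tuple[str, int], float] = {
    ("C", 3): 0.77,
    ("C", 2): 0.67,
    ("C", 1): 0.60,
    ("N", 3): 0.74,
    ("N", 2): 0.62,
    ("N", 1): 0.55,
    ("O", 3): 0.74,
    ("O", 2): 0.62,
    ("F", 3): 0.72,
    ("Cl", 3): 0.99,
    ("Br", 3): 1.14,
    ("I", 3): 1.33,
    ("P", 3): 1.10,
    ("P", 2): 1.00,
    ("S", 3): 1.04,
    ("S", 2): 0.94,
    ("Si", 3): 1.17,
    ("B", 3): 0.88,
}

R_C_SP3 = KIER_RADII[("C", 3)]
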