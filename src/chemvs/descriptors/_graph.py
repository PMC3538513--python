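"""Shared graph machinery for the descriptor modules.

Everything operates on the hydrogen-suppressed :class:`~chemvs.chem_io.MolecularGraph`;
networkx provides shortest paths and the minimum cycle basis (the
smallest-set-of-smallest-rings analogue used for ring counts).
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from ..chem_io import MolecularGraph


def nx_graph(mol: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    return g


def distance_matrix(mol: MolecularGraph) -> np.ndarray:
    """Topological (bond-count) distance matrix; disconnected pairs are -1."""
    n = mol.n_atoms
    dmat = np.full((n, n), -1, dtype=float)
    g = nx_graph(mol)
    for i, dists in nx.all_pairs_shortest_path_length(g):
        for j, d in dists.items():
            dmat[i, j] = d
    return dmat


def sssr_rings(mol: MolecularGraph) -> list[list[int]]:
    """Minimum cycle basis of the graph: one atom-index list per ring.

    The basis size equals the cyclomatic number, matching the ring count
    reported by common descriptor packages.
    """
    if mol.n_atoms == 0:
        return []
    return [list(c) for c in nx.minimum_cycle_basis(nx_graph(mol))]


def ring_bond_set(mol: MolecularGraph) -> set[tuple[int, int]]:
    """Bonds that belong to at least one ring (non-bridge edges)."""
    g = nx_graph(mol)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    out = set()
    for b in mol.bonds:
        if frozenset((b.i, b.j)) not in bridges:
            out.add((min(b.i, b.j), max(b.i, b.j)))
    return out


def enumerate_paths(mol: MolecularGraph, max_len: int | None = None) -> dict[int, int]:
    """Count simple paths by edge length.

    A path is a sequence of distinct atoms joined by bonds; each undirected
    path is counted once.  ``max_len=None`` enumerates all lengths (for the
    total path count).  Returns ``{length: count}`` for lengths >= 1.
    """
    adj = mol.adjacency()
    limit = max_len if max_len is not None else mol.n_atoms - 1

    # iterative DFS from every start atom; count ordered paths then halve
    ordered: dict[int, int] = {}
    for start in range(mol.n_atoms):
        stack: list[tuple[int, list[int]]] = [(start, [start])]
        while stack:
            node, path = stack.pop()
            edges = len(path) - 1
            if edges >= 1:
                ordered[edges] = ordered.get(edges, 0) + 1
            if edges == limit:
                continue
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))
    return {k: v // 2 for k, v in sorted(ordered.items())}


def path_atom_tuples(mol: MolecularGraph, length: int) -> list[tuple[int, ...]]:
    """All simple paths of the given edge length, one tuple per undirected path."""
    adj = mol.adjacency()
    out: list[tuple[int, ...]] = []
    for start in range(mol.n_atoms):
        stack: list[list[int]] = [[start]]
        while stack:
            path = stack.pop()
            if len(path) - 1 == length:
                if path[0] < path[-1] or (path[0] == path[-1] and length == 0):
                    out.append(tuple(path))
                continue
            for nb in adj[path[-1]]:
                if nb not in path:
                    stack.append(path + [nb])
    if length == 0:
        return [(i,) for i in range(mol.n_atoms)]
    return out


def hybridization(mol: MolecularGraph) -> list[int]:
    """Per-atom hybridization class: 1 = sp, 2 = sp2/aromatic, 3 = sp3."""
    n_double = [0] * mol.n_atoms
    n_triple = [0] * mol.n_atoms
    arom = [a.aromatic for a in mol.atoms]
    for b in mol.bonds:
        if b.aromatic:
            continue
        if b.order == 2:
            n_double[b.i] += 1
            n_double[b.j] += 1
        elif b.order == 3:
            n_triple[b.i] += 1
            n_triple[b.j] += 1
    out = []
    for i in range(mol.n_atoms):
        if n_triple[i] >= 1 or n_double[i] >= 2:
            out.append(1)
        elif n_double[i] >= 1 or arom[i]:
            out.append(2)
        else:
            out.append(3)
    return out
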