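"""Shared fixtures: small molecules, SM/product fixture pairs, and
brute-force graph oracles independent of the library code under test."""

from __future__ import annotations

import numpy as np
import pytest

from lsfregio.molgraph import MolecularGraph, parse_molecule

#: Small, chemically varied molecules (all <= 12 heavy atoms).
SMALL_SMILES = [
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1cnccn1",            # pyrazine
    "Cc1ccncc1",           # 4-methylpyridine
    "Cc1ccnc2ccccc12",     # 4-methylquinoline
    "c1ccc2ncccc2c1",      # quinoline
    "Cc1ccccc1",           # toluene
    "CCc1ccccc1",          # ethylbenzene
    "COc1ccncc1",          # 4-methoxypyridine
    "Clc1ccncc1",          # 4-chloropyridine
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "Cn1ccnc1",            # N-methylimidazole
    "CC(=O)c1ccccc1",      # acetophenone
    "C1CCNCC1",            # piperidine
    "Nc1ccccc1",           # aniline
    "N#Cc1ccncc1",         # 4-cyanopyridine
]


@pytest.fixture(scope="session")
def small_molecules() -> dict[str, MolecularGraph]:
    return {s: parse_molecule(s) for s in SMALL_SMILES}


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of networkx/RDKit matching)
# ---------------------------------------------------------------------------

def _graph_dicts(g: MolecularGraph):
    """Element list and bond dict {(i,j): type} with i<j."""
    bonds = {(b.i, b.j): b.bond_type for b in g.bonds}
    return g.elements, bonds


def _edge_compatible(t_sm, t_prod, arom_sm, arom_prod) -> bool:
    if t_sm == t_prod:
        return True
    tolerated = {"aromatic", "single", "double"}
    return (t_sm in tolerated and t_prod in tolerated
            and "aromatic" in (t_sm, t_prod) and arom_sm == arom_prod)


def brute_force_embeddings(sm: MolecularGraph,
                           prod: MolecularGraph) -> list[dict[int, int]]:
    """All induced, element/bond-compatible embeddings by backtracking.

    Exhaustive recursive search over injective assignments; feasible for
    the <= 12-atom fixture molecules. Independent re-implementation of the
    matching semantics: every SM bond maps to a compatible product bond,
    and product bonds between mapped atoms must exist in the SM (induced).
    """
    sm_el, sm_bonds = _graph_dicts(sm)
    prod_el, prod_bonds = _graph_dicts(prod)
    sm_adj = {i: {} for i in range(sm.n_atoms)}
    for (i, j), t in sm_bonds.items():
        sm_adj[i][j] = t
        sm_adj[j][i] = t
    prod_adj = {i: {} for i in range(prod.n_atoms)}
    for (i, j), t in prod_bonds.items():
        prod_adj[i][j] = t
        prod_adj[j][i] = t

    results: list[dict[int, int]] = []
    mapping: dict[int, int] = {}
    used: set[int] = set()

    def extend(i: int) -> None:
        if i == sm.n_atoms:
            results.append(dict(mapping))
            return
        for p in range(prod.n_atoms):
            if p in used or sm_el[i] != prod_el[p]:
                continue
            ok = True
            for q, t_sm in sm_adj[i].items():
                if q < i:
                    t_prod = prod_adj[p].get(mapping[q])
                    if t_prod is None or not _edge_compatible(
                            t_sm, t_prod,
                            sm.aromatic[i] and sm.aromatic[q],
                            prod.aromatic[p]
                            and prod.aromatic[mapping[q]]):
                        ok = False
                        break
            if ok:
                # induced: no extra product bond between mapped atoms
                for q in range(i):
                    if mapping[q] in prod_adj[p] and q not in sm_adj[i]:
                        ok = False
                        break
            if ok:
                mapping[i] = p
                used.add(p)
                extend(i + 1)
                used.discard(p)
                del mapping[i]

    extend(0)
    return results


def brute_force_automorphisms(g: MolecularGraph) -> list[dict[int, int]]:
    """All attribute- and bond-preserving permutations, by backtracking."""
    n = g.n_atoms
    el, bonds = _graph_dicts(g)
    adj = {i: {} for i in range(n)}
    for (i, j), t in bonds.items():
        adj[i][j] = t
        adj[j][i] = t
    attrs = [(el[i], g.h_counts[i], g.formal_charges[i], g.aromatic[i],
              len(adj[i])) for i in range(n)]
    results: list[dict[int, int]] = []
    mapping: dict[int, int] = {}
    used: set[int] = set()

    def extend(i: int) -> None:
        if i == n:
            results.append(dict(mapping))
            return
        for p in range(n):
            if p in used or attrs[i] != attrs[p]:
                continue
            ok = all(mapping[q] in adj[p] and adj[p][mapping[q]] == t
                     for q, t in adj[i].items() if q < i)
            if ok:
                mapping[i] = p
                used.add(p)
                extend(i + 1)
                used.discard(p)
                del mapping[i]

    extend(0)
    return results


def brute_force_orbits(g: MolecularGraph) -> list[int]:
    """Automorphism orbits from the enumerated permutation group."""
    n = g.n_atoms
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for perm in brute_force_automorphisms(g):
        for i in range(n):
            ri, rj = find(i), find(perm[i])
            if ri != rj:
                parent[ri] = rj
    labels = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    return [relabel.setdefault(c, len(relabel)) for c in labels]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
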