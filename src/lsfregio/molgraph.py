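"""Molecular graph data model, featurization, and symmetry classes.

Molecules are handled as heavy-atom (hydrogen-suppressed) graphs: hydrogens
are atom attributes, not nodes. Atom order is the canonical-SMILES output
order, so indices are reproducible across runs for a given structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import Lipinski

from .errors import FeaturizationError, ParseError

#: Order in which bond types are one-hot encoded everywhere in the package.
BOND_TYPES = ("single", "double", "triple", "aromatic")

#: Named element vocabulary; anything else lands in the trailing "other" slot.
ELEMENT_VOCAB = ("B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I",
                 "Si", "Se", "Sn", "Zn")

HYBRIDIZATIONS = ("sp", "sp2", "sp3")

#: Bumped whenever the feature layout changes; stored in model checkpoints.
FEATURE_VERSION = "1"

_RD_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_TO_RD_BOND = {v: k for k, v in _RD_BOND.items()}

_RD_HYB = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}

#: Bond order used for oxidation-state bookkeeping. Aromatic bonds count
#: 1.5 so the result does not depend on an arbitrary Kekulé assignment.
BOND_ORDER = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


@dataclass(frozen=True)
class Bond:
    """Undirected heavy-atom bond, stored once with i < j."""

    i: int
    j: int
    bond_type: str

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError(f"self-bond on atom {self.i}")
        if self.bond_type not in BOND_TYPES:
            raise ValueError(f"unknown bond type {self.bond_type!r}")
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with per-atom chemistry attributes.

    Attributes
    ----------
    elements : element symbol per atom, index 0..n-1.
    h_counts : total (implicit + explicit) hydrogens per atom.
    formal_charges : formal charge per atom.
    aromatic : aromaticity flag per atom.
    hybridizations : "sp" | "sp2" | "sp3" | "other" per atom.
    donor, acceptor : pharmacophore H-bond donor/acceptor flags per atom.
    bonds : list of :class:`Bond`, each stored once with i < j.
    mol_id : free-form identifier (canonical SMILES by default).
    """

    elements: list[str]
    h_counts: list[int]
    formal_charges: list[int]
    aromatic: list[bool]
    hybridizations: list[str]
    donor: list[bool]
    acceptor: list[bool]
    bonds: list[Bond]
    mol_id: str = ""
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.elements)
        for name in ("h_counts", "formal_charges", "aromatic",
                     "hybridizations", "donor", "acceptor"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != atom count")
        if any(h < 0 for h in self.h_counts):
            raise ValueError("negative hydrogen count")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[tuple[int, str]]:
        """Bonded partners of atom i with the bond type, sorted by index."""
        out = [(b.j, b.bond_type) for b in self.bonds if b.i == i]
        out += [(b.i, b.bond_type) for b in self.bonds if b.j == i]
        return sorted(out)

    def degree(self, i: int) -> int:
        """Heavy-atom degree of atom i."""
        return sum(1 for b in self.bonds if i in (b.i, b.j))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el, aromatic=self.aromatic[i])
        for b in self.bonds:
            g.add_edge(b.i, b.j, bond_type=b.bond_type,
                       arom_env=self.aromatic[b.i] and self.aromatic[b.j])
        return g

    def to_rdkit(self) -> Chem.Mol:
        """RDKit molecule with atom indices identical to this graph's."""
        if self._rdmol is not None:
            return self._rdmol
        rw = Chem.RWMol()
        for i, el in enumerate(self.elements):
            a = Chem.Atom(el)
            a.SetFormalCharge(self.formal_charges[i])
            a.SetNumExplicitHs(self.h_counts[i])
            a.SetNoImplicit(True)
            a.SetIsAromatic(self.aromatic[i])
            rw.AddAtom(a)
        for b in self.bonds:
            rw.AddBond(b.i, b.j, _TO_RD_BOND[b.bond_type])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        self._rdmol = mol
        return mol

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: str = "") -> "MolecularGraph":
        donors = {i for (i,) in mol.GetSubstructMatches(Lipinski.HDonorSmarts)}
        accept = {i for (i,) in
                  mol.GetSubstructMatches(Lipinski.HAcceptorSmarts)}
        bonds = []
        for b in mol.GetBonds():
            bt = _RD_BOND.get(b.GetBondType())
            if bt is None:
                raise ParseError(
                    f"unsupported bond type {b.GetBondType()} in {mol_id!r}")
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            bonds.append(Bond(min(i, j), max(i, j), bt))
        atoms = list(mol.GetAtoms())
        return cls(
            elements=[a.GetSymbol() for a in atoms],
            h_counts=[a.GetTotalNumHs() for a in atoms],
            formal_charges=[a.GetFormalCharge() for a in atoms],
            aromatic=[a.GetIsAromatic() for a in atoms],
            hybridizations=[_RD_HYB.get(a.GetHybridization(), "other")
                            for a in atoms],
            donor=[i in donors for i in range(mol.GetNumAtoms())],
            acceptor=[i in accept for i in range(mol.GetNumAtoms())],
            bonds=sorted(bonds, key=lambda b: (b.i, b.j)),
            mol_id=mol_id or Chem.MolToSmiles(mol),
            _rdmol=mol,
        )


def parse_molecule(smiles: str, mol_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a canonically ordered heavy-atom graph.

    The molecule is round-tripped through its canonical SMILES so that atom
    indices follow the canonical output order regardless of how the input
    was written.

    Raises
    ------
    ParseError
        If the SMILES string cannot be parsed or sanitized.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise ParseError(f"canonical SMILES failed to reparse: {canonical!r}")
    return MolecularGraph.from_rdkit(mol, mol_id=mol_id or canonical)


@dataclass
class AtomFeatureMatrix:
    """Per-atom feature rows in a fixed, versioned layout."""

    values: np.ndarray
    columns: list[str]
    version: str = FEATURE_VERSION

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


def feature_columns(include_formal_charge: bool = False) -> list[str]:
    cols = ["atomic_number"]
    cols += [f"element_{e}" for e in ELEMENT_VOCAB] + ["element_other"]
    cols += ["h_donor", "h_acceptor"]
    cols += [f"hyb_{h}" for h in HYBRIDIZATIONS] + ["hyb_other"]
    cols += ["aromatic", "n_hydrogens"]
    if include_formal_charge:
        cols.append("formal_charge")
    return cols


def featurize_atoms(g: MolecularGraph, *, include_formal_charge: bool = False,
                    strict: bool = False) -> AtomFeatureMatrix:
    """Encode basic atomic information as one feature row per atom.

    Columns: atomic number (scaled by 0.1), element one-hot, H-bond
    donor/acceptor flags, hybridization one-hot, aromaticity flag, and the
    hydrogen count. Formal charge is an optional, default-off column.

    Raises
    ------
    FeaturizationError
        In strict mode, if an element is outside the named vocabulary
        (non-strict mode routes it to the "other" slot).
    """
    pt = Chem.GetPeriodicTable()
    cols = feature_columns(include_formal_charge)
    x = np.zeros((g.n_atoms, len(cols)), dtype=np.float64)
    for i, el in enumerate(g.elements):
        c = 0
        x[i, c] = 0.1 * pt.GetAtomicNumber(el)
        c += 1
        if el in ELEMENT_VOCAB:
            x[i, c + ELEMENT_VOCAB.index(el)] = 1.0
        elif strict:
            raise FeaturizationError(
                f"element {el!r} (atom {i}) outside vocabulary")
        else:
            x[i, c + len(ELEMENT_VOCAB)] = 1.0
        c += len(ELEMENT_VOCAB) + 1
        x[i, c] = float(g.donor[i])
        x[i, c + 1] = float(g.acceptor[i])
        c += 2
        hyb = g.hybridizations[i]
        if hyb in HYBRIDIZATIONS:
            x[i, c + HYBRIDIZATIONS.index(hyb)] = 1.0
        else:
            x[i, c + len(HYBRIDIZATIONS)] = 1.0
        c += len(HYBRIDIZATIONS) + 1
        x[i, c] = float(g.aromatic[i])
        x[i, c + 1] = float(g.h_counts[i])
        if include_formal_charge:
            x[i, c + 2] = float(g.formal_charges[i])
    return AtomFeatureMatrix(values=x, columns=cols)


@dataclass
class BondTensor:
    """Adjacency indicator plus per-bond-type one-hot adjacency.

    ``by_type`` stacks one symmetric 0/1 matrix per entry of ``bond_types``;
    ``adjacency`` is their elementwise maximum.
    """

    adjacency: np.ndarray          # (n, n)
    by_type: np.ndarray            # (n_types, n, n)
    bond_types: tuple[str, ...] = BOND_TYPES

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]


def bond_tensor(g: MolecularGraph) -> BondTensor:
    """Build the symmetric adjacency / bond-type tensor of a graph."""
    n = g.n_atoms
    by_type = np.zeros((len(BOND_TYPES), n, n), dtype=np.float64)
    for b in g.bonds:
        t = BOND_TYPES.index(b.bond_type)
        by_type[t, b.i, b.j] = 1.0
        by_type[t, b.j, b.i] = 1.0
    return BondTensor(adjacency=by_type.max(axis=0), by_type=by_type)


def atom_symmetry_classes(g: MolecularGraph) -> list[int]:
    """Automorphism-orbit label per atom.

    Atoms in the same constitutional-symmetry orbit (identical chemical
    environments, hence identical NMR shifts) share a label; labels are the
    RDKit canonical ranks with ties unbroken, so they do not depend on the
    input atom ordering.
    """
    mol = g.to_rdkit()
    ranks = Chem.CanonicalRankAtoms(mol, breakTies=False,
                                    includeChirality=False)
    return list(ranks)


def symmetry_orbits(g: MolecularGraph) -> list[list[int]]:
    """Orbits as sorted index lists, sorted by their smallest member."""
    classes = atom_symmetry_classes(g)
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(classes):
        groups.setdefault(c, []).append(i)
    return sorted(groups.values(), key=lambda o: o[0])
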