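"""Symmetry-aware extraction of reactive-site labels from SM/product pairs.

Late-stage functionalization leaves the substrate core intact: the starting
material (SM) is a subgraph of the product. Every element- and
bond-compatible embedding of the SM into the product is enumerated; a carbon
whose oxidation state or heavy-atom degree changes under any embedding is
labeled reactive. Taking the union over embeddings makes the label set
closed under the SM's automorphism group, so symmetric sites are labeled
together even though only one of them physically reacted.
"""

from __future__ import annotations

from dataclasses import dataclass

from networkx.algorithms import isomorphism

from .errors import DegradedProductError, DomainError
from .molgraph import BOND_ORDER, MolecularGraph

#: Pauling electronegativities for the supported element set.
ELECTRONEGATIVITY = {
    "H": 2.20, "B": 2.04, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "Si": 1.90, "P": 2.19, "S": 2.58, "Cl": 3.16, "Se": 2.55, "Br": 2.96,
    "Sn": 1.96, "I": 2.66, "Zn": 1.65,
}

#: Electronegativity differences at or below this are treated as a tie
#: (contribution 0); covers the C-S pair (2.58 vs 2.55).
_EN_TIE = 0.05


@dataclass
class AtomMapping:
    """Injective map from SM atom indices to product atom indices."""

    sm_to_product: dict[int, int]

    def __getitem__(self, i: int) -> int:
        return self.sm_to_product[i]


@dataclass
class ReactiveSiteLabels:
    """Per-SM-atom binary reactive labels with a provenance note."""

    labels: list[int]
    provenance: str = "automatic"   # automatic | manual | degraded

    @property
    def reactive_set(self) -> set[int]:
        return {i for i, v in enumerate(self.labels) if v}


def _en_sign(a: str, b: str) -> float:
    """+1 if b is more electronegative than a, -1 if less, 0 on a tie."""
    da = ELECTRONEGATIVITY.get(a)
    db = ELECTRONEGATIVITY.get(b)
    if da is None or db is None:
        return 0.0
    diff = db - da
    if abs(diff) <= _EN_TIE:
        return 0.0
    return 1.0 if diff > 0 else -1.0


def oxidation_number(g: MolecularGraph, i: int) -> float:
    """Organic-chemistry oxidation number of carbon atom i.

    Each bond contributes its order times +1 toward a more electronegative
    partner and -1 toward a less electronegative one (each hydrogen counts
    -1); bonds between atoms of equal electronegativity contribute 0.
    Aromatic bonds count order 1.5, which keeps the value independent of the
    arbitrary Kekulé structure (aromatic carbons can therefore carry
    half-integer values; differences under H -> C substitution are integral).

    Raises
    ------
    DomainError
        If atom i is not a carbon.
    """
    if g.elements[i] != "C":
        raise DomainError(f"oxidation_number defined for carbon; atom {i} "
                          f"is {g.elements[i]}")
    total = -1.0 * g.h_counts[i]
    for j, bond_type in g.neighbors(i):
        total += BOND_ORDER[bond_type] * _en_sign("C", g.elements[j])
    return total


def _bond_match(e_prod: dict, e_sm: dict) -> bool:
    # Exact type match, or an aromatic vs single/double mismatch when both
    # bonds sit in an aromatic environment (Kekulé perturbation tolerance).
    t1, t2 = e_sm["bond_type"], e_prod["bond_type"]
    if t1 == t2:
        return True
    tolerated = {"aromatic", "single", "double"}
    return (t1 in tolerated and t2 in tolerated
            and "aromatic" in (t1, t2)
            and e_sm["arom_env"] == e_prod["arom_env"])


def enumerate_subgraph_mappings(sm: MolecularGraph,
                                prod: MolecularGraph) -> list[AtomMapping]:
    """All element/bond-compatible embeddings of the SM into the product.

    The match is node-induced on the mapped atoms: every SM bond must exist
    in the product, and extra product bonds may only involve unmapped
    (newly installed) atoms. Results are returned in a canonical sorted
    order so enumeration is deterministic.

    Raises
    ------
    DegradedProductError
        If no embedding exists (e.g. fragmentation/degradation products
        whose core no longer contains the SM).
    """
    if sm.n_atoms > prod.n_atoms:
        raise DegradedProductError(
            f"starting material ({sm.n_atoms} atoms) larger than product "
            f"({prod.n_atoms} atoms)")
    g_sm = sm.to_networkx()
    g_prod = prod.to_networkx()
    matcher = isomorphism.GraphMatcher(
        g_prod, g_sm,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=_bond_match)
    mappings = []
    for prod_to_sm in matcher.subgraph_isomorphisms_iter():
        mappings.append({v: k for k, v in prod_to_sm.items()})
    if not mappings:
        raise DegradedProductError(
            f"no subgraph embedding of {sm.mol_id!r} in {prod.mol_id!r}; "
            "manual reaction-center elucidation required")
    mappings.sort(key=lambda m: tuple(m[i] for i in range(sm.n_atoms)))
    return [AtomMapping(m) for m in mappings]


def _changed_sites(sm: MolecularGraph, prod: MolecularGraph,
                   mapping: AtomMapping) -> set[int]:
    changed = set()
    for i, el in enumerate(sm.elements):
        if el != "C":
            continue
        j = mapping[i]
        if prod.degree(j) > sm.degree(i):
            changed.add(i)
            continue
        if abs(oxidation_number(sm, i) - oxidation_number(prod, j)) > 1e-9:
            changed.add(i)
    return changed


def label_reactive_sites(sm: MolecularGraph,
                         products: list[MolecularGraph],
                         record_id: str | None = None) -> ReactiveSiteLabels:
    """Label each SM carbon reactive/unreactive from the observed products.

    For every product and every SM-to-product embedding, carbons whose
    oxidation number or heavy-atom degree changed are marked reactive; the
    final label set is the union over all embeddings and products, which
    makes it closed under the SM's automorphism group. An empty product
    list is a negative record and yields an all-zero label vector.

    Raises
    ------
    DegradedProductError
        Propagated (with the record id attached) when some product does not
        contain the SM as a subgraph.
    """
    reactive: set[int] = set()
    for prod in products:
        try:
            mappings = enumerate_subgraph_mappings(sm, prod)
        except DegradedProductError as exc:
            raise DegradedProductError(str(exc), record_id=record_id) from exc
        for mapping in mappings:
            reactive |= _changed_sites(sm, prod, mapping)
    labels = [1 if i in reactive else 0 for i in range(sm.n_atoms)]
    return ReactiveSiteLabels(labels=labels, provenance="automatic")
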