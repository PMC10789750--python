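"""Reaction records, condition one-hot encoding, scaffold splitting, and
13C NMR data handling.

Reaction conditions are free-text tokens in five slots (reagent, oxidant,
solvent, additive, acid); each unique token is one-hot encoded within its
slot, so every unique condition combination maps to a unique binary vector.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import FormatError, SplitError, UnknownConditionError
from .molgraph import MolecularGraph, parse_molecule
from .reaction_center import ReactiveSiteLabels

log = logging.getLogger(__name__)

CONDITION_SLOTS = ("reagent", "oxidant", "solvent", "additive", "acid")

REACTION_CLASSES = ("minisci", "p450", "electrochemical", "photoredox",
                    "other")


def normalize_token(token: str | None) -> str:
    """Case-fold and strip a condition token; empty/missing become "none"."""
    if token is None:
        return "none"
    token = str(token).strip().casefold()
    return token or "none"


@dataclass
class ConditionDescriptor:
    reagent: str = "none"
    oxidant: str = "none"
    solvent: str = "none"
    additive: str = "none"
    acid: str = "none"

    def __post_init__(self):
        for slot in CONDITION_SLOTS:
            setattr(self, slot, normalize_token(getattr(self, slot)))

    def tokens(self) -> tuple[str, ...]:
        return tuple(getattr(self, slot) for slot in CONDITION_SLOTS)


@dataclass
class ReactionRecord:
    """One LSF reaction: substrate, conditions, observed outcome.

    ``products`` may be empty: a negative record, i.e. conditions that gave
    no significant product; all atoms are then labeled unreactive. The
    reaction-class tag is metadata only and is never a model input.
    """

    record_id: str
    sm: MolecularGraph
    conditions: ConditionDescriptor
    products: list[MolecularGraph] = field(default_factory=list)
    labels: ReactiveSiteLabels | None = None
    reaction_class: str = "other"

    def __post_init__(self):
        if self.labels is not None and \
                len(self.labels.labels) != self.sm.n_atoms:
            raise ValueError(f"record {self.record_id}: label length "
                             "!= atom count")
        if self.reaction_class not in REACTION_CLASSES:
            raise ValueError(f"unknown reaction class {self.reaction_class!r}")

    @property
    def is_negative(self) -> bool:
        return not self.products


@dataclass
class ConditionVocabulary:
    """Ordered token lists per condition slot; defines the one-hot layout."""

    slots: dict[str, list[str]]

    def __post_init__(self):
        for name, tokens in self.slots.items():
            if len(set(tokens)) != len(tokens):
                raise ValueError(f"duplicate tokens in slot {name!r}")

    @property
    def length(self) -> int:
        return sum(len(t) for t in self.slots.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.slots, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConditionVocabulary":
        return cls(slots=json.loads(Path(path).read_text()))


def build_condition_vocabulary(
        records: list[ReactionRecord]) -> ConditionVocabulary:
    """Collect sorted unique tokens per slot over all records."""
    slots = {name: set() for name in CONDITION_SLOTS}
    for rec in records:
        for name in CONDITION_SLOTS:
            slots[name].add(getattr(rec.conditions, name))
    return ConditionVocabulary(
        slots={name: sorted(tokens) for name, tokens in slots.items()})


def encode_conditions(c: ConditionDescriptor, vocab: ConditionVocabulary,
                      strict: bool = True) -> np.ndarray:
    """One-hot encode a condition descriptor: exactly one 1 per known slot.

    Raises
    ------
    UnknownConditionError
        In strict mode, if a token is absent from the vocabulary; otherwise
        the slot is left all-zero with a logged warning.
    """
    parts = []
    for name in CONDITION_SLOTS:
        tokens = vocab.slots[name]
        vec = np.zeros(len(tokens), dtype=np.float64)
        token = getattr(c, name)
        try:
            vec[tokens.index(token)] = 1.0
        except ValueError:
            if strict:
                raise UnknownConditionError(
                    f"unseen {name} token {token!r}") from None
            log.warning("unseen %s token %r encoded as all-zero slot",
                        name, token)
        parts.append(vec)
    return np.concatenate(parts)


def decode_conditions(vec: np.ndarray,
                      vocab: ConditionVocabulary) -> ConditionDescriptor:
    """Inverse of :func:`encode_conditions` on known tokens."""
    out = {}
    offset = 0
    for name in CONDITION_SLOTS:
        tokens = vocab.slots[name]
        block = vec[offset:offset + len(tokens)]
        hits = np.flatnonzero(block)
        out[name] = tokens[hits[0]] if len(hits) else "none"
        offset += len(tokens)
    return ConditionDescriptor(**out)


def murcko_scaffold(g: MolecularGraph) -> str:
    """Bemis-Murcko framework SMILES of a molecule ("" for acyclic)."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=g.to_rdkit())


def scaffold_split(records: list[ReactionRecord], test_fraction: float,
                   seed: int) -> tuple[list[ReactionRecord],
                                       list[ReactionRecord]]:
    """Split by Bemis-Murcko scaffold so test molecules are unseen.

    Scaffold groups are shuffled with the given seed and assigned to the
    test fold until it holds at least ``test_fraction`` of the records;
    every reaction of a molecule (and every molecule sharing its scaffold)
    lands in one fold.

    Raises
    ------
    SplitError
        If there are too few scaffolds to form two non-empty folds.
    """
    if not records:
        raise SplitError("no records to split")
    if not 0.0 < test_fraction < 1.0:
        raise SplitError(f"test_fraction {test_fraction} outside (0, 1)")
    groups: dict[str, list[ReactionRecord]] = {}
    for rec in records:
        groups.setdefault(murcko_scaffold(rec.sm), []).append(rec)
    if len(groups) < 2:
        raise SplitError("fewer than 2 distinct scaffolds")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    target = test_fraction * len(records)
    test: list[ReactionRecord] = []
    test_keys = []
    for key in keys:
        if len(test) >= target or len(test_keys) == len(keys) - 1:
            break
        test.extend(groups[key])
        test_keys.append(key)
    train = [r for key in keys if key not in test_keys for r in groups[key]]
    if not train or not test:
        raise SplitError("split produced an empty fold")
    return train, test


@dataclass
class NMRRecord:
    """A molecule with assigned per-carbon 13C shifts (ppm)."""

    graph: MolecularGraph
    shifts: dict[int, float]          # atom index -> ppm
    source_id: str = ""

    def __post_init__(self):
        for i, ppm in self.shifts.items():
            if self.graph.elements[i] != "C":
                raise ValueError(f"shift assigned to non-carbon atom {i}")
            if not np.isfinite(ppm):
                raise ValueError(f"non-finite shift on atom {i}")


def load_nmr_dataset(path: str | Path) -> list[NMRRecord]:
    """Load 13C shifts from CSV (smiles, atom_index, shift_ppm) or SDF.

    SDF molecules must carry a ``Shifts`` property formatted as
    ``index:ppm`` pairs separated by semicolons. Malformed rows are skipped
    with a warning count.

    Raises
    ------
    IOError
        If the file does not exist.
    FormatError
        If more than 10% of rows are malformed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"NMR dataset not found: {path}")
    if path.suffix.lower() == ".sdf":
        return _load_nmr_sdf(path)
    df = pd.read_csv(path)
    required = {"smiles", "atom_index", "shift_ppm"}
    if not required.issubset(df.columns):
        raise FormatError(f"NMR CSV must have columns {sorted(required)}")
    records: list[NMRRecord] = []
    n_bad = 0
    for smiles, sub in df.groupby("smiles", sort=True):
        try:
            g = parse_molecule(str(smiles))
        except Exception:
            n_bad += len(sub)
            continue
        shifts: dict[int, float] = {}
        for _, row in sub.iterrows():
            try:
                i = int(row["atom_index"])
                ppm = float(row["shift_ppm"])
                if not (0 <= i < g.n_atoms) or g.elements[i] != "C" \
                        or not np.isfinite(ppm):
                    raise ValueError
            except (ValueError, TypeError):
                n_bad += 1
                continue
            shifts[i] = ppm
        if shifts:
            records.append(NMRRecord(graph=g, shifts=shifts,
                                     source_id=str(smiles)))
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed NMR rows")
        if n_bad > 0.10 * len(df):
            raise FormatError(
                f"{n_bad}/{len(df)} malformed rows exceeds the 10% limit")
    return records


def _load_nmr_sdf(path: Path) -> list[NMRRecord]:
    records = []
    n_bad = n_total = 0
    for mol in Chem.SDMolSupplier(str(path)):
        n_total += 1
        if mol is None or not mol.HasProp("Shifts"):
            n_bad += 1
            continue
        g = MolecularGraph.from_rdkit(mol)
        shifts = {}
        try:
            for pair in mol.GetProp("Shifts").split(";"):
                i_str, ppm_str = pair.split(":")
                shifts[int(i_str)] = float(ppm_str)
            records.append(NMRRecord(graph=g, shifts=shifts))
        except (ValueError, IndexError):
            n_bad += 1
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed SDF entries")
        if n_total and n_bad > 0.10 * n_total:
            raise FormatError(f"{n_bad}/{n_total} malformed SDF entries")
    return records


def filter_zero_site_records(records: list[ReactionRecord],
                             keep: bool = True) -> list[ReactionRecord]:
    """Keep or drop negative (zero-reactive-site) records.

    ``keep=True`` is the default training configuration: removing the
    unproductive-condition records degrades the model's grasp of condition
    similarity.
    """
    if keep:
        return list(records)
    return [r for r in records if not r.is_negative]


# ---------------------------------------------------------------------------
# Reactions CSV I/O
# ---------------------------------------------------------------------------

REACTION_CSV_COLUMNS = ["record_id", "sm_smiles", "product_smiles",
                        *CONDITION_SLOTS, "class"]


def load_reactions_csv(path: str | Path,
                       with_labels: bool = False) -> list[ReactionRecord]:
    """Read reaction records; products are semicolon-separated SMILES.

    With ``with_labels=True`` an optional ``labels`` column (semicolon-
    separated 0/1 per atom) is parsed into :class:`ReactiveSiteLabels`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"reactions file not found: {path}")
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        sm = parse_molecule(str(row["sm_smiles"]))
        prods = [parse_molecule(p) for p in
                 str(row.get("product_smiles", "")).split(";") if p]
        cond = ConditionDescriptor(**{s: row.get(s, "none")
                                      for s in CONDITION_SLOTS})
        labels = None
        if with_labels and str(row.get("labels", "")):
            vals = [int(v) for v in str(row["labels"]).split(";")]
            labels = ReactiveSiteLabels(labels=vals)
        records.append(ReactionRecord(
            record_id=str(row["record_id"]), sm=sm, conditions=cond,
            products=prods, labels=labels,
            reaction_class=str(row.get("class", "other")) or "other"))
    return records


def save_reactions_csv(records: list[ReactionRecord],
                       path: str | Path, with_labels: bool = False) -> None:
    rows = []
    for rec in records:
        row = {
            "record_id": rec.record_id,
            "sm_smiles": rec.sm.to_smiles(),
            "product_smiles": ";".join(p.to_smiles() for p in rec.products),
            **{s: getattr(rec.conditions, s) for s in CONDITION_SLOTS},
            "class": rec.reaction_class,
        }
        if with_labels and rec.labels is not None:
            row["labels"] = ";".join(str(v) for v in rec.labels.labels)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
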