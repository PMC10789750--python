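"""Message-passing neural network with a universal node and two heads.

The trunk embeds each atom from its bonded neighborhood: per-bond-type
linear messages with sum aggregation and a gated (GRU-style) state update,
repeated for T rounds so information travels T bonds radially. An optional
universal node is bidirectionally bonded to every atom through a dedicated
bond type, giving each atom global context. The same trunk serves two
heads: a linear per-carbon 13C-shift regressor (pretraining task) and a
feed-forward per-atom functionalization-probability classifier that sees
the one-hot reaction-condition vector (fine-tuning task).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .errors import ModelError, TransferError
from .molgraph import (BOND_TYPES, FEATURE_VERSION, BondTensor,
                       MolecularGraph, bond_tensor, feature_columns,
                       featurize_atoms)

#: Message bond types: chemical bonds plus the universal-node connection.
MODEL_BOND_TYPES = BOND_TYPES + ("universal",)

TRUNK_KEYS_STATIC = ("W_in", "b_in", "b_msg", "Wz", "Uz", "bz",
                     "Wh", "Uh", "bh")


@dataclass
class ModelConfig:
    """Architecture hyperparameters; stored with every checkpoint."""

    hidden: int = 200
    rounds: int = 4               # T message passes
    universal_node: bool = True
    cond_dim: int = 0             # condition one-hot length (LSF head)
    feature_version: str = FEATURE_VERSION
    include_formal_charge: bool = False
    seed: int = 0
    shift_mean: float = 100.0     # ppm normalization for the NMR head
    shift_scale: float = 50.0

    @property
    def n_features(self) -> int:
        # +1 for the is-universal indicator column
        return len(feature_columns(self.include_formal_charge)) + 1

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ModelParams:
    """Trunk + head parameters; trunk shapes are task-independent so NMR
    checkpoints transfer onto the LSF task."""

    config: ModelConfig
    tensors: dict[str, Tensor]
    history: list[dict] = field(default_factory=list, repr=False)

    def trunk_keys(self) -> list[str]:
        keys = list(TRUNK_KEYS_STATIC)
        keys += [f"W_msg_{t}" for t in MODEL_BOND_TYPES]
        return keys

    def head_keys(self, task: str) -> list[str]:
        if task == "nmr":
            return ["W_nmr", "b_nmr"]
        if task == "lsf":
            return ["W_l1", "b_l1", "W_l2", "b_l2", "W_l3", "b_l3"]
        raise ValueError(f"unknown task {task!r}")

    def parameters(self, keys: list[str] | None = None) -> list[Tensor]:
        keys = keys if keys is not None else sorted(self.tensors)
        return [self.tensors[k] for k in keys]

    def copy(self) -> "ModelParams":
        tensors = {k: Tensor(v.data.copy(), requires_grad=True)
                   for k, v in self.tensors.items()}
        return ModelParams(config=ModelConfig(**asdict(self.config)),
                           tensors=tensors)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-scale, scale, size=(n_in, n_out))


def init_params(config: ModelConfig) -> ModelParams:
    """Seeded Glorot-uniform initialization of trunk and both heads."""
    rng = np.random.default_rng(config.seed)
    d, f = config.hidden, config.n_features
    t: dict[str, np.ndarray] = {
        "W_in": _glorot(rng, f, d), "b_in": np.zeros(d),
        "b_msg": np.zeros(d),
        "Wz": _glorot(rng, d, d), "Uz": _glorot(rng, d, d),
        "bz": np.zeros(d),
        "Wh": _glorot(rng, d, d), "Uh": _glorot(rng, d, d),
        "bh": np.zeros(d),
        "W_nmr": _glorot(rng, d, 1), "b_nmr": np.zeros(1),
        "W_l1": _glorot(rng, d + config.cond_dim, d), "b_l1": np.zeros(d),
        "W_l2": _glorot(rng, d, d), "b_l2": np.zeros(d),
        "W_l3": _glorot(rng, d, 1), "b_l3": np.zeros(1),
    }
    for bt in MODEL_BOND_TYPES:
        t[f"W_msg_{bt}"] = _glorot(rng, d, d)
    tensors = {k: Tensor(v, requires_grad=True) for k, v in t.items()}
    return ModelParams(config=config, tensors=tensors)


def attach_universal_node(bonds: BondTensor) -> BondTensor:
    """Add one extra node bonded to every atom via the "universal" type.

    Original bonds are untouched; the result has n+1 nodes and one more
    bond-type channel holding the 2n new directed connections.
    """
    n = bonds.n_atoms
    by_type = np.zeros((len(MODEL_BOND_TYPES), n + 1, n + 1))
    by_type[:len(bonds.bond_types), :n, :n] = bonds.by_type
    uni = by_type[len(MODEL_BOND_TYPES) - 1]
    uni[n, :n] = 1.0
    uni[:n, n] = 1.0
    return BondTensor(adjacency=by_type.max(axis=0), by_type=by_type,
                      bond_types=MODEL_BOND_TYPES)


def _pad_bond_channels(bonds: BondTensor) -> BondTensor:
    """Bring a plain chemical BondTensor to the model's channel layout
    (empty universal channel, no extra node)."""
    n = bonds.n_atoms
    by_type = np.zeros((len(MODEL_BOND_TYPES), n, n))
    by_type[:len(bonds.bond_types)] = bonds.by_type
    return BondTensor(adjacency=by_type.max(axis=0), by_type=by_type,
                      bond_types=MODEL_BOND_TYPES)


def message_pass(features: np.ndarray, bonds: BondTensor,
                 params: ModelParams, rounds: int | None = None) -> Tensor:
    """Run T rounds of message passing; returns node embeddings.

    ``features`` must already include the is-universal indicator column and
    one row per node of ``bonds`` (use :func:`prepare_inputs` for graphs).
    After T rounds an atom's embedding depends only on nodes within graph
    distance T, so with the universal node attached every atom sees the
    whole molecule once T >= 2.
    """
    cfg = params.config
    rounds = cfg.rounds if rounds is None else rounds
    if rounds < 1:
        raise ModelError(f"rounds must be >= 1, got {rounds}")
    if features.shape[0] != bonds.n_atoms:
        raise ModelError(f"feature rows {features.shape[0]} != "
                         f"nodes {bonds.n_atoms}")
    if features.shape[1] != cfg.n_features:
        raise ModelError(f"feature columns {features.shape[1]} != "
                         f"configured {cfg.n_features}")
    p = params.tensors
    x = Tensor(features)
    h = (x @ p["W_in"] + p["b_in"]).relu()
    adj = [Tensor(a) for a in bonds.by_type]
    for _ in range(rounds):
        m = p["b_msg"] + sum(
            (adj[k] @ (h @ p[f"W_msg_{bt}"])
             for k, bt in enumerate(MODEL_BOND_TYPES)),
            start=Tensor(np.zeros(1)))
        z = (h @ p["Wz"] + m @ p["Uz"] + p["bz"]).sigmoid()
        cand = (h @ p["Wh"] + m @ p["Uh"] + p["bh"]).tanh()
        h = (1.0 - z) * h + z * cand
    return h


def prepare_inputs(g: MolecularGraph,
                   config: ModelConfig) -> tuple[np.ndarray, BondTensor]:
    """Featurize a molecule for the network.

    Returns the feature matrix (with universal-flag column and, if
    configured, the universal node's row appended) and the matching
    bond tensor in the model's channel layout.
    """
    fm = featurize_atoms(
        g, include_formal_charge=config.include_formal_charge)
    x = np.hstack([fm.values, np.zeros((g.n_atoms, 1))])
    bonds = bond_tensor(g)
    if config.universal_node:
        bonds = attach_universal_node(bonds)
        uni_row = np.zeros((1, x.shape[1]))
        uni_row[0, -1] = 1.0
        x = np.vstack([x, uni_row])
    else:
        bonds = _pad_bond_channels(bonds)
    return x, bonds


def forward_shifts(g: MolecularGraph, params: ModelParams) -> Tensor:
    """Normalized per-atom shift predictions (training graph)."""
    x, bonds = prepare_inputs(g, params.config)
    h = message_pass(x, bonds, params)
    h_atoms = h.rows(np.arange(g.n_atoms))
    return h_atoms @ params.tensors["W_nmr"] + params.tensors["b_nmr"]


def predict_shifts(g: MolecularGraph, params: ModelParams) -> np.ndarray:
    """Predicted 13C shift (ppm) per atom; meaningful for carbons."""
    out = forward_shifts(g, params).data[:, 0]
    cfg = params.config
    return out * cfg.shift_scale + cfg.shift_mean


def forward_reactivity(g: MolecularGraph, condition_vector: np.ndarray,
                       params: ModelParams) -> Tensor:
    """Per-atom functionalization probability (training graph).

    Every atom's trunk embedding is concatenated with the shared one-hot
    condition vector and passed through a 3-layer feed-forward head ending
    in a sigmoid.
    """
    cfg = params.config
    condition_vector = np.asarray(condition_vector, dtype=np.float64)
    if condition_vector.shape != (cfg.cond_dim,):
        raise ModelError(f"condition vector length "
                         f"{condition_vector.shape} != configured "
                         f"({cfg.cond_dim},)")
    x, bonds = prepare_inputs(g, cfg)
    h = message_pass(x, bonds, params)
    h_atoms = h.rows(np.arange(g.n_atoms))
    cond = Tensor(np.tile(condition_vector, (g.n_atoms, 1)))
    p = params.tensors
    z = concat([h_atoms, cond], axis=1)
    z = (z @ p["W_l1"] + p["b_l1"]).relu()
    z = (z @ p["W_l2"] + p["b_l2"]).relu()
    return (z @ p["W_l3"] + p["b_l3"]).sigmoid()


def predict_reactivity(g: MolecularGraph, condition_vector: np.ndarray,
                       params: ModelParams) -> np.ndarray:
    """Per-atom probability of functionalization, in [0, 1]."""
    return forward_reactivity(g, condition_vector, params).data[:, 0]


# ---------------------------------------------------------------------------
# Checkpoint I/O (NumPy .npz with the JSON config embedded)
# ---------------------------------------------------------------------------

def save_params(params: ModelParams, path) -> None:
    arrays = {k: v.data for k, v in params.tensors.items()}
    cfg = json.dumps({**asdict(params.config),
                      "fingerprint": params.config.fingerprint()})
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **arrays)


def load_params(path) -> ModelParams:
    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["__config__"]).decode())
        fingerprint = cfg_raw.pop("fingerprint")
        config = ModelConfig(**cfg_raw)
        if config.fingerprint() != fingerprint:
            raise ModelError("checkpoint fingerprint mismatch")
        tensors = {k: Tensor(data[k], requires_grad=True)
                   for k in data.files if k != "__config__"}
    return ModelParams(config=config, tensors=tensors)


def transfer_trunk(source: ModelParams, target: ModelParams) -> None:
    """Copy trunk weights from ``source`` into ``target`` in place.

    Raises
    ------
    TransferError
        Listing every mismatched tensor shape if the trunks differ.
    """
    mismatches = []
    for key in target.trunk_keys():
        src, dst = source.tensors[key], target.tensors[key]
        if src.data.shape != dst.data.shape:
            mismatches.append(f"{key}: {src.data.shape} vs {dst.data.shape}")
    if mismatches:
        raise TransferError("incompatible trunk: " + "; ".join(mismatches))
    for key in target.trunk_keys():
        target.tensors[key].data = source.tensors[key].data.copy()
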