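"""Variational molecular-graph encoder and modality decoders.

The encoder is a GIN-style message-passing network: per layer, each atom
state is updated as MLP((1 + eps) * h_v + sum_{u ~ v} (h_u + bond_emb)),
the injective sum aggregation; the graph readout is a summation over atoms,
followed by two affine heads producing the mean and log-variance of a
diagonal Gaussian latent p(z | x).  Decoders are one-hidden-layer MLPs from
the latent to each modality's feature space, logistic-squashed into [0, 1]
to match the min-max-scaled targets.

Everything is implemented directly on NumPy arrays with analytic gradients
(hand-derived reverse-mode passes, checked against finite differences in the
test suite), plus an Adam optimizer.  Parameters live in flat name -> array
dicts so checkpointing is a plain .npz archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MolecularGraph",
    "EncoderConfig",
    "DecoderConfig",
    "LatentGaussian",
    "GraphBatch",
    "init_encoder_params",
    "init_decoder_params",
    "encode_batch",
    "encoder_backward",
    "encode",
    "decode_batch",
    "decoder_backward",
    "decode",
    "reparameterize",
    "kl_standard_normal",
    "kl_gradients",
    "Adam",
    "save_checkpoint",
    "load_checkpoint",
    "molecule_from_smiles",
    "SMILES_ATOM_VOCAB",
    "SMILES_BOND_VOCAB",
]


# ---------------------------------------------------------------------------
# molecular graphs and featurization


@dataclass
class MolecularGraph:
    """Undirected labeled graph: categorical atom and bond descriptors."""

    atom_labels: np.ndarray  # (n_atoms,) ints
    bonds: list[tuple[int, int, int]]  # (i, j, bond_label), i != j, undirected

    def __post_init__(self) -> None:
        self.atom_labels = np.asarray(self.atom_labels, dtype=int)
        if self.atom_labels.size < 1:
            raise ValueError("molecule must have at least one atom")
        n = self.atom_labels.size
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return self.atom_labels.size


_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "other"]
_MAX_DEGREE = 6
SMILES_ATOM_VOCAB = len(_ELEMENTS) * (_MAX_DEGREE + 1)
SMILES_BOND_VOCAB = 5  # single, double, triple, aromatic, other


def molecule_from_smiles(smiles: str) -> MolecularGraph:
    """Featurize a SMILES string: atom label = (element, degree), bond = order."""
    from rdkit import Chem  # chemistry kept optional; synthetic mode never needs it

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    labels = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        elem = _ELEMENTS.index(sym) if sym in _ELEMENTS else _ELEMENTS.index("other")
        labels.append(elem * (_MAX_DEGREE + 1) + min(atom.GetDegree(), _MAX_DEGREE))
    order_map = {"SINGLE": 0, "DOUBLE": 1, "TRIPLE": 2, "AROMATIC": 3}
    bonds = []
    for bond in mol.GetBonds():
        lab = order_map.get(bond.GetBondType().name, 4)
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), lab))
    return MolecularGraph(np.array(labels), bonds)


# ---------------------------------------------------------------------------
# configs, params, containers


@dataclass
class EncoderConfig:
    latent_dim: int = 64
    hidden_dim: int = 128
    n_layers: int = 3
    atom_vocab: int = 256
    bond_vocab: int = 4
    logvar_clip: float = 10.0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one message-passing layer")


@dataclass
class DecoderConfig:
    out_dim: int
    latent_dim: int = 64
    hidden_dim: int = 128


@dataclass
class LatentGaussian:
    """Diagonal Gaussian latent: mean and (positive) standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma dimensions differ")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive element-wise")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def init_encoder_params(config: EncoderConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    H, D = config.hidden_dim, config.latent_dim
    params: dict[str, np.ndarray] = {
        "atom_emb": rng.normal(0.0, 0.1, size=(config.atom_vocab, H))
    }
    for l in range(config.n_layers):
        params[f"eps_{l}"] = np.zeros(1)
        params[f"bond_emb_{l}"] = rng.normal(0.0, 0.1, size=(config.bond_vocab, H))
        params[f"w1_{l}"] = _glorot(rng, H, H)
        params[f"b1_{l}"] = np.zeros(H)
        params[f"w2_{l}"] = _glorot(rng, H, H)
        params[f"b2_{l}"] = np.zeros(H)
    params["w_mu"] = _glorot(rng, H, D)
    params["b_mu"] = np.zeros(D)
    params["w_lv"] = _glorot(rng, H, D)
    # start near sigma = 1 but on the small side for stable early training
    params["b_lv"] = np.full(D, -1.0)
    return params


def init_decoder_params(config: DecoderConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        "w1": _glorot(rng, config.latent_dim, config.hidden_dim),
        "b1": np.zeros(config.hidden_dim),
        "w2": _glorot(rng, config.hidden_dim, config.out_dim),
        "b2": np.zeros(config.out_dim),
    }


class GraphBatch:
    """Disjoint union of molecular graphs with flat index arrays.

    Nodes of all graphs are concatenated; ``graph_index`` maps each node to
    its graph, and each undirected bond appears as two directed edges so the
    sum aggregation sees both directions.  Neighbor aggregation is expressed
    as two static sparse products built once per batch: ``adj @ h`` sums
    neighbor states and ``bond_counts @ bond_emb`` sums incident bond
    embeddings (their transposes drive the backward pass).
    """

    def __init__(self, molecules: Sequence[MolecularGraph]):
        from scipy import sparse

        if not molecules:
            raise ValueError("empty batch")
        labels, gidx, src, dst, elab = [], [], [], [], []
        offset = 0
        for g, mol in enumerate(molecules):
            labels.append(mol.atom_labels)
            gidx.append(np.full(mol.n_atoms, g))
            for i, j, lab in mol.bonds:
                src.extend([offset + i, offset + j])
                dst.extend([offset + j, offset + i])
                elab.extend([lab, lab])
            offset += mol.n_atoms
        self.node_labels = np.concatenate(labels)
        self.graph_index = np.concatenate(gidx)
        self.edge_src = np.asarray(src, dtype=int)
        self.edge_dst = np.asarray(dst, dtype=int)
        self.edge_labels = np.asarray(elab, dtype=int)
        self.n_graphs = len(molecules)
        self.n_nodes = self.node_labels.size
        ones = np.ones(self.edge_src.size)
        self.adj = sparse.csr_matrix(
            (ones, (self.edge_dst, self.edge_src)), shape=(self.n_nodes, self.n_nodes)
        )
        n_bond_labels = int(self.edge_labels.max()) + 1 if self.edge_labels.size else 1
        self.bond_counts = sparse.csr_matrix(
            (ones, (self.edge_dst, self.edge_labels)), shape=(self.n_nodes, n_bond_labels)
        )
        self.adj_t = self.adj.T.tocsr()
        self.bond_counts_t = self.bond_counts.T.tocsr()
        self.pool = sparse.csr_matrix(
            (np.ones(self.n_nodes), (self.graph_index, np.arange(self.n_nodes))),
            shape=(self.n_graphs, self.n_nodes),
        )


# ---------------------------------------------------------------------------
# encoder forward / backward


def encode_batch(
    batch: GraphBatch, params: Mapping[str, np.ndarray], config: EncoderConfig
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Forward pass; returns (mu, logvar) of shape (B, D) and a backprop cache."""
    h = params["atom_emb"][batch.node_labels]
    layer_caches = []
    for l in range(config.n_layers):
        eps = params[f"eps_{l}"][0]
        bond_emb = params[f"bond_emb_{l}"][: batch.bond_counts.shape[1]]
        agg = batch.adj @ h + batch.bond_counts @ bond_emb
        m = (1.0 + eps) * h + agg
        a1 = m @ params[f"w1_{l}"] + params[f"b1_{l}"]
        r1 = np.maximum(a1, 0.0)
        h_out = r1 @ params[f"w2_{l}"] + params[f"b2_{l}"]
        layer_caches.append({"h_in": h, "m": m, "a1": a1, "r1": r1})
        h = h_out
    readout = batch.pool @ h
    mu = readout @ params["w_mu"] + params["b_mu"]
    lv_raw = readout @ params["w_lv"] + params["b_lv"]
    c = config.logvar_clip
    logvar = np.clip(lv_raw, -c, c)
    cache = {"batch": batch, "layers": layer_caches, "h_final": h,
             "readout": readout, "lv_raw": lv_raw}
    return mu, logvar, cache


def encoder_backward(
    d_mu: np.ndarray,
    d_logvar: np.ndarray,
    cache: dict,
    params: Mapping[str, np.ndarray],
    config: EncoderConfig,
) -> dict[str, np.ndarray]:
    """Reverse-mode pass through heads, readout, and all GIN layers."""
    batch: GraphBatch = cache["batch"]
    grads: dict[str, np.ndarray] = {}
    c = config.logvar_clip
    inside = (cache["lv_raw"] > -c) & (cache["lv_raw"] < c)
    d_lv_raw = d_logvar * inside
    readout = cache["readout"]
    grads["w_mu"] = readout.T @ d_mu
    grads["b_mu"] = d_mu.sum(axis=0)
    grads["w_lv"] = readout.T @ d_lv_raw
    grads["b_lv"] = d_lv_raw.sum(axis=0)
    d_readout = d_mu @ params["w_mu"].T + d_lv_raw @ params["w_lv"].T
    dh = d_readout[batch.graph_index]
    for l in reversed(range(config.n_layers)):
        lc = cache["layers"][l]
        eps = params[f"eps_{l}"][0]
        grads[f"w2_{l}"] = lc["r1"].T @ dh
        grads[f"b2_{l}"] = dh.sum(axis=0)
        dr1 = dh @ params[f"w2_{l}"].T
        da1 = dr1 * (lc["a1"] > 0)
        grads[f"w1_{l}"] = lc["m"].T @ da1
        grads[f"b1_{l}"] = da1.sum(axis=0)
        dm = da1 @ params[f"w1_{l}"].T
        grads[f"eps_{l}"] = np.array([np.sum(dm * lc["h_in"])])
        dh_in = (1.0 + eps) * dm + batch.adj_t @ dm
        g_bond = np.zeros_like(params[f"bond_emb_{l}"])
        g_bond[: batch.bond_counts.shape[1]] = batch.bond_counts_t @ dm
        grads[f"bond_emb_{l}"] = g_bond
        dh = dh_in
    g_atom = np.zeros_like(params["atom_emb"])
    np.add.at(g_atom, batch.node_labels, dh)
    grads["atom_emb"] = g_atom
    return grads


def encode(
    mol: MolecularGraph, params: Mapping[str, np.ndarray], config: EncoderConfig
) -> LatentGaussian:
    """Encode one molecule to its diagonal Gaussian latent."""
    mu, logvar, _ = encode_batch(GraphBatch([mol]), params, config)
    return LatentGaussian(mu[0], np.exp(0.5 * logvar[0]))


# ---------------------------------------------------------------------------
# decoders


def decode_batch(
    z: np.ndarray, params: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, dict]:
    """Feed-forward decode with logistic squash; returns predictions in (0, 1)."""
    a1 = z @ params["w1"] + params["b1"]
    r1 = np.maximum(a1, 0.0)
    logits = r1 @ params["w2"] + params["b2"]
    out = 1.0 / (1.0 + np.exp(-logits))
    return out, {"z": z, "a1": a1, "r1": r1, "out": out}


def decoder_backward(
    d_logits: np.ndarray, cache: dict, params: Mapping[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Backprop from pre-squash logits; returns (param grads, d_z)."""
    grads = {
        "w2": cache["r1"].T @ d_logits,
        "b2": d_logits.sum(axis=0),
    }
    dr1 = d_logits @ params["w2"].T
    da1 = dr1 * (cache["a1"] > 0)
    grads["w1"] = cache["z"].T @ da1
    grads["b1"] = da1.sum(axis=0)
    dz = da1 @ params["w1"].T
    return grads, dz


def decode(z: np.ndarray, modality: str, decoders: Mapping[str, Mapping[str, np.ndarray]]) -> np.ndarray:
    """Decode one latent sample into the named modality's feature space."""
    if modality not in decoders:
        raise KeyError(f"no decoder for modality {modality!r}")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    out, _ = decode_batch(z, decoders[modality])
    return out[0]


# ---------------------------------------------------------------------------
# latent utilities


def reparameterize(latent: LatentGaussian, noise: np.ndarray) -> np.ndarray:
    """z = mu + sigma * noise (element-wise reparameterization)."""
    noise = np.asarray(noise, dtype=float)
    if noise.shape != latent.mu.shape:
        raise ValueError("noise dimension does not match the latent")
    return latent.mu + latent.sigma * noise


def kl_standard_normal(latent: LatentGaussian) -> float:
    """KL(N(mu, diag sigma^2) || N(0, I)) = 1/2 sum(mu^2 + sigma^2 - log sigma^2 - 1)."""
    s2 = latent.sigma**2
    return float(0.5 * np.sum(latent.mu**2 + s2 - np.log(s2) - 1.0))


def kl_gradients(mu: np.ndarray, logvar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(d KL / d mu, d KL / d logvar) for the standard-normal prior."""
    return mu, 0.5 * (np.exp(logvar) - 1.0)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with bias correction on flat name -> array parameter dicts."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    path: str | Path,
    encoder_params: Mapping[str, np.ndarray],
    decoder_params: Mapping[str, Mapping[str, np.ndarray]],
    encoder_config: EncoderConfig,
    modality_dims: Mapping[str, int],
    extra: Mapping | None = None,
) -> None:
    arrays = {f"enc/{k}": v for k, v in encoder_params.items()}
    for mod, dec in decoder_params.items():
        arrays.update({f"dec/{mod}/{k}": v for k, v in dec.items()})
    meta = {
        "encoder_config": asdict(encoder_config),
        "modality_dims": dict(modality_dims),
        "extra": dict(extra or {}),
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta_json"]))
    encoder_params: dict[str, np.ndarray] = {}
    decoder_params: dict[str, dict[str, np.ndarray]] = {}
    for key in data.files:
        if key == "meta_json":
            continue
        parts = key.split("/")
        if parts[0] == "enc":
            encoder_params[parts[1]] = data[key]
        elif parts[0] == "dec":
            decoder_params.setdefault(parts[1], {})[parts[2]] = data[key]
    config = EncoderConfig(**meta["encoder_config"])
    return encoder_params, decoder_params, config, meta
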