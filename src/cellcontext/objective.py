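"""Information-bottleneck training objective and pretraining loop.

For a molecule x with latent z ~ p(z | x) and a random-walk path P from its
node on the context graph, the per-molecule loss is

    L = (1 / L_walk) * sum_{v in P} alpha_v * nll(decode(z, modality_v), y_v)
        + beta * KL(p(z | x) || N(0, I)),

where alpha_v is the cumulative product of edge weights from the seed to v,
y_v is node v's feature vector, and the divisor is the *configured* walk
length (early-terminated walks therefore down-weight reconstruction).  The
reconstruction term is a decoder-based lower-bound surrogate for the
sufficiency of z about the cellular context; the KL term upper-bounds the
information the latent keeps about the molecule, with beta trading the two
off.  Batch losses are means over molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .context_graph import ContextGraph, NodeKind
from .model import (
    Adam,
    DecoderConfig,
    EncoderConfig,
    GraphBatch,
    LatentGaussian,
    MolecularGraph,
    decode_batch,
    decoder_backward,
    encode_batch,
    encoder_backward,
    init_decoder_params,
    init_encoder_params,
    kl_gradients,
)
from .walks import WalkConfig, WalkPath, sample_walk, walk_rng

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "LossReport",
    "reconstruction_nll",
    "alignment_loss",
    "pretrain",
    "DEFAULT_LIKELIHOODS",
]

_BCE_EPS = 1e-7

#: binary fingerprints get a Bernoulli likelihood; the continuous, min-max
#: scaled morphology and expression targets get a unit-variance Gaussian.
DEFAULT_LIKELIHOODS = {
    "fingerprint": "bernoulli_bce",
    "morphology": "gaussian_mse",
    "expression": "gaussian_mse",
}


@dataclass
class TrainingConfig:
    beta: float = 1e-2
    walk: WalkConfig = field(default_factory=WalkConfig)
    batch_size: int = 128
    epochs: int = 200
    learning_rate: float = 1e-3
    likelihood: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_LIKELIHOODS))
    seed: int = 0
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder_hidden: int = 128
    n_z_samples: int = 1

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        for mod in ("fingerprint", "morphology", "expression"):
            if mod not in self.likelihood:
                raise ValueError(f"likelihood not set for modality {mod!r}")
            if self.likelihood[mod] not in ("gaussian_mse", "bernoulli_bce"):
                raise ValueError(f"unknown likelihood {self.likelihood[mod]!r}")


@dataclass
class LossReport:
    total: float
    reconstruction_per_modality: dict[str, float]
    kl: float
    per_target_terms: list[tuple[str, float, float]]  # (node_id, alpha, nll)

    def recompose(self, beta: float, L: int) -> float:
        """Total rebuilt from the per-target decomposition (identity check)."""
        recon = sum(a * nll for _, a, nll in self.per_target_terms) / L
        return recon + beta * self.kl


def reconstruction_nll(
    prediction: np.ndarray, target: np.ndarray, likelihood: str
) -> float:
    """Negative log-likelihood of a target under the decoded prediction.

    gaussian_mse: 1/2 ||pred - y||^2 (unit variance, constants dropped).
    bernoulli_bce: -sum y log pred + (1 - y) log(1 - pred), pred clamped.
    """
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ValueError(
            f"prediction/target dimension mismatch: {prediction.shape} vs {target.shape}"
        )
    if likelihood == "gaussian_mse":
        return float(0.5 * np.sum((prediction - target) ** 2))
    if likelihood == "bernoulli_bce":
        p = np.clip(prediction, _BCE_EPS, 1.0 - _BCE_EPS)
        return float(-np.sum(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))
    raise ValueError(f"unknown likelihood {likelihood!r}")


def alignment_loss(
    graph: ContextGraph,
    path: WalkPath,
    latent: LatentGaussian,
    z_sample: np.ndarray,
    decoders: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    config: TrainingConfig,
) -> LossReport:
    """Evaluate the per-molecule objective for one walk (reporting path).

    ``decoders`` maps each modality to a callable z -> prediction.  Path
    nodes without a feature are skipped (logged); if none carry a feature
    the loss reduces to beta * KL.
    """
    from .model import kl_standard_normal

    L = config.walk.L
    per_target: list[tuple[str, float, float]] = []
    recon = {m: 0.0 for m in decoders}
    n_used = 0
    for node_id, alpha in path.targets():
        feat = graph.feature(node_id)
        if feat is None:
            logger.debug("path node %r has no feature; skipped", node_id)
            continue
        pred = decoders[feat.modality](z_sample)
        nll = reconstruction_nll(pred, feat.values, config.likelihood[feat.modality])
        per_target.append((node_id, float(alpha), nll))
        recon[feat.modality] = recon.get(feat.modality, 0.0) + alpha * nll / L
        n_used += 1
    if n_used == 0:
        logger.warning("walk from %r hit no feature-bearing nodes", path.start)
    kl = kl_standard_normal(latent)
    total = sum(recon.values()) + config.beta * kl
    return LossReport(total=total, reconstruction_per_modality=recon, kl=kl,
                      per_target_terms=per_target)


# ---------------------------------------------------------------------------
# pretraining


def _collect_targets(graph: ContextGraph, paths: Sequence[WalkPath]):
    """Group (batch row, alpha, target vector) triples by modality."""
    grouped: dict[str, dict[str, list]] = {}
    for row, path in enumerate(paths):
        for node_id, alpha in path.targets():
            feat = graph.feature(node_id)
            if feat is None:
                continue
            g = grouped.setdefault(feat.modality, {"rows": [], "alphas": [], "targets": [], "ids": []})
            g["rows"].append(row)
            g["alphas"].append(alpha)
            g["targets"].append(feat.values)
            g["ids"].append(node_id)
    return grouped


def _batch_forward_backward(
    graph: ContextGraph,
    batch_mols: Sequence[MolecularGraph],
    paths: Sequence[WalkPath],
    encoder_params: dict,
    decoder_params: dict,
    config: TrainingConfig,
    rng: np.random.Generator,
    compute_grads: bool = True,
):
    """One fused forward/backward over a batch; returns (report, grads)."""
    B = len(batch_mols)
    L = config.walk.L
    gbatch = GraphBatch(batch_mols)
    mu, logvar, enc_cache = encode_batch(gbatch, encoder_params, config.encoder)
    sigma = np.exp(0.5 * logvar)
    noise = rng.standard_normal(mu.shape)
    z = mu + sigma * noise

    grouped = _collect_targets(graph, paths)
    dz = np.zeros_like(z)
    dec_grads: dict[str, dict] = {}
    recon_terms: dict[str, float] = {}
    per_target: list[tuple[str, float, float]] = []
    for modality, g in grouped.items():
        rows = np.asarray(g["rows"], dtype=int)
        alphas = np.asarray(g["alphas"], dtype=float)
        Y = np.stack(g["targets"])
        params = decoder_params[modality]
        preds, cache = decode_batch(z[rows], params)
        lik = config.likelihood[modality]
        if lik == "bernoulli_bce":
            p = np.clip(preds, _BCE_EPS, 1.0 - _BCE_EPS)
            nlls = -np.sum(Y * np.log(p) + (1.0 - Y) * np.log(1.0 - p), axis=1)
            d_logits = preds - Y  # sigmoid + BCE
        else:
            nlls = 0.5 * np.sum((preds - Y) ** 2, axis=1)
            d_logits = (preds - Y) * preds * (1.0 - preds)
        scale = alphas / (L * B)
        recon_terms[modality] = float(np.sum(nlls * scale))
        per_target.extend(zip(g["ids"], alphas.tolist(), nlls.tolist()))
        if compute_grads:
            grads_m, dz_rows = decoder_backward(d_logits * scale[:, None], cache, params)
            dec_grads[modality] = grads_m
            np.add.at(dz, rows, dz_rows)

    kl_each = 0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0, axis=1)
    kl_mean = float(kl_each.mean())
    total = sum(recon_terms.values()) + config.beta * kl_mean
    report = {
        "total": total,
        "recon": recon_terms,
        "kl": kl_mean,
        "per_target": per_target,
        "n_molecules": B,
    }
    if not compute_grads:
        return report, None

    d_mu_kl, d_lv_kl = kl_gradients(mu, logvar)
    d_mu = dz + config.beta * d_mu_kl / B
    d_logvar = dz * noise * sigma * 0.5 + config.beta * d_lv_kl / B
    enc_grads = encoder_backward(d_mu, d_logvar, enc_cache, encoder_params, config.encoder)
    for mod in decoder_params:
        if mod not in dec_grads:
            dec_grads[mod] = {k: np.zeros_like(v) for k, v in decoder_params[mod].items()}
    return report, (enc_grads, dec_grads)


def pretrain(
    graph: ContextGraph,
    molecules: Mapping[str, MolecularGraph],
    config: TrainingConfig,
    modality_dims: Mapping[str, int] | None = None,
    batch_callback: Callable[[dict], None] | None = None,
):
    """Jointly optimize the encoder and all modality decoders.

    ``molecules`` maps molecule node ids (present in the graph) to their
    structures.  A fresh walk is sampled per molecule per epoch; the per-walk
    RNG is derived from (run seed, molecule index, epoch), so the trajectory
    is reproducible regardless of shuffling.  Returns
    (encoder_params, decoder_params, training log).
    """
    mol_ids = list(molecules)
    for mid in mol_ids:
        if mid not in graph or graph.kind(mid) != NodeKind.MOLECULE:
            raise ValueError(f"training molecule {mid!r} is not a molecule node in the graph")
    if modality_dims is None:
        modality_dims = _infer_modality_dims(graph)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    encoder_params = init_encoder_params(config.encoder, rng)
    decoder_params = {
        mod: init_decoder_params(
            DecoderConfig(out_dim=dim, latent_dim=config.encoder.latent_dim,
                          hidden_dim=config.decoder_hidden),
            rng,
        )
        for mod, dim in modality_dims.items()
    }
    log: list[dict] = []
    if config.epochs == 0:
        return encoder_params, decoder_params, log

    opt_enc = Adam(encoder_params, lr=config.learning_rate)
    opt_dec = {m: Adam(p, lr=config.learning_rate) for m, p in decoder_params.items()}

    mol_structs = [molecules[m] for m in mol_ids]
    for epoch in range(config.epochs):
        order = rng.permutation(len(mol_ids))
        epoch_tot, epoch_kl, n_batches = 0.0, 0.0, 0
        epoch_recon: dict[str, float] = {}
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            paths = [
                sample_walk(graph, mol_ids[i], config.walk,
                            walk_rng(config.seed, int(i), epoch))
                for i in idx
            ]
            batch_mols = [mol_structs[i] for i in idx]
            report, grads = _batch_forward_backward(
                graph, batch_mols, paths, encoder_params, decoder_params, config, rng
            )
            if batch_callback is not None:
                batch_callback(report)
            if not np.isfinite(report["total"]):
                logger.error("non-finite loss at epoch %d; aborting", epoch)
                return encoder_params, decoder_params, log
            enc_grads, dec_grads = grads
            opt_enc.step(encoder_params, enc_grads)
            for mod, g in dec_grads.items():
                opt_dec[mod].step(decoder_params[mod], g)
            epoch_tot += report["total"]
            epoch_kl += report["kl"]
            for m, v in report["recon"].items():
                epoch_recon[m] = epoch_recon.get(m, 0.0) + v
            n_batches += 1
        entry = {
            "epoch": epoch,
            "total": epoch_tot / n_batches,
            "kl": epoch_kl / n_batches,
            **{f"recon_{m}": v / n_batches for m, v in epoch_recon.items()},
        }
        log.append(entry)
        if epoch == 0 or (epoch + 1) % 50 == 0:
            logger.info("epoch %d: %s", epoch, entry)
    return encoder_params, decoder_params, log


def _infer_modality_dims(graph: ContextGraph) -> dict[str, int]:
    dims: dict[str, int] = {}
    for nid in graph.node_ids():
        feat = graph.feature(nid)
        if feat is not None and feat.modality not in dims:
            dims[feat.modality] = feat.values.size
    return dims
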