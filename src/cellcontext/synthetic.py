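"""Synthetic fixture worlds with shared latent structure across modalities.

Every entity descends from a ground-truth latent factor vector: molecules
get binary fingerprints (thresholded random projections of their latent),
and morphology / expression profiles are logistic-squashed affine maps of
the latents with additive Gaussian noise, so the modalities genuinely share
information the way perturbation readouts of a common biological state do.
A subset of molecules is paired with its own morphology and expression
profiles (chemical perturbations), a subset of genes with morphology
profiles (genetic perturbations), and genes are linked by a sparse random
interaction network.  Downstream labels are thresholded linear functionals
of the molecule latents.

Molecule structures are random labeled trees whose atom labels encode the
fingerprint nibbles (one atom per 4-bit group, label = group << 4 | value),
so structure and fingerprint are mutually consistent and the graph encoder
can be exercised without any chemistry toolkit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .context_graph import (
    ContextEdge,
    ContextGraph,
    ContextNode,
    EdgeProvenance,
    NodeKind,
    TargetFeature,
    add_perturbation_edges,
    aggregate_expression_nodes,
    assemble_graph,
    attach_morphology_to_genes,
    build_similarity_edges,
    minmax_scale,
)
from .model import MolecularGraph

__all__ = ["SyntheticWorld", "generate_world", "world_to_graph",
           "write_world", "load_world", "TREE_ATOM_VOCAB", "TREE_BOND_VOCAB"]

_NIBBLE = 4
TREE_ATOM_VOCAB = 16 * (64 // _NIBBLE)  # positions x nibble values at d_fp = 64
TREE_BOND_VOCAB = 4


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticWorld:
    latents: np.ndarray               # (n_molecules, d_latent)
    gene_latents: np.ndarray          # (n_genes, d_latent)
    molecule_ids: list[str]
    gene_ids: list[str]
    molecule_graphs: dict[str, MolecularGraph]
    fingerprints: pd.DataFrame        # binary, molecules x d_fp
    morphology: pd.DataFrame          # molecules x d_morph (chemical perturbation readout)
    gene_morphology: pd.DataFrame     # genes x d_morph (genetic perturbation readout)
    expression: pd.DataFrame          # molecules x genes
    mol_morph_pairs: list[tuple[str, str]]
    gene_morph_pairs: list[tuple[str, str]]
    mol_expr_ids: list[str]           # molecules with an expression profile
    gene_interactions: list[tuple[str, str]]
    class_labels: pd.DataFrame        # molecules x tasks, in {0, 1}
    reg_labels: pd.Series             # molecules
    groups: pd.Series                 # scaffold-style group id per molecule
    manifest: dict = field(default_factory=dict)


def generate_world(
    n_molecules: int = 500,
    n_genes: int = 60,
    d_latent: int = 8,
    noise_sd: float = 0.3,
    seed: int = 7,
    d_fingerprint: int = 64,
    d_morphology: int = 48,
    n_class_tasks: int = 4,
    mol_morph_fraction: float = 0.7,
    mol_expr_fraction: float = 0.7,
    gene_morph_fraction: float = 0.8,
    gene_mean_degree: float = 4.0,
) -> SyntheticWorld:
    """Generate a fixture world; the manifest regenerates it byte-identically."""
    if min(n_molecules, n_genes, d_latent) < 1:
        raise ValueError("all counts must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if d_fingerprint % _NIBBLE != 0:
        raise ValueError("d_fingerprint must be a multiple of 4")
    params = {k: v for k, v in locals().items()}
    rng = np.random.default_rng(np.random.SeedSequence([seed]))

    h = rng.standard_normal((n_molecules, d_latent))
    g = rng.standard_normal((n_genes, d_latent))
    mol_ids = [f"mol{i:04d}" for i in range(n_molecules)]
    gene_ids = [f"gene{i:03d}" for i in range(n_genes)]

    proj_fp = rng.standard_normal((d_latent, d_fingerprint))
    fingerprints = (h @ proj_fp > 0).astype(float)

    A_morph = rng.standard_normal((d_latent, d_morphology)) / np.sqrt(d_latent)
    morphology = _sigmoid(h @ A_morph + noise_sd * rng.standard_normal((n_molecules, d_morphology)))
    gene_morphology = _sigmoid(g @ A_morph + noise_sd * rng.standard_normal((n_genes, d_morphology)))

    A_expr = rng.standard_normal((d_latent, n_genes)) / np.sqrt(d_latent)
    expression = _sigmoid(h @ A_expr + noise_sd * rng.standard_normal((n_molecules, n_genes)))

    # perturbation pairings: random subsets of entities have measured profiles
    def subset(ids, fraction):
        k = int(round(fraction * len(ids)))
        return sorted(rng.choice(len(ids), size=k, replace=False).tolist())

    mol_morph_idx = subset(mol_ids, mol_morph_fraction)
    mol_expr_idx = subset(mol_ids, mol_expr_fraction)
    gene_morph_idx = subset(gene_ids, gene_morph_fraction)
    mol_morph_pairs = [(mol_ids[i], f"cp:{mol_ids[i]}") for i in mol_morph_idx]
    gene_morph_pairs = [(gene_ids[i], f"cp:{gene_ids[i]}") for i in gene_morph_idx]
    mol_expr_ids = [mol_ids[i] for i in mol_expr_idx]

    p_edge = min(gene_mean_degree / max(n_genes - 1, 1), 1.0)
    gene_interactions = [
        (gene_ids[i], gene_ids[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if rng.random() < p_edge
    ]

    w_cls = rng.standard_normal((d_latent, n_class_tasks))
    class_labels = (h @ w_cls > 0).astype(int)
    w_reg = rng.standard_normal(d_latent)
    reg_labels = h @ w_reg

    # scaffold-style groups from the leading fingerprint nibble: molecules
    # sharing a structural prefix share a group, as scaffolds do
    group_ids = [int("".join(str(int(b)) for b in row[:_NIBBLE]), 2) for row in fingerprints]

    molecule_graphs = {
        mol_ids[i]: _tree_from_fingerprint(fingerprints[i], seed) for i in range(n_molecules)
    }

    return SyntheticWorld(
        latents=h,
        gene_latents=g,
        molecule_ids=mol_ids,
        gene_ids=gene_ids,
        molecule_graphs=molecule_graphs,
        fingerprints=pd.DataFrame(fingerprints, index=mol_ids),
        morphology=pd.DataFrame(morphology, index=mol_ids),
        gene_morphology=pd.DataFrame(gene_morphology, index=gene_ids),
        expression=pd.DataFrame(expression, index=mol_ids, columns=gene_ids),
        mol_morph_pairs=mol_morph_pairs,
        gene_morph_pairs=gene_morph_pairs,
        mol_expr_ids=mol_expr_ids,
        gene_interactions=gene_interactions,
        class_labels=pd.DataFrame(class_labels, index=mol_ids,
                                  columns=[f"task{t}" for t in range(n_class_tasks)]),
        reg_labels=pd.Series(reg_labels, index=mol_ids, name="reg"),
        groups=pd.Series(group_ids, index=mol_ids, name="group"),
        manifest={"generator": params},
    )


def _tree_from_fingerprint(fp_row: np.ndarray, seed: int) -> MolecularGraph:
    """Random labeled tree consistent with a fingerprint.

    One atom per 4-bit fingerprint group; the atom label encodes (group
    position, group value), so the label multiset determines the fingerprint.
    The tree topology and bond labels are drawn from an RNG seeded by the
    fingerprint bytes, keeping structure a deterministic function of the row.
    """
    bits = np.asarray(fp_row, dtype=int)
    n_groups = bits.size // _NIBBLE
    labels = []
    for gidx in range(n_groups):
        nibble = bits[gidx * _NIBBLE : (gidx + 1) * _NIBBLE]
        value = int("".join(map(str, nibble)), 2)
        labels.append(gidx * 16 + value)
    digest = int.from_bytes(bits.astype(np.uint8).tobytes(), "big") % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, digest]))
    bonds = []
    for k in range(1, n_groups):
        parent = int(rng.integers(0, k))  # random recursive-attachment tree
        bonds.append((parent, k, int(rng.integers(0, TREE_BOND_VOCAB))))
    return MolecularGraph(np.array(labels), bonds)


# ---------------------------------------------------------------------------
# graph construction from a world


def world_to_graph(
    world: SyntheticWorld,
    sim_threshold: float = 0.8,
    keep_fraction: float = 0.005,
    expr_top_fraction: float = 0.01,
) -> tuple[ContextGraph, dict]:
    """Build the context graph from a world using the standard rules.

    Perturbation pairings become weight-1 edges; genetic-perturbation
    morphology profiles are folded into their gene nodes as features;
    expression rows become gene-expression nodes with top-cell edges to
    genes; cosine-similarity edges are added within each feature space.
    Returns the graph and the generator's declared counts for bookkeeping.
    """
    mol_nodes = [
        ContextNode(mid, NodeKind.MOLECULE,
                    TargetFeature("fingerprint", world.fingerprints.loc[mid].to_numpy()))
        for mid in world.molecule_ids
    ]

    morph_scaled = minmax_scale(world.morphology.to_numpy())
    morph_lookup = {mid: morph_scaled[i] for i, mid in enumerate(world.molecule_ids)}
    cp_nodes = [
        ContextNode(cp_id, NodeKind.MORPHOLOGY,
                    TargetFeature("morphology", morph_lookup[mol_id]))
        for mol_id, cp_id in world.mol_morph_pairs
    ]

    gene_morph_scaled = minmax_scale(world.gene_morphology.to_numpy())
    gene_profiles = {f"cp:{gid}": gene_morph_scaled[i] for i, gid in enumerate(world.gene_ids)}
    bare_genes = {gid: ContextNode(gid, NodeKind.GENE) for gid in world.gene_ids}
    gene_nodes = attach_morphology_to_genes(world.gene_morph_pairs, gene_profiles, bare_genes)

    if world.mol_expr_ids:
        expr_table = world.expression.loc[world.mol_expr_ids]
        expr_nodes, expr_edges = aggregate_expression_nodes(
            expr_table, expr_top_fraction, gene_node_ids=world.gene_ids
        )
    else:
        expr_nodes, expr_edges = [], []

    mol_morph_edges = add_perturbation_edges(world.mol_morph_pairs)
    interaction_edges = [
        ContextEdge(u, v, 1.0, EdgeProvenance.INTERACTION) for u, v in world.gene_interactions
    ]

    featured_genes = [n for n in gene_nodes.values() if n.feature is not None]
    sim_fp = build_similarity_edges(mol_nodes, sim_threshold, keep_fraction)
    sim_morph = build_similarity_edges(cp_nodes + featured_genes, sim_threshold, keep_fraction)
    sim_expr = build_similarity_edges(expr_nodes, sim_threshold, keep_fraction)

    graph = assemble_graph(
        [mol_nodes, cp_nodes, list(gene_nodes.values()), expr_nodes],
        [mol_morph_edges, expr_edges, interaction_edges, sim_fp, sim_morph, sim_expr],
    )
    declared = {
        "n_molecule_nodes": len(mol_nodes),
        "n_morphology_nodes": len(cp_nodes),
        "n_gene_nodes": len(gene_nodes),
        "n_expression_nodes": len(expr_nodes),
        "n_perturbation_edges": len(mol_morph_edges)
        + sum(1 for e in expr_edges if e.provenance == EdgeProvenance.PERTURBATION),
        "n_expression_top_edges": sum(
            1 for e in expr_edges if e.provenance == EdgeProvenance.EXPRESSION_TOP
        ),
        "n_interaction_edges": len(interaction_edges),
        "n_similarity_edges": len(sim_fp) + len(sim_morph) + len(sim_expr),
    }
    return graph, declared


# ---------------------------------------------------------------------------
# serialization (same delimited dialects the real loaders read)


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"id": world.molecule_ids, "smiles": ""}).to_csv(out / "molecules.csv", index=False)
    world.fingerprints.to_csv(out / "fingerprints.csv", index_label="id")
    world.morphology.to_csv(out / "morphology.csv", index_label="id")
    world.gene_morphology.to_csv(out / "gene_morphology.csv", index_label="id")
    world.expression.to_csv(out / "expression.csv", index_label="id")
    world.class_labels.to_csv(out / "class_labels.csv", index_label="id")
    world.reg_labels.to_frame().to_csv(out / "reg_labels.csv", index_label="id")
    world.groups.to_frame().to_csv(out / "groups.csv", index_label="id")
    pd.DataFrame(world.mol_morph_pairs, columns=["u", "v"]).to_csv(
        out / "pairs_mol_morph.tsv", sep="\t", index=False)
    pd.DataFrame(world.gene_morph_pairs, columns=["u", "v"]).to_csv(
        out / "pairs_gene_morph.tsv", sep="\t", index=False)
    pd.DataFrame({"id": world.mol_expr_ids}).to_csv(out / "mol_expr_ids.tsv", sep="\t", index=False)
    pd.DataFrame(world.gene_interactions, columns=["u", "v"]).to_csv(
        out / "gene_interactions.tsv", sep="\t", index=False)
    trees = {
        mid: {"atoms": mg.atom_labels.tolist(), "bonds": [list(b) for b in mg.bonds]}
        for mid, mg in world.molecule_graphs.items()
    }
    (out / "molecule_graphs.json").write_text(json.dumps(trees))
    (out / "manifest.json").write_text(json.dumps(world.manifest, indent=2, sort_keys=True))


def load_world(in_dir: str | Path) -> SyntheticWorld:
    """Regenerate the world from its manifest (byte-identical by construction)."""
    manifest = json.loads((Path(in_dir) / "manifest.json").read_text())
    return generate_world(**manifest["generator"])
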