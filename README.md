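# cellcontext

Molecular representation learning that looks beyond the molecule: the
package aligns a molecular-graph encoder's latent space with the *cellular
context* of each compound — the cell-morphology and gene-expression changes
its perturbation induces — using an information-bottleneck objective over a
weighted heterogeneous context graph.

It is aimed at computational chemists and cheminformaticians who want
compound representations informed by perturbational readouts (Cell
Painting-style morphology profiles, landmark-gene expression profiles)
rather than structure alone, and at method developers who want a compact,
fully inspectable implementation of decoder-based multimodal alignment,
including a numerical laboratory for the mutual-information bounds that
justify it.

## The method

**Context graph.** Molecules *x*, genes *e*, gene-expression profiles, and
cell-morphology profiles *c* are nodes carrying feature vectors scaled to
[0, 1] (binary fingerprints; CellProfiler-style morphology features;
landmark-gene expression).  Edges carry weights *w* ∈ (0, 1]: chemical and
genetic perturbation pairings get weight exactly 1, cosine-similarity edges
within one feature space (threshold 0.8, global top-0.5 % sparsification)
get the cosine value, gene–gene interactions weight 1, and the top 1 % of
molecule–gene expression cells induce additional edges.

**Random-walk neighborhoods.** For each training molecule a random walk
P_x = x → v₂ → … → v_L with degree-based transition probabilities collects
reconstruction targets; the cumulative weight α_{v_i} = ∏_{j<i} w_j
quantifies how related each visited node is to the seed.

**Information-bottleneck objective.** A GIN-style encoder produces a
diagonal Gaussian latent p(z|x) = N(μ, σ²), sampled by reparameterization;
per-modality MLP decoders q_φ(y|z) reconstruct the walk targets:

    L = (1/L) Σ_{v ∈ P_x} α_v · [−log q_φ(y_v | z)] + β · KL(p(z|x) ‖ N(0, I))

The first term is a decoder-based lower-bound surrogate for I(Z; Y)
(sufficiency: the latent can explain the cellular context); the KL term
upper-bounds I(X; Z) (minimality: discard structure the context does not
need); β trades them off.

**Why decoders, not contrastive encoders.**  On finite joints the package
verifies numerically that the decoder-based bound I_DLB dominates the
InfoNCE-style contrastive bound I_ELB, which saturates at log K:
I(Z;Y) ≥ I_DLB ≥ I_ELB (module `cellcontext.bounds`).

**Evaluation.**  Zero-shot molecule→morphology matching ranks all candidate
profiles by the likelihood of the decoded morphology features (NDCG@k /
HIT@k); downstream property prediction fits a small probe on frozen latent
means under a grouped (scaffold-style) split, reporting AUC / MAE.

Everything runs on bundled synthetic data: worlds of molecules, genes, and
profiles generated from shared latent factors with additive noise, so every
stage is testable with no downloads.  The neural components (encoder,
decoders, Adam) are implemented directly on NumPy with analytic gradients
validated against finite differences.

## Worked example

```python
import dataclasses
import cellcontext as cc
from cellcontext.synthetic import TREE_ATOM_VOCAB, TREE_BOND_VOCAB

world = cc.generate_world(n_molecules=500, n_genes=60, d_latent=8,
                          noise_sd=0.3, seed=7)
graph, counts = cc.world_to_graph(world)
print(graph.summary()["nodes_per_kind"])
# {'molecule': 500, 'gene': 60, 'gene_expression': 350, 'morphology': 350}

config = cc.TrainingConfig(beta=1e-2, epochs=200, seed=3)
config.encoder = dataclasses.replace(config.encoder,
                                     atom_vocab=TREE_ATOM_VOCAB,
                                     bond_vocab=TREE_BOND_VOCAB)
enc, dec, log = cc.pretrain(graph, world.molecule_graphs, config)
print(round(log[0]["total"], 1), "->", round(log[-1]["total"], 1))
# 539.3 -> 10.6

from cellcontext.pipeline import embed_molecules
from cellcontext.retrieval import grouped_split, probe_evaluate
emb = embed_molecules(world.molecule_graphs, enc, config.encoder)
X = emb.to_numpy()[:, :config.encoder.latent_dim]
splits = grouped_split(world.groups.tolist(), (0.6, 0.15, 0.25))
report = probe_evaluate(X, world.class_labels.to_numpy(),
                        "classification", splits, seed=3)
print(round(report["mean"], 3))
# 0.919
```

The training loss falls from ~539 to ~11 over 200 epochs, and a probe on
the learned latent means reaches test AUC ≈ 0.92 on held-out scaffold
groups — versus ≈ 0.69 for the same probe on an untrained encoder's
embeddings, the signature that the latent has absorbed context information
beyond raw structure features.

The same flow is available from the shell:

```bash
cellcontext simulate --n 500 --seed 7 --out runs/world
cellcontext build-graph --world runs/world --out runs/graph
cellcontext pretrain --out runs/demo --epochs 200 --beta 0.01
cellcontext bounds-report --n-joints 50 --alphabet 4 --k 2 --seed 1
```

## Layout

| Module | Role |
| --- | --- |
| `cellcontext.context_graph` | typed nodes/edges, scaling, edge construction, assembly, TSV round-trip |
| `cellcontext.walks` | transition distributions, walk sampling, cumulative weights α |
| `cellcontext.model` | GIN-style variational encoder, MLP decoders, analytic gradients, Adam |
| `cellcontext.objective` | the α-weighted reconstruction + β·KL loss and the pretraining loop |
| `cellcontext.retrieval` | likelihood / cosine ranking, NDCG/HIT, grouped splits, probes |
| `cellcontext.bounds` | exact MI, decoder bound, InfoNCE-style bound, ordering verification |
| `cellcontext.synthetic` | fixture worlds with shared latent factors and perturbation pairings |
| `cellcontext.pipeline` | stage orchestration, manifests, sweeps, CLI backing |

See `docs/methods.md` for modeling assumptions, parameter choices, and
limitations.
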