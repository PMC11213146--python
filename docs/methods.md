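# Methods

This note records the modeling assumptions, parameter choices, and known
limitations behind `cellcontext`, in the order the method runs.

## Context graph

Nodes are typed (molecule, gene, gene-expression profile, morphology
profile) and carry modality-tagged feature vectors min–max scaled to
[0, 1] per dimension within one modality.  Scaling choices:

- Constant columns map to all-zeros, not 0.5: the minimum of a column
  always maps to 0, and a constant column is its own minimum.  This keeps
  outputs in [0, 1] without inventing mass.
- Expression tables are scaled per landmark gene (column-wise across
  molecules).  A raw row with no spread is flagged with a warning; its
  scaled feature is whatever column scaling yields.

Edge construction:

- Perturbation pairings (molecule↔morphology, gene↔morphology,
  molecule↔expression) get weight exactly 1.  Undirected duplicates
  collapse to one edge.
- Cosine-similarity edges are computed within one feature space.  Pairs
  with cosine ≥ 0.8 are candidates; of these, only the top 0.5 % of *all
  possible pairs* (ceiling count, global cut — not per-node top-k) are
  kept, ranked by similarity with lexicographic (u, v) tie-breaks.  The
  ceiling rule never keeps zero edges when candidates exist.  Zero-norm
  vectors are skipped with a log message rather than dividing by zero.
- Genetic-perturbation morphology profiles are folded into gene nodes as
  features (element-wise mean when a gene has several profiles — a
  deterministic, order-independent aggregation).
- Each expression row becomes a gene-expression node linked to its source
  molecule at weight 1; the globally top 1 % of raw expression cells
  additionally link expression nodes to gene nodes.  These edges need a
  weight in (0, 1] but no natural rule exists, so we use the whole-table
  min–max rescale of the cell value clamped into [1e-6, 1] (the clamp only
  matters in the degenerate case where a selected cell is the table
  minimum).
- When two construction routes produce the same (u, v) pair, provenance
  priority resolves it: perturbation > interaction > expression_top >
  similarity.  Perturbation pairings are measured ground truth, so they
  win.

The graph is undirected, self-loop-free, and validated on assembly.  The
0.8 cosine threshold is applied uniformly to all three feature spaces,
including binary fingerprints.

## Random walks

Walks start at a molecule node and visit at most L nodes (seed included;
L = 1 keeps only the seed).  The default transition rule is degree-based —
p(next = u | current) ∝ degree(u) over the current node's neighbors —
with edge-weight-proportional and uniform modes available, since
"degree-based" admits more than one reading and the choice should be
visible, not buried.  Walks may revisit nodes; a revisited node contributes
another (target, α) pair.  Immediate backtracking is allowed.

The cumulative weight α_i is the exact left-fold product of edge weights
from the seed, hence non-increasing along the path.  The seed molecule is
itself a reconstruction target with α = 1: a molecule's own fingerprint is
always decodable from its latent and anchors the structure modality.

Default L = 4.  Per-walk RNGs derive from (run seed, molecule index,
epoch), so walks are reproducible regardless of batch composition and a
fresh walk is drawn per molecule per epoch.

## Encoder, decoders, and objective

The encoder is GIN-style: per layer
h'_v = MLP((1 + ε)·h_v + Σ_{u∼v}(h_u + bond_emb)), with a two-layer ReLU
MLP, sum readout over atoms, and two affine heads for μ and log σ².
Defaults: latent D = 64, hidden width 128, 3 layers — desk-scale sizes,
all configurable.  The log-variance is clamped to [−10, 10] for numerical
stability; σ is per-dimension.  Atom and bond descriptors are categorical
(element × degree and bond order for real molecules via RDKit; generator
labels in synthetic mode).

Decoders are one-hidden-layer MLPs (hidden 128) with a logistic squash,
because every target lives in [0, 1] after scaling.  Likelihoods:
Bernoulli cross-entropy for binary fingerprints, unit-variance Gaussian
(½‖ŷ−y‖², constants dropped) for morphology and expression; predictions
are clamped to [1e-7, 1−1e-7] inside the cross-entropy.

The per-molecule loss divides the α-weighted reconstruction sum by the
*configured* walk length L, not the realized path length, so
early-terminated walks down-weight reconstruction.  One reparameterized
z sample per molecule per step (multi-sample estimation is exposed in the
config but off by default).  The dropped entropy constant H(Y) means
absolute loss values are not comparable to true mutual information; only
differences and trends are meaningful.

All forward/backward passes are hand-derived NumPy (neighbor aggregation as
sparse-matrix products; the test suite checks every gradient against
central finite differences at 1e-4 relative tolerance), optimized with
Adam at learning rate 1e-3, batch size 128.  Training aborts on a
non-finite loss, returning the last finite parameters.

## Mutual-information bounds laboratory

Verification runs on small discrete joints so every closed-form quantity is
exact to machine precision — the price is that the differential-entropy
version of the decoder bound is out of scope (documented, not
approximated).  The decoder bound I_DLB = E log q(y|z) + H(Y) is tight at
q = p(y|z); the contrastive bound is the energy-based K-sample estimator
with negatives drawn i.i.d. from the true y-marginal, Monte-Carlo estimated
with a reported standard error, and cannot exceed log K.  The optimal
critic log p(y|z) uses a finite floor of −30 for zero-probability entries
so partition ratios stay well-defined.  All values are in nats.  Ordering
checks allow 3 Monte-Carlo standard errors of slack on the stochastic side
and 1e-12 on the exact side.

## Synthetic worlds

Each world draws molecule latents h ∈ R^8 and gene latents from a standard
normal.  Fingerprints are thresholded random projections of h (64 bits);
morphology (48 dims) and expression (one dim per gene) are logistic-squashed
affine maps of the latents with N(0, noise_sd²) noise added *before* the
squash, keeping raw features in [0, 1] ahead of the usual column scaling.
Defaults: 500 molecules, 60 genes, noise_sd 0.3 — small enough that a
200-epoch pretraining run takes about a minute on one CPU, large enough
that probes have signal.  70 % of molecules are paired with their own
morphology and expression profiles, 80 % of genes with morphology profiles,
and genes form an Erdős–Rényi interaction network with mean degree 4.

Molecule structures are random labeled trees: one atom per 4-bit
fingerprint group, atom label = (group, nibble value), topology and bond
labels drawn from an RNG keyed by the fingerprint bytes.  The label
multiset therefore determines the fingerprint exactly, making structure and
fingerprint mutually consistent without any chemistry toolkit.  Scaffold
groups for splitting come from the leading fingerprint nibble (16 groups),
mimicking the way real scaffolds correlate with structure.

Labels are thresholded linear functionals of h (4 binary tasks) plus one
linear regression target.  A probe on the true latents reaches AUC ≈ 1, so
probe performance on learned embeddings measures how much of h the encoder
recovered.

What the generator does **not** emulate: batch effects and other technical
confounders, dose–response structure, non-linear biology, realistic
fingerprint sparsity, or assay noise heterogeneity.  Passing tests
demonstrate that the machinery recovers planted shared-latent structure at
desk scale — not that the method works on real Cell Painting / L1000
corpora, which involve orders of magnitude more nodes and far messier
signal.

## Evaluation choices

- Retrieval decodes the latent *mean* (no sampling) and scores candidates
  by −NLL under the morphology decoder's training likelihood; ties break
  by candidate id.  The query's own profile stays in the candidate pool,
  so the truth is always present.
- NDCG with a single relevant item reduces to 1/log2(rank + 1) inside the
  cutoff; HIT@k is the indicator of rank ≤ k.
- Grouped splits use largest-remainder target counts at ratios
  0.6 : 0.15 : 0.25, fill test first, then valid, then train, over groups
  sorted by (size descending, key ascending) — deterministic and as close
  to the requested ratios as group granularity permits.
- Probes are one-hidden-layer (32 units) scikit-learn MLPs; the
  regularization strength is selected on the validation fold from
  {1e-4, 1e-2}.  Degenerate single-class test tasks are skipped and
  reported.

## Problem sizes used in the bundled checks

Brute-force comparisons run at 200 nodes (similarity edges) and full
candidate pools of a few hundred profiles (retrieval).  Bound verification
uses 50 random 4×4 joints and an 8-symbol identity joint at 10⁵ Monte-Carlo
samples.  Pretraining checks use the default 500-molecule world at 200
epochs (three independent seeds), an 80-epoch run per β in the trade-off
sweep, and a 200-molecule world for the 50-epoch per-batch loss-identity
check.  These sizes were chosen so the entire verification remains a
coffee-break job on a single CPU while every statistical assertion keeps a
comfortable margin.

## Known limitations

- No GPU path and no mini-batch parallelism; the NumPy implementation is
  meant for desk-scale corpora (10³–10⁴ molecules), not the 10⁵-node
  graphs of real perturbation atlases.
- The contrastive-bound laboratory uses tabular critics on finite joints;
  neural critics and continuous variables are out of scope.
- Walk transition probabilities are first-order only (no node2vec-style
  p/q biases).
- Imported interaction edges default to weight 1; if a source provides
  confidence scores they are currently ignored.
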