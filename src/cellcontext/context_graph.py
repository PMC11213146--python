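"""Weighted cellular context graph.

Nodes are molecules, genes, gene-expression profiles, and cell-morphology
profiles; each feature-bearing node carries a modality-tagged vector scaled
to [0, 1].  Edges carry a weight in (0, 1]: perturbation pairings get weight
exactly 1, cosine-similarity edges within one feature space get the cosine
value (thresholded and globally sparsified), gene-gene interaction edges are
imported with weight 1, and top expression cells induce edges weighted by the
rescaled expression value.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NodeKind",
    "EdgeProvenance",
    "TargetFeature",
    "ContextNode",
    "ContextEdge",
    "ContextGraph",
    "minmax_scale",
    "add_perturbation_edges",
    "build_similarity_edges",
    "top_expression_cells",
    "aggregate_expression_nodes",
    "attach_morphology_to_genes",
    "assemble_graph",
]


class NodeKind(str, Enum):
    MOLECULE = "molecule"
    GENE = "gene"
    GENE_EXPRESSION = "gene_expression"
    MORPHOLOGY = "morphology"


class EdgeProvenance(str, Enum):
    PERTURBATION = "perturbation"
    SIMILARITY = "similarity"
    INTERACTION = "interaction"
    EXPRESSION_TOP = "expression_top"


#: modality of the feature a node of each kind carries (gene nodes carry the
#: morphology profile of their genetic perturbation)
KIND_MODALITY = {
    NodeKind.MOLECULE: "fingerprint",
    NodeKind.GENE: "morphology",
    NodeKind.GENE_EXPRESSION: "expression",
    NodeKind.MORPHOLOGY: "morphology",
}

#: resolution order when two construction routes produce the same (u, v) edge
_PROVENANCE_PRIORITY = {
    EdgeProvenance.PERTURBATION: 0,
    EdgeProvenance.INTERACTION: 1,
    EdgeProvenance.EXPRESSION_TOP: 2,
    EdgeProvenance.SIMILARITY: 3,
}

MODALITIES = ("fingerprint", "morphology", "expression")


@dataclass
class TargetFeature:
    """Modality-tagged reconstruction target; values must lie in [0, 1]."""

    modality: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature contains non-finite values")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("feature values must lie in [0, 1]")


@dataclass
class ContextNode:
    node_id: str
    kind: NodeKind
    feature: TargetFeature | None = None

    def __post_init__(self) -> None:
        self.kind = NodeKind(self.kind)


@dataclass(frozen=True)
class ContextEdge:
    """Undirected weighted edge; endpoints stored in sorted order."""

    u: str
    v: str
    weight: float
    provenance: EdgeProvenance

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-loop on {self.u!r} not allowed")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"edge weight {self.weight} outside (0, 1]")
        u, v = self.u, self.v
        if u > v:  # canonical orientation so (u, v) == (v, u)
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)
        object.__setattr__(self, "provenance", EdgeProvenance(self.provenance))


def _make_edge(u: str, v: str, weight: float, provenance) -> ContextEdge:
    a, b = (u, v) if u <= v else (v, u)
    return ContextEdge(a, b, float(weight), EdgeProvenance(provenance))


class ContextGraph:
    """Undirected heterogeneous graph over typed, feature-bearing nodes.

    Thin wrapper around :class:`networkx.Graph` enforcing the domain
    invariants (unique ids, weights in (0, 1], no self-loops, endpoints
    present).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, node: ContextNode) -> None:
        if node.node_id in self._g:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self._g.add_node(node.node_id, kind=node.kind, feature=node.feature)

    def add_edge(self, edge: ContextEdge, on_duplicate: str = "error") -> None:
        if edge.u not in self._g or edge.v not in self._g:
            missing = [x for x in (edge.u, edge.v) if x not in self._g]
            raise KeyError(f"edge endpoint(s) not in graph: {missing}")
        if self._g.has_edge(edge.u, edge.v):
            if on_duplicate == "error":
                raise ValueError(f"duplicate edge ({edge.u}, {edge.v})")
            if on_duplicate == "keep_priority":
                old = self._g.edges[edge.u, edge.v]
                old_key = (_PROVENANCE_PRIORITY[old["provenance"]], -old["weight"])
                new_key = (_PROVENANCE_PRIORITY[edge.provenance], -edge.weight)
                if new_key >= old_key:
                    return
            elif on_duplicate == "skip":
                return
        self._g.add_edge(edge.u, edge.v, weight=edge.weight, provenance=edge.provenance)

    # -- queries ----------------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node_ids(self) -> list[str]:
        return list(self._g.nodes)

    def node(self, node_id: str) -> ContextNode:
        data = self._g.nodes[node_id]
        return ContextNode(node_id, data["kind"], data["feature"])

    def kind(self, node_id: str) -> NodeKind:
        return self._g.nodes[node_id]["kind"]

    def feature(self, node_id: str) -> TargetFeature | None:
        return self._g.nodes[node_id]["feature"]

    def set_feature(self, node_id: str, feature: TargetFeature) -> None:
        self._g.nodes[node_id]["feature"] = feature

    def neighbors(self, node_id: str) -> list[str]:
        return sorted(self._g.neighbors(node_id))

    def degree(self, node_id: str) -> int:
        return self._g.degree(node_id)

    def edge_weight(self, u: str, v: str) -> float:
        return self._g.edges[u, v]["weight"]

    def edges(self) -> list[ContextEdge]:
        return [
            _make_edge(u, v, d["weight"], d["provenance"])
            for u, v, d in self._g.edges(data=True)
        ]

    def nodes_of_kind(self, kind: NodeKind) -> list[str]:
        kind = NodeKind(kind)
        return [n for n, d in self._g.nodes(data=True) if d["kind"] == kind]

    def summary(self) -> dict:
        node_counts = {k.value: 0 for k in NodeKind}
        for _, d in self._g.nodes(data=True):
            node_counts[d["kind"].value] += 1
        edge_counts = {p.value: 0 for p in EdgeProvenance}
        for _, _, d in self._g.edges(data=True):
            edge_counts[d["provenance"].value] += 1
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_per_kind": node_counts,
            "edges_per_provenance": edge_counts,
        }

    def validate(self) -> None:
        for u, v, d in self._g.edges(data=True):
            if u == v:
                raise AssertionError(f"self-loop on {u}")
            if not (0.0 < d["weight"] <= 1.0):
                raise AssertionError(f"weight out of range on ({u}, {v})")

    # -- serialization ----------------------------------------------------
    def save(self, out_dir: str | Path, manifest_extra: Mapping | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        node_rows = []
        for nid in self._g.nodes:
            d = self._g.nodes[nid]
            feat = d["feature"]
            node_rows.append(
                {
                    "node_id": nid,
                    "kind": d["kind"].value,
                    "modality": feat.modality if feat is not None else "",
                    "feature": ",".join(repr(float(x)) for x in feat.values) if feat is not None else "",
                }
            )
        pd.DataFrame(node_rows).to_csv(out / "nodes.tsv", sep="\t", index=False)
        edge_rows = [
            {"u": e.u, "v": e.v, "weight": repr(float(e.weight)), "provenance": e.provenance.value}
            for e in self.edges()
        ]
        pd.DataFrame(edge_rows, columns=["u", "v", "weight", "provenance"]).to_csv(
            out / "edges.tsv", sep="\t", index=False
        )
        manifest = {"summary": self.summary()}
        if manifest_extra:
            manifest.update(manifest_extra)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ContextGraph":
        src = Path(in_dir)
        graph = cls()
        nodes = pd.read_csv(src / "nodes.tsv", sep="\t", dtype=str, keep_default_na=False)
        for row in nodes.itertuples(index=False):
            feature = None
            if row.feature:
                values = np.array([float(x) for x in row.feature.split(",")])
                feature = TargetFeature(row.modality, values)
            graph.add_node(ContextNode(row.node_id, NodeKind(row.kind), feature))
        edges = pd.read_csv(src / "edges.tsv", sep="\t", dtype=str, keep_default_na=False)
        for row in edges.itertuples(index=False):
            graph.add_edge(_make_edge(row.u, row.v, float(row.weight), row.provenance))
        return graph


# ---------------------------------------------------------------------------
# feature scaling


def minmax_scale(
    features: np.ndarray, per_dimension: bool = True, return_params: bool = False
):
    """Min-max scale a feature matrix into [0, 1].

    With ``per_dimension`` (the default) each column is scaled independently
    across rows.  Columns with no spread map to all-zeros (the minimum always
    maps to 0, and a constant column is its own minimum).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 1:
        raise ValueError("matrix must have at least one row")
    if not np.all(np.isfinite(X)):
        rows, cols = np.nonzero(~np.isfinite(X))
        raise ValueError(
            f"non-finite input at (row, column) pairs: {list(zip(rows.tolist(), cols.tolist()))[:5]}"
        )
    if per_dimension:
        lo = X.min(axis=0)
        hi = X.max(axis=0)
    else:
        lo = np.full(X.shape[1], X.min())
        hi = np.full(X.shape[1], X.max())
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (X - lo) / safe
    out[:, span == 0] = 0.0
    if return_params:
        return out, (lo, hi)
    return out


# ---------------------------------------------------------------------------
# edge construction


def add_perturbation_edges(
    pairs: Iterable[tuple[str, str]], known_nodes: Mapping[str, ContextNode] | None = None
) -> list[ContextEdge]:
    """Weight-1 edges for perturbation pairings; undirected duplicates collapse."""
    seen: set[tuple[str, str]] = set()
    edges: list[ContextEdge] = []
    for u, v in pairs:
        if u == v:
            raise ValueError(f"self-pair ({u!r}, {u!r}) is not a valid perturbation")
        if known_nodes is not None:
            for x in (u, v):
                if x not in known_nodes:
                    raise KeyError(f"unknown node id {x!r} in perturbation pair")
        key = (u, v) if u <= v else (v, u)
        if key in seen:
            continue
        seen.add(key)
        edges.append(_make_edge(u, v, 1.0, EdgeProvenance.PERTURBATION))
    return edges


def build_similarity_edges(
    nodes: Sequence[ContextNode],
    threshold: float = 0.8,
    keep_fraction: float = 0.005,
) -> list[ContextEdge]:
    """Cosine-similarity edges within one feature space.

    Pairs with cosine >= ``threshold`` are candidates; of those, only the top
    ``keep_fraction`` of all possible pairs (global cut, ceiling count) are
    kept, ranked by similarity with lexicographic (u, v) tie-breaks.  The
    edge weight is the cosine value.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    n = len(nodes)
    if n < 2:
        return []
    X = np.stack([node.feature.values for node in nodes])
    ids = [node.node_id for node in nodes]
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning(
            "skipping %d zero-norm feature vector(s) in similarity computation", int(zero.sum())
        )
    safe = np.where(zero, 1.0, norms)
    U = X / safe[:, None]
    sims = U @ U.T
    candidates: list[tuple[float, str, str]] = []
    for i in range(n):
        if zero[i]:
            continue
        for j in range(i + 1, n):
            if zero[j]:
                continue
            s = sims[i, j]
            if s >= threshold and s > 0.0:
                a, b = (ids[i], ids[j]) if ids[i] <= ids[j] else (ids[j], ids[i])
                candidates.append((float(s), a, b))
    cap = math.ceil(keep_fraction * (n * (n - 1) / 2))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept = candidates[: min(cap, len(candidates))]
    return [
        _make_edge(u, v, min(s, 1.0), EdgeProvenance.SIMILARITY) for s, u, v in kept
    ]


# ---------------------------------------------------------------------------
# expression aggregation


def top_expression_cells(
    expr_table: pd.DataFrame, top_fraction: float
) -> list[tuple[str, str, float]]:
    """Global top cut over all (molecule, gene) expression cells.

    Keeps exactly ``ceil(top_fraction * n_cells)`` cells, ranked by raw value
    with lexicographic (molecule id, gene id) tie-breaks.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    cells = [
        (float(expr_table.iat[i, j]), str(expr_table.index[i]), str(expr_table.columns[j]))
        for i in range(expr_table.shape[0])
        for j in range(expr_table.shape[1])
    ]
    cells.sort(key=lambda t: (-t[0], t[1], t[2]))
    n_keep = math.ceil(top_fraction * len(cells))
    return [(m, g, v) for v, m, g in cells[:n_keep]]


def aggregate_expression_nodes(
    expr_table: pd.DataFrame,
    top_fraction: float = 0.01,
    gene_node_ids: Iterable[str] | None = None,
    expr_node_id: callable = lambda mol: f"expr:{mol}",
) -> tuple[list[ContextNode], list[ContextEdge]]:
    """One gene-expression node per molecule row, plus top-cell edges to genes.

    Each row of the molecules x landmark-genes table becomes a
    ``gene_expression`` node whose feature is the column-wise min-max scaled
    row, linked to its source molecule with a weight-1 perturbation edge.
    The globally top ``top_fraction`` of raw expression cells additionally
    induce ``expression_top`` edges from the expression node to the gene node
    (where such a gene node exists), weighted by the whole-table min-max
    rescale of the cell value, clamped into (0, 1].
    """
    values = expr_table.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression table contains non-finite values")
    scaled = minmax_scale(values, per_dimension=True)
    nodes: list[ContextNode] = []
    edges: list[ContextEdge] = []
    expr_ids: dict[str, str] = {}
    for i, mol in enumerate(expr_table.index):
        mol = str(mol)
        if np.ptp(values[i]) == 0:
            logger.warning("expression row %r has all-equal values", mol)
        eid = expr_node_id(mol)
        expr_ids[mol] = eid
        nodes.append(
            ContextNode(eid, NodeKind.GENE_EXPRESSION, TargetFeature("expression", scaled[i]))
        )
        edges.append(_make_edge(eid, mol, 1.0, EdgeProvenance.PERTURBATION))

    lo, hi = values.min(), values.max()
    gene_filter = set(map(str, gene_node_ids)) if gene_node_ids is not None else None
    for mol, gene, raw in top_expression_cells(expr_table, top_fraction):
        if gene_filter is not None and gene not in gene_filter:
            continue
        w = 1.0 if hi == lo else (raw - lo) / (hi - lo)
        w = min(max(w, 1e-6), 1.0)
        edges.append(_make_edge(expr_ids[mol], gene, w, EdgeProvenance.EXPRESSION_TOP))
    return nodes, edges


# ---------------------------------------------------------------------------
# genetic-perturbation morphology attachment


def attach_morphology_to_genes(
    gene_morphology_pairs: Iterable[tuple[str, str]],
    morphology_features: Mapping[str, np.ndarray],
    gene_nodes: Mapping[str, ContextNode] | None = None,
) -> dict[str, ContextNode]:
    """Attach genetic-perturbation morphology profiles to gene nodes.

    A gene referenced by several pairs gets the element-wise mean of its
    profiles.  Pairs referencing absent genes create the gene node (logged).
    """
    out: dict[str, ContextNode] = dict(gene_nodes) if gene_nodes else {}
    collected: dict[str, list[np.ndarray]] = {}
    for gene, morph_id in gene_morphology_pairs:
        if morph_id not in morphology_features:
            raise KeyError(f"unknown morphology profile id {morph_id!r}")
        collected.setdefault(str(gene), []).append(
            np.asarray(morphology_features[morph_id], dtype=float)
        )
    for gene, vectors in collected.items():
        feature = TargetFeature("morphology", np.mean(np.stack(vectors), axis=0))
        if gene in out:
            out[gene] = ContextNode(gene, out[gene].kind, feature)
        else:
            logger.info("creating gene node %r referenced only by a morphology pair", gene)
            out[gene] = ContextNode(gene, NodeKind.GENE, feature)
    return out


# ---------------------------------------------------------------------------
# assembly


def assemble_graph(
    node_sets: Iterable[Iterable[ContextNode]],
    edge_sets: Iterable[Iterable[ContextEdge]],
) -> ContextGraph:
    """Materialize the context graph, enforcing all invariants.

    Duplicate (u, v) edges from different construction routes resolve by
    provenance priority (perturbation > interaction > expression_top >
    similarity).  Dangling edge endpoints are rejected with their ids.
    """
    graph = ContextGraph()
    for nodes in node_sets:
        for node in nodes:
            graph.add_node(node)
    dangling = []
    for edges in edge_sets:
        for edge in edges:
            if edge.u not in graph or edge.v not in graph:
                dangling.extend(x for x in (edge.u, edge.v) if x not in graph)
                continue
            graph.add_edge(edge, on_duplicate="keep_priority")
    if dangling:
        raise KeyError(f"edges reference missing node ids: {sorted(set(dangling))}")
    graph.validate()
    logger.info("assembled context graph: %s", graph.summary())
    return graph
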