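"""Context-graph construction: scaling, edge rules, assembly, round-trip."""

import math

import numpy as np
import pytest

from cellcontext.context_graph import (
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
    top_expression_cells,
)

import pandas as pd


class TestMinMaxScale:
    def test_linear_map_endpoints(self):
        out = minmax_scale(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        out = minmax_scale(np.array([[5.0], [5.0], [5.0]]))
        assert np.all(out == 0.0)

    def test_matches_elementwise_oracle(self, rng):
        X = rng.normal(size=(3, 2))
        out = minmax_scale(X)
        for j in range(X.shape[1]):
            lo, hi = X[:, j].min(), X[:, j].max()
            for i in range(X.shape[0]):
                assert out[i, j] == pytest.approx((X[i, j] - lo) / (hi - lo), abs=1e-15)

    def test_idempotent(self, rng):
        X = rng.normal(size=(20, 5))
        once = minmax_scale(X)
        assert np.allclose(minmax_scale(once), once)

    def test_rejects_non_finite(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-finite"):
            minmax_scale(X)

    def test_output_in_unit_interval(self, rng):
        out = minmax_scale(rng.normal(size=(50, 7)) * 100)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestPerturbationEdges:
    def test_single_pair_weight_one(self):
        (edge,) = add_perturbation_edges([("m1", "c1")])
        assert (edge.u, edge.v, edge.weight) == ("c1", "m1", 1.0)
        assert edge.provenance == EdgeProvenance.PERTURBATION

    def test_undirected_dedup(self):
        edges = add_perturbation_edges([("m1", "c1"), ("c1", "m1")])
        assert len(edges) == 1

    def test_random_pairs_dedup_matches_set_oracle(self, rng):
        ids = [f"m{i}" for i in range(10)] + [f"c{i}" for i in range(10)]
        pairs = []
        for _ in range(40):
            i, j = rng.choice(10, size=2)
            pairs.append((f"m{i}", f"c{j}"))
        pairs += pairs[:10]  # duplicates
        edges = add_perturbation_edges(pairs)
        oracle = {tuple(sorted(p)) for p in pairs}
        assert len(edges) == len(oracle)
        assert all(e.weight == 1.0 for e in edges)

    def test_unknown_node_rejected(self):
        nodes = {"m1": ContextNode("m1", NodeKind.MOLECULE)}
        with pytest.raises(KeyError, match="c9"):
            add_perturbation_edges([("m1", "c9")], known_nodes=nodes)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            add_perturbation_edges([("m1", "m1")])


def _feature_nodes(X, prefix="n"):
    return [
        ContextNode(f"{prefix}{i:03d}", NodeKind.MORPHOLOGY, TargetFeature("morphology", row))
        for i, row in enumerate(X)
    ]


def _brute_force_similarity(nodes, threshold, keep_fraction):
    n = len(nodes)
    cands = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i].feature.values, nodes[j].feature.values
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0:
                continue
            s = float(np.dot(a / na, b / nb))
            if s >= threshold and s > 0:
                u, v = sorted([nodes[i].node_id, nodes[j].node_id])
                cands.append((s, u, v))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    cap = math.ceil(keep_fraction * n * (n - 1) / 2)
    return {(u, v) for _, u, v in cands[:cap]}


class TestSimilarityEdges:
    def test_identical_vectors_give_weight_one(self):
        v = np.array([0.2, 0.4, 0.4])
        nodes = _feature_nodes(np.stack([v, v]))
        (edge,) = build_similarity_edges(nodes, threshold=0.8, keep_fraction=1.0)
        assert edge.weight == pytest.approx(1.0)

    def test_orthogonal_vectors_give_no_edge(self):
        nodes = _feature_nodes(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert build_similarity_edges(nodes, threshold=0.8, keep_fraction=1.0) == []

    @pytest.mark.parametrize("n,threshold,keep", [(200, 0.8, 0.005), (60, 0.5, 0.1)])
    def test_matches_brute_force_enumeration(self, rng, n, threshold, keep):
        X = rng.normal(size=(n, 8))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        X = np.abs(X)  # unit-interval-friendly features with dense similarities
        X = X / max(1.0, X.max())
        nodes = _feature_nodes(X)
        got = {(e.u, e.v) for e in build_similarity_edges(nodes, threshold, keep)}
        assert got == _brute_force_similarity(nodes, threshold, keep)

    def test_zero_norm_vector_skipped(self):
        X = np.array([[0.0, 0.0], [0.5, 0.5], [0.5, 0.5]])
        nodes = _feature_nodes(X)
        edges = build_similarity_edges(nodes, threshold=0.8, keep_fraction=1.0)
        ids = {e.u for e in edges} | {e.v for e in edges}
        assert "n000" not in ids and len(edges) == 1


class TestExpressionAggregation:
    def test_quarter_fraction_keeps_top_value(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["m1"], columns=list("abcd"))
        nodes, edges = aggregate_expression_nodes(table, top_fraction=0.25)
        top = [e for e in edges if e.provenance == EdgeProvenance.EXPRESSION_TOP]
        assert len(nodes) == 1 and len(top) == 1
        assert {top[0].u, top[0].v} == {"expr:m1", "d"}

    def test_keep_all_limit(self):
        table = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["m1", "m2"], columns=["a", "b"])
        _, edges = aggregate_expression_nodes(table, top_fraction=1.0)
        top = [e for e in edges if e.provenance == EdgeProvenance.EXPRESSION_TOP]
        assert len(top) == 4

    def test_one_percent_selects_global_argmax(self, rng):
        X = rng.normal(size=(10, 10))
        table = pd.DataFrame(X, index=[f"m{i}" for i in range(10)],
                             columns=[f"g{j}" for j in range(10)])
        _, edges = aggregate_expression_nodes(table, top_fraction=0.01)
        top = [e for e in edges if e.provenance == EdgeProvenance.EXPRESSION_TOP]
        i, j = np.unravel_index(np.argmax(X), X.shape)
        assert len(top) == 1
        assert {top[0].u, top[0].v} == {f"expr:m{i}", f"g{j}"}

    def test_candidate_count_is_ceiling_of_fraction(self, rng):
        table = pd.DataFrame(rng.normal(size=(7, 9)))
        for f in (0.01, 0.1, 0.33, 1.0):
            cells = top_expression_cells(table, f)
            assert len(cells) == math.ceil(f * 63)

    def test_perturbation_link_per_row(self):
        table = pd.DataFrame([[0.5, 1.5]], index=["m1"], columns=["a", "b"])
        nodes, edges = aggregate_expression_nodes(table, top_fraction=0.5)
        pert = [e for e in edges if e.provenance == EdgeProvenance.PERTURBATION]
        assert len(pert) == 1 and pert[0].weight == 1.0
        assert nodes[0].kind == NodeKind.GENE_EXPRESSION


class TestAttachMorphology:
    def test_single_pair_attaches_feature(self):
        genes = {"g1": ContextNode("g1", NodeKind.GENE)}
        feats = {"c1": np.array([0.1, 0.9])}
        out = attach_morphology_to_genes([("g1", "c1")], feats, genes)
        assert np.allclose(out["g1"].feature.values, [0.1, 0.9])
        assert out["g1"].feature.modality == "morphology"

    def test_gene_without_pair_stays_featureless(self):
        genes = {"g1": ContextNode("g1", NodeKind.GENE), "g2": ContextNode("g2", NodeKind.GENE)}
        out = attach_morphology_to_genes([("g1", "c1")], {"c1": np.array([0.5])}, genes)
        assert out["g2"].feature is None

    def test_two_pairs_average_elementwise(self):
        genes = {"g1": ContextNode("g1", NodeKind.GENE)}
        feats = {"c1": np.array([0.2, 0.4]), "c2": np.array([0.6, 0.0])}
        out = attach_morphology_to_genes([("g1", "c1"), ("g1", "c2")], feats, genes)
        assert np.allclose(out["g1"].feature.values, np.mean([[0.2, 0.4], [0.6, 0.0]], axis=0))

    def test_absent_gene_created(self):
        out = attach_morphology_to_genes([("gX", "c1")], {"c1": np.array([0.3])}, {})
        assert out["gX"].kind == NodeKind.GENE and out["gX"].feature is not None


class TestAssembleGraph:
    def test_empty_inputs_empty_graph(self):
        graph = assemble_graph([], [])
        assert graph.summary()["n_nodes"] == 0 and graph.summary()["n_edges"] == 0

    def test_small_graph_degrees(self):
        nodes = [ContextNode(i, NodeKind.MOLECULE) for i in ("a", "b", "c")]
        edges = [ContextEdge("a", "b", 1.0, "perturbation"),
                 ContextEdge("b", "c", 0.9, "similarity")]
        graph = assemble_graph([nodes], [edges])
        assert [graph.degree(x) for x in ("a", "b", "c")] == [1, 2, 1]

    def test_dangling_endpoint_rejected(self):
        nodes = [ContextNode("a", NodeKind.MOLECULE)]
        edges = [ContextEdge("a", "zz", 1.0, "perturbation")]
        with pytest.raises(KeyError, match="zz"):
            assemble_graph([nodes], [edges])

    def test_synthetic_counts_match_generator_bookkeeping(self, small_graph):
        graph, declared = small_graph
        summary = graph.summary()
        assert summary["nodes_per_kind"]["molecule"] == declared["n_molecule_nodes"]
        assert summary["nodes_per_kind"]["morphology"] == declared["n_morphology_nodes"]
        assert summary["nodes_per_kind"]["gene"] == declared["n_gene_nodes"]
        assert summary["nodes_per_kind"]["gene_expression"] == declared["n_expression_nodes"]
        assert summary["edges_per_provenance"]["interaction"] == declared["n_interaction_edges"]
        assert summary["edges_per_provenance"]["similarity"] == declared["n_similarity_edges"]

    def test_graph_is_undirected(self, small_graph):
        graph, _ = small_graph
        for edge in graph.edges()[:200]:
            assert edge.v in graph.neighbors(edge.u)
            assert edge.u in graph.neighbors(edge.v)

    def test_all_weights_in_unit_interval(self, small_graph):
        graph, _ = small_graph
        for edge in graph.edges():
            assert 0.0 < edge.weight <= 1.0
            if edge.provenance == EdgeProvenance.PERTURBATION:
                assert edge.weight == 1.0


class TestSerialization:
    def test_round_trip(self, small_graph, tmp_path):
        graph, _ = small_graph
        graph.save(tmp_path / "g")
        loaded = ContextGraph.load(tmp_path / "g")
        assert loaded.summary() == graph.summary()
        nid = graph.nodes_of_kind(NodeKind.MORPHOLOGY)[0]
        assert np.array_equal(loaded.feature(nid).values, graph.feature(nid).values)
        got = {(e.u, e.v, e.weight, e.provenance) for e in loaded.edges()}
        want = {(e.u, e.v, e.weight, e.provenance) for e in graph.edges()}
        assert got == want
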