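"""Graph store, loaders, metapath construction, sampling, and splitting."""

import numpy as np
import pytest

from hetfactor.hetnet import (
    DEFAULT_METAPATHS,
    EdgeSplit,
    HeteroGraph,
    MetapathSpec,
    NegativeSamplingError,
    ReferentialError,
    SchemaError,
    build_metapath_graph,
    load_hetnet,
    make_split,
    sample_neighbors,
    training_graph,
    verify_dataset_statistics,
)
from conftest import toy_hetgraph
from oracles import brute_force_metapath_counts, random_hetgraph


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _write(path, rows, header="source\ttarget"):
    path.write_text("\n".join([header] + rows) + "\n")
    return str(path)


class TestLoader:
    def test_duplicate_rows_collapse(self, tmp_path):
        gd = _write(tmp_path / "gd.tsv", ["gA\tdX", "gA\tdX", "gB\tdX"])
        g = load_hetnet({"G-D": gd})
        assert g.n_edges("G-D") == 2
        assert g.n_nodes("G") == 2 and g.n_nodes("D") == 1

    def test_empty_files_yield_empty_graph(self, tmp_path):
        gd = _write(tmp_path / "gd.tsv", [])
        g = load_hetnet({"G-D": gd})
        assert all(g.n_nodes(t) == 0 for t in "GDOS")
        assert all(g.n_edges(r) == 0 for r in g.edges)

    def test_unknown_relation_is_schema_error(self, tmp_path):
        f = _write(tmp_path / "x.tsv", ["a\tb"])
        with pytest.raises(SchemaError, match="unknown relation"):
            load_hetnet({"G-X": f})

    def test_same_type_edges_deduplicate_across_orientation(self, tmp_path):
        gg = _write(tmp_path / "gg.tsv", ["gA\tgB", "gB\tgA"])
        gd = _write(tmp_path / "gd.tsv", ["gA\tdX"])
        g = load_hetnet({"G-G": gg, "G-D": gd})
        assert g.n_edges("G-G") == 1

    def test_feature_table_defines_node_universe(self, tmp_path):
        gd = _write(tmp_path / "gd.tsv", ["gA\tdX"])
        feat = _write(tmp_path / "genes.tsv", ["gA\t1.0\t0.0"], header="id\tf1\tf2")
        g = load_hetnet({"G-D": gd}, feature_files={"G": feat})
        assert g.get_features("G").shape == (1, 2)

    def test_dangling_endpoint_is_referential_error(self, tmp_path):
        gd = _write(tmp_path / "gd.tsv", ["gA\tdX", "gMissing\tdX"])
        feat = _write(tmp_path / "genes.tsv", ["gA\t1.0"], header="id\tf1")
        with pytest.raises(ReferentialError, match="gMissing"):
            load_hetnet({"G-D": gd}, feature_files={"G": feat})

    def test_directory_layout_roundtrip(self, tmp_path):
        _write(tmp_path / "gene_disease.tsv", ["gA\tdX"])
        _write(tmp_path / "gene_gene.tsv", ["gA\tgB"])
        g = load_hetnet(str(tmp_path))
        assert g.n_edges("G-D") == 1 and g.n_edges("G-G") == 1

    def test_verify_dataset_statistics_flags_mismatch(self, toy_graph):
        report = verify_dataset_statistics(
            toy_graph,
            node_counts={"G": 3, "D": 2},
            edge_counts={"G-D": 4},
        )
        assert report["ok"]
        report = verify_dataset_statistics(
            toy_graph, node_counts={"G": 99}, edge_counts={}
        )
        assert not report["ok"]
        assert report["node_counts"]["G"]["observed"] == 3


# ---------------------------------------------------------------------------
# Graph validation
# ---------------------------------------------------------------------------


class TestValidation:
    def test_out_of_range_endpoint(self):
        g = toy_hetgraph()
        g.edges["G-D"] = np.array([[0, 5]])
        with pytest.raises(ReferentialError):
            g.validate()

    def test_duplicate_node_ids(self):
        g = toy_hetgraph()
        g.node_ids["G"] = ["g0", "g0", "g2"]
        with pytest.raises(SchemaError, match="duplicate"):
            g.validate()

    def test_heterogeneity_property(self):
        # a single-relation, single-type graph is not heterogeneous
        g = HeteroGraph(
            node_ids={"G": ["a", "b"]},
            edges={"G-G": np.array([[0, 1]])},
        )
        with pytest.raises(SchemaError, match="heterogeneous"):
            g.validate()


# ---------------------------------------------------------------------------
# Metapath graphs
# ---------------------------------------------------------------------------


class TestMetapathGraph:
    def test_two_hop_toy(self):
        # G1-D1, D1-G2 -> single GDG edge (G1, G2) of weight 1
        g = HeteroGraph(
            node_ids={"G": ["G1", "G2"], "D": ["D1"], "O": [], "S": []},
            edges={"G-D": np.array([[0, 0], [1, 0]])},
        )
        mg = build_metapath_graph(g, DEFAULT_METAPATHS["GDG"])
        dense = mg.adjacency.toarray()
        assert dense[0, 1] == 1 and dense[1, 0] == 1
        assert np.trace(dense) == 0 and dense.sum() == 2

    def test_no_intermediates_gives_empty_adjacency(self):
        g = HeteroGraph(node_ids={"G": ["G1", "G2"], "D": [], "O": [], "S": []})
        mg = build_metapath_graph(g, DEFAULT_METAPATHS["GDG"])
        assert mg.adjacency.nnz == 0

    def test_length_one_metapath_is_relation_identity(self, toy_graph):
        mg = build_metapath_graph(toy_graph, DEFAULT_METAPATHS["GG"])
        expected = {(0, 1), (1, 0)}
        got = set(zip(*mg.adjacency.nonzero()))
        assert got == expected

    def test_weights_are_bipartite_coproducts(self, small_synth):
        g, _, _ = small_synth
        B = g.biadjacency("G-D").toarray()
        expected = B @ B.T
        np.fill_diagonal(expected, 0)
        mg = build_metapath_graph(g, DEFAULT_METAPATHS["GDG"])
        assert np.array_equal(mg.adjacency.toarray(), expected)

    @pytest.mark.parametrize("name", ["GG", "GDG", "GOG", "DGD", "DSD"])
    @pytest.mark.parametrize("trial", range(3))
    def test_oracle_equivalence_random_graphs(self, name, trial):
        rng = np.random.default_rng(100 * trial + sum(map(ord, name)))
        g = random_hetgraph(rng, max_nodes=40)
        mg = build_metapath_graph(g, DEFAULT_METAPATHS[name])
        expected = brute_force_metapath_counts(g, DEFAULT_METAPATHS[name])
        dense = mg.adjacency.toarray()
        got = {
            (i, j): int(dense[i, j]) for i, j in zip(*np.nonzero(dense))
        }
        assert got == expected

    def test_adjacency_symmetric(self, small_synth):
        g, _, _ = small_synth
        for name in ("GG", "GDG", "GOG", "DGD", "DSD"):
            adj = build_metapath_graph(g, DEFAULT_METAPATHS[name]).adjacency
            assert (adj != adj.T).nnz == 0

    def test_invalid_metapath_spec(self):
        with pytest.raises(SchemaError):
            MetapathSpec("GDS", ("G", "D", "S"))  # endpoints differ
        with pytest.raises(SchemaError):
            MetapathSpec("GSG", ("G", "S", "G"))  # no G-S relation


# ---------------------------------------------------------------------------
# Neighbor sampling
# ---------------------------------------------------------------------------


class TestSampleNeighbors:
    @pytest.fixture()
    def star(self):
        # node 0 connected to 1..250
        n = 251
        edges = np.array([[0, i] for i in range(1, n)])
        g = HeteroGraph(
            node_ids={"G": [f"g{i}" for i in range(n)], "D": ["d0"], "O": [], "S": []},
            edges={"G-G": edges, "G-D": np.array([[0, 0]])},
        )
        return build_metapath_graph(g, DEFAULT_METAPATHS["GG"])

    def test_under_limit_passthrough(self, star):
        out = sample_neighbors(star, node=5, limit=100, seed=0)
        assert list(out) == [0, 5]  # its single neighbor plus itself

    def test_limit_enforced_with_self_appended(self, star):
        out = sample_neighbors(star, node=0, limit=100, seed=0)
        assert len(out) == 101 and out[-1] == 0
        assert len(set(out)) == 101  # sampled without replacement

    def test_seeded_determinism(self, star):
        a = sample_neighbors(star, 0, 100, seed=42)
        b = sample_neighbors(star, 0, 100, seed=42)
        assert np.array_equal(a, b)

    def test_isolated_node_returns_self(self):
        g = HeteroGraph(
            node_ids={"G": ["g0", "g1", "g2"], "D": ["d0"], "O": [], "S": []},
            edges={"G-G": np.array([[0, 1]]), "G-D": np.array([[0, 0]])},
        )
        mg = build_metapath_graph(g, DEFAULT_METAPATHS["GG"])
        assert list(sample_neighbors(mg, 2, 100, seed=0)) == [2]


# ---------------------------------------------------------------------------
# Splitting and negative sampling
# ---------------------------------------------------------------------------


class TestMakeSplit:
    def test_partition_arithmetic(self):
        rng = np.random.default_rng(3)
        # 100 positives on a 25x20 bipartite grid
        keys = rng.choice(25 * 20, size=100, replace=False)
        pos = np.stack([keys // 20, keys % 20], axis=1)
        g = HeteroGraph(
            node_ids={
                "G": [f"g{i}" for i in range(25)],
                "D": [f"d{i}" for i in range(20)],
                "O": ["o0"], "S": ["s0"],
            },
            edges={"G-D": pos, "G-O": np.array([[0, 0]]), "D-S": np.array([[0, 0]])},
        )
        split = make_split(g, test_fraction=0.2, neg_ratio=1.0, seed=0)
        assert len(split.test_pos) == 20 and len(split.test_neg) == 20
        assert len(split.train_pos) == 80 and len(split.train_neg) == 80

    def test_negatives_disjoint_from_original_positives(self, small_synth):
        g, _, _ = small_synth
        split = make_split(g, seed=11)
        pos = {tuple(p) for p in g.edges["G-D"]}
        for part in ("train_neg", "test_neg"):
            assert not ({tuple(p) for p in split.part(part)} & pos)

    def test_split_conservation_and_disjointness(self, small_synth):
        g, _, _ = small_synth
        split = make_split(g, seed=5)
        tr = {tuple(p) for p in split.train_pos}
        te = {tuple(p) for p in split.test_pos}
        assert not (tr & te)
        assert len(tr) + len(te) == g.n_edges("G-D")
        neg = {tuple(p) for p in split.train_neg} | {tuple(p) for p in split.test_neg}
        assert not (neg & (tr | te))

    def test_complete_bipartite_exhausts_non_edges(self):
        pos = np.array([[i, j] for i in range(3) for j in range(2)])
        g = HeteroGraph(
            node_ids={"G": ["a", "b", "c"], "D": ["x", "y"], "O": ["o"], "S": ["s"]},
            edges={"G-D": pos, "G-O": np.array([[0, 0]]), "D-S": np.array([[0, 0]])},
        )
        with pytest.raises(NegativeSamplingError):
            make_split(g, test_fraction=0.5, neg_ratio=1.0, seed=0)

    def test_seeded_determinism(self, small_synth):
        g, _, _ = small_synth
        a, b = make_split(g, seed=9), make_split(g, seed=9)
        for part in EdgeSplit._PARTS:
            assert np.array_equal(a.part(part), b.part(part))

    def test_tsv_roundtrip(self, small_synth, tmp_path):
        g, _, _ = small_synth
        split = make_split(g, seed=2)
        split.save_tsv(str(tmp_path), g)
        back = EdgeSplit.load_tsv(str(tmp_path), g)
        for part in EdgeSplit._PARTS:
            assert np.array_equal(split.part(part), back.part(part))

    def test_training_graph_removes_test_positives(self, small_synth):
        g, _, _ = small_synth
        split = make_split(g, seed=4)
        tg = training_graph(g, split)
        assert tg.n_edges("G-D") == g.n_edges("G-D") - len(split.test_pos)
        remaining = {tuple(p) for p in tg.edges["G-D"]}
        assert not (remaining & {tuple(p) for p in split.test_pos})

    def test_invalid_arguments(self, small_synth):
        g, _, _ = small_synth
        with pytest.raises(ValueError):
            make_split(g, test_fraction=0.0)
        with pytest.raises(ValueError):
            make_split(g, neg_ratio=0.0)
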