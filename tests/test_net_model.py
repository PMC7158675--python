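import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netqap import (
    Network,
    SchemaError,
    SimulationConfig,
    ValidationError,
    generate_cohort,
    read_network,
    read_node_table,
    vectorize,
    write_graphml,
)
from netqap.net_model import (
    DyadicMatrix,
    devectorize,
    dyad_index,
    write_adjacency,
    write_edge_list,
)

from conftest import random_hollow


class TestNodeTable:
    def test_reads_valid_csv(self, toy_frame, tmp_path):
        path = tmp_path / "cohort.csv"
        toy_frame.to_csv(path, index=False)
        table = read_node_table(path)
        assert table.n == 3
        assert table.node_ids == ("A", "B", "C")

    def test_out_of_range_likert_cites_row(self, toy_frame, tmp_path):
        toy_frame.loc[1, "pupil_relevance"] = 9
        path = tmp_path / "cohort.csv"
        toy_frame.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 1"):
            read_node_table(path)

    def test_missing_column_named_in_error(self, toy_frame, tmp_path):
        path = tmp_path / "cohort.csv"
        toy_frame.drop(columns=["gender"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="gender"):
            read_node_table(path)

    def test_duplicate_node_id_rejected(self, toy_frame, tmp_path):
        toy_frame.loc[2, "node_id"] = "A"
        path = tmp_path / "cohort.csv"
        toy_frame.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            read_node_table(path)

    def test_missing_attribute_rejected_at_read(self, toy_frame, tmp_path):
        toy_frame.loc[0, "parent_age"] = np.nan
        path = tmp_path / "cohort.csv"
        toy_frame.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_node_table(path)

    def test_default_cohort_roundtrip_preserves_marginals(self, tmp_path):
        cohort = generate_cohort(SimulationConfig(seed=3)).with_outcome(
            np.ones(49, dtype=int)
        )
        path = tmp_path / "cohort49.csv"
        cohort.to_csv(path)
        table = read_node_table(path)
        assert table.n == 49
        sizes = table.data["class_label"].value_counts().sort_index()
        assert list(sizes) == [18, 12, 9, 10]


class TestNetworkIO:
    def test_edge_list_single_edge(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("sender,receiver\nA,B\n")
        net = read_network(path, ["A", "B", "C"], "school")
        expected = np.zeros((3, 3))
        expected[0, 1] = 1
        assert np.array_equal(net.adjacency, expected)

    def test_self_loop_dropped_with_warning(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("sender,receiver\nA,A\nA,B\n")
        with pytest.warns(UserWarning, match="self-nomination"):
            net = read_network(path, ["A", "B"], "school")
        assert net.adjacency.sum() == 1
        assert net.adjacency[0, 0] == 0

    def test_unknown_node_named_in_error(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("sender,receiver\nA,Z\n")
        with pytest.raises(ValidationError, match="'Z'"):
            read_network(path, ["A", "B"], "school")

    def test_duplicate_edges_collapse(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("sender,receiver\nA,B\nA,B\n")
        net = read_network(path, ["A", "B"], "school")
        assert net.adjacency[0, 1] == 1
        assert net.adjacency.sum() == 1

    def test_non_square_adjacency_rejected(self, tmp_path):
        path = tmp_path / "adj.csv"
        path.write_text(",A,B,C\nA,0,1,0\nB,0,0,1\n")
        with pytest.raises(SchemaError, match="square"):
            read_network(path, ["A", "B", "C"], "school")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_adjacency_roundtrip_identity(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        adj = random_hollow(rng, 7, binary=True).astype(int)
        nodes = [f"N{i}" for i in range(7)]
        net = Network(nodes=nodes, adjacency=adj, context="school")
        path = tmp_path / "adj.csv"
        write_adjacency(net, path)
        back = read_network(path, nodes, "school")
        assert np.array_equal(back.adjacency, adj)

    def test_edge_list_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        adj = random_hollow(rng, 6, binary=True).astype(int)
        nodes = [f"N{i}" for i in range(6)]
        net = Network(nodes=nodes, adjacency=adj, context="after_school")
        path = tmp_path / "edges.csv"
        write_edge_list(net, path)
        back = read_network(path, nodes, "after_school")
        assert np.array_equal(back.adjacency, adj)

    def test_nomination_cap_cohort_network_accepted(self, study49, tmp_path):
        _, networks = study49
        net = networks["school"]
        assert net.n == 49
        assert net.out_degrees().max() <= 8
        path = tmp_path / "school.csv"
        write_adjacency(net, path)
        assert read_network(path, net.nodes, "school").n == 49

    def test_hollow_invariant_enforced(self):
        adj = np.eye(3, dtype=int)
        with pytest.raises(ValidationError, match="diagonal"):
            Network(nodes=["A", "B", "C"], adjacency=adj, context="school")


class TestGraphML:
    def test_export_has_nodes_and_attributes(self, toy_table, tmp_path):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 2] = 1
        net = Network(nodes=toy_table.node_ids, adjacency=adj, context="school")
        path = tmp_path / "net.graphml"
        write_graphml(net, toy_table, path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == {"A", "B", "C"}
        for _, data in g.nodes(data=True):
            assert "gender" in data and "pupil_relevance" in data

    def test_roundtrip_preserves_adjacency(self, toy_table, tmp_path):
        rng = np.random.default_rng(9)
        adj = random_hollow(rng, 3, binary=True).astype(int)
        net = Network(nodes=toy_table.node_ids, adjacency=adj, context="school")
        path = tmp_path / "net.graphml"
        write_graphml(net, toy_table, path)
        g = nx.read_graphml(path)
        back = nx.to_numpy_array(g, nodelist=list(toy_table.node_ids))
        assert np.array_equal(back.astype(int), adj)

    def test_mismatched_rosters_fail_loudly(self, toy_table):
        net = Network(nodes=["X", "Y", "Z"], adjacency=np.zeros((3, 3)), context="school")
        with pytest.raises(ValidationError):
            write_graphml(net, toy_table, "unused.graphml")


class TestVectorize:
    def test_three_by_three_has_six_cells(self):
        m = np.arange(9, dtype=float).reshape(3, 3)
        v = vectorize(m)
        assert v.shape == (6,)
        # row-major, diagonal skipped
        assert list(v) == [1, 2, 3, 5, 6, 7]

    def test_cohort_matrix_has_2352_cells(self):
        assert vectorize(np.zeros((49, 49))).shape == (2352,)

    def test_symmetric_matrix_pairs_agree(self):
        rng = np.random.default_rng(2)
        m = random_hollow(rng, 6)
        m = m + m.T
        v = vectorize(m)
        idx = dyad_index(6)
        pos = {(i, j): k for k, (i, j) in enumerate(map(tuple, idx))}
        for (i, j), k in pos.items():
            assert v[k] == v[pos[(j, i)]]

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2**31 - 1))
    def test_length_and_devectorize_inverse(self, n, seed):
        m = random_hollow(np.random.default_rng(seed), n)
        v = vectorize(m)
        assert v.shape == (n * (n - 1),)
        assert np.array_equal(devectorize(v, n), m)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DyadicMatrix(values=np.zeros((1, 1)), label="x")
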