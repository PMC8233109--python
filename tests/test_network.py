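import networkx as nx
import numpy as np
import pytest

from targetcontrol import DirectedNetwork, RankedTargetSet, make_tree_benchmark
from targetcontrol.io import (
    read_annotations,
    read_edge_list,
    read_network,
    write_edge_list,
)

from conftest import random_instance


class TestTotalDegree:
    def test_counts_in_plus_out(self):
        net = DirectedNetwork.from_edges(
            [("h", "a"), ("h", "b"), ("h", "c"), ("x", "h"), ("y", "h")],
            nodes=["iso"],
        )
        assert net.total_degree("iso") == 0
        assert net.total_degree("h") == 5

    def test_middle_of_path(self, path_net):
        assert path_net.total_degree("v2") == 2

    def test_reciprocal_pair_counts_twice(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "a")])
        assert net.total_degree("a") == 2
        assert net.total_degree("b") == 2

    def test_self_loop_contributes_two(self):
        net = DirectedNetwork.from_edges([("a", "a"), ("a", "b")])
        assert net.total_degree("a") == 3

    def test_unknown_node_named_in_error(self, path_net):
        with pytest.raises(KeyError, match="v99"):
            path_net.total_degree("v99")


class TestReachability:
    def test_forward_and_backward_on_path(self, path_net):
        assert path_net.reachable_set("v1", "forward") == {"v1", "v2", "v3", "v4", "v5"}
        assert path_net.reachable_set("v1", "backward") == {"v1"}
        assert path_net.reachable_set("v3", "backward") == {"v1", "v2", "v3"}

    def test_cycle_reaches_everything(self, cycle3):
        for node in cycle3.nodes:
            assert cycle3.reachable_set(node, "forward") == {"a", "b", "c"}
            assert cycle3.reachable_set(node, "backward") == {"a", "b", "c"}


class TestControlSubgraph:
    def test_drops_nodes_off_walks(self):
        net = DirectedNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("a", "d")]  # d dangles off every a->c walk
        )
        sub = net.control_subgraph("a", {"c"})
        assert set(sub.nodes) == {"a", "b", "c"}

    def test_unreachable_target_leaves_only_driver(self):
        net = DirectedNetwork.from_edges([("a", "b")], nodes=["z"])
        sub = net.control_subgraph("a", {"z"})
        assert set(sub.nodes) == {"a"}

    def test_empty_target_set_rejected(self, path_net):
        with pytest.raises(ValueError, match="[Nn]othing to control"):
            path_net.control_subgraph("v1", set())

    def test_matches_walk_enumeration_on_tree(self):
        """Retained nodes = exactly the nodes on some root-to-target walk.

        Cross-checked against a brute-force enumeration of all directed
        walks of length <= N - 1 from the root.
        """
        bench = make_tree_benchmark(4, seed=3)
        g = bench.network.graph
        targets = set(bench.targets)
        on_walk: set[str] = set()

        def extend(walk):
            if walk[-1] in targets:
                on_walk.update(walk)
            if len(walk) <= bench.network.n_nodes:  # walks up to length N-1
                for nxt in g.successors(walk[-1]):
                    extend(walk + [nxt])

        extend([bench.root])
        sub = bench.network.control_subgraph(bench.root, targets)
        assert set(sub.nodes) == on_walk | {bench.root}

    def test_idempotent_and_monotone(self, rng):
        for _ in range(25):
            net, driver, ranked = random_instance(rng)
            targets = list(ranked)
            sub = net.control_subgraph(driver, targets)
            surviving = [t for t in targets if t in sub]
            if not surviving:
                assert set(sub.nodes) == {driver}
                continue
            again = sub.control_subgraph(driver, surviving)
            assert again == sub
            # every non-driver retained node is fed by at least one edge
            for node in sub.nodes:
                if node != driver:
                    assert sub.graph.in_degree(node) >= 1
            # adding targets never removes nodes
            smaller = net.control_subgraph(driver, targets[:1])
            assert set(smaller.nodes) <= set(sub.nodes)


class TestConstruction:
    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DirectedNetwork.from_edges([("a", "b"), ("a", "b")])

    def test_undirected_graph_rejected(self):
        with pytest.raises(TypeError, match="[Dd]irected"):
            DirectedNetwork(nx.Graph([("a", "b")]))

    def test_ranked_targets_validate_membership(self, path_net):
        with pytest.raises(KeyError):
            RankedTargetSet(["v1", "zz"], path_net)
        with pytest.raises(ValueError):
            RankedTargetSet(["v1", "v1"], path_net)
        with pytest.raises(ValueError):
            RankedTargetSet([], path_net)

    def test_ranking_restriction_preserves_order(self):
        ranked = RankedTargetSet(["c", "a", "b"])
        assert ranked.restricted_to({"a", "b"}).targets == ("a", "b")
        assert ranked.restricted_to(set()) is None


class TestIO:
    @pytest.mark.parametrize("delim,header", [("\t", True), (",", False)])
    def test_edge_list_round_trip(self, tmp_path, delim, header):
        lines = []
        if header:
            lines.append(delim.join(["source", "target", "sign"]))
        lines += [
            delim.join(["a", "b", "activation"]),
            delim.join(["b", "c", "inhibition"]),
            delim.join(["c", "a", "+1"]),
        ]
        path = tmp_path / "edges.txt"
        path.write_text("\n".join(lines) + "\n")
        net = read_edge_list(path)
        assert net.n_nodes == 3 and net.n_edges == 3
        assert net.edge_sign("a", "b") == 1
        assert net.edge_sign("b", "c") == -1
        out = tmp_path / "out.tsv"
        write_edge_list(net, out)
        assert read_edge_list(out) == net

    def test_bad_sign_reports_line(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("a,b,activation\nb,c,sometimes\n")
        with pytest.raises(ValueError, match="2"):
            read_edge_list(path)

    def test_graphml_round_trip_and_undirected_rejection(self, tmp_path, path_net):
        good = tmp_path / "net.graphml"
        nx.write_graphml(path_net.graph, good)
        assert read_network(good) == path_net
        bad = tmp_path / "undirected.graphml"
        nx.write_graphml(nx.Graph([("a", "b")]), bad)
        with pytest.raises(ValueError, match="directed"):
            read_network(bad)

    def test_gml_reader(self, tmp_path, path_net):
        path = tmp_path / "net.gml"
        nx.write_gml(path_net.graph, path)
        assert read_network(path) == path_net

    def test_annotations(self, tmp_path):
        path = tmp_path / "annot.csv"
        path.write_text("node,class\nIFNG,secreted\nSTAT1,signaling\nX,unclassified\n")
        annot = read_annotations(path)
        assert annot == {"IFNG": "secreted", "STAT1": "signaling", "X": "unclassified"}
        bad = tmp_path / "bad.csv"
        bad.write_text("node,class\nA,membrane\n")
        with pytest.raises(ValueError, match="membrane"):
            read_annotations(bad)
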