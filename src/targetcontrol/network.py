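"""Directed-network data model.

The network is the substrate of every controllability computation: a simple
directed graph whose adjacency is treated as binary (an edge either exists or
it does not) regardless of its biological sign.  Edge signs (activation /
inhibition) are stored for annotation and reporting only.

Node identifiers are case-sensitive strings.  Internal dense indices are
assigned by sorted identifier order, so every run is reproducible independent
of insertion order.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from typing import Optional

import networkx as nx

__all__ = [
    "DirectedNetwork",
    "RankedTargetSet",
    "FUNCTIONAL_CLASSES",
    "SIGN_ALIASES",
]

#: Functional classes used to annotate macrophage-network genes.
FUNCTIONAL_CLASSES = ("sensing", "signaling", "transcription", "secreted")

#: Accepted spellings for the optional edge-sign column.
SIGN_ALIASES: Mapping[str, int] = {
    "activation": 1,
    "inhibition": -1,
    "+1": 1,
    "-1": -1,
    "1": 1,
    "+": 1,
    "-": -1,
}


class DirectedNetwork:
    """A simple directed graph with optionally signed edges.

    Parameters
    ----------
    graph:
        A :class:`networkx.DiGraph`.  Edge attribute ``sign`` (``+1``, ``-1``
        or absent) is preserved.  Undirected graphs are rejected: the
        subgraph reduction at the heart of the method is meaningful for
        directed networks only.
    """

    def __init__(self, graph: nx.DiGraph):
        if not isinstance(graph, nx.DiGraph) or graph.is_multigraph():
            raise TypeError(
                "DirectedNetwork requires a simple networkx.DiGraph; "
                "undirected or multigraph input is not supported (the method "
                "is conceived for directed networks only)"
            )
        if graph.number_of_nodes() == 0:
            raise ValueError("network must contain at least one node")
        for node in graph.nodes:
            if not isinstance(node, str):
                raise TypeError(f"node identifiers must be strings, got {node!r}")
        self._graph = graph
        self._nodes = tuple(sorted(graph.nodes))
        self._index = {node: i for i, node in enumerate(self._nodes)}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Optional[Iterable[str]] = None,
    ) -> "DirectedNetwork":
        """Build a network from ``(source, target[, sign])`` tuples.

        ``nodes`` may add isolated nodes.  Duplicate edges are rejected
        because a binary adjacency admits at most one edge per ordered pair.
        """
        graph = nx.DiGraph()
        if nodes is not None:
            graph.add_nodes_from(str(n) for n in nodes)
        seen: set[tuple[str, str]] = set()
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                sign = None
            else:
                u, v, sign = edge
                if isinstance(sign, str):
                    key = sign.strip().lower()
                    if key not in SIGN_ALIASES:
                        raise ValueError(f"unrecognized edge sign {sign!r}")
                    sign = SIGN_ALIASES[key]
                elif sign is not None and sign not in (1, -1):
                    raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
            u, v = str(u), str(v)
            if (u, v) in seen:
                raise ValueError(f"duplicate edge {u!r} -> {v!r}")
            seen.add((u, v))
            if sign is None:
                graph.add_edge(u, v)
            else:
                graph.add_edge(u, v, sign=sign)
        return cls(graph)

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(self._graph.copy())

    # -- basic queries -------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        """Nodes in sorted order (the canonical dense indexing)."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self, data: bool = False):
        return self._graph.edges(data=data)

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and set(
            self._graph.edges
        ) == set(other._graph.edges)

    def index_of(self, node: str) -> int:
        self._require(node)
        return self._index[node]

    def edge_sign(self, source: str, target: str) -> Optional[int]:
        return self._graph.edges[source, target].get("sign")

    def _require(self, node: str) -> None:
        if node not in self._graph:
            raise KeyError(f"unknown node id {node!r}")

    # -- degree and reachability --------------------------------------------

    def total_degree(self, node: str) -> int:
        """In-degree plus out-degree on the binary adjacency.

        A reciprocal pair ``i->j, j->i`` contributes 2 to each endpoint; a
        self-loop contributes 2 (one in, one out).
        """
        self._require(node)
        return self._graph.in_degree(node) + self._graph.out_degree(node)

    def total_degrees(self) -> dict[str, int]:
        return {n: self.total_degree(n) for n in self._nodes}

    def reachable_set(self, source: str, direction: str = "forward") -> set[str]:
        """Nodes reachable from ``source`` (forward) or reaching it (backward).

        The source itself is always included (length-0 walk).
        """
        self._require(source)
        if direction == "forward":
            return nx.descendants(self._graph, source) | {source}
        if direction == "backward":
            return nx.ancestors(self._graph, source) | {source}
        raise ValueError("direction must be 'forward' or 'backward'")

    # -- subgraph reduction ---------------------------------------------------

    def control_subgraph(self, driver: str, targets: Iterable[str]) -> "DirectedNetwork":
        """Restrict the network to nodes on driver-to-target walks.

        The retained node set is (forward-reachable from the driver) inter
        (backward-reachable from any target), plus the driver itself.  Targets
        unreachable from the driver drop out of the result.  All original
        edges between retained nodes are kept.
        """
        targets = set(targets)
        if not targets:
            raise ValueError("nothing to control: empty target set")
        self._require(driver)
        for t in targets:
            self._require(t)
        forward = self.reachable_set(driver, "forward")
        backward: set[str] = set()
        for t in targets:
            backward |= self.reachable_set(t, "backward")
        keep = (forward & backward) | {driver}
        return DirectedNetwork(self._graph.subgraph(keep).copy())

    def without_nodes(self, remove: Iterable[str]) -> "DirectedNetwork":
        """Copy of the network with ``remove`` deleted (for attack simulations)."""
        remove = set(remove)
        keep = [n for n in self._nodes if n not in remove]
        if not keep:
            raise ValueError("removal would leave an empty network")
        return DirectedNetwork(self._graph.subgraph(keep).copy())


class RankedTargetSet:
    """An ordered target set t1 > t2 > ... > tS (position 1 = highest rank).

    The ordering is total: ties must be broken before construction.
    """

    def __init__(self, targets: Sequence[str], network: Optional[DirectedNetwork] = None):
        targets = [str(t) for t in targets]
        if not targets:
            raise ValueError("ranked target set must be non-empty")
        if len(set(targets)) != len(targets):
            raise ValueError("ranked target set contains duplicates")
        if network is not None:
            missing = [t for t in targets if t not in network]
            if missing:
                raise KeyError(f"targets not in network: {missing}")
            if len(targets) > network.n_nodes:
                raise ValueError("more targets than network nodes")
        self._targets = tuple(targets)

    @property
    def targets(self) -> tuple[str, ...]:
        return self._targets

    def __iter__(self):
        return iter(self._targets)

    def __len__(self) -> int:
        return len(self._targets)

    def __getitem__(self, i):
        return self._targets[i]

    def __contains__(self, t) -> bool:
        return t in self._targets

    def __eq__(self, other) -> bool:
        if isinstance(other, RankedTargetSet):
            return self._targets == other._targets
        return NotImplemented

    def __repr__(self) -> str:
        return f"RankedTargetSet({list(self._targets)!r})"

    def restricted_to(self, surviving: Iterable[str]) -> Optional["RankedTargetSet"]:
        """Sub-ranking keeping only ``surviving`` nodes, preserving order.

        Returns ``None`` when no target survives (the caller decides how to
        score that, e.g. as total loss of control).
        """
        surviving = set(surviving)
        kept = [t for t in self._targets if t in surviving]
        return RankedTargetSet(kept) if kept else None

    def permuted(self, order: Sequence[int]) -> "RankedTargetSet":
        """Re-rank by the given permutation of positions (testing helper)."""
        if sorted(order) != list(range(len(self._targets))):
            raise ValueError("order must be a permutation of target positions")
        return RankedTargetSet([self._targets[i] for i in order])
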