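"""Readers and writers for the plain-text formats the toolkit consumes.

Edge lists (TSV/CSV with optional sign column), GraphML/GML networks, node
annotation tables, ranked-target files, and expression matrices with their
sample-metadata sidecar.  Undirected network files are rejected: the
subgraph reduction is meaningful for directed networks only.
"""
from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Mapping
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .activation import ActivationTable, ExpressionTable, FoldChangeVector
from .network import FUNCTIONAL_CLASSES, SIGN_ALIASES, DirectedNetwork, RankedTargetSet
from .stepwise import StepwiseResult

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_network",
    "read_annotations",
    "read_ranked_targets",
    "write_ranked_targets",
    "read_expression",
    "write_expression",
    "write_centrality_table",
    "write_stepwise_json",
    "write_fold_change",
]

_HEADER_WORDS = {"source", "target", "src", "dst", "from", "to", "sign", "interaction"}


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_edge_list(path: Union[str, Path]) -> DirectedNetwork:
    """Read a 2- or 3-column edge list (source, target[, sign]).

    Tab- or comma-delimited; an optional header row is auto-detected.  The
    sign column accepts activation / inhibition / +1 / -1 / 1 / + / -.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty edge list")
    delim = _detect_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    first = [c.strip().lower() for c in rows[0]]
    if any(c in _HEADER_WORDS for c in first):
        rows = rows[1:]
    edges = []
    for lineno, row in enumerate(rows, start=1):
        row = [c.strip() for c in row if c.strip() != ""]
        if len(row) == 2:
            edges.append((row[0], row[1]))
        elif len(row) == 3:
            key = row[2].lower()
            if key not in SIGN_ALIASES:
                raise ValueError(
                    f"{path}:{lineno}: unrecognized sign {row[2]!r} "
                    f"(accepted: {sorted(SIGN_ALIASES)})"
                )
            edges.append((row[0], row[1], SIGN_ALIASES[key]))
        else:
            raise ValueError(
                f"{path}:{lineno}: expected 2 or 3 columns, got {len(row)}"
            )
    return DirectedNetwork.from_edges(edges)


def write_edge_list(
    network: DirectedNetwork, path: Union[str, Path], delimiter: str = "\t"
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["source", "target", "sign"])
        for u, v, data in sorted(network.edges(data=True)):
            sign = data.get("sign")
            label = {1: "activation", -1: "inhibition", None: ""}[sign]
            writer.writerow([u, v, label])


def read_network(path: Union[str, Path]) -> DirectedNetwork:
    """Dispatch on file suffix: .graphml, .gml, else edge list."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        graph = nx.read_graphml(path)
    elif suffix == ".gml":
        graph = nx.read_gml(path)
    else:
        return read_edge_list(path)
    if not graph.is_directed():
        raise ValueError(
            f"{path}: undirected network; the toolkit analyses directed "
            "networks only (the subgraph reduction has no meaning otherwise)"
        )
    graph = nx.DiGraph(graph)  # drop multi-edges / attributes we do not model
    return DirectedNetwork(nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes}))


def read_annotations(
    path: Union[str, Path], network: Optional[DirectedNetwork] = None
) -> dict[str, str]:
    """Node annotation CSV with columns ``node`` and ``class``.

    Classes must be one of sensing / signaling / transcription / secreted or
    ``unclassified``; one class per node.
    """
    table = pd.read_csv(path)
    for col in ("node", "class"):
        if col not in table.columns:
            raise ValueError(f"{path}: annotation file lacks column {col!r}")
    allowed = set(FUNCTIONAL_CLASSES) | {"unclassified"}
    out: dict[str, str] = {}
    for _, row in table.iterrows():
        node, cls = str(row["node"]), str(row["class"]).strip().lower()
        if cls not in allowed:
            raise ValueError(f"{path}: unknown class {cls!r} for node {node!r}")
        if node in out and out[node] != cls:
            raise ValueError(f"{path}: node {node!r} annotated with two classes")
        if network is not None and node not in network:
            raise KeyError(f"{path}: annotated node {node!r} not in network")
        out[node] = cls
    return out


def read_ranked_targets(
    path: Union[str, Path], network: Optional[DirectedNetwork] = None
) -> RankedTargetSet:
    """One target id per line, highest rank first (blank lines/# ignored)."""
    targets = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return RankedTargetSet(targets, network)


def write_ranked_targets(targets: RankedTargetSet, path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in targets))


def read_expression(
    expr_path: Union[str, Path], meta_path: Union[str, Path]
) -> ExpressionTable:
    """Genes-by-samples CSV plus a sidecar sample metadata CSV."""
    values = pd.read_csv(expr_path, index_col=0)
    values.index = values.index.map(str)
    meta = pd.read_csv(meta_path)
    for col in ("sample", "subject", "group", "condition"):
        if col not in meta.columns:
            raise ValueError(f"{meta_path}: metadata lacks column {col!r}")
    meta = meta.set_index("sample")
    return ExpressionTable(values=values, meta=meta)


def write_expression(
    table: ExpressionTable, expr_path: Union[str, Path], meta_path: Union[str, Path]
) -> None:
    table.values.to_csv(expr_path, float_format="%.10g")
    table.meta.to_csv(meta_path)


def write_centrality_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, float_format="%.10g")


def write_stepwise_json(
    results: Union[StepwiseResult, Iterable[StepwiseResult], Mapping[str, StepwiseResult]],
    path: Union[str, Path],
) -> None:
    """Full per-step logs as JSON (one object per driver)."""
    if isinstance(results, StepwiseResult):
        results = [results]
    elif isinstance(results, Mapping):
        results = list(results.values())
    payload = [r.to_dict() for r in results]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_fold_change(fc: FoldChangeVector, path: Union[str, Path]) -> None:
    frame = pd.DataFrame({"delta": fc.delta, "log2_delta": fc.score})
    frame.index.name = "gene"
    frame.to_csv(path, float_format="%.10g")


def activation_to_csv(activation: ActivationTable, path: Union[str, Path]) -> None:
    activation.values.to_csv(path, float_format="%.10g")
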