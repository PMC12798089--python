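"""Readers and writers for graphs, query results, and mined routes.

The canonical on-disk format is a versioned graph JSON (lossless round
trip for both whole graphs and result sets); node/edge tables and
GraphML are export-only views.  All writers are deterministic: fixed key
ordering and fixed row ordering, so identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import networkx as nx
import pandas as pd

from .core_model import (
    Edge,
    EdgeKind,
    FormatError,
    GraphRecord,
    MoleculeNode,
    NOCGraph,
    ReactionNode,
    ResultSet,
)

__all__ = [
    "write_tables",
    "write_graph_json",
    "read_graph_json",
    "write_graphml",
    "routes_to_reaction_strings",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def _node_row(node) -> dict:
    if isinstance(node, MoleculeNode):
        kind, smiles = "molecule", node.smiles
    else:
        kind, smiles = "reaction", node.rxn_smiles
    return {
        "uid": node.uid,
        "kind": kind,
        "smiles": smiles,
        "properties": json.dumps(node.properties, sort_keys=True),
    }


def write_tables(result: ResultSet, with_records_id: bool = True
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of a result set as two DataFrames.

    With ``with_records_id`` each row carries the index of the record it
    came from; without it records are merged and duplicate rows
    collapsed.  Rows are ordered by (record, uid) for determinism.
    """
    node_rows, edge_rows = [], []
    for rec_id, record in enumerate(result.records):
        for uid in sorted(record.nodes):
            row = _node_row(record.nodes[uid])
            if with_records_id:
                row = {"record_id": rec_id, **row}
            node_rows.append(row)
        for edge in sorted(record.edges, key=lambda e: (e.kind.value, e.source, e.target)):
            row = {"kind": edge.kind.value, "source": edge.source, "target": edge.target}
            if with_records_id:
                row = {"record_id": rec_id, **row}
            edge_rows.append(row)
    node_cols = (["record_id"] if with_records_id else []) + [
        "uid", "kind", "smiles", "properties"]
    edge_cols = (["record_id"] if with_records_id else []) + ["kind", "source", "target"]
    nodes = pd.DataFrame(node_rows, columns=node_cols)
    edges = pd.DataFrame(edge_rows, columns=edge_cols)
    if not with_records_id:
        nodes = nodes.drop_duplicates(ignore_index=True)
        edges = edges.drop_duplicates(ignore_index=True)
    return nodes, edges


# ---------------------------------------------------------------------------
# canonical graph JSON


def _nodes_payload(nodes) -> tuple[list, list]:
    molecules, reactions = [], []
    for node in nodes:
        if isinstance(node, MoleculeNode):
            molecules.append({"uid": node.uid, "smiles": node.smiles,
                              "properties": node.properties})
        else:
            reactions.append({"uid": node.uid, "rxn_smiles": node.rxn_smiles,
                              "properties": node.properties})
    molecules.sort(key=lambda d: d["uid"])
    reactions.sort(key=lambda d: d["uid"])
    return molecules, reactions


def _edges_payload(edges) -> list:
    return [{"kind": e.kind.value, "source": e.source, "target": e.target}
            for e in sorted(edges, key=lambda e: (e.kind.value, e.source, e.target))]


def write_graph_json(obj: Union[NOCGraph, ResultSet], path) -> None:
    """Serialize a graph or result set to the canonical versioned JSON."""
    if isinstance(obj, NOCGraph):
        molecules, reactions = _nodes_payload(obj.nodes())
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "graph",
            "molecules": molecules,
            "reactions": reactions,
            "edges": _edges_payload(obj.edges),
        }
    elif isinstance(obj, ResultSet):
        records = []
        for record in obj.records:
            molecules, reactions = _nodes_payload(record.nodes.values())
            records.append({"molecules": molecules, "reactions": reactions,
                            "edges": _edges_payload(record.edges)})
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "resultset",
            "query": obj.query,
            "params": obj.params,
            "records": records,
        }
    else:
        raise FormatError(f"cannot serialize {type(obj).__name__}")
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def _nodes_from_payload(payload) -> dict:
    nodes = {}
    for d in payload.get("molecules", []):
        node = MoleculeNode(d["uid"], d["smiles"], dict(d.get("properties", {})))
        nodes[node.uid] = node
    for d in payload.get("reactions", []):
        node = ReactionNode(d["uid"], d["rxn_smiles"], dict(d.get("properties", {})))
        nodes[node.uid] = node
    return nodes


def _edges_from_payload(payload) -> set[Edge]:
    return {Edge(EdgeKind(d["kind"]), d["source"], d["target"])
            for d in payload.get("edges", [])}


def read_graph_json(path) -> Union[NOCGraph, ResultSet]:
    """Load a file produced by :func:`write_graph_json`."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read graph JSON {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise FormatError(f"{path} is not a graph JSON file (no schema_version)")
    version = payload["schema_version"]
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"unsupported schema version {version}; this build reads version "
            f"{SCHEMA_VERSION}")
    kind = payload.get("kind")
    if kind == "graph":
        graph = NOCGraph()
        for node in _nodes_from_payload(payload).values():
            graph.merge_node(node)
        for edge in _edges_from_payload(payload):
            graph.merge_edge(edge)
        return graph
    if kind == "resultset":
        records = [GraphRecord(nodes=_nodes_from_payload(r),
                               edges=_edges_from_payload(r))
                   for r in payload.get("records", [])]
        return ResultSet(records=records, query=payload.get("query", ""),
                         params=payload.get("params", {}))
    raise FormatError(f"unknown payload kind {kind!r} in {path}")


# ---------------------------------------------------------------------------
# GraphML


def write_graphml(graph: NOCGraph, path) -> None:
    """Export as GraphML with node attributes kind/smiles and edge
    attribute kind, importable by mainstream graph tools."""
    g = nx.DiGraph()
    for uid in sorted(graph.molecules):
        g.add_node(uid, kind="molecule", smiles=graph.molecules[uid].smiles)
    for uid in sorted(graph.reactions):
        g.add_node(uid, kind="reaction", smiles=graph.reactions[uid].rxn_smiles)
    for e in sorted(graph.edges, key=lambda e: (e.kind.value, e.source, e.target)):
        g.add_edge(e.source, e.target, kind=e.kind.value)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# routes as reaction-string lists


def _topological_reactions(record: GraphRecord) -> list[str]:
    """Reactions of one record in deterministic topological order:
    starting-material side first, target-producing reaction last; ties
    broken by uid.  Falls back to uid order for any cyclic remainder."""
    import heapq

    reactions = sorted(u for u, n in record.nodes.items() if isinstance(n, ReactionNode))
    products: dict[str, set[str]] = {r: set() for r in reactions}
    consumers_of_mol: dict[str, set[str]] = {}
    producers_of_mol: dict[str, set[str]] = {}
    for e in record.edges:
        if e.kind is EdgeKind.PRODUCT:
            producers_of_mol.setdefault(e.target, set()).add(e.source)
        else:
            consumers_of_mol.setdefault(e.source, set()).add(e.target)
    succ: dict[str, set[str]] = {r: set() for r in reactions}
    indeg = {r: 0 for r in reactions}
    for mol, prods in producers_of_mol.items():
        for r in prods:
            for c in consumers_of_mol.get(mol, ()):
                if c != r and c not in succ[r]:
                    succ[r].add(c)
    for r in reactions:
        for c in succ[r]:
            indeg[c] += 1
    heap = [r for r in reactions if indeg[r] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        r = heapq.heappop(heap)
        order.append(r)
        for c in sorted(succ[r]):
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    leftover = [r for r in reactions if r not in set(order)]
    return order + leftover


def routes_to_reaction_strings(result: ResultSet, with_records_id: bool = True
                               ) -> list:
    """Reaction strings of each record, topologically ordered.

    Grouped per record when ``with_records_id``; otherwise flattened into
    a single deduplicated list (first occurrence wins).
    """
    grouped = []
    for record in result.records:
        grouped.append([record.nodes[r].rxn_smiles
                        for r in _topological_reactions(record)])
    if with_records_id:
        return grouped
    flat, seen = [], set()
    for strings in grouped:
        for s in strings:
            if s not in seen:
                seen.add(s)
                flat.append(s)
    return flat
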