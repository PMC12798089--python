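"""Query layer over the in-memory bipartite graph.

Provides idempotent merge entry points, neighbourhood accessors,
network-level statistics (roots, leaves, OR nodes, edge averages),
predicate-based subgraph selection, and synthetic-tree extraction (the
backward-reachable closure of a target under bounds).
"""

from __future__ import annotations

from collections import deque
from typing import Callable, Optional, Union

from .core_model import (
    NO_BOUNDS,
    Edge,
    EdgeKind,
    GraphRecord,
    GraphStats,
    MoleculeNode,
    NOCGraph,
    ReactionNode,
    ResultSet,
    RouteQueryBounds,
    SyntheticTree,
)

__all__ = [
    "merge_node",
    "merge_edge",
    "producers",
    "consumers",
    "reactants_of",
    "products_of",
    "or_nodes",
    "stats",
    "select",
    "synthetic_tree",
]


def merge_node(graph: NOCGraph, node: Union[MoleculeNode, ReactionNode]) -> NOCGraph:
    graph.merge_node(node)
    return graph


def merge_edge(graph: NOCGraph, edge: Edge) -> NOCGraph:
    graph.merge_edge(edge)
    return graph


def producers(graph: NOCGraph, molecule_uid: str) -> set[str]:
    """Reactions with a PRODUCT edge into this molecule."""
    return graph.producers(molecule_uid)


def consumers(graph: NOCGraph, molecule_uid: str) -> set[str]:
    """Reactions this molecule feeds through a REACTANT edge."""
    return graph.consumers(molecule_uid)


def reactants_of(graph: NOCGraph, reaction_uid: str) -> set[str]:
    return graph.reactants_of(reaction_uid)


def products_of(graph: NOCGraph, reaction_uid: str) -> set[str]:
    return graph.products_of(reaction_uid)


def or_nodes(graph: NOCGraph) -> set[str]:
    """Molecules with two or more producing reactions (decision points)."""
    return {uid for uid in graph.molecules if len(graph.producers(uid)) >= 2}


def stats(graph: NOCGraph) -> GraphStats:
    """Network statistics.

    Roots are molecules produced by some reaction but consumed by none
    (terminal products); leaves are consumed but never produced (starting
    materials).  Molecules with neither incidence count as neither.
    Averages are ``None`` when the graph has no reactions.
    """
    n_product = sum(1 for e in graph.edges if e.kind is EdgeKind.PRODUCT)
    n_reactant = len(graph.edges) - n_product
    n_roots = n_leaves = 0
    for uid in graph.molecules:
        produced = bool(graph.producers(uid))
        consumed = bool(graph.consumers(uid))
        if produced and not consumed:
            n_roots += 1
        elif consumed and not produced:
            n_leaves += 1
    n_rxn = graph.n_reactions
    return GraphStats(
        n_molecules=graph.n_molecules,
        n_reactions=n_rxn,
        n_product_edges=n_product,
        n_reactant_edges=n_reactant,
        n_roots=n_roots,
        n_leaves=n_leaves,
        n_or_nodes=len(or_nodes(graph)),
        avg_reactants_per_reaction=(n_reactant / n_rxn) if n_rxn else None,
        avg_products_per_reaction=(n_product / n_rxn) if n_rxn else None,
    )


def select(
    graph: NOCGraph,
    node_predicate: Optional[Callable[[Union[MoleculeNode, ReactionNode]], bool]] = None,
    edge_predicate: Optional[Callable[[Edge], bool]] = None,
) -> ResultSet:
    """Predicate-filtered subgraph as a single-record result set.

    The record holds every node satisfying ``node_predicate`` plus every
    edge satisfying ``edge_predicate`` whose endpoints both matched.
    Omitted predicates default to always-true.
    """
    node_predicate = node_predicate or (lambda n: True)
    edge_predicate = edge_predicate or (lambda e: True)
    nodes = {n.uid: n for n in graph.nodes() if node_predicate(n)}
    edges = {e for e in graph.edges
             if e.source in nodes and e.target in nodes and edge_predicate(e)}
    return ResultSet(records=[GraphRecord(nodes=nodes, edges=edges)], query="select")


def synthetic_tree(graph: NOCGraph, target_uid: str,
                   bounds: RouteQueryBounds = NO_BOUNDS) -> SyntheticTree:
    """Backward-reachable closure from the target under bounds.

    Alternates incoming PRODUCT edges (molecule -> its producers) and
    incoming REACTANT edges (reaction -> its reactants).  A molecule's
    depth is the minimum number of reactions separating it from the
    target; expansion stops at stop-marked molecules and once depth
    reaches ``max_number_reactions``.  The result aggregates every
    bounded route to the target and may contain cycles.
    """
    graph._require_molecule(target_uid)
    limit = bounds.max_number_reactions
    sub = NOCGraph()
    sub.merge_node(graph.molecules[target_uid])
    best_depth = {target_uid: 0}
    queue = deque([(target_uid, 0)])
    while queue:
        mol, depth = queue.popleft()
        if depth > best_depth.get(mol, depth):
            continue
        if bounds.is_stop(graph, mol) and mol != target_uid:
            continue
        if limit is not None and depth >= limit:
            continue
        for rxn in sorted(graph.producers(mol)):
            sub.merge_node(graph.reactions[rxn])
            sub.merge_edge(Edge(EdgeKind.PRODUCT, rxn, mol))
            for reactant in sorted(graph.reactants_of(rxn)):
                sub.merge_node(graph.molecules[reactant])
                sub.merge_edge(Edge(EdgeKind.REACTANT, reactant, rxn))
                d = depth + 1
                if reactant not in best_depth or d < best_depth[reactant]:
                    best_depth[reactant] = d
                    queue.append((reactant, d))
    alternatives = {uid: len(sub.producers(uid)) for uid in sub.molecules
                    if len(sub.producers(uid)) >= 2}
    return SyntheticTree(target=target_uid, subgraph=sub, or_nodes=alternatives)
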