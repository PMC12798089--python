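"""Exhaustive enumeration of synthetic routes to a target molecule.

Route semantics are AND/OR: a reaction included in a route requires all
of its reactant molecules (AND), while a molecule with several producing
reactions (an OR node) admits at most one of them as its provenance.
A route is a single-rooted acyclic subgraph oriented toward the target
in which every non-starting molecule has exactly one producing reaction,
expansion never stops early at an expandable molecule, and the longest
linear sequence respects ``max_number_reactions``.

Three enumeration surfaces live here:

* :func:`validate_route` — the declarative validity checker that defines
  what a route *is*; every route produced anywhere in the package passes it.
* :func:`enumerate_routes_bruteforce` — a reference enumerator that tries
  every producing-reaction choice at every molecule and keeps the valid
  assignments.  Exponential; guarded by a node limit.  Used as the
  correctness oracle in tests.
* :func:`extract_subroutes` / :func:`assemble_routes` / :func:`mine_routes`
  — the production two-phase algorithm: a breadth-first backward pass
  collapses choice-free segments into subroutes, then a worklist assembly
  stitches subroute alternatives into complete routes.
"""

from __future__ import annotations

from collections import defaultdict, deque
from typing import Mapping, Optional, Sequence

from .core_model import (
    NO_BOUNDS,
    Edge,
    EdgeKind,
    GraphRecord,
    LeafReason,
    NOCGraph,
    NodeNotFoundError,
    PartialResultError,
    ResultSet,
    Route,
    RouteMetrics,
    RouteQueryBounds,
    SizeGuardError,
    Subroute,
    route_identity,
)

__all__ = [
    "validate_route",
    "enumerate_routes_bruteforce",
    "extract_subroutes",
    "assemble_routes",
    "mine_routes",
    "route_metrics",
    "DEFAULT_ROUTE_BUDGET",
    "DEFAULT_ORACLE_NODE_LIMIT",
]

DEFAULT_ROUTE_BUDGET = 100_000
DEFAULT_ORACLE_NODE_LIMIT = 80


# ---------------------------------------------------------------------------
# small graph helpers on provenance maps / edge sets


def _succ_from_edges(edges) -> dict[str, set[str]]:
    succ: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        succ[e.source].add(e.target)
    return succ


def _succ_from_prov(graph: NOCGraph, prov: Mapping[str, str]) -> dict[str, set[str]]:
    """Successor adjacency (oriented toward the target) of a partial route."""
    succ: dict[str, set[str]] = defaultdict(set)
    for mol, rxn in prov.items():
        succ[rxn].add(mol)
        for x in graph.reactants_of(rxn):
            succ[x].add(rxn)
    return succ


def _reachable(succ: Mapping[str, set[str]], start: str) -> set[str]:
    seen: set[str] = set()
    stack = [start]
    while stack:
        n = stack.pop()
        for nxt in succ.get(n, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def _expansion_creates_cycle(graph: NOCGraph, prov: Mapping[str, str],
                             mol: str, rxn: str) -> bool:
    """Would assigning ``mol <- rxn`` close a cycle in the partial route?

    The assignment adds edges ``x -> rxn`` for every NOC reactant x and
    ``rxn -> mol``; a new cycle exists iff ``mol`` already reaches ``rxn``
    or any of its reactants (or is itself one of them).
    """
    reactants = graph.reactants_of(rxn)
    if mol in reactants:
        return True
    succ = _succ_from_prov(graph, prov)
    reach = _reachable(succ, mol)
    return rxn in reach or bool(reach & reactants)


def _has_cycle(succ: Mapping[str, set[str]]) -> bool:
    # iterative three-colour DFS
    WHITE, GREY, BLACK = 0, 1, 2
    colour: dict[str, int] = defaultdict(int)
    for root in list(succ):
        if colour[root] != WHITE:
            continue
        stack = [(root, iter(sorted(succ.get(root, ()))))]
        colour[root] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == GREY:
                    return True
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(sorted(succ.get(nxt, ())))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
    return False


def _depths_toward_target(succ: Mapping[str, set[str]], target: str,
                          molecules: set[str], reactions: set[str]) -> dict[str, int]:
    """Maximum number of reactions on any path from each node to the target.

    Assumes the successor graph is acyclic.  A molecule's depth is the max
    over its consuming reactions of that reaction's depth plus one; a
    reaction's depth is the max over its in-route product molecules.
    """
    memo: dict[str, int] = {target: 0}

    def depth(node: str) -> int:
        if node in memo:
            return memo[node]
        memo[node] = 0  # placeholder; graph is acyclic so no re-entry on valid input
        nxt = succ.get(node, ())
        if not nxt:
            memo[node] = 0
            return 0
        if node in reactions:
            d = max(depth(m) for m in nxt)
        else:
            d = max(depth(r) + 1 for r in nxt)
        memo[node] = d
        return d

    for n in set(molecules) | set(reactions):
        depth(n)
    return memo


def _longest_sequence_of_prov(graph: NOCGraph, target: str,
                              prov: Mapping[str, str]) -> int:
    succ = _succ_from_prov(graph, prov)
    molecules = {target} | set(prov)
    reactions = set(prov.values())
    for rxn in reactions:
        molecules |= graph.reactants_of(rxn)
    depths = _depths_toward_target(succ, target, molecules, reactions)
    return max((depths[m] for m in molecules), default=0)


# ---------------------------------------------------------------------------
# declarative validity


def validate_route(graph: NOCGraph, route: Route, target_uid: str,
                   bounds: RouteQueryBounds = NO_BOUNDS) -> tuple[bool, list[str]]:
    """Check a route against the declarative definition; returns (valid, violations).

    Checks, in order: single root equal to the target; AND-completeness
    (every route reaction's full reactant set is present); at most one
    incoming PRODUCT edge per molecule; acyclicity; connectivity of every
    node to the target; leaf legality (each starting material is a true
    leaf, stop-marked, or sits exactly at the depth bound); maximality
    (no expandable molecule left unexpanded); and the longest-sequence
    bound.
    """
    violations: list[str] = []
    limit = bounds.max_number_reactions

    molecules = {e.target for e in route.edges if e.kind is EdgeKind.PRODUCT}
    molecules |= {e.source for e in route.edges if e.kind is EdgeKind.REACTANT}
    molecules |= route.molecules | {target_uid}
    reactions = {e.source for e in route.edges if e.kind is EdgeKind.PRODUCT}
    reactions |= {e.target for e in route.edges if e.kind is EdgeKind.REACTANT}
    reactions |= set(route.reactions)

    if not reactions:
        violations.append("route contains no reactions")

    # 1. single root: the target consumes nothing in-route, everything else does
    consumed = {e.source for e in route.edges if e.kind is EdgeKind.REACTANT}
    if target_uid in consumed:
        violations.append("target has an outgoing REACTANT edge inside the route")
    for mol in sorted(molecules - {target_uid}):
        if mol not in consumed:
            violations.append(f"second root: molecule {mol} feeds no in-route reaction")

    # 2. AND-completeness against the NOC
    for rxn in sorted(reactions):
        missing = graph.reactants_of(rxn) - molecules
        if missing:
            violations.append(f"reaction {rxn} is missing reactants {sorted(missing)}")
        for x in graph.reactants_of(rxn) & molecules:
            if Edge(EdgeKind.REACTANT, x, rxn) not in route.edges:
                violations.append(f"missing REACTANT edge {x} -> {rxn}")

    # 3. unique provenance
    produced_by: dict[str, set[str]] = defaultdict(set)
    for e in route.edges:
        if e.kind is EdgeKind.PRODUCT:
            produced_by[e.target].add(e.source)
    for mol, prods in sorted(produced_by.items()):
        if len(prods) > 1:
            violations.append(f"molecule {mol} has {len(prods)} incoming PRODUCT edges")

    # 4. acyclicity
    succ = _succ_from_edges(route.edges)
    cyclic = _has_cycle(succ)
    if cyclic:
        violations.append("route subgraph contains a cycle")

    # 5. connectivity (every node reaches the target)
    pred: dict[str, set[str]] = defaultdict(set)
    for e in route.edges:
        pred[e.target].add(e.source)
    reaching = {target_uid} | _reachable(pred, target_uid)
    stranded = (molecules | reactions) - reaching
    if stranded:
        violations.append(f"nodes with no path to target: {sorted(stranded)}")

    # 6./7. leaf legality and maximality (need depths; skip if cyclic)
    expanded = {mol for mol, prods in produced_by.items() if prods}
    depths = None
    if not cyclic:
        depths = _depths_toward_target(succ, target_uid, molecules, reactions)
    for mol in sorted(molecules):
        stop = bounds.is_stop(graph, mol)
        if mol in expanded:
            if stop:
                violations.append(f"stop-marked molecule {mol} was expanded")
            continue
        if not graph.producers(mol) or stop:
            continue
        if limit is not None and depths is not None and depths.get(mol, 0) == limit:
            continue
        violations.append(
            f"molecule {mol} with producers left unexpanded below the bound (maximality)")

    # 8. longest sequence within bound
    if limit is not None and depths is not None:
        longest = max((depths[m] for m in molecules), default=0)
        if longest > limit:
            violations.append(f"longest sequence {longest} exceeds bound {limit}")

    return (not violations, violations)


# ---------------------------------------------------------------------------
# brute-force reference enumerator (the oracle)


def enumerate_routes_bruteforce(graph: NOCGraph, target_uid: str,
                                bounds: RouteQueryBounds = NO_BOUNDS,
                                node_limit: int = DEFAULT_ORACLE_NODE_LIMIT) -> set:
    """All valid route identities by exhaustive recursive expansion.

    At every molecule the enumerator branches over each producing
    reaction (pruning assignments that close a provenance cycle) and,
    when a depth bound is active, over leaving the molecule as a cut
    leaf; complete assignments are filtered through
    :func:`validate_route` and deduplicated by identity.  Refuses graphs
    above ``node_limit`` nodes.
    """
    if graph.n_nodes > node_limit:
        raise SizeGuardError(
            f"brute-force enumeration refused: {graph.n_nodes} nodes > limit {node_limit}")
    graph._require_molecule(target_uid)
    limit = bounds.max_number_reactions
    identities: set = set()

    def recurse(prov: dict[str, str], pending: tuple[str, ...], in_route: frozenset) -> None:
        if not pending:
            if not prov:
                return
            route = Route.from_provenance(graph, target_uid, prov, bounds)
            ok, _ = validate_route(graph, route, target_uid, bounds)
            if ok:
                identities.add(route_identity(route))
            return
        mol, rest = pending[0], list(pending[1:])
        producer_list = sorted(graph.producers(mol))
        stop = bounds.is_stop(graph, mol)
        if not producer_list or stop or limit is not None:
            # leave unexpanded; validity (dead end / stop / exact-bound cut) checked later
            recurse(prov, tuple(rest), in_route)
        if stop:
            return
        for rxn in producer_list:
            if _expansion_creates_cycle(graph, prov, mol, rxn):
                continue
            prov2 = dict(prov)
            prov2[mol] = rxn
            new = sorted(graph.reactants_of(rxn) - in_route)
            recurse(prov2, tuple(sorted(rest + new)), in_route | set(new))

    recurse({}, (target_uid,), frozenset({target_uid}))
    return identities


# ---------------------------------------------------------------------------
# phase 1: subroute extraction


def _build_subroute(graph: NOCGraph, root: str, choice: str,
                    bounds: RouteQueryBounds) -> Optional[Subroute]:
    """Expand one (root, producing-reaction) alternative into a subroute.

    Forced molecules (single producer, not stop-marked) are absorbed;
    leaves are OR nodes, dead ends, stop-marked molecules, or molecules
    whose forced expansion would close a cycle within the subroute
    (CYCLE_BLOCKED).  Returns None when the choice itself is inadmissible
    (the reaction consumes its own product chain immediately).
    """
    if root in graph.reactants_of(choice):
        return None
    prov = {root: choice}
    nodes = {root, choice}
    edges = {Edge(EdgeKind.PRODUCT, choice, root)}
    leaves: dict[str, LeafReason] = {}
    processed = {root}
    queue: deque[str] = deque()
    for x in sorted(graph.reactants_of(choice)):
        nodes.add(x)
        edges.add(Edge(EdgeKind.REACTANT, x, choice))
        queue.append(x)
    while queue:
        mol = queue.popleft()
        if mol in processed:
            continue
        processed.add(mol)
        producer_list = sorted(graph.producers(mol))
        if bounds.is_stop(graph, mol):
            leaves[mol] = LeafReason.STOP
        elif not producer_list:
            leaves[mol] = LeafReason.DEAD_END
        elif len(producer_list) >= 2:
            leaves[mol] = LeafReason.OR_NODE
        else:
            rxn = producer_list[0]
            if _expansion_creates_cycle(graph, prov, mol, rxn):
                leaves[mol] = LeafReason.CYCLE_BLOCKED
            else:
                prov[mol] = rxn
                nodes.add(rxn)
                edges.add(Edge(EdgeKind.PRODUCT, rxn, mol))
                for x in sorted(graph.reactants_of(rxn)):
                    nodes.add(x)
                    edges.add(Edge(EdgeKind.REACTANT, x, rxn))
                    queue.append(x)
    succ = _succ_from_edges(edges)
    molecules = {n for n in nodes if n in graph.molecules}
    reactions = nodes - molecules
    depth = _depths_toward_target(succ, root, molecules, reactions)
    return Subroute(root=root, choice=choice, nodes=nodes, edges=edges,
                    leaves=leaves, provenance=prov, depth=depth)


def _reachable_closure(graph: NOCGraph, target_uid: str,
                       bounds: RouteQueryBounds) -> set[str]:
    """Molecules backward-reachable from the target within the depth bound
    (minimum-depth accounting), not expanding past stop-marked molecules."""
    limit = bounds.max_number_reactions
    best = {target_uid: 0}
    queue = deque([(target_uid, 0)])
    while queue:
        mol, d = queue.popleft()
        if d > best.get(mol, d):
            continue
        if bounds.is_stop(graph, mol) and mol != target_uid:
            continue
        if limit is not None and d >= limit:
            continue
        for rxn in graph.producers(mol):
            for x in graph.reactants_of(rxn):
                nd = d + 1
                if x not in best or nd < best[x]:
                    best[x] = nd
                    queue.append((x, nd))
    return set(best)


def extract_subroutes(graph: NOCGraph, target_uid: str,
                      bounds: RouteQueryBounds = NO_BOUNDS) -> dict[str, list[Subroute]]:
    """Phase 1: collapse the network below the target into subroutes.

    Returns a mapping whose keys are the target and every backward-
    reachable OR node, each with one subroute per producing-reaction
    alternative.  Stop-marked molecules are never expanded and get an
    empty alternative list.  Depth bounds are enforced during assembly
    (subroutes carry per-node depth offsets), because an OR-node
    subroute's attachment depth is unknown until it is stitched.
    """
    graph._require_molecule(target_uid)
    closure = _reachable_closure(graph, target_uid, bounds)
    keys = {target_uid} | {m for m in closure if len(graph.producers(m)) >= 2}
    out: dict[str, list[Subroute]] = {}
    for key in sorted(keys):
        if bounds.is_stop(graph, key):
            out[key] = []
            continue
        subs = []
        for rxn in sorted(graph.producers(key)):
            sub = _build_subroute(graph, key, rxn, bounds)
            if sub is not None:
                subs.append(sub)
        out[key] = subs
    return out


# ---------------------------------------------------------------------------
# phase 2: route assembly


def _finalize(graph, target_uid, prov, bounds, routes: dict, budget: int) -> None:
    if not prov:
        return
    route = Route.from_provenance(graph, target_uid, prov, bounds)
    ok, _ = validate_route(graph, route, target_uid, bounds)
    if ok:
        routes[route_identity(route)] = route
        if len(routes) > budget:
            raise PartialResultError(
                f"route budget {budget} exceeded", _sorted_routes(routes))


def _sorted_routes(routes: dict) -> list[Route]:
    def key(route: Route):
        return (len(route.reactions), tuple(sorted(route.provenance.items())))
    return sorted(routes.values(), key=key)


def _assemble_unbounded(graph: NOCGraph, smap: Mapping[str, list[Subroute]],
                        target_uid: str, bounds: RouteQueryBounds,
                        budget: int) -> list[Route]:
    """Worklist stitching of whole subroutes (no depth bound).

    A partial route is (provenance, pending OR leaves, visited subroute
    roots).  Each pending leaf is extended by every alternative subroute
    whose merge keeps the provenance graph acyclic; alternatives carrying
    a CYCLE_BLOCKED leaf are inadmissible outright, since the blocking
    cycle lies wholly inside the subroute and persists in any superset.
    Pending leaves already used as subroute roots are simply resolved.
    """
    routes: dict = {}
    work: list[tuple[dict, tuple, frozenset]] = []
    for sub in smap.get(target_uid, []):
        if any(r is LeafReason.CYCLE_BLOCKED for r in sub.leaves.values()):
            continue
        pending = tuple(sorted(m for m, r in sub.leaves.items() if r is LeafReason.OR_NODE))
        work.append((dict(sub.provenance), pending, frozenset({target_uid})))
    while work:
        prov, pending, visited = work.pop()
        while pending and pending[0] in visited:
            pending = pending[1:]
        if not pending:
            _finalize(graph, target_uid, prov, bounds, routes, budget)
            continue
        mol, rest = pending[0], pending[1:]
        for sub in smap.get(mol, []):
            if any(r is LeafReason.CYCLE_BLOCKED for r in sub.leaves.values()):
                continue
            merged = dict(prov)
            conflict = False
            for k, v in sub.provenance.items():
                if merged.setdefault(k, v) != v:
                    conflict = True
                    break
            if conflict:
                continue
            if _has_cycle(_succ_from_prov(graph, merged)):
                continue
            new_or = tuple(m for m, r in sub.leaves.items()
                           if r is LeafReason.OR_NODE and m not in visited)
            work.append((merged, tuple(sorted(set(rest) | set(new_or))),
                         visited | {mol}))
        # a pending leaf with no admissible alternative discards the partial route
    return _sorted_routes(routes)


def _assemble_bounded(graph: NOCGraph, target_uid: str, bounds: RouteQueryBounds,
                      budget: int) -> list[Route]:
    """Stepwise worklist assembly under a depth bound.

    Whole-subroute stitching cannot be truncated eagerly (a later merge
    can raise a shared molecule's depth), so under a bound the assembly
    expands one reaction at a time, pruning provenance cycles and any
    partial route whose longest sequence already exceeds the bound, and
    branching over cut leaves whose legality the validator settles.
    """
    limit = bounds.max_number_reactions
    routes: dict = {}
    work: list[tuple[dict, tuple, frozenset]] = [({}, (target_uid,), frozenset({target_uid}))]
    while work:
        prov, pending, in_route = work.pop()
        if not pending:
            _finalize(graph, target_uid, prov, bounds, routes, budget)
            continue
        mol, rest = pending[0], tuple(pending[1:])
        producer_list = sorted(graph.producers(mol))
        stop = bounds.is_stop(graph, mol)
        # cut-leaf branch: legal when the molecule is a dead end, stop-marked,
        # or ends up exactly at the bound (validated at finalization)
        work.append((prov, rest, in_route))
        if stop:
            continue
        for rxn in producer_list:
            if _expansion_creates_cycle(graph, prov, mol, rxn):
                continue
            prov2 = dict(prov)
            prov2[mol] = rxn
            if _longest_sequence_of_prov(graph, target_uid, prov2) > limit:
                continue
            new = sorted(graph.reactants_of(rxn) - in_route)
            work.append((prov2, tuple(sorted(set(rest) | set(new))), in_route | set(new)))
    return _sorted_routes(routes)


def assemble_routes(graph: NOCGraph, subroute_map: Mapping[str, list[Subroute]],
                    target_uid: str, bounds: RouteQueryBounds = NO_BOUNDS,
                    budget: int = DEFAULT_ROUTE_BUDGET) -> list[Route]:
    """Phase 2: stitch subroutes into complete, validated, deduplicated routes.

    Output is sorted by (number of steps, provenance identity) for
    deterministic results.  Exceeding ``budget`` raises
    :class:`PartialResultError` carrying the routes found so far.
    """
    if bounds.max_number_reactions is None:
        return _assemble_unbounded(graph, subroute_map, target_uid, bounds, budget)
    return _assemble_bounded(graph, target_uid, bounds, budget)


# ---------------------------------------------------------------------------
# top-level mining


def _resolve_target(graph: NOCGraph, target: str) -> str:
    if target in graph.molecules:
        return target
    if target.startswith("M-") or target.startswith("C-"):
        raise NodeNotFoundError(f"target uid not in graph: {target}")
    from .ingestion import canonicalize_molecule

    uid = None
    try:
        from .core_model import compute_uid

        uid = compute_uid("molecule", canonicalize_molecule(target))
    except Exception:
        uid = None
    if uid is None or uid not in graph.molecules:
        raise NodeNotFoundError(f"target SMILES not found in graph: {target}")
    return uid


def mine_routes(graph: NOCGraph, target: str,
                bounds: RouteQueryBounds = NO_BOUNDS,
                budget: int = DEFAULT_ROUTE_BUDGET) -> ResultSet:
    """Enumerate every valid synthetic route to ``target`` under ``bounds``.

    ``target`` may be a molecule uid or a SMILES string (canonicalized,
    then looked up).  Returns a result set with one record per route
    (nodes, edges, the route object, and its metrics), ordered by number
    of steps then identity.  With no bounds the expansion runs until it
    reaches true leaves.
    """
    uid = _resolve_target(graph, target)
    smap = extract_subroutes(graph, uid, bounds)
    routes = assemble_routes(graph, smap, uid, bounds, budget=budget)
    records = []
    for route in routes:
        nodes = {m: graph.molecules[m] for m in route.molecules}
        nodes.update({r: graph.reactions[r] for r in route.reactions})
        records.append(GraphRecord(nodes=nodes, edges=set(route.edges),
                                   route=route, metrics=route_metrics(route)))
    return ResultSet(records=records, query="mine_routes",
                     params={"target": uid,
                             "max_number_reactions": bounds.max_number_reactions,
                             "stop_property": bounds.stop_property})


def route_metrics(route: Route) -> RouteMetrics:
    """Per-route metrics: steps, longest linear sequence, branches, leaves."""
    succ = _succ_from_edges(route.edges)
    molecules = route.molecules
    depths = _depths_toward_target(succ, route.target, molecules, set(route.reactions))
    longest = max((depths[m] for m in molecules), default=0)
    n_leaves = len(route.leaves)
    return RouteMetrics(n_steps=len(route.reactions),
                        longest_sequence=longest,
                        n_branches=max(n_leaves - 1, 0),
                        n_leaves=n_leaves)
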