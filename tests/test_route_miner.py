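"""Route validity, the brute-force oracle, and the two-phase miner."""

import pytest

from nocgraph.core_model import (
    Edge,
    EdgeKind,
    LeafReason,
    NodeNotFoundError,
    PartialResultError,
    Route,
    RouteQueryBounds,
    SizeGuardError,
    route_identity,
)
from nocgraph.benchmark_fixtures import build_abstract_graph, random_noc
from nocgraph.route_miner import (
    assemble_routes,
    enumerate_routes_bruteforce,
    extract_subroutes,
    mine_routes,
    route_metrics,
    validate_route,
)


def mined_identities(graph, target, bounds=RouteQueryBounds()):
    return {rec.route.identity for rec in mine_routes(graph, target, bounds)}


class TestValidateRoute:
    def test_full_chain_is_valid(self, lin):
        graph, lab = lin
        route = Route.from_provenance(
            graph, lab["m3"], {lab["m3"]: lab["r2"], lab["m2"]: lab["r1"]})
        ok, violations = validate_route(graph, route, lab["m3"])
        assert ok, violations

    def test_unexpanded_intermediate_violates_maximality(self, lin):
        graph, lab = lin
        route = Route.from_provenance(graph, lab["m3"], {lab["m3"]: lab["r2"]})
        ok, violations = validate_route(graph, route, lab["m3"])
        assert not ok
        assert any("maximality" in v for v in violations)

    def test_double_provenance_rejected(self, or_graph):
        graph, lab = or_graph
        route = Route.from_provenance(graph, lab["m3"], {lab["m3"]: lab["r1"]})
        tampered = Route(
            target=route.target, provenance=route.provenance, reactions=route.reactions,
            edges=frozenset(route.edges | {Edge(EdgeKind.PRODUCT, lab["r2"], lab["m3"])}),
            leaves=route.leaves)
        ok, violations = validate_route(graph, tampered, lab["m3"])
        assert not ok
        assert any("PRODUCT" in v for v in violations)

    def test_cycle_rejected(self, cyc):
        graph, lab = cyc
        route = Route.from_provenance(
            graph, lab["b"], {lab["b"]: lab["r1"], lab["a"]: lab["r2"]})
        ok, violations = validate_route(graph, route, lab["b"])
        assert not ok
        assert any("cycle" in v for v in violations)

    def test_stop_marked_molecule_must_not_be_expanded(self, lin3):
        graph, lab = lin3
        graph.molecules[lab["m2"]].properties["sm"] = True
        bounds = RouteQueryBounds(stop_property="sm")
        full = Route.from_provenance(
            graph, lab["m4"],
            {lab["m4"]: lab["r3"], lab["m3"]: lab["r2"], lab["m2"]: lab["r1"]}, bounds)
        ok, violations = validate_route(graph, full, lab["m4"], bounds)
        assert not ok
        trimmed = Route.from_provenance(
            graph, lab["m4"], {lab["m4"]: lab["r3"], lab["m3"]: lab["r2"]}, bounds)
        ok, violations = validate_route(graph, trimmed, lab["m4"], bounds)
        assert ok, violations

    def test_bound_cut_leaf_must_sit_exactly_at_bound(self, lin3):
        graph, lab = lin3
        bounds = RouteQueryBounds(max_number_reactions=2)
        at_bound = Route.from_provenance(
            graph, lab["m4"], {lab["m4"]: lab["r3"], lab["m3"]: lab["r2"]}, bounds)
        ok, violations = validate_route(graph, at_bound, lab["m4"], bounds)
        assert ok, violations
        below_bound = Route.from_provenance(
            graph, lab["m4"], {lab["m4"]: lab["r3"]}, bounds)
        ok, _ = validate_route(graph, below_bound, lab["m4"], bounds)
        assert not ok


class TestOracle:
    def test_linear_chain_single_route(self, lin):
        graph, lab = lin
        ids = enumerate_routes_bruteforce(graph, lab["m3"])
        assert len(ids) == 1
        (reactions, _prov), = ids
        assert reactions == {lab["r1"], lab["r2"]}

    def test_or_node_two_routes(self, or_graph):
        graph, lab = or_graph
        assert len(enumerate_routes_bruteforce(graph, lab["m3"])) == 2

    def test_product_rule_on_independent_branches(self, prod):
        graph, lab = prod
        assert len(enumerate_routes_bruteforce(graph, lab["t"])) == 6

    def test_dead_end_target_has_no_routes(self, lin):
        graph, lab = lin
        assert enumerate_routes_bruteforce(graph, lab["m1"]) == set()

    def test_size_guard(self):
        graph, _ = random_noc(30, 30, seed=7)
        with pytest.raises(SizeGuardError):
            enumerate_routes_bruteforce(graph, next(iter(graph.molecules)), node_limit=10)


class TestExtractSubroutes:
    def test_fully_forced_chain_collapses(self, lin):
        graph, lab = lin
        smap = extract_subroutes(graph, lab["m3"])
        assert set(smap) == {lab["m3"]}
        (sub,) = smap[lab["m3"]]
        assert sub.choice == lab["r2"]
        assert sub.leaves == {lab["m1"]: LeafReason.DEAD_END}
        assert set(sub.provenance) == {lab["m3"], lab["m2"]}

    def test_or_target_yields_one_subroute_per_choice(self, or_graph):
        graph, lab = or_graph
        smap = extract_subroutes(graph, lab["m3"])
        assert {s.choice for s in smap[lab["m3"]]} == {lab["r1"], lab["r2"]}

    def test_cycle_blocked_leaf(self, cyc):
        graph, lab = cyc
        smap = extract_subroutes(graph, lab["b"])
        (sub_b,) = smap[lab["b"]]
        assert sub_b.leaves == {lab["a"]: LeafReason.OR_NODE}
        by_choice = {s.choice: s for s in smap[lab["a"]]}
        assert by_choice[lab["r3"]].leaves == {lab["l"]: LeafReason.DEAD_END}
        assert by_choice[lab["r2"]].leaves == {lab["b"]: LeafReason.CYCLE_BLOCKED}

    def test_keys_cover_target_and_reachable_or_nodes(self, bench27):
        graph, lab = bench27
        smap = extract_subroutes(graph, lab["T"])
        assert set(smap) == {lab["T"], lab["A"], lab["B"], lab["H"]}

    def test_stop_marked_or_node_never_expanded(self, or_graph):
        graph, lab = or_graph
        graph.molecules[lab["m3"]].properties["sm"] = True
        smap = extract_subroutes(graph, lab["m3"], RouteQueryBounds(stop_property="sm"))
        assert smap[lab["m3"]] == []


class TestAssembleAndMine:
    def test_matches_oracle_on_fixtures(self, request):
        for fixture, target in [("lin", "m3"), ("or_graph", "m3"), ("prod", "t"),
                                ("cyc", "b"), ("common", "t")]:
            graph, lab = request.getfixturevalue(fixture)
            oracle = enumerate_routes_bruteforce(graph, lab[target])
            assert mined_identities(graph, lab[target]) == oracle

    def test_cycle_fixture_single_route(self, cyc):
        graph, lab = cyc
        routes = mine_routes(graph, lab["b"])
        assert len(routes) == 1
        assert routes.records[0].route.reactions == {lab["r3"], lab["r1"]}

    def test_stop_marks_truncate_or_branches(self, or_graph):
        graph, lab = or_graph
        graph.molecules[lab["m1"]].properties["sm"] = True
        graph.molecules[lab["m2"]].properties["sm"] = True
        bounds = RouteQueryBounds(stop_property="sm")
        routes = mine_routes(graph, lab["m3"], bounds)
        assert len(routes) == 2
        for rec in routes:
            assert rec.metrics.n_steps == 1
            assert set(rec.route.leaves.values()) == {LeafReason.STOP}
        assert mined_identities(graph, lab["m3"], bounds) == \
            enumerate_routes_bruteforce(graph, lab["m3"], bounds)

    def test_bound_cuts_chain(self, lin3):
        graph, lab = lin3
        bounds = RouteQueryBounds(max_number_reactions=2)
        routes = mine_routes(graph, lab["m4"], bounds)
        assert len(routes) == 1
        rec = routes.records[0]
        assert rec.route.reactions == {lab["r3"], lab["r2"]}
        assert rec.route.leaves == {lab["m2"]: LeafReason.BOUND}
        assert mined_identities(graph, lab["m4"], bounds) == \
            enumerate_routes_bruteforce(graph, lab["m4"], bounds)

    def test_every_mined_route_validates(self, bench27):
        graph, lab = bench27
        for target in ("T", "A", "B", "F", "H"):
            for rec in mine_routes(graph, lab[target]):
                ok, violations = validate_route(graph, rec.route, lab[target])
                assert ok, violations

    def test_deterministic_order(self, prod):
        graph, lab = prod
        first = [rec.route.identity for rec in mine_routes(graph, lab["t"])]
        second = [rec.route.identity for rec in mine_routes(graph, lab["t"])]
        assert first == second
        steps = [rec.metrics.n_steps for rec in mine_routes(graph, lab["t"])]
        assert steps == sorted(steps)

    def test_budget_exhaustion_signals_partial(self, prod):
        graph, lab = prod
        with pytest.raises(PartialResultError) as err:
            mine_routes(graph, lab["t"], budget=3)
        assert len(err.value.routes) == 4  # the routes found when the budget tripped

    def test_target_resolution_by_smiles(self):
        from nocgraph.ingestion import ingest

        graph, _ = ingest(["CCO.CC(=O)O>>CCOC(C)=O"])
        routes = mine_routes(graph, "O(CC)C(C)=O")  # non-canonical ester writing
        assert len(routes) == 1
        with pytest.raises(NodeNotFoundError):
            mine_routes(graph, "c1ccccc1")

    def test_monotonicity_in_bound_on_chain(self, lin3):
        graph, lab = lin3
        counts = [len(mine_routes(graph, lab["m4"],
                                  RouteQueryBounds(max_number_reactions=d)))
                  for d in (1, 2, 3)]
        assert counts == [1, 1, 1]
        unbounded = mined_identities(graph, lab["m4"])
        assert mined_identities(graph, lab["m4"],
                                RouteQueryBounds(max_number_reactions=3)) == unbounded


class TestRouteMetrics:
    def test_linear_chain(self, lin):
        graph, lab = lin
        (rec,) = mine_routes(graph, lab["m3"]).records
        assert rec.metrics == route_metrics(rec.route)
        assert (rec.metrics.n_steps, rec.metrics.longest_sequence,
                rec.metrics.n_branches) == (2, 2, 0)

    def test_branched_route(self, prod):
        graph, lab = prod
        for rec in mine_routes(graph, lab["t"]):
            m = rec.metrics
            assert (m.n_steps, m.longest_sequence, m.n_leaves, m.n_branches) == (3, 2, 2, 1)
            assert m.longest_sequence <= m.n_steps


class TestConvergentByproducts:
    def test_multiple_products_single_reaction_provenance(self):
        graph, lab = build_abstract_graph([
            ("r1", ["j"], ["k", "l"]),
            ("r2", ["k", "l"], ["t"]),
        ])
        routes = mine_routes(graph, lab["t"])
        assert len(routes) == 1
        route = routes.records[0].route
        assert route.reactions == {lab["r1"], lab["r2"]}
        assert route.provenance[lab["k"]] == lab["r1"]
        assert route.provenance[lab["l"]] == lab["r1"]
        # both PRODUCT edges of r1 appear, one per provenanced molecule
        prods = {e.target for e in route.edges
                 if e.kind is EdgeKind.PRODUCT and e.source == lab["r1"]}
        assert prods == {lab["k"], lab["l"]}

    def test_unconsumed_byproduct_stays_outside_route(self):
        graph, lab = build_abstract_graph([
            ("r1", ["j"], ["k", "waste"]),
            ("r2", ["k"], ["t"]),
        ])
        (rec,) = mine_routes(graph, lab["t"]).records
        assert lab["waste"] not in rec.route.molecules
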