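"""Deterministic validation graphs and a random AND/OR-network generator.

All fixtures abstract away real chemistry: molecule "SMILES" are plain
labels and reaction strings are label joins, which the core model accepts
because it treats canonical strings as opaque.  The 27-node benchmark
graph packs the five challenge phenomena of real reaction networks —
cycles, double additions / multiple products, common intermediates,
branching within a cycle, and concurrent branching from a single node —
into one graph, and ships frozen route answers (regenerated from the
brute-force oracle in the test suite) for mining from the true root and
from several non-root molecules.
"""

from __future__ import annotations

import random
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import (
    Edge,
    EdgeKind,
    MoleculeNode,
    NOCGraph,
    NodeNotFoundError,
    ReactionNode,
    ValidationError,
    compute_uid,
)

__all__ = [
    "build_abstract_graph",
    "benchmark27",
    "benchmark27_expected_routes",
    "scenario",
    "SCENARIO_NAMES",
    "random_noc",
    "g_lin",
    "g_lin3",
    "g_or",
    "g_prod",
    "g_cyc",
    "g_common",
]


def build_abstract_graph(
    reactions: Sequence[tuple[str, Sequence[str], Sequence[str]]],
    stop_labels: Iterable[str] = (),
    stop_property: str = "startingMaterial",
    extra_molecules: Iterable[str] = (),
) -> tuple[NOCGraph, dict[str, str]]:
    """Build a graph from ``(name, reactants, products)`` triples of labels.

    Returns the graph plus a label -> uid mapping covering both molecule
    labels and reaction names.  ``stop_labels`` molecules get a truthy
    ``stop_property``.
    """
    graph = NOCGraph()
    labels: dict[str, str] = {}
    stop_set = set(stop_labels)

    def molecule(label: str) -> str:
        uid = labels.get(label)
        if uid is None:
            props = {stop_property: True} if label in stop_set else {}
            node = MoleculeNode.from_smiles(label, props)
            graph.merge_molecule(node)
            labels[label] = node.uid
            uid = node.uid
        return uid

    for label in extra_molecules:
        molecule(label)
    for name, reactants, products in reactions:
        rxn_smiles = ".".join(reactants) + ">>" + ".".join(products)
        rxn = ReactionNode.from_rxn_smiles(rxn_smiles)
        graph.merge_reaction(rxn)
        labels[name] = rxn.uid
        for r in reactants:
            graph.merge_edge(Edge(EdgeKind.REACTANT, molecule(r), rxn.uid))
        for p in products:
            graph.merge_edge(Edge(EdgeKind.PRODUCT, rxn.uid, molecule(p)))
    return graph, labels


def _identities(labels: Mapping[str, str],
                answers: Iterable[Iterable[tuple[str, str]]]) -> set:
    """Translate label-space provenance answers into uid-space route identities."""
    out = set()
    for prov_pairs in answers:
        prov = {labels[m]: labels[r] for m, r in prov_pairs}
        out.add((frozenset(prov.values()), frozenset(prov.items())))
    return out


# ---------------------------------------------------------------------------
# small named fixtures used throughout the tests


def g_lin() -> tuple[NOCGraph, dict[str, str]]:
    """Linear chain m1 -r1-> m2 -r2-> m3 (no choices)."""
    return build_abstract_graph([("r1", ["m1"], ["m2"]), ("r2", ["m2"], ["m3"])])


def g_lin3() -> tuple[NOCGraph, dict[str, str]]:
    """Three-reaction chain m1 -> m2 -> m3 -> m4."""
    return build_abstract_graph([
        ("r1", ["m1"], ["m2"]),
        ("r2", ["m2"], ["m3"]),
        ("r3", ["m3"], ["m4"]),
    ])


def g_or() -> tuple[NOCGraph, dict[str, str]]:
    """One OR node: r1 and r2 both produce m3."""
    return build_abstract_graph([("r1", ["m1"], ["m3"]), ("r2", ["m2"], ["m3"])])


def g_prod() -> tuple[NOCGraph, dict[str, str]]:
    """Concurrent branching: t <- r0 <- {a, b}; a has 2 producers, b has 3.

    Independent OR nodes, so the route count is the product 2 x 3 = 6.
    """
    return build_abstract_graph([
        ("r0", ["a", "b"], ["t"]),
        ("ra1", ["la1"], ["a"]),
        ("ra2", ["la2"], ["a"]),
        ("rb1", ["lb1"], ["b"]),
        ("rb2", ["lb2"], ["b"]),
        ("rb3", ["lb3"], ["b"]),
    ])


def g_cyc() -> tuple[NOCGraph, dict[str, str]]:
    """Two-reaction cycle a <-> b with one entry point l."""
    return build_abstract_graph([
        ("r3", ["l"], ["a"]),
        ("r1", ["a"], ["b"]),
        ("r2", ["b"], ["a"]),
    ])


def g_common() -> tuple[NOCGraph, dict[str, str]]:
    """Common intermediate c feeding both branches of t."""
    return build_abstract_graph([
        ("r0", ["a", "b"], ["t"]),
        ("r1", ["c"], ["a"]),
        ("r2", ["c"], ["b"]),
    ])


# ---------------------------------------------------------------------------
# the 27-node benchmark graph

_BENCHMARK27_REACTIONS = [
    # concurrent branching from the root: T needs both OR nodes A and B
    ("R1", ["A", "B", "N"], ["T"]),
    # OR node A: two alternatives
    ("R2", ["C"], ["A"]),
    ("R3", ["D"], ["A"]),
    # OR node B: two alternatives
    ("R4", ["E"], ["B"]),
    ("R5", ["F"], ["B"]),
    # common intermediate G feeds both C and E
    ("R6", ["G"], ["C"]),
    ("R7", ["G"], ["E"]),
    # cycle D <-> H with branching inside it (H is an OR node; R10 exits)
    ("R8", ["H"], ["D"]),
    ("R9", ["D"], ["H"]),
    ("R10", ["I"], ["H"]),
    # multiple products (R11) and double addition (R12); L is also a
    # common intermediate feeding R13
    ("R11", ["J"], ["K", "L"]),
    ("R12", ["K", "L"], ["F"]),
    ("R13", ["L"], ["N"]),
]

# Frozen route answers in label space: target -> list of provenance maps.
# Regenerated from the brute-force oracle by the test suite.
_BENCHMARK27_ANSWERS: dict[str, list[list[tuple[str, str]]]] = {
    "T": [
        [("T", "R1"), ("A", "R2"), ("C", "R6"), ("B", "R4"), ("E", "R7"),
         ("N", "R13"), ("L", "R11")],
        [("T", "R1"), ("A", "R2"), ("C", "R6"), ("B", "R5"), ("F", "R12"),
         ("K", "R11"), ("L", "R11"), ("N", "R13")],
        [("T", "R1"), ("A", "R3"), ("D", "R8"), ("H", "R10"), ("B", "R4"),
         ("E", "R7"), ("N", "R13"), ("L", "R11")],
        [("T", "R1"), ("A", "R3"), ("D", "R8"), ("H", "R10"), ("B", "R5"),
         ("F", "R12"), ("K", "R11"), ("L", "R11"), ("N", "R13")],
    ],
    "A": [
        [("A", "R2"), ("C", "R6")],
        [("A", "R3"), ("D", "R8"), ("H", "R10")],
    ],
    "B": [
        [("B", "R4"), ("E", "R7")],
        [("B", "R5"), ("F", "R12"), ("K", "R11"), ("L", "R11")],
    ],
    "F": [
        [("F", "R12"), ("K", "R11"), ("L", "R11")],
    ],
    "H": [
        [("H", "R10")],
    ],
}


def benchmark27() -> tuple[NOCGraph, dict[str, str]]:
    """The packaged 27-node validation graph (14 molecules + 13 reactions).

    The root is molecule ``T``.  Subgraphs: the D<->H reaction cycle with
    an OR exit inside it, the two-product reaction R11 whose products are
    both consumed by the double addition R12, common intermediates G and
    L, and concurrent branching at the root through OR nodes A and B.
    """
    graph, labels = build_abstract_graph(_BENCHMARK27_REACTIONS)
    assert graph.n_nodes == 27
    return graph, labels


def benchmark27_expected_routes(labels: Mapping[str, str]) -> dict[str, set]:
    """Frozen route-identity answers per mining target (root ``T`` plus
    non-root molecules A, B, F and H), translated into uid space."""
    return {target: _identities(labels, answers)
            for target, answers in _BENCHMARK27_ANSWERS.items()}


# ---------------------------------------------------------------------------
# the five named challenge scenarios

_SCENARIOS: dict[str, tuple] = {
    "cycles": (
        g_cyc,
        {"b": [[("b", "r1"), ("a", "r3")]],
         "a": [[("a", "r3")]]},
    ),
    "multiple_products": (
        lambda: build_abstract_graph([
            ("r1", ["j"], ["k", "l"]),
            ("r2", ["k", "l"], ["t"]),
        ]),
        {"t": [[("t", "r2"), ("k", "r1"), ("l", "r1")]]},
    ),
    "common_intermediates": (
        g_common,
        {"t": [[("t", "r0"), ("a", "r1"), ("b", "r2")]]},
    ),
    "branching_in_cycle": (
        lambda: build_abstract_graph([
            ("r1", ["b"], ["a"]),
            ("r2", ["a"], ["b"]),
            ("r3", ["l1"], ["b"]),
            ("r4", ["l2"], ["b"]),
        ]),
        {"a": [[("a", "r1"), ("b", "r3")], [("a", "r1"), ("b", "r4")]],
         "b": [[("b", "r3")], [("b", "r4")]]},
    ),
    # product rule 2 x 3 over independent OR nodes
    "concurrent_branching": (
        g_prod,
        {"t": [
            [("t", "r0"), ("a", ra), ("b", rb)]
            for ra in ("ra1", "ra2")
            for rb in ("rb1", "rb2", "rb3")
        ]},
    ),
}

SCENARIO_NAMES = tuple(sorted(_SCENARIOS))


def scenario(name: str) -> tuple[NOCGraph, dict[str, str], dict[str, set]]:
    """A minimal graph exhibiting one challenge phenomenon.

    Returns ``(graph, labels, expected)`` where ``expected`` maps each
    listed target uid to its frozen set of route identities.
    """
    if name not in _SCENARIOS:
        raise NodeNotFoundError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    builder, answers = _SCENARIOS[name]
    graph, labels = builder()
    expected = {labels[target]: _identities(labels, provs)
                for target, provs in answers.items()}
    return graph, labels, expected


# ---------------------------------------------------------------------------
# random AND/OR network generator


def random_noc(n_molecules: int, n_reactions: int, or_density: float = 0.0,
               cycle_rate: float = 0.0, max_arity: int = 3,
               seed: int = 0) -> tuple[NOCGraph, dict[str, str]]:
    """Seeded random bipartite AND/OR network for property-based testing.

    Molecules are indexed ``m000..``; a layered acyclic base is built by
    letting each reaction produce a molecule and consume strictly
    higher-indexed ones (deeper toward the leaves).  Extra producing
    reactions are then added to random molecules until the OR-node
    fraction approaches ``or_density``, and with probability
    ``cycle_rate`` a reaction additionally consumes a lower-indexed
    molecule (a back-edge, possibly closing cycles).  Deterministic for a
    fixed seed.
    """
    if n_molecules < 2 or n_reactions < 1:
        raise ValidationError("need at least 2 molecules and 1 reaction")
    if not (0.0 <= or_density <= 1.0 and 0.0 <= cycle_rate <= 1.0):
        raise ValidationError("or_density and cycle_rate must lie in [0, 1]")
    if max_arity < 1:
        raise ValidationError("max_arity must be >= 1")
    rng = random.Random(seed)
    width = max(3, len(str(n_molecules - 1)))
    names = [f"m{i:0{width}d}" for i in range(n_molecules)]

    specs: list[tuple[str, list[str], list[str]]] = []
    seen_strings: set[str] = set()

    def add_reaction(product_idx: int) -> bool:
        hi = list(range(product_idx + 1, n_molecules))
        if not hi:
            return False
        arity = rng.randint(1, max_arity)
        reactants = sorted(rng.sample(hi, min(arity, len(hi))))
        if product_idx > 0 and rng.random() < cycle_rate:
            back = rng.randrange(0, product_idx)
            if back not in reactants:
                reactants = sorted(reactants + [back])
        products = [product_idx]
        key = ".".join(names[i] for i in reactants) + ">>" + names[product_idx]
        if key in seen_strings:
            return False
        seen_strings.add(key)
        specs.append((f"r{len(specs)}", [names[i] for i in reactants],
                      [names[i] for i in products]))
        return True

    # base layer: one producer per molecule so the OR fraction starts at zero
    produced: list[int] = []
    for _ in range(n_reactions):
        unproduced = [i for i in range(n_molecules - 1) if i not in set(produced)]
        if not unproduced:
            break
        for _attempt in range(20):
            p = rng.choice(unproduced)
            if add_reaction(p):
                produced.append(p)
                break

    if not specs:
        raise ValidationError("infeasible parameters: no reactions could be generated")

    # raise the OR fraction by adding alternative producers
    if or_density > 0:
        target_or = or_density * n_molecules
        counts: dict[int, int] = {}
        for p in produced:
            counts[p] = counts.get(p, 0) + 1
        n_or = sum(1 for c in counts.values() if c >= 2)
        attempts = 0
        while n_or < target_or and attempts < 20 * n_molecules:
            attempts += 1
            singles = [p for p, c in counts.items() if c == 1 and p < n_molecules - 1]
            if not singles:
                break  # every producible molecule is already an OR node
            p = rng.choice(singles)
            if add_reaction(p):
                counts[p] += 1
                if counts[p] == 2:
                    n_or += 1

    graph, labels = build_abstract_graph(specs, extra_molecules=names)
    return graph, labels
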