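"""Core typed data model for bipartite reaction-molecule networks.

A Network of Organic Chemistry (NOC) is a directed bipartite graph:
molecule nodes connect to reaction nodes through REACTANT edges
(molecule -> reaction) and reaction nodes connect to molecule nodes
through PRODUCT edges (reaction -> molecule).  Every node carries a
content-derived unique identifier, so merging the same chemistry twice
is idempotent by construction.

This module houses the node/edge/graph types, the synthetic-route and
subroute definitions used by the route miner, query-result packaging,
and identifier computation.  It has no chemistry dependencies: SMILES
strings are treated as opaque canonical labels here (canonicalization
lives in :mod:`nocgraph.ingestion`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Iterator, Mapping, Optional, Union

__all__ = [
    "NocError",
    "ValidationError",
    "IntegrityError",
    "NodeNotFoundError",
    "FormatError",
    "SizeGuardError",
    "PartialResultError",
    "EdgeKind",
    "LeafReason",
    "compute_uid",
    "MoleculeNode",
    "ReactionNode",
    "Edge",
    "NOCGraph",
    "ReactionRoles",
    "RouteQueryBounds",
    "Subroute",
    "Route",
    "route_identity",
    "RouteMetrics",
    "SyntheticTree",
    "GraphRecord",
    "ResultSet",
    "GraphStats",
]

Scalar = Union[str, int, float, bool]


class NocError(Exception):
    """Base class for all package errors."""


class ValidationError(NocError):
    """Input failed chemical or structural validation."""


class IntegrityError(NocError):
    """An operation would violate a graph invariant."""


class NodeNotFoundError(NocError, KeyError):
    """A uid (or target SMILES) is not present in the graph."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message readable
        return Exception.__str__(self)


class FormatError(NocError):
    """A serialized artifact is malformed or has an unsupported version."""


class SizeGuardError(NocError):
    """A brute-force operation refused an input above its size limit."""


class PartialResultError(NocError):
    """Route enumeration hit its budget; carries the routes found so far."""

    def __init__(self, message: str, routes: list) -> None:
        super().__init__(message)
        self.routes = routes


class EdgeKind(str, Enum):
    PRODUCT = "PRODUCT"    # reaction -> molecule
    REACTANT = "REACTANT"  # molecule -> reaction


class LeafReason(str, Enum):
    """Why expansion of a molecule stopped at a route/subroute leaf."""

    OR_NODE = "OR_NODE"              # multiple producers; a decision point
    DEAD_END = "DEAD_END"            # no producing reaction in the network
    STOP = "STOP"                    # stop-property marked (e.g. startingMaterial)
    BOUND = "BOUND"                  # depth bound reached
    CYCLE_BLOCKED = "CYCLE_BLOCKED"  # expansion would revisit an already-used path


_KIND_PREFIX = {"molecule": "M-", "reaction": "C-"}


def compute_uid(kind: str, canonical_string: str) -> str:
    """Deterministic content-derived identifier for a node.

    Molecules are prefixed ``M-``, reactions (chemical equations) ``C-``,
    followed by the first 32 hex digits of the SHA-256 of the canonical
    string.  Distinct kinds can therefore never collide.
    """
    if kind not in _KIND_PREFIX:
        raise ValidationError(f"unknown node kind {kind!r}")
    if not canonical_string:
        raise ValidationError("cannot compute a uid from an empty string")
    digest = hashlib.sha256(canonical_string.encode("utf-8")).hexdigest()[:32]
    return _KIND_PREFIX[kind] + digest


def _check_properties(properties: Mapping[str, Scalar]) -> dict:
    for key, value in properties.items():
        if not isinstance(key, str) or not key:
            raise ValidationError(f"property keys must be non-empty strings, got {key!r}")
        if not isinstance(value, (str, int, float, bool)):
            raise ValidationError(
                f"property {key!r} must be a scalar (str/int/float/bool), got {type(value).__name__}"
            )
    return dict(properties)


@dataclass
class MoleculeNode:
    """A molecule, keyed by a uid derived from its canonical SMILES."""

    uid: str
    smiles: str
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValidationError("MoleculeNode.smiles must be non-empty")
        if self.uid != compute_uid("molecule", self.smiles):
            raise IntegrityError(f"uid {self.uid!r} is not derived from smiles {self.smiles!r}")
        self.properties = _check_properties(self.properties)

    @classmethod
    def from_smiles(cls, smiles: str, properties: Optional[Mapping[str, Scalar]] = None) -> "MoleculeNode":
        return cls(compute_uid("molecule", smiles), smiles, dict(properties or {}))


@dataclass
class ReactionNode:
    """A chemical equation, keyed by a uid derived from its two-sided reaction SMILES."""

    uid: str
    rxn_smiles: str
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = self.rxn_smiles.split(">>")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValidationError(
                f"rxn_smiles must be 'reactants>>products' with both sides non-empty: {self.rxn_smiles!r}"
            )
        self.properties = _check_properties(self.properties)

    @classmethod
    def from_rxn_smiles(cls, rxn_smiles: str, properties: Optional[Mapping[str, Scalar]] = None,
                        uid_source: Optional[str] = None) -> "ReactionNode":
        """Build a reaction node; ``uid_source`` overrides the string the uid is hashed from
        (used by no-validation ingestion, where identity is the raw input string)."""
        return cls(compute_uid("reaction", uid_source or rxn_smiles), rxn_smiles, dict(properties or {}))


@dataclass(frozen=True)
class Edge:
    kind: EdgeKind
    source: str
    target: str

    def __post_init__(self) -> None:
        if not isinstance(self.kind, EdgeKind):
            object.__setattr__(self, "kind", EdgeKind(self.kind))


class NOCGraph:
    """In-memory bipartite reaction-molecule graph with idempotent merge.

    PRODUCT edges run reaction -> molecule, REACTANT edges molecule ->
    reaction; insertions violating this direction law, or referencing
    absent endpoints, raise :class:`IntegrityError`.  Merging a node whose
    uid already exists updates its properties (last-write-wins) and never
    duplicates the node; merging an existing edge is a no-op.
    """

    def __init__(self) -> None:
        self.molecules: dict[str, MoleculeNode] = {}
        self.reactions: dict[str, ReactionNode] = {}
        self.edges: set[Edge] = set()
        self._producers: dict[str, set[str]] = {}    # molecule -> reactions producing it
        self._consumers: dict[str, set[str]] = {}    # molecule -> reactions consuming it
        self._reactants: dict[str, set[str]] = {}    # reaction -> reactant molecules
        self._products: dict[str, set[str]] = {}     # reaction -> product molecules

    # -- merge ---------------------------------------------------------------

    def merge_molecule(self, node: MoleculeNode) -> MoleculeNode:
        existing = self.molecules.get(node.uid)
        if existing is None:
            self.molecules[node.uid] = MoleculeNode(node.uid, node.smiles, dict(node.properties))
            return self.molecules[node.uid]
        existing.properties.update(node.properties)
        return existing

    def merge_reaction(self, node: ReactionNode) -> ReactionNode:
        existing = self.reactions.get(node.uid)
        if existing is None:
            self.reactions[node.uid] = ReactionNode(node.uid, node.rxn_smiles, dict(node.properties))
            return self.reactions[node.uid]
        existing.properties.update(node.properties)
        return existing

    def merge_node(self, node: Union[MoleculeNode, ReactionNode]):
        if isinstance(node, MoleculeNode):
            return self.merge_molecule(node)
        if isinstance(node, ReactionNode):
            return self.merge_reaction(node)
        raise IntegrityError(f"not a graph node: {type(node).__name__}")

    def merge_edge(self, edge: Edge) -> None:
        if edge.kind is EdgeKind.PRODUCT:
            ok = edge.source in self.reactions and edge.target in self.molecules
        else:
            ok = edge.source in self.molecules and edge.target in self.reactions
        if not ok:
            missing = [u for u in (edge.source, edge.target)
                       if u not in self.molecules and u not in self.reactions]
            if missing:
                raise IntegrityError(f"edge endpoint(s) not in graph: {missing}")
            raise IntegrityError(
                f"{edge.kind.value} edge direction law violated: {edge.source} -> {edge.target}"
            )
        if edge in self.edges:
            return
        self.edges.add(edge)
        if edge.kind is EdgeKind.PRODUCT:
            self._producers.setdefault(edge.target, set()).add(edge.source)
            self._products.setdefault(edge.source, set()).add(edge.target)
        else:
            self._consumers.setdefault(edge.source, set()).add(edge.target)
            self._reactants.setdefault(edge.target, set()).add(edge.source)

    # -- accessors -----------------------------------------------------------

    def _require_molecule(self, uid: str) -> None:
        if uid not in self.molecules:
            raise NodeNotFoundError(f"molecule uid not in graph: {uid}")

    def _require_reaction(self, uid: str) -> None:
        if uid not in self.reactions:
            raise NodeNotFoundError(f"reaction uid not in graph: {uid}")

    def producers(self, molecule_uid: str) -> set[str]:
        self._require_molecule(molecule_uid)
        return set(self._producers.get(molecule_uid, ()))

    def consumers(self, molecule_uid: str) -> set[str]:
        self._require_molecule(molecule_uid)
        return set(self._consumers.get(molecule_uid, ()))

    def reactants_of(self, reaction_uid: str) -> set[str]:
        self._require_reaction(reaction_uid)
        return set(self._reactants.get(reaction_uid, ()))

    def products_of(self, reaction_uid: str) -> set[str]:
        self._require_reaction(reaction_uid)
        return set(self._products.get(reaction_uid, ()))

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_nodes(self) -> int:
        return len(self.molecules) + len(self.reactions)

    def nodes(self) -> Iterator[Union[MoleculeNode, ReactionNode]]:
        yield from self.molecules.values()
        yield from self.reactions.values()

    def has_node(self, uid: str) -> bool:
        return uid in self.molecules or uid in self.reactions

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NOCGraph):
            return NotImplemented
        return (
            {u: (n.smiles, n.properties) for u, n in self.molecules.items()}
            == {u: (n.smiles, n.properties) for u, n in other.molecules.items()}
            and {u: (n.rxn_smiles, n.properties) for u, n in self.reactions.items()}
            == {u: (n.rxn_smiles, n.properties) for u, n in other.reactions.items()}
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (f"NOCGraph(n_molecules={self.n_molecules}, n_reactions={self.n_reactions}, "
                f"n_edges={len(self.edges)})")

    def copy(self) -> "NOCGraph":
        g = NOCGraph()
        for node in self.nodes():
            g.merge_node(node)
        for edge in self.edges:
            g.merge_edge(edge)
        return g


@dataclass
class ReactionRoles:
    """Species lists of a parsed reaction string, by role."""

    reactants: list[str]
    agents: list[str]
    products: list[str]


@dataclass(frozen=True)
class RouteQueryBounds:
    """User-defined bounds on route expansion.

    ``max_number_reactions`` caps the longest linear sequence — the maximum
    number of reactions on any starting-material-to-target path within a
    route.  ``stop_property`` names a node property whose truthy value
    halts expansion at that molecule (e.g. ``"startingMaterial"``).
    """

    max_number_reactions: Optional[int] = None
    stop_property: Optional[str] = None

    def __post_init__(self) -> None:
        if self.max_number_reactions is not None and self.max_number_reactions < 1:
            raise ValidationError("max_number_reactions must be >= 1 when given")

    def is_stop(self, graph: NOCGraph, molecule_uid: str) -> bool:
        if self.stop_property is None:
            return False
        node = graph.molecules.get(molecule_uid)
        return bool(node is not None and node.properties.get(self.stop_property))


NO_BOUNDS = RouteQueryBounds()


@dataclass
class Subroute:
    """A collapsed choice-free segment of the network.

    Rooted at the target or at one (OR node, producing reaction)
    alternative; forced single-producer molecules are absorbed until an
    OR node, dead end, stop-marked molecule, or cycle block is hit.
    ``provenance`` records the producing reaction chosen/forced for each
    expanded molecule; ``depth`` records each node's maximum reaction
    depth below the subroute root.
    """

    root: str
    choice: Optional[str]
    nodes: set[str]
    edges: set[Edge]
    leaves: dict[str, LeafReason]
    provenance: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)


@dataclass
class Route:
    """A single-rooted acyclic synthetic route oriented toward ``target``.

    ``provenance`` maps every non-starting molecule to its unique producing
    reaction; ``leaves`` are the starting materials with their termination
    reasons.  Edges include, per reaction, all of its REACTANT edges (AND
    semantics) and PRODUCT edges only toward molecules whose provenance is
    that reaction (byproducts outside the route are omitted).
    """

    target: str
    provenance: dict[str, str]
    reactions: frozenset[str]
    edges: frozenset[Edge]
    leaves: dict[str, LeafReason]

    @property
    def molecules(self) -> set[str]:
        return set(self.provenance) | set(self.leaves)

    @property
    def identity(self):
        return route_identity(self)

    @classmethod
    def from_provenance(cls, graph: NOCGraph, target: str, provenance: Mapping[str, str],
                        bounds: RouteQueryBounds = NO_BOUNDS) -> "Route":
        """Derive the full route subgraph (edges, leaves) from a provenance map."""
        provenance = dict(provenance)
        reactions = frozenset(provenance.values())
        molecules = {target} | set(provenance)
        for rxn in reactions:
            molecules |= graph.reactants_of(rxn)
        edges: set[Edge] = set()
        for mol, rxn in provenance.items():
            edges.add(Edge(EdgeKind.PRODUCT, rxn, mol))
        for rxn in reactions:
            for mol in graph.reactants_of(rxn):
                edges.add(Edge(EdgeKind.REACTANT, mol, rxn))
        leaves: dict[str, LeafReason] = {}
        for mol in molecules - set(provenance):
            if bounds.is_stop(graph, mol):
                leaves[mol] = LeafReason.STOP  # explicit user mark wins over dead-end
            elif not graph.producers(mol):
                leaves[mol] = LeafReason.DEAD_END
            else:
                leaves[mol] = LeafReason.BOUND
        return cls(target=target, provenance=provenance, reactions=reactions,
                   edges=frozenset(edges), leaves=leaves)


def route_identity(route: Route):
    """Hashable identity of a route: its reaction set plus the provenance
    assignment of every molecule.  Independent of any listing order."""
    return (frozenset(route.reactions), frozenset(route.provenance.items()))


@dataclass(frozen=True)
class RouteMetrics:
    n_steps: int
    longest_sequence: int
    n_branches: int
    n_leaves: int


@dataclass
class SyntheticTree:
    """Union of all routes converging on ``target`` (may contain cycles)."""

    target: str
    subgraph: NOCGraph
    or_nodes: dict[str, int]


@dataclass
class GraphRecord:
    """One query match: a consistent set of nodes plus edges among them."""

    nodes: dict[str, Union[MoleculeNode, ReactionNode]]
    edges: set[Edge]
    route: Optional[Route] = None
    metrics: Optional[RouteMetrics] = None

    def __post_init__(self) -> None:
        for edge in self.edges:
            if edge.source not in self.nodes or edge.target not in self.nodes:
                raise IntegrityError(f"record edge endpoint missing: {edge}")


@dataclass
class ResultSet:
    """Ordered collection of graph records returned by a query."""

    records: list[GraphRecord] = field(default_factory=list)
    query: str = ""
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GraphRecord]:
        return iter(self.records)

    @classmethod
    def from_graph(cls, graph: NOCGraph, query: str = "graph",
                   params: Optional[dict] = None) -> "ResultSet":
        record = GraphRecord(nodes={n.uid: n for n in graph.nodes()}, edges=set(graph.edges))
        return cls(records=[record], query=query, params=dict(params or {}))


@dataclass
class GraphStats:
    n_molecules: int
    n_reactions: int
    n_product_edges: int
    n_reactant_edges: int
    n_roots: int
    n_leaves: int
    n_or_nodes: int
    avg_reactants_per_reaction: Optional[float]
    avg_products_per_reaction: Optional[float]
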