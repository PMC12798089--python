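"""Reaction-string ingestion: parse, validate, canonicalize, deduplicate.

Reaction strings follow the three-role reaction-SMILES convention
``reactants>agents>products`` with dot-separated species.  With
validation enabled each species is canonicalized (atom maps stripped,
stereochemistry preserved), species appearing on both sides are
reassigned to the agent role, roles are deduplicated, and the reaction
identity is the role-sorted two-sided canonical string — so two
differently written forms of the same transformation merge into one
reaction node.  With validation disabled, duplicates are detected by
exact string equality of the raw inputs.

Agents are excluded from the core bipartite graph and kept as a reaction
property.  Ingestion is chunked and order-independent: the graph merge
is commutative, associative, and idempotent, so any chunk size or worker
count yields the same graph.
"""

from __future__ import annotations

import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from rdkit import Chem
from rdkit import RDLogger

from .core_model import (
    Edge,
    EdgeKind,
    IntegrityError,
    MoleculeNode,
    NOCGraph,
    ReactionNode,
    ReactionRoles,
    ValidationError,
    compute_uid,
)

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as structured errors

__all__ = [
    "IngestionConfig",
    "IngestionReport",
    "parse_reaction_string",
    "canonicalize_molecule",
    "assign_roles",
    "canonical_reaction_string",
    "build_graph_elements",
    "ingest",
]


@dataclass(frozen=True)
class IngestionConfig:
    validate: bool = True
    reaction_column: str = "reaction"
    chunk_size: int = 1000
    n_workers: int = 1
    on_error: str = "skip_and_log"  # or "fail_fast"

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValidationError("chunk_size must be >= 1")
        if self.n_workers < 1:
            raise ValidationError("n_workers must be >= 1")
        if self.on_error not in ("skip_and_log", "fail_fast"):
            raise ValidationError("on_error must be 'skip_and_log' or 'fail_fast'")


@dataclass
class IngestionReport:
    n_input_rows: int = 0
    n_failed: int = 0
    n_unique_reactions: int = 0
    n_unique_molecules: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input_rows": self.n_input_rows,
                "n_failed": self.n_failed,
                "n_unique_reactions": self.n_unique_reactions,
                "n_unique_molecules": self.n_unique_molecules,
                "failures": [{"row": r, "reason": why} for r, why in self.failures],
            },
            indent=2,
            sort_keys=True,
        )


def parse_reaction_string(s: str) -> ReactionRoles:
    """Split ``reactants>agents>products`` into role lists.

    The middle role may be empty (``A>>B``).  Raises ValidationError on a
    wrong separator count or an empty reactant/product role, naming the
    offending role.
    """
    parts = s.strip().split(">")
    if len(parts) != 3:
        raise ValidationError(
            f"reaction string must contain exactly two '>' separators, "
            f"found {len(parts) - 1}: {s!r}")
    role_names = ("reactants", "agents", "products")
    roles = []
    for name, part in zip(role_names, parts):
        species = [tok.strip() for tok in part.split(".") if tok.strip()]
        if name != "agents" and not species:
            raise ValidationError(f"empty {name} role in reaction string {s!r}")
        roles.append(species)
    return ReactionRoles(reactants=roles[0], agents=roles[1], products=roles[2])


def canonicalize_molecule(smiles: str) -> str:
    """Canonical SMILES of a molecule; atom-map numbers are stripped,
    stereochemistry descriptors are preserved.  Idempotent."""
    if not smiles:
        raise ValidationError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def _dedup(seq: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def assign_roles(roles: ReactionRoles) -> ReactionRoles:
    """Move species appearing in both reactants and products to agents.

    One instance is removed from each side per match; duplicates within a
    role are then collapsed.  Raises ValidationError when either side
    empties out (a degenerate, no-transformation reaction).  Expects
    per-molecule canonicalized input so matching is by chemical identity.
    """
    from collections import Counter

    r_count = Counter(roles.reactants)
    p_count = Counter(roles.products)
    moved = []
    for smi in sorted(r_count.keys() & p_count.keys()):
        k = min(r_count[smi], p_count[smi])
        r_count[smi] -= k
        p_count[smi] -= k
        moved.append(smi)
    reactants = _dedup(s for s in roles.reactants if r_count.get(s, 0) > 0)
    products = _dedup(s for s in roles.products if p_count.get(s, 0) > 0)
    agents = _dedup(list(roles.agents) + moved)
    if not reactants or not products:
        raise ValidationError(
            "degenerate reaction: a role emptied out after role reassignment")
    return ReactionRoles(reactants=reactants, agents=agents, products=products)


def canonical_reaction_string(roles: ReactionRoles) -> str:
    """Role-sorted two-sided canonical reaction SMILES (agents excluded)."""
    return ".".join(sorted(roles.reactants)) + ">>" + ".".join(sorted(roles.products))


def build_graph_elements(
    roles: ReactionRoles,
    raw: Optional[str] = None,
) -> tuple[list, list[Edge]]:
    """Expand validated roles into one reaction node, its distinct
    reactant/product molecule nodes, and the corresponding edges.

    ``raw`` overrides the string the reaction uid is derived from (used
    by no-validation ingestion, where identity is the raw input string).
    """
    rxn_smiles = canonical_reaction_string(roles) if raw is None else (
        ".".join(roles.reactants) + ">>" + ".".join(roles.products))
    props = {"agents": ".".join(roles.agents)} if roles.agents else {}
    rxn = ReactionNode.from_rxn_smiles(rxn_smiles, props, uid_source=raw)
    nodes: list = [rxn]
    edges: list[Edge] = []
    seen: dict[str, MoleculeNode] = {}
    for smi in _dedup(roles.reactants):
        node = seen.setdefault(smi, MoleculeNode.from_smiles(smi))
        edges.append(Edge(EdgeKind.REACTANT, node.uid, rxn.uid))
    for smi in _dedup(roles.products):
        node = seen.setdefault(smi, MoleculeNode.from_smiles(smi))
        edges.append(Edge(EdgeKind.PRODUCT, rxn.uid, node.uid))
    nodes.extend(seen.values())
    return nodes, edges


def _process_row(raw: str, validate: bool) -> tuple[list, list[Edge]]:
    roles = parse_reaction_string(raw)
    if validate:
        roles = ReactionRoles(
            reactants=[canonicalize_molecule(s) for s in roles.reactants],
            agents=[canonicalize_molecule(s) for s in roles.agents],
            products=[canonicalize_molecule(s) for s in roles.products],
        )
        roles = assign_roles(roles)
        return build_graph_elements(roles)
    return build_graph_elements(roles, raw=raw.strip())


def _rows_from_input(rows, reaction_column: str) -> list[str]:
    try:
        import pandas as pd
    except ImportError:  # pragma: no cover
        pd = None
    if pd is not None and isinstance(rows, pd.DataFrame):
        if reaction_column not in rows.columns:
            raise IntegrityError(
                f"reaction column {reaction_column!r} not in table columns "
                f"{list(rows.columns)}")
        return [str(x) for x in rows[reaction_column].tolist()]
    return [str(x) for x in rows]


def ingest(rows, config: IngestionConfig = IngestionConfig(),
           graph: Optional[NOCGraph] = None) -> tuple[NOCGraph, IngestionReport]:
    """Ingest reaction strings (sequence or DataFrame) into a graph.

    Rows are processed in chunks of ``config.chunk_size`` (optionally on a
    thread pool of ``config.n_workers``); because node/edge merge is
    idempotent and order-independent, the resulting graph is identical
    for any chunking or worker count.  Per-row failures are skipped and
    logged in the report, or raised immediately with ``fail_fast``.
    """
    raw_rows = _rows_from_input(rows, config.reaction_column)
    graph = graph if graph is not None else NOCGraph()
    report = IngestionReport(n_input_rows=len(raw_rows))

    def process_chunk(chunk: list[tuple[int, str]]):
        out = []
        for idx, raw in chunk:
            try:
                out.append((idx, _process_row(raw, config.validate), None))
            except ValidationError as exc:
                out.append((idx, None, str(exc)))
        return out

    chunks = [
        list(enumerate(raw_rows))[i:i + config.chunk_size]
        for i in range(0, len(raw_rows), config.chunk_size)
    ]
    if config.n_workers > 1 and len(chunks) > 1:
        with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
            results = list(pool.map(process_chunk, chunks))
    else:
        results = [process_chunk(c) for c in chunks]

    seen_reactions: set[str] = set()
    seen_molecules: set[str] = set()
    for chunk_result in results:
        for idx, elements, error in chunk_result:
            if error is not None:
                if config.on_error == "fail_fast":
                    raise ValidationError(f"row {idx}: {error}")
                report.n_failed += 1
                report.failures.append((idx, error))
                continue
            nodes, edges = elements
            for node in nodes:
                graph.merge_node(node)
                if isinstance(node, ReactionNode):
                    seen_reactions.add(node.uid)
                else:
                    seen_molecules.add(node.uid)
            for edge in edges:
                graph.merge_edge(edge)
    report.n_unique_reactions = len(seen_reactions)
    report.n_unique_molecules = len(seen_molecules)
    return graph, report
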