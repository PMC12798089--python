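# nocgraph

Reaction-network construction and exhaustive synthetic-route mining.

`nocgraph` turns collections of reaction strings into a **Network of
Organic Chemistry (NOC)**: a bipartite directed graph whose nodes are
molecules and chemical equations, connected by REACTANT edges
(molecule → reaction) and PRODUCT edges (reaction → molecule).  On top
of that graph it answers the question synthesis planners actually ask:
*what are all the ways this network knows how to make molecule X?*

It is aimed at cheminformaticians and synthesis-planning researchers
who have reaction data (patent extractions, ELN exports, curated route
sets) and want network-level analysis — connectivity statistics,
decision-point (OR-node) structure, synthetic trees — and exhaustive,
reproducible route enumeration without standing up a graph-database
server.

## The model

**Graph.**  Every node carries a content-derived identifier (`M-`/`C-`
prefix plus a SHA-256 digest of its canonical string), so inserting the
same chemistry twice merges instead of duplicating.  Ingestion parses
three-role reaction SMILES (`reactants>agents>products`), canonicalizes
each species (atom maps stripped, stereochemistry kept), moves species
that appear on both sides into the agent role, and identifies a
reaction by its role-sorted two-sided canonical string — so
`OCC.CC(=O)O>>CCOC(C)=O` and `CC(=O)O.CCO>>CCOC(C)=O` become one node.
Agents are kept as reaction metadata, outside the bipartite core.

**Routes.**  Nodes have AND/OR semantics.  A reaction in a route
requires *all* of its reactant molecules (AND).  A molecule with
several producing reactions is an **OR node**: each incoming PRODUCT
edge is an alternative provenance and a route may use at most one.  A
*synthetic route* to a target `t` is an acyclic subgraph oriented
toward `t` in which every non-starting molecule has exactly one
producing reaction, every included reaction is reactant-complete, and
expansion never stops early: a leaf is a true starting material (no
producers anywhere in the network), a molecule the user stop-marked
(e.g. `startingMaterial`), or a cut sitting exactly at the depth bound.
Two bounds tame combinatorial explosion: `max_number_reactions` caps
the longest linear sequence (the maximum number of reactions on any
leaf-to-target path), and `stop_property` halts expansion at marked
molecules.  A route's identity is its reaction set plus the provenance
assignment, which is what "number of distinct routes" counts.

**Mining.**  Enumeration runs in two phases.  Phase 1 walks backward
from the target and collapses choice-free segments (molecules with a
single producer) into *subroutes*, each rooted at the target or at one
(OR node, producing reaction) alternative and terminating at OR nodes,
dead ends, stop marks, or cycle blocks.  Phase 2 stitches subroute
alternatives together over a worklist, pruning provenance cycles,
validating every completed candidate against the declarative route
definition, and deduplicating by identity.  A brute-force enumerator
(`enumerate_routes_bruteforce`) tries every producing-reaction choice
at every molecule and serves as an independent correctness oracle in
the test suite, together with a packaged 27-node benchmark graph and a
seeded random AND/OR-network generator.

## Worked example

```python
from nocgraph import RouteQueryBounds, ingest, mine_routes, stats
from nocgraph.export_io import routes_to_reaction_strings

rows = [
    "CCO.CC(=O)O>>CCOC(C)=O",        # Fischer esterification
    "OCC.CC(=O)O>>CCOC(C)=O",        # the same reaction, written differently
    "CC(=O)Cl.CCO>>CCOC(C)=O",       # acyl-chloride route to the same ester
    "CCOC(C)=O>>CC(=O)OC(C)=O",      # ester -> anhydride
]
graph, report = ingest(rows)
print(graph.n_molecules, graph.n_reactions)   # 5 3
s = stats(graph)
print(s.n_roots, s.n_leaves, s.n_or_nodes)    # 1 3 1

routes = mine_routes(graph, "CC(=O)OC(C)=O")
print(len(routes))                            # 2
for rec in routes:
    print(rec.metrics.n_steps, rec.metrics.longest_sequence)   # 2 2 (both)
```

Four input rows become three reaction nodes: the first two are the same
esterification after canonicalization and merge into one node, which
makes ethyl acetate an OR node (two producers).  Mining the anhydride
therefore finds exactly two routes of two steps each — one through the
acid, one through the acyl chloride — and
`routes_to_reaction_strings(routes)` emits each as reaction strings in
synthesis order, target-producing reaction last.  With
`RouteQueryBounds(max_number_reactions=1)` only one truncated route
remains, its cut molecule reported as a BOUND leaf.

The same operations are available from the shell:

```bash
nocgraph build --input reactions.csv --column reaction --out graph.json
nocgraph stats graph.json
nocgraph mine graph.json --target-smiles "CC(=O)OC(C)=O" --max-reactions 4 \
    --out routes.json
nocgraph fixture --name benchmark27 --out bench.json
```

## Full-scale workflow

Desk-scale tests use packaged fixtures only.  To reproduce a
large-scale build, point `nocgraph build` at a reaction CSV such as the
public MIT USPTO-480k set (479,035 reaction strings; ~30 min with
validation on one worker-class machine), then `nocgraph stats` for
network statistics and `nocgraph mine --target-smiles
"CC(=O)Nc1ccc(O)cc1" --max-reactions 4` to enumerate bounded routes to
a target such as paracetamol.  Full-scale node/edge counts are
sensitive to the canonicalization toolkit version.

## Limitations

Route mining is exhaustive by design; synthetic trees with many
interacting OR nodes can hold millions of routes, so use the bounds and
the route budget (`PartialResultError` carries whatever was found when
the budget trips).  Reagents/agents are not part of the core graph, no
route scoring or ranking is performed, and persistence is the canonical
graph JSON (GraphML and node/edge tables are export-only).  See
`docs/methods.md` for the algorithmic details and design choices.
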