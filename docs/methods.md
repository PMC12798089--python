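# Methods

This note documents the data model, the route-mining algorithm, the
numerical and design choices behind them, and what the packaged
fixtures and generators do and do not emulate.

## Graph model and identifiers

A NOC is a directed bipartite multigraph-free structure: molecule and
reaction nodes, REACTANT edges (molecule → reaction) and PRODUCT edges
(reaction → molecule), with `(kind, source, target)` unique.  Node
identity is content-derived: `M-`/`C-` plus the first 32 hex digits of
the SHA-256 of the canonical string (128 bits; collisions are
negligible at any realistic corpus size, and the kind prefix separates
the two namespaces unconditionally).  Merge is last-write-wins on
properties and set-semantics on edges, which makes graph construction
commutative, associative, and idempotent — the property the chunked,
multi-worker ingestion contract rests on.

Properties are untyped scalar maps (string/number/boolean).  Stop
flags such as `startingMaterial` are ordinary properties; the route
miner reads whichever property name the query's `stop_property` names
and treats any truthy value as a stop.

## Ingestion and standardization scope

With validation on, each species is parsed by RDKit, atom-map numbers
are stripped (they are bookkeeping that defeats deduplication),
stereochemistry descriptors are preserved (they are chemistry), and the
canonical SMILES is RDKit's.  Role reassignment moves species whose
canonical SMILES appears among both reactants and products to the agent
role (one instance per side per match), then deduplicates within roles;
a reaction whose reactant or product side empties out is rejected as
degenerate.  Reaction identity is the role-sorted two-sided canonical
string, agents excluded.  No tautomer or salt normalization is
attempted: deeper curation is a property of the upstream data pipeline,
not of this graph layer, and full-scale node counts on public corpora
shift with the canonicalization toolkit version for exactly this
reason.

With validation off, rows are parsed structurally but identity is the
raw input string, so deduplication is exact string equality — useful
when the input is already standardized, and the behaviour the
validation-monotonicity law (validated reaction count ≤ raw count) is
tested against.

Agents are recorded as a reaction property and excluded from the
bipartite core; extending the schema with reagent nodes is out of
scope here.

## Route semantics

A route to target `t` is fully determined by a provenance map
`ρ: molecule → producing reaction`.  Its subgraph contains `t`, every
molecule in `dom(ρ)`, every reactant of every used reaction (AND
completeness), one PRODUCT edge per assigned molecule, and all REACTANT
edges of used reactions.  By-products of a used reaction that nothing
in the route consumes stay outside the route, which preserves the
one-incoming-PRODUCT invariant when one reaction legitimately supplies
two different route molecules (double additions / multiple products).

`validate_route` is the single authority on validity.  It checks, in
order: a unique root equal to the target; AND completeness; at most one
incoming PRODUCT edge per molecule; acyclicity; connectivity of every
node to the target; leaf legality and maximality (a leaf must be a true
dead end, stop-marked, or sit exactly at the depth bound — anything
expandable left unexpanded is a violation, so prefixes of routes are
not routes); and the longest-sequence bound.  Depths are computed as
the maximum number of reactions on any node-to-target path by dynamic
programming over the acyclic route graph.

Boundary decisions:

* `max_number_reactions` bounds the **longest linear sequence**, not
  the total step count; a bound-4 route can hold seven reactions across
  branches.
* A target with no producing reaction (or itself stop-marked) has zero
  routes; the empty provenance map is not a route.
* A molecule that is both stop-marked and a true dead end is reported
  as a STOP leaf: the explicit user mark wins.
* Bound-truncated routes are identities in their own query; no
  deduplication against fuller routes from other bounds is attempted.

## Two-phase mining

**Phase 1 (subroute extraction).**  A breadth-first backward pass from
the target identifies the decision points (the target plus every
backward-reachable OR node; under a bound, reachability is cut at
minimum depth equal to the bound, which is sound because any molecule
whose minimum depth exceeds the bound cannot appear in a bounded
route).  For each (root, producing reaction) pair the choice-free
segment below it is collapsed into a subroute: molecules with exactly
one producer are absorbed; OR nodes, dead ends, and stop-marked
molecules become leaves.  A forced expansion that would close a cycle
*within the subroute's own provenance* is blocked and the molecule
becomes a CYCLE_BLOCKED leaf; because such a cycle lies wholly inside
the subroute, it persists in any superset, so the block is
attachment-independent.  Cross-subroute cycles are instead caught at
assembly time by a global acyclicity check — this split reproduces the
classic relationship-uniqueness traversal filter without making
subroutes depend on their discovery path.

**Phase 2 (assembly).**  With no depth bound, partial routes
(provenance map, pending OR leaves, visited subroute roots) are
extended by every alternative subroute of each pending leaf: merges
that close a provenance cycle are skipped, alternatives carrying a
CYCLE_BLOCKED leaf are inadmissible outright (an unreachable forced
intermediate is not silently treated as purchasable), pending leaves
already used as roots are simply resolved, and a pending leaf with no
admissible alternative discards the partial route.  Under a depth
bound, assembly switches to stepwise (single-reaction) expansion with
eager cycle and depth pruning, branching over cut leaves; whole-subroute
attachment cannot be truncated eagerly because a later merge of a
shared intermediate can raise a molecule's maximum depth after the
subroute was attached, which would silently drop valid cut variants.
Every completed candidate passes through `validate_route` and is
deduplicated by identity, so the declarative definition — not the
search structure — decides what counts as a route.

Determinism: alternatives are explored in lexicographic uid order and
the output is sorted by (number of steps, provenance identity).  The
route budget (default 100,000) raises a partial-result error carrying
the routes found so far.

**Oracle.**  `enumerate_routes_bruteforce` recursively branches over
every producing reaction at every molecule (plus the cut-leaf branch
when a bound is active), prunes provenance cycles, and filters through
`validate_route`.  It is exponential and refuses graphs above a node
limit (default 80).  The test suite and the acceptance script hold the
two-phase miner to identity-set equality with this oracle on every
packaged fixture and on hundreds of seeded random networks, with and
without bounds and stop marks.

## Fixtures and the random generator

The packaged 27-node benchmark (14 molecules, 13 reactions, root `T`)
contains all five challenge phenomena as identifiable subgraphs: the
D↔H reaction cycle, branching inside that cycle (H has an in-cycle and
an out-of-cycle producer), the two-product reaction R11 feeding the
double addition R12, common intermediates G and L, and concurrent
branching at the root through independent OR nodes A and B.  Frozen
route answers ship for the root and four non-root targets and are
regenerated from the oracle in CI; the molecule/reaction split and
topology are this package's own construction, documented here as the
reference benchmark.

`random_noc(n_molecules, n_reactions, or_density, cycle_rate,
max_arity, seed)` builds a layered acyclic base (each reaction produces
one previously unproduced molecule and consumes strictly deeper ones),
then adds alternative producers to single-producer molecules until the
OR fraction approaches `or_density`, and lets each reaction consume one
shallower molecule with probability `cycle_rate` (back-edges, possibly
closing cycles).  Defaults used across the tests — up to 20 molecules
and ~40 total nodes, OR density up to 0.5, cycle rate up to 0.3, arity
up to 3 — keep the oracle tractable (hundreds of graphs in seconds)
while covering the regimes where the algorithm historically breaks:
dense OR structure, shared intermediates, and cycles.  What the
generator does **not** emulate: real SMILES chemistry (labels are
opaque), reagent metadata, the heavy-tailed degree distributions of
patent corpora, and million-route synthetic trees.  Passing tests
therefore certify algorithmic correctness of the graph/route semantics,
not chemical data quality at corpus scale.

## Known limitations

* Exhaustive enumeration is the point, and its cost is exponential in
  the number of interacting OR nodes; bounds, stop marks, and the
  route budget are the mitigation — no scoring, ranking, or learned
  pruning is attempted.
* The "product-to-molecule ratio" sometimes quoted for large corpora
  has no recoverable definition in terms of the node/edge counts this
  package computes and is deliberately not implemented as a named
  statistic.
* The in-memory store targets desk-to-workstation scale; there is no
  disk-backed index, transactional concurrency, or query language.
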