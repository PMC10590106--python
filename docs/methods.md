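# Methods

## Data model

A knowledge graph is a set of typed nodes plus a multiset of directed
triples (head, relation, tail). Triples stay directed for serialization
and for the schema view (the projection of every triple through the
node-type map), but all traversal is undirected: head and tail are
neighbors of each other. Degree counts incident edges, not distinct
neighbors, so parallel edges under different relations each contribute;
the relation profile g(r) — the proportion of a node's incident edges
carrying relation r — is defined over the same edge multiset, which
keeps the walk bias self-consistent. Instance self-loops are rejected
at load time; type-level loops (e.g. a Protein–Protein interaction
relation) are expected and appear in the schema view.

Node types form a forest: `DarkKinase` and `LightKinase` declare
`Protein` as parent. All type-sensitive operations (pattern matching,
start-node eligibility, typed negative sampling) resolve a node's label
through this hierarchy, so a dark kinase satisfies a `Protein`
constraint without losing its specific label.

## Curation filters

Raw source-export tables are reduced before graph construction by pure
row predicates, all with strict inequalities:

- pathway memberships: evidence code must be in the allowed set
  (default `{TAS}`, manually curated only);
- pathway hierarchy: rows under an excluded root are dropped unless the
  pathway also lies under (or is) a keep root — keep overrides exclude.
  Defaults carry the excluded `R-HSA-1643685` (Disease) / kept
  `R-HSA-5663205` (Infectious disease) pair. Explicit root lists were
  chosen over a depth cutoff because they express both the
  "whole subtree" and the "children of top level" readings;
- GO annotations: any term with more than 5,000 associations is removed
  entirely (all its rows);
- protein–protein interactions: experimental score strictly over 700
  and at least one kinase endpoint;
- PTMs: confidence strictly over 1.0;
- domain annotations: `Pkinase` and `Pkinase_Tyr` rows removed (in a
  kinase-only protein set the kinase domain itself is uninformative).

Each filter is idempotent and permutation-invariant; tests compare
surviving-row counts against brute-force scans of the same predicate.

## Patterns and automata

Pattern text is whitespace-separated tokens over the declared type
alphabet: literals, positive classes `[A,B]`, negated classes `[^A,B]`,
each with an optional quantifier `+ * ?`. The full class of regular
patterns is supported (not just the canonical
`Protein [^Pathway]+ Protein Pathway`) because the compilation cost of
generality is negligible: a Thompson NFA followed by subset
construction yields a DFA over the concrete label alphabet. Subtype
admission happens at construction time — each token's matched-label set
is computed through the hierarchy (`Protein` admits `DarkKinase`;
`[^Protein]` rejects it) — so stepping the DFA with a node's concrete
label needs no runtime projection.

The DFA's undefined transitions are the zero-probability steps of the
walker. Correctness is established by exhaustive comparison with an
independent recursive-descent matcher on all 5,461 strings of length
≤ 6 over a 4-letter alphabet, for a battery of seven patterns.

## Walk sampling

At node v with DFA state q the next step distribution is built in two
stages: an edge type r is drawn with probability proportional to g(r),
restricted to edge types possessing at least one admissible neighbor
(dead relations are excluded before normalization, otherwise walks
could stall on probability mass that can never be spent); within r, a
neighbor u is drawn with probability proportional to 1/degree(u),
normalized over r's admissible neighbors. A `single-stage` mode is also
provided that normalizes g(r)·1/degree(u) jointly over all admissible
pairs; the two readings differ whenever relations share neighbors of
unequal degree, and the two-stage form is the default because it
matches the stated sampling procedure (choose a relation, then choose
within it). Probabilities can be computed in exact rational arithmetic
for testing; the sampler uses floats.

Walks collect `walk_length` (L) nodes, default 5 (chosen as the
smallest length that completes the canonical pattern plus one reverse
step; the pattern requires at least 4). Each eligible start node —
any node whose (resolved) type the pattern admits in its first position
— starts `num_walks` (NW) walks, default 40, the most
replicate-consistent value in the 10–80 sweep protocol. A start with no
admissible first move contributes a single length-1 walk rather than NW
identical copies.

A walk that reaches an accepting state with budget left re-emits the
terminal node once, then moves backward: each reverse step pops the DFA
state stack and samples (with the same bias) among neighbors of the
current node whose type is admissible from the popped-to state. One
reversal pass is performed — the walk never re-enters forward mode and
never exceeds L — because nothing licenses oscillation and a single
pass keeps the budget semantics simple. Note that for the canonical
pattern the popped-to state still admits every non-pathway type (the
middle `+` makes the automaton permissive), so reverse steps are free
"random direction" moves; for strictly literal patterns the popped-to
state pins the reverse position to the state before the popped
transition. Walks may end early when stuck (no admissible neighbor);
truncated walks are kept. Walkers never exclude the previous node, so
immediate backtracking is legal — it is part of the stated transition
distribution.

Reproducibility: each (start, repetition) pair gets its own RNG stream
spawned as `SeedSequence(master_seed, spawn_key=(start_index, rep))`,
making corpora byte-identical across runs and independent of
generation order.

## Embeddings

Walks are sentences for skip-gram with negative sampling, implemented
in numpy and trained single-threaded so fixed seeds give byte-identical
matrices. Defaults: dimension 128, window 5 (dynamically shrunk per
center as in word2vec), 5 negatives, 5 epochs, min_count 1, learning
rate 0.025 decaying linearly to 1e-4, unigram^0.75 noise distribution.
Negatives equal to the true context are skipped. The returned vector
for each node is the sum of its input and output vectors: the
input–output product carries first-order (direct co-occurrence)
similarity, input–input carries second-order (shared-context)
similarity, and their sum keeps both — useful here because a
protein–pathway pair is scored directly from its two vectors.

A heterogeneous variant restricts negative sampling to the coarse type
group of the context node, with three groups — Protein, Pathway,
Others — mirroring the 3-way coarsening also used by the PCA
diagnostic. It is opt-in (`type_coarsening=True`); the default
objective is plain SGNS.

Embeddings serialize to word2vec text format (`vocab_size d` header).
`pca_projection` and `type_separation_score` (silhouette over coarse
groups in PCA space) are provided as diagnostics.

## Link prediction

Positives are the edges of the relation of interest; a seeded shuffle
holds out `holdout_fraction` (default 50%) of them, and held-out edges
are removed from the graph before walking so the embedding never sees
them. Negatives are typed non-edges sampled uniformly without
replacement from the full enumerated non-edge space (exact, no
rejection loop), excluding held-out pairs; their count matches the
positives. Features are Hadamard products; the classifier is
scikit-learn logistic regression. The one-vs-rest mode trains one
binary model per pathway class with per-class negative counts matched
to that class's positives. Refitting k-fold cross-validation runs on
the training half only; the holdout is evaluated once (AUC as the
Mann–Whitney rank statistic with ties counting half, f1 at the 0.5
threshold), with per-fold values over a seeded partition of the test
set reported as a dispersion estimate.

Prediction lists keep candidates whose positive-class probability is
strictly over the cutoff. The default candidate universe is
{dark proteins with no known link} × {pathways} minus known positives.
Replicate overlap — the robustness metric — is computed per protein as
|intersection| / |union| × 100 of the cutoff-filtered prediction sets
across replicates, plus the global intersection ("all overlap") across
every replicate of every swept NW value.

## Interpretation

A prediction (p, w) is explained by the walks containing both p and w.
When more than `max_walks` support it, a seeded uniform subsample is
taken (default 5, matching the number of displayed paths in typical
figures). Nodes appearing in at least `min_support` distinct walks
(default 5; within-walk repeats count once) are the common
intermediates; the induced subgraph over them is exported as
tab-separated edge and node-attribute tables loadable in Cytoscape.

## Synthetic study conditions

The generator emulates the shape of a kinase-centric KG: 3 pathways ×
30 proteins (default), each protein connected to a few pathway-specific
context nodes of seven types (MolecularFunction, CellularComponent,
BiologicalProcess, FunctionalDomain, PTM, Chemical, Disease),
within-pathway PPIs at density 0.15 with 1% cross-pathway noise, and 6
high-degree decoy hub nodes with Pareto-tailed (exponent 2.5)
attachment so the inverse-degree bias has something to suppress. A
fifth of each pathway's proteins are dark: their `hasPathway` edge is
withheld from the emitted graph and recorded in the ground truth.
Shared context nodes are the planted signal carrier — co-membership is
expressed through shared intermediates, the same mechanism the
interpretation module surfaces — with PPIs as a secondary signal.

What this does and does not show: passing tests demonstrate that the
method recovers planted membership signal carried by shared typed
context in a hub-skewed heterogeneous graph at desk scale (a few
hundred nodes). The generator does not reproduce the absolute scale
(10^6 nodes), the empirical degree distribution, annotation noise, or
the redundancy structure of real curated databases, so test metrics
are not forecasts of performance on a real KG.

The source-table emitter produces raw-style tables whose values
straddle every curation boundary (scores {650, 700, 701}, confidences
{0.9, 1.0, 1.5}, a GO term at the cap and one just over, TAS and IEA
rows, kinase-domain rows) so each filter rule is exercised at its
threshold by construction.

## Numerical choices and degenerate inputs

- All observable orders are deterministic (sorted ids / relations);
  seeded runs are byte-reproducible end to end.
- Transition probabilities sum to exactly 1 in rational arithmetic;
  the float sampler renormalizes defensively before drawing.
- Empty transition distributions signal "stuck" rather than raising.
- A degree-0 node has no relation profile (error), an empty corpus
  cannot be trained on (error), single-label test sets have no AUC
  (error), and cross-validation folds that end up single-label are
  skipped (reported as None when no fold survives).
- Confidence cutoffs and all curation thresholds are strict.

## Replicate-overlap study conditions

The sweep protocol runs NW ∈ {10..80} × 3 replicates at full scale; the
shipped demonstrations and the acceptance script use a scaled-down grid
(NW ∈ {10, 40} × 3 replicates) at the 0.7 confidence cutoff — one of
the cutoffs the robustness analysis itself uses — because at desk scale
the dark-protein confidences concentrate between 0.7 and 0.95 and the
0.95 cutoff empties every set, which exercises nothing.

## Known limitations

- The reverse phase may step onto a second terminal-type node without
  re-triggering reversal (single-pass by design).
- One-vs-rest predictions for a pathway class unseen in training fall
  back to the mean over class models.
- The SGNS trainer is single-threaded by design; it trades speed for
  bit-reproducibility and is sized for desk-scale graphs, not 10^6-node
  KGs.
- Curation operates on simplified tab-separated exports, not native
  database dump formats.
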