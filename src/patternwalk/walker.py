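"""Pattern-constrained, inverse-degree-biased random walks.

At each forward step the walker sees the current DFA state and the
current node's incident edges.  The next node is chosen in two stages:

1. an edge (relation) type r is drawn with probability proportional to
   g(r), the proportion of the node's incident edges carrying r,
   restricted to relations with at least one pattern-admissible
   neighbor;
2. within that relation, a neighbor v is drawn with probability
   proportional to 1/degree(v), normalized over the relation's
   admissible neighbors.

Neighbors whose type the DFA rejects in the current state get
probability zero.  The inverse-degree bias suppresses hubs, steering
walks toward the sparse neighborhoods of understudied nodes.

An alternative ``single-stage`` bias normalizes g(r) * 1/degree(v)
jointly over all admissible (relation, neighbor) pairs; both modes are
exposed because the two readings give different distributions whenever
relations share neighbors of unequal degree.

When a walk reaches an accepting (terminal-type) node with budget to
spare, the terminal node is collected again and the walk continues in
reverse: the DFA state stack is popped one position per step and a
neighbor admissible at the popped-to state is sampled with the same
bias.  One reversal pass is performed; a walk never exceeds its length
budget and may end early when no admissible neighbor exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Optional

import numpy as np

from .kg import KnowledgeGraph
from .pattern import DFA, REJECT

Bias = Literal["two-stage", "single-stage"]

FORWARD = "forward"
REVERSE = "reverse"


class WalkError(Exception):
    pass


class StartTypeError(WalkError):
    """Walk started from a node whose type the pattern does not admit."""


class ConfigurationError(WalkError):
    pass


@dataclass(frozen=True)
class WalkConfig:
    """Sampling hyperparameters.

    walk_length (L) counts nodes collected per walk; num_walks (NW) is the
    number of repetitions per eligible start node.  The shipped defaults
    are NW=40 (the most replicate-consistent setting in the sweep range
    10-80) and L=5.
    """

    walk_length: int = 5
    num_walks: int = 40
    seed: int = 0
    start_types: Optional[frozenset[str]] = None
    bias: Bias = "two-stage"

    def __post_init__(self):
        if self.walk_length < 2:
            raise ConfigurationError("walk_length must be >= 2")
        if self.num_walks < 1:
            raise ConfigurationError("num_walks must be >= 1")


@dataclass(frozen=True)
class Walk:
    nodes: tuple[str, ...]
    types: tuple[str, ...]
    phases: tuple[str, ...]  # FORWARD | REVERSE per position

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class WalkCorpus:
    walks: list[Walk]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.walks)

    def __iter__(self):
        return iter(self.walks)

    def sentences(self) -> list[list[str]]:
        return [list(w.nodes) for w in self.walks]


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------


def transition_distribution(
    graph: KnowledgeGraph,
    dfa: DFA,
    state: int,
    node: str,
    bias: Bias = "two-stage",
    exact: bool = False,
):
    """Probability of each admissible (relation, neighbor) next step.

    Returns a dict mapping (relation, neighbor) -> probability; the empty
    dict is the stuck signal.  With ``exact=True`` probabilities are
    ``fractions.Fraction`` and sum to 1 exactly.
    """
    one = Fraction(1) if exact else 1.0
    incident = graph.neighbors(node)
    if not incident:
        return {}
    # admissibility: neighbor's concrete label must have a defined transition
    admissible: list[tuple[str, str]] = []
    for rel, nbr in incident:
        if dfa.step(state, graph.node_type(nbr)) is not REJECT:
            admissible.append((rel, nbr))
    if not admissible:
        return {}

    probs: dict[tuple[str, str], object] = {}
    if bias == "single-stage":
        # printed-formula reading: g(r) * invdeg normalized jointly
        rel_counts = graph.relation_counts(node)
        deg = graph.degree(node)
        weights = {}
        for rel, nbr in admissible:
            w = (one * rel_counts[rel] / deg) * (one / graph.degree(nbr))
            weights[(rel, nbr)] = weights.get((rel, nbr), 0 * one) + w
        total = sum(weights.values())
        for key, w in weights.items():
            probs[key] = w / total
    else:
        # two-stage: relation by g(r) over live relations, then inverse degree
        rel_counts = graph.relation_counts(node)
        by_rel: dict[str, list[str]] = {}
        for rel, nbr in admissible:
            by_rel.setdefault(rel, []).append(nbr)
        live_total = sum(rel_counts[r] for r in by_rel)
        for rel, nbrs in by_rel.items():
            p_rel = one * rel_counts[rel] / live_total
            inv = {}
            for nbr in nbrs:  # parallel edges to the same neighbor accumulate
                inv[nbr] = inv.get(nbr, 0 * one) + one / graph.degree(nbr)
            z = sum(inv.values())
            for nbr, w in inv.items():
                key = (rel, nbr)
                probs[key] = probs.get(key, 0 * one) + p_rel * w / z
    return probs


def _sample(probs: dict, rng: np.random.Generator):
    keys = sorted(probs)
    p = np.array([float(probs[k]) for k in keys], dtype=float)
    p /= p.sum()
    idx = rng.choice(len(keys), p=p)
    return keys[idx]


# ---------------------------------------------------------------------------
# walk generation
# ---------------------------------------------------------------------------


def generate_walk(
    graph: KnowledgeGraph,
    dfa: DFA,
    start: str,
    config: WalkConfig,
    rng: np.random.Generator,
) -> Walk:
    """One pattern-constrained walk from ``start`` (forward + optional reverse)."""
    start_label = graph.node_type(start)
    state = dfa.step(dfa.start, start_label)
    if state is REJECT:
        raise StartTypeError(f"node {start!r} of type {start_label!r} cannot start the pattern")
    if config.start_types is not None:
        lineage = set(graph.hierarchy.ancestors(start_label))
        if not (lineage & set(config.start_types)):
            raise StartTypeError(f"type {start_label!r} not in configured start types")

    nodes = [start]
    types = [start_label]
    phases = [FORWARD]
    stack = [dfa.start, state]
    budget = config.walk_length

    # forward phase: walk until acceptance, budget, or stuck
    while len(nodes) < budget and not dfa.is_accepting(stack[-1]):
        probs = transition_distribution(graph, dfa, stack[-1], nodes[-1], config.bias)
        if not probs:
            return Walk(tuple(nodes), tuple(types), tuple(phases))  # ended early
        rel, nbr = _sample(probs, rng)
        nodes.append(nbr)
        types.append(graph.node_type(nbr))
        phases.append(FORWARD)
        stack.append(dfa.step(stack[-1], types[-1]))

    if not dfa.is_accepting(stack[-1]) or len(nodes) >= budget:
        return Walk(tuple(nodes), tuple(types), tuple(phases))

    # reverse phase: re-collect the terminal node, then walk back through
    # pattern positions by popping the state stack
    nodes.append(nodes[-1])
    types.append(types[-1])
    phases.append(REVERSE)
    while len(nodes) < budget and len(stack) > 1:
        stack.pop()
        state = stack[-1]
        probs = transition_distribution(graph, dfa, state, nodes[-1], config.bias)
        if not probs:
            break
        rel, nbr = _sample(probs, rng)
        nodes.append(nbr)
        types.append(graph.node_type(nbr))
        phases.append(REVERSE)
    return Walk(tuple(nodes), tuple(types), tuple(phases))


def eligible_starts(graph: KnowledgeGraph, dfa: DFA, config: WalkConfig) -> list[str]:
    out = []
    for node in graph.nodes:
        label = graph.node_type(node)
        if dfa.step(dfa.start, label) is REJECT:
            continue
        if config.start_types is not None:
            lineage = set(graph.hierarchy.ancestors(label))
            if not (lineage & set(config.start_types)):
                continue
        out.append(node)
    return out


def generate_corpus(graph: KnowledgeGraph, dfa: DFA, config: WalkConfig) -> WalkCorpus:
    """num_walks seeded walks from every eligible start node (sorted order).

    Per-(start, repetition) RNG streams are spawned from the master seed
    with ``numpy.random.SeedSequence(seed, spawn_key=(start_idx, rep))``,
    so corpora are reproducible and independent of generation order.
    Start nodes with no admissible first step contribute a single
    length-1 walk instead of num_walks identical ones.
    """
    starts = eligible_starts(graph, dfa, config)
    if not starts:
        raise ConfigurationError("no eligible start nodes for this pattern")
    walks: list[Walk] = []
    for start_idx, start in enumerate(starts):
        state = dfa.step(dfa.start, graph.node_type(start))
        first = transition_distribution(graph, dfa, state, start, config.bias)
        if not first:
            walks.append(
                Walk((start,), (graph.node_type(start),), (FORWARD,))
            )
            continue
        for rep in range(config.num_walks):
            seq = np.random.SeedSequence(config.seed, spawn_key=(start_idx, rep))
            rng = np.random.default_rng(seq)
            walks.append(generate_walk(graph, dfa, start, config, rng))
    metadata = {
        "seed": config.seed,
        "walk_length": config.walk_length,
        "num_walks": config.num_walks,
        "bias": config.bias,
        "start_types": sorted(config.start_types) if config.start_types else None,
        "graph_fingerprint": graph.fingerprint(),
    }
    return WalkCorpus(walks, metadata)


# ---------------------------------------------------------------------------
# corpus I/O: one walk per line, ids space-separated, JSON metadata sidecar
# ---------------------------------------------------------------------------


def write_corpus(corpus: WalkCorpus, path) -> None:
    path = str(path)
    with open(path, "w", encoding="utf-8") as fh:
        for walk in corpus.walks:
            fh.write(" ".join(walk.nodes) + "\n")
    sidecar = dict(corpus.metadata)
    sidecar["types"] = [list(w.types) for w in corpus.walks]
    sidecar["phases"] = [list(w.phases) for w in corpus.walks]
    with open(path + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=0, sort_keys=True)


def read_corpus(path) -> WalkCorpus:
    path = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [line.split() for line in fh if line.strip()]
    try:
        with open(path + ".meta.json", "r", encoding="utf-8") as fh:
            sidecar = json.load(fh)
    except FileNotFoundError:
        sidecar = {}
    types = sidecar.pop("types", None)
    phases = sidecar.pop("phases", None)
    walks = []
    for i, nodes in enumerate(lines):
        t = tuple(types[i]) if types else ("",) * len(nodes)
        p = tuple(phases[i]) if phases else (FORWARD,) * len(nodes)
        walks.append(Walk(tuple(nodes), t, p))
    return WalkCorpus(walks, sidecar)
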