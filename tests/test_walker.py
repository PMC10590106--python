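from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from patternwalk import (
    KnowledgeGraph,
    TypeHierarchy,
    WalkConfig,
    compile_dfa,
    generate_corpus,
    generate_walk,
    parse_pattern,
    read_corpus,
    transition_distribution,
    write_corpus,
)
from patternwalk.pattern import REJECT
from patternwalk.walker import (
    FORWARD,
    REVERSE,
    ConfigurationError,
    StartTypeError,
    eligible_starts,
)

from conftest import ALPHABET4, random_typed_graph


def dfa_for(graph, text="Protein [^Pathway]+ Protein Pathway"):
    labels = set(graph.schema_view().node_types)
    labels |= {a for t in labels for a in graph.hierarchy.ancestors(t)}
    labels |= {"Protein", "Pathway"}  # pattern vocabulary even when absent from the fixture
    return compile_dfa(parse_pattern(text, labels), labels, graph.hierarchy)


class TestTransitionDistribution:
    def test_inverse_degree_star(self):
        """Admissible neighbors of degree {1,2,4} get probabilities {4/7, 2/7, 1/7}."""
        nodes = {"c": "Protein", "a": "GOTerm", "b": "GOTerm", "d": "GOTerm",
                 "b2": "Disease", "d2": "Disease", "d3": "Disease", "d4": "Disease"}
        triples = [("c", "r", "a"), ("c", "r", "b"), ("c", "r", "d"),
                   ("b", "r", "b2"), ("d", "r", "d2"), ("d", "r", "d3"), ("d", "r", "d4")]
        g = KnowledgeGraph(nodes, triples)
        dfa = dfa_for(g)
        state = dfa.step(dfa.start, "Protein")
        probs = transition_distribution(g, dfa, state, "c", exact=True)
        assert probs[("r", "a")] == Fraction(4, 7)
        assert probs[("r", "b")] == Fraction(2, 7)
        assert probs[("r", "d")] == Fraction(1, 7)

    def test_disallowed_type_gets_zero(self, chain_graph):
        dfa = dfa_for(chain_graph)
        state = dfa.step(dfa.start, "Protein")  # [^Pathway]+ next: Pathway rejected
        nodes = {"p": "Protein", "w": "Pathway", "g": "GOTerm"}
        g = KnowledgeGraph(nodes, [("p", "r", "w"), ("p", "r", "g")])
        dfa2 = dfa_for(g)
        s = dfa2.step(dfa2.start, "Protein")
        probs = transition_distribution(g, dfa2, s, "p")
        assert ("r", "w") not in probs
        assert probs[("r", "g")] == 1.0

    def test_two_stage_relation_proportions(self):
        """g(r) proportions {3/4, 1/4} carry through to unit-degree neighbors."""
        nodes = {"c": "Protein", "x1": "GOTerm", "x2": "GOTerm", "x3": "GOTerm",
                 "y1": "Disease"}
        triples = [("c", "a", "x1"), ("c", "a", "x2"), ("c", "a", "x3"), ("c", "b", "y1")]
        g = KnowledgeGraph(nodes, triples)
        dfa = dfa_for(g)
        s = dfa.step(dfa.start, "Protein")
        probs = transition_distribution(g, dfa, s, "c", exact=True)
        assert sum(p for (r, _), p in probs.items() if r == "a") == Fraction(3, 4)
        assert probs[("b", "y1")] == Fraction(1, 4)

    @pytest.mark.parametrize("bias", ["two-stage", "single-stage"])
    def test_probability_conservation_exact(self, bias):
        rng = np.random.default_rng(11)
        g = random_typed_graph(rng, n_nodes=30, n_edges=80)
        dfa = dfa_for(g)
        checked = 0
        for node in g.nodes:
            if g.node_type(node) != "Protein" or g.degree(node) == 0:
                continue
            s = dfa.step(dfa.start, g.node_type(node))
            probs = transition_distribution(g, dfa, s, node, bias=bias, exact=True)
            if probs:
                assert sum(probs.values()) == Fraction(1)
                checked += 1
        assert checked > 5

    def test_empty_mapping_is_stuck_signal(self):
        g = KnowledgeGraph({"p": "Protein", "w": "Pathway"}, [("p", "r", "w")])
        dfa = dfa_for(g)
        s = dfa.step(dfa.start, "Protein")
        assert transition_distribution(g, dfa, s, "p") == {}

    def test_monte_carlo_frequencies_within_3_se(self):
        """10^5 draws from the degree-{1,2,4} star match {4/7, 2/7, 1/7}."""
        nodes = {"c": "Protein", "a": "GOTerm", "b": "GOTerm", "d": "GOTerm",
                 "b2": "Disease", "d2": "Disease", "d3": "Disease", "d4": "Disease"}
        triples = [("c", "r", "a"), ("c", "r", "b"), ("c", "r", "d"),
                   ("b", "r", "b2"), ("d", "r", "d2"), ("d", "r", "d3"), ("d", "r", "d4")]
        g = KnowledgeGraph(nodes, triples)
        dfa = dfa_for(g)
        s = dfa.step(dfa.start, "Protein")
        probs = transition_distribution(g, dfa, s, "c")
        keys = sorted(probs)
        p = np.array([probs[k] for k in keys])
        rng = np.random.default_rng(42)
        n = 100_000
        draws = rng.choice(len(keys), size=n, p=p / p.sum())
        freqs = np.bincount(draws, minlength=len(keys)) / n
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freqs - p) <= 3 * se)


class TestGenerateWalk:
    def test_chain_walks_valid_and_full_chain_reachable(self, chain_graph):
        """On the p1—g1—p2—w1 chain every sampled walk is a valid pattern
        prefix; the full chain [p1,g1,p2,w1] is reachable (the walker may
        also legally backtrack p1<->g1, so the forward phase is stochastic)."""
        dfa = dfa_for(chain_graph)
        seen_full = False
        for seed in range(20):
            rng = np.random.default_rng(seed)
            walk = generate_walk(chain_graph, dfa, "p1", WalkConfig(walk_length=4), rng)
            assert all(ph == FORWARD for ph in walk.phases)
            dfa.reverse_state_track(list(walk.types))  # raises if invalid prefix
            if walk.nodes == ("p1", "g1", "p2", "w1"):
                seen_full = True
        assert seen_full

    def test_chain_reversal_with_budget(self, chain_graph):
        """Once the forward phase reaches w1 with budget left, the
        continuation is forced: re-emit w1, then one reverse step to p2
        (the only admissible Protein neighbor)."""
        dfa = dfa_for(chain_graph)
        checked = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            walk = generate_walk(chain_graph, dfa, "p1", WalkConfig(walk_length=6), rng)
            if walk.nodes[:4] == ("p1", "g1", "p2", "w1"):
                assert walk.nodes == ("p1", "g1", "p2", "w1", "w1", "p2")
                assert walk.phases == (FORWARD,) * 4 + (REVERSE,) * 2
                checked += 1
        assert checked > 0

    def test_pathway_start_is_error(self, chain_graph):
        dfa = dfa_for(chain_graph)
        rng = np.random.default_rng(0)
        with pytest.raises(StartTypeError):
            generate_walk(chain_graph, dfa, "w1", WalkConfig(), rng)

    def test_stuck_walk_kept_truncated(self):
        # p's only neighbor is a Pathway, rejected as the second position:
        # the walk ends early at length 1 and is still emitted
        g = KnowledgeGraph({"p": "Protein", "w": "Pathway"}, [("p", "r", "w")])
        dfa = dfa_for(g)
        rng = np.random.default_rng(0)
        walk = generate_walk(g, dfa, "p", WalkConfig(walk_length=5), rng)
        assert walk.nodes == ("p",)
        assert walk.phases == (FORWARD,)

    def test_forward_prefix_always_valid_and_reverse_after_accept(self):
        rng_graph = np.random.default_rng(5)
        g = random_typed_graph(rng_graph, n_nodes=40, n_edges=120)
        dfa = dfa_for(g)
        cfg = WalkConfig(walk_length=7, num_walks=5, seed=3)
        corpus = generate_corpus(g, dfa, cfg)
        for walk in corpus:
            fwd = [t for t, ph in zip(walk.types, walk.phases) if ph == FORWARD]
            stack = dfa.reverse_state_track(fwd)  # raises if invalid prefix
            if REVERSE in walk.phases:
                assert dfa.is_accepting(stack[-1])
                # re-emission: first reverse position repeats the terminal node
                i = walk.phases.index(REVERSE)
                assert walk.nodes[i] == walk.nodes[i - 1]


class TestCorpus:
    def test_walk_count(self, chain_graph):
        dfa = dfa_for(chain_graph)
        cfg = WalkConfig(walk_length=4, num_walks=10, seed=1)
        corpus = generate_corpus(chain_graph, dfa, cfg)
        # eligible starts: p1, p2 (Protein), both admit a first step
        assert len(corpus) == 20

    def test_determinism_same_seed(self):
        g = random_typed_graph(np.random.default_rng(9), n_nodes=30, n_edges=90)
        dfa = dfa_for(g)
        cfg = WalkConfig(walk_length=5, num_walks=4, seed=7)
        c1 = generate_corpus(g, dfa, cfg)
        c2 = generate_corpus(g, dfa, cfg)
        assert c1.walks == c2.walks

    def test_different_seeds_differ(self):
        g = random_typed_graph(np.random.default_rng(9), n_nodes=30, n_edges=90)
        dfa = dfa_for(g)
        c1 = generate_corpus(g, dfa, WalkConfig(walk_length=5, num_walks=4, seed=7))
        c2 = generate_corpus(g, dfa, WalkConfig(walk_length=5, num_walks=4, seed=8))
        assert c1.walks != c2.walks

    def test_no_eligible_starts_is_configuration_error(self):
        g = KnowledgeGraph({"w": "Pathway", "d": "Disease"}, [("w", "r", "d")])
        dfa = dfa_for(g)
        with pytest.raises(ConfigurationError):
            generate_corpus(g, dfa, WalkConfig())

    def test_start_types_filter(self, hierarchy):
        g = KnowledgeGraph(
            {"d": "DarkKinase", "p": "Protein", "g": "GOTerm", "q": "Protein", "w": "Pathway"},
            [("d", "r", "g"), ("p", "r", "g"), ("g", "r", "q"), ("q", "hasPathway", "w")],
            hierarchy,
        )
        dfa = dfa_for(g)
        cfg = WalkConfig(start_types=frozenset({"DarkKinase"}))
        assert eligible_starts(g, dfa, cfg) == ["d"]

    def test_round_trip(self, tmp_path, chain_graph):
        dfa = dfa_for(chain_graph)
        corpus = generate_corpus(chain_graph, dfa, WalkConfig(walk_length=6, num_walks=3, seed=2))
        path = tmp_path / "corpus.txt"
        write_corpus(corpus, path)
        text = path.read_text().splitlines()
        assert text[0].split() == list(corpus.walks[0].nodes)
        loaded = read_corpus(path)
        assert [w.nodes for w in loaded] == [w.nodes for w in corpus]
        assert [w.phases for w in loaded] == [w.phases for w in corpus]

    def test_empty_corpus_write(self, tmp_path):
        from patternwalk.walker import WalkCorpus

        path = tmp_path / "empty.txt"
        write_corpus(WalkCorpus([], {"seed": 0}), path)
        assert path.read_text() == ""
        assert len(read_corpus(path)) == 0


class TestBiasProperties:
    def test_hub_suppression_on_power_law_graph(self):
        """Inverse-degree walks visit lower-degree nodes than uniform walks."""
        from patternwalk.synthetic import SyntheticKGConfig, generate

        g, _ = generate(SyntheticKGConfig(seed=23))
        dfa = dfa_for(g)
        cfg = WalkConfig(walk_length=5, num_walks=5, seed=13)
        corpus = generate_corpus(g, dfa, cfg)
        biased_mean = np.mean([g.degree(n) for w in corpus for n in w.nodes[1:]])

        # uniform baseline: same constraint, neighbor chosen uniformly
        rng = np.random.default_rng(13)
        uniform_degrees = []
        starts = eligible_starts(g, dfa, cfg)
        for start in starts:
            for _ in range(cfg.num_walks):
                state = dfa.step(dfa.start, g.node_type(start))
                node, stack = start, [dfa.start, state]
                for _step in range(cfg.walk_length - 1):
                    if dfa.is_accepting(stack[-1]):
                        break
                    options = [
                        (r, nbr)
                        for r, nbr in g.neighbors(node)
                        if dfa.step(stack[-1], g.node_type(nbr)) is not REJECT
                    ]
                    if not options:
                        break
                    r, nbr = options[rng.integers(len(options))]
                    stack.append(dfa.step(stack[-1], g.node_type(nbr)))
                    node = nbr
                    uniform_degrees.append(g.degree(node))
        assert biased_mean < np.mean(uniform_degrees)
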