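import numpy as np
import pytest

from patternwalk import (
    DEFAULT_PATTERN_TEXT,
    KnowledgeGraph,
    TypeHierarchy,
    compile_dfa,
    parse_pattern,
)

ALPHABET4 = {"Protein", "Pathway", "GOTerm", "Disease"}


@pytest.fixture(scope="session")
def hierarchy():
    return TypeHierarchy({"DarkKinase": "Protein", "LightKinase": "Protein"})


@pytest.fixture
def star_graph():
    """Hub c with edges (c,a,n1), (c,a,n2), (c,b,n3)."""
    nodes = {"c": "Protein", "n1": "GOTerm", "n2": "GOTerm", "n3": "Pathway", "iso": "Protein"}
    triples = [("c", "a", "n1"), ("c", "a", "n2"), ("c", "b", "n3")]
    return KnowledgeGraph(nodes, triples)


@pytest.fixture
def chain_graph():
    """p1—g1—p2—w1: unique admissible choice at every step of the canonical pattern."""
    nodes = {"p1": "Protein", "g1": "GOTerm", "p2": "Protein", "w1": "Pathway"}
    triples = [("p1", "hasGO", "g1"), ("g1", "hasGO", "p2"), ("p2", "hasPathway", "w1")]
    return KnowledgeGraph(nodes, triples)


@pytest.fixture(scope="session")
def canonical_dfa():
    pattern = parse_pattern("Protein [^Pathway]+ Protein Pathway", ALPHABET4)
    return compile_dfa(pattern, ALPHABET4)


def random_typed_graph(rng: np.random.Generator, n_nodes: int = 40, n_edges: int = 100):
    """Random heterogeneous multigraph for fuzz fixtures."""
    types = ["Protein", "Pathway", "GOTerm", "Disease"]
    relations = ["hasPathway", "hasGO", "assoc", "ppi"]
    nodes = {f"n{i}": types[rng.integers(len(types))] for i in range(n_nodes)}
    ids = list(nodes)
    triples = []
    while len(triples) < n_edges:
        h, t = rng.choice(ids, size=2, replace=False)
        triples.append((h, relations[rng.integers(len(relations))], t))
    return KnowledgeGraph(nodes, triples)


def brute_force_match(tokens, labels, hierarchy=None):
    """Independent recursive-descent matcher over pattern tokens.

    Kept free of any automaton machinery so it can serve as the oracle
    for the compiled DFA.
    """
    from patternwalk.kg import TypeHierarchy
    from patternwalk.pattern import Quantifier

    hierarchy = hierarchy or TypeHierarchy()

    def match(ti: int, li: int) -> bool:
        if ti == len(tokens):
            return li == len(labels)
        token = tokens[ti]
        q = token.quantifier
        if q == Quantifier.ONE:
            return (
                li < len(labels)
                and token.matches(labels[li], hierarchy)
                and match(ti + 1, li + 1)
            )
        if q == Quantifier.OPTIONAL:
            if match(ti + 1, li):
                return True
            return (
                li < len(labels)
                and token.matches(labels[li], hierarchy)
                and match(ti + 1, li + 1)
            )
        if q == Quantifier.ZERO_OR_MORE:
            if match(ti + 1, li):
                return True
            j = li
            while j < len(labels) and token.matches(labels[j], hierarchy):
                j += 1
                if match(ti + 1, j):
                    return True
            return False
        if q == Quantifier.ONE_OR_MORE:
            j = li
            while j < len(labels) and token.matches(labels[j], hierarchy):
                j += 1
                if match(ti + 1, j):
                    return True
            return False
        raise AssertionError(q)

    return match(0, 0)


def all_strings(alphabet, max_len):
    """Every label sequence of length 0..max_len (exhaustive oracle input)."""
    import itertools

    letters = sorted(alphabet)
    for length in range(max_len + 1):
        yield from itertools.product(letters, repeat=length)
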