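"""Regular patterns over node-type labels and their compiled automata.

A walk constraint such as ``Protein [^Pathway]+ Protein Pathway`` is a
regular expression whose alphabet is the node-type vocabulary: the walk
must start at a Protein, traverse one or more non-Pathway nodes, pass a
second Protein and end on a Pathway.  The pattern is compiled via a
Thompson NFA and subset construction into a DFA whose undefined
transitions carry zero walk probability.

Subtype labels are admitted wherever an ancestor is: a token
``Protein`` matches a ``DarkKinase`` node when the hierarchy declares
``DarkKinase -> Protein``.  Negated classes respect the hierarchy too:
``[^Protein]`` rejects a DarkKinase.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .kg import TypeHierarchy


class PatternError(Exception):
    """Base class for pattern errors."""


class PatternSyntaxError(PatternError):
    """Malformed pattern text."""


class VocabularyError(PatternError):
    """Pattern uses a label outside the declared type alphabet."""


class Quantifier(enum.Enum):
    ONE = ""
    ONE_OR_MORE = "+"
    ZERO_OR_MORE = "*"
    OPTIONAL = "?"


@dataclass(frozen=True)
class Token:
    """One pattern position: a literal, positive class or negated class."""

    labels: frozenset[str]
    negated: bool
    quantifier: Quantifier = Quantifier.ONE

    def matches(self, label: str, hierarchy: TypeHierarchy) -> bool:
        lineage = set(hierarchy.ancestors(label))
        hit = bool(lineage & self.labels)
        return not hit if self.negated else hit

    def __str__(self) -> str:
        if self.negated:
            body = "[^" + ",".join(sorted(self.labels)) + "]"
        elif len(self.labels) == 1:
            body = next(iter(self.labels))
        else:
            body = "[" + ",".join(sorted(self.labels)) + "]"
        return body + self.quantifier.value


@dataclass(frozen=True)
class RegularPattern:
    tokens: tuple[Token, ...]
    text: str

    def __post_init__(self):
        if len(self.tokens) < 2:
            raise PatternSyntaxError("a pattern needs at least 2 tokens")


REJECT = object()  # sentinel returned by DFA.step for undefined transitions

_QUANTIFIERS = {q.value: q for q in Quantifier if q.value}


def parse_pattern(text: str, alphabet: set[str]) -> RegularPattern:
    """Parse whitespace-separated pattern text over the declared type alphabet.

    Grammar per token: ``Label``, ``[A,B]`` (positive class) or ``[^A,B]``
    (negated class), each optionally suffixed with ``+ * ?``.
    """
    raw = text.split()
    if not raw:
        raise PatternSyntaxError("empty pattern")
    tokens = []
    for i, chunk in enumerate(raw, 1):
        quant = Quantifier.ONE
        if chunk and chunk[-1] in _QUANTIFIERS:
            quant = _QUANTIFIERS[chunk[-1]]
            chunk = chunk[:-1]
        if not chunk:
            raise PatternSyntaxError(f"bare quantifier at token {i}")
        if chunk.startswith("["):
            if not chunk.endswith("]") or len(chunk) < 3:
                raise PatternSyntaxError(f"unterminated class at token {i}")
            body = chunk[1:-1]
            negated = body.startswith("^")
            if negated:
                body = body[1:]
            labels = [lab for lab in body.split(",") if lab]
            if not labels:
                raise PatternSyntaxError(f"empty class at token {i}")
        else:
            negated = False
            labels = [chunk]
        for lab in labels:
            if lab not in alphabet:
                raise VocabularyError(f"unknown type label {lab!r} at token {i}")
        tokens.append(Token(frozenset(labels), negated, quant))
    return RegularPattern(tuple(tokens), text)


class DFA:
    """Deterministic automaton over node-type labels.

    ``transition`` is a partial map (state, label) -> state; walking code
    treats a missing entry as probability zero.  States are small ints,
    0 is the start state.
    """

    def __init__(
        self,
        n_states: int,
        transition: dict[tuple[int, str], int],
        accepting: frozenset[int],
        alphabet: frozenset[str],
    ):
        self.n_states = n_states
        self.transition = transition
        self.accepting = accepting
        self.alphabet = alphabet
        admissible: dict[int, set[str]] = {s: set() for s in range(n_states)}
        for (state, label), _target in transition.items():
            admissible[state].add(label)
        self._admissible = {s: frozenset(v) for s, v in admissible.items()}

    @property
    def start(self) -> int:
        return 0

    def step(self, state: int, label: str):
        """Next state, or the REJECT sentinel when the transition is undefined."""
        if not (0 <= state < self.n_states):
            raise ValueError(f"state {state} outside the state set")
        return self.transition.get((state, label), REJECT)

    def admissible_labels(self, state: int) -> frozenset[str]:
        if not (0 <= state < self.n_states):
            raise ValueError(f"state {state} outside the state set")
        return self._admissible[state]

    def is_accepting(self, state: int) -> bool:
        return state in self.accepting

    def matches(self, type_sequence: Sequence[str]) -> bool:
        state = self.start
        for label in type_sequence:
            state = self.step(state, label)
            if state is REJECT:
                return False
        return state in self.accepting

    def reverse_state_track(self, consumed: Sequence[str]) -> list[int]:
        """Stack of states visited while consuming a valid prefix (start first).

        The walker's reverse mode pops this stack: each pop re-enters the
        previous pattern position.
        """
        stack = [self.start]
        for label in consumed:
            nxt = self.step(stack[-1], label)
            if nxt is REJECT:
                raise ValueError(f"{list(consumed)!r} is not a valid prefix (failed at {label!r})")
            stack.append(nxt)
        return stack


def compile_dfa(
    pattern: RegularPattern,
    alphabet: set[str],
    hierarchy: Optional[TypeHierarchy] = None,
) -> DFA:
    """Compile a pattern to a DFA via Thompson NFA + subset construction.

    The DFA alphabet is the full declared label set (subtypes included), so
    stepping with a node's concrete label needs no projection: a
    ``DarkKinase`` label transitions wherever ``Protein`` is admissible.
    """
    hierarchy = hierarchy or TypeHierarchy()
    labels = sorted(alphabet)

    # Thompson construction: NFA states are ints, transitions on label sets,
    # plus epsilon moves.  Each token contributes a (enter, exit) fragment.
    eps: dict[int, set[int]] = {}
    moves: dict[int, list[tuple[frozenset[str], int]]] = {}
    counter = [0]

    def new_state() -> int:
        counter[0] += 1
        return counter[0] - 1

    def add_eps(a: int, b: int) -> None:
        eps.setdefault(a, set()).add(b)

    start = new_state()
    current = start
    for token in pattern.tokens:
        matched = frozenset(lab for lab in labels if token.matches(lab, hierarchy))
        frag_in = new_state()
        frag_out = new_state()
        moves.setdefault(frag_in, []).append((matched, frag_out))
        if token.quantifier is Quantifier.ONE:
            add_eps(current, frag_in)
        elif token.quantifier is Quantifier.ONE_OR_MORE:
            add_eps(current, frag_in)
            add_eps(frag_out, frag_in)
        elif token.quantifier is Quantifier.ZERO_OR_MORE:
            add_eps(current, frag_in)
            add_eps(current, frag_out)
            add_eps(frag_out, frag_in)
        elif token.quantifier is Quantifier.OPTIONAL:
            add_eps(current, frag_in)
            add_eps(current, frag_out)
        current = frag_out
    nfa_accept = current

    def eps_closure(states: frozenset[int]) -> frozenset[int]:
        out = set(states)
        stack = list(states)
        while stack:
            s = stack.pop()
            for t in eps.get(s, ()):
                if t not in out:
                    out.add(t)
                    stack.append(t)
        return frozenset(out)

    # subset construction over the concrete label alphabet
    start_set = eps_closure(frozenset({start}))
    index: dict[frozenset[int], int] = {start_set: 0}
    order = [start_set]
    transition: dict[tuple[int, str], int] = {}
    i = 0
    while i < len(order):
        cur = order[i]
        for lab in labels:
            nxt = set()
            for s in cur:
                for matched, target in moves.get(s, ()):
                    if lab in matched:
                        nxt.add(target)
            if not nxt:
                continue
            closed = eps_closure(frozenset(nxt))
            if closed not in index:
                index[closed] = len(order)
                order.append(closed)
            transition[(index[cur], lab)] = index[closed]
        i += 1

    accepting = frozenset(index[s] for s in order if nfa_accept in s)
    return DFA(len(order), transition, accepting, frozenset(labels))


DEFAULT_PATTERN_TEXT = "Protein [^Pathway]+ Protein Pathway"
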