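"""CTL (computation tree logic) over finite state graphs.

Formulas are built from atoms comparing an entity's level with a
constant (``p53=1``, ``IGF>=0``), boolean connectives, and the eight
path-quantified temporal operators ``EX AX EF AF EG AG E[.U.] A[.U.]``.
Evaluation is the standard fixpoint labeling, with *finite-path*
semantics at deadlocks: a maximal path ending in a state without
successors counts as a full path.  Concretely, ``EX`` is false and
``AX`` vacuously true at deadlocks, ``AG phi`` can hold on a terminating
path, and ``AF phi`` at a deadlock requires ``phi`` there.

Grammar (EBNF)::

    formula  ::= iff
    iff      ::= implies ( "<->" implies )*
    implies  ::= or ( "->" implies )?          (right associative)
    or       ::= and ( "|" and )*
    and      ::= unary ( "&" unary )*
    unary    ::= "!" unary
               | ("EX"|"AX"|"EF"|"AF"|"EG"|"AG") unary
               | "E" "[" formula "U" formula "]"
               | "A" "[" formula "U" formula "]"
               | "(" formula ")" | "true" | "false" | atom
    atom     ::= NAME ("="|">="|"<="|">"|"<") INT

Entity names may contain letters, digits, ``_``, ``/``, ``.`` and ``-``
(a ``-`` immediately followed by ``>`` terminates the name so that
``->`` still parses as implication).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

from .brn import State, StateGraph

# ---------------------------------------------------------------------------
# Abstract syntax


@dataclass(frozen=True)
class CTLFormula:
    def __str__(self) -> str:
        return to_text(self)


@dataclass(frozen=True)
class TrueF(CTLFormula):
    pass


@dataclass(frozen=True)
class FalseF(CTLFormula):
    pass


@dataclass(frozen=True)
class Atom(CTLFormula):
    entity: str
    op: str  # one of = >= <= > <
    level: int


@dataclass(frozen=True)
class Not(CTLFormula):
    child: CTLFormula


@dataclass(frozen=True)
class And(CTLFormula):
    left: CTLFormula
    right: CTLFormula


@dataclass(frozen=True)
class Or(CTLFormula):
    left: CTLFormula
    right: CTLFormula


@dataclass(frozen=True)
class Implies(CTLFormula):
    left: CTLFormula
    right: CTLFormula


@dataclass(frozen=True)
class Iff(CTLFormula):
    left: CTLFormula
    right: CTLFormula


@dataclass(frozen=True)
class Temporal(CTLFormula):
    """Unary temporal operator: op in {EX, AX, EF, AF, EG, AG}."""

    op: str
    child: CTLFormula


@dataclass(frozen=True)
class Until(CTLFormula):
    """``E[left U right]`` or ``A[left U right]``; quant in {E, A}."""

    quant: str
    left: CTLFormula
    right: CTLFormula


def EX(f):  # noqa: N802 - conventional CTL operator names
    return Temporal("EX", f)


def AX(f):  # noqa: N802
    return Temporal("AX", f)


def EF(f):  # noqa: N802
    return Temporal("EF", f)


def AF(f):  # noqa: N802
    return Temporal("AF", f)


def EG(f):  # noqa: N802
    return Temporal("EG", f)


def AG(f):  # noqa: N802
    return Temporal("AG", f)


def state_atom(entities: List[str], state: State) -> CTLFormula:
    """Conjunctive atom pinning every coordinate of ``state``."""
    f: CTLFormula = Atom(entities[0], "=", state[0])
    for name, lvl in zip(entities[1:], state[1:]):
        f = And(f, Atom(name, "=", lvl))
    return f


# ---------------------------------------------------------------------------
# Parsing


class CTLSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<iff><->)
  | (?P<implies>->)
  | (?P<cmp>>=|<=|=|>|<)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<lbrk>\[)
  | (?P<rbrk>\])
  | (?P<not>!)
  | (?P<and>&)
  | (?P<or>\|)
  | (?P<int>\d+)
  | (?P<name>[^\W\d](?:[\w/.]|-(?!>))*)
    """,
    re.VERBOSE | re.UNICODE,
)

_TEMPORAL_OPS = {"EX", "AX", "EF", "AF", "EG", "AG"}


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise CTLSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> Tuple[str, str, int]:
        return self.tokens[self.i]

    def next(self) -> Tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, value: str | None = None) -> Tuple[str, str, int]:
        tok = self.next()
        if tok[0] != kind or (value is not None and tok[1] != value):
            raise CTLSyntaxError(
                f"expected {value or kind!r}, found {tok[1] or 'end of input'!r}", tok[2]
            )
        return tok

    def parse(self) -> CTLFormula:
        f = self.iff()
        tok = self.peek()
        if tok[0] != "eof":
            raise CTLSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return f

    def iff(self) -> CTLFormula:
        f = self.implies()
        while self.peek()[0] == "iff":
            self.next()
            f = Iff(f, self.implies())
        return f

    def implies(self) -> CTLFormula:
        f = self.or_()
        if self.peek()[0] == "implies":
            self.next()
            return Implies(f, self.implies())
        return f

    def or_(self) -> CTLFormula:
        f = self.and_()
        while self.peek()[0] == "or":
            self.next()
            f = Or(f, self.and_())
        return f

    def and_(self) -> CTLFormula:
        f = self.unary()
        while self.peek()[0] == "and":
            self.next()
            f = And(f, self.unary())
        return f

    def unary(self) -> CTLFormula:
        kind, value, pos = self.peek()
        if kind == "not":
            self.next()
            return Not(self.unary())
        if kind == "lpar":
            self.next()
            f = self.iff()
            self.expect("rpar")
            return f
        if kind == "name":
            if value in _TEMPORAL_OPS and not self._starts_atom(self.i + 1):
                self.next()
                return Temporal(value, self.unary())
            if value in ("E", "A") and self.tokens[self.i + 1][0] == "lbrk":
                self.next()
                self.expect("lbrk")
                left = self.iff()
                self.expect("name", "U")
                right = self.iff()
                self.expect("rbrk")
                return Until(value, left, right)
            if value == "true" and not self._starts_atom(self.i + 1):
                self.next()
                return TrueF()
            if value == "false" and not self._starts_atom(self.i + 1):
                self.next()
                return FalseF()
            return self.atom()
        raise CTLSyntaxError(f"unexpected token {value or 'end of input'!r}", pos)

    def _starts_atom(self, i: int) -> bool:
        # "EX=1" is an atom for an entity literally named EX
        return self.tokens[i][0] == "cmp"

    def atom(self) -> CTLFormula:
        name = self.expect("name")
        op = self.expect("cmp")
        level = self.expect("int")
        return Atom(name[1], op[1], int(level[1]))


def parse_formula(text: str) -> CTLFormula:
    """Parse ``text`` into a :class:`CTLFormula`.

    Unknown entity names are *not* rejected here; they surface when the
    formula is evaluated against a concrete state graph.
    """
    return _Parser(text).parse()


def to_text(f: CTLFormula) -> str:
    """Render ``f`` so that ``parse_formula(to_text(f)) == f``."""
    if isinstance(f, TrueF):
        return "true"
    if isinstance(f, FalseF):
        return "false"
    if isinstance(f, Atom):
        return f"{f.entity}{f.op}{f.level}"
    if isinstance(f, Not):
        return f"!({to_text(f.child)})"
    if isinstance(f, And):
        return f"({to_text(f.left)} & {to_text(f.right)})"
    if isinstance(f, Or):
        return f"({to_text(f.left)} | {to_text(f.right)})"
    if isinstance(f, Implies):
        return f"({to_text(f.left)} -> {to_text(f.right)})"
    if isinstance(f, Iff):
        return f"({to_text(f.left)} <-> {to_text(f.right)})"
    if isinstance(f, Temporal):
        return f"{f.op}({to_text(f.child)})"
    if isinstance(f, Until):
        return f"{f.quant}[({to_text(f.left)}) U ({to_text(f.right)})]"
    raise TypeError(f"not a CTL formula: {f!r}")


# ---------------------------------------------------------------------------
# Fixpoint labeling


class UnknownAtomError(KeyError):
    pass


def _atom_states(graph: StateGraph, atom: Atom) -> FrozenSet[State]:
    if atom.entity not in graph.entities:
        raise UnknownAtomError(
            f"atom references unknown entity {atom.entity!r}; "
            f"graph entities are {graph.entities}"
        )
    i = graph.index_of(atom.entity)
    ops = {
        "=": lambda a, b: a == b,
        ">=": lambda a, b: a >= b,
        "<=": lambda a, b: a <= b,
        ">": lambda a, b: a > b,
        "<": lambda a, b: a < b,
    }
    cmp = ops[atom.op]
    return frozenset(s for s in graph.states if cmp(s[i], atom.level))


def satisfying_states(graph: StateGraph, formula: CTLFormula) -> FrozenSet[State]:
    """Exact satisfaction set of ``formula`` by bottom-up fixpoint labeling."""
    all_states = frozenset(graph.states)

    def sat(f: CTLFormula) -> FrozenSet[State]:
        if isinstance(f, TrueF):
            return all_states
        if isinstance(f, FalseF):
            return frozenset()
        if isinstance(f, Atom):
            return _atom_states(graph, f)
        if isinstance(f, Not):
            return all_states - sat(f.child)
        if isinstance(f, And):
            return sat(f.left) & sat(f.right)
        if isinstance(f, Or):
            return sat(f.left) | sat(f.right)
        if isinstance(f, Implies):
            return (all_states - sat(f.left)) | sat(f.right)
        if isinstance(f, Iff):
            l, r = sat(f.left), sat(f.right)
            return (l & r) | (all_states - l - r)
        if isinstance(f, Temporal):
            child = sat(f.child)
            if f.op == "EX":
                return _ex(graph, child)
            if f.op == "AX":
                return all_states - _ex(graph, all_states - child)
            if f.op == "EF":
                return _eu(graph, all_states, child)
            if f.op == "AF":
                return _af(graph, child)
            if f.op == "EG":
                return _eg(graph, child)
            if f.op == "AG":
                # dual of EF on the complement
                return all_states - _eu(graph, all_states, all_states - child)
        if isinstance(f, Until):
            if f.quant == "E":
                return _eu(graph, sat(f.left), sat(f.right))
            return _au(graph, sat(f.left), sat(f.right))
        raise TypeError(f"not a CTL formula: {f!r}")

    return sat(formula)


def _ex(graph: StateGraph, target: FrozenSet[State]) -> FrozenSet[State]:
    return frozenset(
        s for s in graph.states if any(t in target for t in graph.successors_of(s))
    )


def _eu(
    graph: StateGraph, hold: FrozenSet[State], goal: FrozenSet[State]
) -> FrozenSet[State]:
    """Least fixpoint for ``E[hold U goal]`` by backward chaining."""
    sat = set(goal)
    frontier = list(goal)
    while frontier:
        t = frontier.pop()
        for s in graph.predecessors_of(t):
            if s not in sat and s in hold:
                sat.add(s)
                frontier.append(s)
    return frozenset(sat)


def _af(graph: StateGraph, goal: FrozenSet[State]) -> FrozenSet[State]:
    """``AF goal`` under finite-path semantics: a deadlock satisfies it
    only via ``goal`` itself (its one maximal path stops there)."""
    return _au(graph, frozenset(graph.states), goal)


def _au(
    graph: StateGraph, hold: FrozenSet[State], goal: FrozenSet[State]
) -> FrozenSet[State]:
    """Least fixpoint for ``A[hold U goal]`` (finite-path semantics).

    A non-goal state qualifies when it satisfies ``hold``, has at least
    one successor, and *all* successors already qualify.
    """
    sat = set(goal)
    remaining = {
        s: graph.out_degree(s)
        for s in graph.states
        if s not in goal
    }
    frontier = list(goal)
    while frontier:
        t = frontier.pop()
        for s in graph.predecessors_of(t):
            if s in sat or s not in remaining:
                continue
            remaining[s] -= 1
            if remaining[s] == 0 and s in hold and graph.out_degree(s) > 0:
                sat.add(s)
                frontier.append(s)
    return frozenset(sat)


def _eg(graph: StateGraph, hold: FrozenSet[State]) -> FrozenSet[State]:
    """Greatest fixpoint for ``EG hold``: a maximal all-``hold`` path,
    where a path may legitimately end in a deadlock."""
    sat = set(hold)
    changed = True
    while changed:
        changed = False
        for s in list(sat):
            succ = graph.successors_of(s)
            if succ and not any(t in sat for t in succ):
                sat.remove(s)
                changed = True
    return frozenset(sat)


def holds_at(graph: StateGraph, formula: CTLFormula, state: State) -> bool:
    """Whether ``formula`` holds at ``state`` (membership in the
    satisfaction set)."""
    return state in satisfying_states(graph, formula)


def witness_path(graph: StateGraph, goal: FrozenSet[State], start: State):
    """A shortest path from ``start`` to any state in ``goal`` (a simple
    EF witness), or None if unreachable."""
    from collections import deque

    parent: Dict[State, State] = {start: start}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        if s in goal:
            path = [s]
            while parent[s] != s:
                s = parent[s]
                path.append(s)
            return list(reversed(path))
        for t in graph.successors_of(s):
            if t not in parent:
                parent[t] = s
                queue.append(t)
    return None
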