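"""Kinetic-logic data model and asynchronous dynamics.

A biological regulatory network (BRN) is a labeled directed graph whose
nodes are entities (genes, proteins) taking small discrete levels
``0..max_level`` and whose edges carry a threshold and a sign.  A
predecessor of an entity is a *resource* in a given state when it helps
the entity: an activator at or above its threshold, or an inhibitor below
its threshold.  A total map ``K(entity, resource set) -> target level``
(the logical parameters) then drives the dynamics: each entity moves one
discrete step toward its current target, asynchronously (one entity per
transition).  The asynchronous state graph over the full product space is
the object every downstream analysis consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Sequence, Tuple

State = Tuple[int, ...]
ResourceSet = FrozenSet[str]

ACTIVATION = "+"
INHIBITION = "-"


@dataclass(frozen=True)
class Entity:
    """A network node with levels ``{0, ..., max_level}``."""

    name: str
    max_level: int = 1


@dataclass(frozen=True)
class Interaction:
    """A signed, thresholded edge ``source -> target``.

    ``sign`` is ``"+"`` (activation) or ``"-"`` (inhibition); the
    interaction is *effective* once the source level reaches ``threshold``.
    """

    source: str
    target: str
    sign: str
    threshold: int = 1


class TotalityError(KeyError):
    """A logical-parameter table is missing one or more required entries."""


class StateSpaceError(ValueError):
    """The requested product state space exceeds the configured cap."""


class BRN:
    """A biological regulatory network: ordered entities plus interactions.

    The entity declaration order is significant: states are tuples in
    this order and every printed state follows it.
    """

    def __init__(self, entities: Sequence[Entity], interactions: Iterable[Interaction]):
        self.entities: List[Entity] = list(entities)
        self.interactions: List[Interaction] = list(interactions)
        self._index: Dict[str, int] = {e.name: i for i, e in enumerate(self.entities)}
        self._preds: Dict[str, List[Interaction]] = {e.name: [] for e in self.entities}
        for ia in self.interactions:
            if ia.target in self._preds:
                self._preds[ia.target].append(ia)

    # -- introspection -------------------------------------------------
    @property
    def names(self) -> List[str]:
        return [e.name for e in self.entities]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown entity {name!r}") from None

    def entity(self, name: str) -> Entity:
        return self.entities[self.index(name)]

    def max_level(self, name: str) -> int:
        return self.entity(name).max_level

    def predecessors(self, name: str) -> List[Interaction]:
        """Incoming interactions of ``name`` (its regulators)."""
        self.index(name)
        return list(self._preds[name])

    def predecessor_names(self, name: str) -> List[str]:
        return [ia.source for ia in self.predecessors(name)]

    def resource_sets(self, name: str) -> List[ResourceSet]:
        """All subsets of the regulators of ``name``, in canonical order
        (by size, then by sorted member names)."""
        preds = sorted(self.predecessor_names(name))
        subsets = [
            frozenset(c)
            for r in range(len(preds) + 1)
            for c in itertools.combinations(preds, r)
        ]
        return subsets

    def n_states(self) -> int:
        n = 1
        for e in self.entities:
            n *= e.max_level + 1
        return n

    def states(self) -> Iterator[State]:
        """All states of the product space, lexicographic order."""
        ranges = [range(e.max_level + 1) for e in self.entities]
        return itertools.product(*ranges)

    def is_valid_state(self, state: State) -> bool:
        return len(state) == len(self.entities) and all(
            0 <= lvl <= e.max_level for lvl, e in zip(state, self.entities)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"BRN({len(self.entities)} entities, {len(self.interactions)} interactions)"


def validate_brn(brn: BRN) -> List[str]:
    """Return every well-formedness violation of ``brn`` (empty iff valid).

    Violations are returned as human-readable strings with entity/edge
    context; they are data, not exceptions.
    """
    violations: List[str] = []
    seen_names = set()
    for ent in brn.entities:
        if ent.name in seen_names:
            violations.append(f"duplicate entity name {ent.name!r}")
        seen_names.add(ent.name)
        if ent.max_level < 1:
            violations.append(f"entity {ent.name!r}: max_level must be >= 1, got {ent.max_level}")
    seen_edges = set()
    out_thresholds: Dict[str, set] = {}
    out_degree: Dict[str, int] = {}
    for ia in brn.interactions:
        edge = (ia.source, ia.target)
        if edge in seen_edges:
            violations.append(f"duplicate interaction {ia.source!r} -> {ia.target!r}")
        seen_edges.add(edge)
        for endpoint in (ia.source, ia.target):
            if endpoint not in seen_names:
                violations.append(
                    f"interaction {ia.source!r} -> {ia.target!r}: undeclared entity {endpoint!r}"
                )
        if ia.sign not in (ACTIVATION, INHIBITION):
            violations.append(
                f"interaction {ia.source!r} -> {ia.target!r}: sign must be '+' or '-', got {ia.sign!r}"
            )
        if ia.source in seen_names:
            rmax = brn.max_level(ia.source)
            if not (1 <= ia.threshold <= rmax):
                violations.append(
                    f"interaction {ia.source!r} -> {ia.target!r}: threshold {ia.threshold} "
                    f"outside [1, {rmax}]"
                )
            out_thresholds.setdefault(ia.source, set()).add(ia.threshold)
            out_degree[ia.source] = out_degree.get(ia.source, 0) + 1
    for name, thresholds in out_thresholds.items():
        if len(thresholds) > out_degree.get(name, 0):
            violations.append(
                f"entity {name!r}: {len(thresholds)} distinct outgoing thresholds exceed "
                f"out-degree {out_degree.get(name, 0)}"
            )
    return violations


class Parameterization:
    """Total map from ``(entity, resource set)`` to a target level.

    The table must contain an entry for every entity and every subset of
    its regulators; :meth:`validate_total` reports all missing entries.
    """

    def __init__(self, table: Mapping[Tuple[str, ResourceSet], int]):
        self.table: Dict[Tuple[str, ResourceSet], int] = {
            (ent, frozenset(res)): int(v) for (ent, res), v in table.items()
        }

    def get(self, entity: str, resources: ResourceSet) -> int:
        try:
            return self.table[(entity, frozenset(resources))]
        except KeyError:
            raise TotalityError(
                f"no logical parameter K_({entity}),{sorted(resources)}"
            ) from None

    def missing_entries(self, brn: BRN) -> List[Tuple[str, ResourceSet]]:
        missing = []
        for name in brn.names:
            for rs in brn.resource_sets(name):
                if (name, rs) not in self.table:
                    missing.append((name, rs))
        return missing

    def validate_total(self, brn: BRN) -> None:
        missing = self.missing_entries(brn)
        if missing:
            detail = ", ".join(f"K_({e}),{sorted(r)}" for e, r in missing)
            raise TotalityError(f"parameterization not total; missing: {detail}")
        for (ent, _), value in self.table.items():
            hi = brn.max_level(ent)
            if not (0 <= value <= hi):
                raise ValueError(
                    f"parameter value {value} for entity {ent!r} outside [0, {hi}]"
                )

    def is_monotone(self, brn: BRN) -> bool:
        """Snoussi condition: adding a resource never lowers the target."""
        for name in brn.names:
            sets = brn.resource_sets(name)
            for r1 in sets:
                for r2 in sets:
                    if r1 < r2 and self.get(name, r1) > self.get(name, r2):
                        return False
        return True

    def items_canonical(self) -> List[Tuple[str, ResourceSet, int]]:
        return sorted(
            ((e, r, v) for (e, r), v in self.table.items()),
            key=lambda t: (t[0], len(t[1]), sorted(t[1])),
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Parameterization) and self.table == other.table

    def __hash__(self) -> int:
        return hash(frozenset(self.table.items()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameterization({len(self.table)} entries)"


def compute_resources(brn: BRN, state: State, entity: str) -> ResourceSet:
    """The regulators of ``entity`` currently helping it.

    An activator is a resource when its level is at or above the edge
    threshold; an inhibitor is a resource when its level is *below* the
    threshold (absence of inhibition helps).
    """
    if not brn.is_valid_state(state):
        raise ValueError(f"invalid state {state!r} for this network")
    resources = set()
    for ia in brn.predecessors(entity):
        level = state[brn.index(ia.source)]
        if ia.sign == ACTIVATION and level >= ia.threshold:
            resources.add(ia.source)
        elif ia.sign == INHIBITION and level < ia.threshold:
            resources.add(ia.source)
    return frozenset(resources)


def target_level(brn: BRN, k: Parameterization, state: State, entity: str) -> int:
    """The level ``entity`` currently tends toward: ``K(entity, resources)``."""
    return k.get(entity, compute_resources(brn, state, entity))


def successors(brn: BRN, k: Parameterization, state: State) -> set:
    """Asynchronous successors of ``state``: one entity steps one unit
    toward its target.  Empty iff ``state`` is a fixed point (deadlock)."""
    out = set()
    for i, ent in enumerate(brn.entities):
        tgt = target_level(brn, k, state, ent.name)
        cur = state[i]
        if cur < tgt:
            out.add(state[:i] + (cur + 1,) + state[i + 1 :])
        elif cur > tgt:
            out.add(state[:i] + (cur - 1,) + state[i + 1 :])
    return out


@dataclass
class StateGraph:
    """Asynchronous state graph: all states of the product space plus the
    unit-step transitions between them.

    ``entities`` records the coordinate order of the state tuples.  The
    adjacency representation is lightweight (plain dicts) because
    parameter synthesis builds hundreds of thousands of these; use
    :meth:`to_networkx` for graph algorithms.
    """

    entities: List[str]
    states: List[State]
    adj: Dict[State, Tuple[State, ...]]
    pred: Dict[State, Tuple[State, ...]] = field(default=None, repr=False)

    def __post_init__(self):
        if self.pred is None:
            pred: Dict[State, List[State]] = {s: [] for s in self.states}
            for s, targets in self.adj.items():
                for t in targets:
                    pred[t].append(s)
            self.pred = {s: tuple(v) for s, v in pred.items()}

    def successors_of(self, state: State) -> Tuple[State, ...]:
        return self.adj[state]

    def predecessors_of(self, state: State) -> Tuple[State, ...]:
        return self.pred[state]

    def out_degree(self, state: State) -> int:
        return len(self.adj[state])

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return sum(len(v) for v in self.adj.values())

    def edges(self) -> Iterator[Tuple[State, State]]:
        for s in self.states:
            for t in self.adj[s]:
                yield (s, t)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.edges())
        g.graph["entities"] = list(self.entities)
        return g

    def index_of(self, name: str) -> int:
        return self.entities.index(name)


def build_state_graph(
    brn: BRN, k: Parameterization, max_states: int = 2**20
) -> StateGraph:
    """Build the full asynchronous state graph of ``brn`` under ``k``.

    The node set is the whole product space; raising
    :class:`StateSpaceError` when it would exceed ``max_states`` guards
    against combinatorial blow-up.
    """
    n = brn.n_states()
    if n > max_states:
        raise StateSpaceError(
            f"state space has {n} states, exceeding the cap of {max_states}"
        )
    k.validate_total(brn)
    states = list(brn.states())
    adj = {s: tuple(sorted(successors(brn, k, s))) for s in states}
    return StateGraph(entities=brn.names, states=states, adj=adj)
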