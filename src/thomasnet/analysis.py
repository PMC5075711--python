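"""State-graph analytics: fixed points, elementary cycles, risk-zone
classification and trajectory queries.

A fixed point (deadlock) is a state with no outgoing transition — every
entity already sits at its target.  Elementary cycles are directed
cycles visiting no state twice, identified up to rotation; in the
regulatory-network reading they are sustained qualitative oscillations,
while deadlocks are terminal phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .brn import State, StateGraph


class CycleCapError(RuntimeError):
    """More elementary cycles than the configured cap."""


def find_deadlocks(graph: StateGraph) -> Set[State]:
    """All states with out-degree 0 (every entity at its target)."""
    return {s for s in graph.states if graph.out_degree(s) == 0}


def canonical_cycle(cycle: Sequence[State]) -> Tuple[State, ...]:
    """Rotate ``cycle`` so its lexicographically smallest state comes
    first; cycles equal up to rotation get equal canonical forms."""
    cyc = list(cycle)
    i = cyc.index(min(cyc))
    return tuple(cyc[i:] + cyc[:i])


def enumerate_elementary_cycles(
    graph: StateGraph, max_nodes: int = 2**14, max_cycles: int = 10**6
) -> List[Tuple[State, ...]]:
    """Complete, duplicate-free list of elementary directed cycles.

    Cycles are canonicalized by rotation (smallest state first) and the
    list is sorted, so output order is deterministic.  Johnson-style
    enumeration via networkx does the heavy lifting.
    """
    if graph.n_states > max_nodes:
        raise CycleCapError(
            f"graph has {graph.n_states} nodes, exceeding the cap of {max_nodes}"
        )
    g = graph.to_networkx()
    cycles = []
    for cyc in nx.simple_cycles(g):
        cycles.append(canonical_cycle(cyc))
        if len(cycles) > max_cycles:
            raise CycleCapError(f"more than {max_cycles} elementary cycles")
    cycles.sort()
    return cycles


@dataclass
class ZoneScheme:
    """Ordered first-match classification rule.

    Each block carries ``where`` (required entity levels), optional
    ``exclude`` clauses (a state matching any is pushed past the block),
    and at most one block may be ``otherwise`` (catch-all).
    """

    blocks: List[dict]
    name: str = "zones"

    @classmethod
    def from_config(cls, cfg: dict) -> "ZoneScheme":
        return cls(blocks=list(cfg["blocks"]), name=cfg.get("name", "zones"))

    def zone_names(self) -> List[str]:
        return [b["name"] for b in self.blocks]

    def classify(self, state: State, entities: Sequence[str]) -> str:
        idx = {name: i for i, name in enumerate(entities)}
        fallback = None
        for block in self.blocks:
            if block.get("otherwise"):
                fallback = block["name"]
                continue
            where = block.get("where", {})
            unknown = [m for m in where if m not in idx]
            if unknown:
                raise KeyError(f"zone scheme references unknown entities {unknown}")
            if not all(state[idx[m]] == lvl for m, lvl in where.items()):
                continue
            excluded = False
            for clause in block.get("exclude", []):
                if all(state[idx[m]] == lvl for m, lvl in clause.items()):
                    excluded = True
                    break
            if not excluded:
                return block["name"]
        if fallback is None:
            raise ValueError(f"state {state} matches no zone block and no catch-all exists")
        return fallback


@dataclass
class ZonePartition:
    blocks: Dict[str, FrozenSet[State]]
    scheme_name: str = "zones"

    def zone_of(self, state: State) -> str:
        for name, members in self.blocks.items():
            if state in members:
                return name
        raise KeyError(f"state {state} not classified")

    def is_partition_of(self, states: Sequence[State]) -> bool:
        union: Set[State] = set()
        total = 0
        for members in self.blocks.values():
            union |= members
            total += len(members)
        return total == len(union) == len(set(states)) and union == set(states)


def classify_zones(graph: StateGraph, scheme: ZoneScheme) -> ZonePartition:
    """Partition all states by the first-match ``scheme``."""
    blocks: Dict[str, Set[State]] = {name: set() for name in scheme.zone_names()}
    for s in graph.states:
        blocks[scheme.classify(s, graph.entities)].add(s)
    return ZonePartition(
        blocks={name: frozenset(v) for name, v in blocks.items()},
        scheme_name=scheme.name,
    )


def fixture_partition(zone_lists: Dict[str, Sequence[State]]) -> ZonePartition:
    """A partition given verbatim as state lists (fixture mode)."""
    return ZonePartition(
        blocks={name: frozenset(tuple(s) for s in states) for name, states in zone_lists.items()},
        scheme_name="fixture",
    )


def find_paths(
    graph: StateGraph, source: State, target: State, max_length: int
) -> Tuple[List[Tuple[State, ...]], bool]:
    """All simple paths ``source -> target`` up to ``max_length`` edges,
    plus a reachability flag computed by unbounded search.

    ``source == target`` yields the trivial empty path and is reachable.
    """
    for s in (source, target):
        if s not in graph.adj:
            raise KeyError(f"state {s} not in graph")
    if source == target:
        return [(source,)], True
    g = graph.to_networkx()
    paths = [tuple(p) for p in nx.all_simple_paths(g, source, target, cutoff=max_length)]
    paths.sort()
    reachable = nx.has_path(g, source, target)
    return paths, reachable


@dataclass
class AnalysisReport:
    """Structured summary of a state-graph analysis, serializable to JSON."""

    entities: List[str]
    n_states: int
    n_transitions: int
    deadlocks: List[State]
    cycles: List[Tuple[State, ...]]
    zones: Optional[ZonePartition] = None
    reachability: Dict[str, bool] = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def to_dict(self) -> dict:
        out = {
            "entities": self.entities,
            "n_states": self.n_states,
            "n_transitions": self.n_transitions,
            "deadlocks": [list(s) for s in sorted(self.deadlocks)],
            "n_cycles": self.n_cycles,
            "cycles": [[list(s) for s in cyc] for cyc in self.cycles],
            "reachability": dict(self.reachability),
        }
        if self.zones is not None:
            out["zones"] = {
                name: [list(s) for s in sorted(members)]
                for name, members in self.zones.blocks.items()
            }
        return out


def analyze(
    graph: StateGraph,
    scheme: Optional[ZoneScheme] = None,
    reachability_queries: Sequence[Tuple[State, State]] = (),
) -> AnalysisReport:
    """Run the full analytic battery on one state graph."""
    deadlocks = sorted(find_deadlocks(graph))
    cycles = enumerate_elementary_cycles(graph)
    zones = classify_zones(graph, scheme) if scheme is not None else None
    reach = {}
    g = graph.to_networkx()
    for src, dst in reachability_queries:
        key = f"{tuple(src)}->{tuple(dst)}"
        reach[key] = bool(nx.has_path(g, tuple(src), tuple(dst)))
    return AnalysisReport(
        entities=list(graph.entities),
        n_states=graph.n_states,
        n_transitions=graph.n_transitions,
        deadlocks=deadlocks,
        cycles=cycles,
        zones=zones,
        reachability=reach,
    )
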