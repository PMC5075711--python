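"""Logical-parameter synthesis: enumerate candidate parameterizations of
a BRN and keep the ones whose asynchronous state graphs satisfy a set of
CTL properties.

This is the classic model-checking-driven selection workflow: the
candidate space is the product, over entities, of all total tables
``resource set -> target level``; optional structural constraints
(Snoussi monotonicity, observability) prune tables entity-locally before
any state graph is built.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .brn import BRN, Parameterization, ResourceSet, State, build_state_graph
from .ctl import CTLFormula, satisfying_states

log = logging.getLogger(__name__)


class SearchSpaceError(ValueError):
    """The candidate space exceeds the configured cap."""


@dataclass(frozen=True)
class SynthesisConstraints:
    """Structural constraints applied during enumeration.

    monotonicity
        Snoussi condition: adding a resource never lowers the target.
    observability
        Every regulator changes some parameter value of its target
        (dropping it from at least one resource set changes K).
    value_bounds
        Optional per-entity ``(low, high)`` bounds on target levels.
    """

    monotonicity: bool = False
    observability: bool = False
    value_bounds: Optional[Dict[str, Tuple[int, int]]] = None


@dataclass
class SynthesisResult:
    accepted: List[Parameterization]
    tested_count: int
    formulas: List[CTLFormula]
    mode: str
    initial_states: Optional[Tuple[State, ...]] = None


def _entity_tables(
    brn: BRN, name: str, constraints: SynthesisConstraints
) -> List[Dict[Tuple[str, ResourceSet], int]]:
    """All admissible parameter tables for one entity, canonical order."""
    sets = brn.resource_sets(name)
    lo, hi = 0, brn.max_level(name)
    if constraints.value_bounds and name in constraints.value_bounds:
        blo, bhi = constraints.value_bounds[name]
        lo, hi = max(lo, blo), min(hi, bhi)
    regulators = brn.predecessor_names(name)
    tables = []
    for values in itertools.product(range(lo, hi + 1), repeat=len(sets)):
        assignment = dict(zip(sets, values))
        if constraints.monotonicity:
            ok = all(
                assignment[r1] <= assignment[r2]
                for r1 in sets
                for r2 in sets
                if r1 < r2
            )
            if not ok:
                continue
        if constraints.observability and regulators:
            observable = True
            for reg in regulators:
                if not any(
                    assignment[rs] != assignment[rs | {reg}]
                    for rs in sets
                    if reg not in rs
                ):
                    observable = False
                    break
            if not observable:
                continue
        tables.append({(name, rs): v for rs, v in assignment.items()})
    return tables


def enumerate_parameterizations(
    brn: BRN,
    constraints: SynthesisConstraints = SynthesisConstraints(),
    max_candidates: int = 2**21,
) -> Iterator[Parameterization]:
    """Lazily yield every parameterization admissible under
    ``constraints``, in deterministic lexicographic order (entities in
    declaration order; resource sets by size then name; values
    ascending)."""
    per_entity = [_entity_tables(brn, name, constraints) for name in brn.names]
    total = 1
    for tables in per_entity:
        total *= len(tables)
    if total > max_candidates:
        raise SearchSpaceError(
            f"candidate space has {total} parameterizations, exceeding the cap "
            f"of {max_candidates}"
        )
    for combo in itertools.product(*per_entity):
        table: Dict[Tuple[str, ResourceSet], int] = {}
        for part in combo:
            table.update(part)
        yield Parameterization(table)


def count_parameterizations(
    brn: BRN, constraints: SynthesisConstraints = SynthesisConstraints()
) -> int:
    """Size of the candidate space without materializing it.

    Unconstrained, this is the product over entities of
    ``(max_level+1) ** 2**(number of regulators)``; with constraints the
    per-entity admissible tables are counted (still without building any
    cross-entity combination).
    """
    total = 1
    if not constraints.monotonicity and not constraints.observability and not constraints.value_bounds:
        for name in brn.names:
            n_sets = 2 ** len(brn.predecessor_names(name))
            total *= (brn.max_level(name) + 1) ** n_sets
        return total
    for name in brn.names:
        total *= len(_entity_tables(brn, name, constraints))
    return total


def filter_by_ctl(
    brn: BRN,
    formulas: Sequence[CTLFormula],
    constraints: SynthesisConstraints = SynthesisConstraints(),
    mode: str = "initial-states",
    initial_states: Optional[Sequence[State]] = None,
    max_candidates: int = 2**21,
    max_states: int = 2**20,
    progress_every: int = 0,
) -> SynthesisResult:
    """Keep the parameterizations whose state graph satisfies every
    formula.

    mode
        ``"initial-states"`` (default): each formula must hold at every
        state in ``initial_states`` (required in this mode).
        ``"all-states"``: each formula must hold at every state.
    """
    if mode not in ("initial-states", "all-states"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if mode == "initial-states":
        if not initial_states:
            raise ValueError("initial-states mode requires initial_states")
        init = tuple(tuple(s) for s in initial_states)
    else:
        init = None

    accepted: List[Parameterization] = []
    tested = 0
    for k in enumerate_parameterizations(brn, constraints, max_candidates):
        tested += 1
        graph = build_state_graph(brn, k, max_states=max_states)
        ok = True
        for formula in formulas:
            sat = satisfying_states(graph, formula)
            if mode == "all-states":
                if len(sat) != graph.n_states:
                    ok = False
                    break
            else:
                if not all(s in sat for s in init):
                    ok = False
                    break
        if ok:
            accepted.append(k)
        if progress_every and tested % progress_every == 0:
            log.info("synthesis: tested %d candidates, %d accepted", tested, len(accepted))
    if tested == 0:
        raise SearchSpaceError("empty enumeration: no admissible parameterization")
    return SynthesisResult(
        accepted=accepted,
        tested_count=tested,
        formulas=list(formulas),
        mode=mode,
        initial_states=init,
    )
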