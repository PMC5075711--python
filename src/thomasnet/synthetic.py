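"""Synthetic network generators: random multivalued BRNs, random
(optionally monotone) parameterizations, and canonical feedback motifs
with known dynamics.

These give every pipeline stage reproducible, download-free inputs with
the structure the analysis assumes.  All generation is seeded; no global
random state is touched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .brn import (
    ACTIVATION,
    INHIBITION,
    BRN,
    Entity,
    Interaction,
    Parameterization,
)

MOTIF_NAMES = (
    "negative-2-loop",
    "positive-2-loop",
    "input-chain",
    "p53-mdm2-oscillator",
)


def random_brn(
    n_entities: int,
    edge_density: float,
    max_level: int = 1,
    seed: int = 0,
    allow_self_loops: bool = False,
) -> BRN:
    """A random valid BRN with ``n_entities`` nodes.

    Each ordered pair (excluding self loops by default) carries an edge
    with probability ``edge_density``; signs are uniform over {+,-} and
    thresholds uniform over the legal range of the source.
    """
    if n_entities < 1:
        raise ValueError("n_entities must be >= 1")
    if not (0 <= edge_density <= 1):
        raise ValueError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    entities = [Entity(f"n{i}", max_level=max_level) for i in range(n_entities)]
    interactions = []
    for src in entities:
        for tgt in entities:
            if src.name == tgt.name and not allow_self_loops:
                continue
            if rng.random() < edge_density:
                interactions.append(
                    Interaction(
                        source=src.name,
                        target=tgt.name,
                        sign=ACTIVATION if rng.random() < 0.5 else INHIBITION,
                        threshold=int(rng.integers(1, src.max_level + 1)),
                    )
                )
    return BRN(entities, interactions)


def random_parameterization(
    brn: BRN, monotone: bool = False, seed: int = 0
) -> Parameterization:
    """A random total parameterization of ``brn``.

    With ``monotone`` set, values respect the Snoussi condition
    (resource-set inclusion never lowers the target): values are drawn
    per resource set and then propagated upward through the inclusion
    lattice by taking maxima.
    """
    rng = np.random.default_rng(seed)
    table = {}
    for name in brn.names:
        hi = brn.max_level(name)
        sets = brn.resource_sets(name)  # sorted by size then names
        values: Dict[frozenset, int] = {}
        for rs in sets:
            v = int(rng.integers(0, hi + 1))
            if monotone:
                below = [values[r] for r in sets if r < rs and r in values]
                if below:
                    v = max([v] + below)
            values[rs] = v
        for rs, v in values.items():
            table[(name, rs)] = v
    return Parameterization(table)


@dataclass(frozen=True)
class MotifSpec:
    name: str
    max_level: int = 1


@dataclass
class MotifResult:
    brn: BRN
    parameterization: Parameterization
    expectations: Dict[str, object] = field(default_factory=dict)


def motif(spec: MotifSpec) -> MotifResult:
    """A named feedback motif with a machine-checkable expectation record.

    ``positive-2-loop``
        Mutual inhibition (a toggle switch): exactly the two exclusive
        fixed points (1,0) and (0,1).
    ``negative-2-loop`` / ``p53-mdm2-oscillator``
        Activation paired with inhibition: no fixed point and a
        sustained 4-state oscillation.
    ``input-chain``
        An input entity feeding an activation cascade; single fixed
        point with everything on.
    """
    name = spec.name
    if name == "positive-2-loop":
        brn = BRN(
            [Entity("a"), Entity("b")],
            [
                Interaction("a", "b", INHIBITION),
                Interaction("b", "a", INHIBITION),
            ],
        )
        k = Parameterization(
            {
                ("a", frozenset()): 0,
                ("a", frozenset({"b"})): 1,
                ("b", frozenset()): 0,
                ("b", frozenset({"a"})): 1,
            }
        )
        expectations = {"fixed_points": {(1, 0), (0, 1)}, "n_cycles_min": 0, "n_cycles_max": 0}
    elif name in ("negative-2-loop", "p53-mdm2-oscillator"):
        a, b = (("p53", "Mdm2") if name == "p53-mdm2-oscillator" else ("a", "b"))
        brn = BRN(
            [Entity(a), Entity(b)],
            [
                Interaction(a, b, ACTIVATION),
                Interaction(b, a, INHIBITION),
            ],
        )
        k = Parameterization(
            {
                (a, frozenset()): 0,
                (a, frozenset({b})): 1,
                (b, frozenset()): 0,
                (b, frozenset({a})): 1,
            }
        )
        expectations = {
            "fixed_points": set(),
            "n_cycles_min": 1,
            "cycle": ((0, 0), (1, 0), (1, 1), (0, 1)),
        }
    elif name == "input-chain":
        brn = BRN(
            [Entity("i"), Entity("a"), Entity("b")],
            [
                Interaction("i", "a", ACTIVATION),
                Interaction("a", "b", ACTIVATION),
            ],
        )
        k = Parameterization(
            {
                ("i", frozenset()): 1,
                ("a", frozenset()): 0,
                ("a", frozenset({"i"})): 1,
                ("b", frozenset()): 0,
                ("b", frozenset({"a"})): 1,
            }
        )
        expectations = {"fixed_points": {(1, 1, 1)}, "n_cycles_min": 0, "n_cycles_max": 0}
    else:
        raise ValueError(f"unknown motif {name!r}; known: {MOTIF_NAMES}")
    return MotifResult(brn=brn, parameterization=k, expectations=expectations)
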