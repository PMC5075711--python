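"""Continuous/hybrid Petri-net engine with mass-action kinetics.

Places hold non-negative (real-valued, for continuous places) token
markings; transitions fire at rate ``k * prod(m_input ** weight)`` over
their normal and test inputs.  Normal input arcs consume tokens, test
arcs only read them (enzymatic role), and an inhibitory arc blocks the
transition entirely while its source marking is at or above the arc
weight.  Two engines share one model description:

* a deterministic ODE integrator (``simulate_ode``) for the continuous
  reading, and
* a run-averaged stochastic simulator (``simulate_stochastic_avg``)
  firing unit token quanta with exponential waiting times, whose mean
  trajectory converges to the ODE solution for well-stirred mass-action
  nets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

NORMAL = "normal"
INHIBITORY = "inhibitory"
TEST = "test"


@dataclass(frozen=True)
class Place:
    name: str
    kind: str = "continuous"  # or "discrete"
    initial_marking: float = 0.0


@dataclass(frozen=True)
class Transition:
    name: str
    rate_constant: float = 1.0
    kinetics: str = "mass-action"  # Michaelis-Menten hook reserved, unused


@dataclass(frozen=True)
class Arc:
    source: str
    target: str
    kind: str = NORMAL
    weight: float = 1.0


class HPNStructureError(ValueError):
    pass


@dataclass
class HPNModel:
    places: List[Place]
    transitions: List[Transition]
    arcs: List[Arc]
    name: str = "hpn"
    variant: str = ""

    def __post_init__(self):
        self._place_idx = {p.name: i for i, p in enumerate(self.places)}
        self._trans_idx = {t.name: i for i, t in enumerate(self.transitions)}
        self.validate()
        # per-transition compiled views
        self._inputs: List[List[Tuple[int, float, str]]] = [[] for _ in self.transitions]
        self._outputs: List[List[Tuple[int, float]]] = [[] for _ in self.transitions]
        for arc in self.arcs:
            if arc.source in self._place_idx:
                ti = self._trans_idx[arc.target]
                self._inputs[ti].append((self._place_idx[arc.source], arc.weight, arc.kind))
            else:
                ti = self._trans_idx[arc.source]
                self._outputs[ti].append((self._place_idx[arc.target], arc.weight))

    def validate(self) -> None:
        for p in self.places:
            if p.initial_marking < 0:
                raise HPNStructureError(f"place {p.name!r}: negative initial marking")
            if p.kind == "discrete" and p.initial_marking != int(p.initial_marking):
                raise HPNStructureError(f"discrete place {p.name!r}: non-integer marking")
        for t in self.transitions:
            if t.rate_constant <= 0:
                raise HPNStructureError(f"transition {t.name!r}: rate must be > 0")
        for arc in self.arcs:
            src_place = arc.source in self._place_idx
            tgt_place = arc.target in self._place_idx
            src_trans = arc.source in self._trans_idx
            tgt_trans = arc.target in self._trans_idx
            if not ((src_place and tgt_trans) or (src_trans and tgt_place)):
                raise HPNStructureError(
                    f"arc {arc.source!r} -> {arc.target!r} must connect a place and a transition"
                )
            if arc.kind not in (NORMAL, INHIBITORY, TEST):
                raise HPNStructureError(f"arc kind {arc.kind!r} unknown")
            if arc.kind in (INHIBITORY, TEST) and not (src_place and tgt_trans):
                raise HPNStructureError(
                    f"{arc.kind} arc must run place -> transition ({arc.source!r} -> {arc.target!r})"
                )
            if arc.weight <= 0:
                raise HPNStructureError(f"arc {arc.source!r} -> {arc.target!r}: weight must be > 0")

    @property
    def place_names(self) -> List[str]:
        return [p.name for p in self.places]

    def initial_marking(self) -> np.ndarray:
        return np.array([p.initial_marking for p in self.places], dtype=float)

    def structural_counts(self) -> Tuple[int, int, int]:
        return (len(self.places), len(self.transitions), len(self.arcs))

    def rates(
        self,
        marking: np.ndarray,
        smooth_gate: bool = False,
        hill: float = 10.0,
        gate_ramp: float = 0.0,
    ) -> np.ndarray:
        """Mass-action transition rates at ``marking``.

        Inhibitory inputs gate the rate to 0 once their marking reaches
        the arc weight.  ``gate_ramp`` > 0 replaces the step by a narrow
        linear ramp of that width just below the weight (the ODE engine
        uses this: a hard step creates sliding-mode equilibria exactly at
        the threshold that stall step-size control).  ``smooth_gate``
        instead applies a Hill factor ``w^h / (w^h + m^h)``.
        """
        m = np.maximum(marking, 0.0)
        out = np.empty(len(self.transitions))
        for ti, trans in enumerate(self.transitions):
            rate = trans.rate_constant
            for pi, weight, kind in self._inputs[ti]:
                if kind == INHIBITORY:
                    if smooth_gate:
                        rate *= weight**hill / (weight**hill + m[pi] ** hill)
                    elif gate_ramp > 0:
                        rate *= min(1.0, max(0.0, (weight - m[pi]) / gate_ramp))
                    elif m[pi] >= weight:
                        rate = 0.0
                        break
                else:  # normal and test arcs both contribute mass-action factors
                    rate *= m[pi] ** weight
            out[ti] = rate
        return out

    def stoichiometry(self) -> np.ndarray:
        """Net token change per place (rows) and transition (columns);
        test and inhibitory arcs contribute no flux."""
        s = np.zeros((len(self.places), len(self.transitions)))
        for ti in range(len(self.transitions)):
            for pi, weight, kind in self._inputs[ti]:
                if kind == NORMAL:
                    s[pi, ti] -= weight
            for pi, weight in self._outputs[ti]:
                s[pi, ti] += weight
        return s


@dataclass
class Trace:
    """A simulated time series: strictly increasing time grid plus one
    marking series per place, with provenance metadata."""

    time: np.ndarray
    series: Dict[str, np.ndarray]
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time grid must be strictly increasing")

    def __getitem__(self, place: str) -> np.ndarray:
        try:
            return self.series[place]
        except KeyError:
            raise KeyError(f"unknown place {place!r}") from None

    @property
    def places(self) -> List[str]:
        return list(self.series)

    def to_frame(self):
        import pandas as pd

        data = {"time": self.time}
        data.update(self.series)
        return pd.DataFrame(data)


def simulate_ode(
    model: HPNModel,
    t_end: float,
    n_points: int = 1001,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    smooth_gate: bool = False,
    gate_ramp: float = 1e-3,
) -> Trace:
    """Deterministic continuous trajectory of ``model`` on a uniform
    grid of ``n_points`` over ``[0, t_end]``.

    Inhibitory gates are regularized with a linear ramp of width
    ``gate_ramp`` (in tokens) so that self-limiting loops settle at
    their threshold instead of chattering the integrator; set it to 0
    for the exact discontinuous gate.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    stoich = model.stoichiometry()
    ramp = 0.0 if smooth_gate else gate_ramp

    def rhs(_t, y):
        return stoich @ model.rates(y, smooth_gate=smooth_gate, gate_ramp=ramp)

    grid = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        model.initial_marking(),
        t_eval=grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed for model {model.name!r}: {sol.message}")
    values = np.maximum(sol.y, 0.0)  # clip integrator noise below zero
    series = {name: values[i] for i, name in enumerate(model.place_names)}
    return Trace(
        time=sol.t,
        series=series,
        provenance={"engine": "ode", "model": model.name, "variant": model.variant},
    )


def _ssa_run(
    model: HPNModel, t_end: float, grid: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Gillespie run with unit token quanta, sampled onto ``grid``."""
    marking = model.initial_marking()
    n_places = len(model.places)
    out = np.zeros((n_places, len(grid)))
    gi = 0
    t = 0.0
    while True:
        props = model.rates(marking)
        # discrete enabling: consuming transitions need their tokens present
        for ti in range(len(model.transitions)):
            if props[ti] <= 0:
                continue
            for pi, weight, kind in model._inputs[ti]:
                if kind == NORMAL and marking[pi] < weight:
                    props[ti] = 0.0
                    break
        total = props.sum()
        if total <= 0:
            out[:, gi:] = marking[:, None]
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        while gi < len(grid) and grid[gi] < t_next:
            out[:, gi] = marking
            gi += 1
        if gi >= len(grid) or t_next > t_end:
            if gi < len(grid):
                out[:, gi:] = marking[:, None]
            break
        t = t_next
        ti = rng.choice(len(props), p=props / total)
        for pi, weight, kind in model._inputs[ti]:
            if kind == NORMAL:
                marking[pi] -= weight
        for pi, weight in model._outputs[ti]:
            marking[pi] += weight
    return out


def simulate_stochastic_avg(
    model: HPNModel,
    runs: int,
    t_end: float,
    seed: int,
    n_points: int = 1001,
) -> Trace:
    """Mean trajectory over ``runs`` stochastic firings.

    Each run draws exponential waiting times from the mass-action
    propensities and fires single transitions (random firing order);
    averaging many runs recovers the smooth signaling-rate picture.
    Reproducible for a fixed ``seed``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    grid = np.linspace(0.0, t_end, n_points)
    root = np.random.default_rng(seed)
    acc = np.zeros((len(model.places), n_points))
    for child in root.spawn(runs):
        acc += _ssa_run(model, t_end, grid, child)
    acc /= runs
    series = {name: acc[i] for i, name in enumerate(model.place_names)}
    return Trace(
        time=grid,
        series=series,
        provenance={
            "engine": "stochastic-avg",
            "model": model.name,
            "variant": model.variant,
            "runs": runs,
            "seed": seed,
        },
    )


@dataclass
class PlateauStats:
    value: float
    spread: float  # max - min over the window (flatness diagnostic)

    def __float__(self) -> float:
        return self.value


def plateau_level(trace: Trace, place: str, window: float = 0.2) -> PlateauStats:
    """Mean marking of ``place`` over the trailing ``window`` fraction of
    the trace, with a flatness diagnostic (max minus min)."""
    if not (0 < window <= 1):
        raise ValueError("window must lie in (0, 1]")
    series = trace[place]
    n = max(1, int(round(len(series) * window)))
    tail = series[-n:]
    return PlateauStats(value=float(np.mean(tail)), spread=float(np.max(tail) - np.min(tail)))


# ---------------------------------------------------------------------------
# Reference models of the ER-alpha signaling case study.
#
# Seven places: the growth-factor ligand pool (IGF-1/EGF), its membrane
# receptors (IGF-1R/EGFR), the ligand-receptor complex, the ER-alpha
# transcription factor, and the three tumor suppressors BRCA1, p53 and
# Mdm2.  Both variants have exactly 8 transitions and 18 arcs; ligand
# and receptor start with 5 tokens and every mass-action rate constant
# is 1.  The wiring (which arcs are test/inhibitory, where degradation
# sits) is one reconstruction consistent with the qualitative contract:
# it lives in data, not code, so alternatives can be swapped in.

LIGAND = "IGF-1/EGF"
RECEPTOR = "IGF-1R/EGFR"
COMPLEX = "Complex"
ER = "ER-alpha"
BRCA1 = "BRCA1"
P53 = "p53"
MDM2 = "Mdm2"


def build_homeostatic_model() -> HPNModel:
    """Normal (homeostatic) wiring: receptor signaling raises the tumor
    suppressors, and Mdm2 feedback shuts down both ER-alpha and further
    p53 production, keeping ER-alpha below every tumor suppressor."""
    from . import io as _io

    return _io.load_packaged_hpn("hpn_homeostatic.yaml")


def build_pathological_model() -> HPNModel:
    """Disease wiring: ER-alpha suppresses p53, tumor-suppressor feedback
    onto ER-alpha is gone, and the ligand -> complex -> ER-alpha chain is
    conservative with no ER-alpha sink, so ER-alpha climbs to the whole
    initial ligand/receptor stock (5)."""
    from . import io as _io

    return _io.load_packaged_hpn("hpn_pathological.yaml")
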