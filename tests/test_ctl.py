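"""CTL parsing and fixpoint labeling, cross-checked against an
independent explicit-path oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thomasnet.brn import StateGraph
from thomasnet.ctl import (
    AF,
    AG,
    And,
    Atom,
    AX,
    EF,
    EG,
    EX,
    FalseF,
    Iff,
    Implies,
    Not,
    Or,
    TrueF,
    Until,
    UnknownAtomError,
    holds_at,
    parse_formula,
    satisfying_states,
    state_atom,
    to_text,
    witness_path,
)

# ---------------------------------------------------------------------------
# Explicit-path oracle: evaluates temporal operators by enumerating
# simple paths and lassos instead of fixpoint labeling.  A maximal path
# either ends in a deadlock or loops back onto itself.


def _exists_path(graph, start, hold, goal):
    """Is there a path from start through `hold` states to a `goal` state?"""
    if start in goal:
        return True
    if start not in hold:
        return False
    stack, seen = [start], {start}
    while stack:
        s = stack.pop()
        for t in graph.successors_of(s):
            if t in goal:
                return True
            if t in hold and t not in seen:
                seen.add(t)
                stack.append(t)
    return False


def _exists_maximal_path_within(graph, start, region):
    """Is there a maximal path from start staying inside `region`
    (a lasso inside region, or a region path ending at a deadlock)?"""
    if start not in region:
        return False

    def dfs(node, on_path):
        if graph.out_degree(node) == 0:
            return True
        for t in graph.successors_of(node):
            if t in on_path:
                return True  # lasso closed
            if t in region:
                if dfs(t, on_path | {t}):
                    return True
        return False

    return dfs(start, frozenset({start}))


def oracle_sat(graph, f):
    states = frozenset(graph.states)
    if isinstance(f, TrueF):
        return states
    if isinstance(f, FalseF):
        return frozenset()
    if isinstance(f, Atom):
        i = graph.index_of(f.entity)
        ops = {"=": "__eq__", ">=": "__ge__", "<=": "__le__", ">": "__gt__", "<": "__lt__"}
        return frozenset(s for s in states if getattr(s[i], ops[f.op])(f.level))
    if isinstance(f, Not):
        return states - oracle_sat(graph, f.child)
    if isinstance(f, And):
        return oracle_sat(graph, f.left) & oracle_sat(graph, f.right)
    if isinstance(f, Or):
        return oracle_sat(graph, f.left) | oracle_sat(graph, f.right)
    if isinstance(f, Implies):
        return (states - oracle_sat(graph, f.left)) | oracle_sat(graph, f.right)
    if isinstance(f, Iff):
        l, r = oracle_sat(graph, f.left), oracle_sat(graph, f.right)
        return (l & r) | (states - l - r)
    if isinstance(f, Until):
        hold, goal = oracle_sat(graph, f.left), oracle_sat(graph, f.right)
        if f.quant == "E":
            return frozenset(s for s in states if _exists_path(graph, s, hold, goal))
        # A[hold U goal] fails iff some path avoids goal until leaving
        # hold, or avoids goal forever (lasso/deadlock outside goal)
        bad_region = states - goal
        escape = bad_region - hold  # ~goal & ~hold

        def fails(s):
            if s in goal:
                return False
            if s in escape:
                return True
            if _exists_path(graph, s, bad_region, escape):
                return True
            return _exists_maximal_path_within(graph, s, bad_region)

        return frozenset(s for s in states if not fails(s))
    # temporal unaries
    child = oracle_sat(graph, f.child)
    if f.op == "EX":
        return frozenset(s for s in states if any(t in child for t in graph.successors_of(s)))
    if f.op == "AX":
        return frozenset(s for s in states if all(t in child for t in graph.successors_of(s)))
    if f.op == "EF":
        return frozenset(s for s in states if _exists_path(graph, s, states, child))
    if f.op == "AF":
        return frozenset(
            s for s in states if not _exists_maximal_path_within(graph, s, states - child)
        )
    if f.op == "EG":
        return frozenset(s for s in states if _exists_maximal_path_within(graph, s, child))
    if f.op == "AG":
        bad = states - child
        return frozenset(s for s in states if not _exists_path(graph, s, states, bad))
    raise AssertionError(f.op)


def random_graph(n, density, seed):
    rng = np.random.default_rng(seed)
    states = [(i,) for i in range(n)]
    adj = {
        s: tuple(t for t in states if t != s and rng.random() < density) for s in states
    }
    return StateGraph(entities=["x"], states=states, adj=adj)


def random_formula(rng, depth=3):
    if depth == 0 or rng.random() < 0.3:
        return Atom("x", rng.choice(["=", ">=", "<=", ">", "<"]), int(rng.integers(0, 5)))
    roll = rng.random()
    if roll < 0.2:
        return Not(random_formula(rng, depth - 1))
    if roll < 0.45:
        ctor = [And, Or, Implies, Iff][int(rng.integers(0, 4))]
        return ctor(random_formula(rng, depth - 1), random_formula(rng, depth - 1))
    if roll < 0.85:
        op = [EX, AX, EF, AF, EG, AG][int(rng.integers(0, 6))]
        return op(random_formula(rng, depth - 1))
    return Until(
        "E" if rng.random() < 0.5 else "A",
        random_formula(rng, depth - 1),
        random_formula(rng, depth - 1),
    )


# ---------------------------------------------------------------------------
# Parser


class TestParser:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("EF(p53=1)", EF(Atom("p53", "=", 1))),
            ("AG(IGF>=0)", AG(Atom("IGF", ">=", 0))),
            ("E[(p53=1) U (Mdm2=1)]", Until("E", Atom("p53", "=", 1), Atom("Mdm2", "=", 1))),
            ("!a=1 & b<2", And(Not(Atom("a", "=", 1)), Atom("b", "<", 2))),
            ("a=1 -> b=1 -> c=1", Implies(Atom("a", "=", 1), Implies(Atom("b", "=", 1), Atom("c", "=", 1)))),
            ("ER-alpha=1", Atom("ER-alpha", "=", 1)),
            ("IGF-1R/EGFR>=1", Atom("IGF-1R/EGFR", ">=", 1)),
            ("true | false", Or(TrueF(), FalseF())),
        ],
    )
    def test_parse_examples(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("text", ["EF(", "a=1 &", "E[a=1 U ]", "a==1", "1=a", ""])
    def test_syntax_errors_carry_position(self, text):
        with pytest.raises(ValueError):
            parse_formula(text)

    def test_round_trip_fixed_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            f = random_formula(rng)
            assert parse_formula(to_text(f)) == f

    @given(st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_property(self, seed):
        f = random_formula(np.random.default_rng(seed))
        assert parse_formula(to_text(f)) == f


# ---------------------------------------------------------------------------
# Labeling semantics


class TestLabeling:
    def test_tautology_holds_everywhere(self, case_graph):
        f = parse_formula("IGF-1R/EGFR>=0")
        assert satisfying_states(case_graph, f) == frozenset(case_graph.states)

    def test_ground_state_can_reach_the_metastatic_deadlock(self, case_graph):
        goal = state_atom(case_graph.entities, (1, 1, 0, 0, 0))
        sat = satisfying_states(case_graph, EF(goal))
        assert (0, 0, 0, 0, 0) in sat

    def test_ex_is_false_at_fixed_points(self, case_graph):
        sat = satisfying_states(case_graph, EX(TrueF()))
        assert (1, 1, 0, 0, 0) not in sat
        assert (1, 1, 1, 1, 1) not in sat

    def test_ax_vacuous_and_ag_holds_at_deadlock(self, case_graph):
        dead = (1, 1, 0, 0, 0)
        assert holds_at(case_graph, AX(FalseF()), dead)
        # a terminating maximal path counts as a full path
        atom = state_atom(case_graph.entities, dead)
        assert holds_at(case_graph, AG(atom), dead)

    def test_excluded_middle(self, case_graph):
        f = Or(Atom("p53", "=", 1), Not(Atom("p53", "=", 1)))
        assert satisfying_states(case_graph, f) == frozenset(case_graph.states)

    def test_au_on_two_state_chain(self):
        g = StateGraph(entities=["x"], states=[(0,), (1,)], adj={(0,): ((1,),), (1,): ()})
        f = Until("A", Atom("x", "=", 0), Atom("x", "=", 1))
        assert holds_at(g, f, (0,))

    def test_unknown_atom_raises(self, case_graph):
        with pytest.raises(UnknownAtomError):
            satisfying_states(case_graph, Atom("ghost", "=", 1))

    def test_evaluation_is_pure(self, case_graph):
        f = parse_formula("EF(ER-alpha=1 & p53=0)")
        assert satisfying_states(case_graph, f) == satisfying_states(case_graph, f)

    def test_ef_monotone_under_edge_addition(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            g = random_graph(6, 0.2, seed)
            goal = Atom("x", "<", 2)
            before = satisfying_states(g, EF(goal))
            # add one random edge
            s = g.states[int(rng.integers(0, 6))]
            t = g.states[int(rng.integers(0, 6))]
            adj = dict(g.adj)
            if t not in adj[s] and t != s:
                adj[s] = adj[s] + (t,)
            g2 = StateGraph(entities=["x"], states=list(g.states), adj=adj)
            after = satisfying_states(g2, EF(goal))
            assert before <= after

    @pytest.mark.parametrize("seed", range(15))
    def test_dualities_on_random_graphs(self, seed):
        g = random_graph(7, 0.3, seed)
        rng = np.random.default_rng(seed + 1000)
        phi = random_formula(rng, depth=2)
        all_states = frozenset(g.states)
        assert satisfying_states(g, AX(phi)) == all_states - satisfying_states(g, EX(Not(phi)))
        assert satisfying_states(g, AG(phi)) == all_states - satisfying_states(g, EF(Not(phi)))
        assert satisfying_states(g, AF(phi)) == all_states - satisfying_states(g, EG(Not(phi)))

    @pytest.mark.parametrize("seed", range(25))
    def test_fixpoint_labeling_matches_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        g = random_graph(n, float(rng.uniform(0.1, 0.5)), seed + 77)
        for _ in range(6):
            f = random_formula(rng, depth=3)
            assert satisfying_states(g, f) == oracle_sat(g, f)

    def test_witness_path_is_a_real_path(self, case_graph):
        goal = frozenset({(1, 1, 0, 0, 0)})
        path = witness_path(case_graph, goal, (0, 0, 0, 0, 0))
        assert path is not None and path[-1] in goal
        for a, b in zip(path, path[1:]):
            assert b in case_graph.successors_of(a)
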