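"""Core kinetic-logic semantics: resources, targets, asynchronous steps
and state-graph construction."""

import pytest

from thomasnet.brn import (
    BRN,
    Entity,
    Interaction,
    Parameterization,
    StateSpaceError,
    TotalityError,
    build_state_graph,
    compute_resources,
    successors,
    target_level,
    validate_brn,
)
from thomasnet.synthetic import motif, MotifSpec, random_brn, random_parameterization

IGF, ER, BRCA1, P53, MDM2 = "IGF-1R/EGFR", "ER-alpha", "BRCA1", "p53", "Mdm2"


def brute_force_successors(brn, k, state):
    """Literal re-application of the evolution rules, independent of the
    implementation under test: recompute each entity's resource set by
    scanning all interactions, look up its target, and move one step."""
    out = set()
    names = brn.names
    for i, name in enumerate(names):
        resources = set()
        for ia in brn.interactions:
            if ia.target != name:
                continue
            level = state[names.index(ia.source)]
            if (ia.sign == "+" and level >= ia.threshold) or (
                ia.sign == "-" and level < ia.threshold
            ):
                resources.add(ia.source)
        target = k.get(name, frozenset(resources))
        if state[i] < target:
            out.add(state[:i] + (state[i] + 1,) + state[i + 1 :])
        elif state[i] > target:
            out.add(state[:i] + (state[i] - 1,) + state[i + 1 :])
    return out


class TestValidation:
    def test_case_study_network_is_well_formed(self, case_network):
        brn, _ = case_network
        assert validate_brn(brn) == []

    @pytest.mark.parametrize(
        "entities, interactions, fragment",
        [
            (
                [Entity("a"), Entity("b")],
                [Interaction("a", "b", "+", threshold=2)],
                "threshold",
            ),
            (
                [Entity("a"), Entity("b")],
                [Interaction("a", "b", "+"), Interaction("a", "b", "-")],
                "duplicate interaction",
            ),
            (
                [Entity("a")],
                [Interaction("a", "ghost", "+")],
                "undeclared",
            ),
            (
                [Entity("a", max_level=0)],
                [],
                "max_level",
            ),
        ],
    )
    def test_violations_are_reported_with_context(self, entities, interactions, fragment):
        violations = validate_brn(BRN(entities, interactions))
        assert violations, "expected at least one violation"
        assert any(fragment in v for v in violations)


class TestResources:
    def test_input_entity_has_no_resources_anywhere(self, case_network):
        brn, _ = case_network
        for state in brn.states():
            assert compute_resources(brn, state, IGF) == frozenset()

    def test_p53_resources_at_ground_state(self, case_network):
        # both inhibitors (ER-alpha, Mdm2) below threshold: dormancy helps
        brn, _ = case_network
        assert compute_resources(brn, (0, 0, 0, 0, 0), P53) == {ER, MDM2}

    def test_p53_resources_at_saturated_state(self, case_network):
        # activator BRCA1 present; both inhibitors active hence excluded
        brn, _ = case_network
        assert compute_resources(brn, (1, 1, 1, 1, 1), P53) == {BRCA1}

    def test_unknown_entity_raises(self, case_network):
        brn, _ = case_network
        with pytest.raises(KeyError):
            compute_resources(brn, (0, 0, 0, 0, 0), "nope")

    def test_resources_ignore_non_predecessor_levels(self):
        brn = random_brn(5, edge_density=0.4, seed=11)
        state = (0,) * 5
        for name in brn.names:
            preds = set(brn.predecessor_names(name))
            base = compute_resources(brn, state, name)
            for i, other in enumerate(brn.names):
                if other in preds or other == name:
                    continue
                bumped = state[:i] + (1,) + state[i + 1 :]
                assert compute_resources(brn, bumped, name) == base


class TestTargets:
    @pytest.mark.parametrize(
        "state, entity, expected",
        [
            ((0, 0, 0, 0, 0), P53, 1),
            ((0, 0, 0, 0, 0), IGF, 1),
            ((1, 1, 1, 1, 1), IGF, 1),
            ((0, 0, 0, 0, 0), ER, 0),
            ((0, 0, 0, 0, 0), MDM2, 0),
            ((0, 0, 0, 1, 0), MDM2, 1),
        ],
    )
    def test_selected_parameter_lookups(self, case_network, state, entity, expected):
        brn, k = case_network
        assert target_level(brn, k, state, entity) == expected

    def test_missing_entry_is_totality_error(self):
        brn = BRN([Entity("a")], [])
        k = Parameterization({})
        with pytest.raises(TotalityError):
            target_level(brn, k, (0,), "a")


class TestSuccessors:
    def test_metastatic_state_is_deadlocked(self, case_network):
        brn, k = case_network
        assert successors(brn, k, (1, 1, 0, 0, 0)) == set()

    def test_saturated_state_is_also_fixed(self, case_network):
        brn, k = case_network
        assert successors(brn, k, (1, 1, 1, 1, 1)) == set()

    def test_ground_state_has_two_exits(self, case_network):
        # the receptor switches on, and p53 rises (no inhibitor active)
        brn, k = case_network
        assert successors(brn, k, (0, 0, 0, 0, 0)) == {
            (1, 0, 0, 0, 0),
            (0, 0, 0, 1, 0),
        }

    def test_isolated_stable_entity_has_no_moves(self):
        brn = BRN([Entity("a")], [])
        k = Parameterization({("a", frozenset()): 0})
        assert successors(brn, k, (0,)) == set()

    def test_agrees_with_literal_rule_application(self):
        import numpy as np

        rng = np.random.default_rng(2024)
        checked = 0
        for trial in range(120):
            n = int(rng.integers(1, 5))
            brn = random_brn(
                n,
                edge_density=float(rng.uniform(0, 1)),
                max_level=int(rng.integers(1, 4)),
                seed=int(rng.integers(0, 2**31)),
            )
            k = random_parameterization(brn, seed=int(rng.integers(0, 2**31)))
            states = list(brn.states())
            for _ in range(10):
                s = states[int(rng.integers(0, len(states)))]
                assert successors(brn, k, s) == brute_force_successors(brn, k, s)
                checked += 1
        assert checked >= 1000


class TestStateGraph:
    def test_case_study_product_space(self, case_graph):
        assert case_graph.n_states == 32

    def test_single_rising_entity(self):
        brn = BRN([Entity("a")], [])
        k = Parameterization({("a", frozenset()): 1})
        g = build_state_graph(brn, k)
        assert g.n_states == 2
        assert list(g.edges()) == [((0,), (1,))]

    def test_mutual_inhibition_has_two_fixed_points(self):
        res = motif(MotifSpec("positive-2-loop"))
        g = build_state_graph(res.brn, res.parameterization)
        fixed = {s for s in g.states if g.out_degree(s) == 0}
        assert fixed == {(1, 0), (0, 1)}

    def test_state_space_cap(self):
        brn = BRN([Entity(f"e{i}", max_level=3) for i in range(6)], [])
        k = random_parameterization(brn, seed=0)
        with pytest.raises(StateSpaceError):
            build_state_graph(brn, k, max_states=1000)

    def test_every_transition_is_a_unit_step(self):
        for seed in range(20):
            brn = random_brn(3, edge_density=0.6, max_level=2, seed=seed)
            k = random_parameterization(brn, seed=seed + 100)
            g = build_state_graph(brn, k)
            for s, t in g.edges():
                diffs = [abs(a - b) for a, b in zip(s, t)]
                assert sum(diffs) == 1 and max(diffs) == 1

    def test_deadlock_iff_every_entity_at_target(self, case_network, case_graph):
        brn, k = case_network
        for s in case_graph.states:
            at_target = all(
                target_level(brn, k, s, name) == s[i]
                for i, name in enumerate(brn.names)
            )
            assert (case_graph.out_degree(s) == 0) == at_target
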