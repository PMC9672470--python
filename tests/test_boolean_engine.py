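"""Rule synthesis, synchronous update, storage counters and attractors."""

import pytest

from sarconet.boolean_engine import (
    ModelState,
    find_attractor,
    measure_activity,
    phenotype_scores,
    simulate,
    step,
    synthesize_rules,
)
from sarconet.fixtures import FixtureSpec, random_network
from sarconet.network_core import (
    Element,
    NetworkError,
    Reaction,
    build_network,
)
from sarconet.perturbation import PerturbationSchedule


def storage_chain(extra_edges=()):
    """input -> S(storage) -> X."""
    elements = [
        Element("in"),
        Element("S", is_storage=True, element_class="metabolite"),
        Element("X"),
    ]
    reactions = [
        Reaction("r1", "activity_flow", ("in",), ("S",)),
        Reaction("r2", "activity_flow", ("S",), ("X",)),
    ] + list(extra_edges)
    return build_network(elements, reactions)


class TestRuleSynthesis:
    def test_single_edge_singleton_clause(self, flow_network):
        model = synthesize_rules(flow_network([("A", 1, "B")]))
        assert model.rules["B"].activator_clauses == (frozenset({"A"}),)

    def test_enzymatic_reaction_is_and_gate(self):
        net = build_network(
            [Element(x) for x in "sep"],
            [Reaction("r", "enzymatic", ("s",), ("p",), ("e",))],
        )
        model = synthesize_rules(net)
        assert model.rules["p"].activator_clauses == (frozenset({"s", "e"}),)

    def test_or_across_reactions_and_not_gate(self, flow_network):
        net = flow_network([("A1", 1, "B"), ("A2", 1, "B"), ("I", -1, "B")])
        rule = synthesize_rules(net).rules["B"]
        assert set(rule.activator_clauses) == {frozenset({"A1"}), frozenset({"A2"})}
        assert rule.inhibitors == {"I"}
        # B ON iff (A1 | A2) & !I
        model = synthesize_rules(net)
        for a1 in (0, 1):
            for a2 in (0, 1):
                for i in (0, 1):
                    st = ModelState.make(
                        {"A1": bool(a1), "A2": bool(a2), "I": bool(i), "B": False}
                    )
                    nxt = step(model, st)
                    assert nxt.binary_map["B"] == bool((a1 or a2) and not i)

    def test_disease_inputs_kept_separate(self):
        net = build_network(
            [Element("dz", element_class="disease"), Element("A"), Element("B")],
            [
                Reaction("r1", "activity_flow", ("A",), ("B",)),
                Reaction("r2", "activity_flow", ("dz",), ("B",), sign=-1),
            ],
        )
        rule = synthesize_rules(net).rules["B"]
        assert rule.disease_inhibitors == {"dz"}
        assert rule.inhibitors == frozenset()

    def test_consumption_edges_not_gated_by_default(self):
        net = build_network(
            [Element(x) for x in "sep"],
            [Reaction("r", "enzymatic", ("s",), ("p",), ("e",))],
        )
        assert synthesize_rules(net).rules["s"].is_input
        strict = synthesize_rules(net, consumption_as_inhibition=True)
        assert strict.rules["s"].inhibitors == {"e"}


class TestStep:
    def test_storage_counter_fills_when_satisfied(self):
        model = synthesize_rules(storage_chain())
        st = ModelState.make({"in": True, "X": False}, {"S": 0})
        assert step(model, st).counter_map["S"] == 1

    def test_storage_drains_but_stays_on_as_input(self):
        model = synthesize_rules(storage_chain())
        st = ModelState.make({"in": False, "X": False}, {"S": 3})
        nxt = step(model, st)
        assert nxt.counter_map["S"] == 2
        assert nxt.binary_map["X"] is True  # S counted ON while counter > 0

    def test_storage_counter_floors_at_zero(self):
        model = synthesize_rules(storage_chain())
        st = ModelState.make({"in": False, "X": False}, {"S": 0})
        assert step(model, st).counter_map["S"] == 0

    def test_clamp_overrides_rule(self, flow_network):
        model = synthesize_rules(flow_network([("A", 1, "B")]))
        st = ModelState.make({"A": True, "B": False})
        nxt = step(model, st, clamps={"B": False})
        assert nxt.binary_map["B"] is False

    def test_clamp_unknown_id_rejected(self, flow_network):
        model = synthesize_rules(flow_network([("A", 1, "B")]))
        with pytest.raises(NetworkError):
            step(model, model.initial_state(), clamps={"nope": True})

    def test_input_elements_hold_state(self, flow_network):
        model = synthesize_rules(flow_network([("A", 1, "B")]))
        st = ModelState.make({"A": True, "B": False})
        for _ in range(3):
            st = step(model, st)
            assert st.binary_map["A"] is True


class TestStorageLinearity:
    @pytest.mark.parametrize("m", [1, 5, 20])
    def test_fill_m_drain_m(self, m):
        """Input ON for m steps then OFF: the counter climbs for m steps
        and drains for m steps; it is positive in the 2m - 1 intermediate
        states (it is back at 0 when the m-th drain lands)."""
        model = synthesize_rules(storage_chain())
        schedule = lambda t: {"in": t <= m}
        trace = simulate(model, 3 * m + 5, schedule=schedule)
        on_steps = [t for t, st in enumerate(trace.states) if st.is_on("S")]
        assert on_steps == list(range(2, 2 * m + 1))  # one-step input delay


class TestDiseasePrecedence:
    def test_disease_forces_storage_output_off(self):
        net = build_network(
            [
                Element("in"),
                Element("dz", element_class="disease"),
                Element("S", is_storage=True, element_class="metabolite"),
                Element("X"),
            ],
            [
                Reaction("r1", "activity_flow", ("in",), ("S",)),
                Reaction("r2", "activity_flow", ("S",), ("X",)),
                Reaction("r3", "activity_flow", ("dz",), ("S",), sign=-1),
            ],
        )
        model = synthesize_rules(net)
        st = ModelState.make({"in": True, "dz": True, "X": False}, {"S": 5})
        nxt = step(model, st)
        assert nxt.counter_map["S"] == 4  # disease blocks the fill rule
        assert "S" in nxt.suppressed
        assert not nxt.is_on("S")
        assert step(model, nxt).binary_map["X"] is False

    def test_ordinary_inhibitor_only_blocks_rule(self):
        net = build_network(
            [
                Element("in"),
                Element("inh"),
                Element("S", is_storage=True, element_class="metabolite"),
                Element("X"),
            ],
            [
                Reaction("r1", "activity_flow", ("in",), ("S",)),
                Reaction("r2", "activity_flow", ("S",), ("X",)),
                Reaction("r3", "activity_flow", ("inh",), ("S",), sign=-1),
            ],
        )
        model = synthesize_rules(net)
        st = ModelState.make({"in": True, "inh": True, "X": False}, {"S": 5})
        nxt = step(model, st)
        assert nxt.counter_map["S"] == 4  # drains: rule blocked
        assert nxt.is_on("S")  # but still contributes ON


class TestFindAttractor:
    def test_acyclic_cascade_reaches_stable_state(self, flow_network):
        model = synthesize_rules(flow_network([("A", 1, "B"), ("B", 1, "C")]))
        st = ModelState.make({"A": True, "B": False, "C": False})
        att = find_attractor(model, st)
        assert att.kind == "stable" and att.period == 1
        assert att.states[0].binary_map == {"A": True, "B": True, "C": True}

    def test_negative_feedback_oscillates(self, flow_network):
        # A -> B, B -| A; A is self-sustained (constitutive unless inhibited)
        net = flow_network([("A", 1, "B"), ("B", -1, "A")])
        model = synthesize_rules(net)
        st = ModelState.make({"A": True, "B": False})
        att = find_attractor(model, st)
        assert att.kind == "oscillating"
        # brute force over all 4 states: trajectory from (1,0)
        states = {(a, b): (int(not b), int(a)) for a in (0, 1) for b in (0, 1)}
        seq, seen = (1, 0), []
        while seq not in seen:
            seen.append(seq)
            seq = states[seq]
        cycle_len = len(seen) - seen.index(seq)
        assert att.period == cycle_len

    def test_no_attractor_within_budget_reported_not_raised(self):
        model = synthesize_rules(storage_chain())
        st = ModelState.make({"in": True, "X": False}, {"S": 0})
        att = find_attractor(model, st, max_steps=5, hash_cap=10**6)
        assert att.kind == "none" and not att.found

    def test_exhaustive_state_graph_battery(self):
        """On random storage-free networks, the detected cycle is a true
        cycle and every trajectory enters it."""
        for seed in (0, 1, 2, 3, 4, 5):
            net = random_network(
                FixtureSpec(seed=seed, n_elements=6, density=0.3,
                            negative_fraction=0.4)
            )
            model = synthesize_rules(net)
            ids = sorted(net.elements)
            for mask in range(2 ** len(ids)):
                st = ModelState.make(
                    {e: bool(mask >> i & 1) for i, e in enumerate(ids)}
                )
                att = find_attractor(model, st, max_steps=200)
                assert att.found
                # brute-force trajectory from st
                cur, seen = st, []
                while cur not in seen:
                    seen.append(cur)
                    cur = step(model, cur)
                cycle = seen[seen.index(cur):]
                assert set(cycle) == set(att.states)
                assert att.period == len(cycle)
                assert att.transient_length == seen.index(cur)

    def test_toy_map_food_on_oscillates_glycolysis_vs_glycogen_synthesis(
        self, toy_model
    ):
        att = find_attractor(
            toy_model,
            schedule=PerturbationSchedule("food_intake", "clamp_on"),
            max_steps=500,
        )
        assert att.kind == "oscillating"
        varying = set()
        first = att.states[0].binary_map
        for st in att.states[1:]:
            varying |= {k for k, v in st.binary_map.items() if v != first[k]}
        assert {"glycolysis", "glycogen_synthesis"} <= varying


class TestActivityAndScores:
    def test_activity_is_direct_ratio(self, flow_network):
        model = synthesize_rules(flow_network([("A", 1, "B")]))
        schedule = lambda t: {"A": t % 4 == 0}  # ON 25 of 100 steps
        trace = simulate(model, 100, schedule=schedule)
        act = measure_activity(trace, ["A"], 100)
        assert act["A"] == pytest.approx(0.25)

    def test_clamped_off_element_has_zero_activity(self, flow_network):
        model = synthesize_rules(flow_network([("A", 1, "B")]))
        trace = simulate(model, 50, schedule=lambda t: {"B": False})
        assert measure_activity(trace, ["B"], 50)["B"] == 0.0

    def test_recount_oracle(self, toy_model):
        from sarconet.perturbation import nutrition_schedule

        trace = simulate(toy_model, 60, schedule=nutrition_schedule("well_nourished"))
        act = measure_activity(trace, None, 40)
        for eid, val in act.items():
            manual = sum(st.is_on(eid) for st in trace.states[-40:]) / 40
            assert val == manual

    def test_window_longer_than_trace_rejected(self, toy_model):
        trace = simulate(toy_model, 10)
        with pytest.raises(NetworkError):
            measure_activity(trace, ["insulin"], 11)

    def test_trace_length_contract(self, toy_model):
        assert len(simulate(toy_model, 50).states) == 51

    def test_determinism_bit_for_bit(self, toy_model):
        from sarconet.perturbation import nutrition_schedule

        s = nutrition_schedule("undernourished")
        t1 = simulate(toy_model, 80, schedule=s)
        t2 = simulate(toy_model, 80, schedule=s)
        assert t1 == t2

    def test_phenotype_score_formulas(self):
        act = {
            "apoptosis": 0.2,
            "proteolysis": 0.3,
            "cell_differentiation": 0.1,
            "protein_synthesis": 0.2,
        }
        sc = phenotype_scores(act)
        assert sc["catabolism"] == pytest.approx(0.5)
        assert sc["anabolism"] == pytest.approx(0.3)
        assert sc["sarcopenia"] == pytest.approx(0.2)
        zero = phenotype_scores({k: 0.0 for k in act})
        assert zero["sarcopenia"] == 0.0
        even = phenotype_scores(
            {"apoptosis": 0.25, "proteolysis": 0.25,
             "cell_differentiation": 0.25, "protein_synthesis": 0.25}
        )
        assert even["sarcopenia"] == 0.0

    def test_missing_phenotype_named(self):
        with pytest.raises(NetworkError, match="apoptosis"):
            phenotype_scores({"proteolysis": 0.1})


class TestMonotoneClamps:
    def test_clamp_on_never_decreases_downstream_activity(self, flow_network):
        net = flow_network([("A", 1, "B"), ("B", 1, "C"), ("C", 1, "D")])
        model = synthesize_rules(net)
        free = simulate(model, 50, schedule=lambda t: {"A": t % 3 == 0})
        clamped = simulate(
            model, 50, schedule=lambda t: {"A": True}
        )
        a_free = measure_activity(free, ["D"], 50)["D"]
        a_clamped = measure_activity(clamped, ["D"], 50)["D"]
        assert a_clamped >= a_free
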