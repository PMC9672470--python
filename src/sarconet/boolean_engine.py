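"""Synchronous Boolean simulation with storage counters.

Every element's next state is a pure function of the previous global
state.  Rules are synthesized from the reaction structure of the map:

* each producing reaction contributes one AND-clause over its substrate
  (or auto-complex) and catalysts; several producing reactions combine by
  OR;
* plain positive arrows contribute singleton clauses;
* explicit negative regulators (negative activity-flow arrows, inhibition
  modifiers) become NOT terms that must be OFF;
* interactions sourced at disease elements are kept apart as
  *disease inhibitors* and take precedence: an active disease input forces
  its target OFF, even the ON-contribution of a storage element.

Elements with no inputs at all are treated as model inputs: they hold
their initial state unless a clamp or schedule drives them.  Elements with
only NOT terms are constitutively active unless inhibited (for instance
ketogenesis, which runs whenever hepatic glucose is absent).

Storage elements (glycogen) carry a non-negative integer counter instead
of a bit: +1 at every step whose rule is satisfied, -1 (floored at zero)
otherwise, and they contribute ON to downstream rules while the counter is
positive.  This lets a binary model accumulate a reserve during feeding
and spend it after the stimulus has subsided.

Consumption edges produced by enzymatic conversion, (enzyme|-1|substrate),
are topological bookkeeping and are *not* NOT-gated by default: a storage
reserve could never net-fill if every enzyme switched its own substrate
off one step after activating.  ``consumption_as_inhibition=True`` opts
into the stricter reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .network_core import MolecularNetwork, NetworkError, complex_id

__all__ = [
    "BooleanRule",
    "BooleanModel",
    "ModelState",
    "SimulationTrace",
    "Attractor",
    "synthesize_rules",
    "step",
    "simulate",
    "find_attractor",
    "measure_activity",
    "phenotype_scores",
    "PHENOTYPE_INPUTS",
    "DEFAULT_HASH_CAP",
]

DEFAULT_HASH_CAP = 64

#: the four muscle phenotypes entering the composite scores
PHENOTYPE_INPUTS = (
    "apoptosis",
    "proteolysis",
    "cell_differentiation",
    "protein_synthesis",
)


@dataclass(frozen=True)
class BooleanRule:
    """OR of AND-clauses, gated by NOT terms.

    ``target`` is ON next step iff some activator clause has all members
    ON, no ordinary inhibitor is ON, and no disease inhibitor is ON.  A
    rule with no clauses but at least one inhibitor is constitutive-unless-
    inhibited.  A rule with neither is an input element.
    """

    target: str
    activator_clauses: tuple[frozenset[str], ...] = ()
    inhibitors: frozenset[str] = frozenset()
    disease_inhibitors: frozenset[str] = frozenset()

    @property
    def is_input(self) -> bool:
        return (
            not self.activator_clauses
            and not self.inhibitors
            and not self.disease_inhibitors
        )

    def describe(self) -> str:
        if self.is_input:
            return f"{self.target} := <input>"
        parts = []
        if self.activator_clauses:
            ors = [
                "(" + " & ".join(sorted(c)) + ")" for c in self.activator_clauses
            ]
            parts.append(" | ".join(sorted(ors)))
        else:
            parts.append("TRUE")
        for i in sorted(self.inhibitors):
            parts.append(f"!{i}")
        for i in sorted(self.disease_inhibitors):
            parts.append(f"!{i}[disease]")
        return f"{self.target} := " + " & ".join(parts)


@dataclass(frozen=True)
class ModelState:
    """Binary states plus integer counters for storage elements.

    ``suppressed`` records storage elements whose output was forced OFF by
    an active disease input when this state was produced.
    """

    binary: tuple[tuple[str, bool], ...]
    counters: tuple[tuple[str, int], ...] = ()
    suppressed: frozenset[str] = frozenset()

    @classmethod
    def make(cls, binary: dict, counters: dict | None = None, suppressed=frozenset()):
        return cls(
            tuple(sorted(binary.items())),
            tuple(sorted((counters or {}).items())),
            frozenset(suppressed),
        )

    @property
    def binary_map(self) -> dict[str, bool]:
        return dict(self.binary)

    @property
    def counter_map(self) -> dict[str, int]:
        return dict(self.counters)

    def is_on(self, element_id: str) -> bool:
        """Effective contribution of an element as an input to others."""
        cm = self.counter_map
        if element_id in cm:
            return cm[element_id] > 0 and element_id not in self.suppressed
        return self.binary_map[element_id]

    def hashed(self, cap: int = DEFAULT_HASH_CAP):
        return (
            self.binary,
            tuple((k, min(v, cap)) for k, v in self.counters),
            self.suppressed,
        )


class BooleanModel:
    """Rules keyed by element id, plus which elements are storage."""

    def __init__(self, network: MolecularNetwork, rules: dict[str, BooleanRule]):
        self.network = network
        self.rules = rules
        self.storage = frozenset(
            el.id for el in network.elements.values() if el.is_storage
        )

    def __contains__(self, eid: str) -> bool:
        return eid in self.rules

    def initial_state(self) -> ModelState:
        binary = {
            el.id: el.initial_state
            for el in self.network.elements.values()
            if not el.is_storage
        }
        counters = {
            el.id: int(el.initial_state) for el in self.network.elements.values()
            if el.is_storage
        }
        return ModelState.make(binary, counters)

    def describe(self) -> str:
        return "\n".join(
            self.rules[eid].describe() for eid in sorted(self.rules)
        )


def synthesize_rules(
    network: MolecularNetwork, consumption_as_inhibition: bool = False
) -> BooleanModel:
    """Derive one Boolean rule per element from reactions and interactions.

    Reactions provide the AND structure; interactions not derivable from
    any reaction (e.g. disease inputs injected directly into the merged
    graph) contribute singleton clauses or NOT terms.
    """
    clauses: dict[str, list[frozenset[str]]] = {eid: [] for eid in network.elements}
    inhibitors: dict[str, set[str]] = {eid: set() for eid in network.elements}
    disease_inh: dict[str, set[str]] = {eid: set() for eid in network.elements}

    def is_disease(eid: str) -> bool:
        return network.elements[eid].element_class == "disease"

    def add_positive(target: str, clause: frozenset[str]) -> None:
        if clause not in clauses[target]:
            clauses[target].append(clause)

    def add_negative(target: str, source: str) -> None:
        if is_disease(source):
            disease_inh[target].add(source)
        else:
            inhibitors[target].add(source)

    covered: set[tuple[str, int, str]] = set()
    for reaction in network.reactions:
        if reaction.kind == "activity_flow":
            src, tgt = reaction.substrates[0], reaction.products[0]
            covered.add((src, reaction.sign, tgt))
            if reaction.sign > 0:
                add_positive(tgt, frozenset({src}))
            else:
                add_negative(tgt, src)
            continue
        # enzymatic
        if len(reaction.substrates) == 1:
            eff = reaction.substrates[0]
        else:
            eff = complex_id(reaction.substrates)
            add_positive(eff, frozenset(reaction.substrates))
            for s in reaction.substrates:
                covered.add((s, 1, eff))
        for p in reaction.products:
            add_positive(p, frozenset({eff, *reaction.catalysts}))
            covered.add((eff, 1, p))
            for e in reaction.catalysts:
                covered.add((e, 1, p))
            for mid, msign in reaction.modifiers:
                covered.add((mid, msign, p))
                if msign > 0:
                    add_positive(p, frozenset({mid}))
                else:
                    add_negative(p, mid)
        for e in reaction.catalysts:
            covered.add((e, -1, eff))
            if consumption_as_inhibition:
                add_negative(eff, e)

    # interactions with no originating reaction (disease inputs, curated
    # extra edges in hand-built networks)
    for ia in network.interactions:
        if ia.triple in covered:
            continue
        if ia.consumption:
            if consumption_as_inhibition:
                add_negative(ia.target, ia.source)
            continue
        if ia.sign > 0:
            add_positive(ia.target, frozenset({ia.source}))
        else:
            add_negative(ia.target, ia.source)

    rules = {}
    for eid in network.elements:
        rules[eid] = BooleanRule(
            target=eid,
            activator_clauses=tuple(clauses[eid]),
            inhibitors=frozenset(inhibitors[eid]),
            disease_inhibitors=frozenset(disease_inh[eid]),
        )
    model = BooleanModel(network, rules)
    for eid in model.storage:
        r = rules[eid]
        if r.is_input:
            raise NetworkError(
                f"storage element {eid!r} participates in no rule; a counter "
                f"needs at least one producing reaction or regulator"
            )
    return model


def _rule_satisfied(rule: BooleanRule, state: ModelState) -> bool:
    if rule.activator_clauses:
        ok = any(
            all(state.is_on(m) for m in clause) for clause in rule.activator_clauses
        )
    else:
        # constitutive-unless-inhibited (only meaningful with NOT terms)
        ok = bool(rule.inhibitors or rule.disease_inhibitors)
    if not ok:
        return False
    return not any(state.is_on(i) for i in rule.inhibitors)


def _disease_active(rule: BooleanRule, state: ModelState) -> bool:
    return any(state.is_on(d) for d in rule.disease_inhibitors)


def step(model: BooleanModel, state: ModelState, clamps: dict | None = None) -> ModelState:
    """One synchronous update; ``clamps`` override rules for this step.

    Clamp values are booleans keyed by element id.  Clamping a storage
    element forces its effective output for the produced state without
    touching the counter.
    """
    clamps = clamps or {}
    for eid in clamps:
        if eid not in model.rules:
            raise NetworkError(f"clamp on unknown element id: {eid!r}")
    binary: dict[str, bool] = {}
    counters: dict[str, int] = {}
    suppressed: set[str] = set()
    forced_storage: dict[str, bool] = {}

    for eid, rule in model.rules.items():
        if eid in model.storage:
            counter = state.counter_map[eid]
            disease = _disease_active(rule, state)
            satisfied = (not disease) and _rule_satisfied(rule, state)
            counter = counter + 1 if satisfied else max(0, counter - 1)
            counters[eid] = counter
            if disease:
                suppressed.add(eid)
            if eid in clamps:
                forced_storage[eid] = bool(clamps[eid])
            continue
        if eid in clamps:
            binary[eid] = bool(clamps[eid])
            continue
        if rule.is_input:
            binary[eid] = state.binary_map[eid]
            continue
        if _disease_active(rule, state):
            binary[eid] = False
            continue
        binary[eid] = _rule_satisfied(rule, state)

    # clamps on storage force the effective output, not the counter
    for eid, val in forced_storage.items():
        if val:
            suppressed.discard(eid)
            if counters[eid] == 0:
                counters[eid] = 1
        else:
            suppressed.add(eid)
    return ModelState.make(binary, counters, suppressed)


@dataclass(frozen=True)
class SimulationTrace:
    """States s_0 .. s_N (initial state included) plus per-step clamps."""

    states: tuple[ModelState, ...]
    clamps_applied: tuple[tuple[tuple[str, bool], ...], ...] = ()

    def __len__(self) -> int:
        return len(self.states)

    @property
    def steps(self) -> int:
        return len(self.states) - 1

    def to_frame(self):
        import pandas as pd

        rows = []
        for st in self.states:
            row = {k: int(v) for k, v in st.binary}
            row.update({k: v for k, v in st.counters})
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.index.name = "step"
        return frame


def simulate(
    model: BooleanModel,
    steps: int,
    initial_state: ModelState | None = None,
    schedule=None,
) -> SimulationTrace:
    """Run ``steps`` synchronous updates from the initial state.

    ``schedule`` maps a 1-based step index to a clamp dict (see the
    perturbation module); ``None`` means free-running.
    """
    state = initial_state if initial_state is not None else model.initial_state()
    states = [state]
    applied = []
    for t in range(1, steps + 1):
        clamps = schedule(t) if schedule is not None else {}
        state = step(model, state, clamps)
        states.append(state)
        applied.append(tuple(sorted(clamps.items())))
    return SimulationTrace(tuple(states), tuple(applied))


@dataclass(frozen=True)
class Attractor:
    kind: str  # "stable" | "oscillating" | "none"
    states: tuple[ModelState, ...]
    period: int
    transient_length: int

    @property
    def found(self) -> bool:
        return self.kind != "none"


def find_attractor(
    model: BooleanModel,
    initial_state: ModelState | None = None,
    schedule=None,
    max_steps: int = 1000,
    hash_cap: int = DEFAULT_HASH_CAP,
) -> Attractor:
    """Iterate until a (state, schedule-phase) pair repeats.

    Storage counters are capped at ``hash_cap`` for cycle detection only —
    dynamics within the run are exact — so a perpetually filling reserve
    still terminates (it is reported as part of the repeating state with a
    pegged counter).  Without a repeat within ``max_steps`` the result has
    kind "none" rather than raising.
    """
    if max_steps < 1:
        raise NetworkError("max_steps must be >= 1")
    phase_period = getattr(schedule, "period", None) if schedule is not None else None
    state = initial_state if initial_state is not None else model.initial_state()
    seen: dict[tuple, int] = {}
    history = [state]
    for t in range(max_steps + 1):
        phase = (t % phase_period) if phase_period else 0
        key = (state.hashed(hash_cap), phase)
        if key in seen:
            start = seen[key]
            cycle = tuple(history[start:t])
            period = t - start
            return Attractor(
                kind="stable" if period == 1 else "oscillating",
                states=cycle,
                period=period,
                transient_length=start,
            )
        seen[key] = t
        clamps = schedule(t + 1) if schedule is not None else {}
        state = step(model, state, clamps)
        history.append(state)
    return Attractor(kind="none", states=(), period=0, transient_length=max_steps)


def measure_activity(trace: SimulationTrace, element_ids=None, n: int | None = None):
    """Fraction of ON states per element over the final ``n`` steps.

    Storage elements count as ON while their counter is positive.  The
    initial state is not an update and is excluded from the window.
    """
    total = trace.steps
    if n is None:
        n = total
    if n > total or n < 1:
        raise NetworkError(f"window n={n} outside trace of {total} steps")
    window = trace.states[-n:]
    if element_ids is None:
        element_ids = [k for k, _ in trace.states[0].binary] + [
            k for k, _ in trace.states[0].counters
        ]
    return {
        eid: sum(1 for st in window if st.is_on(eid)) / n for eid in element_ids
    }


def phenotype_scores(activity: dict[str, float]) -> dict[str, float]:
    """Composite muscle phenotype scores from elementary activities.

    catabolism = p(apoptosis) + p(proteolysis);
    anabolism = p(cell_differentiation) + p(protein_synthesis);
    sarcopenia = catabolism - anabolism.  The sums are not renormalized, so
    catabolism/anabolism lie in [0, 2] and sarcopenia in [-2, 2].
    """
    missing = [p for p in PHENOTYPE_INPUTS if p not in activity]
    if missing:
        raise NetworkError(f"missing phenotype activities: {missing}")
    catabolism = activity["apoptosis"] + activity["proteolysis"]
    anabolism = activity["cell_differentiation"] + activity["protein_synthesis"]
    return {
        "catabolism": catabolism,
        "anabolism": anabolism,
        "sarcopenia": catabolism - anabolism,
    }
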