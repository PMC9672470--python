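"""Signed directed molecular interaction networks.

A disease map is a collection of SBML-style reactions over biological
entities (proteins, metabolites, receptors, phenotypes, diseases, ...).
For topological and logical analysis the reactions are flattened into a
single directed graph whose edges are *signed* interaction triples
``(source | sign | target)`` with sign +1 (activation) or -1 (inhibition).

Enzymatic reactions — synthesis of a product ``p`` from a substrate ``s``
catalyzed by an enzyme ``e`` — expand into the triplet
``(s|+1|p), (e|+1|p), (e|-1|s)``, the last edge recording consumption of
the substrate by the enzyme.  Reactions with several substrates first fuse
them into an auto-generated complex node; reactions with several products
repeat the triplet per product.  Plain activity-flow arrows map to a single
signed edge.

A path through the graph carries a length ``L`` (number of edges) and a
type ``T`` in {-1, +1}, the product of its edge signs: +1 means the path is
net-activating, -1 net-inhibiting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "ELEMENT_CLASSES",
    "COMPARTMENTS",
    "Element",
    "SignedInteraction",
    "Reaction",
    "Path",
    "MolecularNetwork",
    "NetworkError",
    "ValidationError",
    "MergeConflictError",
    "reaction_to_interactions",
    "build_network",
    "merge_networks",
    "complex_id",
]

ELEMENT_CLASSES = frozenset(
    {
        "gene",
        "protein",
        "receptor",
        "ion_channel",
        "metabolite",
        "phenotype",
        "disease",
        "complex",
        "clinical_feature",
    }
)

COMPARTMENTS = frozenset({"intestine", "liver", "muscle", "extracellular"})


class NetworkError(Exception):
    """Base class for network construction errors."""


class ValidationError(NetworkError):
    """A reaction or element violates its structural invariants."""


class MergeConflictError(NetworkError):
    """The same element id carries contradictory metadata across submaps."""


@dataclass(frozen=True)
class Element:
    """A node of the interaction network.

    ``is_storage`` marks integer-counter elements (glycogen): their Boolean
    state is a non-negative fill level rather than a bit.  ``initial_state``
    seeds the simulation (input elements such as digestive enzymes and
    transporters start ON).
    """

    id: str
    display_name: str = ""
    element_class: str = "protein"
    compartment: str = "extracellular"
    is_storage: bool = False
    initial_state: bool = False
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValidationError(
                f"element {self.id!r}: unknown element_class {self.element_class!r}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"element {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id)
        object.__setattr__(self, "annotations", tuple(self.annotations))


@dataclass(frozen=True)
class SignedInteraction:
    """An edge triple (source | sign | target), sign in {-1, +1}.

    ``is_disease_input`` flags edges sourced at disease elements; the
    Boolean layer gives these precedence over ordinary inhibitors.
    ``consumption`` marks the (enzyme | -1 | substrate) edges produced by
    enzymatic conversion, which are topological bookkeeping rather than
    regulatory inhibition.
    """

    source: str
    sign: int
    target: str
    provenance: str = ""
    is_disease_input: bool = False
    consumption: bool = False

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValidationError(
                f"interaction {self.source}->{self.target}: sign must be -1 or +1"
            )

    @property
    def triple(self) -> tuple[str, int, str]:
        return (self.source, self.sign, self.target)


@dataclass(frozen=True)
class Reaction:
    """A map reaction, either a plain signed arrow or an enzymatic step.

    Activity-flow reactions have exactly one substrate and one product and
    carry their sign in ``sign``.  Enzymatic reactions need at least one
    substrate, product and catalyst; ``modifiers`` holds additional
    (element id, sign) regulators.
    """

    id: str
    kind: str  # "activity_flow" | "enzymatic"
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    catalysts: tuple[str, ...] = ()
    modifiers: tuple[tuple[str, int], ...] = ()
    sign: int = 1
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", tuple(self.substrates))
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(self, "catalysts", tuple(self.catalysts))
        object.__setattr__(self, "modifiers", tuple(tuple(m) for m in self.modifiers))
        if self.kind == "activity_flow":
            if len(self.substrates) != 1 or len(self.products) != 1:
                raise ValidationError(
                    f"reaction {self.id!r}: activity_flow needs exactly one "
                    f"source and one target"
                )
            if self.sign not in (-1, 1):
                raise ValidationError(f"reaction {self.id!r}: sign must be -1 or +1")
        elif self.kind == "enzymatic":
            if not self.substrates or not self.products:
                raise ValidationError(
                    f"reaction {self.id!r}: enzymatic reaction needs >=1 substrate "
                    f"and >=1 product"
                )
            if not self.catalysts:
                raise ValidationError(
                    f"reaction {self.id!r}: enzymatic reaction without catalyst"
                )
        else:
            raise ValidationError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        for mid, msign in self.modifiers:
            if msign not in (-1, 1):
                raise ValidationError(
                    f"reaction {self.id!r}: modifier {mid!r} sign must be -1 or +1"
                )


@dataclass(frozen=True)
class Path:
    """An interaction sequence with length L and type T = product of signs."""

    steps: tuple[SignedInteraction, ...]

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ValidationError("a path has at least one step")
        for a, b in zip(steps, steps[1:]):
            if a.target != b.source:
                raise ValidationError(
                    f"broken path: step into {a.target!r} followed by step "
                    f"out of {b.source!r}"
                )

    @property
    def source(self) -> str:
        return self.steps[0].source

    @property
    def target(self) -> str:
        return self.steps[-1].target

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def ptype(self) -> int:
        t = 1
        for s in self.steps:
            t *= s.sign
        return t

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.steps[0].source,) + tuple(s.target for s in self.steps)


def complex_id(substrate_ids) -> str:
    """Deterministic id for an auto-generated substrate complex."""
    return "cplx:" + "+".join(sorted(substrate_ids))


def _complex_element(substrate_ids, elements_by_id) -> Element:
    comps = {
        elements_by_id[s].compartment for s in substrate_ids if s in elements_by_id
    }
    compartment = comps.pop() if len(comps) == 1 else "extracellular"
    cid = complex_id(substrate_ids)
    return Element(
        id=cid,
        display_name=cid,
        element_class="complex",
        compartment=compartment,
    )


def reaction_to_interactions(
    reaction: Reaction, elements_by_id: dict[str, Element] | None = None
) -> tuple[list[SignedInteraction], Element | None]:
    """Convert one reaction into its signed interaction triples.

    Returns (interactions, new_complex_element_or_None).  Multi-substrate
    enzymatic reactions synthesize one complex element whose id is derived
    from the sorted substrate ids, so conversion is reproducible.
    """
    elements_by_id = elements_by_id or {}
    prov = reaction.provenance
    if reaction.kind == "activity_flow":
        (src,), (tgt,) = reaction.substrates, reaction.products
        return [SignedInteraction(src, reaction.sign, tgt, provenance=prov)], None

    new_complex: Element | None = None
    out: list[SignedInteraction] = []
    if len(reaction.substrates) == 1:
        eff_substrate = reaction.substrates[0]
    else:
        new_complex = _complex_element(reaction.substrates, elements_by_id)
        eff_substrate = new_complex.id
        for s in reaction.substrates:
            out.append(SignedInteraction(s, 1, eff_substrate, provenance=prov))
    for p in reaction.products:
        out.append(SignedInteraction(eff_substrate, 1, p, provenance=prov))
        for e in reaction.catalysts:
            out.append(SignedInteraction(e, 1, p, provenance=prov))
        for mid, msign in reaction.modifiers:
            out.append(SignedInteraction(mid, msign, p, provenance=prov))
    # consumption of the (effective) substrate by each catalyst; shared
    # across products, deduplicated downstream
    for e in reaction.catalysts:
        out.append(
            SignedInteraction(e, -1, eff_substrate, provenance=prov, consumption=True)
        )
    return out, new_complex


class MolecularNetwork:
    """A signed directed graph plus the reactions it was derived from.

    Elements are keyed by id; interactions are kept in deterministic order
    with set semantics on the (source, sign, target) triple.  The reaction
    collection is retained because Boolean rule synthesis needs the AND
    structure (substrate AND enzyme) that flattening to edges loses.
    """

    def __init__(
        self,
        elements=(),
        interactions=(),
        reactions=(),
        validate: bool = True,
    ) -> None:
        self.elements: dict[str, Element] = {}
        for el in elements:
            if el.id in self.elements:
                raise ValidationError(f"duplicate element id: {el.id!r}")
            self.elements[el.id] = el
        self.reactions: list[Reaction] = list(reactions)
        self._triples: dict[tuple[str, int, str], SignedInteraction] = {}
        for ia in interactions:
            self.add_interaction(ia)
        if validate:
            self.validate()

    # -- mutation -----------------------------------------------------
    def add_interaction(self, ia: SignedInteraction) -> None:
        prev = self._triples.get(ia.triple)
        if prev is None:
            self._triples[ia.triple] = ia
        elif prev.consumption and not ia.consumption:
            # a curated negative arrow outranks a bookkeeping duplicate
            self._triples[ia.triple] = replace(
                ia, is_disease_input=prev.is_disease_input or ia.is_disease_input
            )

    # -- views --------------------------------------------------------
    @property
    def interactions(self) -> list[SignedInteraction]:
        return sorted(
            self._triples.values(), key=lambda ia: (ia.source, ia.target, ia.sign)
        )

    def successors(self, node: str) -> list[SignedInteraction]:
        return [ia for ia in self.interactions if ia.source == node]

    def __contains__(self, element_id: str) -> bool:
        return element_id in self.elements

    def __len__(self) -> int:
        return len(self.elements)

    def validate(self) -> None:
        for ia in self._triples.values():
            for end in (ia.source, ia.target):
                if end not in self.elements:
                    raise ValidationError(
                        f"interaction {ia.source}->{ia.target} references "
                        f"unknown element {end!r}"
                    )
            src = self.elements[ia.source]
            if src.element_class == "disease" and not ia.is_disease_input:
                raise ValidationError(
                    f"disease element {ia.source!r} may only source "
                    f"disease-input interactions"
                )

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "sarconet-network",
            "version": 1,
            "elements": [
                {
                    "id": el.id,
                    "display_name": el.display_name,
                    "element_class": el.element_class,
                    "compartment": el.compartment,
                    "is_storage": el.is_storage,
                    "initial_state": el.initial_state,
                    "annotations": list(el.annotations),
                }
                for el in sorted(self.elements.values(), key=lambda e: e.id)
            ],
            "interactions": [
                {
                    "source": ia.source,
                    "sign": ia.sign,
                    "target": ia.target,
                    "provenance": ia.provenance,
                    "is_disease_input": ia.is_disease_input,
                    "consumption": ia.consumption,
                }
                for ia in self.interactions
            ],
            "reactions": [
                {
                    "id": r.id,
                    "kind": r.kind,
                    "substrates": list(r.substrates),
                    "products": list(r.products),
                    "catalysts": list(r.catalysts),
                    "modifiers": [list(m) for m in r.modifiers],
                    "sign": r.sign,
                    "provenance": r.provenance,
                }
                for r in sorted(self.reactions, key=lambda r: r.id)
            ],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, doc: dict) -> "MolecularNetwork":
        elements = [
            Element(
                id=e["id"],
                display_name=e.get("display_name", e["id"]),
                element_class=e.get("element_class", "protein"),
                compartment=e.get("compartment", "extracellular"),
                is_storage=bool(e.get("is_storage", False)),
                initial_state=bool(e.get("initial_state", False)),
                annotations=tuple(e.get("annotations", ())),
            )
            for e in doc.get("elements", [])
        ]
        interactions = [
            SignedInteraction(
                source=i["source"],
                sign=int(i["sign"]),
                target=i["target"],
                provenance=i.get("provenance", ""),
                is_disease_input=bool(i.get("is_disease_input", False)),
                consumption=bool(i.get("consumption", False)),
            )
            for i in doc.get("interactions", [])
        ]
        reactions = [
            Reaction(
                id=r["id"],
                kind=r["kind"],
                substrates=tuple(r.get("substrates", ())),
                products=tuple(r.get("products", ())),
                catalysts=tuple(r.get("catalysts", ())),
                modifiers=tuple((m[0], int(m[1])) for m in r.get("modifiers", ())),
                sign=int(r.get("sign", 1)),
                provenance=r.get("provenance", ""),
            )
            for r in doc.get("reactions", [])
        ]
        return cls(elements, interactions, reactions)

    def to_edge_tsv(self) -> str:
        lines = ["source\tsign\ttarget\tprovenance"]
        for ia in self.interactions:
            lines.append(f"{ia.source}\t{ia.sign:+d}\t{ia.target}\t{ia.provenance}")
        return "\n".join(lines) + "\n"


def build_network(elements, reactions) -> MolecularNetwork:
    """Convert reactions into a deduplicated signed interaction network.

    Interactions sourced at disease-class elements are flagged as disease
    inputs automatically.  Auto-complex elements are synthesized with
    deterministic ids so rebuilding from the same input is byte-identical.
    """
    elements = list(elements)
    by_id: dict[str, Element] = {}
    collisions = []
    for el in elements:
        if el.id in by_id:
            collisions.append(el.id)
        by_id[el.id] = el
    if collisions:
        raise ValidationError(f"duplicate element ids: {sorted(set(collisions))}")

    net = MolecularNetwork(elements=by_id.values(), reactions=reactions, validate=False)
    for reaction in reactions:
        for eid in (
            *reaction.substrates,
            *reaction.products,
            *reaction.catalysts,
            *(m for m, _ in reaction.modifiers),
        ):
            if eid not in by_id:
                raise ValidationError(
                    f"reaction {reaction.id!r} references unknown element {eid!r}"
                )
        interactions, cplx = reaction_to_interactions(reaction, by_id)
        if cplx is not None and cplx.id not in net.elements:
            net.elements[cplx.id] = cplx
            by_id[cplx.id] = cplx
        for ia in interactions:
            if by_id[ia.source].element_class == "disease":
                ia = replace(ia, is_disease_input=True)
            net.add_interaction(ia)
    net.validate()
    return net


def merge_networks(networks) -> MolecularNetwork:
    """Union of submaps into a single graph.

    Elements with identical ids are unified (extracellular species shared
    between submaps); interactions are deduplicated by triple.  Conflicting
    element_class or compartment for the same id is a merge conflict.
    """
    networks = list(networks)
    if not networks:
        raise NetworkError("nothing to merge")
    merged_elements: dict[str, Element] = {}
    for net in networks:
        for el in net.elements.values():
            prev = merged_elements.get(el.id)
            if prev is None:
                merged_elements[el.id] = el
            else:
                if prev.element_class != el.element_class:
                    raise MergeConflictError(
                        f"element {el.id!r}: conflicting element_class "
                        f"({prev.element_class!r} vs {el.element_class!r})"
                    )
                if prev.compartment != el.compartment:
                    raise MergeConflictError(
                        f"element {el.id!r}: conflicting compartment "
                        f"({prev.compartment!r} vs {el.compartment!r})"
                    )
                merged_elements[el.id] = replace(
                    prev,
                    is_storage=prev.is_storage or el.is_storage,
                    initial_state=prev.initial_state or el.initial_state,
                    annotations=tuple(
                        dict.fromkeys(prev.annotations + el.annotations)
                    ),
                )
    merged = MolecularNetwork(
        elements=merged_elements.values(),
        reactions=[r for net in networks for r in net.reactions],
        validate=False,
    )
    for net in networks:
        for ia in net.interactions:
            merged.add_interaction(ia)
    merged.validate()
    return merged
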