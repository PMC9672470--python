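"""Reading and writing tissue submaps.

Two on-disk formats are supported:

* a JSON network dialect (the native serialization of
  :class:`~sarconet.network_core.MolecularNetwork`), used for fixtures,
  intermediate artifacts and CLI plumbing;
* SBML Level 2/3 core with optional CellDesigner annotations, the format
  disease-map submaps are curated in.

The SBML reader is deliberately qualitative: stoichiometry and boundary
conditions are ignored (with a log note when stoichiometry differs from
1), reversible reactions are treated forward-only with a warning, and
species are classified by the CellDesigner species class when present,
defaulting to ``protein`` otherwise.  Species located inside the named
tissue compartment are assigned to it; everything else is extracellular.
Modifier species map to signs through a configurable table combining SBO
terms and CellDesigner modification types: catalysis/stimulation is +1,
inhibition is -1.  Reactions with at least one catalytic modifier are
classified enzymatic; single-reactant single-product reactions without
one become activity-flow arrows whose sign comes from the reaction-level
SBO term (inhibition arrows are negative).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path as FsPath

from lxml import etree

from .network_core import (
    COMPARTMENTS,
    Element,
    MolecularNetwork,
    NetworkError,
    Reaction,
    build_network,
)

__all__ = [
    "read_submap",
    "write_submap_sbml",
    "read_fixture_json",
    "write_fixture_json",
    "IngestionError",
    "MODIFIER_SIGN_TABLE",
    "SBO_REACTION_SIGNS",
]

log = logging.getLogger(__name__)


class IngestionError(NetworkError):
    """Input document cannot be interpreted as a submap."""


_SBML_NS_L2 = "http://www.sbml.org/sbml/level2"
_SBML_NS_L3 = "http://www.sbml.org/sbml/level3/version1/core"
_CD_NS = "http://www.sbml.org/2001/ns/celldesigner"

#: modifier classification -> sign; keys are upper-cased SBO terms or
#: CellDesigner modification types.  Extend or override via the
#: ``modifier_signs`` argument of :func:`read_submap`.
MODIFIER_SIGN_TABLE = {
    # SBO: catalyst / stimulator flavors
    "SBO:0000013": ("catalyst", 1),
    "SBO:0000460": ("catalyst", 1),
    "SBO:0000461": ("catalyst", 1),
    "SBO:0000459": ("modifier", 1),
    "SBO:0000170": ("modifier", 1),
    "SBO:0000021": ("modifier", 1),
    # SBO: inhibitor flavors
    "SBO:0000020": ("modifier", -1),
    "SBO:0000169": ("modifier", -1),
    "SBO:0000536": ("modifier", -1),
    # CellDesigner modification types
    "CATALYSIS": ("catalyst", 1),
    "UNKNOWN_CATALYSIS": ("catalyst", 1),
    "PHYSICAL_STIMULATION": ("modifier", 1),
    "TRIGGER": ("modifier", 1),
    "MODULATION": ("modifier", 1),
    "INHIBITION": ("modifier", -1),
    "UNKNOWN_INHIBITION": ("modifier", -1),
}

#: reaction-level SBO terms carrying the sign of plain arrows
SBO_REACTION_SIGNS = {
    "SBO:0000170": 1,   # stimulation
    "SBO:0000171": 1,   # necessary stimulation
    "SBO:0000169": -1,  # inhibition
    "SBO:0000407": -1,  # absolute inhibition
}

_CD_CLASS_MAP = {
    "PROTEIN": "protein",
    "GENE": "gene",
    "RNA": "gene",
    "RECEPTOR": "receptor",
    "ION_CHANNEL": "ion_channel",
    "SIMPLE_MOLECULE": "metabolite",
    "ION": "metabolite",
    "PHENOTYPE": "phenotype",
    "DEGRADED": "metabolite",
    "DRUG": "metabolite",
    "COMPLEX": "complex",
    "DISEASE": "disease",
    "CLINICAL_FEATURE": "clinical_feature",
}
_CLASS_CD_MAP = {
    "protein": "PROTEIN",
    "gene": "GENE",
    "receptor": "RECEPTOR",
    "ion_channel": "ION_CHANNEL",
    "metabolite": "SIMPLE_MOLECULE",
    "phenotype": "PHENOTYPE",
    "complex": "COMPLEX",
    "disease": "DISEASE",
    "clinical_feature": "CLINICAL_FEATURE",
}


def _localname(el) -> str:
    return etree.QName(el).localname


def _find_all(parent, localname):
    return [el for el in parent.iter() if _localname(el) == localname]


def _children(parent, localname):
    return [el for el in parent if _localname(el) == localname]


def read_submap(
    source,
    tissue_label: str,
    modifier_signs: dict | None = None,
) -> tuple[list[Element], list[Reaction]]:
    """Parse an SBML submap into elements and reactions.

    ``source`` is a file path or file-like object; ``tissue_label`` names
    the tissue compartment (intestine, liver or muscle) whose species
    become intracellular; everything else is extracellular.
    """
    if tissue_label not in COMPARTMENTS - {"extracellular"}:
        raise IngestionError(f"tissue_label must be a tissue, got {tissue_label!r}")
    signs = dict(MODIFIER_SIGN_TABLE)
    if modifier_signs:
        signs.update({k.upper(): v for k, v in modifier_signs.items()})
    try:
        tree = etree.parse(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise IngestionError(f"cannot parse SBML: {exc}") from exc
    root = tree.getroot()
    if _localname(root) != "sbml":
        raise IngestionError(f"not an SBML document (root <{root.tag}>)")
    models = _children(root, "model")
    if not models:
        raise IngestionError("SBML document has no <model>")
    model = models[0]

    # compartments: the one matching tissue_label is intracellular
    comp_kind: dict[str, str] = {}
    for comp in _find_all(model, "compartment"):
        cid = comp.get("id")
        cname = (comp.get("name") or cid or "").lower()
        if cid is None:
            continue
        if tissue_label in (cid.lower(), cname):
            comp_kind[cid] = tissue_label
        elif cname in ("extracellular", "default", "outside", "") or cid.lower() in (
            "extracellular",
            "default",
        ):
            comp_kind[cid] = "extracellular"
        else:
            comp_kind[cid] = "unknown"

    elements: list[Element] = []
    for sp in _find_all(model, "species"):
        sid = sp.get("id")
        if sid is None:
            continue
        comp = sp.get("compartment", "")
        kind = comp_kind.get(comp, "unknown")
        if kind == "unknown":
            log.warning(
                "species %s in unknown compartment %r; treating as extracellular",
                sid,
                comp,
            )
            kind = "extracellular"
        cd_class = None
        for cls_el in sp.iter(f"{{{_CD_NS}}}class"):
            cd_class = (cls_el.text or "").strip().upper()
            break
        element_class = _CD_CLASS_MAP.get(cd_class or "", "protein")
        storage = False
        for st_el in sp.iter():
            if _localname(st_el) == "storage":
                storage = (st_el.text or "").strip().lower() == "true"
        init = sp.get("initialConcentration") or sp.get("initialAmount") or "0"
        try:
            initial_state = float(init) > 0
        except ValueError:
            initial_state = False
        annotations = []
        for note in sp.iter():
            if _localname(note) == "annotationRef" and note.text:
                annotations.append(note.text.strip())
        elements.append(
            Element(
                id=sid,
                display_name=sp.get("name") or sid,
                element_class=element_class,
                compartment=kind,
                is_storage=storage,
                initial_state=initial_state,
                annotations=tuple(annotations),
            )
        )
    known = {el.id for el in elements}

    reactions: list[Reaction] = []
    for rx in _find_all(model, "reaction"):
        rid = rx.get("id") or f"rx{len(reactions)}"
        if rx.get("reversible", "false").lower() == "true":
            log.warning("reaction %s is reversible; treating forward-only", rid)

        def _refs(listname):
            refs = []
            for lst in _children(rx, listname):
                for ref in lst:
                    if "speciesReference" in _localname(ref) or _localname(
                        ref
                    ) == "modifierSpeciesReference":
                        sp_id = ref.get("species")
                        if sp_id not in known:
                            raise IngestionError(
                                f"reaction {rid!r} references unknown species "
                                f"{sp_id!r}"
                            )
                        stoich = ref.get("stoichiometry")
                        if stoich not in (None, "1", "1.0"):
                            log.info(
                                "reaction %s: ignoring stoichiometry %s on %s",
                                rid,
                                stoich,
                                sp_id,
                            )
                        refs.append((sp_id, ref))
                    else:
                        refs.append((None, ref))
            return [(s, r) for s, r in refs if s is not None]

        substrates = [s for s, _ in _refs("listOfReactants")]
        products = [s for s, _ in _refs("listOfProducts")]

        # celldesigner modification types, keyed by modifier species
        cd_types: dict[str, str] = {}
        for mod in rx.iter(f"{{{_CD_NS}}}modification"):
            mid, mtype = mod.get("modifiers"), mod.get("type")
            if mid and mtype:
                cd_types[mid] = mtype.upper()

        catalysts: list[str] = []
        modifiers: list[tuple[str, int]] = []
        for sp_id, ref in _refs("listOfModifiers"):
            key = (ref.get("sboTerm") or cd_types.get(sp_id) or "").upper()
            role, sign = signs.get(key, ("catalyst", 1))
            if role == "catalyst":
                catalysts.append(sp_id)
            else:
                modifiers.append((sp_id, sign))

        prov = rx.get("metaid") or ""
        if catalysts:
            reactions.append(
                Reaction(
                    rid,
                    "enzymatic",
                    tuple(substrates),
                    tuple(products),
                    tuple(catalysts),
                    tuple(modifiers),
                    provenance=prov,
                )
            )
        else:
            if len(substrates) != 1 or len(products) != 1:
                raise IngestionError(
                    f"reaction {rid!r} has no catalyst and is not a simple "
                    f"arrow ({len(substrates)} reactants, {len(products)} "
                    f"products)"
                )
            sign = SBO_REACTION_SIGNS.get((rx.get("sboTerm") or "").upper(), 1)
            # a lone negative modifier on a plain arrow also means inhibition
            for _, msign in modifiers:
                sign = min(sign, msign)
            reactions.append(
                Reaction(
                    rid,
                    "activity_flow",
                    tuple(substrates),
                    tuple(products),
                    sign=sign,
                    provenance=prov,
                )
            )
    return elements, reactions


def write_submap_sbml(
    elements, reactions, tissue_label: str, path=None
) -> bytes:
    """Serialize elements/reactions as SBML L3 with CellDesigner classes.

    The writer is the inverse of :func:`read_submap` for the feature subset
    the toolkit uses (qualitative species, enzymatic + activity-flow
    reactions, signed modifiers); it exists so fixture submaps can be
    round-tripped through the SBML path without any downloaded content.
    """
    nsmap = {None: _SBML_NS_L3, "celldesigner": _CD_NS}
    sbml = etree.Element(f"{{{_SBML_NS_L3}}}sbml", nsmap=nsmap, level="3", version="1")
    model = etree.SubElement(sbml, f"{{{_SBML_NS_L3}}}model", id=f"{tissue_label}_submap")
    comps = etree.SubElement(model, f"{{{_SBML_NS_L3}}}listOfCompartments")
    for cid in (tissue_label, "extracellular"):
        etree.SubElement(
            comps, f"{{{_SBML_NS_L3}}}compartment", id=cid, name=cid, constant="true"
        )
    species_list = etree.SubElement(model, f"{{{_SBML_NS_L3}}}listOfSpecies")
    for el in sorted(elements, key=lambda e: e.id):
        comp = el.compartment if el.compartment == tissue_label else "extracellular"
        sp = etree.SubElement(
            species_list,
            f"{{{_SBML_NS_L3}}}species",
            id=el.id,
            name=el.display_name,
            compartment=comp,
            constant="false",
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
        )
        sp.set("initialConcentration", "1" if el.initial_state else "0")
        ann = etree.SubElement(sp, f"{{{_SBML_NS_L3}}}annotation")
        ext = etree.SubElement(ann, f"{{{_CD_NS}}}extension")
        cls = etree.SubElement(ext, f"{{{_CD_NS}}}class")
        cls.text = _CLASS_CD_MAP.get(el.element_class, "PROTEIN")
        storage = etree.SubElement(ext, f"{{{_CD_NS}}}storage")
        storage.text = "true" if el.is_storage else "false"
        for ref in el.annotations:
            note = etree.SubElement(ext, f"{{{_CD_NS}}}annotationRef")
            note.text = ref

    rx_list = etree.SubElement(model, f"{{{_SBML_NS_L3}}}listOfReactions")
    for r in sorted(reactions, key=lambda r: r.id):
        rx = etree.SubElement(
            rx_list, f"{{{_SBML_NS_L3}}}reaction", id=r.id, reversible="false"
        )
        if r.kind == "activity_flow" and r.sign < 0:
            rx.set("sboTerm", "SBO:0000169")
        elif r.kind == "activity_flow":
            rx.set("sboTerm", "SBO:0000170")
        if r.provenance:
            rx.set("metaid", r.provenance)
        lor = etree.SubElement(rx, f"{{{_SBML_NS_L3}}}listOfReactants")
        for s in r.substrates:
            etree.SubElement(
                lor,
                f"{{{_SBML_NS_L3}}}speciesReference",
                species=s,
                stoichiometry="1",
                constant="true",
            )
        lop = etree.SubElement(rx, f"{{{_SBML_NS_L3}}}listOfProducts")
        for p in r.products:
            etree.SubElement(
                lop,
                f"{{{_SBML_NS_L3}}}speciesReference",
                species=p,
                stoichiometry="1",
                constant="true",
            )
        if r.catalysts or r.modifiers:
            lom = etree.SubElement(rx, f"{{{_SBML_NS_L3}}}listOfModifiers")
            for e in r.catalysts:
                etree.SubElement(
                    lom,
                    f"{{{_SBML_NS_L3}}}modifierSpeciesReference",
                    species=e,
                    sboTerm="SBO:0000013",
                )
            for mid, msign in r.modifiers:
                etree.SubElement(
                    lom,
                    f"{{{_SBML_NS_L3}}}modifierSpeciesReference",
                    species=mid,
                    sboTerm="SBO:0000020" if msign < 0 else "SBO:0000459",
                )
    blob = etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if path is not None:
        FsPath(path).write_bytes(blob)
    return blob


def read_fixture_json(source) -> MolecularNetwork:
    """Load a network from the JSON dialect (path, stream or dict)."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        try:
            doc = json.loads(FsPath(source).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise IngestionError(f"cannot read network JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise IngestionError("network document must be a JSON object")
    fmt = doc.get("format", "sarconet-network")
    if fmt != "sarconet-network":
        raise IngestionError(f"unexpected document format {fmt!r}")
    for key in ("elements", "interactions", "reactions"):
        if key in doc and not isinstance(doc[key], list):
            raise IngestionError(f"/{key}: expected a JSON array")
    try:
        return MolecularNetwork.from_dict(doc)
    except (KeyError, TypeError) as exc:
        raise IngestionError(f"malformed network document: {exc}") from exc


def write_fixture_json(network: MolecularNetwork, path=None) -> str:
    text = network.to_json()
    if path is not None:
        FsPath(path).write_text(text + "\n")
    return text
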