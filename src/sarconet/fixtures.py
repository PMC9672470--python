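"""Deterministic test networks: a toy carbohydrate-muscle-disease map and
seeded random signed digraphs.

The toy map is a structural miniature of a tissue-crossing disease map,
not a content copy of any published submap.  It wires the carbohydrate
backbone — food intake, SGLT1-mediated intestinal glucose absorption
(SLC5A1), blood glucose, insulin/glucagon counter-regulation, hepatic
glucose, glycogen as an integer storage element filled by glycogen
synthase and drained through glycogenolysis, glycolysis with ATP product
inhibition, and ketogenesis as a fasting response — into muscle phenotypes
(protein synthesis, cell differentiation, proteolysis, apoptosis and the
composite catabolism/anabolism/sarcopenia read-outs), plus two disease
nodes: LC (liver cirrhosis) inhibiting hepatic glucose handling and ID
(intestinal dysfunction) inhibiting absorption.

Qualitative behaviors the wiring is designed to show (mirroring how a
liver-muscle axis responds to feeding frequency): glycogen fills during
feeding blocks and drains during fasting, with glycogenolysis keeping
blood glucose intermittently available until the reserve is empty; under
sparse feeding the reserve hits zero every cycle, under frequent feeding
it grows without bound; glucose scarcity raises proteolysis and apoptosis
and suppresses protein synthesis, so scarcity-inducing perturbations push
the sarcopenia score up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_core import (
    Element,
    MolecularNetwork,
    NetworkError,
    Reaction,
    build_network,
)

__all__ = ["toy_map", "toy_submaps", "random_network", "FixtureSpec"]


def _toy_elements() -> list[Element]:
    E = Element
    return [
        # intestine
        E("food_intake", "food intake", "clinical_feature", "extracellular"),
        E("glucose_intestine", "glucose (intestinal lumen)", "metabolite", "intestine"),
        E("SLC5A1", "SGLT1 glucose transporter", "ion_channel", "intestine",
          initial_state=True),
        E("ID", "intestinal dysfunction", "disease", "intestine"),
        # bloodstream / hormones
        E("glucose_blood", "blood glucose", "metabolite", "extracellular"),
        E("insulin", "insulin", "protein", "extracellular"),
        E("glucagon", "glucagon", "protein", "extracellular"),
        # liver
        E("glucose_liver", "hepatic glucose", "metabolite", "liver"),
        E("glycogen_synthase", "glycogen synthase", "protein", "liver"),
        E("glycogen", "hepatic glycogen", "metabolite", "liver", is_storage=True),
        E("glycogenolysis", "glycogenolysis", "phenotype", "liver"),
        E("glycogen_synthesis", "glycogen synthesis", "phenotype", "liver"),
        E("glycolysis", "glycolysis", "phenotype", "liver"),
        E("ATP", "ATP", "metabolite", "liver"),
        E("ketogenesis", "ketogenesis", "phenotype", "liver"),
        E("LC", "liver cirrhosis", "disease", "liver"),
        E("inflammation", "systemic inflammation", "phenotype", "extracellular"),
        E("ketone_bodies", "ketone bodies", "metabolite", "extracellular"),
        # muscle
        E("SLC2A4", "GLUT4 glucose transporter", "receptor", "muscle"),
        E("glucose_muscle", "muscle glucose", "metabolite", "muscle"),
        E("protein_synthesis", "protein synthesis", "phenotype", "muscle"),
        E("cell_differentiation", "cell differentiation", "phenotype", "muscle"),
        E("proteolysis", "proteolysis", "phenotype", "muscle"),
        E("apoptosis", "apoptosis", "phenotype", "muscle"),
        E("catabolism", "catabolism", "phenotype", "muscle"),
        E("anabolism", "anabolism", "phenotype", "muscle"),
        E("sarcopenia", "sarcopenia", "phenotype", "muscle"),
    ]


def _toy_reactions() -> list[Reaction]:
    R = Reaction

    def flow(rid, src, tgt, sign=1):
        return R(rid, "activity_flow", (src,), (tgt,), sign=sign, provenance="toy")

    return [
        # intestine: digestion and SGLT1-mediated absorption
        flow("r_food_glc", "food_intake", "glucose_intestine"),
        R("r_sglt1_uptake", "enzymatic", ("glucose_intestine",), ("glucose_blood",),
          ("SLC5A1",), provenance="toy"),
        # hormonal control; gut glucose raises insulin ahead of the blood
        # peak (incretin-like), fasting insulin fall derepresses both
        # glucagon and glycogenolysis
        flow("r_glc_insulin", "glucose_blood", "insulin"),
        flow("r_gi_insulin", "glucose_intestine", "insulin"),
        flow("r_cephalic_ins", "food_intake", "insulin"),
        flow("r_ins_glucagon", "insulin", "glucagon", sign=-1),
        # liver glucose handling and glycogen storage; glucagon-driven
        # glycogenolysis releases stored glucose into the blood, and while
        # food is coming in, dietary glucose spares the reserve
        flow("r_glc_liver", "glucose_blood", "glucose_liver"),
        flow("r_ins_gys", "insulin", "glycogen_synthase"),
        R("r_glycogen_synthesis", "enzymatic", ("glucose_liver",),
          ("glycogen", "glycogen_synthesis"), ("glycogen_synthase",),
          provenance="toy"),
        R("r_glycogen_sparing", "enzymatic", ("glycogen",), ("glycogen",),
          ("food_intake",), provenance="toy"),
        flow("r_glucagon_gp", "glucagon", "glycogenolysis"),
        R("r_glycogenolysis", "enzymatic", ("glycogen",), ("glucose_blood",),
          ("glycogenolysis",), provenance="toy"),
        # hepatic glycolysis with ATP product inhibition (negative feedback)
        flow("r_glc_glycolysis", "glucose_liver", "glycolysis"),
        R("r_glycolysis_atp", "enzymatic", ("glucose_liver",), ("ATP",),
          ("glycolysis",), provenance="toy"),
        flow("r_atp_glycolysis", "ATP", "glycolysis", sign=-1),
        flow("r_glycolysis_gsyn", "glycolysis", "glycogen_synthesis", sign=-1),
        # ketogenesis: glucagon-driven, shut off while hepatic glucose
        # lasts; ketone bodies reach the muscle through the bloodstream
        flow("r_glucagon_keto", "glucagon", "ketogenesis"),
        flow("r_keto", "glucose_liver", "ketogenesis", sign=-1),
        flow("r_keto_kb", "ketogenesis", "ketone_bodies"),
        # muscle: insulin-dependent GLUT4 uptake
        flow("r_ins_glut4", "insulin", "SLC2A4"),
        R("r_glut4_uptake", "enzymatic", ("glucose_blood",), ("glucose_muscle",),
          ("SLC2A4",), provenance="toy"),
        # muscle phenotypes: the fasting hormone axis (glucagon, prolonged
        # scarcity marked by ketogenesis) drives the catabolic arms, and
        # systemic inflammation both drives them and blocks anabolism
        flow("r_glcm_ps", "glucose_muscle", "protein_synthesis"),
        flow("r_infl_ps", "inflammation", "protein_synthesis", sign=-1),
        flow("r_ins_cd", "insulin", "cell_differentiation"),
        flow("r_infl_cd", "inflammation", "cell_differentiation", sign=-1),
        flow("r_glucagon_prot", "glucagon", "proteolysis"),
        flow("r_infl_prot", "inflammation", "proteolysis"),
        flow("r_kb_apop", "ketone_bodies", "apoptosis"),
        flow("r_infl_apop", "inflammation", "apoptosis"),
        flow("r_prot_cat", "proteolysis", "catabolism"),
        flow("r_apop_cat", "apoptosis", "catabolism"),
        flow("r_ps_ana", "protein_synthesis", "anabolism"),
        flow("r_cd_ana", "cell_differentiation", "anabolism"),
        flow("r_cat_sarc", "catabolism", "sarcopenia"),
        flow("r_ana_sarc", "anabolism", "sarcopenia", sign=-1),
        # disease inputs (flagged automatically: sources are disease-class);
        # both diseases also feed the blood secretome: liver injury and a
        # disrupted epithelial barrier cause systemic inflammation
        flow("r_lc_liver", "LC", "glucose_liver", sign=-1),
        flow("r_lc_gp", "LC", "glycogenolysis", sign=-1),
        flow("r_lc_infl", "LC", "inflammation"),
        flow("r_id_sglt1", "ID", "SLC5A1", sign=-1),
        flow("r_id_glc", "ID", "glucose_intestine", sign=-1),
        flow("r_id_infl", "ID", "inflammation"),
    ]


#: which toy elements belong to which tissue submap (extracellular species
#: are shared between all three, as in a modularized disease map)
_SUBMAP_TISSUE = {"intestine", "liver", "muscle"}


def toy_map() -> MolecularNetwork:
    """The full toy map as a single merged network."""
    return build_network(_toy_elements(), _toy_reactions())


def toy_submaps() -> dict[str, MolecularNetwork]:
    """The toy map split into three tissue submaps sharing extracellular
    elements, for exercising merge and SBML round-trips."""
    elements = _toy_elements()
    by_id = {e.id: e for e in elements}
    reactions = _toy_reactions()
    submaps = {}
    for tissue in sorted(_SUBMAP_TISSUE):
        r_in = []
        for r in reactions:
            involved = {
                by_id[eid].compartment
                for eid in (*r.substrates, *r.products, *r.catalysts,
                            *(m for m, _ in r.modifiers))
            }
            tissues = involved & _SUBMAP_TISSUE
            # a reaction belongs to the tissue of its intracellular members;
            # purely extracellular reactions live in the liver submap (the
            # hormonal hub), mirroring how shared signaling is usually filed
            home = min(tissues) if tissues else "liver"
            if home == tissue:
                r_in.append(r)
        ids = set()
        for r in r_in:
            ids.update(r.substrates, r.products, r.catalysts,
                       (m for m, _ in r.modifiers))
        submaps[tissue] = build_network(
            [by_id[i] for i in sorted(ids)], r_in
        )
    return submaps


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a reproducible random signed digraph."""

    seed: int
    n_elements: int = 10
    density: float = 0.2
    negative_fraction: float = 0.3
    include_diseases: bool = False
    include_storage: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.density <= 1):
            raise NetworkError("density must be in (0, 1]")
        if not (0 <= self.negative_fraction <= 1):
            raise NetworkError("negative_fraction must be in [0, 1]")
        if self.n_elements < 2:
            raise NetworkError("need at least 2 elements")


def random_network(spec: FixtureSpec) -> MolecularNetwork:
    """Seeded Erdos-Renyi style signed digraph (self-loops allowed).

    Each ordered pair (including self-pairs) carries an edge with
    probability ``density``; each edge is negative with probability
    ``negative_fraction``.  Identical specs produce identical serialized
    networks.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"n{i:02d}" for i in range(spec.n_elements)]
    elements = [
        Element(nm, element_class="protein", compartment="extracellular")
        for nm in names
    ]
    if spec.include_diseases:
        elements.append(Element("dz", element_class="disease",
                                compartment="extracellular"))
    reactions = []
    k = 0
    for src in names:
        for tgt in names:
            if rng.random() < spec.density:
                sign = -1 if rng.random() < spec.negative_fraction else 1
                reactions.append(
                    Reaction(f"e{k:03d}", "activity_flow", (src,), (tgt,),
                             sign=sign)
                )
                k += 1
    if spec.include_storage and reactions:
        elements.append(Element("store", is_storage=True,
                                element_class="metabolite",
                                compartment="extracellular"))
        reactions.append(
            Reaction(f"e{k:03d}", "activity_flow", (names[0],), ("store",))
        )
        k += 1
    if spec.include_diseases:
        reactions.append(
            Reaction(f"e{k:03d}", "activity_flow", ("dz",), (names[0],), sign=-1)
        )
    return build_network(elements, reactions)
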