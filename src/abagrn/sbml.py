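"""SBML Level 3 export and round-trip import for the model's own dialect.

The exported document is plain SBML L3 core: unit definitions for the
internal hour/micromolar system, one compartment, species with
``boundaryCondition`` marking clamped inputs, global parameters, and
reactions whose kinetic laws are explicit mass-action MathML
(``kf*A*B - kr*C`` for reversible binding, ``k*X`` otherwise).  A small
annotation block in the package's namespace records the reaction kind and
species roles so that :func:`read_sbml` can reconstruct an equivalent
:class:`~abagrn.network.ModelDefinition`; any SBML tool that ignores
annotations still sees a complete, simulatable model.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .network import (
    ModelDefinition,
    ParamEntry,
    ParameterTable,
    ReactionSpec,
    SpeciesDecl,
)

__all__ = ["export_sbml", "write_sbml", "read_sbml", "SBML_NS", "ANNOT_NS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://abagrn.invalid/sbml-annotations"

_UNIT_DEFS = {
    # id -> list of (kind, exponent, multiplier)
    "hour": [("second", 1, 3600.0)],
    "per_hour": [("second", -1, 1 / 3600.0)],
    "micromolar": [("mole", 1, 1e-6), ("litre", -1, 1.0)],
    "per_micromolar_hour": [("mole", -1, 1e-6), ("litre", 1, 1.0),
                            ("second", -1, 1 / 3600.0)],
}

_UNIT_IDS = {"1/h": "per_hour", "1/(uM*h)": "per_micromolar_hour",
             "uM": "micromolar"}
_UNIT_IDS_BACK = {v: k for k, v in _UNIT_IDS.items()}


def _math_ci(parent, name):
    ET.SubElement(parent, f"{{{MATHML_NS}}}ci").text = f" {name} "


def _mass_action_math(rxn: ReactionSpec) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")

    def product_term(parent, param, participants):
        apply_ = ET.SubElement(parent, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply_, f"{{{MATHML_NS}}}times")
        _math_ci(apply_, param)
        for sp, stoich in participants:
            for _ in range(stoich):
                _math_ci(apply_, sp)

    if rxn.kind == "reversible_binding":
        outer = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(outer, f"{{{MATHML_NS}}}minus")
        product_term(outer, rxn.forward_param, rxn.reactants)
        product_term(outer, rxn.reverse_param, rxn.products)
    else:
        product_term(math, rxn.forward_param, rxn.reactants)
    return math


def export_sbml(model: ModelDefinition, model_id: str = "abagrn") -> ET.Element:
    """Build the SBML document tree for a model."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("abagrn", ANNOT_NS)

    sbml = ET.Element(f"{{{SBML_NS}}}sbml", level="3", version="2")
    mdl = ET.SubElement(sbml, f"{{{SBML_NS}}}model", id=model_id,
                        substanceUnits="micromolar", timeUnits="hour",
                        extentUnits="micromolar")
    annot = ET.SubElement(mdl, f"{{{SBML_NS}}}annotation")
    info = ET.SubElement(annot, f"{{{ANNOT_NS}}}model")
    info.set("cellVolumeUm3", repr(model.cell_volume))
    info.set("geneCopies", str(model.gene_copies))
    if model.disabled_reactions:
        info.set("disabledReactions",
                 " ".join(sorted(model.disabled_reactions)))

    units = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfUnitDefinitions")
    for uid, parts in _UNIT_DEFS.items():
        ud = ET.SubElement(units, f"{{{SBML_NS}}}unitDefinition", id=uid)
        lst = ET.SubElement(ud, f"{{{SBML_NS}}}listOfUnits")
        for kind, exp, mult in parts:
            ET.SubElement(lst, f"{{{SBML_NS}}}unit", kind=kind,
                          exponent=str(exp), scale="0", multiplier=repr(mult))

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment", id="cell",
                  spatialDimensions="3", size=repr(model.cell_volume),
                  constant="true")

    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for sp in model.species:
        el = ET.SubElement(
            sps, f"{{{SBML_NS}}}species", id=sp.name, compartment="cell",
            initialConcentration=repr(sp.initial_concentration),
            substanceUnits="micromolar", hasOnlySubstanceUnits="false",
            boundaryCondition="true" if sp.clamped else "false",
            constant="false")
        a = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(a, f"{{{ANNOT_NS}}}species", role=sp.role)

    pars = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for name, entry in model.parameters.items():
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", id=name,
                      value=repr(entry.value),
                      units=_UNIT_IDS.get(entry.unit, "dimensionless"),
                      constant="true" if entry.fixed else "false")

    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rxn in model.reactions:
        el = ET.SubElement(
            rxns, f"{{{SBML_NS}}}reaction", id=rxn.name,
            reversible="true" if rxn.kind == "reversible_binding" else "false")
        a = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        meta = ET.SubElement(a, f"{{{ANNOT_NS}}}reaction", kind=rxn.kind,
                             forwardParam=rxn.forward_param)
        if rxn.reverse_param:
            meta.set("reverseParam", rxn.reverse_param)
        meta.set("reactants", " ".join(f"{sp}:{st}" for sp, st in rxn.reactants))
        meta.set("products", " ".join(f"{sp}:{st}" for sp, st in rxn.products))
        if rxn.reactants:
            lst = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sp, st in rxn.reactants:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              species=sp, stoichiometry=str(st),
                              constant="true")
        if rxn.products:
            lst = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sp, st in rxn.products:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              species=sp, stoichiometry=str(st),
                              constant="true")
        kl = ET.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_mass_action_math(rxn))
    return sbml


def write_sbml(model: ModelDefinition, path: str | Path,
               model_id: str = "abagrn") -> None:
    tree = ET.ElementTree(export_sbml(model, model_id))
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")


def _parse_pairs(text: str) -> tuple[tuple[str, int], ...]:
    if not text:
        return ()
    return tuple((sp, int(st)) for sp, st in
                 (item.split(":") for item in text.split()))


def read_sbml(path: str | Path) -> ModelDefinition:
    """Reconstruct a ModelDefinition from a document written by write_sbml."""
    root = ET.parse(path).getroot()
    mdl = root.find(f"{{{SBML_NS}}}model")
    if mdl is None:
        raise ValueError("not an SBML document: no <model> element")
    info = mdl.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}model")
    cell_volume = float(info.get("cellVolumeUm3", "50"))
    gene_copies = int(info.get("geneCopies", "2"))
    disabled = frozenset((info.get("disabledReactions") or "").split())

    species = []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        meta = el.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}species")
        species.append(SpeciesDecl(
            name=el.get("id"),
            role=meta.get("role") if meta is not None else "protein",
            clamped=el.get("boundaryCondition") == "true",
            initial_concentration=float(el.get("initialConcentration", "0")),
        ))

    entries = {}
    for el in mdl.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        entries[el.get("id")] = ParamEntry(
            value=float(el.get("value")),
            unit=_UNIT_IDS_BACK.get(el.get("units"), el.get("units")),
            fixed=el.get("constant") == "true",
        )

    reactions = []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        meta = el.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}reaction")
        if meta is None:
            raise ValueError(f"reaction {el.get('id')}: missing dialect annotation")
        reactions.append(ReactionSpec(
            name=el.get("id"),
            reactants=_parse_pairs(meta.get("reactants", "")),
            products=_parse_pairs(meta.get("products", "")),
            kind=meta.get("kind"),
            forward_param=meta.get("forwardParam"),
            reverse_param=meta.get("reverseParam"),
        ))

    return ModelDefinition(
        species=tuple(species),
        reactions=tuple(reactions),
        parameters=ParameterTable(entries),
        cell_volume=cell_volume,
        gene_copies=gene_copies,
        disabled_reactions=disabled,
    )
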