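"""Minimal SBML Level 3 export of the network for interoperability.

Writes a single-compartment SBML Level 3 Version 2 core document with
the species (initial concentrations from the default initial condition,
G-actin as a constant boundary species), the nine reactions, and
mass-action kinetic laws as MathML with local k_on/k_off parameters.
The writer is intentionally small and hand-rolled on ``xml.etree``; it
covers exactly the constructs this model uses.
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree as ET

from .network import NetworkModel
from .params import CellParameterSet
from .steady import default_initial_state

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math(expr: ET.Element) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(expr)
    return math


def _ci(name: str) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _apply(op: str, *args: ET.Element) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}apply")
    el.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    for a in args:
        el.append(a)
    return el


def _times(*names: str) -> ET.Element:
    return _apply("times", *[_ci(n) for n in names])


def export_sbml(
    model: NetworkModel, params: CellParameterSet, path: str | Path | None = None
) -> str:
    """Serialize the model to an SBML string (and optionally a file)."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": "filonet", "name": "Eps8_IRSp53_VASP_network"})

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "size": "1", "spatialDimensions": "3", "constant": "true"},
    )

    init = default_initial_state(model, params)
    species_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for i, sp in enumerate(model.species):
        clamped = sp.name in model.clamped
        ET.SubElement(
            species_el,
            f"{{{SBML_NS}}}species",
            {
                "id": sp.name,
                "name": sp.name,
                "compartment": "cell",
                "initialConcentration": repr(float(init[i])),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "true" if clamped else "false",
                "constant": "true" if clamped else "false",
            },
        )

    rxns_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rxn in model.reactions:
        r_el = ET.SubElement(
            rxns_el,
            f"{{{SBML_NS}}}reaction",
            {
                "id": f"R{rxn.rid}",
                "name": rxn.label,
                "reversible": "true" if rxn.reversible else "false",
            },
        )
        reactants = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfReactants")
        for name in rxn.substrates:
            ET.SubElement(
                reactants,
                f"{{{SBML_NS}}}speciesReference",
                {"species": name, "stoichiometry": "1", "constant": "true"},
            )
        if rxn.products:
            products = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfProducts")
            for name in rxn.products:
                ET.SubElement(
                    products,
                    f"{{{SBML_NS}}}speciesReference",
                    {"species": name, "stoichiometry": "1", "constant": "true"},
                )
        if rxn.kind == "polymerization":
            mods = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfModifiers")
            ET.SubElement(
                mods, f"{{{SBML_NS}}}modifierSpeciesReference", {"species": "B"}
            )

        kin = ET.SubElement(r_el, f"{{{SBML_NS}}}kineticLaw")
        if rxn.kind == "binding":
            k_on, k_off = params.kinetics[rxn.rid]
            expr = _apply(
                "minus",
                _times("k_on", *rxn.substrates),
                _times("k_off", *rxn.products),
            )
            local = (("k_on", k_on), ("k_off", k_off))
        elif rxn.kind == "polymerization":
            k_pol, k_depol = params.kinetics[rxn.rid]
            expr = _apply(
                "minus", _times("k_pol", "Ga", "B"), _times("k_depol", "B")
            )
            local = (("k_pol", k_pol), ("k_depol", k_depol))
        else:  # turnover
            expr = _times("k_turn", "Fa")
            local = (("k_turn", params.k_turn),)
        kin.append(_math(expr))
        locals_el = ET.SubElement(kin, f"{{{SBML_NS}}}listOfLocalParameters")
        for pname, pvalue in local:
            ET.SubElement(
                locals_el,
                f"{{{SBML_NS}}}localParameter",
                {"id": pname, "value": repr(float(pvalue))},
            )

    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text)
    return text
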