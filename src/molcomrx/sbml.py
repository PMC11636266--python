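"""SBML Level 3 Version 1 serialisation of the receiver circuit model.

Writes the reaction network as a self-contained SBML document: species with
initial amounts, kinetic laws and assignment rules as content MathML
(generated from the symbolic rate expressions), and one timed event per
arrival injection, so the model can be exchanged with SBML-aware simulators.

A lightweight reader is also provided; it recovers the document structure
(species, reactions, events, initial amounts and injection schedules) for
round-trip checks.  It is a structural reader, not a general SBML simulator.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

import sympy as sp
from sympy.printing.mathml import mathml

from .circuit import SPECIES, CircuitModel

__all__ = ["export_sbml", "read_sbml_summary", "SbmlSummary"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"


def _math_element(expr: sp.Expr) -> ET.Element:
    """Content-MathML <math> element for a sympy expression."""
    inner = mathml(expr, disable_split_super_sub=True)
    return ET.fromstring(f'<math xmlns="{MATHML_NS}">{inner}</math>')


def _event_trigger_math(time_s: float) -> ET.Element:
    inner = (
        "<apply><geq/>"
        f'<csymbol encoding="text" definitionURL="{TIME_CSYMBOL}">t</csymbol>'
        f"<cn>{time_s!r}</cn></apply>"
    )
    return ET.fromstring(f'<math xmlns="{MATHML_NS}">{inner}</math>')


def export_sbml(model: CircuitModel, path) -> None:
    """Write the circuit model (reactions, rules, injection events) as SBML L3V1."""
    ET.register_namespace("", SBML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": "receiver_circuit"})

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "size": "1", "spatialDimensions": "3", "constant": "true"},
    )

    species_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for name, amount in zip(SPECIES, model.initial_state):
        ET.SubElement(
            species_el,
            f"{{{SBML_NS}}}species",
            {
                "id": name,
                "compartment": "cell",
                "initialAmount": repr(float(amount)),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )

    params_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for target in model.assignments:
        ET.SubElement(
            params_el,
            f"{{{SBML_NS}}}parameter",
            {"id": target, "value": "0", "constant": "false"},
        )

    rules_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfRules")
    for target, expr in model.assignments.items():
        rule = ET.SubElement(rules_el, f"{{{SBML_NS}}}assignmentRule", {"variable": target})
        rule.append(_math_element(expr))

    rxns_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rxn in model.reactions:
        rxn_el = ET.SubElement(
            rxns_el, f"{{{SBML_NS}}}reaction", {"id": rxn.name, "reversible": "false"}
        )
        reactants = {s: -c for s, c in rxn.stoichiometry.items() if c < 0}
        products = {s: c for s, c in rxn.stoichiometry.items() if c > 0}
        if reactants:
            lst = ET.SubElement(rxn_el, f"{{{SBML_NS}}}listOfReactants")
            for s, c in reactants.items():
                ET.SubElement(
                    lst,
                    f"{{{SBML_NS}}}speciesReference",
                    {"species": s, "stoichiometry": str(c), "constant": "true"},
                )
        if products:
            lst = ET.SubElement(rxn_el, f"{{{SBML_NS}}}listOfProducts")
            for s, c in products.items():
                ET.SubElement(
                    lst,
                    f"{{{SBML_NS}}}speciesReference",
                    {"species": s, "stoichiometry": str(c), "constant": "true"},
                )
        law = ET.SubElement(rxn_el, f"{{{SBML_NS}}}kineticLaw")
        law.append(_math_element(rxn.rate))

    if model.events:
        events_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfEvents")
        for i, (t, amounts) in enumerate(model.events):
            ev = ET.SubElement(
                events_el,
                f"{{{SBML_NS}}}event",
                {"id": f"injection_{i}", "useValuesFromTriggerTime": "true"},
            )
            trig = ET.SubElement(
                ev,
                f"{{{SBML_NS}}}trigger",
                {"initialValue": "false", "persistent": "true"},
            )
            trig.append(_event_trigger_math(t))
            assigns = ET.SubElement(ev, f"{{{SBML_NS}}}listOfEventAssignments")
            for species, amount in amounts.items():
                ea = ET.SubElement(
                    assigns, f"{{{SBML_NS}}}eventAssignment", {"variable": species}
                )
                inner = f"<apply><plus/><ci>{species}</ci><cn>{amount!r}</cn></apply>"
                ea.append(ET.fromstring(f'<math xmlns="{MATHML_NS}">{inner}</math>'))

    tree = ET.ElementTree(root)
    ET.indent(tree)
    try:
        tree.write(path, xml_declaration=True, encoding="UTF-8")
    except OSError as exc:
        raise OSError(f"could not write SBML document to {path}: {exc}") from exc


@dataclass(frozen=True)
class SbmlSummary:
    """Structural view of an SBML document, for round-trip verification."""

    species: dict          # id -> initial amount
    n_reactions: int
    n_rules: int
    events: list           # (trigger time, {species: injected amount})


def read_sbml_summary(path) -> SbmlSummary:
    """Parse an SBML L3 file back into its structural summary."""
    tree = ET.parse(path)
    ns = {"s": SBML_NS, "m": MATHML_NS}
    mdl = tree.getroot().find("s:model", ns)
    if mdl is None:
        raise ValueError(f"{path} has no <model> element")
    species = {
        el.attrib["id"]: float(el.attrib.get("initialAmount", "nan"))
        for el in mdl.findall("s:listOfSpecies/s:species", ns)
    }
    n_reactions = len(mdl.findall("s:listOfReactions/s:reaction", ns))
    n_rules = len(mdl.findall("s:listOfRules/s:assignmentRule", ns))
    events = []
    for ev in mdl.findall("s:listOfEvents/s:event", ns):
        cn = ev.find("s:trigger/m:math/m:apply/m:cn", ns)
        t = float(cn.text) if cn is not None else float("nan")
        amounts = {}
        for ea in ev.findall("s:listOfEventAssignments/s:eventAssignment", ns):
            target = ea.attrib["variable"]
            add = ea.find("m:math/m:apply/m:cn", ns)
            amounts[target] = float(add.text) if add is not None else float("nan")
        events.append((t, amounts))
    return SbmlSummary(species=species, n_reactions=n_reactions, n_rules=n_rules, events=events)
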