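"""Minimal SBML Level 3 (Version 2 core) export of a reaction network.

A compact, hand-written emitter covering what interoperability needs: the
compartment, every species with its initial concentration, and every reaction
with reversibility and stoichiometry.  Kinetic laws are intentionally left
out — the mass-action semantics live in :mod:`braferk.kinetics` — and rate
constants are recorded as model parameters so a consumer can reattach them.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

from lxml import etree

from .network import ReactionNetwork

__all__ = ["write_sbml", "network_to_sbml"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def _sid(name: str) -> str:
    """Sanitise a species name into a valid SBML SId (dots become underscores)."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name.replace("·", "_"))
    return sid if re.match(r"^[A-Za-z_]", sid) else f"s_{sid}"


def network_to_sbml(network: ReactionNetwork,
                    constants: Mapping[str, float] | None = None,
                    initial: Mapping[str, float] | None = None) -> bytes:
    """Serialise the network to SBML L3V2 XML bytes."""
    initial = initial or {}
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap={None: _SBML_NS},
                         level="3", version="2")
    model = etree.SubElement(sbml, f"{{{_SBML_NS}}}model", id="braf_mek_erk_cascade",
                             substanceUnits="mole", timeUnits="second",
                             extentUnits="mole")
    comps = etree.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{_SBML_NS}}}compartment", id="cell", constant="true",
                     spatialDimensions="3", size="1")
    lspecies = etree.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for s in network.species:
        etree.SubElement(
            lspecies, f"{{{_SBML_NS}}}species", id=_sid(s.name), name=s.name,
            compartment="cell", hasOnlySubstanceUnits="false",
            boundaryCondition="false", constant="false",
            initialConcentration=repr(float(initial.get(s.name, 0.0))))
    if constants:
        lparams = etree.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
        for name, value in constants.items():
            etree.SubElement(lparams, f"{{{_SBML_NS}}}parameter", id=name,
                             value=repr(float(value)), constant="true")
    lreact = etree.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rx = etree.SubElement(lreact, f"{{{_SBML_NS}}}reaction",
                              id=_sid(r.rid), name=r.rid,
                              reversible="true" if r.kind == "binding" else "false")
        lre = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
        for n in r.reactants:
            etree.SubElement(lre, f"{{{_SBML_NS}}}speciesReference",
                             species=_sid(n), stoichiometry="1", constant="true")
        lpr = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
        for n in r.products:
            etree.SubElement(lpr, f"{{{_SBML_NS}}}speciesReference",
                             species=_sid(n), stoichiometry="1", constant="true")
    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_sbml(network: ReactionNetwork, path: str | Path,
               constants: Mapping[str, float] | None = None,
               initial: Mapping[str, float] | None = None) -> None:
    Path(path).write_bytes(network_to_sbml(network, constants, initial))
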