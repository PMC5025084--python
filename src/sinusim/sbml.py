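"""Export of the single-compartment kinetic core to SBML Level 3.

Writes the hepatocyte reaction network of one sinusoid compartment
(species, reactions, kinetic laws) as an SBML L3 core document for
cross-tool inspection.  Hormone and oxygen concentrations are exported
as boundary species at the chosen compartment's levels, and each
process's Hill-product rate law is emitted as explicit MathML.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.dom import minidom

from .ratelaws import RateTerm, TermKind
from .state import BLOOD_SPECIES, HEP_SPECIES
from .transport import SinusoidModel

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math(expr: ET.Element) -> ET.Element:
    m = ET.Element(f"{{{MATHML_NS}}}math")
    m.append(expr)
    return m


def _num(value: float) -> ET.Element:
    cn = ET.Element(f"{{{MATHML_NS}}}cn")
    cn.text = repr(float(value))
    return cn


def _ci(name: str) -> ET.Element:
    ci = ET.Element(f"{{{MATHML_NS}}}ci")
    ci.text = f" {name} "
    return ci


def _apply(op: str, *args: ET.Element) -> ET.Element:
    a = ET.Element(f"{{{MATHML_NS}}}apply")
    a.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    for x in args:
        a.append(x)
    return a


def _hill_math(species: str, K: float, n: float, inhibition: bool) -> ET.Element:
    cn_pow = _apply("power", _ci(species), _num(n))
    kn_pow = _apply("power", _num(K), _num(n))
    denom = _apply("plus", kn_pow, cn_pow)
    num = kn_pow if inhibition else cn_pow
    return _apply("divide", num, denom)


def _term_math(term: RateTerm, ins_eff: float, gln_eff: float) -> ET.Element | None:
    k = term.kind
    if k in (TermKind.SUBSTRATE, TermKind.ACTIVATION):
        return _hill_math(term.species, term.K, term.n, False)
    if k == TermKind.INHIBITION:
        return _hill_math(term.species, term.K, term.n, True)
    if k == TermKind.LINEAR:
        return _apply("divide", _ci(term.species), _num(term.K))
    if k == TermKind.OXYGEN:
        return _hill_math("oxygen", term.K, term.n, False)
    # hormone factors: constant at the exported compartment's effective
    # hormone level
    c = ins_eff if k in (TermKind.INSULIN_ACT, TermKind.INSULIN_INH) else gln_eff
    inhib = k in (TermKind.INSULIN_INH, TermKind.GLUCAGON_INH)
    x = (c / term.K) ** term.n
    h = (1.0 / (1.0 + x)) if inhib else (x / (1.0 + x))
    return _num(term.base + term.amp * h)


def export_sbml(model: SinusoidModel, compartment_index: int = 0,
                path=None) -> str:
    """Serialise the kinetic core of one compartment as SBML L3.

    Returns the XML string (and writes it to ``path`` if given).
    """
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    n = model.n_compartments
    if not 0 <= compartment_index < n:
        raise ValueError(f"compartment index out of range 0..{n - 1}")
    i = compartment_index
    ref = model.params.reference_state
    phys = model.params.physiology

    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {
        "id": f"hepatocyte_compartment_{i + 1}",
        "name": f"Zonated hepatocyte kinetic core, compartment {i + 1} of {n}",
        "substanceUnits": "micromole", "timeUnits": "second",
        "volumeUnits": "litre", "extentUnits": "micromole"})
    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment", {
        "id": "hepatocyte", "spatialDimensions": "3",
        "size": repr(phys.compartment_hepatocyte_volume_l),
        "constant": "true"})
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment", {
        "id": "blood", "spatialDimensions": "3",
        "size": repr(phys.compartment_blood_volume_l), "constant": "true"})

    species_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for name in HEP_SPECIES:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": name, "compartment": "hepatocyte",
            "initialConcentration": repr(float(ref.get(name, 0.0))),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false"})
    for name in BLOOD_SPECIES:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": name, "compartment": "blood",
            "initialConcentration": repr(float(ref.get(name, 0.0))),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "true",
            "constant": "false"})

    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    ins = ref.get("insulin", 0.0) * model.insulin_reception[i]
    gln = ref.get("glucagon", 0.0) * model.glucagon_reception[i]
    for pname, proc in model.params.processes.items():
        m_i = model.zonation[pname].multipliers[i]
        for part in proc.parts:
            rid = part.name.replace("::", "_")
            rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", {
                "id": rid, "reversible": "false"})
            reac = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            prod = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp, coef in part.stoichiometry.items():
                parent = reac if coef < 0 else prod
                ET.SubElement(parent, f"{{{SBML_NS}}}speciesReference", {
                    "species": sp, "stoichiometry": repr(abs(float(coef))),
                    "constant": "true"})
            kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
            factors = [_num(part.vb * m_i)]
            for term in part.terms:
                f = _term_math(term, ins, gln)
                if f is not None:
                    factors.append(f)
            expr = factors[0] if len(factors) == 1 else _apply("times", *factors)
            kl.append(_math(expr))

    raw = ET.tostring(sbml, encoding="unicode")
    pretty = minidom.parseString(raw).toprettyxml(indent="  ")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(pretty)
    return pretty
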