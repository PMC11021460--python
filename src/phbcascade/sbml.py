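"""SBML Level 3 export/import of the cascade model.

The writer emits SBML L3v2 core: species carry the internal/boundary
role in ``boundaryCondition``, reactions carry exact stoichiometry and
reversibility, kinetic constants live in ``localParameter`` entries
(``vmax``, ``keq``, ``c_bind``, ``n_exp``, ``km_<species>``) with the
rate-law family named in a package annotation, and the
substrate-exhaustion stop event is an SBML ``event`` whose trigger is
written in MathML.  The reader accepts exactly what the writer emits
and rejects documents containing constructs outside that subset,
listing them, rather than guessing.
"""

from __future__ import annotations

from fractions import Fraction

from lxml import etree

from .kinetics import KineticParameters, ReactionParams, ScenarioSpec
from .network import Network, Reaction, Species

__all__ = ["export_sbml", "import_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:phbcascade:ratelaw"

_RATE_LAW_NAMES = {False: "irreversible_mm", True: "reversible_mm"}


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def export_sbml(
    network: Network,
    params: KineticParameters | None = None,
    scenario: ScenarioSpec | None = None,
) -> bytes:
    """Serialize network (+ optional kinetics and stop event) to SBML L3."""
    nsmap = {None: SBML_NS, "phb": ANNOT_NS, "math": MATHML_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, _q("model"), id=f"phbcascade_{network.variant}",
                             name=f"maltodextrin-PHB cascade ({network.variant})")
    comps = etree.SubElement(model, _q("listOfCompartments"))
    etree.SubElement(comps, _q("compartment"), id="pot", constant="true", size="1",
                     spatialDimensions="3")

    sp_list = etree.SubElement(model, _q("listOfSpecies"))
    initial = dict(scenario.initial) if scenario else {}
    for s in network.species:
        el = etree.SubElement(
            sp_list, _q("species"), id=_sid(s.id), name=s.name, compartment="pot",
            boundaryCondition="true" if s.role == "boundary" else "false",
            hasOnlySubstanceUnits="false", constant="false",
            initialConcentration=repr(float(initial.get(s.id, s.initial_conc))),
        )
        if s.composition:
            annot = etree.SubElement(el, _q("annotation"))
            comp = etree.SubElement(annot, _q("composition", ANNOT_NS))
            for elem, count in sorted(s.composition.items()):
                comp.set(elem, str(count))

    rx_list = etree.SubElement(model, _q("listOfReactions"))
    for r in network.reactions:
        el = etree.SubElement(rx_list, _q("reaction"), id=_sid(r.id), name=r.name,
                              reversible="true" if r.reversible else "false")
        reac = etree.SubElement(el, _q("listOfReactants"))
        prod = etree.SubElement(el, _q("listOfProducts"))
        for sid, c in sorted(r.stoich.items()):
            parent = reac if c < 0 else prod
            etree.SubElement(parent, _q("speciesReference"), species=_sid(sid),
                             stoichiometry=str(abs(float(c))), constant="true")
        if params is not None:
            p = params[r.id]
            kl = etree.SubElement(el, _q("kineticLaw"))
            annot = etree.SubElement(kl, _q("annotation"))
            law = "phac_binding_mm" if r.id == "PhaC" else _RATE_LAW_NAMES[r.reversible]
            etree.SubElement(annot, _q("rateLaw", ANNOT_NS)).set("type", law)
            lps = etree.SubElement(kl, _q("listOfLocalParameters"))

            def lp(pid: str, value: float) -> None:
                etree.SubElement(lps, _q("localParameter"), id=pid, value=repr(float(value)))

            lp("vmax", p.vmax)
            if p.keq is not None:
                lp("keq", p.keq)
            if p.c_bind is not None:
                lp("c_bind", p.c_bind)
            if p.n is not None:
                lp("n_exp", p.n)
            for sid, km in sorted(p.km.items()):
                lp(f"km_{_sid(sid)}", km)

    if scenario is not None:
        evs = etree.SubElement(model, _q("listOfEvents"))
        ev = etree.SubElement(evs, _q("event"), id="substrate_exhausted",
                              useValuesFromTriggerTime="true")
        trig = etree.SubElement(ev, _q("trigger"), initialValue="true", persistent="true")
        math = etree.SubElement(trig, _q("math", MATHML_NS))
        apply_ = etree.SubElement(math, _q("apply", MATHML_NS))
        etree.SubElement(apply_, _q("leq", MATHML_NS))
        etree.SubElement(apply_, _q("ci", MATHML_NS)).text = _sid("MD")
        cn = etree.SubElement(apply_, _q("cn", MATHML_NS))
        cn.text = repr(scenario.residual_fraction * float(scenario.initial.get("MD", 0.0)))
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def import_sbml(document: bytes | str):
    """Parse an SBML document written by :func:`export_sbml`.

    Returns ``(network, params_or_None, event_threshold_or_None)``.
    Raises ``ValueError`` listing any unsupported constructs.
    """
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    model = root.find(_q("model"))
    if model is None:
        raise ValueError("unsupported SBML: no <model>")
    supported = {
        _q(t) for t in ("listOfCompartments", "listOfSpecies", "listOfReactions",
                        "listOfEvents", "annotation", "notes")
    }
    unknown = sorted({c.tag for c in model if c.tag not in supported})
    if unknown:
        raise ValueError(f"unsupported SBML constructs: {unknown}")

    species = []
    initial = {}
    for el in model.findall(f"{_q('listOfSpecies')}/{_q('species')}"):
        comp: dict[str, int] = {}
        cel = el.find(f"{_q('annotation')}/{_q('composition', ANNOT_NS)}")
        if cel is not None:
            comp = {k: int(v) for k, v in cel.attrib.items()}
        sid = _unsid(el.get("id"))
        species.append(Species(
            id=sid, name=el.get("name", sid),
            role="boundary" if el.get("boundaryCondition") == "true" else "internal",
            composition=comp,
        ))
        initial[sid] = float(el.get("initialConcentration", "0"))

    reactions = []
    param_recs: dict[str, ReactionParams] = {}
    has_kinetics = False
    for el in model.findall(f"{_q('listOfReactions')}/{_q('reaction')}"):
        stoich: dict[str, Fraction] = {}
        for ref in el.findall(f"{_q('listOfReactants')}/{_q('speciesReference')}"):
            stoich[_unsid(ref.get("species"))] = -Fraction(ref.get("stoichiometry"))
        for ref in el.findall(f"{_q('listOfProducts')}/{_q('speciesReference')}"):
            stoich[_unsid(ref.get("species"))] = Fraction(ref.get("stoichiometry"))
        rid = _unsid(el.get("id"))
        reactions.append(Reaction(id=rid, name=el.get("name", rid), stoich=stoich,
                                  reversible=el.get("reversible") == "true"))
        kl = el.find(_q("kineticLaw"))
        if kl is not None:
            has_kinetics = True
            kw: dict = {"vmax": 0.0, "km": {}}
            for lp in kl.findall(f"{_q('listOfLocalParameters')}/{_q('localParameter')}"):
                pid, value = lp.get("id"), float(lp.get("value"))
                if pid == "vmax":
                    kw["vmax"] = value
                elif pid == "keq":
                    kw["keq"] = value
                elif pid == "c_bind":
                    kw["c_bind"] = value
                elif pid == "n_exp":
                    kw["n"] = value
                elif pid.startswith("km_"):
                    kw["km"][_unsid(pid[3:])] = value
                else:
                    raise ValueError(f"unsupported local parameter {pid!r}")
            param_recs[rid] = ReactionParams(**kw)

    threshold = None
    ev = model.find(f"{_q('listOfEvents')}/{_q('event')}")
    if ev is not None:
        cn = ev.find(f"{_q('trigger')}/{_q('math', MATHML_NS)}/{_q('apply', MATHML_NS)}/{_q('cn', MATHML_NS)}")
        if cn is None:
            raise ValueError("unsupported SBML event trigger")
        threshold = float(cn.text)

    net = Network(species=tuple(species), reactions=tuple(reactions),
                  variant=(model.get("id") or "custom").removeprefix("phbcascade_"))
    params = KineticParameters(param_recs) if has_kinetics else None
    return net, params, threshold


# SBML SIds must match [A-Za-z_][A-Za-z0-9_]*; "6PG" etc. need an escape.
def _sid(sid: str) -> str:
    return f"_{sid}" if sid[0].isdigit() else sid


def _unsid(sid: str) -> str:
    return sid[1:] if sid.startswith("_") and sid[1:2].isdigit() else sid
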