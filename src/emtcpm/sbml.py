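"""Minimal SBML reader for mass-action reaction networks.

Supported subset: species with initial concentrations, global and
reaction-local parameters, and reactions whose kinetic law is a pure product
of ``<ci>`` references (and optional ``<cn>`` constants) -- i.e. mass-action
rates written explicitly, such as ``k1 * phi * E * B``.  Rules, events,
function definitions and any other MathML constructs are rejected with an
explicit error naming the offending construct.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .errors import ModelFormatError, UnsupportedSBMLError

_UNSUPPORTED_LISTS = (
    "listOfRules", "listOfEvents", "listOfFunctionDefinitions",
    "listOfConstraints", "listOfInitialAssignments", "listOfCompartmentTypes",
)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(node, name):
    return [c for c in node if isinstance(c.tag, str) and _local(c.tag) == name]


def _find(node, name):
    hits = _children(node, name)
    return hits[0] if hits else None


def _parse_product_math(math):
    """Flatten a MathML product into a list of ci names / cn constants."""
    kids = [c for c in math if isinstance(c.tag, str)]
    if len(kids) != 1:
        raise UnsupportedSBMLError("kineticLaw math must contain one expression")
    node = kids[0]
    factors = []

    def walk(n):
        tag = _local(n.tag)
        if tag == "ci":
            factors.append(("ref", n.text.strip()))
        elif tag == "cn":
            factors.append(("const", float(n.text.strip())))
        elif tag == "apply":
            ops = [c for c in n if isinstance(c.tag, str)]
            if not ops or _local(ops[0].tag) != "times":
                op = _local(ops[0].tag) if ops else "empty apply"
                raise UnsupportedSBMLError(
                    f"unsupported MathML operator '{op}': only products of "
                    "ci/cn factors (mass action) are supported")
            for c in ops[1:]:
                walk(c)
        else:
            raise UnsupportedSBMLError(f"unsupported MathML element '{tag}'")

    walk(node)
    return factors


def parse_sbml(path):
    """Parse an SBML file into a plain description dict.

    Returns dict with keys ``species`` (list of (id, initial)), ``parameters``
    (list of (id, value)) and ``reactions`` (list of dicts with ``id``,
    ``reactants``/``products`` as (species, stoich) lists and ``factors``).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise ModelFormatError(f"{path} is not an SBML document "
                               f"(root element '{_local(root.tag)}')")
    model = _find(root, "model")
    if model is None:
        raise ModelFormatError("SBML document has no <model> element")
    for bad in _UNSUPPORTED_LISTS:
        if _find(model, bad) is not None:
            raise UnsupportedSBMLError(f"SBML construct '{bad}' is not supported")

    species = []
    los = _find(model, "listOfSpecies")
    if los is not None:
        for sp in _children(los, "species"):
            sid = sp.get("id")
            if sid is None:
                raise ModelFormatError("species without id")
            init = float(sp.get("initialConcentration",
                                 sp.get("initialAmount", 0.0)))
            species.append((sid, init))

    parameters = []
    lop = _find(model, "listOfParameters")
    if lop is not None:
        for pm in _children(lop, "parameter"):
            parameters.append((pm.get("id"), float(pm.get("value", 0.0))))

    reactions = []
    lor = _find(model, "listOfReactions")
    if lor is not None:
        for rx in _children(lor, "reaction"):
            rid = rx.get("id", f"r{len(reactions)}")

            def refs(list_name):
                lst = _find(rx, list_name)
                out = []
                if lst is not None:
                    for ref in _children(lst, "speciesReference"):
                        out.append((ref.get("species"),
                                    float(ref.get("stoichiometry", 1.0))))
                return out

            kl = _find(rx, "kineticLaw")
            if kl is None:
                raise UnsupportedSBMLError(
                    f"reaction '{rid}' has no kineticLaw (required)")
            local = []
            for list_name in ("listOfParameters", "listOfLocalParameters"):
                llp = _find(kl, list_name)
                if llp is not None:
                    for pm in list(llp):
                        if isinstance(pm.tag, str):
                            local.append((pm.get("id"), float(pm.get("value", 0.0))))
            math = _find(kl, "math")
            if math is None:
                raise UnsupportedSBMLError(f"reaction '{rid}' kineticLaw has no math")
            factors = _parse_product_math(math)
            reactions.append({
                "id": rid,
                "reactants": refs("listOfReactants"),
                "products": refs("listOfProducts"),
                "local_parameters": local,
                "factors": factors,
            })
    return {"species": species, "parameters": parameters, "reactions": reactions}
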