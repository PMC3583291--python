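"""SBML exchange for the aggregation models.

Exports a :class:`~plaquesim.model.ModelSpec` as an SBML Level 3 Version 2
document (species, parameters, reactions with explicit MathML kinetic laws,
and time-triggered events for interventions) and imports such documents back,
inferring each reaction's hazard kind from the structure of its kinetic law.
Level 2 documents are accepted on import.  Unrecognised rate laws are
rejected with an explicit error, never silently approximated.

Kinetic laws are written in substance units (items), so the MathML
expression evaluates to the stochastic hazard directly — there is no
concentration/amount ambiguity.

The writer/reader is a purpose-built subset implementation on ``lxml``; it
covers exactly the constructs these models use.
"""

from __future__ import annotations

from fractions import Fraction

import sympy
from lxml import etree

from .model import (
    HazardKind,
    ModelSpec,
    ParameterSet,
    Reaction,
    SpeciesState,
    TimedEvent,
)

__all__ = ["export_sbml", "import_sbml", "UnsupportedConstructError",
           "UnsupportedRateLawError"]

SBML_L3V2_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
ANNOT_NS = "https://plaquesim.readthedocs.io/schema"

_M = "{%s}" % MATHML_NS


class UnsupportedConstructError(ValueError):
    """The document uses an SBML construct outside the supported subset."""


class UnsupportedRateLawError(UnsupportedConstructError):
    """A kinetic law does not match any supported hazard kind."""


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _m(tag: str, *children, text: str | None = None, **attrs) -> etree._Element:
    el = etree.Element(_M + tag, **attrs)
    if text is not None:
        el.text = text
    for c in children:
        el.append(c)
    return el


def _cn(value: float) -> etree._Element:
    if float(value).is_integer():
        return _m("cn", text=str(int(value)), type="integer")
    return _m("cn", text=repr(float(value)))


def _ci(name: str) -> etree._Element:
    return _m("ci", text=f" {name} ")


def _kinetic_math(r: Reaction) -> etree._Element:
    k = _ci(r.rate_param)
    kind = r.kind
    if kind is HazardKind.ZEROTH_ORDER:
        expr = k
    elif kind is HazardKind.FIRST_ORDER:
        (s,) = r.reactants
        expr = _m("apply", _m("times"), k, _ci(s))
    elif kind is HazardKind.SECOND_ORDER_HOMODIMER:
        (s,) = r.reactants
        expr = _m(
            "apply",
            _m("times"),
            k,
            _ci(s),
            _m("apply", _m("minus"), _ci(s), _cn(1)),
            _m("cn", text="0.5"),
        )
    elif kind is HazardKind.SECOND_ORDER_HETERO:
        names = list(r.reactants)
        if len(names) == 1 and r.modifier:
            names.append(r.modifier)
        expr = _m("apply", _m("times"), k, _ci(names[0]), _ci(names[1]))
    elif kind is HazardKind.HILL_GROWTH:
        (s,) = r.reactants
        m, h = r.modifier, r.aux_param
        sq = lambda name: _m("apply", _m("power"), _ci(name), _cn(2))  # noqa: E731
        expr = _m(
            "apply",
            _m("times"),
            k,
            _ci(s),
            _m("apply", _m("divide"), sq(m),
               _m("apply", _m("plus"), sq(h), sq(m))),
        )
    elif kind is HazardKind.FIRST_ORDER_SCALED:
        (s,) = r.reactants
        expr = _m(
            "apply",
            _m("times"),
            k,
            _ci(s),
            _m("apply", _m("divide"), _ci(r.modifier), _ci(r.aux_param)),
        )
    else:  # pragma: no cover - exhaustive over HazardKind
        raise UnsupportedConstructError(f"hazard kind {kind}")
    return _m("math", expr)


def export_sbml(spec: ModelSpec) -> bytes:
    """Serialise ``spec`` as an SBML L3V2 document (UTF-8 bytes)."""
    S = "{%s}" % SBML_L3V2_NS
    nsmap = {None: SBML_L3V2_NS}
    root = etree.Element(S + "sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, S + "model", id=spec.name or "model")

    annot = etree.SubElement(model, S + "annotation")
    etree.SubElement(
        annot,
        "{%s}modelInfo" % ANNOT_NS,
        nsmap={"ps": ANNOT_NS},
        plaqueThreshold=str(spec.plaque_threshold),
        variant=spec.variant,
    )

    comps = etree.SubElement(model, S + "listOfCompartments")
    etree.SubElement(
        comps, S + "compartment", id="cell", constant="true", size="1",
        spatialDimensions="3",
    )

    event_params = {p for e in spec.events for p in e.parameter_assignments}
    event_species = {s for e in spec.events for s in e.species_assignments}

    sp_list = etree.SubElement(model, S + "listOfSpecies")
    for s in spec.species:
        etree.SubElement(
            sp_list,
            S + "species",
            id=s.name,
            compartment="cell",
            initialAmount=str(float(s.count)),
            hasOnlySubstanceUnits="true",
            boundaryCondition="true" if s.constant else "false",
            constant="true" if (s.constant and s.name not in event_species)
            else "false",
        )

    par_list = etree.SubElement(model, S + "listOfParameters")
    for name, value in spec.parameters.items():
        etree.SubElement(
            par_list,
            S + "parameter",
            id=name,
            value=repr(float(value)),
            constant="false" if name in event_params else "true",
        )

    rx_list = etree.SubElement(model, S + "listOfReactions")
    for r in spec.reactions:
        rx = etree.SubElement(rx_list, S + "reaction", id=r.id, reversible="false")
        if r.reactants:
            lo = etree.SubElement(rx, S + "listOfReactants")
            for sp, n in r.reactants.items():
                etree.SubElement(
                    lo, S + "speciesReference", species=sp,
                    stoichiometry=str(float(n)), constant="true",
                )
        if r.products:
            lo = etree.SubElement(rx, S + "listOfProducts")
            for sp, n in r.products.items():
                etree.SubElement(
                    lo, S + "speciesReference", species=sp,
                    stoichiometry=str(float(n)), constant="true",
                )
        modifiers = []
        if r.modifier and r.modifier not in r.reactants:
            modifiers.append(r.modifier)
        if modifiers:
            lo = etree.SubElement(rx, S + "listOfModifiers")
            for sp in modifiers:
                etree.SubElement(lo, S + "modifierSpeciesReference", species=sp)
        kl = etree.SubElement(rx, S + "kineticLaw")
        kl.append(_kinetic_math(r))

    if spec.events:
        ev_list = etree.SubElement(model, S + "listOfEvents")
        for i, e in enumerate(spec.events):
            ev = etree.SubElement(
                ev_list, S + "event", id=f"event{i}",
                useValuesFromTriggerTime="true",
            )
            trig = etree.SubElement(
                ev, S + "trigger", initialValue="true", persistent="true"
            )
            t_sym = _m("csymbol", text=" t ", encoding="text",
                       definitionURL=TIME_URL)
            trig.append(_m("math", _m("apply", _m("geq"), t_sym, _cn(e.time))))
            loa = etree.SubElement(ev, S + "listOfEventAssignments")
            for sp, v in e.species_assignments.items():
                ea = etree.SubElement(loa, S + "eventAssignment", variable=sp)
                ea.append(_m("math", _cn(float(v))))
            for p, v in e.parameter_assignments.items():
                ea = etree.SubElement(loa, S + "eventAssignment", variable=p)
                ea.append(_m("math", _cn(float(v))))

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _mathml_to_sympy(node: etree._Element) -> sympy.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise UnsupportedConstructError("math element must have one child")
        return _mathml_to_sympy(children[0])
    if tag == "ci":
        return sympy.Symbol(node.text.strip())
    if tag == "cn":
        cn_type = node.get("type", "real")
        if cn_type == "integer":
            return sympy.Integer(int(node.text.strip()))
        if cn_type in ("real", None):
            return sympy.Rational(Fraction(node.text.strip()))
        raise UnsupportedConstructError(f"cn type {cn_type!r}")
    if tag == "csymbol":
        if node.get("definitionURL") == TIME_URL:
            return sympy.Symbol("__time__")
        raise UnsupportedConstructError(f"csymbol {node.get('definitionURL')}")
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_sympy(c) for c in children[1:]]
        if op == "times":
            return sympy.Mul(*args)
        if op == "plus":
            return sympy.Add(*args)
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            return args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op in ("geq", "gt"):
            return sympy.GreaterThan(*args) if op == "geq" else sympy.StrictGreaterThan(*args)
        raise UnsupportedConstructError(f"MathML operator {op!r}")
    raise UnsupportedConstructError(f"MathML element {tag!r}")


def _equal(a: sympy.Expr, b: sympy.Expr) -> bool:
    return sympy.simplify(a - b) == 0


def _classify_rate_law(
    rid: str,
    expr: sympy.Expr,
    reactants: dict[str, int],
    modifiers: list[str],
    species: set[str],
    params: set[str],
    constant_species: set[str],
) -> tuple[HazardKind, str, str | None, str | None]:
    """Infer (kind, rate_param, modifier, aux_param) from a kinetic law."""
    syms = {str(s) for s in expr.free_symbols}
    p_syms = sorted(syms & params)
    dynamic_reactants = [s for s in reactants if s not in constant_species]

    def fail() -> UnsupportedRateLawError:
        return UnsupportedRateLawError(
            f"reaction {rid!r}: kinetic law {sympy.sstr(expr)} does not match "
            "any supported hazard form (mass action up to second order, "
            "Hill-saturating growth, or enzyme-scaled first order)"
        )

    if not dynamic_reactants:
        for p in p_syms:
            if _equal(expr, sympy.Symbol(p)):
                return HazardKind.ZEROTH_ORDER, p, None, None
        raise fail()

    s1 = dynamic_reactants[0]
    S = sympy.Symbol(s1)
    # homodimer: k * S * (S - 1) / 2
    if reactants.get(s1, 1) >= 2 or len(dynamic_reactants) == 1:
        for p in p_syms:
            if _equal(expr, sympy.Symbol(p) * S * (S - 1) / 2):
                return HazardKind.SECOND_ORDER_HOMODIMER, p, None, None
    if len(dynamic_reactants) == 2:
        a, b = dynamic_reactants
        for p in p_syms:
            if _equal(expr, sympy.Symbol(p) * sympy.Symbol(a) * sympy.Symbol(b)):
                return HazardKind.SECOND_ORDER_HETERO, p, None, None
        raise fail()
    for m in modifiers:
        M = sympy.Symbol(m)
        for p in p_syms:
            P = sympy.Symbol(p)
            for q in p_syms:
                if q == p:
                    continue
                Q = sympy.Symbol(q)
                if _equal(expr, P * S * M**2 / (Q**2 + M**2)):
                    return HazardKind.HILL_GROWTH, p, m, q
                if _equal(expr, P * S * M / Q):
                    return HazardKind.FIRST_ORDER_SCALED, p, m, q
            if _equal(expr, P * S * M):
                return HazardKind.SECOND_ORDER_HETERO, p, m, None
    for p in p_syms:
        if _equal(expr, sympy.Symbol(p) * S):
            return HazardKind.FIRST_ORDER, p, None, None
    raise fail()


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _find_all(parent: etree._Element | None, name: str) -> list[etree._Element]:
    if parent is None:
        return []
    return [c for c in parent.iter() if isinstance(c.tag, str)
            and _localname(c) == name]


def _find_one(parent: etree._Element, name: str) -> etree._Element | None:
    hits = [c for c in parent if isinstance(c.tag, str) and _localname(c) == name]
    return hits[0] if hits else None


def import_sbml(document: bytes | str) -> ModelSpec:
    """Parse an SBML document (Level 3, or Level 2) into a ModelSpec.

    The kinetic law of every reaction must match one of the supported hazard
    forms; anything else raises :class:`UnsupportedRateLawError`.
    """
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    if _localname(root) != "sbml":
        raise UnsupportedConstructError("not an SBML document")
    model = _find_one(root, "model")
    if model is None:
        raise UnsupportedConstructError("document has no model element")

    for bad in ("listOfRules", "listOfConstraints", "listOfFunctionDefinitions"):
        if _find_one(model, bad) is not None:
            raise UnsupportedConstructError(f"unsupported construct: {bad}")

    species: list[SpeciesState] = []
    constant_species: set[str] = set()
    for el in _find_all(_find_one(model, "listOfSpecies"), "species"):
        name = el.get("id")
        amount = float(el.get("initialAmount", "0") or 0)
        constant = el.get("boundaryCondition") == "true" or el.get("constant") == "true"
        if constant:
            constant_species.add(name)
        species.append(SpeciesState(name, int(round(amount)), constant=constant))

    params = ParameterSet()
    for el in _find_all(_find_one(model, "listOfParameters"), "parameter"):
        params[el.get("id")] = float(el.get("value", "0") or 0)

    species_names = {s.name for s in species}
    reactions: list[Reaction] = []
    for el in _find_all(_find_one(model, "listOfReactions"), "reaction"):
        rid = el.get("id")
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        for ref in _find_all(_find_one(el, "listOfReactants"), "speciesReference"):
            reactants[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
        for ref in _find_all(_find_one(el, "listOfProducts"), "speciesReference"):
            products[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
        modifiers = [
            ref.get("species")
            for ref in _find_all(
                _find_one(el, "listOfModifiers"), "modifierSpeciesReference"
            )
        ]
        kl = _find_one(el, "kineticLaw")
        if kl is None:
            raise UnsupportedConstructError(f"reaction {rid!r} has no kinetic law")
        local = _find_one(kl, "listOfLocalParameters") or _find_one(
            kl, "listOfParameters"
        )
        for lp in _find_all(local, "parameter") + _find_all(local, "localParameter"):
            params[lp.get("id")] = float(lp.get("value", "0") or 0)
        math_el = _find_one(kl, "math")
        expr = _mathml_to_sympy(math_el)
        kind, rate_param, modifier, aux = _classify_rate_law(
            rid, expr, reactants, modifiers, species_names, set(params),
            constant_species,
        )
        reactions.append(
            Reaction(
                id=rid,
                reactants=reactants,
                products=products,
                kind=kind,
                rate_param=rate_param,
                modifier=modifier,
                aux_param=aux,
            )
        )

    events: list[TimedEvent] = []
    for el in _find_all(_find_one(model, "listOfEvents"), "event"):
        trig = _find_one(el, "trigger")
        rel = _mathml_to_sympy(_find_one(trig, "math"))
        t_sym = sympy.Symbol("__time__")
        if not isinstance(rel, (sympy.GreaterThan, sympy.StrictGreaterThan)) or (
            rel.lhs != t_sym
        ):
            raise UnsupportedConstructError(
                f"event {el.get('id')!r}: only time-threshold triggers are supported"
            )
        t_trigger = float(rel.rhs)
        sp_assign: dict[str, int] = {}
        par_assign: dict[str, float] = {}
        for ea in _find_all(_find_one(el, "listOfEventAssignments"), "eventAssignment"):
            var = ea.get("variable")
            value = _mathml_to_sympy(_find_one(ea, "math"))
            if not value.is_number:
                raise UnsupportedConstructError(
                    f"event assignment to {var!r} is not a constant"
                )
            if var in species_names:
                sp_assign[var] = int(round(float(value)))
            elif var in params:
                par_assign[var] = float(value)
            else:
                raise UnsupportedConstructError(f"event assigns unknown id {var!r}")
        events.append(TimedEvent(t_trigger, sp_assign, par_assign))

    plaque_threshold = 30
    variant = ""
    for el in model.iter("{%s}modelInfo" % ANNOT_NS):
        plaque_threshold = int(el.get("plaqueThreshold", "30"))
        variant = el.get("variant", "")

    return ModelSpec(
        name=model.get("id") or "model",
        species=species,
        parameters=params,
        reactions=reactions,
        events=events,
        plaque_threshold=plaque_threshold,
        variant=variant,
    )
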