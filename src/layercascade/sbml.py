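"""SBML import and export (Level 2 / Level 3 core subset).

Supported on import: compartments (their ids become numeric parameters set to
their size), species with initial concentration or amount, global and
reaction-local parameters, function definitions (inlined), kinetic laws as
content MathML, and assignment rules whose right-hand side reduces to a pure
function of time -- these become :class:`~layercascade.network.InputSignal`
objects.  Everything else (events, algebraic rules, rate rules, delays,
state-dependent assignment rules, stoichiometry math) raises
:class:`~layercascade.errors.UnsupportedSBMLError` -- never a silent omission.

Species flagged ``boundaryCondition`` or ``constant`` keep their initial value
(their stoichiometric rows are dropped).  The ODE convention is the plain
stoichiometric form ``x' = S v``; models whose kinetic laws already include a
compartment volume factor are imported as written, with the compartment size
substituted as a constant.

Export writes Level 3 Version 2 core.  Only networks whose rate laws are
symbolic can be exported; piecewise-constant input schedules become
assignment rules with MathML piecewise over csymbol time.
"""

from __future__ import annotations

import math
from pathlib import Path

import sympy as sp
from lxml import etree

from .errors import SBMLValidationError, UnsupportedSBMLError
from .network import InputSignal, RateLaw, Reaction, ReactionNetwork

__all__ = ["import_sbml", "export_sbml"]

_TIME_URLS = ("symbols/time",)
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _local(el) -> str:
    return etree.QName(el).localname


def _children(el):
    return [c for c in el if isinstance(c.tag, str)]


# ---------------------------------------------------------------------------
# content MathML -> sympy
# ---------------------------------------------------------------------------

_NARY = {
    "plus": lambda args: sp.Add(*args) if args else sp.Integer(0),
    "times": lambda args: sp.Mul(*args) if args else sp.Integer(1),
}
_UNARY = {
    "exp": sp.exp,
    "ln": sp.log,
    "abs": sp.Abs,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "sinh": sp.sinh,
    "cosh": sp.cosh,
    "tanh": sp.tanh,
    "arcsin": sp.asin,
    "arccos": sp.acos,
    "arctan": sp.atan,
}
_RELATIONS = {
    "lt": sp.StrictLessThan,
    "leq": sp.LessThan,
    "gt": sp.StrictGreaterThan,
    "geq": sp.GreaterThan,
    "eq": sp.Eq,
    "neq": sp.Ne,
}


def _parse_cn(el) -> sp.Expr:
    typ = el.get("type", "real")
    if typ in ("real", "integer", "double"):
        text = (el.text or "").strip()
        return sp.Integer(int(text)) if typ == "integer" else sp.Float(float(text))
    if typ == "e-notation":
        parts = [t.strip() for t in el.itertext() if t.strip()]
        if len(parts) != 2:
            raise SBMLValidationError("malformed e-notation <cn>")
        return sp.Float(float(parts[0]) * 10 ** float(parts[1]))
    if typ == "rational":
        parts = [t.strip() for t in el.itertext() if t.strip()]
        return sp.Rational(int(parts[0]), int(parts[1]))
    raise UnsupportedSBMLError(f"<cn> type {typ!r} not supported")


def _mathml_to_sympy(el, fundefs: dict) -> sp.Expr:
    tag = _local(el)
    if tag == "math":
        kids = _children(el)
        if len(kids) != 1:
            raise SBMLValidationError("<math> must have exactly one child")
        return _mathml_to_sympy(kids[0], fundefs)
    if tag == "cn":
        return _parse_cn(el)
    if tag == "ci":
        return sp.Symbol((el.text or "").strip())
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        if any(u in url for u in _TIME_URLS):
            return sp.Symbol("t")
        raise UnsupportedSBMLError(f"csymbol {url!r} (e.g. delay) not supported")
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    if tag in ("true", "false"):
        return sp.true if tag == "true" else sp.false
    if tag == "piecewise":
        pieces = []
        for part in _children(el):
            kids = _children(part)
            if _local(part) == "piece":
                val, cond = (_mathml_to_sympy(k, fundefs) for k in kids)
                pieces.append((val, cond))
            elif _local(part) == "otherwise":
                pieces.append((_mathml_to_sympy(kids[0], fundefs), True))
        return sp.Piecewise(*pieces)
    if tag == "lambda":
        bvars = []
        body = None
        for kid in _children(el):
            if _local(kid) == "bvar":
                bvars.append(_mathml_to_sympy(_children(kid)[0], fundefs))
            else:
                body = _mathml_to_sympy(kid, fundefs)
        return sp.Lambda(tuple(bvars), body)
    if tag == "apply":
        kids = _children(el)
        op, args_el = kids[0], kids[1:]
        opname = _local(op)
        args = None
        if opname not in ("ci",):
            args = [_mathml_to_sympy(a, fundefs) for a in args_el]
        if opname in _NARY:
            return _NARY[opname](args)
        if opname == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if opname == "divide":
            return args[0] / args[1]
        if opname == "power":
            return args[0] ** args[1]
        if opname == "root":
            degree = 2
            return args[0] ** sp.Rational(1, degree)
        if opname == "log":
            base = 10
            return sp.log(args[0], base)
        if opname in _UNARY:
            return _UNARY[opname](args[0])
        if opname in _RELATIONS:
            return _RELATIONS[opname](args[0], args[1])
        if opname == "and":
            return sp.And(*args)
        if opname == "or":
            return sp.Or(*args)
        if opname == "not":
            return sp.Not(args[0])
        if opname == "ci":
            fname = (op.text or "").strip()
            if fname not in fundefs:
                raise UnsupportedSBMLError(f"call of unknown function {fname!r}")
            args = [_mathml_to_sympy(a, fundefs) for a in args_el]
            return fundefs[fname](*args)
        raise UnsupportedSBMLError(f"MathML operator <{opname}> not supported")
    raise UnsupportedSBMLError(f"MathML element <{tag}> not supported")


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------


def _find(parent, name):
    if parent is None:
        return None
    for el in parent:
        if isinstance(el.tag, str) and _local(el) == name:
            return el
    return None


def _findall(parent, name):
    if parent is None:
        return []
    return [el for el in parent if isinstance(el.tag, str) and _local(el) == name]


def import_sbml(path) -> ReactionNetwork:
    """Read an SBML file into a :class:`ReactionNetwork`."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root) != "sbml":
        raise SBMLValidationError("not an SBML document")
    model = _find(root, "model")
    if model is None:
        raise SBMLValidationError("SBML document has no <model>")

    for unsupported in ("listOfEvents", "listOfConstraints"):
        if _find(model, unsupported) is not None:
            raise UnsupportedSBMLError(f"{unsupported} is not supported")

    # function definitions (inlined into every expression via sympy Lambda)
    fundefs: dict[str, sp.Lambda] = {}
    for fd in _findall(_find(model, "listOfFunctionDefinitions"), "functionDefinition"):
        m = _find(fd, "math")
        lam = _mathml_to_sympy(m, fundefs)
        if not isinstance(lam, sp.Lambda):
            raise SBMLValidationError("functionDefinition math must be a lambda")
        fundefs[fd.get("id")] = lam

    # constants: compartments and parameters
    consts: dict[sp.Symbol, sp.Expr] = {}
    for comp in _findall(_find(model, "listOfCompartments"), "compartment"):
        size = comp.get("size", comp.get("volume", "1"))
        consts[sp.Symbol(comp.get("id"))] = sp.Float(float(size))
    for par in _findall(_find(model, "listOfParameters"), "parameter"):
        val = par.get("value")
        if val is not None:
            consts[sp.Symbol(par.get("id"))] = sp.Float(float(val))

    # species
    species, x0, dynamic = [], [], []
    for spc in _findall(_find(model, "listOfSpecies"), "species"):
        sid = spc.get("id")
        conc = spc.get("initialConcentration", spc.get("initialAmount"))
        if conc is None:
            raise SBMLValidationError(f"species {sid!r} has no initial value")
        fixed = spc.get("boundaryCondition") == "true" or spc.get("constant") == "true"
        species.append(sid)
        x0.append(float(conc))
        dynamic.append(not fixed)

    # rules
    inputs: list[InputSignal] = []
    input_names: set[str] = set()
    rules = _find(model, "listOfRules")
    for rule in _children(rules) if rules is not None else []:
        kind = _local(rule)
        if kind != "assignmentRule":
            raise UnsupportedSBMLError(f"{kind} is not supported")
        var = rule.get("variable")
        expr = _mathml_to_sympy(_find(rule, "math"), fundefs).xreplace(consts)
        free = {str(s) for s in expr.free_symbols}
        if free <= {"t"}:
            inputs.append(InputSignal(var, expr=expr))
            input_names.add(var)
            consts.pop(sp.Symbol(var), None)
        else:
            raise UnsupportedSBMLError(
                f"assignment rule for {var!r} depends on {sorted(free - {'t'})}; "
                "only pure functions of time are supported"
            )

    # reactions
    reactions = []
    for rx in _findall(_find(model, "listOfReactions"), "reaction"):
        rid = rx.get("id")
        stoich: dict[str, float] = {}
        for ref in _findall(_find(rx, "listOfReactants"), "speciesReference"):
            if _find(ref, "stoichiometryMath") is not None:
                raise UnsupportedSBMLError("stoichiometryMath is not supported")
            s = ref.get("species")
            if dynamic[species.index(s)]:
                stoich[s] = stoich.get(s, 0.0) - float(ref.get("stoichiometry", 1))
        for ref in _findall(_find(rx, "listOfProducts"), "speciesReference"):
            s = ref.get("species")
            if dynamic[species.index(s)]:
                stoich[s] = stoich.get(s, 0.0) + float(ref.get("stoichiometry", 1))
        stoich = {s: c for s, c in stoich.items() if c != 0.0}
        kl = _find(rx, "kineticLaw")
        if kl is None:
            raise SBMLValidationError(f"reaction {rid!r} has no kinetic law")
        local: dict[sp.Symbol, sp.Expr] = {}
        for lp_list in ("listOfParameters", "listOfLocalParameters"):
            for par in _findall(_find(kl, lp_list), "parameter") + _findall(
                _find(kl, lp_list), "localParameter"
            ):
                local[sp.Symbol(par.get("id"))] = sp.Float(float(par.get("value")))
        expr = _mathml_to_sympy(_find(kl, "math"), fundefs)
        expr = expr.xreplace(local).xreplace(consts)
        # boundary species are constants: substitute their initial value
        for i, sid in enumerate(species):
            if not dynamic[i]:
                expr = expr.xreplace({sp.Symbol(sid): sp.Float(x0[i])})
        unknown = (
            {str(s) for s in expr.free_symbols}
            - set(species)
            - input_names
            - {"t"}
        )
        if unknown:
            raise SBMLValidationError(
                f"kinetic law of {rid!r} has unresolved symbols {sorted(unknown)}"
            )
        reactions.append(
            Reaction(rid, stoich, RateLaw(expr=expr), reversible=rx.get("reversible") == "true")
        )

    return ReactionNetwork(
        species=species,
        x0=x0,
        reactions=reactions,
        inputs=inputs,
        name=model.get("id", model.get("name", "sbml_model")),
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_TIME_URL = "http://www.sbml.org/sbml/symbols/time"


def _sym_to_mathml(expr: sp.Expr, time_symbol: str = "t") -> etree._Element:
    """Content-MathML element for a sympy expression."""

    def M(tag, *kids, text=None, **attrs):
        el = etree.SubElement(parent_stack[-1], f"{{{_MATHML_NS}}}{tag}", **attrs)
        if text is not None:
            el.text = text
        parent_stack.append(el)
        for k in kids:
            emit(k)
        parent_stack.pop()
        return el

    def emit(e):
        if isinstance(e, sp.Symbol):
            if str(e) == time_symbol:
                M("csymbol", text="t", definitionURL=_TIME_URL, encoding="text")
            else:
                M("ci", text=str(e))
        elif isinstance(e, (sp.Integer, int)):
            M("cn", text=str(int(e)), type="integer")
        elif isinstance(e, sp.Rational) and not isinstance(e, sp.Integer):
            M("cn", text=str(float(e)))
        elif isinstance(e, (sp.Float, float)):
            M("cn", text=repr(float(e)))
        elif isinstance(e, sp.Add):
            M("apply", *(["plus_op"] + list(e.args)))
        elif isinstance(e, sp.Mul):
            M("apply", *(["times_op"] + list(e.args)))
        elif isinstance(e, sp.Pow):
            M("apply", "power_op", e.base, e.exp)
        elif isinstance(e, sp.exp):
            M("apply", "exp_op", e.args[0])
        elif isinstance(e, sp.log):
            M("apply", "ln_op", e.args[0])
        elif isinstance(e, sp.Piecewise):
            el = etree.SubElement(parent_stack[-1], f"{{{_MATHML_NS}}}piecewise")
            parent_stack.append(el)
            for val, cond in e.args:
                if cond is sp.true:
                    part = etree.SubElement(el, f"{{{_MATHML_NS}}}otherwise")
                    parent_stack.append(part)
                    emit(val)
                    parent_stack.pop()
                else:
                    part = etree.SubElement(el, f"{{{_MATHML_NS}}}piece")
                    parent_stack.append(part)
                    emit(val)
                    emit(cond)
                    parent_stack.pop()
            parent_stack.pop()
        elif isinstance(e, sp.And):
            M("apply", *(["and_op"] + list(e.args)))
        elif isinstance(e, sp.Or):
            M("apply", *(["or_op"] + list(e.args)))
        elif isinstance(e, (sp.StrictLessThan, sp.LessThan, sp.StrictGreaterThan, sp.GreaterThan)):
            op = {
                sp.StrictLessThan: "lt",
                sp.LessThan: "leq",
                sp.StrictGreaterThan: "gt",
                sp.GreaterThan: "geq",
            }[type(e)]
            M("apply", f"{op}_op", e.lhs, e.rhs)
        elif isinstance(e, str) and e.endswith("_op"):
            etree.SubElement(parent_stack[-1], f"{{{_MATHML_NS}}}{e[:-3]}")
        else:
            raise UnsupportedSBMLError(f"cannot export expression node {e!r} to MathML")

    holder = etree.Element(f"{{{_MATHML_NS}}}math")
    parent_stack = [holder]
    emit(sp.sympify(expr))
    return holder


def export_sbml(network: ReactionNetwork, path) -> None:
    """Write a network with symbolic rate laws as SBML Level 3 Version 2."""
    for r in network.reactions:
        if not r.rate.symbolic:
            raise UnsupportedSBMLError(
                f"reaction {r.id!r} has an opaque callable rate law; "
                "only symbolic rate laws can be exported"
            )
    nsmap = {None: _SBML_NS}
    root = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, f"{{{_SBML_NS}}}model", id=network.name or "model")
    comps = etree.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    etree.SubElement(
        comps, f"{{{_SBML_NS}}}compartment", id="cell", size="1", constant="true"
    )
    spl = etree.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for sid, c0 in zip(network.species, network.x0):
        etree.SubElement(
            spl,
            f"{{{_SBML_NS}}}species",
            id=sid,
            compartment="cell",
            initialConcentration=repr(float(c0)),
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )
    if network.inputs:
        pl = etree.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
        rl = etree.SubElement(model, f"{{{_SBML_NS}}}listOfRules")
        for name, sig in network.inputs.items():
            etree.SubElement(
                pl, f"{{{_SBML_NS}}}parameter", id=name, value="0", constant="false"
            )
            rule = etree.SubElement(
                rl, f"{{{_SBML_NS}}}assignmentRule", variable=name
            )
            rule.append(_sym_to_mathml(_signal_expr(sig)))
    rxl = etree.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rx = etree.SubElement(
            rxl,
            f"{{{_SBML_NS}}}reaction",
            id=r.id,
            reversible="true" if r.reversible else "false",
        )
        reactants = {s: -c for s, c in r.stoich.items() if c < 0}
        products = {s: c for s, c in r.stoich.items() if c > 0}
        for tag, side in (("listOfReactants", reactants), ("listOfProducts", products)):
            if not side:
                continue
            lst = etree.SubElement(rx, f"{{{_SBML_NS}}}{tag}")
            for s, c in side.items():
                etree.SubElement(
                    lst,
                    f"{{{_SBML_NS}}}speciesReference",
                    species=s,
                    stoichiometry=repr(float(c)),
                    constant="true",
                )
        kl = etree.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        kl.append(_sym_to_mathml(r.rate.expr))
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def _signal_expr(sig: InputSignal) -> sp.Expr:
    t = sp.Symbol("t")
    if sig.expr is not None:
        return sig.expr
    if sig.schedule is None:
        raise UnsupportedSBMLError(
            f"input {sig.name!r} is an opaque callable; cannot export"
        )
    pieces = []
    for t0, t1, val in sig.schedule:
        if math.isinf(t1):
            pieces.append((sp.Float(val), sp.true))
        else:
            pieces.append((sp.Float(val), sp.And(t >= t0, t < t1)))
    return sp.Piecewise(*pieces)
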