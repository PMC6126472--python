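"""Read and write metabolic networks: tabular TSV dialect and SBML L3+fbc.

The tabular dialect is UTF-8, tab-separated, with a ``[metabolites]`` section
(id, name, compartment, formula) and a ``[reactions]`` section (id, name,
equation, lower_bound, upper_bound, category, subsystem).  Equations use
compartment-tagged metabolite ids with ``<=>`` (reversible) or ``-->``
(irreversible) arrows, e.g. ``1 ac_e <=>`` for an exchange or
``accoa_c + 2 atp_c --> cit_c``.

SBML is Level 3 Version 1 with the fbc package carrying flux bounds and the
biomass objective; the SBML compartment attribute takes precedence over the
id suffix when the two disagree.
"""

from __future__ import annotations

import re
from pathlib import Path

import libsbml

from .network import (
    COMPARTMENTS,
    DEFAULT_BOUND,
    MetabolicNetwork,
    Metabolite,
    NetworkValidationError,
    Reaction,
)

__all__ = ["load_network", "write_network", "FormatError"]


class FormatError(ValueError):
    """A file could not be parsed in the declared format."""


def load_network(path: str | Path, format: str = "tabular") -> MetabolicNetwork:
    """Load and validate a network from ``path`` in the given format
    (``"tabular"`` or ``"sbml"``); reaction categories are inferred when
    absent."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        net = _read_tabular(path)
    elif format == "sbml":
        net = _read_sbml(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    net.infer_categories()
    net.validate()
    return net


def write_network(network: MetabolicNetwork, path: str | Path, format: str = "tabular") -> Path:
    """Write a validated network so that a reload reproduces it up to ordering."""
    network.infer_categories()
    network.validate()
    path = Path(path)
    if format == "tabular":
        _write_tabular(network, path)
    elif format == "sbml":
        _write_sbml(network, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->")


def parse_equation(eq: str, line_no: int | None = None) -> tuple[dict[str, float], bool]:
    """Parse ``"a A_c + b B_c <=> c C_c"`` into (stoichiometry, reversible)."""
    where = f" (line {line_no})" if line_no is not None else ""
    arrow = next((a for a in _ARROWS if a in eq), None)
    if arrow is None:
        raise FormatError(f"equation {eq!r} has no '<=>' or '-->' arrow{where}")
    lhs, rhs = eq.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise FormatError(f"dangling '+' in equation {eq!r}{where}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise FormatError(
                        f"bad coefficient {parts[0]!r} in equation {eq!r}{where}"
                    ) from exc
                met = parts[1]
            else:
                raise FormatError(f"cannot parse term {term!r} in equation {eq!r}{where}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise FormatError(f"equation {eq!r} has empty stoichiometry{where}")
    return stoich, arrow == "<=>"


def format_equation(rxn: Reaction) -> str:
    def side(items: dict[str, float]) -> str:
        return " + ".join(
            met if coeff == 1 else f"{coeff:.10g} {met}"
            for met, coeff in sorted(items.items())
        )

    arrow = "<=>" if rxn.reversible else "-->"
    return f"{side(rxn.reactants)} {arrow} {side(rxn.products)}".strip()


def _read_tabular(path: Path) -> MetabolicNetwork:
    objective_id: str | None = None
    default_bound = DEFAULT_BOUND
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    section = None
    header: list[str] = []

    for line_no, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*objective:\s*(\S+)", line)
            if m:
                objective_id = m.group(1)
            m = re.match(r"#\s*default_bound:\s*(\S+)", line)
            if m:
                default_bound = float(m.group(1))
            continue
        if line.startswith("["):
            section = line.strip().strip("[]").lower()
            header = []
            continue
        cells = line.split("\t")
        if not header:
            header = [c.strip() for c in cells]
            continue
        row = dict(zip(header, cells))
        if section == "metabolites":
            try:
                metabolites.append(
                    Metabolite(
                        id=row["id"],
                        name=row.get("name", "") or "",
                        compartment=row.get("compartment", "") or "",
                        formula=row.get("formula") or None,
                    )
                )
            except (KeyError, NetworkValidationError) as exc:
                raise FormatError(f"bad metabolite row at line {line_no}: {exc}") from exc
        elif section == "reactions":
            try:
                stoich, reversible = parse_equation(row["equation"], line_no)
                lb = float(row["lower_bound"]) if row.get("lower_bound", "") != "" else (
                    -default_bound if reversible else 0.0
                )
                ub = float(row["upper_bound"]) if row.get("upper_bound", "") != "" else default_bound
                reactions.append(
                    Reaction(
                        id=row["id"],
                        name=row.get("name", "") or "",
                        stoichiometry=stoich,
                        lower_bound=lb,
                        upper_bound=ub,
                        category=(row.get("category") or None),
                        subsystem=(row.get("subsystem") or None),
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"bad reaction row at line {line_no}: {exc}") from exc
        else:
            raise FormatError(f"data outside a [metabolites]/[reactions] section at line {line_no}")

    if not metabolites:
        # metabolite section optional: declare from equations
        seen: dict[str, Metabolite] = {}
        for rxn in reactions:
            for met in rxn.stoichiometry:
                if met not in seen:
                    seen[met] = Metabolite(id=met)
        metabolites = list(seen.values())

    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        default_bound=default_bound,
        id=path.stem,
    )


def _write_tabular(network: MetabolicNetwork, path: Path) -> None:
    lines = ["# chlamydyn tabular network v1"]
    if network.objective_id:
        lines.append(f"# objective: {network.objective_id}")
    lines.append(f"# default_bound: {network.default_bound:.10g}")
    lines.append("[metabolites]")
    lines.append("id\tname\tcompartment\tformula")
    for met in network.metabolites:
        lines.append(f"{met.id}\t{met.name}\t{met.compartment}\t{met.formula or ''}")
    lines.append("[reactions]")
    lines.append("id\tname\tequation\tlower_bound\tupper_bound\tcategory\tsubsystem")
    for rxn in network.reactions:
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(rxn),
                    f"{rxn.lower_bound:.10g}",
                    f"{rxn.upper_bound:.10g}",
                    rxn.category or "",
                    rxn.subsystem or "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# SBML L3V1 + fbc
# ---------------------------------------------------------------------------

def _sbml_id(raw: str) -> str:
    """SBML SIds must match [A-Za-z_][A-Za-z0-9_]*; escape everything else."""
    out = re.sub(r"[^A-Za-z0-9_]", lambda m: f"__{ord(m.group(0)):x}__", raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _un_sbml_id(sid: str) -> str:
    out = re.sub(r"__([0-9a-f]+)__", lambda m: chr(int(m.group(1), 16)), sid)
    if out.startswith("_") and not sid.startswith("__"):
        # leading underscore added by _sbml_id for ids starting with a digit
        if len(out) > 1 and out[1].isdigit():
            out = out[1:]
    return out


def _read_sbml(path: Path) -> MetabolicNetwork:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise FormatError(f"{path} contains no SBML model")

    comp_name = {}
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        name = comp.getName() or comp.getId()
        comp_name[comp.getId()] = name if name in COMPARTMENTS else None

    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        met_id = _un_sbml_id(sp.getId())
        compartment = comp_name.get(sp.getCompartment())
        if compartment is None:
            raise NetworkValidationError(
                f"species {met_id!r}: unknown compartment {sp.getCompartment()!r}"
            )
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        metabolites.append(
            Metabolite(id=met_id, name=sp.getName() or "", compartment=compartment,
                       formula=formula)
        )

    fbc_model = model.getPlugin("fbc")
    objective_id = None
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = _un_sbml_id(obj.getFluxObjective(0).getReaction())

    def param_value(pid: str, fallback: float) -> float:
        p = model.getParameter(pid)
        return p.getValue() if p is not None else fallback

    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            met = _un_sbml_id(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            met = _un_sbml_id(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        fbc_rxn = rxn.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if fbc_rxn is not None:
            if fbc_rxn.isSetLowerFluxBound():
                lb = param_value(fbc_rxn.getLowerFluxBound(), lb)
            if fbc_rxn.isSetUpperFluxBound():
                ub = param_value(fbc_rxn.getUpperFluxBound(), ub)
        category = None
        notes = rxn.getNotesString() if rxn.isSetNotes() else ""
        m = re.search(r"category:\s*(\w+)", notes)
        if m:
            category = m.group(1)
        subsystem = None
        m = re.search(r"subsystem:\s*([^<\n]+)", notes)
        if m:
            subsystem = m.group(1).strip() or None
        reactions.append(
            Reaction(
                id=_un_sbml_id(rxn.getId()),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                category=category,
                subsystem=subsystem,
            )
        )

    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        id=_un_sbml_id(model.getId()) or path.stem,
    )


def _check(code: int, what: str) -> None:
    if code not in (libsbml.LIBSBML_OPERATION_SUCCESS, None):
        raise RuntimeError(f"libsbml call failed ({what}): code {code}")


def _write_sbml(network: MetabolicNetwork, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_sbml_id(network.id))
    fbc_model = model.getPlugin("fbc")
    fbc_model.setStrict(False)

    used_comps = sorted({m.compartment for m in network.metabolites})
    for comp in used_comps:
        c = model.createCompartment()
        c.setId(COMPARTMENTS[comp])
        c.setName(comp)
        c.setConstant(True)

    for met in network.metabolites:
        sp = model.createSpecies()
        sp.setId(_sbml_id(met.id))
        sp.setName(met.name)
        sp.setCompartment(COMPARTMENTS[met.compartment])
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in network.reactions:
        r = model.createReaction()
        r.setId(_sbml_id(rxn.id))
        r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for met, coeff in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(_sbml_id(met))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        fbc_rxn = r.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_param(rxn.upper_bound))
        notes = f"<p>category: {rxn.category}</p>"
        if rxn.subsystem:
            notes += f"<p>subsystem: {rxn.subsystem}</p>"
        _check(
            r.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{notes}</body>'
            ),
            f"notes for {rxn.id}",
        )

    if network.objective_id:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_id(network.objective_id))
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")
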