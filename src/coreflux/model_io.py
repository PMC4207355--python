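"""Reading and writing metabolic models: SBML Level 3 + FBC, and a tabular
two-file TSV format for fixtures and spreadsheets.

The SBML path goes through python-libsbml and follows the community id
conventions (``M_``/``R_``/``G_`` prefixes, FBC flux-bound parameters,
FBC gene-product associations, an FBC objective for the biomass reaction).
The tabular format is a directory holding ``reactions.tsv`` (reaction_id,
name, equation, lower, upper, gpr, objective) and ``metabolites.tsv``
(id, name, compartment, formula, charge).
"""

from __future__ import annotations

import os
import re
from typing import Mapping, Optional

import libsbml
import pandas as pd

from .balance import check_balance, rebalance  # noqa: F401  (module surface)
from .gpr import GPRExpr, parse_gpr
from .network import (
    DEFAULT_BOUND,
    MetabolicNetwork,
    MetaboliteRecord,
    NetworkValidationError,
    ReactionRecord,
)

__all__ = [
    "read_model",
    "write_model",
    "ModelParseError",
    "formula_to_dict",
    "dict_to_formula",
    "parse_equation",
    "format_equation",
]


class ModelParseError(ValueError):
    """Malformed model file; the message names the offending entity."""


# ---------------------------------------------------------------------------
# Formula strings
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_to_dict(text: str) -> dict[str, int]:
    """Parse ``C6H12O6`` into ``{"C": 6, "H": 12, "O": 6}``."""
    if not text:
        return {}
    out: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ModelParseError(f"bad formula {text!r} at offset {pos}")
        element, count = match.group(1), match.group(2)
        out[element] = out.get(element, 0) + (int(count) if count else 1)
        pos = match.end()
    if pos != len(text):
        raise ModelParseError(f"bad formula {text!r} at offset {pos}")
    return out


def dict_to_formula(formula: Mapping[str, int]) -> str:
    """Render a formula map in Hill order (C, H, then alphabetical)."""
    def key(sym: str) -> tuple[int, str]:
        return {"C": (0, ""), "H": (1, "")}.get(sym, (2, sym))

    parts = []
    for sym in sorted(formula, key=key):
        n = formula[sym]
        if n == 0:
            continue
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Reaction equation strings (tabular format)
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into a stoichiometry map and a reversibility flag.

    ``<=>``/``<->`` mark reversible reactions.  Either side may be empty
    (exchange reactions are written ``"A ->"`` or ``"-> A"``).
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ModelParseError(f"equation {text!r} has no arrow")
    left, right = text.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelParseError(f"empty term in equation {text!r}")
            bits = term.split()
            if len(bits) == 1:
                coeff, met = 1.0, bits[0]
            elif len(bits) == 2:
                try:
                    coeff = float(bits[0])
                except ValueError as exc:
                    raise ModelParseError(f"bad coefficient in term {term!r}") from exc
                met = bits[1]
            else:
                raise ModelParseError(f"bad term {term!r} in equation {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelParseError(f"equation {text!r} has no net stoichiometry")
    return stoich, reversible


def format_equation(stoichiometry: Mapping[str, float], reversible: bool) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for met, coeff in items:
            coeff = abs(coeff)
            parts.append(met if coeff == 1 else f"{coeff:g} {met}")
        return " + ".join(parts)

    consumed = sorted((m, c) for m, c in stoichiometry.items() if c < 0)
    produced = sorted((m, c) for m, c in stoichiometry.items() if c > 0)
    arrow = "<=>" if reversible else "->"
    return f"{side(consumed)} {arrow} {side(produced)}".strip()


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def read_model(
    path: str,
    format: Optional[str] = None,
    default_bound: float = DEFAULT_BOUND,
) -> MetabolicNetwork:
    """Load a metabolic model from SBML (L3+FBC) or the tabular TSV format.

    ``format`` is ``"sbml"`` or ``"tabular"``; when omitted it is inferred
    from the path (directories and ``.tsv`` files are tabular, anything
    else SBML).  Reactions without explicit bounds get the default bound
    magnitude (±``default_bound`` if reversible, else [0, ``default_bound``]).
    """
    if format is None:
        format = "tabular" if os.path.isdir(path) or path.endswith(".tsv") else "sbml"
    if format == "sbml":
        return _read_sbml(path, default_bound)
    if format == "tabular":
        return _read_tabular(path, default_bound)
    raise ValueError(f"unknown model format {format!r}")


def write_model(network: MetabolicNetwork, path: str, format: Optional[str] = None) -> None:
    """Write a model so that :func:`read_model` round-trips it losslessly."""
    if format is None:
        format = "tabular" if os.path.isdir(path) or path.endswith(".tsv") else "sbml"
    if format == "sbml":
        _write_sbml(network, path)
    elif format == "tabular":
        _write_tabular(network, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: str, default_bound: float) -> MetabolicNetwork:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error: {first.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ModelParseError("document contains no SBML model")
    if model.getNumSpecies() == 0 or model.getNumReactions() == 0:
        raise NetworkValidationError("empty model: no species or no reactions")

    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = formula_to_dict(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        metabolites.append(
            MetaboliteRecord(
                id=_strip("M_", sp.getId()),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
                charge=charge,
            )
        )

    fbc_model = model.getPlugin("fbc")
    gene_labels: dict[str, str] = {}
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip("G_", gp.getId())

    reactions = []
    seen: set[str] = set()
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = _strip("R_", rxn.getId())
        if rid in seen:
            raise NetworkValidationError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        if not stoich:
            raise ModelParseError(f"reaction {rid!r} has no participants")

        lower = -default_bound if rxn.getReversible() else 0.0
        upper = default_bound
        fbc_rxn = rxn.getPlugin("fbc")
        gpr = None
        if fbc_rxn is not None:
            lower = _bound_value(model, fbc_rxn.getLowerFluxBound(), lower)
            upper = _bound_value(model, fbc_rxn.getUpperFluxBound(), upper)
            gpa = fbc_rxn.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                infix = gpa.getAssociation().toInfix(True)
                for gp_id, label in gene_labels.items():
                    infix = re.sub(rf"\b{re.escape(gp_id)}\b", label, infix)
                gpr = parse_gpr(infix)
        reactions.append(
            ReactionRecord(
                id=rid,
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                gpr=gpr,
            )
        )

    biomass = None
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass = _strip("R_", obj.getFluxObjective(0).getReaction())
    if biomass is None:
        biomass = next((r.id for r in reactions if "biomass" in r.id.lower()), None)

    return MetabolicNetwork(metabolites, reactions, biomass, id=model.getId() or "model")


def _bound_value(model: libsbml.Model, param_id: str, fallback: float) -> float:
    if not param_id:
        return fallback
    param = model.getParameter(param_id)
    return param.getValue() if param is not None else fallback


def _write_sbml(network: MetabolicNetwork, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_sanitize(network.id))
    fbc_model = model.getPlugin("fbc")
    fbc_model.setStrict(True)

    compartments = sorted({m.compartment for m in network.metabolites})
    for comp in compartments:
        c = model.createCompartment()
        c.setId(_sanitize(comp))
        c.setConstant(True)
        c.setSize(1.0)

    for met in network.metabolites:
        sp = model.createSpecies()
        sp.setId("M_" + _sanitize(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula is not None:
            fbc_sp.setChemicalFormula(dict_to_formula(met.formula))
        if met.charge is not None:
            fbc_sp.setCharge(int(met.charge))

    for gene in sorted(network.genes):
        gp = fbc_model.createGeneProduct()
        gp.setId("G_" + _sanitize(gene))
        gp.setLabel(gene)

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
        r.setId("R_" + _sanitize(rxn.id))
        r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies("M_" + _sanitize(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        fbc_rxn = r.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = fbc_rxn.createGeneProductAssociation()
            gpa.setAssociation(_gpr_to_fbc(rxn.gpr), True, False)

    if network.biomass_reaction is not None:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sanitize(network.biomass_reaction))
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"could not write SBML to {path}")


def _gpr_to_fbc(gpr: GPRExpr) -> str:
    if gpr.kind == "gene":
        return "G_" + _sanitize(gpr.gene)
    sep = " and " if gpr.kind == "and" else " or "
    return "(" + sep.join(_gpr_to_fbc(c) for c in gpr.children) + ")"


_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sanitize(sid: str) -> str:
    sid = _SID_BAD.sub("_", sid)
    if sid and sid[0].isdigit():
        sid = "_" + sid
    return sid


# ---------------------------------------------------------------------------
# Tabular
# ---------------------------------------------------------------------------

REACTIONS_TSV = "reactions.tsv"
METABOLITES_TSV = "metabolites.tsv"


def _tabular_paths(path: str) -> tuple[str, str]:
    if os.path.isdir(path) or not path.endswith(".tsv"):
        return os.path.join(path, REACTIONS_TSV), os.path.join(path, METABOLITES_TSV)
    return path, os.path.join(os.path.dirname(path), METABOLITES_TSV)


def _read_tabular(path: str, default_bound: float) -> MetabolicNetwork:
    rxn_path, met_path = _tabular_paths(path)
    for p in (rxn_path, met_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    met_df = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxn_df = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    if met_df.empty or rxn_df.empty:
        raise NetworkValidationError("empty model: no metabolites or no reactions")

    metabolites = []
    for _, row in met_df.iterrows():
        metabolites.append(
            MetaboliteRecord(
                id=row["id"],
                name=row.get("name", ""),
                compartment=row.get("compartment", "c") or "c",
                formula=formula_to_dict(row["formula"]) if row.get("formula") else None,
                charge=int(row["charge"]) if row.get("charge") not in ("", None) else None,
            )
        )

    reactions = []
    biomass = None
    seen: set[str] = set()
    for _, row in rxn_df.iterrows():
        rid = row["reaction_id"]
        if rid in seen:
            raise NetworkValidationError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich, reversible = parse_equation(row["equation"])
        lower = float(row["lower"]) if row.get("lower") not in ("", None) else (
            -default_bound if reversible else 0.0
        )
        upper = float(row["upper"]) if row.get("upper") not in ("", None) else default_bound
        gpr = parse_gpr(row["gpr"]) if row.get("gpr") else None
        reactions.append(
            ReactionRecord(
                id=rid,
                name=row.get("name", ""),
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                gpr=gpr,
            )
        )
        if row.get("objective") in ("1", "true", "True"):
            biomass = rid

    return MetabolicNetwork(metabolites, reactions, biomass)


def _write_tabular(network: MetabolicNetwork, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    rxn_path, met_path = _tabular_paths(path)
    met_rows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": dict_to_formula(m.formula) if m.formula is not None else "",
            "charge": "" if m.charge is None else m.charge,
        }
        for m in network.metabolites
    ]
    rxn_rows = [
        {
            "reaction_id": r.id,
            "name": r.name,
            "equation": format_equation(r.stoichiometry, r.reversible),
            "lower": r.lower_bound,
            "upper": r.upper_bound,
            "gpr": r.gpr.to_string() if r.gpr is not None else "",
            "objective": 1 if r.id == network.biomass_reaction else "",
        }
        for r in network.reactions
    ]
    pd.DataFrame(met_rows).to_csv(met_path, sep="\t", index=False)
    pd.DataFrame(rxn_rows).to_csv(rxn_path, sep="\t", index=False)
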