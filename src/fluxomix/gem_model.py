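"""Genome-scale metabolic model containers and I/O.

A metabolic model is a set of metabolites and reactions; each reaction has
flux bounds (mmol/gDCW/h), an optional gene-protein-reaction (GPR) boolean
rule, and signed stoichiometric coefficients (negative = consumed).  The
stoichiometric matrix S (metabolites x reactions) built here is the equality
constraint ``S v = 0`` of every flux computation downstream.

Two serializations are supported: SBML Level 3 with the fbc extension
(bounds as parameters, GPR as gene-product associations) and a plain-text
TSV dialect (a directory with ``reactions.tsv`` and ``metabolites.tsv``,
reaction chemistry as an equation string such as
``1 glc[e] + 1 atp[c] -> 1 g6p[c]``; the arrow ``<=>`` marks reversibility).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse

DEFAULT_UB = 1000.0  # default flux cap, mmol/gDCW/h
DEFAULT_LB_REVERSIBLE = -1000.0

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "GprNode",
    "parse_gpr",
    "gpr_to_string",
    "gpr_genes",
    "read_model",
    "write_model",
    "build_stoichiometric_matrix",
    "ModelValidationError",
    "ModelParseError",
]


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed in its declared dialect."""


class ModelValidationError(ValueError):
    """Raised when a model violates structural invariants."""


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprNode:
    """Node of an AND/OR gene-association tree.

    ``op`` is ``"gene"`` (leaf; ``children`` holds the gene id string),
    ``"and"`` or ``"or"``.
    """

    op: str
    children: tuple

    def __post_init__(self):
        if self.op not in ("gene", "and", "or"):
            raise ValueError(f"invalid GPR node op {self.op!r}")


_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule: str) -> GprNode | None:
    """Parse a boolean gene-association rule into an AND/OR tree.

    Accepts parenthesized expressions over ``and`` / ``or`` (case
    insensitive).  An empty/blank rule yields ``None``.  Anything that is not
    a gene token, operator or parenthesis is a parse error — silent GPR
    corruption would be untestable downstream.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _GPR_TOKEN.findall(rule)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        node = parse_and()
        parts = [node]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_and())
        if len(parts) == 1:
            return parts[0]
        return GprNode("or", tuple(parts))

    def parse_and():
        node = parse_atom()
        parts = [node]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_atom())
        if len(parts) == 1:
            return parts[0]
        return GprNode("and", tuple(parts))

    def parse_atom():
        tok = peek()
        if tok is None:
            raise ModelParseError(f"truncated GPR rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelParseError(f"unbalanced parentheses in GPR: {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelParseError(f"unexpected token {tok!r} in GPR: {rule!r}")
        return GprNode("gene", (take(),))

    tree = parse_or()
    if pos != len(tokens):
        raise ModelParseError(f"trailing tokens in GPR: {rule!r}")
    return tree


def gpr_to_string(node: GprNode | None) -> str:
    """Canonical textual form of a GPR tree (ORs of ANDs, parenthesized)."""
    if node is None:
        return ""
    if node.op == "gene":
        return node.children[0]
    sep = f" {node.op} "
    parts = []
    for child in node.children:
        s = gpr_to_string(child)
        if child.op != "gene" and child.op != node.op:
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def gpr_genes(node: GprNode | None) -> set:
    """All gene ids referenced by a GPR tree."""
    if node is None:
        return set()
    if node.op == "gene":
        return {node.children[0]}
    out = set()
    for child in node.children:
        out |= gpr_genes(child)
    return out


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict      # metabolite id -> signed coefficient
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    name: str = ""
    gene_association: GprNode | None = None
    subsystem: str | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def is_exchange(self, compartments: Mapping[str, str]) -> bool:
        """True iff the reaction moves exactly one extracellular species
        across the system boundary (single non-zero stoichiometric entry)."""
        if len(self.stoichiometry) != 1:
            return False
        (mid,) = self.stoichiometry
        return compartments.get(mid) == "e"


@dataclass
class MetabolicModel:
    id: str
    metabolites: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    objective: dict = field(default_factory=dict)   # reaction id -> coefficient
    biomass_reaction_id: str | None = None
    atp_maintenance_reaction_id: str | None = None
    compartments: dict = field(default_factory=dict)  # token -> display name

    # -- lookups -----------------------------------------------------------
    def metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def metabolite_compartments(self) -> dict:
        return {m.id: m.compartment for m in self.metabolites}

    def exchange_reaction_ids(self) -> list:
        comp = self.metabolite_compartments()
        return [r.id for r in self.reactions if r.is_exchange(comp)]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    name=r.name,
                    gene_association=r.gene_association,
                    subsystem=r.subsystem,
                )
                for r in self.reactions
            ],
            genes=list(self.genes),
            objective=dict(self.objective),
            biomass_reaction_id=self.biomass_reaction_id,
            atp_maintenance_reaction_id=self.atp_maintenance_reaction_id,
            compartments=dict(self.compartments),
        )

    # -- validation --------------------------------------------------------
    def validate(self, strict: bool = True) -> list:
        """Check structural invariants; return the list of problems.

        With ``strict=True`` (default) any problem raises
        :class:`ModelValidationError` listing every offender.
        """
        problems = []
        met_ids = self.metabolite_ids()
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            problems.append(f"duplicate metabolite ids: {dupes}")
        rxn_ids = self.reaction_ids()
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            problems.append(f"duplicate reaction ids: {dupes}")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for r in self.reactions:
            if not r.stoichiometry:
                problems.append(f"reaction {r.id}: empty stoichiometry")
            dangling = sorted(set(r.stoichiometry) - met_set)
            if dangling:
                problems.append(f"reaction {r.id}: unknown metabolites {dangling}")
            for mid, coef in r.stoichiometry.items():
                if coef == 0 or not math.isfinite(coef):
                    problems.append(
                        f"reaction {r.id}: coefficient {coef} for {mid}"
                    )
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            unknown_genes = sorted(gpr_genes(r.gene_association) - gene_set)
            if unknown_genes:
                problems.append(f"reaction {r.id}: unknown genes {unknown_genes}")
        rxn_set = set(rxn_ids)
        bad_obj = sorted(set(self.objective) - rxn_set)
        if bad_obj:
            problems.append(f"objective references unknown reactions {bad_obj}")
        for label, rid in (
            ("biomass", self.biomass_reaction_id),
            ("ATP maintenance", self.atp_maintenance_reaction_id),
        ):
            if rid is not None and rid not in rxn_set:
                problems.append(f"{label} reaction id {rid!r} does not resolve")
        declared = set(self.compartments) if self.compartments else None
        if declared is not None:
            for m in self.metabolites:
                if m.compartment not in declared:
                    problems.append(
                        f"metabolite {m.id}: compartment {m.compartment!r} "
                        f"not declared"
                    )
        if problems and strict:
            raise ModelValidationError("; ".join(problems))
        return problems


@dataclass
class StoichiometricMatrix:
    """Sparse m x n stoichiometric matrix with explicit row/column orderings."""

    values: sparse.csc_matrix
    row_index: list   # metabolite ids
    col_index: list   # reaction ids

    @property
    def shape(self):
        return self.values.shape

    @property
    def degenerate(self) -> bool:
        """True when the model has no internal metabolites (0 x n matrix)."""
        return self.values.shape[0] == 0

    def to_dense(self) -> np.ndarray:
        return self.values.toarray()


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S with rows in model metabolite order, columns in reaction
    order; entry (i, j) is the signed coefficient of metabolite i in
    reaction j."""
    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()
    row_of = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            rows.append(row_of[mid])
            cols.append(j)
            data.append(float(coef))
    values = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return StoichiometricMatrix(values=values, row_index=met_ids, col_index=rxn_ids)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$")


def _parse_equation(eq: str, rid: str) -> tuple:
    """Parse ``a A + b B -> c C`` / ``<=>`` into (stoichiometry, reversible)."""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>")
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        reversible = False
    else:
        raise ModelParseError(f"reaction {rid}: equation lacks an arrow: {eq!r}")
    stoich: dict = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM.match(term)
            if m is None:
                raise ModelParseError(f"reaction {rid}: bad term {term!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            mid = m.group(2)
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    return stoich, reversible


def _format_equation(rxn: Reaction) -> str:
    def fmt(coef):
        return repr(abs(coef))  # shortest exact round-trip representation

    lhs = [f"{fmt(c)} {m}" for m, c in sorted(rxn.stoichiometry.items()) if c < 0]
    rhs = [f"{fmt(c)} {m}" for m, c in sorted(rxn.stoichiometry.items()) if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _read_tsv(path: Path, strict: bool) -> MetabolicModel:
    rxn_path = path / "reactions.tsv"
    met_path = path / "metabolites.tsv"
    for p in (rxn_path, met_path):
        if not p.exists():
            raise ModelParseError(f"missing table {p}")
    mets_df = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxns_df = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    metabolites = [
        Metabolite(
            id=row["id"],
            name=row.get("name", ""),
            compartment=row.get("compartment", "c") or "c",
            formula=(row.get("formula") or None),
        )
        for _, row in mets_df.iterrows()
    ]
    reactions = []
    objective: dict = {}
    biomass_id = None
    atpm_id = None
    genes: set = set()
    for _, row in rxns_df.iterrows():
        rid = row["id"]
        stoich, reversible = _parse_equation(row["equation"], rid)
        lb_raw, ub_raw = row.get("lb", ""), row.get("ub", "")
        lb = float(lb_raw) if lb_raw != "" else (
            DEFAULT_LB_REVERSIBLE if reversible else 0.0
        )
        ub = float(ub_raw) if ub_raw != "" else DEFAULT_UB
        gpr = parse_gpr(row.get("gpr", ""))
        genes |= gpr_genes(gpr)
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            name=row.get("name", ""),
            gene_association=gpr,
            subsystem=(row.get("subsystem") or None),
        )
        reactions.append(rxn)
        obj_raw = row.get("objective_coef", "")
        if obj_raw not in ("", "0", "0.0"):
            objective[rid] = float(obj_raw)
        role = row.get("role", "")
        if role == "biomass":
            biomass_id = rid
        elif role == "atp_maintenance":
            atpm_id = rid
    compartments = sorted({m.compartment for m in metabolites})
    model = MetabolicModel(
        id=path.name,
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(genes),
        objective=objective,
        biomass_reaction_id=biomass_id,
        atp_maintenance_reaction_id=atpm_id,
        compartments={c: c for c in compartments},
    )
    model.validate(strict=strict)
    return model


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    mets_df = pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "formula": [m.formula or "" for m in model.metabolites],
        }
    )
    roles = []
    for r in model.reactions:
        if r.id == model.biomass_reaction_id:
            roles.append("biomass")
        elif r.id == model.atp_maintenance_reaction_id:
            roles.append("atp_maintenance")
        else:
            roles.append("")
    rxns_df = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "name": [r.name for r in model.reactions],
            "equation": [_format_equation(r) for r in model.reactions],
            "lb": [repr(r.lower_bound) for r in model.reactions],
            "ub": [repr(r.upper_bound) for r in model.reactions],
            "gpr": [gpr_to_string(r.gene_association) for r in model.reactions],
            "subsystem": [r.subsystem or "" for r in model.reactions],
            "objective_coef": [
                repr(model.objective[r.id]) if r.id in model.objective else ""
                for r in model.reactions
            ],
            "role": roles,
        }
    )
    mets_df.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxns_df.to_csv(path / "reactions.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------

_SBO_ATP_MAINTENANCE = 630
_SBO_BIOMASS = 629


def _sanitize_sid(token: str) -> str:
    """Map an arbitrary id onto a valid SBML SId (SBML ids must match
    ``[A-Za-z_][A-Za-z0-9_]*``); reversible mapping for our id conventions."""
    out = token.replace("[", "__LB__").replace("]", "__RB__")
    out = re.sub(r"[^A-Za-z0-9_]", "_", out)
    if not re.match(r"[A-Za-z_]", out):
        out = "_" + out
    return out


def _unsanitize_sid(sid: str) -> str:
    return sid.replace("__LB__", "[").replace("__RB__", "]")


def _gpr_to_fbc(node: GprNode, assoc, sid_of_gene):
    import libsbml

    if node.op == "gene":
        ref = assoc.createGeneProductRef()
        ref.setGeneProduct(sid_of_gene[node.children[0]])
        return
    container = assoc.createAnd() if node.op == "and" else assoc.createOr()
    for child in node.children:
        _gpr_to_fbc_child(child, container, sid_of_gene)


def _gpr_to_fbc_child(node: GprNode, container, sid_of_gene):
    if node.op == "gene":
        ref = container.createGeneProductRef()
        ref.setGeneProduct(sid_of_gene[node.children[0]])
    elif node.op == "and":
        sub = container.createAnd()
        for child in node.children:
            _gpr_to_fbc_child(child, sub, sid_of_gene)
    else:
        sub = container.createOr()
        for child in node.children:
            _gpr_to_fbc_child(child, sub, sid_of_gene)


def _fbc_to_gpr(assoc, gene_of_sid) -> GprNode:
    import libsbml

    if assoc.isGeneProductRef():
        return GprNode("gene", (gene_of_sid[assoc.getGeneProduct()],))
    op = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _fbc_to_gpr(assoc.getAssociation(i), gene_of_sid)
        for i in range(assoc.getNumAssociations())
    )
    return GprNode(op, children)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize_sid(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    comps = model.compartments or {
        c: c for c in sorted({m.compartment for m in model.metabolites})
    }
    for token, name in comps.items():
        comp = sbml_model.createCompartment()
        comp.setId(_sanitize_sid(token))
        comp.setName(name)
        comp.setConstant(True)

    sid_of_met = {}
    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sid = _sanitize_sid(m.id)
        sid_of_met[m.id] = sid
        sp.setId(sid)
        sp.setName(m.name or m.id)
        sp.setCompartment(_sanitize_sid(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)

    sid_of_gene = {}
    for g in model.genes:
        gp = mplug.createGeneProduct()
        sid = "G_" + _sanitize_sid(g)
        sid_of_gene[g] = sid
        gp.setId(sid)
        gp.setLabel(g)

    # flux bounds as shared/per-reaction parameters
    def make_param(value: float, pid: str) -> str:
        p = sbml_model.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        return pid

    for i, r in enumerate(model.reactions):
        rxn = sbml_model.createReaction()
        rsid = "R_" + _sanitize_sid(r.id)
        rxn.setId(rsid)
        rxn.setName(r.name or r.id)
        rxn.setFast(False)
        rxn.setReversible(r.reversible)
        if r.id == model.atp_maintenance_reaction_id:
            rxn.setSBOTerm(_SBO_ATP_MAINTENANCE)
        elif r.id == model.biomass_reaction_id:
            rxn.setSBOTerm(_SBO_BIOMASS)
        for mid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(sid_of_met[mid])
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(make_param(r.lower_bound, f"lb_{i}"))
        rplug.setUpperFluxBound(make_param(r.upper_bound, f"ub_{i}"))
        if r.gene_association is not None:
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_fbc(r.gene_association, gpa, sid_of_gene)
        if r.subsystem:
            rxn.appendNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, coef in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction("R_" + _sanitize_sid(rid))
            fo.setCoefficient(coef)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _read_sbml(path: Path, strict: bool) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"no <model> element in {path}")
    mplug = sbml_model.getPlugin("fbc")

    compartments = {}
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        compartments[_unsanitize_sid(comp.getId())] = comp.getName() or comp.getId()

    met_of_sid = {}
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        mid = _unsanitize_sid(sp.getId())
        met_of_sid[sp.getId()] = mid
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        metabolites.append(
            Metabolite(
                id=mid,
                name=sp.getName() or "",
                compartment=_unsanitize_sid(sp.getCompartment()),
                formula=formula,
            )
        )

    gene_of_sid = {}
    genes = []
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or _unsanitize_sid(gp.getId())
            gene_of_sid[gp.getId()] = label
            genes.append(label)

    def strip_prefix(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    reactions = []
    atpm_id = None
    biomass_id = None
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = _unsanitize_sid(strip_prefix(rxn.getId(), "R_"))
        stoich: dict = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            mid = met_of_sid[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            mid = met_of_sid[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        rplug = rxn.getPlugin("fbc")
        lb = DEFAULT_LB_REVERSIBLE if rxn.getReversible() else 0.0
        ub = DEFAULT_UB
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = sbml_model.getParameter(rplug.getLowerFluxBound()).getValue()
            if rplug.isSetUpperFluxBound():
                ub = sbml_model.getParameter(rplug.getUpperFluxBound()).getValue()
        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _fbc_to_gpr(
                rplug.getGeneProductAssociation().getAssociation(), gene_of_sid
            )
        subsystem = None
        if rxn.isSetNotes():
            m = re.search(r"SUBSYSTEM:\s*([^<]+)", rxn.getNotesString())
            if m:
                subsystem = m.group(1).strip()
        if rxn.getSBOTerm() == _SBO_ATP_MAINTENANCE:
            atpm_id = rid
        elif rxn.getSBOTerm() == _SBO_BIOMASS:
            biomass_id = rid
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name="" if rxn.getName() == rid else (rxn.getName() or ""),
                gene_association=gpr,
                subsystem=subsystem,
            )
        )

    objective: dict = {}
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            rid = _unsanitize_sid(strip_prefix(fo.getReaction(), "R_"))
            objective[rid] = fo.getCoefficient()

    model = MetabolicModel(
        id=_unsanitize_sid(sbml_model.getId()) or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(set(genes)),
        objective=objective,
        biomass_reaction_id=biomass_id,
        atp_maintenance_reaction_id=atpm_id,
        compartments=compartments,
    )
    model.validate(strict=strict)
    return model


# ---------------------------------------------------------------------------
# Public readers/writers
# ---------------------------------------------------------------------------

def read_model(path, format: str = None, strict: bool = True) -> MetabolicModel:
    """Read a metabolic model from SBML (``.xml``/``.sbml`` file) or the TSV
    dialect (directory).  ``format`` may be ``"sbml"`` or ``"tsv"``; when
    omitted it is inferred from the path."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.is_dir() else "sbml"
    if format == "tsv":
        return _read_tsv(path, strict=strict)
    if format == "sbml":
        if not path.exists():
            raise ModelParseError(f"no such file: {path}")
        return _read_sbml(path, strict=strict)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = None) -> None:
    """Serialize a validated model; inverse of :func:`read_model`."""
    model.validate(strict=True)
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix in (".xml", ".sbml") else "tsv"
    if format == "tsv":
        _write_tsv(model, path)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
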