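"""Metabolic model representation, SBML I/O and structural manipulations.

The central container is :class:`MetabolicModel`: a compartmentalised
stoichiometric model with flux bounds and boolean gene-protein-reaction
(GPR) rules per reaction.  Exchange reactions (single-metabolite boundary
reactions) encode the growth medium through their bounds.  Two structural
operations matter downstream:

* artificial drains (``add_drain`` / ``add_objective_drain``) — irreversible
  sinks used to unblock dead-end metabolites and to express biosynthetic
  objectives such as "maximise net production of metabolite X";
* reversible splitting (``split_reversible``) — rewrites every reversible
  reaction as a forward/backward irreversible pair so that absolute fluxes
  become linear, a prerequisite for the inconsistency LP.

SBML is read and written through libsbml.  Level 3 + fbc (bounds as
parameters, GPRs as gene-product associations) is the written dialect; the
reader additionally understands the legacy Level 2 COBRA "notes" encoding
(``GENE_ASSOCIATION`` notes, kinetic-law bound parameters).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import libsbml
import numpy as np
from scipy import sparse

__all__ = [
    "INTERNAL_INF",
    "ARTIFICIAL_PREFIX",
    "GPRTree",
    "Reaction",
    "MetabolicModel",
    "ModelError",
    "SBMLReadError",
    "GPRParseError",
    "parse_gpr",
    "read_sbml_model",
    "write_sbml_model",
    "add_drain",
    "add_objective_drain",
    "split_reversible",
    "model_summary",
]

#: Finite stand-in for unbounded fluxes (COBRA convention); keeps LPs bounded.
INTERNAL_INF = 1000.0

#: Reactions with this id prefix are artificial (drains, objectives) and are
#: excluded from contribution statistics and network projection.
ARTIFICIAL_PREFIX = "ART_"


class ModelError(ValueError):
    """Structural problem with a metabolic model."""


class SBMLReadError(ModelError):
    """The SBML document could not be parsed into a model."""


class GPRParseError(ModelError):
    """A GPR rule string is malformed."""

    def __init__(self, message: str, position: int | None = None,
                 reaction: str | None = None):
        self.position = position
        self.reaction = reaction
        prefix = f"reaction {reaction!r}: " if reaction else ""
        suffix = f" (at position {position})" if position is not None else ""
        super().__init__(f"{prefix}{message}{suffix}")


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRTree:
    """Boolean gene rule: leaves are gene ids, internal nodes AND/OR.

    Evaluation on expression values follows the min/max convention:
    AND maps to ``min`` over children, OR maps to ``max``.
    """

    op: str  # "gene", "and" or "or"
    gene: str | None = None
    children: tuple["GPRTree", ...] = ()

    def __post_init__(self):
        if self.op == "gene":
            if not self.gene:
                raise GPRParseError("gene leaf without identifier")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise GPRParseError(f"{self.op!r} node needs >= 2 children")
        else:
            raise GPRParseError(f"unknown GPR operator {self.op!r}")

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, values: Mapping[str, float]) -> float:
        """Min/max evaluation of the rule over per-gene values."""
        if self.op == "gene":
            return float(values[self.gene])
        agg = min if self.op == "and" else max
        return agg(child.evaluate(values) for child in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesise an OR nested under an AND (and binds tighter)
            if self.op == "and" and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize_gpr(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            tokens.append(("op", low, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse_gpr(text: str | None) -> GPRTree | None:
    """Parse a GPR rule string into a :class:`GPRTree`.

    ``and`` binds tighter than ``or``; both are left-associative and
    case-insensitive.  An empty/whitespace string maps to ``None`` (no rule).

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or misplaced operators, with the offending
        character position.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize_gpr(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GPRTree:
        nonlocal pos
        node = parse_and()
        children = [node]
        while (tok := peek()) and tok[:2] == ("op", "or"):
            pos += 1
            children.append(parse_and())
        if len(children) == 1:
            return node
        return GPRTree("or", children=tuple(children))

    def parse_and() -> GPRTree:
        nonlocal pos
        node = parse_atom()
        children = [node]
        while (tok := peek()) and tok[:2] == ("op", "and"):
            pos += 1
            children.append(parse_atom())
        if len(children) == 1:
            return node
        return GPRTree("and", children=tuple(children))

    def parse_atom() -> GPRTree:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError("unexpected end of GPR rule", len(text))
        kind, value, at = tok
        if kind == "gene":
            pos += 1
            return GPRTree("gene", gene=value)
        if kind == "paren" and value == "(":
            pos += 1
            node = parse_or()
            closing = peek()
            if closing is None or closing[1] != ")":
                raise GPRParseError("unbalanced parentheses", at)
            pos += 1
            return node
        raise GPRParseError(f"unexpected token {value!r}", at)

    tree = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing input {tokens[pos][1]!r}", tokens[pos][2])
    return tree


# ---------------------------------------------------------------------------
# Reactions and models
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and an optional GPR rule.

    Stoichiometry maps metabolite ids to signed coefficients (negative =
    consumed).  ``is_exchange`` marks single-metabolite boundary reactions;
    ``artificial`` marks drains/objectives introduced by the pipeline.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = INTERNAL_INF
    gpr: GPRTree | None = None
    is_exchange: bool = False
    artificial: bool = False

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        self.lower_bound = _clamp_bound(self.lower_bound)
        self.upper_bound = _clamp_bound(self.upper_bound)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


def _clamp_bound(value: float) -> float:
    if math.isinf(value):
        return math.copysign(INTERNAL_INF, value)
    return float(value)


@dataclass
class MetabolicModel:
    """Compartmentalised stoichiometric model.

    ``metabolites`` maps metabolite id -> compartment id; ``reactions`` maps
    reaction id -> :class:`Reaction` (insertion-ordered).
    """

    metabolites: dict[str, str]
    reactions: dict[str, Reaction]
    objective_reaction: str | None = None
    id: str = "model"
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}")
            if rxn.is_exchange and len(rxn.stoichiometry) != 1:
                raise ModelError(
                    f"exchange reaction {rxn.id!r} touches "
                    f"{len(rxn.stoichiometry)} metabolites")
        if (self.objective_reaction is not None
                and self.objective_reaction not in self.reactions):
            raise ModelError(
                f"objective reaction {self.objective_reaction!r} not in model")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective_reaction=self.objective_reaction,
            id=self.id,
            metadata=dict(self.metadata),
        )

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self.reactions:
            raise ModelError(f"duplicate reaction id {reaction.id!r}")
        for met in reaction.stoichiometry:
            if met not in self.metabolites:
                raise ModelError(
                    f"reaction {reaction.id!r} references unknown metabolite {met!r}")
        self.reactions[reaction.id] = reaction

    @property
    def exchange_reactions(self) -> list[str]:
        return [rid for rid, r in self.reactions.items() if r.is_exchange]

    @property
    def compartments(self) -> list[str]:
        return sorted(set(self.metabolites.values()))

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr is not None:
                out |= rxn.gpr.genes()
        return out

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Sparse S (metabolites x reactions) plus row/column id orderings."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                data.append(float(coef))
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
        return S, met_ids, rxn_ids

    def metabolite_degree(self, include_artificial: bool = False) -> dict[str, int]:
        """Number of reactions each metabolite participates in."""
        deg = {m: 0 for m in self.metabolites}
        for rxn in self.reactions.values():
            if rxn.artificial and not include_artificial:
                continue
            for met in rxn.stoichiometry:
                deg[met] += 1
        return deg


# ---------------------------------------------------------------------------
# Drains and reversible splitting
# ---------------------------------------------------------------------------

def add_drain(model: MetabolicModel, metabolite_id: str,
              prefix: str = "DRAIN") -> MetabolicModel:
    """Return a copy of *model* with an irreversible sink for a metabolite.

    The drain consumes one unit of the metabolite, has bounds
    ``[0, INTERNAL_INF]`` and no GPR (so it counts as expressed downstream).
    Used to unblock dead-end metabolites that would otherwise forbid any
    steady-state flux through reactions producing them.
    """
    if metabolite_id not in model.metabolites:
        raise ModelError(f"unknown metabolite {metabolite_id!r}")
    drain_id = f"{ARTIFICIAL_PREFIX}{prefix}_{metabolite_id}"
    if drain_id in model.reactions:
        raise ModelError(f"drain {drain_id!r} already present")
    new = model.copy()
    new.add_reaction(Reaction(
        id=drain_id,
        stoichiometry={metabolite_id: -1.0},
        lower_bound=0.0,
        upper_bound=INTERNAL_INF,
        gpr=None,
        is_exchange=False,
        artificial=True,
    ))
    return new


def add_objective_drain(model: MetabolicModel,
                        metabolite_id: str) -> MetabolicModel:
    """Like :func:`add_drain` but the new sink becomes the FBA objective.

    This is how a terminal biosynthetic objective ("maximise net production
    of metabolite X") is expressed as a reaction flux.
    """
    new = add_drain(model, metabolite_id, prefix="OBJ")
    new.objective_reaction = f"{ARTIFICIAL_PREFIX}OBJ_{metabolite_id}"
    new.metadata["objective_metabolite"] = metabolite_id
    return new


REVERSE_SUFFIX = "__rev"


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Replace every reversible reaction by an irreversible forward/backward pair.

    The forward reaction keeps the original id with bounds ``[0, ub]``; the
    backward reaction gets the ``__rev`` suffix, negated stoichiometry and
    bounds ``[0, -lb]``.  Net flux in the original model corresponds to
    ``v_fwd - v_rev``, so the two steady-state flux spaces are in bijection
    and the FBA optimum is preserved.  The mapping new id -> (original id,
    sign) is stored under ``metadata["split_map"]``.
    """
    new = MetabolicModel(
        metabolites=dict(model.metabolites),
        reactions={},
        objective_reaction=model.objective_reaction,
        id=model.id,
        metadata=dict(model.metadata),
    )
    split_map: dict[str, tuple[str, int]] = {}
    for rid, rxn in model.reactions.items():
        if rxn.reversible:
            fwd = rxn.copy()
            fwd.lower_bound = 0.0
            new.reactions[rid] = fwd
            rev = Reaction(
                id=rid + REVERSE_SUFFIX,
                stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
                lower_bound=0.0,
                upper_bound=-rxn.lower_bound,
                gpr=rxn.gpr,
                is_exchange=rxn.is_exchange,
                artificial=rxn.artificial,
            )
            new.reactions[rev.id] = rev
            split_map[rid] = (rid, 1)
            split_map[rev.id] = (rid, -1)
        else:
            new.reactions[rid] = rxn.copy()
            split_map[rid] = (rid, 1)
    new.metadata["split_map"] = split_map
    return new


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

def _sanitize_sid(raw: str) -> str:
    out = []
    for i, ch in enumerate(raw):
        if ch.isalnum() or ch == "_":
            out.append(ch)
        else:
            out.append("_")
    sid = "".join(out)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def write_sbml_model(model: MetabolicModel, path: str) -> None:
    """Write *model* as SBML Level 3 Version 1 with the fbc v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in model.compartments:
        c = sm.createCompartment()
        c.setId(_sanitize_sid(comp))
        c.setConstant(True)
        c.setSize(1.0)
        c.setSpatialDimensions(3)

    for met, comp in model.metabolites.items():
        s = sm.createSpecies()
        s.setId(_sanitize_sid(met))
        s.setCompartment(_sanitize_sid(comp))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        s.setInitialConcentration(0.0)

    for gene in sorted(model.genes()):
        gp = mplug.createGeneProduct()
        gp.setId(_sanitize_sid(gene))
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid, rxn in model.reactions.items():
        r = sm.createReaction()
        r.setId(_sanitize_sid(rid))
        r.setFast(False)
        r.setReversible(rxn.reversible)
        for met, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(_sanitize_sid(met))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(rxn.gpr.to_string(), True, False)

    obj_rxn = model.objective_reaction
    if obj_rxn is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fo = objective.createFluxObjective()
        fo.setReaction(_sanitize_sid(obj_rxn))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"could not write SBML to {path!r}")


def _association_to_tree(assoc, labels: Mapping[str, str]) -> GPRTree:
    if assoc is None:
        raise SBMLReadError("empty gene-product association")
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        gp_id = assoc.getGeneProduct()
        return GPRTree("gene", gene=labels.get(gp_id, gp_id))
    if code in (libsbml.SBML_FBC_AND, libsbml.SBML_FBC_OR):
        op = "and" if code == libsbml.SBML_FBC_AND else "or"
        children = tuple(
            _association_to_tree(assoc.getAssociation(i), labels)
            for i in range(assoc.getNumAssociations()))
        if len(children) == 1:
            return children[0]
        return GPRTree(op, children=children)
    raise SBMLReadError(f"unsupported association type code {code}")


def _notes_gene_association(reaction) -> str | None:
    notes = reaction.getNotesString() if reaction.isSetNotes() else ""
    for line in notes.splitlines():
        stripped = line.strip()
        for tag in ("GENE_ASSOCIATION:", "GENE ASSOCIATION:"):
            if tag in stripped:
                text = stripped.split(tag, 1)[1]
                for closer in ("</p>", "</body>", "</html>", "</notes>"):
                    text = text.replace(closer, "")
                return text.strip()
    return None


def read_sbml_model(path: str, exchange_prefix: str = "EX_") -> MetabolicModel:
    """Read an SBML file (L3+fbc or L2 COBRA-notes dialect) into a model.

    Exchange reactions are detected by single-metabolite stoichiometry or by
    the configurable id prefix; the ``ART_`` prefix marks artificial
    reactions.  Infinite bounds are clamped to ``INTERNAL_INF``.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise SBMLReadError(f"unparsable SBML {path!r}: " + "; ".join(msgs[:3]))
    sm = doc.getModel()
    if sm is None:
        raise SBMLReadError(f"no model element in {path!r}")

    mplug = sm.getPlugin("fbc")
    labels: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            labels[gp.getId()] = gp.getLabel() or gp.getId()

    metabolites: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are implicit sinks, not balanced
        metabolites[sp.getId()] = sp.getCompartment() or "default"

    reactions: dict[str, Reaction] = {}
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in metabolites:
                stoich[ref.getSpecies()] = (
                    stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry())
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in metabolites:
                stoich[ref.getSpecies()] = (
                    stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry())
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        if not stoich:
            continue  # pure boundary <-> boundary reaction carries no constraint

        lb, ub = (-INTERNAL_INF, INTERNAL_INF) if sr.getReversible() \
            else (0.0, INTERNAL_INF)
        rplug = sr.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            p = sm.getParameter(rplug.getLowerFluxBound())
            if p is not None:
                lb = p.getValue()
            p = sm.getParameter(rplug.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()
        elif sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            for name, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                par = kl.getParameter(name)
                if par is not None:
                    if setter == "lb":
                        lb = par.getValue()
                    else:
                        ub = par.getValue()

        gpr: GPRTree | None = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            gpr = _association_to_tree(assoc, labels)
        else:
            text = _notes_gene_association(sr)
            if text:
                try:
                    gpr = parse_gpr(text)
                except GPRParseError as exc:
                    raise GPRParseError(str(exc), reaction=rid) from exc

        reactions[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            is_exchange=(not rid.startswith(ARTIFICIAL_PREFIX)
                         and (len(stoich) == 1
                              or rid.startswith(exchange_prefix))),
            artificial=rid.startswith(ARTIFICIAL_PREFIX),
        )

    objective = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction=objective if objective in reactions else None,
        id=sm.getId() or "model",
    )
    model.validate()
    return model


def model_summary(model: MetabolicModel) -> dict:
    """JSON-serialisable overview: counts, compartments, exchanges, objective."""
    return {
        "id": model.id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes()),
        "n_reactions_without_gpr": sum(
            1 for r in model.reactions.values() if r.gpr is None),
        "compartments": model.compartments,
        "exchange_reactions": model.exchange_reactions,
        "objective_reaction": model.objective_reaction,
    }


def save_model_summary(model: MetabolicModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model_summary(model), fh, indent=2)
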