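"""Data model for constraint-based metabolic networks.

The central container is :class:`MetabolicModel`, a plain in-memory
representation of a stoichiometric network: compartments, metabolites with
elemental composition and charge, and reactions with bounds, gene
associations and a functional category tag.  SBML (Level 3 with the
flux-balance-constraints package, Level 2 with kinetic-law bound parameters
on read) is the canonical serialization.  The module also provides the
elemental/charge balance checker used to validate networks before any
flux computation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelSummary",
    "BalanceFinding",
    "parse_formula",
    "format_formula",
    "read_sbml",
    "write_sbml",
    "stoichiometric_matrix",
    "check_balance",
    "summarize",
]

#: Recognised reaction categories.  ``exchange``, ``biomass`` and ``pseudo``
#: reactions are exempt from mass balancing; the remaining three partition
#: the chemistry proper.
CATEGORIES = ("metabolic", "transport", "spontaneous", "exchange", "biomass", "pseudo")

DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelIntegrityError(ValueError):
    """A reference inside the model points at a missing component."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element-count map.

    The empty string is a valid, massless composition (used for pseudo
    species such as photons).  Isotope markers, R-groups and parenthesised
    sub-formulas are not supported and raise ``ValueError``.
    """
    if formula is None:
        raise ValueError("formula is None")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element, num = m.group(1), m.group(2)
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render an element-count map in Hill order (C, H, then alphabetical)."""
    def key(el: str) -> tuple[int, str]:
        return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

    parts = []
    for el in sorted(counts, key=key):
        n = counts[el]
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None  # None = unknown composition
    charge: int | None = None

    def copy(self) -> "Metabolite":
        return replace(self, formula=None if self.formula is None else dict(self.formula))


@dataclass
class Reaction:
    id: str
    name: str = ""
    #: metabolite id -> signed stoichiometric coefficient (negative = consumed)
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    #: boolean expression over gene ids, e.g. ``"g1 and (g2 or g3)"``; "" = none
    gene_association: str = ""
    category: str = "metabolic"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown reaction category {self.category!r}")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set[str]:
        """Gene ids referenced by the association expression."""
        tokens = re.findall(r"[A-Za-z0-9_.-]+", self.gene_association)
        return {t for t in tokens if t.lower() not in {"and", "or"}}

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str = "model"
    #: compartment id -> display name
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str | None = None

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return out

    # -- mutation helpers ------------------------------------------------
    def remove_reactions(self, rxn_ids) -> None:
        drop = set(rxn_ids)
        self.reactions = [r for r in self.reactions if r.id not in drop]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelIntegrityError` on broken references."""
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            raise ModelIntegrityError(f"duplicate metabolite ids in {self.id!r}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            raise ModelIntegrityError(f"duplicate reaction ids in {self.id!r}")
        met_set = set(met_ids)
        for m in self.metabolites:
            if m.compartment not in self.compartments:
                raise ModelIntegrityError(
                    f"metabolite {m.id!r} references unknown compartment "
                    f"{m.compartment!r}"
                )
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in met_set:
                    raise ModelIntegrityError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
        if self.objective_id is not None and self.objective_id not in set(rxn_ids):
            raise ModelIntegrityError(
                f"objective reaction {self.objective_id!r} not in model"
            )


@dataclass(frozen=True)
class ModelSummary:
    n_genes: int
    n_enzymes: int
    n_metabolic_reactions: int
    n_metabolites: int
    n_spontaneous: int
    n_transport: int
    n_compartments: int


@dataclass(frozen=True)
class BalanceFinding:
    """One conservation violation: reaction, element symbol or ``"charge"``
    or ``"unknown"``, and the signed imbalance (products minus substrates)."""

    reaction_id: str
    quantity: str
    imbalance: float


# ---------------------------------------------------------------------------
# matrices and checks
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> sparse.csc_matrix:
    """Sparse stoichiometric matrix S (metabolites x reactions), ordered by
    declaration order."""
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_pos[mid])
            cols.append(j)
            vals.append(float(coef))
    return sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


#: H and O imbalances are reported like any other element but are commonly
#: inspected separately: protonation-state conventions (intracellular pH is
#: not constant over the diurnal cycle) make them dialect-dependent.
DEFAULT_BALANCE_ELEMENTS = ("C", "N", "O", "P", "S")

_UNBALANCED_CATEGORIES = {"exchange", "biomass", "pseudo"}


def check_balance(
    model: MetabolicModel,
    elements: tuple[str, ...] = DEFAULT_BALANCE_ELEMENTS,
    check_charge: bool = True,
    tol: float = 1e-9,
) -> list[BalanceFinding]:
    """Check elemental and charge conservation of every chemical reaction.

    Exchange, biomass and pseudo reactions are skipped.  A metabolite with
    no formula (or, for the charge check, no charge) in a checked reaction
    yields an ``"unknown"`` finding rather than an exception.
    """
    mets = model._met_index()
    findings: list[BalanceFinding] = []
    for rxn in model.reactions:
        if rxn.category in _UNBALANCED_CATEGORIES:
            continue
        unknown = False
        for mid in rxn.stoichiometry:
            m = mets[mid]
            if m.formula is None or (check_charge and m.charge is None):
                unknown = True
        if unknown:
            findings.append(BalanceFinding(rxn.id, "unknown", math.nan))
            continue
        for el in elements:
            total = sum(
                coef * mets[mid].formula.get(el, 0)
                for mid, coef in rxn.stoichiometry.items()
            )
            if abs(total) > tol:
                findings.append(BalanceFinding(rxn.id, el, total))
        if check_charge:
            total = sum(
                coef * mets[mid].charge for mid, coef in rxn.stoichiometry.items()
            )
            if abs(total) > tol:
                findings.append(BalanceFinding(rxn.id, "charge", total))
    return findings


def summarize(model: MetabolicModel) -> ModelSummary:
    """Count network components the way reconstruction papers report them.

    ``n_enzymes`` counts distinct non-empty gene-association expressions over
    metabolic and transport reactions (isoreactions catalysed by the same
    enzyme or complex collapse onto one entry).
    """
    by_cat: dict[str, int] = {c: 0 for c in CATEGORIES}
    enzymes: set[str] = set()
    for r in model.reactions:
        by_cat[r.category] += 1
        if r.category in ("metabolic", "transport") and r.gene_association.strip():
            enzymes.add(_normalize_gpr(r.gene_association))
    return ModelSummary(
        n_genes=len(model.genes),
        n_enzymes=len(enzymes),
        n_metabolic_reactions=by_cat["metabolic"],
        n_metabolites=len(model.metabolites),
        n_spontaneous=by_cat["spontaneous"],
        n_transport=by_cat["transport"],
        n_compartments=len(model.compartments),
    )


def _normalize_gpr(expr: str) -> str:
    return " ".join(expr.lower().split())


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Accepts Level 3 with the fbc package (bounds as flux-bound parameters,
    formulas/charges as fbc attributes) and Level 2 with ``LOWER_BOUND`` /
    ``UPPER_BOUND`` kinetic-law parameters.  Missing bounds default to
    (-1000, 1000) for reversible and (0, 1000) for irreversible reactions.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ValueError(
                f"SBML parse error in {path} at line {err.getLine()}: "
                f"{err.getMessage()}"
            )
    sb = doc.getModel()
    if sb is None:
        raise ValueError(f"SBML file {path} contains no model")

    model = MetabolicModel(id=sb.getId() or "model")
    for i in range(sb.getNumCompartments()):
        comp = sb.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    boundary: set[str] = set()
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = parse_formula(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        elif sp.isSetCharge():  # L2 charge attribute
            charge = sp.getCharge()
        if formula is None and sp.isSetNotes() and "massless: true" in sp.getNotesString():
            formula = {}
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        model.metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
            )
        )

    fbc = sb.getPlugin("fbc")
    param_values = {
        sb.getParameter(i).getId(): sb.getParameter(i).getValue()
        for i in range(sb.getNumParameters())
    }

    known_mets = {m.id for m in model.metabolites}
    for i in range(sb.getNumReactions()):
        sr = sb.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            sid = ref.getSpecies()
            if sid in boundary:
                continue
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            sid = ref.getSpecies()
            if sid in boundary:
                continue
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        for sid in stoich:
            if sid not in known_mets:
                raise ModelIntegrityError(
                    f"reaction {sr.getId()!r} references undeclared species {sid!r}"
                )

        lb, ub = None, None
        fbc_r = sr.getPlugin("fbc")
        if fbc_r is not None and fbc_r.isSetLowerFluxBound():
            lb = param_values.get(fbc_r.getLowerFluxBound())
            ub = param_values.get(fbc_r.getUpperFluxBound())
        elif sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
        if lb is None:
            lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        gpr = ""
        if fbc_r is not None:
            ga = fbc_r.getGeneProductAssociation()
            if ga is not None:
                gpr = _gpr_from_association(ga.getAssociation(), fbc)

        category = _category_from_notes(sr)
        if category is None:
            category = _infer_category(stoich, model, gpr, sr)
        model.reactions.append(
            Reaction(
                id=sr.getId(),
                name=sr.getName() or sr.getId(),
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_association=gpr,
                category=category,
            )
        )

    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = obj.getFluxObjective(0).getReaction()
    if model.objective_id is None:
        for r in model.reactions:
            if r.category == "biomass":
                model.objective_id = r.id
                break
    model.validate()
    return model


def _gpr_from_association(assoc, fbc_plugin) -> str:
    import libsbml

    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        gp = fbc_plugin.getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() or gp.getId() if gp is not None else assoc.getGeneProduct()
    op = "and" if assoc.isFbcAnd() else "or"
    parts = [
        _gpr_from_association(assoc.getAssociation(i), fbc_plugin)
        for i in range(assoc.getNumAssociations())
    ]
    return "(" + f" {op} ".join(parts) + ")"


_NOTES_CATEGORY = re.compile(r"category\s*:\s*([a-z]+)", re.IGNORECASE)


def _category_from_notes(sr) -> str | None:
    if not sr.isSetNotes():
        return None
    m = _NOTES_CATEGORY.search(sr.getNotesString())
    if m and m.group(1).lower() in CATEGORIES:
        return m.group(1).lower()
    return None


def _infer_category(stoich, model, gpr, sr) -> str:
    """Heuristic classification for third-party SBML without category tags."""
    if len(stoich) <= 1:
        return "exchange"
    comps = {model.metabolite(mid).compartment for mid in stoich}
    if len(comps) >= 2:
        return "transport"
    name = (sr.getName() or sr.getId()).lower()
    if "biomass" in name:
        return "biomass"
    if not gpr and ("spontaneous" in name or "non-enzymatic" in name):
        return "spontaneous"
    return "metabolic"


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 Version 1 with the fbc package."""
    import libsbml

    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(model.id)
    fbc = sb.getPlugin("fbc")
    fbc.setStrict(False)

    for cid, cname in model.compartments.items():
        comp = sb.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sb.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        fbc_sp = sp.getPlugin("fbc")
        if m.formula:
            fbc_sp.setChemicalFormula(format_formula(m.formula))
        elif m.formula == {}:
            # massless pseudo-species (photon, pmf tokens): the fbc package
            # rejects an empty chemicalFormula, so flag it in the notes
            sp.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                "<p>massless: true</p></body>"
            )
        if m.charge is not None:
            fbc_sp.setCharge(int(m.charge))

    genes = sorted(model.genes)
    for g in genes:
        gp = fbc.createGeneProduct()
        gp.setId(_sanitize_sid(g))
        gp.setLabel(g)

    params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in params:
            pid = f"fb_{len(params)}"
            p = sb.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            params[value] = pid
        return params[value]

    for r in model.reactions:
        sr = sb.createReaction()
        sr.setId(r.id)
        sr.setName(r.name)
        sr.setReversible(r.lower_bound < 0)
        sr.setFast(False)
        for mid, coef in r.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        fbc_r = sr.getPlugin("fbc")
        fbc_r.setLowerFluxBound(bound_param(r.lower_bound))
        fbc_r.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gene_association.strip():
            ga = fbc_r.createGeneProductAssociation()
            expr = re.sub(
                r"[A-Za-z0-9_.-]+",
                lambda m: m.group(0)
                if m.group(0).lower() in ("and", "or")
                else _sanitize_sid(m.group(0)),
                r.gene_association,
            )
            ga.setAssociation(expr)
        sr.setNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>category: {r.category}</p></body>"
        )

    if model.objective_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


def _sanitize_sid(gene: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", gene)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "G_" + sid
    return sid
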