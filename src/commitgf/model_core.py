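"""Data model for metabolic networks, standard-format I/O, namespace
normalization, and the LP/FBA contract used by every other module.

A model is a stoichiometric network over metabolites that live in one of two
compartments, cytosol ``"c"`` and extracellular space ``"e"`` (a periplasmic
compartment, when present in an input file, is collapsed into ``"e"`` on
translation).  Fluxes are in mmol·gDW⁻¹·h⁻¹, except the biomass reaction whose
flux is a specific growth rate in h⁻¹.  Exchange reactions follow the usual
sign convention: negative flux is uptake, positive flux is secretion, so a
growth medium is expressed as lower-bound magnitudes on exchange reactions.

Two interchange dialects are supported: SBML Level 3 with the FBC package
(via libsbml) and a JSON dialect documented in ``docs/model_json_schema.md``
whose structure mirrors the in-memory classes one-to-one.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

# ---------------------------------------------------------------------------
# Global numerical and namespace constants
# ---------------------------------------------------------------------------

#: Feasibility / optimality / "flux-carrying" tolerance used package-wide.
FLUX_EPS = 1e-6

#: Default magnitude for unconstrained flux bounds.
DEFAULT_BOUND = 1000.0

#: Canonical compartment vocabulary.
CYTOSOL = "c"
EXTRACELLULAR = "e"
BOUNDARY = "boundary"
COMPARTMENTS = (CYTOSOL, EXTRACELLULAR, BOUNDARY)

#: Canonical proton identifier and its known alias (both encode H+).
PROTON_ID = "MNXM1"
PROTON_ALIAS = "MNXM01"

KIND_INTERNAL = "internal"
KIND_TRANSPORT = "transport"
KIND_EXCHANGE = "exchange"
KIND_SINK = "sink"
KIND_BIOMASS = "biomass"
REACTION_KINDS = (KIND_INTERNAL, KIND_TRANSPORT, KIND_EXCHANGE, KIND_SINK, KIND_BIOMASS)


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed under the named dialect."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

MetKey = tuple[str, str]  # (metabolite id, compartment)


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")

    @property
    def key(self) -> MetKey:
        return (self.id, self.compartment)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[MetKey, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    ec_numbers: set[str] = field(default_factory=set)
    kind: str = KIND_INTERNAL

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound > upper_bound"
            )
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < -FLUX_EPS and self.upper_bound > FLUX_EPS

    def compartments(self) -> set[str]:
        return {c for (_, c) in self.stoichiometry}

    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            ec_numbers=set(self.ec_numbers),
            kind=self.kind,
        )


_GPR_TOKEN = re.compile(r"[()]|\band\b|\bor\b|\bAND\b|\bOR\b")


def gpr_genes(gpr: str) -> set[str]:
    """Gene identifiers appearing in a boolean gene-protein-reaction rule."""
    return {tok for tok in _GPR_TOKEN.sub(" ", gpr).split() if tok}


def infer_kind(stoichiometry: Mapping[MetKey, float], biomass: bool = False) -> str:
    """Infer a reaction's kind from its structure.

    Single extracellular/boundary metabolite -> exchange; single cytosolic
    metabolite -> sink; more than one compartment -> transport; else internal.
    """
    if biomass:
        return KIND_BIOMASS
    comps = {c for (_, c) in stoichiometry}
    if len(stoichiometry) == 1:
        comp = next(iter(comps))
        if comp in (EXTRACELLULAR, BOUNDARY):
            return KIND_EXCHANGE
        return KIND_SINK
    if len(comps - {BOUNDARY}) > 1 or BOUNDARY in comps:
        return KIND_TRANSPORT
    return KIND_INTERNAL


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[MetKey, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: set[str] = field(default_factory=set)
    biomass_id: Optional[str] = None

    # -- construction helpers ------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {met.id}: compartment {met.compartment!r} not in {COMPARTMENTS}"
            )
        self.metabolites.setdefault(met.key, met)

    def add_reaction(self, rxn: Reaction, create_missing: bool = False) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        dangling = [k for k in rxn.stoichiometry if k not in self.metabolites]
        if dangling:
            if not create_missing:
                raise ModelValidationError(
                    f"reaction {rxn.id} references undeclared metabolites: {sorted(dangling)}"
                )
            for met_id, comp in dangling:
                self.add_metabolite(Metabolite(met_id, comp))
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.genes()
        if rxn.kind == KIND_BIOMASS and self.biomass_id is None:
            self.biomass_id = rxn.id

    def remove_reaction(self, rxn_id: str) -> Reaction:
        rxn = self.reactions.pop(rxn_id)
        if self.biomass_id == rxn_id:
            self.biomass_id = None
        return rxn

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={k: replace(m) for k, m in self.metabolites.items()},
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            genes=set(self.genes),
            biomass_id=self.biomass_id,
        )

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for key in rxn.stoichiometry:
                if key not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references undeclared metabolite {key}"
                    )
        if self.biomass_id is not None:
            if self.biomass_id not in self.reactions:
                raise ModelValidationError(f"biomass_id {self.biomass_id} unresolved")
            if self.reactions[self.biomass_id].kind != KIND_BIOMASS:
                raise ModelValidationError(
                    f"biomass_id {self.biomass_id} is not a biomass reaction"
                )

    # -- views ---------------------------------------------------------------

    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def metabolite_ids(self) -> set[str]:
        return {mid for (mid, _) in self.metabolites}

    def ec_numbers(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.ec_numbers
        return out

    def exchanges_for(self, met_id: str) -> list[Reaction]:
        """Exchange reactions touching metabolite `met_id` (extracellular)."""
        return [
            r
            for r in self.reactions.values()
            if r.kind == KIND_EXCHANGE
            and any(mid == met_id for (mid, _) in r.stoichiometry)
        ]

    def stoichiometric_matrix(self) -> tuple[list[MetKey], list[str], sparse.csr_matrix]:
        """Return (metabolite keys, reaction ids, S) with S[i, j] the
        coefficient of metabolite i in reaction j (rows/cols sorted by id)."""
        met_keys = sorted(self.metabolites)
        rxn_ids = sorted(self.reactions)
        met_index = {k: i for i, k in enumerate(met_keys)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for key, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[key])
                cols.append(j)
                data.append(coef)
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(met_keys), len(rxn_ids))
        )
        return met_keys, rxn_ids, S


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
            }
            for _, m in sorted(model.metabolites.items())
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": [
                    [mid, comp, coef]
                    for (mid, comp), coef in sorted(r.stoichiometry.items())
                ],
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "ec_numbers": sorted(r.ec_numbers),
                "kind": r.kind,
            }
            for _, r in sorted(model.reactions.items())
        ],
        "genes": sorted(model.genes),
        "biomass_id": model.biomass_id,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(id=data["id"])
    for m in data.get("metabolites", []):
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                compartment=m["compartment"],
                name=m.get("name", ""),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
        )
    for r in data.get("reactions", []):
        stoich = {(mid, comp): float(coef) for mid, comp, coef in r["stoichiometry"]}
        model.add_reaction(
            Reaction(
                id=r["id"],
                stoichiometry=stoich,
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=r.get("gpr", ""),
                ec_numbers=set(r.get("ec_numbers", [])),
                kind=r.get("kind", infer_kind(stoich)),
            )
        )
    model.genes |= set(data.get("genes", []))
    model.biomass_id = data.get("biomass_id")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC dialect (libsbml)
# ---------------------------------------------------------------------------

_SBML_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sbml_id(raw: str) -> str:
    out = _SBML_BAD.sub("__", raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sbml_id(model.id))
    sm.setName(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    for comp in sorted({m.compartment for m in model.metabolites.values()} | {CYTOSOL}):
        c = sm.createCompartment()
        c.setId(_sbml_id(comp))
        c.setConstant(True)

    for key in sorted(model.metabolites):
        met = model.metabolites[key]
        sp = sm.createSpecies()
        sp.setId(_sbml_id(f"M_{met.id}_{met.compartment}"))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sbml_id(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_id(f"G_{gene}"))
        gp.setLabel(gene)

    # flux bounds as shared or per-reaction parameters
    def _param(value: float, pid: str) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        sr = sm.createReaction()
        sid = _sbml_id(f"R_{rid}")
        sr.setId(sid)
        sr.setName(rid)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_param(rxn.lower_bound, f"{sid}_lb"))
        rplug.setUpperFluxBound(_param(rxn.upper_bound, f"{sid}_ub"))
        for (mid, comp), coef in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sbml_id(f"M_{mid}_{comp}"))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(rxn.gpr)  # tokens matched against labels
        if rxn.ec_numbers:
            sr.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'><p>EC: "
                + ";".join(sorted(rxn.ec_numbers))
                + "</p></body>"
            )
    if model.biomass_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_id(f"R_{model.biomass_id}"))
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, path)


_EC_NOTE = re.compile(r"EC:\s*([^<]+)")


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ModelFormatError(
            f"SBML parse failure at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelFormatError("SBML file contains no model element")
    model = MetabolicModel(id=sm.getName() or sm.getId())

    species_key: dict[str, MetKey] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        sid = sp.getId()
        comp = sp.getCompartment()
        raw = sid
        if raw.startswith("M_"):
            raw = raw[2:]
        if raw.endswith("_" + comp):
            raw = raw[: -(len(comp) + 1)]
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        met = Metabolite(
            id=raw,
            compartment=comp,
            name=sp.getName() or raw,
            formula=formula,
            charge=charge,
        )
        model.add_metabolite(met)
        species_key[sid] = met.key

    gene_label = {}
    mplug = sm.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    biomass_sid = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            biomass_sid = obj.getFluxObjective(0).getReaction()

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[MetKey, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() not in species_key:
                raise ModelValidationError(
                    f"reaction {sr.getId()} references undeclared species {ref.getSpecies()}"
                )
            key = species_key[ref.getSpecies()]
            stoich[key] = stoich.get(key, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() not in species_key:
                raise ModelValidationError(
                    f"reaction {sr.getId()} references undeclared species {ref.getSpecies()}"
                )
            key = species_key[ref.getSpecies()]
            stoich[key] = stoich.get(key, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_BOUND
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
        gpr = ""
        if rplug is not None and rplug.getGeneProductAssociation() is not None:
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = _association_to_string(assoc, gene_label)
        ec: set[str] = set()
        if sr.isSetNotes():
            m = _EC_NOTE.search(sr.getNotesString())
            if m:
                ec = {e for e in m.group(1).strip().split(";") if e}
        rid = sr.getName() or sr.getId()
        kind = infer_kind(stoich, biomass=(sr.getId() == biomass_sid))
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                ec_numbers=ec,
                kind=kind,
            )
        )
        if sr.getId() == biomass_sid:
            model.biomass_id = rid
    model.validate()
    return model


def _association_to_string(assoc, gene_label: dict[str, str]) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return gene_label.get(gid, gid[2:] if gid.startswith("G_") else gid)
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _association_to_string(assoc.getAssociation(i), gene_label)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _association_to_string(assoc.getAssociation(i), gene_label)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    return ""


def read_model(path: str, dialect: str = "json") -> MetabolicModel:
    """Read a metabolic model from `path` under the named dialect."""
    if dialect == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"JSON parse failure at line {exc.lineno}: {exc.msg}")
        return model_from_dict(data)
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str, dialect: str = "json") -> None:
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Namespace translation and proton normalization
# ---------------------------------------------------------------------------


@dataclass
class TranslationReport:
    untranslated_metabolites: set[str] = field(default_factory=set)
    untranslated_reactions: set[str] = field(default_factory=set)
    merged_metabolites: list[tuple[str, str, str]] = field(default_factory=list)
    formula_conflicts: list[tuple[str, str, str]] = field(default_factory=list)
    duplicate_reaction_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (
            self.untranslated_metabolites
            or self.untranslated_reactions
            or self.merged_metabolites
            or self.formula_conflicts
            or self.duplicate_reaction_pairs
        )


PERIPLASM_IDS = {"p", "periplasm"}


def translate_namespace(
    model: MetabolicModel,
    met_map: Mapping[str, str],
    rxn_map: Mapping[str, str],
) -> tuple[MetabolicModel, TranslationReport]:
    """Rewrite metabolite/reaction identifiers into a common namespace.

    Metabolites that become identical after translation are merged within
    each compartment; any periplasmic compartment is relabelled
    extracellular.  Conflicting formulas between merged metabolites are
    recorded (first-seen formula kept).  Reactions that become
    stoichiometrically identical duplicates are retained (deduplication
    belongs to consensus merging) but reported.
    """
    report = TranslationReport()
    out = MetabolicModel(id=model.id, genes=set(model.genes))

    key_map: dict[MetKey, MetKey] = {}
    for key in sorted(model.metabolites):
        met = model.metabolites[key]
        comp = EXTRACELLULAR if met.compartment in PERIPLASM_IDS else met.compartment
        new_id = met_map.get(met.id)
        if new_id is None:
            new_id = met.id
            if met_map:
                report.untranslated_metabolites.add(met.id)
        new_key = (new_id, comp)
        key_map[key] = new_key
        if new_key in out.metabolites:
            existing = out.metabolites[new_key]
            if new_id != met.id or comp != met.compartment:
                report.merged_metabolites.append((met.id, existing.id, comp))
            if met.formula and existing.formula and met.formula != existing.formula:
                report.formula_conflicts.append((new_id, existing.formula, met.formula))
        else:
            out.add_metabolite(
                Metabolite(new_id, comp, met.name, met.formula, met.charge)
            )

    seen_stoich: dict[tuple, str] = {}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        new_id = rxn_map.get(rid)
        if new_id is None:
            new_id = rid
            if rxn_map:
                report.untranslated_reactions.add(rid)
        stoich: dict[MetKey, float] = {}
        for key, coef in rxn.stoichiometry.items():
            new_key = key_map[key]
            stoich[new_key] = stoich.get(new_key, 0.0) + coef
        stoich = {k: v for k, v in stoich.items() if abs(v) > 1e-12}
        new_rxn = rxn.copy()
        new_rxn.id = new_id
        if new_rxn.id in out.reactions:
            new_rxn.id = f"{new_id}__dup{rid}"
        new_rxn.stoichiometry = stoich
        canon = tuple(sorted(stoich.items()))
        if canon in seen_stoich:
            report.duplicate_reaction_pairs.append((seen_stoich[canon], new_rxn.id))
        else:
            seen_stoich[canon] = new_rxn.id
        out.add_reaction(new_rxn)
    out.biomass_id = model.biomass_id if model.biomass_id in out.reactions else None
    return out, report


def normalize_protons(
    model: MetabolicModel, alias: str = PROTON_ALIAS, canonical: str = PROTON_ID
) -> MetabolicModel:
    """Replace the proton alias id with the canonical id, merging duplicates."""
    out = MetabolicModel(id=model.id, genes=set(model.genes))
    for key in sorted(model.metabolites):
        met = model.metabolites[key]
        mid = canonical if met.id == alias else met.id
        if (mid, met.compartment) not in out.metabolites:
            out.add_metabolite(
                Metabolite(mid, met.compartment, met.name, met.formula, met.charge)
            )
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid].copy()
        stoich: dict[MetKey, float] = {}
        for (mid, comp), coef in rxn.stoichiometry.items():
            if mid == alias:
                mid = canonical
            stoich[(mid, comp)] = stoich.get((mid, comp), 0.0) + coef
        rxn.stoichiometry = {k: v for k, v in stoich.items() if abs(v) > 1e-12}
        out.add_reaction(rxn)
    out.biomass_id = model.biomass_id
    return out


def normalize_stoichiometry(stoich: Mapping[MetKey, float], alias: str = PROTON_ALIAS,
                            canonical: str = PROTON_ID) -> dict[MetKey, float]:
    """Proton-alias normalization for a bare stoichiometry map."""
    out: dict[MetKey, float] = {}
    for (mid, comp), coef in stoich.items():
        if mid == alias:
            mid = canonical
        key = (mid, comp)
        out[key] = out.get(key, 0.0) + coef
    return {k: v for k, v in out.items() if abs(v) > 1e-12}


# ---------------------------------------------------------------------------
# LP / FBA contract
# ---------------------------------------------------------------------------


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]
    v_bio: Optional[float] = None


_LP_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    model: MetabolicModel,
    objective: Mapping[str, float],
    extra_bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    minimize_one_norm: bool = False,
) -> FluxResult:
    """Maximize `objective` (a reaction-id -> coefficient map) subject to
    S·v = 0 and flux bounds.

    When ``minimize_one_norm`` is set, a second LP minimizes Σ|v| while
    holding the primary objective at its optimum (relative tolerance 1e-6),
    which suppresses futile cycles.  Infeasibility and unboundedness are
    reported in the result status, never raised.
    """
    unknown = [r for r in objective if r not in model.reactions]
    if unknown:
        raise KeyError(f"objective references unknown reactions: {unknown}")

    met_keys, rxn_ids, S = model.stoichiometric_matrix()
    n = len(rxn_ids)
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    bounds = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if extra_bounds and rid in extra_bounds:
            lb, ub = extra_bounds[rid]
        bounds.append((lb, ub))
    c = np.zeros(n)
    for rid, coef in objective.items():
        c[idx[rid]] = -coef  # linprog minimizes

    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    status = _LP_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxResult(status=status, objective_value=float("nan"), fluxes={})
    opt = -res.fun
    fluxes = {rid: float(res.x[idx[rid]]) for rid in rxn_ids}

    if minimize_one_norm:
        fluxes, opt = _one_norm_stage(model, rxn_ids, S, bounds, c, opt)

    v_bio = fluxes.get(model.biomass_id) if model.biomass_id else None
    # conservation check: componentwise |S v| within tolerance
    v = np.array([fluxes[rid] for rid in rxn_ids])
    resid = np.abs(S.dot(v)).max() if n else 0.0
    if resid > 1e-5:
        return FluxResult(status="infeasible", objective_value=float("nan"), fluxes={})
    return FluxResult(status="optimal", objective_value=float(opt), fluxes=fluxes, v_bio=v_bio)


def _one_norm_stage(model, rxn_ids, S, bounds, c, opt):
    """Minimize Σ|v| subject to S·v = 0, bounds, and c·v at its optimum."""
    n = len(rxn_ids)
    # split v = p - q with p, q >= 0
    split_bounds = []
    for lb, ub in bounds:
        if lb >= 0:
            split_bounds.append(((lb, ub), (0.0, 0.0)))
        elif ub <= 0:
            split_bounds.append(((0.0, 0.0), (-ub, -lb)))
        else:
            split_bounds.append(((0.0, ub), (0.0, -lb)))
    p_bounds = [b[0] for b in split_bounds]
    q_bounds = [b[1] for b in split_bounds]
    A_eq = sparse.hstack([S, -S]).tocsr()
    b_eq = np.zeros(S.shape[0])
    # keep primary objective: (-c)·v >= opt - tol  ->  c·(p - q) <= -opt + tol
    tol = 1e-6 * max(1.0, abs(opt))
    A_ub = sparse.hstack(
        [sparse.csr_matrix(c.reshape(1, -1)), sparse.csr_matrix(-c.reshape(1, -1))]
    )
    b_ub = np.array([-opt + tol])
    cost = np.ones(2 * n)
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=p_bounds + q_bounds,
        method="highs",
    )
    if res.status != 0:  # fall back to the stage-1 solution
        raise RuntimeError("one-norm stage unexpectedly failed")
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v[j]) for j, rid in enumerate(rxn_ids)}
    achieved = -float(np.dot(c, v))
    return fluxes, achieved


def fba(model: MetabolicModel, minimize_one_norm: bool = False,
        extra_bounds: Optional[Mapping[str, tuple[float, float]]] = None) -> FluxResult:
    """Flux balance analysis: maximize the biomass reaction."""
    if model.biomass_id is None:
        raise ModelValidationError(f"model {model.id} has no biomass reaction")
    return solve_lp(
        model,
        {model.biomass_id: 1.0},
        extra_bounds=extra_bounds,
        minimize_one_norm=minimize_one_norm,
    )


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------


def apply_medium(
    model: MetabolicModel, medium: Mapping[str, float]
) -> tuple[MetabolicModel, list[str]]:
    """Return a copy of `model` whose exchange lower bounds realize `medium`
    (metabolite id -> maximal uptake rate).

    Exchanges for medium metabolites get lower bound −uptake; all other
    exchanges are closed for uptake (lower bound 0) while secretion stays
    open.  Exchange reactions are created for medium metabolites that lack
    one; the list of created exchange ids is returned alongside.
    """
    out = model.copy()
    created: list[str] = []
    for rxn in out.reactions.values():
        if rxn.kind != KIND_EXCHANGE:
            continue
        ((mid, _),) = rxn.stoichiometry.keys()
        uptake = medium.get(mid)
        rxn.lower_bound = -abs(uptake) if uptake is not None else 0.0
        rxn.upper_bound = max(rxn.upper_bound, 0.0)
    for mid in sorted(medium):
        if out.exchanges_for(mid):
            continue
        key = (mid, EXTRACELLULAR)
        if key not in out.metabolites:
            out.add_metabolite(Metabolite(mid, EXTRACELLULAR))
        ex_id = f"EX_{mid}"
        if ex_id in out.reactions:
            ex_id = f"EX_{mid}_med"
        out.add_reaction(
            Reaction(
                id=ex_id,
                stoichiometry={key: -1.0},
                lower_bound=-abs(medium[mid]),
                upper_bound=DEFAULT_BOUND,
                kind=KIND_EXCHANGE,
            )
        )
        created.append(ex_id)
    return out, created


def read_medium(path: str) -> dict[str, float]:
    """Read a medium TSV (metabolite_id, max_uptake)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_medium(medium: Mapping[str, float], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(medium.items()), columns=["metabolite_id", "max_uptake"]
    ).to_csv(path, sep="\t", index=False)


def read_id_map(path: str) -> dict[str, str]:
    """Read an identifier map TSV (source_id, target_id)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    src = df.iloc[:, 0].astype(str)
    if src.duplicated().any():
        dups = sorted(src[src.duplicated()].unique())
        raise ModelValidationError(f"id map has duplicate source keys: {dups}")
    return dict(zip(src, df.iloc[:, 1].astype(str)))
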