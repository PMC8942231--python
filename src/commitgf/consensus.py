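"""Merging several draft reconstructions of one organism into a consensus.

Drafts produced by different reconstruction pipelines overlap only partially
once translated into a common namespace.  Metabolites are deduplicated by
(identifier, compartment); reactions are matched by cosine similarity of
their stoichiometric vectors, which recognizes duplicates that run in the
opposite direction, lack protons, or whose coefficients differ by a common
factor.  Matched reactions are unified with permissive direction/reversibility
(reversible wins), OR-combined gene rules, and a preference for the
mass-balanced variant when stoichiometries conflict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .model_core import (
    CYTOSOL,
    DEFAULT_BOUND,
    KIND_BIOMASS,
    KIND_EXCHANGE,
    KIND_SINK,
    MetKey,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    PROTON_ID,
    Reaction,
    normalize_stoichiometry,
)

COSINE_TOL = 1e-9
#: Default match threshold: exact up to protons / scale / sign.
DEFAULT_COSINE_THRESHOLD = 1.0 - 1e-9

RELATION_IDENTICAL = "identical"
RELATION_REVERSED = "reversed"
RELATION_SCALED = "scaled"
RELATION_PROTON_VARIANT = "proton_variant"
RELATION_DISTINCT = "distinct"


@dataclass
class ReactionMatch:
    rxn_a: str
    rxn_b: str
    cosine: float
    relation: str
    mass_balance_agreement: Optional[bool] = None
    reversibility_agreement: Optional[bool] = None
    direction_agreement: Optional[bool] = None
    protonation_agreement: Optional[bool] = None


@dataclass
class ConsensusReport:
    source_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    merges: list[ReactionMatch] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Boundary stripping
# ---------------------------------------------------------------------------

_STRIP_KINDS = {KIND_EXCHANGE, KIND_SINK, KIND_BIOMASS}


def strip_boundary(model: MetabolicModel) -> MetabolicModel:
    """Remove exchange, sink, and biomass reactions (idempotent)."""
    out = model.copy()
    for rid in [r for r, rxn in out.reactions.items() if rxn.kind in _STRIP_KINDS]:
        out.remove_reaction(rid)
    out.biomass_id = None
    return out


# ---------------------------------------------------------------------------
# Cosine similarity of stoichiometric vectors
# ---------------------------------------------------------------------------


def _vectorize(stoich: Mapping[MetKey, float], drop_protons: bool) -> dict[MetKey, float]:
    if drop_protons:
        return {k: v for k, v in stoich.items() if k[0] != PROTON_ID}
    return dict(stoich)


def cosine_similarity(rxn_a: Reaction, rxn_b: Reaction, ignore_protons: bool = False) -> float:
    """Cosine of the two stoichiometric vectors over the union of
    (metabolite, compartment) keys; in [-1, 1]."""
    a = _vectorize(normalize_stoichiometry(rxn_a.stoichiometry), ignore_protons)
    b = _vectorize(normalize_stoichiometry(rxn_b.stoichiometry), ignore_protons)
    if not a or not b:
        raise ValueError(
            f"cosine undefined: reaction empty after proton removal "
            f"({rxn_a.id} vs {rxn_b.id})"
        )
    keys = sorted(set(a) | set(b))
    va = np.array([a.get(k, 0.0) for k in keys])
    vb = np.array([b.get(k, 0.0) for k in keys])
    return float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))


def match_reactions(rxn_a: Reaction, rxn_b: Reaction,
                    threshold: float = DEFAULT_COSINE_THRESHOLD) -> ReactionMatch:
    """Classify the structural relation between two reactions."""
    try:
        cos_strict = cosine_similarity(rxn_a, rxn_b, ignore_protons=False)
    except ValueError:
        cos_strict = 0.0
    try:
        cos_np = cosine_similarity(rxn_a, rxn_b, ignore_protons=True)
    except ValueError:
        cos_np = cos_strict

    a = normalize_stoichiometry(rxn_a.stoichiometry)
    b = normalize_stoichiometry(rxn_b.stoichiometry)
    same_protons = {k: v for k, v in a.items() if k[0] == PROTON_ID} == {
        k: v for k, v in b.items() if k[0] == PROTON_ID
    }
    if abs(cos_strict - 1.0) <= COSINE_TOL:
        relation = RELATION_IDENTICAL if a == b else RELATION_SCALED
        cosine = cos_strict
    elif abs(cos_strict + 1.0) <= COSINE_TOL:
        relation = RELATION_REVERSED
        cosine = cos_strict
    elif abs(abs(cos_np) - 1.0) <= COSINE_TOL:
        relation = RELATION_PROTON_VARIANT
        cosine = cos_np
    else:
        relation = RELATION_DISTINCT
        cosine = cos_strict
    return ReactionMatch(
        rxn_a=rxn_a.id,
        rxn_b=rxn_b.id,
        cosine=cosine,
        relation=relation,
        reversibility_agreement=rxn_a.reversible == rxn_b.reversible,
        direction_agreement=cosine >= 0,
        protonation_agreement=same_protons,
    )


# ---------------------------------------------------------------------------
# Mass balance from chemical formulas
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for elem, count in _ELEMENT.findall(formula):
        out[elem] = out.get(elem, 0) + (int(count) if count else 1)
    return out


def is_mass_balanced(rxn: Reaction, model: MetabolicModel) -> Optional[bool]:
    """True/False if all metabolite formulas are known, None otherwise."""
    totals: dict[str, float] = {}
    for key, coef in rxn.stoichiometry.items():
        met = model.metabolites.get(key)
        if met is None or not met.formula:
            return None
        for elem, count in parse_formula(met.formula).items():
            totals[elem] = totals.get(elem, 0.0) + coef * count
    return all(abs(v) < 1e-9 for v in totals.values())


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def _or_gpr(a: str, b: str) -> str:
    if not a:
        return b
    if not b or a == b:
        return a
    return f"({a}) or ({b})"


def _coeff_score(stoich: Mapping[MetKey, float]) -> float:
    """Smaller means more canonical (smallest integer-like coefficients)."""
    coefs = np.abs(np.array(list(stoich.values())))
    return float(coefs.sum() / coefs.min())


def _unify(existing: Reaction, incoming: Reaction, match: ReactionMatch,
           consensus: MetabolicModel, donor: MetabolicModel,
           report: ConsensusReport) -> None:
    """Fold `incoming` into `existing` in place (permissive union)."""
    inc = incoming.copy()
    if match.cosine < 0:  # align directions: flip the incoming reaction
        inc.stoichiometry = {k: -v for k, v in inc.stoichiometry.items()}
        inc.lower_bound, inc.upper_bound = -incoming.upper_bound, -incoming.lower_bound

    bal_existing = is_mass_balanced(existing, consensus)
    bal_incoming = is_mass_balanced(inc, donor)
    match.mass_balance_agreement = (
        None if bal_existing is None or bal_incoming is None
        else bal_existing == bal_incoming
    )
    exist_stoich = normalize_stoichiometry(existing.stoichiometry)
    inc_stoich = normalize_stoichiometry(inc.stoichiometry)
    if exist_stoich != inc_stoich:
        # prefer the mass-balanced variant; otherwise the one with the
        # smallest integer-like coefficients; ties keep the existing one
        take_incoming = False
        if bal_incoming and bal_existing is False:
            take_incoming = True
        elif bal_existing and bal_incoming is False:
            take_incoming = False
        elif _coeff_score(inc_stoich) < _coeff_score(exist_stoich) - 1e-12:
            take_incoming = True
        if take_incoming:
            for met_id, comp in inc_stoich:
                if (met_id, comp) not in consensus.metabolites:
                    src = donor.metabolites.get((met_id, comp))
                    consensus.add_metabolite(
                        src if src is not None else Metabolite(met_id, comp)
                    )
            existing.stoichiometry = inc_stoich
        report.conflicts.append(
            f"{existing.id}: stoichiometry variants differ "
            f"({match.relation}); kept {'incoming' if take_incoming else 'existing'}"
        )
    existing.lower_bound = min(existing.lower_bound, inc.lower_bound)
    existing.upper_bound = max(existing.upper_bound, inc.upper_bound)
    existing.gpr = _or_gpr(existing.gpr, inc.gpr)
    existing.ec_numbers |= inc.ec_numbers


def merge_drafts(
    drafts: Sequence[MetabolicModel],
    cosine_threshold: float = DEFAULT_COSINE_THRESHOLD,
) -> tuple[MetabolicModel, ConsensusReport]:
    """Merge ≥2 boundary-stripped drafts (common namespace) into a consensus.

    Drafts are folded pairwise in input order; within a draft, reactions are
    visited in sorted-id order so the outcome is reproducible.  A reaction is
    unified with a consensus reaction when the proton-insensitive |cosine|
    meets `cosine_threshold`; the unified reaction takes the permissive
    direction union and the OR of the source gene rules.
    """
    if len(drafts) < 2:
        raise ValueError("merge_drafts requires at least two drafts")
    report = ConsensusReport()
    for d in drafts:
        report.source_counts[d.id] = {
            "reactions": len(d.reactions),
            "metabolites": len(d.metabolites),
            "genes": len(d.genes),
        }

    consensus = drafts[0].copy()
    consensus.id = "consensus_" + "_".join(d.id for d in drafts)
    for donor in drafts[1:]:
        for key in sorted(donor.metabolites):
            if key not in consensus.metabolites:
                consensus.add_metabolite(donor.metabolites[key])
        for rid in sorted(donor.reactions):
            incoming = donor.reactions[rid]
            best: Optional[ReactionMatch] = None
            best_target: Optional[Reaction] = None
            for cid in sorted(consensus.reactions):
                cand = consensus.reactions[cid]
                m = match_reactions(cand, incoming)
                if abs(m.cosine) >= cosine_threshold and (
                    best is None or abs(m.cosine) > abs(best.cosine)
                ):
                    best, best_target = m, cand
            if best is not None and best_target is not None:
                _unify(best_target, incoming, best, consensus, donor, report)
                report.merges.append(best)
            else:
                new_rxn = incoming.copy()
                if new_rxn.id in consensus.reactions:
                    new_rxn.id = f"{rid}__{donor.id}"
                    report.conflicts.append(
                        f"id collision for {rid}: distinct stoichiometry, "
                        f"renamed to {new_rxn.id}"
                    )
                consensus.add_reaction(new_rxn, create_missing=True)
        consensus.genes |= donor.genes
    return consensus, report


# ---------------------------------------------------------------------------
# Universal biomass and reference scoring
# ---------------------------------------------------------------------------


def add_universal_biomass(
    model: MetabolicModel,
    biomass_spec: Mapping[str, float],
    biomass_id: str = "BIOMASS",
) -> MetabolicModel:
    """Append one biomass reaction with the given stoichiometry
    (metabolite id -> coefficient, negative = consumed).

    Precursors absent from the model are added as cytosolic species.
    """
    if not biomass_spec:
        raise ValueError("empty biomass specification rejected")
    if model.biomass_id is not None:
        raise ValueError(f"model {model.id} already has a biomass reaction")
    out = model.copy()
    stoich: dict[MetKey, float] = {}
    for mid in sorted(biomass_spec):
        key = (mid, CYTOSOL)
        if key not in out.metabolites:
            out.add_metabolite(Metabolite(mid, CYTOSOL))
        stoich[key] = float(biomass_spec[mid])
    out.add_reaction(
        Reaction(
            id=biomass_id,
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            kind=KIND_BIOMASS,
        )
    )
    out.biomass_id = biomass_id
    return out


def read_biomass_spec(path: str) -> dict[str, float]:
    """Read a biomass spec TSV (metabolite_id, coefficient)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def reference_similarity(
    model: MetabolicModel,
    reference: MetabolicModel,
    feature: str = "metabolites",
) -> tuple[float, float]:
    """(sensitivity, precision) of the model's feature set against a
    manually curated reference.

    TP = shared features, FP = model-only, FN = reference-only; true
    negatives are unknowable, so only these two scores are defined.
    """
    if feature == "metabolites":
        fm, fr = model.metabolite_ids(), reference.metabolite_ids()
    elif feature == "ec_numbers":
        fm, fr = model.ec_numbers(), reference.ec_numbers()
    else:
        raise ValueError(f"unknown feature {feature!r}")
    if not fr:
        raise ValueError(f"reference feature set {feature!r} is empty")
    tp = len(fm & fr)
    fp = len(fm - fr)
    fn = len(fr - fm)
    sensitivity = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return sensitivity, precision
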