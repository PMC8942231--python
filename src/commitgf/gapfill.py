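"""Weighted-LP gap filling of a single metabolic model against a universal
candidate-reaction database, plus the post-hoc secretion LP.

The candidate pool is the chemically balanced part of a universal reaction
database, cleaned of boundary-touching reactions, reactions in generic
(untranslatable) compartments, and reactions with stoichiometric
coefficients above 20.  Each candidate receives a category cost — transport
100, non-transport (metabolic) 50, transport of a highly permeable
metabolite 50, sequence-evidenced 25, reversing an existing model reaction
25, uptake of a community-secreted metabolite 1, exchange 10⁵ — and the
gap-filling LP maximizes

    α · v_bio − Σᵢ costᵢ · |vᵢ|

over the merged network (candidate fluxes split into forward/backward parts
so |vᵢ| is linear), scanning α upward by doubling until the biomass flux
reaches its lower limit.  Candidates carrying flux form the raw solution,
which a greedy pass then prunes to local minimality.  Secretion capability
is assessed afterwards by maximizing the summed flux of temporary sink
reactions while biomass stays within a factor f of its optimum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model_core import (
    BOUNDARY,
    CYTOSOL,
    DEFAULT_BOUND,
    EXTRACELLULAR,
    FLUX_EPS,
    KIND_EXCHANGE,
    KIND_TRANSPORT,
    MetKey,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_medium,
    fba,
    infer_kind,
    normalize_stoichiometry,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class WeightConfig:
    """Gap-filling weights and biomass/secretion parameters.

    Costs are per unit flux through an added candidate; the biomass upper
    limit (2.81 h⁻¹, the growth rate of very fast growing bacteria) keeps
    the LP from pushing biomass to the generic flux bound, and the lower
    limit (10⁻³ h⁻¹, the slow end of soil microbes) defines "functional".
    """

    transport: float = 100.0
    metabolic: float = 50.0
    reverse_direction: float = 25.0
    permeable_transport: float = 50.0
    sequence_evidence: float = 25.0
    uptake_secreted: float = 1.0
    exchange: float = 1e5
    biomass_ub: float = 2.81
    biomass_lb: float = 1e-3
    secretion_factor: float = 0.9  # f: tolerated growth reduction is 10%
    growth_reduction_threshold: float = 0.10
    evidence_evalue_cutoff: float = 1e-6
    # α-scan schedule for the weighted gap-filling LP
    alpha_start: float = 1.0
    alpha_factor: float = 2.0
    alpha_max: float = 1e6
    candidate_bound: float = 1000.0
    sink_cost: float = 0.0  # weight of candidate sinks in in-objective mode
    flux_eps: float = FLUX_EPS

    def __post_init__(self) -> None:
        if not (0 < self.secretion_factor <= 1):
            raise ValueError("secretion factor f must be in (0, 1]")
        if not (0 < self.biomass_lb < self.biomass_ub):
            raise ValueError("need 0 < biomass_lb < biomass_ub")
        for name in ("transport", "metabolic", "reverse_direction",
                     "permeable_transport", "sequence_evidence",
                     "uptake_secreted", "exchange"):
            if getattr(self, name) <= 0:
                raise ValueError(f"weight {name} must be positive")


# categories, for reporting
CAT_TRANSPORT = "transport"
CAT_METABOLIC = "metabolic"
CAT_PERMEABLE_TRANSPORT = "permeable_transport"
CAT_SEQUENCE = "sequence_evidence"
CAT_UPTAKE_SECRETED = "uptake_secreted"
CAT_EXCHANGE = "exchange"
CAT_REVERSE = "reverse_direction"

MAX_STOICH_COEF = 20.0


# ---------------------------------------------------------------------------
# Database preparation
# ---------------------------------------------------------------------------


@dataclass
class GapFillDatabase:
    reactions: dict[str, Reaction] = field(default_factory=dict)
    permeable_transport_ids: set[str] = field(default_factory=set)
    drop_report: dict[str, int] = field(default_factory=dict)
    costs: dict[str, tuple[str, float]] = field(default_factory=dict)

    def extracellular_metabolites(self) -> set[str]:
        out = set()
        for rxn in self.reactions.values():
            out |= {mid for (mid, c) in rxn.stoichiometry if c == EXTRACELLULAR}
        return out


_TERM = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+?)@(\S+)\s*$")


def parse_equation(equation: str) -> tuple[dict[MetKey, float], bool]:
    """Parse an equation string like ``"2 A@c + B@c = C@e"``.

    ``=`` separates sides of a reversible reaction, ``-->`` of an
    irreversible one.  Compartment tokens are kept verbatim (validation of
    the compartment vocabulary happens in :func:`prepare_database`).
    Returns (stoichiometry, reversible).
    """
    if "-->" in equation:
        lhs, rhs = equation.split("-->", 1)
        reversible = False
    elif "=" in equation:
        lhs, rhs = equation.split("=", 1)
        reversible = True
    else:
        raise ValueError(f"equation lacks a '=' or '-->' separator: {equation!r}")
    stoich: dict[MetKey, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM.match(term)
            if m is None:
                raise ValueError(f"cannot parse equation term {term!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            key = (m.group(2), m.group(3))
            stoich[key] = stoich.get(key, 0.0) + sign * coef
    return {k: v for k, v in stoich.items() if abs(v) > 1e-12}, reversible


_BOUNDARY_TOKENS = {BOUNDARY, "BOUNDARY", "@BOUNDARY"}
_ALLOWED_COMPARTMENTS = {CYTOSOL, EXTRACELLULAR}


def prepare_database(
    raw: pd.DataFrame,
    candidate_bound: float = 1000.0,
) -> GapFillDatabase:
    """Build the candidate pool from a raw reaction table.

    Expected columns: ``id``, ``equation``, ``balanced`` (boolean flag);
    optional ``ec``.  Exclusion rules, applied in order and counted in the
    drop report: unbalanced; touches the boundary pseudo-compartment;
    touches a generic compartment (anything other than cytosol or
    extracellular); any |coefficient| above 20.  The proton alias is
    normalized before the coefficient check.
    """
    db = GapFillDatabase()
    report = {"unbalanced": 0, "boundary": 0, "generic_compartment": 0,
              "coefficient": 0, "kept": 0}
    for _, row in raw.iterrows():
        rid = str(row["id"])
        stoich, reversible = parse_equation(str(row["equation"]))
        balanced = row["balanced"]
        if isinstance(balanced, str):
            balanced = balanced.strip().upper() in {"T", "TRUE", "1", "B"}
        if not bool(balanced):
            report["unbalanced"] += 1
            continue
        comps = {c for (_, c) in stoich}
        if comps & _BOUNDARY_TOKENS:
            report["boundary"] += 1
            continue
        if comps - _ALLOWED_COMPARTMENTS:
            report["generic_compartment"] += 1
            continue
        stoich = normalize_stoichiometry(stoich)
        if any(abs(c) > MAX_STOICH_COEF for c in stoich.values()):
            report["coefficient"] += 1
            continue
        ec = set()
        if "ec" in raw.columns and isinstance(row.get("ec"), str) and row["ec"]:
            ec = {e for e in row["ec"].split(";") if e}
        db.reactions[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=-candidate_bound if reversible else 0.0,
            upper_bound=candidate_bound,
            ec_numbers=ec,
            kind=infer_kind(stoich),
        )
        report["kept"] += 1
    db.drop_report = report
    return db


def read_database(path: str, candidate_bound: float = 1000.0) -> GapFillDatabase:
    """Read a database TSV (id, equation, balanced[, ec])."""
    return prepare_database(pd.read_csv(path, sep="\t"), candidate_bound)


# ---------------------------------------------------------------------------
# Evidence and cost resolution
# ---------------------------------------------------------------------------


def read_evidence(path: str) -> dict[tuple[str, str], float]:
    """Read a sequence-evidence TSV (model_id, reaction_id, evalue)."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.iloc[0]), str(r.iloc[1])): float(r.iloc[2]) for _, r in df.iterrows()
    }


def resolve_costs(
    db: GapFillDatabase,
    model_id: str,
    evidence: Mapping[tuple[str, str], float],
    permeable_ids: set[str],
    secreted_pool: set[str],
    config: WeightConfig,
) -> GapFillDatabase:
    """Assign each candidate the minimum applicable category cost.

    Exchange reactions cost `exchange`, except uptake of a metabolite
    secreted by already gap-filled community members, which costs
    `uptake_secreted`.  Transport reactions cost `transport`, reduced to
    `permeable_transport` when they carry a permeable metabolite.  Other
    reactions cost `metabolic`.  Sequence evidence at or below the E-value
    cutoff reduces any non-exchange reaction to `sequence_evidence`.
    """
    from .permeability import annotate_transport_permeability

    out = replace(db, costs={},
                  permeable_transport_ids=annotate_transport_permeability(db, permeable_ids))
    for rid, rxn in db.reactions.items():
        if rxn.kind == KIND_EXCHANGE:
            ((mid, _),) = rxn.stoichiometry.keys()
            if mid in secreted_pool:
                cat, cost = CAT_UPTAKE_SECRETED, config.uptake_secreted
            else:
                cat, cost = CAT_EXCHANGE, config.exchange
        elif rxn.kind == KIND_TRANSPORT:
            if rid in out.permeable_transport_ids:
                cat, cost = CAT_PERMEABLE_TRANSPORT, config.permeable_transport
            else:
                cat, cost = CAT_TRANSPORT, config.transport
        else:
            cat, cost = CAT_METABOLIC, config.metabolic
        if rxn.kind != KIND_EXCHANGE:
            ev = evidence.get((model_id, rid))
            if ev is not None and ev <= config.evidence_evalue_cutoff:
                if config.sequence_evidence < cost:
                    cat, cost = CAT_SEQUENCE, config.sequence_evidence
        out.costs[rid] = (cat, cost)
    return out


def pool_uptake_candidates(
    pool: set[str], config: WeightConfig
) -> tuple[dict[str, Reaction], dict[str, tuple[str, float]]]:
    """Uptake candidates (exchange + e→c transport, cost `uptake_secreted`
    each) for every metabolite in the accumulated community-secreted pool."""
    rxns: dict[str, Reaction] = {}
    costs: dict[str, tuple[str, float]] = {}
    for mid in sorted(pool):
        ex_id, tr_id = f"EXpool_{mid}", f"TRpool_{mid}"
        rxns[ex_id] = Reaction(
            id=ex_id,
            stoichiometry={(mid, EXTRACELLULAR): -1.0},
            lower_bound=-config.candidate_bound,
            upper_bound=config.candidate_bound,
            kind=KIND_EXCHANGE,
        )
        rxns[tr_id] = Reaction(
            id=tr_id,
            stoichiometry={(mid, EXTRACELLULAR): -1.0, (mid, CYTOSOL): 1.0},
            lower_bound=-config.candidate_bound,
            upper_bound=config.candidate_bound,
            kind=KIND_TRANSPORT,
        )
        costs[ex_id] = (CAT_UPTAKE_SECRETED, config.uptake_secreted)
        costs[tr_id] = (CAT_UPTAKE_SECRETED, config.uptake_secreted)
    return rxns, costs


# ---------------------------------------------------------------------------
# Gap-filling LP
# ---------------------------------------------------------------------------


@dataclass
class GapFillSolution:
    model_id: str
    added_reactions: dict[str, tuple[str, float]]  # id -> (category, cost)
    reversed_reactions: set[str]
    v_bio: float
    secreted: set[str]
    imported: set[str]
    medium: dict[str, float]
    model: MetabolicModel
    status: str = "ok"
    blocked_precursors: set[str] = field(default_factory=set)

    @property
    def n_added(self) -> int:
        return len(self.added_reactions)

    @property
    def total_cost(self) -> float:
        return sum(c for (_, c) in self.added_reactions.values())


class GapFillError(RuntimeError):
    pass


def _merge_lp(model, candidates, costs, config, alpha):
    """Build and solve max α·v_bio − Σ cost·(f+b) over model ∪ candidates."""
    met_keys = sorted(
        set(model.metabolites)
        | {k for r in candidates.values() for k in r.stoichiometry}
    )
    met_index = {k: i for i, k in enumerate(met_keys)}
    model_ids = sorted(model.reactions)
    cand_ids = sorted(candidates)

    cols, bounds, obj = [], [], []
    var_names: list[tuple[str, str]] = []  # (kind, rxn id) kind in {m, f, b}
    for rid in model_ids:
        rxn = model.reactions[rid]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rid == model.biomass_id:
            lb, ub = 0.0, min(ub, config.biomass_ub)
        cols.append(rxn.stoichiometry)
        bounds.append((lb, ub))
        obj.append(alpha if rid == model.biomass_id else 0.0)
        var_names.append(("m", rid))
    for rid in cand_ids:
        rxn = candidates[rid]
        cost = costs[rid][1]
        cols.append(rxn.stoichiometry)
        bounds.append((0.0, min(rxn.upper_bound, config.candidate_bound)))
        obj.append(-cost)
        var_names.append(("f", rid))
        if rxn.lower_bound < 0:
            cols.append({k: -v for k, v in rxn.stoichiometry.items()})
            bounds.append((0.0, min(-rxn.lower_bound, config.candidate_bound)))
            obj.append(-cost)
            var_names.append(("b", rid))

    rows, ccols, data = [], [], []
    for j, stoich in enumerate(cols):
        for key, coef in stoich.items():
            rows.append(met_index[key])
            ccols.append(j)
            data.append(coef)
    A = sparse.csr_matrix((data, (rows, ccols)), shape=(len(met_keys), len(cols)))
    res = linprog(
        -np.array(obj), A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return None, var_names
    return res.x, var_names


def _growth(model: MetabolicModel, config: WeightConfig) -> float:
    """Optimal biomass flux with the biomass LP cap applied; 0 on failure."""
    bid = model.biomass_id
    cap = {bid: (0.0, min(model.reactions[bid].upper_bound, config.biomass_ub))}
    res = fba(model, extra_bounds=cap)
    return res.objective_value if res.status == "optimal" else 0.0


def _blocked_precursors(model: MetabolicModel, candidates, config) -> set[str]:
    """Biomass precursors unproducible even with every candidate open."""
    full = model.copy()
    for rid, rxn in candidates.items():
        if rid not in full.reactions:
            full.add_reaction(rxn.copy(), create_missing=True)
    blocked = set()
    bid = full.biomass_id
    precursors = [
        key for key, coef in full.reactions[bid].stoichiometry.items() if coef < 0
    ]
    for key in precursors:
        sink_id = "SINKTEST"
        probe = full.copy()
        probe.add_reaction(
            Reaction(sink_id, {key: -1.0}, 0.0, DEFAULT_BOUND, kind="sink")
        )
        from .model_core import solve_lp

        res = solve_lp(probe, {sink_id: 1.0})
        if res.status != "optimal" or res.objective_value < config.flux_eps:
            blocked.add(key[0])
    return blocked


def fast_gap_fill(
    model: MetabolicModel,
    db: GapFillDatabase,
    medium: Mapping[str, float],
    config: WeightConfig = WeightConfig(),
    extra_candidates: Optional[dict[str, Reaction]] = None,
    extra_costs: Optional[dict[str, tuple[str, float]]] = None,
) -> GapFillSolution:
    """Gap fill one model on a medium against a cost-resolved database.

    Scans the biomass weight α upward (doubling from `alpha_start`, capped
    at `alpha_max`) until the LP solution grows at ≥ `biomass_lb`; flux-
    carrying candidates are added, direction reversals applied, and the
    solution greedily pruned in decreasing cost order.  If no α achieves
    growth, the result reports the biomass precursors that stay blocked
    even with the full candidate pool open.
    """
    if model.biomass_id is None:
        raise GapFillError(f"model {model.id} has no biomass reaction")
    if not medium:
        raise GapFillError("gap filling requires a nonempty medium")
    if not db.costs:
        raise GapFillError("database has no resolved costs; run resolve_costs first")

    base, medium_added = apply_medium(model, medium)

    candidates: dict[str, Reaction] = {}
    costs: dict[str, tuple[str, float]] = {}
    for rid, rxn in db.reactions.items():
        if rid in base.reactions:
            continue
        candidates[rid] = rxn
        costs[rid] = db.costs[rid]
    if extra_candidates:
        for rid, rxn in extra_candidates.items():
            if rid not in base.reactions and rid not in candidates:
                # skip pool exchanges duplicating an existing model exchange
                if rxn.kind == KIND_EXCHANGE:
                    ((mid, _),) = rxn.stoichiometry.keys()
                    if base.exchanges_for(mid):
                        continue
                candidates[rid] = rxn
                costs[rid] = extra_costs[rid]
    # direction-reversal candidates for irreversible model reactions
    reversal_of: dict[str, str] = {}
    for rid in sorted(base.reactions):
        rxn = base.reactions[rid]
        if rxn.kind in (KIND_EXCHANGE, "sink", "biomass"):
            continue
        if rxn.lower_bound >= 0:
            rev_id = f"REV_{rid}"
            candidates[rev_id] = Reaction(
                id=rev_id,
                stoichiometry={k: -v for k, v in rxn.stoichiometry.items()},
                lower_bound=0.0,
                upper_bound=config.candidate_bound,
                kind=rxn.kind,
            )
            costs[rev_id] = (CAT_REVERSE, config.reverse_direction)
            reversal_of[rev_id] = rid

    # α scan
    alpha = config.alpha_start
    solution_x = None
    var_names = None
    while alpha <= config.alpha_max:
        x, names = _merge_lp(base, candidates, costs, config, alpha)
        if x is not None:
            bio_idx = names.index(("m", base.biomass_id))
            if x[bio_idx] >= config.biomass_lb - 1e-9:
                solution_x, var_names = x, names
                break
        alpha *= config.alpha_factor

    if solution_x is None:
        return GapFillSolution(
            model_id=model.id,
            added_reactions={},
            reversed_reactions=set(),
            v_bio=0.0,
            secreted=set(),
            imported=set(),
            medium=dict(medium),
            model=base,
            status="infeasible",
            blocked_precursors=_blocked_precursors(base, candidates, config),
        )

    # net candidate fluxes
    net: dict[str, float] = {}
    for (kind, rid), val in zip(var_names, solution_x):
        if kind == "f":
            net[rid] = net.get(rid, 0.0) + val
        elif kind == "b":
            net[rid] = net.get(rid, 0.0) - val
    used = {rid for rid, v in net.items() if abs(v) > config.flux_eps}

    filled = base.copy()
    added: dict[str, tuple[str, float]] = {}
    reversed_rxns: set[str] = set()
    for rid in sorted(used):
        if rid in reversal_of:
            target = filled.reactions[reversal_of[rid]]
            target.lower_bound = -config.candidate_bound
            reversed_rxns.add(reversal_of[rid])
            added[rid] = costs[rid]
        else:
            filled.add_reaction(candidates[rid].copy(), create_missing=True)
            added[rid] = costs[rid]

    # greedy pruning, most expensive first; ties by id for determinism
    for rid in sorted(added, key=lambda r: (-added[r][1], r)):
        if rid in reversal_of:
            target = filled.reactions[reversal_of[rid]]
            saved = target.lower_bound
            target.lower_bound = model.reactions[reversal_of[rid]].lower_bound
            if _growth(filled, config) >= config.biomass_lb - 1e-9:
                del added[rid]
                reversed_rxns.discard(reversal_of[rid])
            else:
                target.lower_bound = saved
        else:
            saved_rxn = filled.remove_reaction(rid)
            if _growth(filled, config) >= config.biomass_lb - 1e-9:
                del added[rid]
            else:
                filled.add_reaction(saved_rxn, create_missing=True)

    # final flux state and imported metabolites
    bid = filled.biomass_id
    cap = {bid: (0.0, min(filled.reactions[bid].upper_bound, config.biomass_ub))}
    res = fba(filled, minimize_one_norm=True, extra_bounds=cap)
    imported: set[str] = set()
    introduced_uptakes = set(medium_added) | {
        rid for rid in added if filled.reactions.get(rid) is not None
        and filled.reactions[rid].kind == KIND_EXCHANGE
    }
    for rid in introduced_uptakes:
        rxn = filled.reactions.get(rid)
        if rxn is None:
            continue
        if res.fluxes.get(rid, 0.0) < -config.flux_eps:
            ((mid, _),) = rxn.stoichiometry.keys()
            imported.add(mid)

    return GapFillSolution(
        model_id=model.id,
        added_reactions=added,
        reversed_reactions=reversed_rxns,
        v_bio=float(res.v_bio if res.status == "optimal" else 0.0),
        secreted=set(),
        imported=imported,
        medium=dict(medium),
        model=filled,
    )


# ---------------------------------------------------------------------------
# Secretion LP
# ---------------------------------------------------------------------------


def secretion_lp(
    model: MetabolicModel,
    config: WeightConfig = WeightConfig(),
    permeable_ids: Optional[set[str]] = None,
    mode: str = "post_hoc",
) -> set[str]:
    """Metabolites the (gap-filled, growing) model can secrete.

    ``post_hoc``: determine the optimal biomass flux first, add temporary
    sink reactions for every cytosolic metabolite that is permeable or
    takes part in a model transport reaction, and maximize the summed sink
    flux subject to v_bio ≥ f·v_bio_opt (sinks bounded to [0, 1000]).
    Sinks carrying flux above tolerance mark secreted metabolites.  The
    summed objective has degenerate optima (exporting a precursor ties with
    exporting its product), so sinks left at zero are re-checked by
    individual maximization under the same biomass constraint — a
    metabolite counts as secretable iff its export alone can exceed
    tolerance without cutting growth below f·v_bio_opt.  Metabolites that
    already have an uptake in the model are not reported.
    ``in_objective``: single LP maximizing Σ sinks + v_bio jointly (the
    sink weight comes from ``config.sink_cost``; biomass keeps its cap).
    Temporary sinks never persist in the model.
    """
    from .model_core import solve_lp

    permeable_ids = permeable_ids or set()
    if model.biomass_id is None:
        raise GapFillError(f"model {model.id} has no biomass reaction")
    v_opt = _growth(model, config)
    if v_opt < config.biomass_lb - 1e-9:
        raise GapFillError(f"model {model.id} does not grow on its medium")

    transport_mets = set()
    for rxn in model.reactions.values():
        if rxn.kind == KIND_TRANSPORT:
            transport_mets |= {mid for (mid, _) in rxn.stoichiometry}
    candidates = sorted(
        mid
        for (mid, comp) in model.metabolites
        if comp == CYTOSOL and (mid in permeable_ids or mid in transport_mets)
    )
    if not candidates:
        return set()

    probe = model.copy()
    sink_ids = {}
    for mid in candidates:
        sid = f"SEC_SINK_{mid}"
        probe.add_reaction(
            Reaction(sid, {(mid, CYTOSOL): -1.0}, 0.0, config.candidate_bound,
                     kind="sink")
        )
        sink_ids[sid] = mid

    bid = probe.biomass_id
    bio_ub = min(probe.reactions[bid].upper_bound, config.biomass_ub)
    if mode == "post_hoc":
        target = config.secretion_factor * v_opt
        res = solve_lp(
            probe,
            {sid: 1.0 for sid in sink_ids},
            extra_bounds={bid: (target, bio_ub)},
        )
        if res.status != "optimal":
            raise GapFillError(f"secretion LP failed with status {res.status}")
        flux = dict(res.fluxes)
        for sid in sink_ids:
            if flux.get(sid, 0.0) > config.flux_eps:
                continue
            single = solve_lp(probe, {sid: 1.0}, extra_bounds={bid: (target, bio_ub)})
            if single.status == "optimal":
                flux[sid] = single.fluxes.get(sid, 0.0)
        res_fluxes = flux
    elif mode == "in_objective":
        obj = {sid: 1.0 - config.sink_cost for sid in sink_ids}
        obj[bid] = 1.0
        res = solve_lp(probe, obj, extra_bounds={bid: (0.0, bio_ub)})
        if res.status != "optimal":
            raise GapFillError(f"secretion LP failed with status {res.status}")
        res_fluxes = res.fluxes
    else:
        raise ValueError(f"unknown secretion mode {mode!r}")

    has_uptake = {
        mid
        for mid in sink_ids.values()
        if any(r.lower_bound < -config.flux_eps for r in model.exchanges_for(mid))
    }
    return {
        mid
        for sid, mid in sink_ids.items()
        if res_fluxes.get(sid, 0.0) > config.flux_eps and mid not in has_uptake
    }


def materialize_secretion(model: MetabolicModel, secreted: set[str]) -> MetabolicModel:
    """Add a c→e export transport and a secretion-only exchange for each
    secreted metabolite lacking an export path; no sink reactions persist."""
    out = model.copy()
    for mid in sorted(secreted):
        ckey = (mid, CYTOSOL)
        if ckey not in out.metabolites:
            raise ValueError(f"secreted metabolite {mid} not in cytosol of {model.id}")
        ekey = (mid, EXTRACELLULAR)
        has_transport = any(
            r.kind == KIND_TRANSPORT
            and ckey in r.stoichiometry
            and ekey in r.stoichiometry
            for r in out.reactions.values()
        )
        if not has_transport:
            if ekey not in out.metabolites:
                out.add_metabolite(Metabolite(mid, EXTRACELLULAR))
            out.add_reaction(
                Reaction(
                    id=f"TSEC_{mid}",
                    stoichiometry={ckey: -1.0, ekey: 1.0},
                    lower_bound=0.0,
                    upper_bound=DEFAULT_BOUND,
                    kind=KIND_TRANSPORT,
                )
            )
        if not out.exchanges_for(mid):
            out.add_reaction(
                Reaction(
                    id=f"EXSEC_{mid}",
                    stoichiometry={ekey: -1.0},
                    lower_bound=0.0,
                    upper_bound=DEFAULT_BOUND,
                    kind=KIND_EXCHANGE,
                )
            )
    return out


def solution_frame(solutions: Sequence[GapFillSolution]) -> pd.DataFrame:
    """Flatten gap-fill solutions into a (model, reaction, category, cost)
    table, sorted for byte-stable output."""
    rows = []
    for sol in solutions:
        for rid in sorted(sol.added_reactions):
            cat, cost = sol.added_reactions[rid]
            rows.append(
                {"model": sol.model_id, "reaction": rid, "category": cat, "cost": cost}
            )
    return pd.DataFrame(rows, columns=["model", "reaction", "category", "cost"])
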