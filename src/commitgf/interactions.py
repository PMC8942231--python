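"""Post-hoc analysis of a community run: exchanged-metabolite pools, an
uptake-blocking dependency screen, taxonomic aggregation, and an
interaction graph comparable with external predictions.

The dependency screen blocks, one at a time, the uptake of every metabolite
whose import a member gained during conditional gap filling, and records the
ratio of the blocked growth rate to the reference growth rate.  Both states
are evaluated with one-norm flux minimization so futile cycles carry no
flux; a strict loop-law (MILP) mode is available as a flag.  Ratios at or
above 0.99 are treated as "no dependence" to avoid false-positive responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, Bounds, milp

from .community import CommunityRun
from .gapfill import WeightConfig
from .model_core import (
    FLUX_EPS,
    KIND_EXCHANGE,
    MetabolicModel,
    fba,
)

#: Growth-ratio threshold above which a blocked uptake counts as
#: "no dependence".
DEPENDENCE_THRESHOLD = 0.99


@dataclass
class ExchangeTable:
    frame: pd.DataFrame  # metabolite, secreting, importing, class_label


@dataclass
class DependencyMatrix:
    ratios: pd.DataFrame  # models x metabolites, NaN where not imported
    threshold: float = DEPENDENCE_THRESHOLD


# ---------------------------------------------------------------------------
# Exchanged metabolites
# ---------------------------------------------------------------------------


def exchanged_pool(
    run: CommunityRun, class_labels: Optional[Mapping[str, str]] = None
) -> ExchangeTable:
    """Metabolites secreted by ≥1 member AND imported by ≥1 other member,
    excluding the minimal-medium nutrients.

    A member both secreting and importing the same metabolite does not by
    itself create an exchange; a distinct importer is required.
    """
    class_labels = class_labels or {}
    secretors: dict[str, set[str]] = {}
    importers: dict[str, set[str]] = {}
    for mid, sol in run.best.solutions.items():
        for met in sol.secreted:
            secretors.setdefault(met, set()).add(mid)
        for met in sol.imported:
            importers.setdefault(met, set()).add(mid)
    rows = []
    for met in sorted(set(secretors) & set(importers)):
        if met in run.minimal_medium:
            continue
        sec = secretors[met]
        imp = importers[met]
        if len(sec) == 1 and imp <= sec:  # self-exchange only
            continue
        rows.append(
            {
                "metabolite": met,
                "secreting": ";".join(sorted(sec)),
                "importing": ";".join(sorted(imp)),
                "class_label": class_labels.get(met, ""),
            }
        )
    return ExchangeTable(
        pd.DataFrame(rows, columns=["metabolite", "secreting", "importing", "class_label"])
    )


# ---------------------------------------------------------------------------
# Dependency screen
# ---------------------------------------------------------------------------


def _uptake_bounds(model: MetabolicModel, met: str, closed: bool):
    """Extra-bounds override closing (or not) every uptake of `met`."""
    out = {}
    for rxn in model.exchanges_for(met):
        lb = 0.0 if closed else rxn.lower_bound
        out[rxn.id] = (lb, rxn.upper_bound)
    return out


def _reference_growth(model: MetabolicModel, config: WeightConfig, loopless: bool) -> float:
    bid = model.biomass_id
    cap = {bid: (0.0, min(model.reactions[bid].upper_bound, config.biomass_ub))}
    if loopless:
        res = loopless_fba(model, extra_bounds=cap)
    else:
        res = fba(model, minimize_one_norm=True, extra_bounds=cap)
    if res.status != "optimal":
        raise RuntimeError(f"member {model.id} infeasible in reference state")
    return res.objective_value


def dependency_screen(
    run: CommunityRun,
    config: WeightConfig = WeightConfig(),
    loopless: bool = False,
) -> DependencyMatrix:
    """Blocked-uptake growth-ratio matrix over the best ordering's members.

    Entry (model, metabolite) = v_bio(uptake of metabolite blocked) divided
    by v_bio(reference), clipped to [0, 1]; computed only for metabolites in
    the member's gap-fill import set (the matrix is sparse by construction).
    Numerator and denominator receive the same one-norm / loop-law
    treatment.  Ratios ≥ threshold are reported as 1 (no dependence).
    """
    mets = sorted({m for sol in run.best.solutions.values() for m in sol.imported})
    models = sorted(run.best.solutions)
    ratios = pd.DataFrame(np.nan, index=models, columns=mets, dtype=float)
    for mid in models:
        sol = run.best.solutions[mid]
        model = sol.model
        v_ref = _reference_growth(model, config, loopless)
        bid = model.biomass_id
        cap = {bid: (0.0, min(model.reactions[bid].upper_bound, config.biomass_ub))}
        for met in sorted(sol.imported):
            bounds = dict(cap)
            bounds.update(_uptake_bounds(model, met, closed=True))
            if loopless:
                res = loopless_fba(model, extra_bounds=bounds)
            else:
                res = fba(model, minimize_one_norm=True, extra_bounds=bounds)
            v = res.objective_value if res.status == "optimal" else 0.0
            ratio = float(np.clip(v / v_ref if v_ref > 0 else 0.0, 0.0, 1.0)) + 0.0
            if ratio >= DEPENDENCE_THRESHOLD:
                ratio = 1.0
            ratios.loc[mid, met] = ratio
    return DependencyMatrix(ratios=ratios)


# ---------------------------------------------------------------------------
# Strict loop-law FBA (MILP)
# ---------------------------------------------------------------------------


def loopless_fba(
    model: MetabolicModel,
    extra_bounds: Optional[Mapping[str, tuple[float, float]]] = None,
):
    """FBA with loop-law constraints (big-M MILP).

    Internal (non-exchange) reactions get a binary direction indicator and
    the energy-like potential constraint that forbids flux around closed
    internal cycles.  Intended for the dependency screen on small models;
    the relaxed one-norm treatment is the default elsewhere.
    """
    from .model_core import FluxResult

    met_keys, rxn_ids, S = model.stoichiometric_matrix()
    n = len(rxn_ids)
    internal = [
        j for j, rid in enumerate(rxn_ids)
        if model.reactions[rid].kind not in (KIND_EXCHANGE, "sink", "biomass")
    ]
    ni = len(internal)
    bid = model.biomass_id
    if bid is None:
        raise ValueError("loopless FBA needs a biomass objective")
    bio_j = rxn_ids.index(bid)

    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    if extra_bounds:
        for rid, (l, u) in extra_bounds.items():
            j = rxn_ids.index(rid)
            lb[j], ub[j] = l, u

    M = 1000.0
    K = 100.0  # potential bound
    # variables: v (n), a (ni binary), g (ni potentials)
    nv = n + 2 * ni
    c = np.zeros(nv)
    c[bio_j] = -1.0

    cons = [LinearConstraint(sparse.hstack(
        [S, sparse.csr_matrix((S.shape[0], 2 * ni))]), 0.0, 0.0)]

    rows_A, vals_A, lo, hi = [], [], [], []

    def add(con_row: dict[int, float], lo_v: float, hi_v: float) -> None:
        rows_A.append(con_row)
        lo.append(lo_v)
        hi.append(hi_v)

    for k, j in enumerate(internal):
        aj = n + k
        gj = n + ni + k
        # v_j <= M a_j and v_j >= -M (1 - a_j):  v_j - M a_j in [-M, 0]
        add({j: 1.0, aj: -M}, -M, 0.0)
        # g_j in [-K, -1] when a_j = 1 ; [1, K] when a_j = 0
        # -K + (1-K)(1-a_j) <= ... encode: g_j + (K+1) a_j in [1, K]
        add({gj: 1.0, aj: K + 1.0}, 1.0, K)

    # loop law: G_internal^T g = 0 for internal nullspace — implemented via
    # S_int nullspace basis rows: sum over internal columns.  Use the
    # internal stoichiometric submatrix: g must satisfy N^T g = 0 where N is
    # a nullspace basis of S restricted to internal reactions.
    S_int = S[:, internal].toarray()
    if ni:
        null = _nullspace(S_int)
        for b in null.T:
            row = {n + ni + k: float(b[k]) for k in range(ni) if abs(b[k]) > 1e-9}
            if row:
                add(row, 0.0, 0.0)

    if rows_A:
        data, ri, ci = [], [], []
        for i, row in enumerate(rows_A):
            for jx, v in row.items():
                ri.append(i)
                ci.append(jx)
                data.append(v)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows_A), nv))
        cons.append(LinearConstraint(A, np.array(lo), np.array(hi)))

    lbs = np.concatenate([lb, np.zeros(ni), -K * np.ones(ni)])
    ubs = np.concatenate([ub, np.ones(ni), K * np.ones(ni)])
    integrality = np.concatenate([np.zeros(n), np.ones(ni), np.zeros(ni)])
    res = milp(c, constraints=cons, bounds=Bounds(lbs, ubs), integrality=integrality)
    if res.status != 0 or res.x is None:
        return FluxResult(status="infeasible", objective_value=float("nan"), fluxes={})
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(rxn_ids)}
    return FluxResult(
        status="optimal",
        objective_value=float(-res.fun),
        fluxes=fluxes,
        v_bio=fluxes[bid],
    )


def _nullspace(A: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    _, s, vt = np.linalg.svd(A)
    rank = int((s > tol * max(A.shape)).sum()) if s.size else 0
    return vt[rank:].T


# ---------------------------------------------------------------------------
# Aggregation and interaction graph
# ---------------------------------------------------------------------------


def aggregate_by_group(
    table: ExchangeTable,
    grouping: Mapping[str, str],
    abundance: Mapping[str, float],
) -> pd.DataFrame:
    """Per (family, metabolite, direction) flow weights.

    Weight = member count × summed family abundance; zero-abundance rows are
    kept and flagged so downstream plots can drop them explicitly.
    """
    models = set()
    for _, row in table.frame.iterrows():
        models |= set(row["secreting"].split(";")) if row["secreting"] else set()
        models |= set(row["importing"].split(";")) if row["importing"] else set()
    missing = sorted(m for m in models if m and m not in grouping)
    if missing:
        raise ValueError(f"models missing from grouping: {missing}")

    fam_abundance: dict[str, float] = {}
    for mid, fam in grouping.items():
        fam_abundance[fam] = fam_abundance.get(fam, 0.0) + float(abundance.get(mid, 0.0))

    rows = []
    for _, row in table.frame.iterrows():
        for direction, col in (("export", "secreting"), ("import", "importing")):
            members = [m for m in row[col].split(";") if m]
            per_family: dict[str, int] = {}
            for m in members:
                fam = grouping[m]
                per_family[fam] = per_family.get(fam, 0) + 1
            for fam, count in sorted(per_family.items()):
                weight = count * fam_abundance.get(fam, 0.0)
                rows.append(
                    {
                        "family": fam,
                        "metabolite": row["metabolite"],
                        "direction": direction,
                        "member_count": count,
                        "weight": weight,
                        "zero_abundance": fam_abundance.get(fam, 0.0) == 0.0,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["family", "metabolite", "direction", "member_count", "weight",
                 "zero_abundance"],
    )


def interaction_graph(run: CommunityRun) -> set[frozenset]:
    """Undirected member pairs with non-empty overlap between one member's
    secreted set and the other's imported set."""
    sols = run.best.solutions
    edges: set[frozenset] = set()
    ids = sorted(sols)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if (sols[a].secreted & sols[b].imported) or (
                sols[b].secreted & sols[a].imported
            ):
                edges.add(frozenset((a, b)))
    return edges


def graph_agreement(
    edges_a: set[frozenset], edges_b: set[frozenset], members: Sequence[str]
) -> dict[str, float]:
    """Fractions of all possible pairs that both, either, or neither graph
    predicts as interacting."""
    ids = sorted(members)
    all_pairs = {
        frozenset((a, b)) for i, a in enumerate(ids) for b in ids[i + 1:]
    }
    n = len(all_pairs)
    if n == 0:
        raise ValueError("need at least two members")
    both = len(edges_a & edges_b & all_pairs)
    either = len((edges_a ^ edges_b) & all_pairs)
    neither = n - both - either
    return {
        "both": both / n,
        "either": either / n,
        "neither": neither / n,
        "agreement": (both + neither) / n,
    }


def write_edge_list(edges: set[frozenset], path: str) -> None:
    rows = sorted(tuple(sorted(e)) for e in edges)
    pd.DataFrame(rows, columns=["model_a", "model_b"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str) -> set[frozenset]:
    df = pd.read_csv(path, sep="\t")
    return {frozenset((str(a), str(b))) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
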