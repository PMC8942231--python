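"""Synthetic communities with planted cross-feeding structure, and the
reaction-removal recovery benchmark.

Each community member is a small cell: it imports D-glucose and phosphate,
runs a linear core pathway to a member-specific biomass precursor, and its
biomass reaction consumes that precursor, phosphate, and any cross-fed
nutrients.  A cross-feeding edge (producer, metabolite, consumer) plants a
two-step synthesis branch for the metabolite in the producer (who can spare
enough carbon to secrete it within the 10% growth-reduction budget) and an
auxotrophy in the consumer, whose own model carries only the e→c
transporter: on a minimal medium the consumer's cheapest individual repair
is re-adding the synthesis branch from the database, while in a community
context the cheapest completion is uptake of the secreted metabolite.  The
universal database holds every member reaction plus mass-balanced decoys,
and the property table makes exactly the cross-fed metabolites (and
glucose) membrane-permeable, with a configurable fraction of XLogP3 values
missing (recoverable by 1-NN imputation from planted near-duplicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .community import (
    CommunityError,
    derive_minimal_medium,
    individual_baseline,
    run_commit,
)
from .gapfill import GapFillDatabase, WeightConfig, prepare_database
from .model_core import (
    CYTOSOL,
    DEFAULT_BOUND,
    EXTRACELLULAR,
    KIND_BIOMASS,
    KIND_EXCHANGE,
    KIND_INTERNAL,
    KIND_TRANSPORT,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_medium,
    fba,
)

CARBON_SOURCE = "glc"
PHOSPHATE = "pi"
DEFAULT_UPTAKE = 10.0


@dataclass
class CommunitySpec:
    n_members: int = 3
    core_pathway_length: int = 4
    cross_feeding: Optional[list[tuple[str, str, str]]] = None  # (producer, met, consumer)
    n_cross_feeding: int = 1
    n_decoys: int = 6
    missing_xlogp3_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_pathway_length < 2:
            raise ValueError("core pathway length must be >= 2")
        if self.n_members < 1:
            raise ValueError("need at least one member")

    def member_ids(self) -> list[str]:
        return [f"org{i + 1}" for i in range(self.n_members)]


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    models: dict[str, MetabolicModel]
    db: GapFillDatabase
    db_table: pd.DataFrame
    properties: pd.DataFrame
    auxo_media: dict[str, dict[str, float]]
    cross_feeding: list[tuple[str, str, str]]
    permeable_ids: set[str]
    minimal_medium: dict[str, float] = field(default_factory=dict)


def _draw_edges(spec: CommunitySpec, rng: np.random.Generator) -> list[tuple[str, str, str]]:
    ids = spec.member_ids()
    if spec.cross_feeding is not None:
        for producer, met, consumer in spec.cross_feeding:
            if producer not in ids or consumer not in ids:
                raise CommunityError(
                    f"cross-feeding edge ({producer}, {met}, {consumer}) references "
                    f"undeclared members (declared: {ids})"
                )
            if producer == consumer:
                raise CommunityError(
                    f"self-feeding edge for {producer} is not satisfiable"
                )
        return list(spec.cross_feeding)
    if spec.n_members < 2 or spec.n_cross_feeding == 0:
        return []
    edges = []
    for k in range(spec.n_cross_feeding):
        producer, consumer = rng.choice(spec.n_members, size=2, replace=False)
        edges.append((ids[producer], f"aa_{k + 1}", ids[consumer]))
    return edges


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Deterministically build (models, database, property table, auxotrophic
    media) for the given community specification."""
    rng = np.random.default_rng(spec.seed)
    edges = _draw_edges(spec, rng)
    ids = spec.member_ids()
    incoming: dict[str, list[str]] = {m: [] for m in ids}
    outgoing: dict[str, list[str]] = {m: [] for m in ids}
    for producer, met, consumer in edges:
        outgoing[producer].append(met)
        incoming[consumer].append(met)

    db_rows: list[dict] = []
    seen_db: set[str] = set()

    def db_row(rid: str, equation: str, ec: str = "") -> None:
        if rid not in seen_db:
            seen_db.add(rid)
            db_rows.append({"id": rid, "equation": equation, "balanced": "T", "ec": ec})

    models: dict[str, MetabolicModel] = {}
    auxo_media: dict[str, dict[str, float]] = {}
    cross_fed = sorted({met for _, met, _ in edges})

    for mid in ids:
        model = MetabolicModel(id=mid)
        L = spec.core_pathway_length

        def add(rid: str, stoich: dict, lb: float, ub: float, kind: str,
                in_db: bool = True, gpr: str = "", ec: str = "") -> None:
            model.add_reaction(
                Reaction(rid, stoich, lb, ub, gpr=gpr,
                         ec_numbers={ec} if ec else set(), kind=kind),
                create_missing=True,
            )
            if in_db and kind != KIND_BIOMASS:
                db_row(rid, _equation(stoich, lb < 0), ec)

        add("EX_glc", {(CARBON_SOURCE, EXTRACELLULAR): -1.0}, 0.0, DEFAULT_BOUND,
            KIND_EXCHANGE)
        add("EX_pi", {(PHOSPHATE, EXTRACELLULAR): -1.0}, 0.0, DEFAULT_BOUND,
            KIND_EXCHANGE)
        add("T_glc", {(CARBON_SOURCE, EXTRACELLULAR): -1.0,
                      (CARBON_SOURCE, CYTOSOL): 1.0},
            -DEFAULT_BOUND, DEFAULT_BOUND, KIND_TRANSPORT)
        add("T_pi", {(PHOSPHATE, EXTRACELLULAR): -1.0, (PHOSPHATE, CYTOSOL): 1.0},
            -DEFAULT_BOUND, DEFAULT_BOUND, KIND_TRANSPORT)

        prev = (CARBON_SOURCE, CYTOSOL)
        for j in range(1, L + 1):
            cur = (f"{mid}_int{j}", CYTOSOL)
            add(f"P_{mid}_{j}", {prev: -1.0, cur: 1.0}, 0.0, DEFAULT_BOUND,
                KIND_INTERNAL, gpr=f"{mid}_g{j}", ec=f"1.1.1.{j}")
            prev = cur

        biomass_stoich = {prev: -1.0, (PHOSPHATE, CYTOSOL): -1.0}
        for met in sorted(incoming[mid]):
            biomass_stoich[(met, CYTOSOL)] = -1.0
            add(f"T_{met}", {(met, EXTRACELLULAR): -1.0, (met, CYTOSOL): 1.0},
                -DEFAULT_BOUND, DEFAULT_BOUND, KIND_TRANSPORT)
        for met in sorted(outgoing[mid]):
            add(f"SYN1_{met}", {(CARBON_SOURCE, CYTOSOL): -1.0,
                                (f"{met}_pre", CYTOSOL): 1.0},
                0.0, DEFAULT_BOUND, KIND_INTERNAL)
            add(f"SYN2_{met}", {(f"{met}_pre", CYTOSOL): -1.0, (met, CYTOSOL): 1.0},
                0.0, DEFAULT_BOUND, KIND_INTERNAL)
        add(f"BIO_{mid}", biomass_stoich, 0.0, DEFAULT_BOUND, KIND_BIOMASS,
            in_db=False)
        model.biomass_id = f"BIO_{mid}"
        models[mid] = model

        medium = {CARBON_SOURCE: DEFAULT_UPTAKE, PHOSPHATE: DEFAULT_UPTAKE}
        for met in incoming[mid]:
            medium[met] = DEFAULT_UPTAKE
        auxo_media[mid] = medium

    # synthesis branches and exchanges for every cross-fed metabolite are in
    # the universal pool even when no member carries them
    for met in cross_fed:
        db_row(f"SYN1_{met}",
               _equation({(CARBON_SOURCE, CYTOSOL): -1.0, (f"{met}_pre", CYTOSOL): 1.0}, False))
        db_row(f"SYN2_{met}",
               _equation({(f"{met}_pre", CYTOSOL): -1.0, (met, CYTOSOL): 1.0}, False))
        db_row(f"T_{met}",
               _equation({(met, EXTRACELLULAR): -1.0, (met, CYTOSOL): 1.0}, True))
        db_row(f"EX_{met}", _equation({(met, EXTRACELLULAR): -1.0}, True))
    db_row("EX_glc", _equation({(CARBON_SOURCE, EXTRACELLULAR): -1.0}, True))
    db_row("EX_pi", _equation({(PHOSPHATE, EXTRACELLULAR): -1.0}, True))

    for k in range(spec.n_decoys):
        a, b = f"dec{k + 1}a", f"dec{k + 1}b"
        coef = int(rng.integers(1, 4))
        db_row(f"DEC_{k + 1}",
               _equation({(a, CYTOSOL): -float(coef), (b, CYTOSOL): float(coef)},
                         bool(rng.integers(0, 2))))

    db_table = pd.DataFrame(db_rows, columns=["id", "equation", "balanced", "ec"])
    db = prepare_database(db_table)

    properties = _property_table(models, cross_fed, spec, rng)
    from .permeability import permeable_metabolites, properties_from_frame

    permeable_ids = permeable_metabolites(properties_from_frame(properties))

    community = SyntheticCommunity(
        spec=spec,
        models=models,
        db=db,
        db_table=db_table,
        properties=properties,
        auxo_media=auxo_media,
        cross_feeding=edges,
        permeable_ids=permeable_ids,
    )
    community.minimal_medium = derive_minimal_medium(
        auxo_media, carbon_source=CARBON_SOURCE, exclude=cross_fed,
        default_uptake=DEFAULT_UPTAKE,
    )
    return community


def _equation(stoich: dict, reversible: bool) -> str:
    lhs = " + ".join(
        f"{abs(c):g} {m}@{comp}" for (m, comp), c in sorted(stoich.items()) if c < 0
    )
    rhs = " + ".join(
        f"{abs(c):g} {m}@{comp}" for (m, comp), c in sorted(stoich.items()) if c > 0
    )
    sep = "=" if reversible else "-->"
    return f"{lhs} {sep} {rhs}".strip()


def _property_table(models, cross_fed, spec: CommunitySpec,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Molecular-property rows: cross-fed metabolites and glucose pass the
    permeability rules, everything else fails on size; a seeded fraction of
    XLogP3 entries is blanked, each with a planted near-duplicate donor row
    so 1-NN imputation restores a compliant value."""
    all_mets = sorted({mid for m in models.values() for mid in m.metabolite_ids()})
    rows = []
    for met in all_mets:
        permeable = met in cross_fed or met == CARBON_SOURCE
        if permeable:
            mw = float(rng.uniform(100, 260))
            tpsa = float(rng.uniform(30, 110))
            hbd, hba = int(rng.integers(0, 4)), int(rng.integers(0, 7))
            rb = int(rng.integers(0, 6))
            xlogp3 = float(rng.uniform(0.0, 3.0))
        else:
            mw = float(rng.uniform(550, 900))
            tpsa = float(rng.uniform(150, 300))
            hbd, hba = int(rng.integers(6, 10)), int(rng.integers(11, 16))
            rb = int(rng.integers(11, 18))
            xlogp3 = float(rng.uniform(-5.0, -1.0))
        rows.append({"metabolite_id": met, "MW": mw, "TPSA": tpsa, "HBD": hbd,
                     "HBA": hba, "RB": rb, "XLogP3": xlogp3})
    n_missing = int(round(spec.missing_xlogp3_frac * len(rows)))
    blank = rng.choice(len(rows), size=n_missing, replace=False) if n_missing else []
    donors = []
    for i in sorted(blank):
        row = rows[i]
        donors.append(
            {
                "metabolite_id": f"ref_{row['metabolite_id']}",
                "MW": row["MW"] * (1 + rng.normal(0, 1e-3)),
                "TPSA": row["TPSA"] * (1 + rng.normal(0, 1e-3)),
                "HBD": row["HBD"],
                "HBA": row["HBA"],
                "RB": row["RB"],
                "XLogP3": row["XLogP3"],
            }
        )
        row["XLogP3"] = np.nan
    return pd.DataFrame(rows + donors,
                        columns=["metabolite_id", "MW", "TPSA", "HBD", "HBA",
                                 "RB", "XLogP3"])


# ---------------------------------------------------------------------------
# Reaction-removal recovery benchmark
# ---------------------------------------------------------------------------


def eligible_reactions(model: MetabolicModel, medium, config: WeightConfig) -> list[str]:
    """Flux-carrying internal reactions at the one-norm-minimal optimum on
    the given medium (cycle-only reactions carry no flux there)."""
    fed, _ = apply_medium(model, medium)
    bid = fed.biomass_id
    cap = {bid: (0.0, min(fed.reactions[bid].upper_bound, config.biomass_ub))}
    res = fba(fed, minimize_one_norm=True, extra_bounds=cap)
    if res.status != "optimal":
        raise CommunityError(f"model {model.id} does not grow before removal")
    return sorted(
        rid
        for rid, rxn in model.reactions.items()
        if rxn.kind == KIND_INTERNAL and abs(res.fluxes.get(rid, 0.0)) > config.flux_eps
    )


def knockout_benchmark(
    community: SyntheticCommunity,
    fractions: Sequence[float] = (0.01, 0.02, 0.05, 0.10),
    n_reps: int = 50,
    seed: int = 0,
    config: WeightConfig = WeightConfig(),
    n_orderings: int = 2,
) -> pd.DataFrame:
    """Remove random flux-carrying internal reactions and score how many the
    gap filler re-adds, with (conditional) and without (individual)
    consideration of the community.

    Per (fraction, replicate, member, mode): ⌈fraction·n_eligible⌉ eligible
    reactions are removed from each member; precision and recall are
    computed per member over added-vs-removed reaction identities (strict id
    matching, so functionally equivalent additions count as false
    positives).  Replicates where removal makes biomass structurally
    unreachable are marked unrecoverable and carry NaN scores.
    """
    rng = np.random.default_rng(seed)
    base_models = community.models
    eligible = {
        mid: eligible_reactions(base_models[mid], community.auxo_media[mid], config)
        for mid in sorted(base_models)
    }
    rows = []
    for rep in range(n_reps):
        for frac in fractions:
            removed: dict[str, list[str]] = {}
            damaged: dict[str, MetabolicModel] = {}
            for mid in sorted(base_models):
                pool = eligible[mid]
                k = min(len(pool), math.ceil(frac * len(pool)))
                picks = sorted(rng.choice(len(pool), size=k, replace=False))
                removed[mid] = [pool[i] for i in picks]
                dm = base_models[mid].copy()
                for rid in removed[mid]:
                    dm.remove_reaction(rid)
                damaged[mid] = dm

            added: dict[str, dict[str, set[str]]] = {"conditional": {}, "individual": {}}
            unrecoverable = False
            try:
                run = run_commit(
                    damaged, community.db, community.minimal_medium,
                    community.auxo_media, config,
                    n_orderings=n_orderings,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    permeable_ids=community.permeable_ids,
                )
                added["conditional"] = {
                    mid: set(sol.added_reactions)
                    for mid, sol in run.best.solutions.items()
                }
            except CommunityError:
                unrecoverable = True
            indiv = individual_baseline(
                damaged, community.db, community.minimal_medium, config,
                permeable_ids=community.permeable_ids,
            )
            if any(sol.status != "ok" for sol in indiv.values()):
                unrecoverable = True
            added["individual"] = {
                mid: set(sol.added_reactions) for mid, sol in indiv.items()
            }

            for mode in ("conditional", "individual"):
                for mid in sorted(base_models):
                    rem = set(removed[mid])
                    add_set = added[mode].get(mid, set())
                    recovered = add_set & rem
                    precision = len(recovered) / len(add_set) if add_set else np.nan
                    recall = len(recovered) / len(rem) if rem else np.nan
                    rows.append(
                        {
                            "fraction": frac,
                            "replicate": rep,
                            "model": mid,
                            "mode": mode,
                            "n_removed": len(rem),
                            "n_added": len(add_set),
                            "n_recovered": len(recovered),
                            "precision": np.nan if unrecoverable else precision,
                            "recall": np.nan if unrecoverable else recall,
                            "unrecoverable": unrecoverable,
                        }
                    )
    return pd.DataFrame(rows)
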