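"""Community-conditional gap filling.

Members of a microbial community are gap-filled one after another along a
random ordering: the first member on its auxotrophic medium (its required
nutrients are assumed to come from the rest of the community), each later
member on the shared minimal medium plus cheap uptake candidates for every
metabolite already secreted by the gap-filled members before it.  After a
member is filled, its secretable metabolites (permeability- and
growth-budget-limited) extend the community pool.  A configurable number of
random orderings is explored and the best one selected lexicographically on
four criteria: fewest total added reactions, then strongest dependence of
the first member on later secretions, then most permeable metabolites, then
highest summed growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gapfill import (
    GapFillDatabase,
    GapFillError,
    GapFillSolution,
    WeightConfig,
    fast_gap_fill,
    materialize_secretion,
    pool_uptake_candidates,
    resolve_costs,
    secretion_lp,
)
from .model_core import MetabolicModel

#: Default criterion order (lexicographic); a leading '-' maximizes.
DEFAULT_CRITERIA = (
    "total_added_reactions",
    "-first_member_dependence",
    "-total_permeable",
    "-biomass_sum",
)


@dataclass
class OrderingResult:
    order: tuple[str, ...]
    solutions: dict[str, GapFillSolution]
    pool_trajectory: list[set[str]]
    total_added_reactions: int
    first_member_dependence: int
    total_permeable: int
    biomass_sum: float
    failed_member: Optional[str] = None

    @property
    def failed(self) -> bool:
        return self.failed_member is not None

    def criteria_tuple(self, order: Sequence[str] = DEFAULT_CRITERIA) -> tuple:
        vals = []
        for crit in order:
            sign = 1.0
            if crit.startswith("-"):
                sign, crit = -1.0, crit[1:]
            vals.append(sign * getattr(self, crit))
        return tuple(vals)


@dataclass
class CommunityRun:
    n_orderings: int
    seed: Optional[int]
    best: OrderingResult
    all_criteria: pd.DataFrame
    minimal_medium: dict[str, float]
    auxo_media: dict[str, dict[str, float]]


class CommunityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Minimal medium
# ---------------------------------------------------------------------------


def derive_minimal_medium(
    auxo_media: Mapping[str, Mapping[str, float]],
    carbon_source: str,
    exclude: Sequence[str] = (),
    default_uptake: float = 10.0,
) -> dict[str, float]:
    """Intersect the members' auxotrophic media, drop the configured
    organic/amino-acid ids, and add the designated carbon source."""
    if not auxo_media:
        raise CommunityError("need at least one member's auxotrophic medium")
    media = list(auxo_media.values())
    common = set(media[0])
    for m in media[1:]:
        common &= set(m)
    common -= set(exclude) - {carbon_source}
    if not common and carbon_source is None:
        raise CommunityError(
            "empty medium intersection after filtering; per-member media: "
            + "; ".join(f"{k}={sorted(v)}" for k, v in auxo_media.items())
        )
    medium = {
        mid: min(float(m.get(mid, default_uptake)) for m in media) for mid in common
    }
    if carbon_source is not None:
        medium.setdefault(carbon_source, default_uptake)
    return medium


# ---------------------------------------------------------------------------
# Single ordering
# ---------------------------------------------------------------------------


def run_ordering(
    models: Mapping[str, MetabolicModel],
    db: GapFillDatabase,
    order: Sequence[str],
    minimal_medium: Mapping[str, float],
    auxo_media: Mapping[str, Mapping[str, float]],
    config: WeightConfig = WeightConfig(),
    evidence: Optional[Mapping[tuple[str, str], float]] = None,
    permeable_ids: Optional[set[str]] = None,
) -> OrderingResult:
    """Gap fill the members along one ordering, accumulating the pool of
    secreted metabolites; the first member runs on its auxotrophic medium."""
    if sorted(order) != sorted(models):
        raise CommunityError("order must be a permutation of the model ids")
    evidence = evidence or {}
    permeable_ids = permeable_ids or set()

    pool: set[str] = set()
    pool_trajectory: list[set[str]] = []
    solutions: dict[str, GapFillSolution] = {}
    for i, mid in enumerate(order):
        model = models[mid]
        db_m = resolve_costs(db, mid, evidence, permeable_ids, pool, config)
        if i == 0:
            medium = dict(auxo_media[mid])
            extra, extra_costs = {}, {}
        else:
            medium = dict(minimal_medium)
            extra, extra_costs = pool_uptake_candidates(pool, config)
        sol = fast_gap_fill(
            model, db_m, medium, config,
            extra_candidates=extra, extra_costs=extra_costs,
        )
        if sol.status != "ok":
            return OrderingResult(
                order=tuple(order),
                solutions=solutions,
                pool_trajectory=pool_trajectory,
                total_added_reactions=0,
                first_member_dependence=0,
                total_permeable=0,
                biomass_sum=0.0,
                failed_member=mid,
            )
        secreted = secretion_lp(sol.model, config, permeable_ids=permeable_ids)
        sol.secreted = secreted
        sol.model = materialize_secretion(sol.model, secreted)
        solutions[mid] = sol
        pool |= secreted
        pool_trajectory.append(set(pool))

    first = solutions[order[0]]
    later_secreted: set[str] = set()
    for mid in order[1:]:
        later_secreted |= solutions[mid].secreted
    return OrderingResult(
        order=tuple(order),
        solutions=solutions,
        pool_trajectory=pool_trajectory,
        total_added_reactions=sum(s.n_added for s in solutions.values()),
        first_member_dependence=len(first.imported & later_secreted),
        total_permeable=sum(len(s.secreted) for s in solutions.values()),
        biomass_sum=float(sum(s.v_bio for s in solutions.values())),
    )


# ---------------------------------------------------------------------------
# Full run over random orderings
# ---------------------------------------------------------------------------


def _sample_orderings(
    ids: Sequence[str], n_orderings: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Distinct random permutations (all of them when n! ≤ n_orderings)."""
    n = len(ids)
    n_total = math.factorial(n)
    if n_total <= n_orderings:
        return [tuple(p) for p in permutations(sorted(ids))]
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[str, ...]] = []
    ids_sorted = sorted(ids)
    while len(out) < n_orderings:
        perm = tuple(ids_sorted[j] for j in rng.permutation(n))
        if perm not in seen:
            seen.add(perm)
            out.append(perm)
    return out


def run_commit(
    models: Mapping[str, MetabolicModel],
    db: GapFillDatabase,
    minimal_medium: Mapping[str, float],
    auxo_media: Mapping[str, Mapping[str, float]],
    config: WeightConfig = WeightConfig(),
    n_orderings: int = 100,
    seed: Optional[int] = None,
    evidence: Optional[Mapping[tuple[str, str], float]] = None,
    permeable_ids: Optional[set[str]] = None,
    criteria: Sequence[str] = DEFAULT_CRITERIA,
) -> CommunityRun:
    """Explore random member orderings and keep the lexicographic optimum.

    Fully reproducible for a fixed seed; failed orderings are recorded in
    the criteria table but excluded from optimum selection.
    """
    if n_orderings < 1:
        raise CommunityError("n_orderings must be >= 1")
    rng = np.random.default_rng(seed)
    orders = _sample_orderings(list(models), n_orderings, rng)

    results: list[OrderingResult] = []
    rows = []
    for k, order in enumerate(orders):
        res = run_ordering(
            models, db, order, minimal_medium, auxo_media, config,
            evidence=evidence, permeable_ids=permeable_ids,
        )
        results.append(res)
        rows.append(
            {
                "ordering": k,
                "order": ">".join(order),
                "failed": res.failed,
                "failed_member": res.failed_member or "",
                "total_added_reactions": res.total_added_reactions,
                "first_member_dependence": res.first_member_dependence,
                "total_permeable": res.total_permeable,
                "biomass_sum": res.biomass_sum,
            }
        )
    table = pd.DataFrame(rows)
    ok = [r for r in results if not r.failed]
    if not ok:
        raise CommunityError(
            "all orderings failed; failures: "
            + ", ".join(f"{r.order}: {r.failed_member}" for r in results)
        )
    best = min(ok, key=lambda r: (r.criteria_tuple(criteria), r.order))
    return CommunityRun(
        n_orderings=len(orders),
        seed=seed,
        best=best,
        all_criteria=table,
        minimal_medium=dict(minimal_medium),
        auxo_media={k: dict(v) for k, v in auxo_media.items()},
    )


def individual_baseline(
    models: Mapping[str, MetabolicModel],
    db: GapFillDatabase,
    minimal_medium: Mapping[str, float],
    config: WeightConfig = WeightConfig(),
    evidence: Optional[Mapping[tuple[str, str], float]] = None,
    permeable_ids: Optional[set[str]] = None,
) -> dict[str, GapFillSolution]:
    """Gap fill every member independently on the minimal medium: no
    community pool, no uptake discounts; same configuration otherwise."""
    evidence = evidence or {}
    permeable_ids = permeable_ids or set()
    out: dict[str, GapFillSolution] = {}
    for mid in sorted(models):
        db_m = resolve_costs(db, mid, evidence, permeable_ids, set(), config)
        out[mid] = fast_gap_fill(models[mid], db_m, dict(minimal_medium), config)
    return out
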