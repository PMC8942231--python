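"""Database preparation, cost resolution, the gap-filling LP (checked
against an exhaustive subset-enumeration oracle), and the secretion LP."""

import itertools

import numpy as np
import pandas as pd
import pytest

from commitgf.gapfill import (
    GapFillError,
    WeightConfig,
    fast_gap_fill,
    materialize_secretion,
    parse_equation,
    pool_uptake_candidates,
    prepare_database,
    resolve_costs,
    secretion_lp,
)
from commitgf.model_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_medium,
    fba,
)

CFG = WeightConfig()


# ---------------------------------------------------------------------------
# database preparation
# ---------------------------------------------------------------------------


def _db_frame(rows):
    return pd.DataFrame(rows, columns=["id", "equation", "balanced"])


def test_parse_equation_forms():
    stoich, rev = parse_equation("2 A@c + B@c = C@e")
    assert stoich == {("A", "c"): -2.0, ("B", "c"): -1.0, ("C", "e"): 1.0}
    assert rev
    stoich, rev = parse_equation("A@c --> B@c")
    assert not rev
    with pytest.raises(ValueError):
        parse_equation("A@c B@c")


@pytest.mark.parametrize(
    "row,dropped_as",
    [
        ({"id": "u", "equation": "A@c = B@c", "balanced": "F"}, "unbalanced"),
        ({"id": "b", "equation": "A@e = A@BOUNDARY", "balanced": "T"}, "boundary"),
        ({"id": "g", "equation": "A@MNXD1 = B@MNXD1", "balanced": "T"}, "generic_compartment"),
        ({"id": "c21", "equation": "21 A@c = B@c", "balanced": "T"}, "coefficient"),
    ],
)
def test_prepare_database_drop_rules(row, dropped_as):
    db = prepare_database(_db_frame([row]))
    assert db.reactions == {}
    assert db.drop_report[dropped_as] == 1


def test_prepare_database_coefficient_20_retained():
    db = prepare_database(_db_frame([{"id": "ok", "equation": "20 A@c = B@c",
                                      "balanced": "T"}]))
    assert "ok" in db.reactions


def test_prepare_database_proton_alias_normalized():
    db = prepare_database(
        _db_frame([{"id": "r", "equation": "A@c + MNXM01@c = B@c + MNXM1@c",
                    "balanced": "T"}])
    )
    stoich = db.reactions["r"].stoichiometry
    assert ("MNXM01", "c") not in stoich
    # -1 (alias) and +1 (canonical) cancel
    assert ("MNXM1", "c") not in stoich


def test_prepare_database_full_filter_table():
    """A 50-reaction table with one violation of each rule keeps exactly the
    intended reactions."""
    rows = [
        {"id": f"keep{i}", "equation": f"m{i}a@c = m{i}b@c", "balanced": "T"}
        for i in range(46)
    ]
    rows += [
        {"id": "bad_bal", "equation": "x@c = y@c", "balanced": "F"},
        {"id": "bad_bnd", "equation": "x@e = x@BOUNDARY", "balanced": "T"},
        {"id": "bad_gen", "equation": "x@MNXD1 = y@MNXD1", "balanced": "T"},
        {"id": "bad_coef", "equation": "21 x@c = y@c", "balanced": "T"},
    ]
    db = prepare_database(_db_frame(rows))
    assert sorted(db.reactions) == sorted(f"keep{i}" for i in range(46))
    assert db.drop_report == {
        "unbalanced": 1, "boundary": 1, "generic_compartment": 1,
        "coefficient": 1, "kept": 46,
    }


# ---------------------------------------------------------------------------
# cost resolution
# ---------------------------------------------------------------------------


def _small_db():
    return prepare_database(_db_frame([
        {"id": "TRP", "equation": "P@e = P@c", "balanced": "T"},      # permeable transport
        {"id": "TRX", "equation": "X@e = X@c", "balanced": "T"},      # plain transport
        {"id": "MET", "equation": "A@c = B@c", "balanced": "T"},      # metabolic
        {"id": "EXS", "equation": "S@e = ", "balanced": "T"},         # exchange, pool met
        {"id": "EXZ", "equation": "Z@e = ", "balanced": "T"},         # exchange
    ]))


def test_resolve_costs_categories():
    db = _small_db()
    out = resolve_costs(db, "m1", {("m1", "MET"): 1e-8},
                        permeable_ids={"P"}, secreted_pool={"S"}, config=CFG)
    assert out.costs["TRP"] == ("permeable_transport", 50.0)
    assert out.costs["TRX"] == ("transport", 100.0)
    assert out.costs["MET"] == ("sequence_evidence", 25.0)
    assert out.costs["EXS"] == ("uptake_secreted", 1.0)
    assert out.costs["EXZ"] == ("exchange", 1e5)


def test_resolve_costs_evalue_cutoff():
    db = _small_db()
    fail = resolve_costs(db, "m1", {("m1", "MET"): 1e-5}, set(), set(), CFG)
    assert fail.costs["MET"] == ("metabolic", 50.0)
    edge = resolve_costs(db, "m1", {("m1", "MET"): 1e-6}, set(), set(), CFG)
    assert edge.costs["MET"] == ("sequence_evidence", 25.0)


# ---------------------------------------------------------------------------
# gap-filling fixtures and exhaustive oracle
# ---------------------------------------------------------------------------


def _gap_model():
    """Chain with the internal step B->C missing: EX_A, T_A, A->B, C->bio."""
    m = MetabolicModel(id="gappy")
    for mid, comp in [("A", "e"), ("A", "c"), ("B", "c"), ("C", "c")]:
        m.add_metabolite(Metabolite(mid, comp))
    m.add_reaction(Reaction("EX_A", {("A", "e"): -1.0}, 0.0, DEFAULT_BOUND, kind="exchange"))
    m.add_reaction(Reaction("T_A", {("A", "e"): -1.0, ("A", "c"): 1.0}, 0.0, DEFAULT_BOUND,
                            kind="transport"))
    m.add_reaction(Reaction("R_AB", {("A", "c"): -1.0, ("B", "c"): 1.0}, 0.0, DEFAULT_BOUND))
    m.add_reaction(Reaction("BIO", {("C", "c"): -1.0}, 0.0, DEFAULT_BOUND, kind="biomass"))
    m.biomass_id = "BIO"
    return m


def _gap_db(extra_rows=()):
    rows = [
        {"id": "FIX_BC", "equation": "B@c --> C@c", "balanced": "T"},
        {"id": "BYP1", "equation": "B@c --> Q@c", "balanced": "T"},
        {"id": "BYP2", "equation": "Q@c --> C@c", "balanced": "T"},
    ]
    rows.extend(extra_rows)
    return prepare_database(_db_frame(rows))


def exhaustive_min_cost(model, db, medium, config):
    """Oracle: cheapest candidate subset whose addition restores growth,
    found by enumerating subsets in increasing cost order."""
    cand = sorted(db.reactions)
    subsets = []
    for r in range(len(cand) + 1):
        for sub in itertools.combinations(cand, r):
            subsets.append((sum(db.costs[c][1] for c in sub), sub))
    subsets.sort(key=lambda t: (t[0], t[1]))
    for cost, sub in subsets:
        probe, _ = apply_medium(model, medium)
        for rid in sub:
            if rid not in probe.reactions:
                probe.add_reaction(db.reactions[rid].copy(), create_missing=True)
        bid = probe.biomass_id
        cap = {bid: (0.0, min(probe.reactions[bid].upper_bound, config.biomass_ub))}
        res = fba(probe, extra_bounds=cap)
        if res.status == "optimal" and res.objective_value >= config.biomass_lb - 1e-9:
            return cost, set(sub)
    return None, None


def test_already_growing_model_adds_nothing(chain):
    db = resolve_costs(_gap_db(), "chain", {}, set(), set(), CFG)
    sol = fast_gap_fill(chain, db, {"A": 10.0}, CFG)
    assert sol.status == "ok"
    assert sol.added_reactions == {}
    assert sol.v_bio >= CFG.biomass_lb


def test_single_missing_reaction_restored_over_costlier_bypass():
    model = _gap_model()
    db = resolve_costs(_gap_db(), model.id, {}, set(), set(), CFG)
    sol = fast_gap_fill(model, db, {"A": 10.0}, CFG)
    assert sol.status == "ok"
    assert set(sol.added_reactions) == {"FIX_BC"}
    oracle_cost, oracle_set = exhaustive_min_cost(model, db, {"A": 10.0}, CFG)
    assert sol.total_cost == oracle_cost
    assert set(sol.added_reactions) == oracle_set


def test_pool_uptake_preferred_over_synthesis():
    """When B is importable from the community pool, uptake (cost 1) beats
    re-synthesis (cost 50)."""
    model = _gap_model()
    model.remove_reaction("R_AB")  # B unreachable internally
    db = _gap_db([{"id": "SYN_B", "equation": "A@c --> B@c", "balanced": "T"}])
    db = resolve_costs(db, model.id, {}, set(), {"B"}, CFG)
    extra, extra_costs = pool_uptake_candidates({"B"}, CFG)
    sol = fast_gap_fill(model, db, {"A": 10.0}, CFG,
                        extra_candidates=extra, extra_costs=extra_costs)
    assert sol.status == "ok"
    added = set(sol.added_reactions)
    assert "FIX_BC" in added
    assert {"EXpool_B", "TRpool_B"} <= added
    assert "SYN_B" not in added
    assert "B" in sol.imported


def test_gap_fill_matches_exhaustive_oracle_on_fixture_family():
    """Solution cost equals the exhaustive subset-enumeration minimum on
    fixtures with <= 12 candidates."""
    rng = np.random.default_rng(0)
    for k in range(6):
        model = _gap_model()
        decoys = [
            {"id": f"D{k}_{i}", "equation": f"d{k}{i}a@c --> d{k}{i}b@c", "balanced": "T"}
            for i in range(int(rng.integers(2, 9)))
        ]
        db = resolve_costs(_gap_db(decoys), model.id, {}, set(), set(), CFG)
        assert len(db.reactions) <= 12
        sol = fast_gap_fill(model, db, {"A": 10.0}, CFG)
        oracle_cost, _ = exhaustive_min_cost(model, db, {"A": 10.0}, CFG)
        assert sol.status == "ok"
        assert sol.total_cost == oracle_cost


def test_reversal_candidate_used_when_cheapest():
    """A wrong-direction model reaction is reversed (cost 25) instead of
    adding the 50-cost database fix."""
    model = _gap_model()
    model.remove_reaction("R_AB")
    # model carries B->A (wrong way); reversing it is the cheapest repair
    model.add_reaction(Reaction("R_BA", {("B", "c"): -1.0, ("A", "c"): 1.0},
                                0.0, DEFAULT_BOUND))
    db = _gap_db([{"id": "SYN_AB", "equation": "A@c --> B@c", "balanced": "T"}])
    db = resolve_costs(db, model.id, {}, set(), set(), CFG)
    sol = fast_gap_fill(model, db, {"A": 10.0}, CFG)
    assert sol.status == "ok"
    assert sol.reversed_reactions == {"R_BA"}
    assert "SYN_AB" not in sol.added_reactions
    assert sol.model.reactions["R_BA"].lower_bound < 0


def test_infeasible_names_blocked_precursors():
    model = _gap_model()
    db = resolve_costs(prepare_database(_db_frame(
        [{"id": "NOP", "equation": "x@c --> y@c", "balanced": "T"}]
    )), model.id, {}, set(), set(), CFG)
    sol = fast_gap_fill(model, db, {"A": 10.0}, CFG)
    assert sol.status == "infeasible"
    assert "C" in sol.blocked_precursors


def test_solution_is_locally_minimal():
    model = _gap_model()
    db = resolve_costs(_gap_db(), model.id, {}, set(), set(), CFG)
    sol = fast_gap_fill(model, db, {"A": 10.0}, CFG)
    for rid in sol.added_reactions:
        probe = sol.model.copy()
        probe.remove_reaction(rid)
        bid = probe.biomass_id
        cap = {bid: (0.0, min(probe.reactions[bid].upper_bound, CFG.biomass_ub))}
        res = fba(probe, extra_bounds=cap)
        assert res.status != "optimal" or res.objective_value < CFG.biomass_lb


def test_biomass_within_limits_on_gapfill_medium():
    model = _gap_model()
    db = resolve_costs(_gap_db(), model.id, {}, set(), set(), CFG)
    sol = fast_gap_fill(model, db, {"A": 10.0}, CFG)
    assert CFG.biomass_lb <= sol.v_bio <= CFG.biomass_ub + 1e-6


# ---------------------------------------------------------------------------
# secretion LP
# ---------------------------------------------------------------------------


def _secretor_model(bypass_yield=1.0):
    """Grows at uptake rate; can divert carbon into a permeable product P."""
    m = MetabolicModel(id="sec")
    for mid, comp in [("A", "e"), ("A", "c"), ("B", "c"), ("P", "c")]:
        m.add_metabolite(Metabolite(mid, comp))
    m.add_reaction(Reaction("EX_A", {("A", "e"): -1.0}, -10.0, DEFAULT_BOUND,
                            kind="exchange"))
    m.add_reaction(Reaction("T_A", {("A", "e"): -1.0, ("A", "c"): 1.0}, 0.0,
                            DEFAULT_BOUND, kind="transport"))
    m.add_reaction(Reaction("R_AB", {("A", "c"): -1.0, ("B", "c"): 1.0}, 0.0,
                            DEFAULT_BOUND))
    m.add_reaction(Reaction("R_AP", {("A", "c"): -1.0, ("P", "c"): float(bypass_yield)},
                            0.0, DEFAULT_BOUND))
    m.add_reaction(Reaction("BIO", {("B", "c"): -1.0}, 0.0, DEFAULT_BOUND,
                            kind="biomass"))
    m.biomass_id = "BIO"
    return m


def test_overflow_metabolite_reported():
    m = _secretor_model()
    secreted = secretion_lp(m, CFG, permeable_ids={"P"})
    assert "P" in secreted


def test_uptake_metabolites_excluded_from_report():
    m = _secretor_model()
    secreted = secretion_lp(m, CFG, permeable_ids={"P", "A"})
    assert "A" not in secreted  # EX_A has an open uptake


def test_secretion_respects_growth_budget():
    """Reported metabolites are each secretable at v_bio >= f * v_opt."""
    from commitgf.model_core import solve_lp

    m = _secretor_model()
    v_opt = min(fba(m).objective_value, CFG.biomass_ub)
    secreted = secretion_lp(m, CFG, permeable_ids={"P"})
    for mid in secreted:
        probe = m.copy()
        probe.add_reaction(Reaction("SNK", {(mid, "c"): -1.0}, 0.0, 1000.0, kind="sink"))
        res = solve_lp(probe, {"SNK": 1.0},
                       extra_bounds={"BIO": (CFG.secretion_factor * v_opt, CFG.biomass_ub)})
        assert res.status == "optimal"
        assert res.fluxes["SNK"] > CFG.flux_eps
        assert res.fluxes["BIO"] >= CFG.secretion_factor * v_opt - 1e-6


def test_f_equal_one_only_zero_cost_products():
    """With f = 1 nothing that competes with biomass for carbon is
    secretable; a by-product decoupled from growth still is."""
    m = _secretor_model()
    # by-product W produced alongside B at no extra cost, with an export path
    # so growth is possible without the temporary sinks
    m.add_metabolite(Metabolite("W", "c"))
    m.add_metabolite(Metabolite("W", "e"))
    m.remove_reaction("R_AB")
    m.add_reaction(Reaction("R_AB", {("A", "c"): -1.0, ("B", "c"): 1.0, ("W", "c"): 1.0},
                            0.0, DEFAULT_BOUND))
    m.add_reaction(Reaction("T_W", {("W", "c"): -1.0, ("W", "e"): 1.0}, 0.0,
                            DEFAULT_BOUND, kind="transport"))
    m.add_reaction(Reaction("EX_W", {("W", "e"): -1.0}, 0.0, DEFAULT_BOUND,
                            kind="exchange"))
    # uptake below the biomass cap: the optimum leaves no carbon slack
    m.reactions["EX_A"].lower_bound = -2.0
    cfg = WeightConfig(secretion_factor=1.0)
    secreted = secretion_lp(m, cfg, permeable_ids={"P", "W"})
    assert "W" in secreted   # free by-product
    assert "P" not in secreted  # costs carbon -> would cut biomass


def test_non_growing_model_raises():
    m = _secretor_model()
    closed, _ = apply_medium(m, {})
    with pytest.raises(GapFillError, match="grow"):
        secretion_lp(closed, CFG, permeable_ids={"P"})


def test_secretion_lp_in_objective_mode():
    m = _secretor_model()
    secreted = secretion_lp(m, CFG, permeable_ids={"P"}, mode="in_objective")
    assert "P" in secreted


# ---------------------------------------------------------------------------
# materialize_secretion
# ---------------------------------------------------------------------------


def test_materialize_empty_is_identity(chain):
    out = materialize_secretion(chain, set())
    assert sorted(out.reactions) == sorted(chain.reactions)


def test_materialize_adds_transport_and_exchange():
    m = _secretor_model()
    out = materialize_secretion(m, {"P"})
    assert len(out.reactions) == len(m.reactions) + 2
    assert ("P", "e") in out.metabolites
    assert out.reactions["TSEC_P"].kind == "transport"
    ex = out.reactions["EXSEC_P"]
    assert ex.kind == "exchange" and ex.lower_bound == 0.0  # secretion-only
    # idempotent
    again = materialize_secretion(out, {"P"})
    assert len(again.reactions) == len(out.reactions)
    assert not any(r.kind == "sink" for r in again.reactions.values())
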