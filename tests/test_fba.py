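import numpy as np
import pytest
from scipy.optimize import linprog

from strepflux import (
    MediumSpec,
    apply_medium,
    fba,
    fix_flux,
    fva,
    mass_balance_residual,
    pfba_fluxes,
)
from strepflux.model import build_stoich_matrix

from helpers import build_model, model_arrays, random_lp_model, vertex_enumeration_max


def test_chain_optimum_is_uptake_bound(chain):
    res = fba(chain, "BIO", "max")
    assert res.ok
    assert res.objective_value == pytest.approx(10.0)
    assert mass_balance_residual(chain, res.fluxes) <= 1e-6


def test_fixed_flux_beyond_capacity_is_infeasible(chain):
    clamped = chain.copy()
    clamped.set_bounds("BIO", 11.0, 11.0)
    res = fba(clamped, "BIO", "max")
    assert res.status == "infeasible"
    assert res.objective_value is None


def test_branched_yields_match_vertex_enumeration():
    """Two routes with different product yields: the LP must pick the
    enumeration optimum, not a local branch."""
    model = build_model(
        {
            "EX_A": {"stoich": {"A_e": -1}, "lb": -10, "ub": 0},
            "R_hi": {"stoich": {"A_e": -1, "P_c": 2}, "ub": 4},
            "R_lo": {"stoich": {"A_e": -1, "P_c": 1}},
            "SINK_P": {"stoich": {"P_c": -1}},
        }
    )
    S, lb, ub = model_arrays(model)
    c = np.array([0.0, 0.0, 0.0, 1.0])
    expected = vertex_enumeration_max(S, lb, ub, c)
    res = fba(model, "SINK_P", "max")
    assert res.ok
    assert res.objective_value == pytest.approx(expected, abs=1e-8)


@pytest.mark.parametrize("seed", range(10))
def test_random_models_match_vertex_enumeration(seed):
    rng = np.random.default_rng(1000 + seed)
    model, S, lb, ub = random_lp_model(rng)
    j = int(rng.integers(0, len(model.reactions)))
    c = np.zeros(len(model.reactions))
    c[j] = 1.0
    expected = vertex_enumeration_max(S, lb, ub, c)
    res = fba(model, model.reactions[j].id, "max")
    assert res.ok
    assert res.objective_value == pytest.approx(expected, abs=1e-7)
    assert mass_balance_residual(model, res.fluxes) <= 1e-6


def test_agrees_with_independent_cobra_solver(toy):
    """Dual-route check: our scipy-HiGHS optimum equals cobrapy+GLPK on
    the same model."""
    from strepflux.io import to_cobra

    model, _ = toy
    ours = fba(model, "BIOMASS", "max").objective_value
    cm = to_cobra(model)
    theirs = cm.optimize().objective_value
    assert ours == pytest.approx(theirs, rel=1e-6)


def test_pfba_prefers_short_route():
    """Two equivalent routes A→B, one direct and one via an extra step:
    parsimony sends all flux through the shorter one."""
    model = build_model(
        {
            "EX_A": {"stoich": {"A_e": -1}, "lb": -10, "ub": 0},
            "DIRECT": {"stoich": {"A_e": -1, "B_c": 1}},
            "LONG1": {"stoich": {"A_e": -1, "X_c": 1}},
            "LONG2": {"stoich": {"X_c": -1, "B_c": 1}},
            "BIO": {"stoich": {"B_c": -1}},
        },
        objective="BIO",
    )
    res = pfba_fluxes(model)
    assert res.ok
    assert res.objective_value == pytest.approx(10.0)
    assert res.fluxes["DIRECT"] == pytest.approx(10.0, abs=1e-6)
    assert res.fluxes["LONG1"] == pytest.approx(0.0, abs=1e-6)


def test_pfba_matches_fba_on_single_path(chain):
    plain = fba(chain)
    parsi = pfba_fluxes(chain)
    assert parsi.objective_value == pytest.approx(plain.objective_value)
    for rid, v in plain.fluxes.items():
        assert parsi.fluxes[rid] == pytest.approx(v, abs=1e-6)


def test_pfba_drives_futile_cycle_to_zero():
    """A thermodynamically meaningless 2-cycle can carry arbitrary flux
    at the FBA optimum; the L1 step must zero it."""
    model = build_model(
        {
            "EX_A": {"stoich": {"A_e": -1}, "lb": -5, "ub": 0},
            "R1": {"stoich": {"A_e": -1, "B_c": 1}},
            "CYC_F": {"stoich": {"B_c": -1, "C_c": 1}, "lb": -1000},
            "CYC_B": {"stoich": {"C_c": -1, "B_c": 1}, "lb": -1000},
            "BIO": {"stoich": {"B_c": -1}},
        },
        objective="BIO",
    )
    res = pfba_fluxes(model)
    assert res.objective_value == pytest.approx(5.0)
    assert abs(res.fluxes["CYC_F"]) <= 1e-6
    assert abs(res.fluxes["CYC_B"]) <= 1e-6


def test_fva_chain_ranges(chain):
    ranges = fva(chain, ["BIO"], fix_objective_fraction=0.0, objective_id="BIO")
    assert ranges["BIO"] == pytest.approx((0.0, 10.0))
    full = fva(chain, ["BIO"], fix_objective_fraction=1.0, objective_id="BIO")
    assert full["BIO"] == pytest.approx((10.0, 10.0))


def test_fva_dead_end_is_zero(chain):
    model = chain.copy()
    model.metabolites.append(type(model.metabolites[0])("dead_c"))
    model.reactions.append(
        type(model.reactions[0])("R_dead", {"A_e": -1, "dead_c": 1})
    )
    ranges = fva(model, ["R_dead"], objective_id="BIO")
    assert ranges["R_dead"] == pytest.approx((0.0, 0.0), abs=1e-9)


def test_fva_bounds_random_feasible_samples():
    """Any feasible flux lies inside its FVA interval (100 random
    feasible points from random objective directions)."""
    rng = np.random.default_rng(7)
    model, S, lb, ub = random_lp_model(rng)
    obj = model.reactions[0].id
    ranges = fva(model, objective_id=obj, fix_objective_fraction=0.0)
    n = len(model.reactions)
    # samples must satisfy the same objective >= 0 restriction FVA applies
    obj_row = np.zeros((1, n))
    obj_row[0, 0] = -1.0
    for _ in range(100):
        c = rng.normal(size=n)
        res = linprog(c, A_ub=obj_row, b_ub=[0.0], A_eq=S,
                      b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        assert res.status == 0
        for j, r in enumerate(model.reactions):
            lo, hi = ranges[r.id]
            assert lo - 1e-7 <= res.x[j] <= hi + 1e-7


def test_objective_invariant_under_reordering_and_reversible_split(toy):
    model, truth = toy
    base = fba(model, "BIOMASS").objective_value

    shuffled = model.copy()
    shuffled.reactions = shuffled.reactions[::-1]
    assert fba(shuffled, "BIOMASS").objective_value == pytest.approx(base)

    # split the reversible carbon exchange into two irreversible halves
    split = model.copy()
    ex = split.reaction("EX_carbon")
    fwd_ub, rev_cap = ex.upper_bound, -ex.lower_bound
    ex.lower_bound = 0.0
    rev = type(ex)(
        "EX_carbon_rev",
        {m: -c for m, c in ex.stoichiometry.items()},
        lower_bound=0.0,
        upper_bound=rev_cap,
    )
    split.reactions.append(rev)
    assert fba(split, "BIOMASS").objective_value == pytest.approx(base)


def test_strong_duality_on_small_instance(chain):
    """Primal optimum equals the dual objective reconstructed from the
    solver's marginals (equality + bound multipliers)."""
    S, lb, ub = model_arrays(chain)
    c = np.zeros(len(chain.reactions))
    c[[r.id for r in chain.reactions].index("BIO")] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    dual = (
        res.eqlin.marginals @ np.zeros(S.shape[0])
        + res.lower.marginals @ lb
        + res.upper.marginals @ ub
    )
    assert res.fun == pytest.approx(dual, abs=1e-8)


def test_apply_medium_sets_uptake_bounds(toy):
    model, _ = toy
    out = apply_medium(model, MediumSpec({"EX_carbon": 5.0}))
    assert out.reaction("EX_carbon").lower_bound == -5.0
    # unlisted exchanges: uptake blocked, secretion untouched
    assert out.reaction("EX_product").lower_bound == 0.0
    assert out.reaction("EX_product").upper_bound == 1000.0
    # original untouched
    assert model.reaction("EX_carbon").lower_bound == -10.0


def test_apply_medium_unknown_exchange(toy):
    model, _ = toy
    with pytest.raises(KeyError, match="EX_bogus"):
        apply_medium(model, MediumSpec({"EX_bogus": 1.0}))


def test_fix_flux(chain):
    fixed = fix_flux(chain, "BIO", 0.012)
    r = fixed.reaction("BIO")
    assert (r.lower_bound, r.upper_bound) == (0.012, 0.012)
    blocked = fix_flux(chain, "BIO", 0.0)
    assert fba(blocked, "BIO").objective_value == pytest.approx(0.0)
    with pytest.raises(ValueError):
        fix_flux(chain, "BIO", 2000.0)
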