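import numpy as np
import pandas as pd
import pytest

from strepflux import (
    ExpressionProfile,
    ImatError,
    SimulationConstraints,
    census_active,
    census_summary,
    classify_reactions,
    compute_thresholds,
    imat,
    pfba_fluxes,
)
from strepflux.expression import HIGH, LOW, MODERATE

from helpers import (
    brute_force_imat_score,
    build_model,
    chain_model,
    random_imat_instance,
)


def _profile(values, tp="T1"):
    genes = [f"g{i}" for i in range(len(values))]
    return ExpressionProfile(pd.DataFrame({tp: values}, index=genes))


# -- quartile thresholds -----------------------------------------------------

@pytest.mark.parametrize(
    "values, q1, q3",
    [
        ([0, 10, 20, 30, 40], 10.0, 30.0),
        (list(range(1, 9)), 2.75, 6.25),  # linear-interpolation quantiles
        ([7.0] * 6, 7.0, 7.0),
    ],
)
def test_quartiles(values, q1, q3):
    profile = _profile(values)
    assert compute_thresholds(profile, "T1") == pytest.approx((q1, q3))


def test_quartiles_need_at_least_four_genes():
    with pytest.raises(ValueError, match="4 genes"):
        compute_thresholds(_profile([1, 2, 3]), "T1")


# -- reaction classification -------------------------------------------------

@pytest.fixture
def classify_case():
    model = build_model(
        {
            "R_or": {"stoich": {"A_c": -1, "B_c": 1}, "gpr": "g_hi or g_lo"},
            "R_and": {"stoich": {"B_c": -1, "C_c": 1}, "gpr": "g_hi and g_lo"},
            "R_none": {"stoich": {"C_c": -1, "D_c": 1}},
            "R_missing": {"stoich": {"D_c": -1, "A_c": 1}, "gpr": "g_hi and g_gone"},
        }
    )
    profile = ExpressionProfile(
        pd.DataFrame({"T1": [100.0, 1.0, 10.0, 12.0]},
                     index=["g_hi", "g_lo", "x1", "x2"])
    )
    return model, profile


def test_classification_rules(classify_case):
    model, profile = classify_case
    classes = classify_reactions(model, profile, (5.0, 50.0), "T1")
    assert classes["R_or"] == HIGH       # best paralog 100 > Q3
    assert classes["R_and"] == LOW       # scarcest subunit 1 < Q1
    assert classes["R_none"] == MODERATE  # empty GPR
    assert classes["R_missing"] == MODERATE  # unmeasured AND member


def test_classification_rejects_inverted_thresholds(classify_case):
    model, profile = classify_case
    with pytest.raises(ValueError):
        classify_reactions(model, profile, (50.0, 5.0), "T1")


def test_profile_rejects_negative_rpkm(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text("gene_id\tT1\ng1\t-3\ng2\t1\n")
    with pytest.raises(ValueError):
        ExpressionProfile.from_tsv(str(path))


def test_profile_tsv_round_trip(tmp_path):
    profile = _profile([1.0, 5.0, 9.0, 13.0])
    path = tmp_path / "expr.tsv"
    profile.to_tsv(str(path))
    again = ExpressionProfile.from_tsv(str(path))
    pd.testing.assert_frame_equal(again.data, profile.data, check_names=False)


# -- iMAT --------------------------------------------------------------------

def test_all_high_feasible_chain_fully_active():
    model = chain_model(uptake=10.0)
    classes = {r.id: HIGH for r in model.reactions}
    result = imat(model, classes, epsilon=0.001)
    assert result.ok
    assert result.consistency_score == len(model.reactions)
    assert all(result.active.values())


def test_conflicting_calls_resolved_to_best_pattern():
    """A LOW call in the middle of an otherwise HIGH chain: satisfying it
    would silence the whole path, so the optimum sacrifices exactly it."""
    model = chain_model(uptake=10.0)
    classes = {"EX_A": HIGH, "R1": LOW, "BIO": HIGH}
    result = imat(model, classes, epsilon=0.001)
    assert result.consistency_score == 2
    assert result.active["R1"]


@pytest.mark.parametrize("seed", range(8))
def test_score_matches_brute_force_on_random_tiny_models(seed):
    rng = np.random.default_rng(4000 + seed)
    model, classes = random_imat_instance(rng)
    eps = 0.01
    result = imat(model, classes, epsilon=eps)
    expected = brute_force_imat_score(model, classes, {}, eps)
    assert result.consistency_score == expected


def test_raising_epsilon_never_improves_score():
    rng = np.random.default_rng(99)
    model, classes = random_imat_instance(rng)
    scores = [imat(model, classes, epsilon=e).consistency_score
              for e in (0.001, 0.1, 1.0, 5.0)]
    assert all(b <= a for a, b in zip(scores, scores[1:]))


def test_infeasible_fixed_rates_name_the_clamp(toy):
    model, truth = toy
    constraints = SimulationConstraints(growth_rate_fix=truth.max_mu * 3)
    with pytest.raises(ImatError, match="growth"):
        imat(model, {r.id: MODERATE for r in model.reactions}, constraints)


def test_all_moderate_reduces_to_feasibility_with_pfba_census(toy):
    """With no expression calls iMAT only finds *a* feasible state; its
    census under clamped rates matches a parsimonious FBA census."""
    model, truth = toy
    mu = 0.5 * truth.max_mu
    constraints = SimulationConstraints(
        growth_rate_fix=mu,
        product_rate_fix=0.5 * truth.max_qp,
        product_reaction_id=truth.product_id,
    )
    classes = {r.id: MODERATE for r in model.reactions}
    result = imat(model, classes, constraints)
    assert result.consistency_score == 0

    from strepflux.expression import _apply_constraints

    clamped = _apply_constraints(model, constraints)
    parsi = pfba_fluxes(clamped, truth.biomass_id)
    c_imat = census_active(result, model)
    c_pfba = census_active(
        type(result)(status="optimal", consistency_score=0, fluxes=parsi.fluxes),
        model,
    )
    assert c_imat.n_active == c_pfba.n_active


# -- census ------------------------------------------------------------------

def test_census_counts_and_subsystems(toy):
    model, _ = toy
    fluxes = {r.id: 0.0 for r in model.reactions}
    fluxes["R_core_1"] = 0.5
    fluxes["T_carbon"] = 1e-9  # below threshold: not flux-carrying
    from strepflux import ImatResult

    result = ImatResult(status="optimal", consistency_score=0, fluxes=fluxes)
    census = census_active(result, model, zero_threshold=1e-6)
    assert census.n_active == 1
    assert census.per_subsystem == {"Central metabolism": 1}


def test_census_all_zero(toy):
    model, _ = toy
    from strepflux import ImatResult

    result = ImatResult(
        status="optimal", consistency_score=0,
        fluxes={r.id: 0.0 for r in model.reactions},
    )
    assert census_active(result, model).n_active == 0


def test_census_summary_mean_and_sd():
    counts = [350, 475, 380, 363]
    mean, sd = census_summary(counts)
    arr = np.array(counts, dtype=float)
    assert mean == pytest.approx(arr.mean())
    assert sd == pytest.approx(
        np.sqrt(((arr - arr.mean()) ** 2).sum() / (len(arr) - 1))
    )
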