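import numpy as np
import pytest

from strepflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyModelSpec,
    ValidationError,
    build_stoich_matrix,
    generate_toy_model,
    model_stats,
    read_model,
    validate,
    write_model,
)
from strepflux.gpr import parse_gpr
from strepflux.model import detect_exchanges, flag_gap_fills

from helpers import build_model


def test_empty_model_rejected():
    with pytest.raises(ValidationError, match="empty model"):
        validate(MetabolicModel(name="x"))


def test_dangling_reference_rejected():
    model = MetabolicModel(
        name="x",
        metabolites=[Metabolite("A_c")],
        reactions=[Reaction("r", {"A_c": -1, "ghost_c": 1})],
    )
    with pytest.raises(ValidationError, match="ghost_c"):
        validate(model)


def test_duplicate_ids_rejected():
    model = MetabolicModel(
        name="x",
        metabolites=[Metabolite("A_c")],
        reactions=[Reaction("r", {"A_c": -1}), Reaction("r", {"A_c": 1})],
    )
    with pytest.raises(ValidationError, match="duplicate"):
        validate(model)


def test_stoich_matrix_chain():
    """∅↔A, A→B, B→∅ gives 2×3 columns (+1,0), (−1,+1), (0,−1)."""
    model = build_model(
        {
            "EX_A": {"stoich": {"A_c": 1}, "lb": -10},
            "R1": {"stoich": {"A_c": -1, "B_c": 1}},
            "SINK_B": {"stoich": {"B_c": -1}},
        }
    )
    sm = build_stoich_matrix(model)
    assert sm.shape == (2, 3)
    dense = sm.matrix.toarray()
    ia, ib = sm.metabolite_index["A_c"], sm.metabolite_index["B_c"]
    assert dense[ia].tolist() == [1, -1, 0]
    assert dense[ib].tolist() == [0, 1, -1]


def test_stoich_matrix_keeps_isolated_metabolite_row():
    model = build_model({"R1": {"stoich": {"A_c": -1, "B_c": 1}}})
    model.metabolites.append(Metabolite("lonely_c"))
    sm = build_stoich_matrix(model)
    assert sm.shape == (3, 1)
    assert sm.matrix.toarray()[sm.metabolite_index["lonely_c"]].tolist() == [0.0]


def test_matrix_columns_reconstruct_stoichiometry(toy):
    model, _ = toy
    sm = build_stoich_matrix(model)
    for r in model.reactions:
        assert sm.column(r.id) == r.stoichiometry


def test_model_stats_counts():
    model = build_model(
        {
            "EX_A": {"stoich": {"A_e": -1}, "lb": -10},
            "R1": {"stoich": {"A_e": -1, "B_c": 1}, "gpr": "g1 and g2"},
            "R2": {"stoich": {"B_c": -1, "C_c": 1}},
        }
    )
    stats = model_stats(model)
    assert stats == {
        "n_genes": 2,
        "n_reactions": 3,
        "n_gene_associated": 1,
        "n_non_gene_associated": 2,
        "n_exchange": 1,
        "n_metabolites": 3,
    }


def test_gap_fill_flag_derivation():
    model = build_model(
        {
            "EX_A": {"stoich": {"A_e": -1}, "lb": -10},
            "R_orphan": {"stoich": {"A_e": -1, "B_c": 1}},
            "R_known": {"stoich": {"B_c": -1, "C_c": 1}, "gpr": "g1"},
        }
    )
    flags = {r.id: r.is_gap_fill for r in model.reactions}
    assert flags == {"EX_A": False, "R_orphan": True, "R_known": False}


def test_stats_stable_under_reordering(toy):
    model, _ = toy
    stats = model_stats(model)
    shuffled = model.copy()
    shuffled.reactions = shuffled.reactions[::-1]
    shuffled.metabolites = shuffled.metabolites[::-1]
    detect_exchanges(shuffled)
    flag_gap_fills(shuffled)
    assert model_stats(shuffled) == stats


@pytest.mark.parametrize("fmt, suffix", [("sbml", "m.xml"), ("tsv", "m_dir")])
def test_round_trip(tmp_path, toy, fmt, suffix):
    """write → read → write → read preserves stoichiometry, bounds and
    GPR gene sets for both on-disk dialects."""
    model, _ = toy
    p1 = str(tmp_path / suffix)
    write_model(model, p1, fmt)
    once = read_model(p1, fmt)
    p2 = str(tmp_path / ("again_" + suffix))
    write_model(once, p2, fmt)
    twice = read_model(p2, fmt)

    for other in (once, twice):
        assert sorted(other.reaction_ids) == sorted(model.reaction_ids)
        assert sorted(other.metabolite_ids) == sorted(model.metabolite_ids)
        for r in model.reactions:
            r2 = other.reaction(r.id)
            assert r2.stoichiometry == pytest.approx(r.stoichiometry)
            assert r2.lower_bound == pytest.approx(r.lower_bound)
            assert r2.upper_bound == pytest.approx(r.upper_bound)
            assert r2.genes == r.genes
            assert r2.is_exchange == r.is_exchange
    assert once.objective_reaction_id == model.objective_reaction_id


def test_read_tsv_toy(tmp_path):
    """A hand-written 3-reaction TSV (exchange, conversion, sink) loads
    into 3 reactions over 2 metabolites."""
    path = tmp_path / "reactions.tsv"
    path.write_text(
        "id\tname\tequation\tlower_bound\tupper_bound\tgpr\tsubsystem\tobjective\n"
        "EX_A\t\tA_e <->\t-10\t1000\t\t\t\n"
        "R1\t\tA_e --> B_c\t0\t1000\tg1\t\t\n"
        "BIO\tbiomass\tB_c -->\t0\t1000\t\t\t1\n"
    )
    model = read_model(str(path))
    assert len(model.reactions) == 3
    assert len(model.metabolites) == 2
    assert model.objective_reaction_id == "BIO"
    assert model.reaction("EX_A").lower_bound == -10
    assert model.reaction("EX_A").is_exchange
    assert model.reaction("R1").genes == {"g1"}
    assert model.metabolite("A_e").compartment == "e"


def test_sbml_dialect_readable_by_reference_reader(tmp_path, toy):
    """Written SBML is valid L3-fbc: the independent cobrapy reader
    recovers the same reaction count, bounds and gene associations."""
    import cobra.io

    model, _ = toy
    path = str(tmp_path / "toy.xml")
    write_model(model, path, "sbml")
    cm = cobra.io.read_sbml_model(path)
    assert len(cm.reactions) == len(model.reactions)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        assert cr.lower_bound == pytest.approx(r.lower_bound)
        assert {g.id for g in cr.genes} == set(r.genes)
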