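"""Synthetic models and expression tables with known ground truth.

The generated toy network mirrors, at miniature scale, the structure the
real analyses depend on: a single carbon source, a linear core, a
biomass branch, and an antibiotic branch assembled from several
precursors — one of them (the ethylmalonyl-CoA analog) produced by a
single-gene, capacity-limited supply reaction.  That planted supply step
is the in-silico analog of crotonyl-CoA carboxylase/reductase feeding a
polyketide pathway: it is the reaction an enforced-objective scan must
recover.  Decoy reactions carry complex (AND) and paralog (OR) GPRs, a
gene-less (gap-fill-style) transporter and exchange reactions, so every
target-filter rule is exercised.

All optima are available in closed form from the construction, making
the toys usable as independent oracles for the LP machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expression import ExpressionProfile, compute_thresholds
from .gpr import parse_gpr
from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    detect_exchanges,
    flag_gap_fills,
    validate,
)

PLANTED_SUPPLY_ID = "R_ccr"
BIOMASS_ID = "BIOMASS"
PRODUCT_ID = "R_product"
CARBON_EXCHANGE_ID = "EX_carbon"
PRODUCT_EXCHANGE_ID = "EX_product"


@dataclass
class ToyModelSpec:
    """Parameters of the generated toy network.

    ``biomass_yield`` is in gDW per mmol carbon, so the maximum growth
    rate is uptake × yield.  ``supply_capacity`` caps the planted
    precursor-supply reaction and, when binding, sets the maximum
    product rate.  ``product_precursors`` lists (metabolite id,
    stoichiometry) pairs consumed per unit product; the *last* entry is
    the planted, capacity-limited one.
    """

    n_core_reactions: int = 3
    uptake_capacity: float = 10.0
    biomass_yield: float = 0.1
    supply_capacity: float = 0.5
    product_precursors: tuple[tuple[str, float], ...] = (
        ("mal_c", 1.0),
        ("mmal_c", 1.0),
        ("emal_c", 1.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uptake_capacity <= 0 or self.biomass_yield <= 0:
            raise ValueError("uptake capacity and biomass yield must be > 0")
        if self.supply_capacity <= 0:
            raise ValueError("planted supply capacity must be > 0")
        if self.n_core_reactions < 1 or not self.product_precursors:
            raise ValueError("need >= 1 core reaction and >= 1 precursor")

    @classmethod
    def random(cls, seed: int) -> "ToyModelSpec":
        """Draw realistic toy parameters reproducibly from a seed."""
        rng = np.random.default_rng(seed)
        uptake = float(rng.uniform(5.0, 15.0))
        yld = float(rng.uniform(0.05, 0.2))
        precursors = (("mal_c", 1.0), ("mmal_c", 1.0), ("emal_c", 1.0))
        sigma = sum(s for _, s in precursors)
        s_planted = precursors[-1][1]
        # keep the planted cap strictly binding vs. carbon availability
        cap = float(rng.uniform(0.1, 0.8) * s_planted * uptake / sigma)
        return cls(
            n_core_reactions=int(rng.integers(2, 5)),
            uptake_capacity=uptake,
            biomass_yield=yld,
            supply_capacity=cap,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Closed-form optima and planted structure of a generated toy."""

    max_mu: float
    max_qp: float
    biomass_id: str
    product_id: str
    carbon_exchange_id: str
    planted_supply_reaction: str
    expected_filtered_targets: frozenset[str]
    expected_exclusions: dict[str, str]
    growth_pathway_reactions: frozenset[str]
    product_pathway_reactions: frozenset[str]
    growth_pathway_genes: frozenset[str]
    product_pathway_genes: frozenset[str]


def generate_toy_model(spec: ToyModelSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Build the toy network and its analytic ground truth.

    Carbon flows EX_carbon → core chain → a branch metabolite consumed
    either by the biomass branch (drain at 1/yield) or converted to the
    precursor pool feeding product assembly.  The planted supply step
    caps the product rate at ``supply_capacity / s_planted`` (chosen
    below the carbon-limited ceiling), so max μ = uptake × yield and
    max q_p = supply_capacity / s_planted.
    """
    sigma = sum(s for _, s in spec.product_precursors)
    s_planted = spec.product_precursors[-1][1]
    qp_supply = spec.supply_capacity / s_planted
    qp_carbon = spec.uptake_capacity / sigma
    max_qp = min(qp_supply, qp_carbon)
    max_mu = spec.uptake_capacity * spec.biomass_yield

    mets = [Metabolite("carbon_e", compartment="e"), Metabolite("carbon_c")]
    rxns: list[Reaction] = [
        Reaction(
            CARBON_EXCHANGE_ID,
            {"carbon_e": -1.0},
            lower_bound=-spec.uptake_capacity,
            upper_bound=1000.0,
            subsystem="Exchange",
        ),
        Reaction(
            "T_carbon",
            {"carbon_e": -1.0, "carbon_c": 1.0},
            gpr=parse_gpr("g_transport"),
            subsystem="Transport",
        ),
    ]
    # linear core chain carbon_c -> x1 -> ... -> prec_a_c
    prev = "carbon_c"
    for i in range(1, spec.n_core_reactions + 1):
        nxt = "prec_a_c" if i == spec.n_core_reactions else f"core_{i}_c"
        if nxt != "prec_a_c":
            mets.append(Metabolite(nxt))
        rxns.append(
            Reaction(
                f"R_core_{i}",
                {prev: -1.0, nxt: 1.0},
                gpr=parse_gpr(f"g_core_{i}"),
                subsystem="Central metabolism",
            )
        )
        prev = nxt
    mets += [Metabolite("prec_a_c"), Metabolite("bio_prec_c"), Metabolite("prec_b_c")]

    # biomass branch: precursor activation then the biomass drain
    rxns.append(
        Reaction(
            "R_bio_aux",
            {"prec_a_c": -1.0, "bio_prec_c": 1.0},
            gpr=parse_gpr("g_bio"),
            subsystem="Biomass precursors",
        )
    )
    # biomass drains two precursor pools in measured proportions; total
    # carbon cost per unit growth is 1/yield
    rxns.append(
        Reaction(
            BIOMASS_ID,
            {
                "bio_prec_c": -0.5 / spec.biomass_yield,
                "prec_a_c": -0.5 / spec.biomass_yield,
            },
            name="biomass assembly",
            subsystem="Biomass",
        )
    )
    # product side: shared-precursor activation (complex-encoded decoy)
    rxns.append(
        Reaction(
            "R_ab",
            {"prec_a_c": -1.0, "prec_b_c": 1.0},
            gpr=parse_gpr("g_ab1 and g_ab2"),
            subsystem="Precursor supply",
        )
    )
    # one supply reaction per product precursor; the last is the planted,
    # capacity-limited single-gene step, the middle ones are decoys
    supply_ids: list[str] = []
    product_genes: set[str] = {"g_ab1", "g_ab2", "g_prod", "g_export"}
    for k, (met_id, _) in enumerate(spec.product_precursors):
        mets.append(Metabolite(met_id))
        last = k == len(spec.product_precursors) - 1
        if last:
            rid, rule, ub = PLANTED_SUPPLY_ID, "g_ccr", spec.supply_capacity
        elif k == 0:
            rid, rule, ub = f"R_sup_{k}", f"g_sup_{k}", 1000.0
        else:
            rid, rule, ub = f"R_sup_{k}", f"g_sup_{k}a or g_sup_{k}b", 1000.0
        rxns.append(
            Reaction(
                rid,
                {"prec_b_c": -1.0, met_id: 1.0},
                upper_bound=ub,
                gpr=parse_gpr(rule),
                subsystem="Precursor supply",
            )
        )
        supply_ids.append(rid)
        product_genes |= parse_gpr(rule).genes
    mets += [Metabolite("product_c"), Metabolite("product_e", compartment="e")]
    rxns.append(
        Reaction(
            PRODUCT_ID,
            {**{m: -s for m, s in spec.product_precursors}, "product_c": 1.0},
            name="antibiotic assembly",
            gpr=parse_gpr("g_prod"),
            subsystem="Antibiotic biosynthesis",
        )
    )
    # gene-less export step (gap-fill-style decoy) and the product exchange
    rxns.append(
        Reaction(
            "T_product",
            {"product_c": -1.0, "product_e": 1.0},
            subsystem="Transport",
        )
    )
    rxns.append(
        Reaction(
            PRODUCT_EXCHANGE_ID,
            {"product_e": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Exchange",
        )
    )

    model = MetabolicModel(
        name=f"toy_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=BIOMASS_ID,
    )
    detect_exchanges(model)
    flag_gap_fills(model)
    validate(model)

    growth_rxns = frozenset(
        [CARBON_EXCHANGE_ID, "T_carbon", "R_bio_aux", BIOMASS_ID]
        + [f"R_core_{i}" for i in range(1, spec.n_core_reactions + 1)]
    )
    product_rxns = frozenset(
        ["R_ab", PRODUCT_ID, "T_product", PRODUCT_EXCHANGE_ID] + supply_ids
    )
    growth_genes = frozenset(
        ["g_transport", "g_bio"] + [f"g_core_{i}" for i in range(1, spec.n_core_reactions + 1)]
    )
    truth = GroundTruth(
        max_mu=max_mu,
        max_qp=max_qp,
        biomass_id=BIOMASS_ID,
        product_id=PRODUCT_ID,
        carbon_exchange_id=CARBON_EXCHANGE_ID,
        planted_supply_reaction=PLANTED_SUPPLY_ID,
        expected_filtered_targets=frozenset(
            [PLANTED_SUPPLY_ID, "R_sup_0", PRODUCT_ID]
        ),
        expected_exclusions={
            "R_ab": "multi_gene",
            "T_product": "gap_fill",
            PRODUCT_EXCHANGE_ID: "exchange",
            **{
                rid: "multi_gene"
                for rid in supply_ids[1:-1]
            },
        },
        growth_pathway_reactions=growth_rxns,
        product_pathway_reactions=product_rxns,
        growth_pathway_genes=growth_genes,
        product_pathway_genes=frozenset(product_genes | {"g_ccr"}),
    )
    return model, truth


def shared_precursor_toy(uptake: float = 10.0) -> tuple[MetabolicModel, float]:
    """A minimal network where biomass and product draw the same
    precursor 1:1, so the Pareto front is the line μ + q_p = uptake.
    Returns (model, uptake)."""
    mets = [Metabolite("s_e", compartment="e"), Metabolite("s_c")]
    rxns = [
        Reaction("EX_S", {"s_e": -1.0}, lower_bound=-uptake, upper_bound=1000.0),
        Reaction("T_S", {"s_e": -1.0, "s_c": 1.0}),
        Reaction(BIOMASS_ID, {"s_c": -1.0}, name="biomass assembly"),
        Reaction(PRODUCT_ID, {"s_c": -1.0}, name="product assembly"),
    ]
    model = MetabolicModel(
        name="shared_precursor_toy",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=BIOMASS_ID,
    )
    detect_exchanges(model)
    flag_gap_fills(model)
    return validate(model), uptake


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

#: log-normal medians (RPKM) of the three expression components; 10 matches
#: the conventional detection baseline for expressed genes
HIGH_MEDIAN = 200.0
BACKGROUND_MEDIAN = 10.0
LOW_MEDIAN = 0.5
#: default log-scale noise; gives well-separated components (~5% overlap
#: between adjacent components at the quartile boundaries)
DEFAULT_NOISE_SD = 0.4

ActiveSets = Union[set, frozenset, dict]


def generate_expression(
    model: MetabolicModel,
    active_gene_set: ActiveSets,
    timepoints: Sequence[str] = ("T1", "T2", "T3", "T4"),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    low_gene_set: Optional[ActiveSets] = None,
    n_background: Optional[int] = None,
) -> ExpressionProfile:
    """Synthesize an RPKM table with a planted quartile structure.

    Active genes draw from a high log-normal component (median 200,
    above the table's empirical Q3 with high probability), planted-low
    genes from a low component (median 0.5), and background filler genes
    from a moderate component (median 10) that anchors the quartiles
    between the planted components.  ``active_gene_set`` (and optionally
    ``low_gene_set``) may be a single set applied to every time point or
    a mapping time point -> set.  Deterministic per seed.
    """

    def per_tp(sets: Optional[ActiveSets], tp: str, default: frozenset) -> frozenset:
        if sets is None:
            return default
        if isinstance(sets, dict):
            return frozenset(sets.get(tp, ()))
        return frozenset(sets)

    model_genes = model.genes
    for tp in timepoints:
        extra = per_tp(active_gene_set, tp, frozenset()) - model_genes
        if extra:
            raise ValueError(f"active genes not in model at {tp}: {sorted(extra)}")

    if n_background is None:
        n_background = max(30, 3 * len(model_genes))
    background = [f"bg_{i:04d}" for i in range(n_background)]
    genes = sorted(model_genes) + background
    rng = np.random.default_rng(seed)
    data = {}
    for tp in timepoints:
        active = per_tp(active_gene_set, tp, frozenset())
        low = per_tp(low_gene_set, tp, model_genes - active)
        medians = np.array(
            [
                HIGH_MEDIAN
                if g in active
                else (LOW_MEDIAN if g in low else BACKGROUND_MEDIAN)
                for g in genes
            ]
        )
        noise = rng.normal(0.0, noise_sd, size=len(genes))
        data[tp] = medians * np.exp(noise)
    return ExpressionProfile(data=pd.DataFrame(data, index=pd.Index(genes, name="gene_id")))


def gene_class_recovery(
    profile: ExpressionProfile,
    timepoint: str,
    active_genes: frozenset,
    low_genes: frozenset,
) -> float:
    """Fraction of planted genes whose quartile classification matches
    the plant: active genes above Q3, low genes below Q1."""
    q1, q3 = compute_thresholds(profile, timepoint)
    levels = profile.values_at(timepoint)
    total = correct = 0
    for g in active_genes:
        total += 1
        correct += levels[g] > q3
    for g in low_genes:
        total += 1
        correct += levels[g] < q1
    return correct / total if total else float("nan")
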