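"""Growth-medium simulations and growth-rate validation.

Two experiment designs are covered:

* defined **minimal media** — salt exchanges opened wide (uptake 10
  mmol·gDW⁻¹·h⁻¹, non-limiting) plus a single carbon source at its
  measured uptake rate; the model's predicted growth rate μ is the FBA
  optimum of the biomass reaction, compared against measured rates with
  a Pearson correlation;
* a **complex medium** rich in amino acids (yeast-extract-like) — all
  twenty proteinogenic amino-acid exchanges opened at a small common
  uptake, the growth rate clamped to its measured value, and the
  specific production rate q_p of a secondary metabolite predicted as
  the FBA maximum of its synthesis/secretion reaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .fba import FBAError, MediumSpec, apply_medium, fba, fix_flux
from .model import MetabolicModel

#: non-limiting uptake used for salts in minimal media (mmol·gDW⁻¹·h⁻¹)
SALT_UPTAKE = 10.0
#: common per-amino-acid uptake in the complex medium (mmol·gDW⁻¹·h⁻¹)
DEFAULT_AA_UPTAKE = 0.015


@dataclass
class SimulationConstraints:
    """Experimentally fixed rates applied before an optimization."""

    medium: Optional[MediumSpec] = None
    growth_rate_fix: Optional[float] = None  # μ, h⁻¹
    product_rate_fix: Optional[float] = None  # q_p, mmol·gDW⁻¹·h⁻¹
    product_reaction_id: Optional[str] = None

    def __post_init__(self) -> None:
        for v, label in ((self.growth_rate_fix, "growth_rate_fix"),
                         (self.product_rate_fix, "product_rate_fix")):
            if v is not None and v < 0:
                raise ValueError(f"{label} must be non-negative, got {v}")


@dataclass
class GrowthPrediction:
    mu: float
    status: str

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


@dataclass
class GrowthComparison:
    predicted: list[float]
    observed: list[float]
    pearson_r: float
    p_value: float


def build_minimal_medium(
    model: MetabolicModel,
    carbon_exchange_id: str,
    carbon_uptake: float,
    salt_exchange_ids: Sequence[str] = (),
    salt_uptake: float = SALT_UPTAKE,
) -> MediumSpec:
    """Minimal medium: named salts at a non-limiting uptake, one carbon
    source at its measured uptake, everything else closed.  Salt ids not
    present in the model are skipped with a warning (id conventions vary
    between reconstructions)."""
    exch = {r.id for r in model.exchange_reactions}
    components = {}
    for sid in salt_exchange_ids:
        if sid in exch:
            components[sid] = salt_uptake
        else:
            warnings.warn(f"salt exchange {sid!r} not in model; skipped")
    if carbon_exchange_id not in exch:
        raise KeyError(f"carbon source exchange {carbon_exchange_id!r} not in model")
    components[carbon_exchange_id] = carbon_uptake
    return MediumSpec(components=components, closed_default=True)


def simulate_minimal_medium(model: MetabolicModel, medium: MediumSpec) -> GrowthPrediction:
    """Predicted μ = FBA optimum of the biomass reaction on the medium.
    An infeasible medium yields μ = 0 flagged infeasible."""
    constrained = apply_medium(model, medium)
    result = fba(constrained, model.objective_reaction_id, "max")
    if not result.ok:
        return GrowthPrediction(mu=0.0, status=result.status)
    return GrowthPrediction(mu=result.objective_value, status="optimal")


def simulate_complex_medium(
    model: MetabolicModel,
    product_reaction_id: str,
    growth_rate: float,
    aa_exchange_ids: Sequence[str],
    aa_uptake: float = DEFAULT_AA_UPTAKE,
    extra_medium: Optional[MediumSpec] = None,
    closed_default: bool = True,
) -> float:
    """Predicted q_p on an amino-acid-rich medium with growth clamped.

    Every listed amino-acid exchange is opened at ``aa_uptake``;
    ``extra_medium`` components (salts, a carbon source) are merged in.
    With ``closed_default`` every other exchange has its uptake blocked;
    pass False to keep the model's own exchange bounds as the base
    medium.  The biomass flux is fixed to ``growth_rate`` and the
    product reaction maximized.  Raises :class:`FBAError` if the clamped
    growth rate is infeasible on the medium.
    """
    components = {rid: aa_uptake for rid in aa_exchange_ids}
    if extra_medium is not None:
        components.update(extra_medium.components)
    constrained = apply_medium(
        model, MediumSpec(components=components, closed_default=closed_default)
    )
    constrained = fix_flux(constrained, model.objective_reaction_id, growth_rate)
    result = fba(constrained, product_reaction_id, "max")
    if not result.ok:
        raise FBAError(
            f"growth rate {growth_rate} is {result.status} under the complex medium"
        )
    return result.objective_value


def compare_growth(
    predictions: Sequence[float], observations: Sequence[float]
) -> GrowthComparison:
    """Pearson product-moment correlation (two-sided p) between predicted
    and observed growth rates across media."""
    if len(predictions) != len(observations):
        raise ValueError("prediction and observation vectors differ in length")
    if len(predictions) < 3:
        raise ValueError("need at least 3 paired media for a correlation")
    import numpy as np

    if np.std(predictions) == 0 or np.std(observations) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(predictions, observations)
    return GrowthComparison(
        predicted=list(predictions),
        observed=list(observations),
        pearson_r=float(r),
        p_value=float(p),
    )
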